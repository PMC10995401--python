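# asymperm

Free-energy analysis of peptide translocation across **asymmetric lipid
membranes**: umbrella-sampling unbiasing (WHAM), assembly of subprocess
free-energy profiles into full translocation paths, directional
translocation barriers and permeability models, and leaflet tensions from
lateral pressure profiles.

## Who this is for

Researchers running coarse-grained or atomistic free-energy calculations of
peptide (or lipid) permeation through bilayers whose two leaflets differ in
composition or lipid number. For such membranes the crossing is no longer
direction-symmetric: the peptide adsorbs with different strength on the two
leaflets, and the barrier it must climb depends on which leaflet it inserts
from. This package provides the post-simulation analysis chain for that
situation, together with a synthetic-data module that generates biased
sampling on analytic landscapes with known ground truth, so every stage is
testable without molecular dynamics.

## The model

The collective variable is the oriented distance ξ between a peptide
terminus' center of mass and the *local* membrane center of mass (lipid
beads within a 2.0 nm cylinder around the terminus). Umbrella windows
restrain ξ with harmonic springs `U_i(ξ) = (k_i/2)(ξ − ξ_i)²`, laid out in
tiers: 0.1 nm spacing with 1000 kJ mol⁻¹ nm⁻² springs near the membrane
surface and transmembrane state, 0.05 nm with 5000 kJ mol⁻¹ nm⁻² near the
center, 3000 kJ mol⁻¹ nm⁻² in between. The window histograms are combined
by the self-consistent WHAM equations

```
p(ξ) = Σᵢ Hᵢ(ξ) / Σᵢ Nᵢ exp[(fᵢ − Uᵢ(ξ))/kT],
exp(−fᵢ/kT) = Σ_ξ p(ξ) exp[−Uᵢ(ξ)/kT],
```

giving `G(ξ) = −kT ln p(ξ)` (kT = 2.577 kJ/mol at 310 K), anchored to the
solvent plateau. Subprocess profiles (adsorption/insertion × terminus ×
leaflet) are joined into full directional paths by least-squares constant
offsets over their overlaps — free-energy constants are pure gauge.

The **translocation barrier** ΔΔG_B of a directional crossing is the
largest climb from a preceding local minimum to a later maximum along the
travel direction; relative permeability is `P ∝ exp(−ΔΔG_B/kT)`. The
classical serial-resistance model `1/P_AB = 1/P_A + 1/P_B` predicts the
asymmetric membrane from the two pure ones but is blind to direction; the
corrected estimator

```
ΔΔG_B ≈ (max G_pure,entry + max G_pure,exit)/2 − G_adsorbed(pure entry)
```

restores the direction dependence through the insertion-side adsorbed
state. Leaflet tensions come from stress profiles via
`P_L = −(σxx+σyy)/2`, `P_N = −σzz`, `γ± = ∫ (P_N − P_L) dz` over each
half-space about the tail-density midplane (1 bar·nm = 0.1 mN/m).

## Worked example

```python
import numpy as np
from asymperm.demo import demo_landscapes
from asymperm.landscapes import landscape_profile
from asymperm.transport import model_comparison

upper, lower, asym = demo_landscapes(switch_width=0.1)
pa = landscape_profile(asym)
table = model_comparison({("N", "upper"): pa, ("C", "lower"): pa},
                         landscape_profile(upper), landscape_profile(lower))
print(table[["entry_side", "true_barrier", "serial_barrier",
             "estimator_barrier"]].round(2).to_string(index=False))
```

prints

```
entry_side  true_barrier  serial_barrier  estimator_barrier
     upper         148.1           166.0              138.0
     lower         178.1           166.0              168.0
```

The two pure membranes have barriers 166 (shallow adsorption, high center)
and 140 kJ/mol (deep adsorption, low center). The true directional barriers
of the blended asymmetric membrane differ by 30 kJ/mol — exactly the
difference in adsorbed-state depths — while the serial-resistance value
(166.0 kJ/mol) cannot distinguish the directions and misses the
lower-entry barrier by 12 kJ/mol. The corrected estimator tracks the
direction dependence (its residual 10 kJ/mol offset here comes from the
blended maximum sitting below the pure-maxima average for this landscape
pair).

The same chain is available from a shell:

```bash
asymperm demo --seed 7 --out-dir demo_out
asymperm barriers --profile demo_out/asym.dat --out barriers.json
asymperm tension --stress demo_out/stress.dat --density demo_out/density.dat --out t.json
```

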