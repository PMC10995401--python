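# Methods

This note documents the models, numerical choices and limitations behind
`asymperm`. Units throughout: free energies in kJ/mol, lengths in nm,
stresses in bar, tensions in mN/m, kT = 0.0083145 × 310 ≈ 2.577 kJ/mol
(all thermodynamics is evaluated at 310 K; barrier-to-permeability ratios
are therefore convention-dependent and we state the convention as
per-molecule kT at 310 K with proportionality constant 1).

## Synthetic translocation landscapes

Pure-membrane landscapes are a solvent plateau plus truncated-Gaussian
features: a central barrier, two adsorption wells at ±z_w, and optional
headgroup barriers. Each bump is `exp(−d²/2σ²) − exp(−c²/2σ²)` clipped at
zero beyond its cutoff c, so the landscape is continuous and *exactly*
equal to the plateau outside the solvent boundary. Because neighbouring
bumps overlap, the three amplitudes are solved from a 3×3 linear system so
the landscape passes exactly through its control points (G at the center,
wells, and headgroups). This functional form was an open design choice (a
real study only yields tabulated curves); Gaussians were chosen because
they are smooth, closed-form differentiable (the Langevin sampler needs
dG/dz), and their parameters map one-to-one onto the features a
practitioner reads off a translocation profile.

Asymmetric-membrane landscapes are the sigmoidal blend
`G = w·G_lower + (1−w)·G_upper` with `w(z) = 1/(1+exp((z−z_c)/λ))`. The
switch width λ directly controls the width of the intermediate region
between the two leaflet-mimicking regions; λ defaults to 0.25 nm, a value
that puts the transition well inside the membrane core while leaving the
adsorption wells essentially untouched. The blend is a pointwise convex
combination, so the asymmetric landscape is always bracketed by its
parents.

The default demo membrane pair emulates a cationic peptide on a
PE-like/PG-like bilayer: upper leaflet with shallow adsorption
(−10 kJ/mol) and a high center (156), lower leaflet with deep adsorption
(−40) and a lower center (100), giving pure-membrane barriers of 166 and
140 kJ/mol and an adsorbed-depth difference of 30 kJ/mol — the regime in
which the serial-resistance permeability model fails.

## Umbrella windows and the biased sampler

`make_window_scheme` reproduces the tiered layouts used for insertion
sampling: 0.05 nm spacing with 5000 kJ mol⁻¹ nm⁻² springs in a center
band, 0.1 nm with 1000 kJ mol⁻¹ nm⁻² in the surface band (given in |z| and
mirrored), and 3000 kJ mol⁻¹ nm⁻² in between. Within each band the spacing
is exact; one shorter transitional gap may occur at a band boundary, and a
window sitting exactly on a boundary takes the center tier. Band edges are
exposed as parameters rather than hard-coded per-membrane layouts, since
real window counts vary with membrane thickness.

The per-window sampler targets the biased Boltzmann density
`∝ exp(−[G(z) + (k/2)(z−z₀)²]/kT)`. Two schemes are provided:

* **random-walk Metropolis** (default): proposal standard deviation
  2.4·√(kT/k), the optimal-scaling choice for one-dimensional random-walk
  Metropolis; acceptance sits near 40–50% and the integrated
  autocorrelation time is ≈4 steps at every force-constant tier. It is
  unconditionally stable, which matters at the 5000 kJ mol⁻¹ nm⁻² tier.
* **overdamped Langevin** (Euler–Maruyama): provided for users who want
  genuine dynamics; a stability check refuses steps with
  D·dt·k_total/kT > 1 and suggests a dt. Note the O(dt) discretization
  bias in the stationary variance (≈ 1/(1 − c/2) inflation with
  c = D·dt·k_eff/kT); choose dt so c ≲ 0.1 if moments matter.

Only the stationary distribution is contractual — both schemes are tested
against direct Boltzmann quadrature, including a bimodal window at a
barrier top. `sample_scheme` advances all windows of a scheme as one
batched Metropolis chain (windows never interact, so this is exact) with a
single seed; every stochastic operation takes an explicit seed and no
global random state is used. The first 10% of each chain is discarded as
equilibration by default.

## WHAM

`solve_wham` iterates the standard self-consistent equations on shared
0.02 nm bins (at most half the finest window spacing) until the maximum
change of any window constant f_i is below 1e-6 kJ/mol (gauge fixed by
f_0 = 0), typically 3–5·10⁴ iterations for a 190 kJ/mol-range profile with
~80 windows; the iteration is two matrix-vector products per step and runs
in seconds. Bins never visited stay NaN. A disconnected histogram-overlap
graph raises an error listing the components, and an overlap matrix
(pairwise sum of minima of normalized histograms) is available as a
spacing diagnostic — at the standard tiers the thinnest adjacent overlaps
are a few percent at tier boundaries, which is still far from
disconnection.

The profile zero is the mean over a declared solvent-plateau region. The
automatic default uses the top 10% of the *window-covered* range, not of
the sampled range: bins beyond the outermost window hold only a few
heavily re-weighted stray samples and make an unreliable anchor.

Errors come from a moving-block bootstrap within each window (block length
≈ 2× the integrated autocorrelation time, capped at n/10), re-solving WHAM
per replicate, re-anchoring each replicate to the same reference region,
and taking the pointwise standard deviation. The error method is a
documented stand-in — the error estimator used for the original profiles
is not specified anywhere we could follow — and it fails loudly if more
than 20% of replicates do not converge.

As an independent cross-check (in the test suite only), a
maximum-likelihood WHAM minimizes the convex negative log-likelihood with
L-BFGS and an analytic, log-sum-exp-stabilized gradient. The two routes
agree to ≲0.003 kJ/mol on the acceptance problem; the tested bound is
0.05 kJ/mol.

## Profile assembly

Subprocess profiles each carry an arbitrary constant. `align_segments`
finds the least-squares constant offset over a declared overlap interval
(closed form: the mean difference); a constant is the *only* admissible
transform because free-energy constants are pure gauge. The in-house
alignment procedure used for the original joined profiles is not public;
least squares over overlaps is our documented choice, not a reproduction.

`join_translocation` maps the four segments of a directional path (entry
adsorption, entry insertion, mirrored exit insertion, mirrored exit
adsorption) onto one path coordinate (entry solvent at positive values),
chain-aligns them over 0.3 nm overlap windows centered in each pairwise
support intersection (the adsorbed-minimum and transmembrane
neighbourhoods; configurable), and merges them with linear cross-fade
weights that ramp to zero at each segment end — exactly-aligned segments
merge exactly (the reassembly identity holds to <1e-9 kJ/mol) and noisy
ones merge continuously. The result is zero-referenced at the entry
solvent plateau (outermost 0.5 nm). For symmetric membranes, segments
present for one side stand in for both and the join is invariant under
entry-side swap. States are annotated on the joined path: solvent (1),
adsorbed minimum (2a), transmembrane (4a, the stationary point nearest the
center); the terminus-inserted state (3a) is marked schematically at the
2a–4a midpoint since it is not a free-energy feature. Interpolation is
monotone cubic (PCHIP) on G to avoid overshoot at sharp barriers, linear
on error bands.

`classify_regions` sweeps inward from each solvent end and keeps the
maximal contiguous run where the asymmetric profile stays within a
threshold (default 5 kJ/mol, matching the stated calculation-error bound
of the profiles this analysis targets) of the corresponding pure profile;
the remainder is the intermediate region. If the two sweeps overlap (e.g.
the asymmetric profile equals one pure profile everywhere) there is no
intermediate region and the upper sweep keeps its full extent — the split
is otherwise arbitrary and this convention keeps the degenerate case
predictable. On blended landscapes the intermediate width grows strictly
monotonically with the blend width λ.

## Barriers and permeability models

`directional_barrier` computes max over the path of (G − running minimum)
along the travel direction, which equals the brute-force maximum over all
ordered (minimum, maximum) pairs (property-tested against the double
loop). Monotone-descending profiles get barrier 0 with a flag rather than
an error. The adsorbed minimum used by the corrected estimator is the
deepest local minimum on the entry side; an explicit coordinate overrides
the search (needed e.g. for idealized profiles without a literal local
minimum). This simplification of the "within 1.5 nm of the headgroups"
idea was adopted because synthetic profiles need not have a headgroup
maximum to anchor the search; the 1.5 nm window still applies when an
explicit coordinate is given.

The solubility-diffusion integral `P = [∫ exp(G/kT) dz]⁻¹` with unit
diffusivity is the exact oracle: it is additive in resistance over
adjoining intervals, so it satisfies the serial identity exactly when the
two halves are genuinely independent, and exposes the failure when
adsorbed-state depths differ. Permeabilities are relative throughout —
absolute permeabilities would require diffusivity profiles that are out of
scope.

## Leaflet tensions

`pressures_from_stress` applies `P_L = −(σxx+σyy)/2`, `P_N = −σzz`
pointwise. The midplane is the density-weighted mean of the lipid-tail
density by default; a peak-midpoint convention (midpoint of the two
outermost tail-density peaks) is available behind a flag — the estimator
behind published midplanes is unspecified, so both are labelled choices.
Tensions are trapezoidal integrals of (P_N − P_L) over each half-space; a
grid point is interpolated exactly at the midplane so the split is exact
and γ+ + γ− is invariant to the midplane choice to machine precision
(~1e-16 mN/m in practice). Unit chain: bar and nm in, mN/m out via
1 bar·nm = 0.1 mN/m, asserted in a unit test. The synthetic stress
generator places Gaussian lobes in (P_N − P_L) whose half-space integrals
have closed forms (error functions), recorded as metadata — the oracle for
the quadrature; with lobes at ±1.0 nm and σ = 0.3 nm the cross-talk
between half-spaces is below 0.1%.

## Problem sizes and statistical behaviour

The WHAM acceptance run uses 81 windows × 64 000 Metropolis steps (10%
equilibration discard, ≈4.7M production samples, under a minute on one
CPU). The dominant error mode is not per-bin noise but a smooth
end-to-end tilt: each window adds an O(kT·√(2τ/n)) error to its
free-energy constant and these accumulate as a random walk across ~80
windows. At this problem size the gauge-aligned RMSD against the analytic
truth is 0.2–0.5 kJ/mol over seeds (bound tested: 1.0), measured over bins
with ≥10 samples. Halving the autocorrelation time via the 2.4σ proposal
scaling halves this tilt at fixed cost.

## What the synthetic data does and does not show

The generator reproduces the *structure* of translocation free-energy data
— plateau/wells/barriers, leaflet asymmetry as a smooth blend, tiered
window schemes, Boltzmann-distributed window samples, stress profiles with
prescribed leaflet tensions — with known ground truth. It does not emulate
peptide conformational dynamics, window-to-window correlated
configurations, membrane undulations feeding the collective variable,
anharmonic bias responses, or slow orthogonal degrees of freedom that
cause real hysteresis. Passing tests therefore validate the *analysis
chain* (unbiasing, alignment, barrier and tension extraction), not the
adequacy of any particular simulation protocol; the microsecond-scale
barriers of real coarse-grained membranes (presented in the literature at
the 129–196 kJ/mol scale) are not reproducible at desk scale and are not
targets of the synthetic runs.

## Other conventions and degenerate inputs

* Leaflet number asymmetry is 100·|N_up − N_low|/(N_up + N_low), reported
  both unrounded and rounded (144/106 → 15.2 → 15%) — the only formula
  consistent with the quoted worked example.
* Net peptide charge: +1 per Lys/Arg, −1 per Asp/Glu, +1 for a charged
  N-terminus, −1 for a free C-terminus (0 when amidated). Histidine is
  neutral: the sequences this tool targets contain none, and a fixed
  convention beats a pKa model the data cannot support.
* The collective-variable cylinder test applies the minimum image in x/y
  only; z (the membrane normal) is non-periodic. The cylinder is centered
  on the probe group's instantaneous xy center of mass at every
  evaluation.
* Unbiased windows (k = 0) are allowed and reduce WHAM to
  −kT·ln(histogram) up to a constant, a tested identity.
* Config files are YAML; all tabulated data are whitespace-column text
  with `#`/`@` comment headers, written at full double precision (%.17g)
  so read/write round-trips are exact.

## Known limitations

* No replica exchange between windows, no 2-D WHAM, no MBAR production
  path (a maximum-likelihood solver exists only as a test oracle).
* The bootstrap error band assumes block resampling captures the chain's
  dependence structure; for strongly multimodal windows the blocks would
  need to span barrier-crossing times.
* `classify_regions` assumes all three profiles are referenced to their
  own solvent plateaus; inconsistent referencing shifts regions silently.
* The corrected barrier estimator presumes the asymmetric maximum is near
  the pure-maxima average; for very wide blend switches (λ ≳ 0.5 nm with
  strongly unequal pure maxima) the blended maximum can deviate by a few
  kJ/mol, as quantified in the acceptance report.
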