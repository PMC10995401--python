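"""Physical constants and unit conversions used across the package."""

#: Gas constant in kJ/(mol K).
KJ_PER_MOL_PER_K = 0.0083145

#: Thermal energy kT at 310 K in kJ/mol (the temperature of the simulations
#: this analysis chain targets).
KT_310K = KJ_PER_MOL_PER_K * 310.0  # ~2.577 kJ/mol

#: 1 bar * nm expressed in mN/m (1 bar = 1e5 N/m^2; 1e5 N/m^2 * 1e-9 m
#: = 1e-4 N/m = 0.1 mN/m).
BAR_NM_TO_MN_PER_M = 0.1
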