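"""Unit conversion constants.

Internal hemodynamic computations run in CGS (cm, g, s); pressures are
reported in mmHg at the interfaces.  All conversion factors are defined
here once.
"""

# 1 Pa = 10 dyn/cm^2 (barye)
PA_TO_CGS = 10.0
CGS_TO_PA = 0.1

# 1 mmHg = 133.322 Pa = 1333.22 dyn/cm^2
MMHG_TO_PA = 133.322
PA_TO_MMHG = 1.0 / MMHG_TO_PA
MMHG_TO_CGS = MMHG_TO_PA * PA_TO_CGS
CGS_TO_MMHG = 1.0 / MMHG_TO_CGS

# Physical constants
FARADAY = 96485.33212  # C/mol
R_GAS = 8.314462618    # J/(mol K)
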