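"""Single source of truth for pipeline default parameters.

Every threshold used by more than one module (library, CLI, config schema)
is defined here so that ``--help`` text, config validation and the library
can never disagree.
"""

#: Differential-expression gates (gene level).
FDR_MAX = 0.1
FOLD_MIN = 1.5

#: Small-RNA count handling.
MIN_COUNT = 25
CPM_SCALE = 1e6
LOG_PSEUDOCOUNT = 1.0
MIRNA_P_MAX = 0.05

#: Monte Carlo hub test.
N_ITERATIONS = 10_000
HUB_P_MAX = 0.05

#: Promoter extraction and PWM scanning.
UPSTREAM = 1000
DOWNSTREAM = 500
PWM_P_MAX = 5e-6
PWM_PSEUDOCOUNT = 0.25
SCORE_BIN_WIDTH = 0.01
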