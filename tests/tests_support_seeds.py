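"""Fixed master seeds for the reproduction tests (single source of truth).

The frame cache in conftest keys on (scenario, reps, seed), so tests that
share a seed constant also share the underlying simulations.
"""

SEED_P = 1001
SEED_NM50 = 1002
SEED_NM5 = 1003
SEED_NEOLITHIC = 1004
SEED_LADDER_NM25 = 1006
SEED_PODS = 1051
SEED_KS = 1061
SEED_FIG5 = 1070
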