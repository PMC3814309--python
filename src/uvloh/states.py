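"""Shared per-SNP zygosity state codes."""

HET = 0
HOM_P1 = 1
HOM_P2 = 2
NOCALL = 3

STATE_NAMES = {HET: "HET", HOM_P1: "HOM_P1", HOM_P2: "HOM_P2", NOCALL: "NOCALL"}
STATE_CODES = {name: code for code, name in STATE_NAMES.items()}
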