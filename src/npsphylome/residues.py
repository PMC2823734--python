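"""Canonical amino-acid alphabet shared by the generator and the scanner."""

AMINO = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO)}
N_AA = len(AMINO)
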