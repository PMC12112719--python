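"""Shared scaffold constants.

The design scaffold is human ubiquitin (UniProt P0CG48, residues 1-76).
All sequence operations work on the standard 20-letter amino-acid alphabet.
"""

AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)

#: Human ubiquitin wild type, residues 1-76 of UniProt P0CG48.
UBIQUITIN_WT: str = (
    "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQL"
    "EDGRTLSDYNIQKESTLHLVLRLRGG"
)

assert len(UBIQUITIN_WT) == 76
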