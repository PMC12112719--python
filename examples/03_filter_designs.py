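"""Filter generated designs by identity, length and model confidence.

The design windows are those of the funnel: 75-90% identity to the
ubiquitin wild type, 72-84 residues, and no residue with pLDDT < 50.
"""

from ubdesign.constants import UBIQUITIN_WT
from ubdesign.fixtures import FixtureConfig, make_plddt_tracks
from ubdesign.seq_filters import filter_generated, plddt_filter

# hand-made candidates: the wild type itself, a truncation, and a variant
# with 10 scattered substitutions
variant = list(UBIQUITIN_WT)
for pos in (5, 15, 25, 33, 41, 47, 55, 63, 68, 71):
    variant[pos] = "W" if variant[pos] != "W" else "Y"
candidates = [
    ("wild_type", UBIQUITIN_WT),
    ("truncated", UBIQUITIN_WT[:70]),
    ("variant_10sub", "".join(variant)),
]

kept, report = filter_generated(candidates)
print(report.to_string(index=False))
print(f"kept: {[k for k, _ in kept]}")
print("The wild type fails (identity 1.00 > 0.90), the truncation fails the")
print("length window, the 10-substitution variant (identity 0.868) passes.\n")

models, planted_fails = make_plddt_tracks(FixtureConfig(seed=7))
survivors, mean_plddt = plddt_filter(models)
print(f"confidence filter: kept {len(survivors)}/{len(models)} models "
      f"(mean pLDDT {mean_plddt:.1f}); the {len(planted_fails)} discarded "
      "models each have a region below pLDDT 50.")
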