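"""Triage a docking deck: interface filter, diversity clustering, funnel.

Uses a synthetic two-mini-protein deck whose greedy ground truth is known
by construction.
"""

from ubdesign.fixtures import FixtureConfig, make_pose_deck
from ubdesign.pose_triage import (
    InterfacePatch,
    TriageConfig,
    funnel_select,
    greedy_diverse_top,
    interface_filter,
    mean_top_k,
)

deck, truth = make_pose_deck(FixtureConfig(seed=5, pose_deck_size=100))
cfg = TriageConfig()

rec_patch = InterfacePatch("receptor", frozenset(range(5, 16)))
lig_patch = InterfacePatch("ligand", frozenset(range(1, 13)))
in_contact = interface_filter(deck, rec_patch, lig_patch, cfg)
print(f"interface filter: {len(in_contact)}/{len(deck)} poses keep the two "
      "patches within 10 A")

kept = greedy_diverse_top(in_contact, cfg)
print(f"greedy clustering: {len(kept)} mutually diverse poses "
      f"(pairwise L-RMSD > {cfg.diversity_rmsd} A), best first")
print(f"best pose: {kept[0].pose_id}  score {kept[0].score:.2f}")

score = mean_top_k([p.score for p in kept], cfg.docking_top_k)
print(f"mean top-{cfg.docking_top_k} binding energy: {score:.2f}")

candidates = {"cand_A": score, "cand_B": score + 3.0, "cand_C": score - 1.0}
survivors = funnel_select(candidates)
print(f"funnel over three candidates: kept {survivors} — candidates whose")
print("mean energy is above the across-candidate average are discarded.")
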