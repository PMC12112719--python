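"""Docking-pose triage: interface filtering, diversity clustering and the
cross-candidate energy funnel.

The funnel keeps docking poses that (i) bring the two predicted interface
patches within contact distance, then (ii) greedily selects up to 50
low-energy, mutually diverse poses (pairwise L-RMSD > 2 Å), and finally
(iii) discards candidates whose mean top-k binding energy is worse (higher)
than the average over all candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .struct_geom import Pose, StructureModel, ligand_rmsd


@dataclass(frozen=True)
class InterfacePatch:
    """Predicted interacting residues of one partner (1-based author
    indices, any chain)."""

    role: str  # "receptor" | "ligand"
    residues: frozenset[int]

    def __post_init__(self) -> None:
        if self.role not in ("receptor", "ligand"):
            raise ValueError("role must be 'receptor' or 'ligand'")
        if not self.residues:
            raise ValueError("patch is empty")


@dataclass(frozen=True)
class TriageConfig:
    contact_cutoff: float = 10.0     # Å, patch-patch Cα contact
    diversity_rmsd: float = 2.0      # Å, minimum pairwise L-RMSD kept
    max_kept_poses: int = 50
    docking_top_k: int = 50          # poses averaged at the docking stage
    refine_top_k: int = 10           # poses averaged at the refinement stage
    exclusion_patch: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if min(self.contact_cutoff, self.diversity_rmsd) <= 0:
            raise ValueError("cutoffs must be positive")
        if min(self.max_kept_poses, self.docking_top_k, self.refine_top_k) < 1:
            raise ValueError("counts must be positive")


def _patch_coords(model: StructureModel, residues: frozenset[int]) -> np.ndarray:
    by_index = {r.index: r for r in model.residues}
    missing = residues - by_index.keys()
    if missing:
        raise ValueError(f"patch residues absent from structure: {sorted(missing)}")
    return np.array([by_index[i].ca for i in sorted(residues)])


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return float(d.min())


def interface_filter(
    poses: Sequence[Pose],
    receptor_patch: InterfacePatch,
    ligand_patch: InterfacePatch,
    cfg: TriageConfig | None = None,
) -> list[Pose]:
    """Keep poses whose interface patches are within the contact cutoff.

    A pose survives iff the minimum Cα-Cα distance between the receptor
    patch and the ligand patch is <= cutoff (a distance of exactly the
    cutoff is kept).  With an exclusion patch configured (e.g. a receptor
    dimerization area), poses whose ligand has *any* Cα within the cutoff
    of the exclusion patch are additionally discarded.
    """
    cfg = cfg or TriageConfig()
    kept = []
    for pose in poses:
        rp = _patch_coords(pose.receptor, receptor_patch.residues)
        lp = _patch_coords(pose.ligand, ligand_patch.residues)
        if _min_dist(rp, lp) > cfg.contact_cutoff:
            continue
        if cfg.exclusion_patch is not None:
            xp = _patch_coords(pose.receptor, cfg.exclusion_patch)
            lig_all = pose.ligand.coords("CA")
            if _min_dist(xp, lig_all) <= cfg.contact_cutoff:
                continue
        kept.append(pose)
    return kept


def greedy_diverse_top(
    poses: Sequence[Pose], cfg: TriageConfig | None = None
) -> list[Pose]:
    """Greedy energy/diversity clustering.

    Poses are visited in ascending score order (ties broken by pose id); a
    pose is kept iff its L-RMSD to *every* already-kept pose is strictly
    greater than the diversity threshold, stopping once ``max_kept_poses``
    poses are kept.  The returned list is score-ordered and always contains
    the best-scoring pose.
    """
    cfg = cfg or TriageConfig()
    ordered = sorted(poses, key=lambda p: (p.score, p.pose_id))
    kept: list[Pose] = []
    for pose in ordered:
        if len(kept) >= cfg.max_kept_poses:
            break
        if all(ligand_rmsd(pose, k) > cfg.diversity_rmsd for k in kept):
            kept.append(pose)
    return kept


def mean_top_k(scores: Sequence[float], k: int) -> float:
    """Mean of the k lowest (best) binding energies; plain mean if fewer."""
    if len(scores) == 0:
        raise ValueError("no scores supplied")
    if k < 1:
        raise ValueError("k must be positive")
    ordered = sorted(float(s) for s in scores)
    return float(np.mean(ordered[:k]))


def funnel_select(candidate_scores: Mapping[str, float]) -> list[str]:
    """Discard candidates with a mean binding energy above the across-
    candidate average; scores exactly at the mean survive.

    At least one candidate (the argmin) always survives.  Output preserves
    input order.
    """
    if not candidate_scores:
        raise ValueError("no candidates supplied")
    mu = float(np.mean(list(candidate_scores.values())))
    return [cand for cand, s in candidate_scores.items() if s <= mu]
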