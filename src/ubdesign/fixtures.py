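"""Seeded synthetic-data generators.

Every stage of the funnel is testable offline: these generators emulate
the shapes and marginals of the study data — a 759-sequence scaffold
library with per-target binder-class counts, ubiquitin-like 72-84-residue
variants, docking decks with a known diverse low-energy subset, model
confidence tracks with planted failures, and per-residue decomposition
tables with planted hotspots.  Fixtures plant known answers; they do not
imitate real binding physics.

All generators are bit-reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import AA_ALPHABET, UBIQUITIN_WT
from .energetics import DecompositionTable, EnergyFrame, ResidueKey
from .seq_data import DatasetConfig, SequenceRecord, classify_binder
from .seq_filters import ModelQuality
from .struct_geom import Pose, StructureModel, chain_from_sequence

#: K_D bands (nM) sampled log-uniformly per binder class.
KD_BANDS = {"SB": (0.1, 10.0), "MB": (10.0, 100.0), "WB": (100.0, 10000.0)}

_TABLE4_MARGINALS = {
    "HER2": {"SB": 72, "MB": 59, "WB": 16},
    "FINC_EDB": {"SB": 36, "MB": 32, "WB": 18},
    "Others": {"SB": 127, "MB": 208, "WB": 191},
}


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    library_size: int = 759
    monomer_count: int = 329
    class_marginals: dict[str, dict[str, int]] = field(
        default_factory=lambda: {t: dict(c) for t, c in _TABLE4_MARGINALS.items()}
    )
    pose_deck_size: int = 100
    score_noise: float = 0.0
    planted_hotspot_count: int = 3
    plddt_model_count: int = 112
    plddt_fail_count: int = 11

    def __post_init__(self) -> None:
        total = sum(sum(c.values()) for c in self.class_marginals.values())
        if total != self.library_size:
            raise ValueError(
                f"class marginals sum to {total}, expected library_size={self.library_size}"
            )
        if not 0 <= self.monomer_count <= self.library_size:
            raise ValueError("monomer_count must be within library_size")


# ---------------------------------------------------------------------------
# Sequence library


def _scaffold_variant(
    rng: np.random.Generator,
    motifs: tuple[str, ...],
    insertion_prob: float = 0.25,
    max_len: int = 84,
) -> str:
    """A ubiquitin variant with 5-20 substitutions, an optional short loop
    insertion, a motif start and no internal motif occurrence."""
    while True:
        seq = list(UBIQUITIN_WT)
        seq[:3] = rng.choice(motifs)
        n_sub = int(rng.integers(5, 21))
        positions = rng.choice(np.arange(3, len(seq)), size=n_sub, replace=False)
        for p in positions:
            choices = [a for a in AA_ALPHABET if a != seq[p]]
            seq[p] = choices[int(rng.integers(len(choices)))]
        if rng.random() < insertion_prob:
            ins_len = int(rng.integers(1, max_len - len(seq) + 1))
            ins = "".join(
                AA_ALPHABET[int(rng.integers(20))] for _ in range(ins_len)
            )
            at = int(rng.integers(6, 12))  # first loop region
            seq[at:at] = list(ins)
        out = "".join(seq)
        if all(out.find(m, 1) == -1 for m in motifs):
            return out


def make_library(cfg: FixtureConfig | None = None) -> list[SequenceRecord]:
    """Synthetic scaffold library with the configured per-target class
    marginals.

    Monomeric records carry one scaffold variant; dimeric records are two
    motif-started variants concatenated, so curation splits them back at
    the planted junction.  K_D is drawn log-uniformly inside the class band
    and is always consistent with `classify_binder`.
    """
    cfg = cfg or FixtureConfig()
    rng = np.random.default_rng(cfg.seed)
    motifs = DatasetConfig().split_motifs
    slots = [
        (target, cls)
        for target, counts in cfg.class_marginals.items()
        for cls, n in counts.items()
        for _ in range(n)
    ]
    is_monomer = np.zeros(len(slots), dtype=bool)
    is_monomer[rng.permutation(len(slots))[: cfg.monomer_count]] = True
    records = []
    tally: dict[tuple[str, str], int] = {}
    for i, (target, cls) in enumerate(slots):
        lo, hi = KD_BANDS[cls]
        kd = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        # guard against the vanishing chance of rounding onto a boundary
        kd = min(max(kd, lo * 1.0001), hi * 0.9999)
        assert classify_binder(kd) == cls
        seq = _scaffold_variant(rng, motifs)
        if not is_monomer[i]:
            seq = seq + _scaffold_variant(rng, motifs)
        tally[(target, cls)] = tally.get((target, cls), 0) + 1
        records.append(
            SequenceRecord(
                id=f"{target}_{cls}_{tally[(target, cls)]:03d}",
                sequence=seq,
                kd_nM=kd,
                target=target,
                binder_class=cls,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Model-confidence tracks


def make_plddt_tracks(
    cfg: FixtureConfig | None = None,
) -> tuple[list[ModelQuality], set[str]]:
    """Confidence tracks with a planted set of failing models.

    Passing models stay in [70, 98] everywhere; failing models get one
    region dipping below 50.  Returns the tracks and the failing ids.
    """
    cfg = cfg or FixtureConfig()
    rng = np.random.default_rng(cfg.seed + 1)
    fail_ids = set()
    fail = rng.permutation(cfg.plddt_model_count)[: cfg.plddt_fail_count]
    models = []
    for i in range(cfg.plddt_model_count):
        length = int(rng.integers(72, 85))
        track = rng.uniform(70.0, 98.0, size=length)
        if i in fail:
            start = int(rng.integers(0, length - 5))
            track[start : start + 5] = rng.uniform(20.0, 49.5, size=5)
            fail_ids.add(f"model_{i:03d}")
        models.append(ModelQuality(f"model_{i:03d}", tuple(track.round(2))))
    return models, fail_ids


# ---------------------------------------------------------------------------
# Pose decks


def _helix(sequence: str, chain_id: str, origin: np.ndarray) -> StructureModel:
    n = len(sequence)
    t = np.arange(n)
    coords = np.column_stack(
        [
            2.3 * np.cos(np.deg2rad(100.0) * t),
            2.3 * np.sin(np.deg2rad(100.0) * t),
            1.5 * t,
        ]
    ) + origin
    return chain_from_sequence(sequence, coords, chain_id)


def _rigid(rng: np.random.Generator, max_angle_deg: float, max_shift: float):
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, np.deg2rad(max_angle_deg))
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    t = rng.uniform(-max_shift, max_shift, size=3)
    return R, t


def oracle_ligand_rmsd(p: Pose, q: Pose) -> float:
    """Independent L-RMSD route used for fixture ground truth: receptor
    superposition via scipy's rotation alignment instead of the package's
    own Kabsch."""
    rec_p, rec_q = p.receptor.coords("CA"), q.receptor.coords("CA")
    cp, cq = rec_p.mean(axis=0), rec_q.mean(axis=0)
    rot, _ = Rotation.align_vectors(rec_p - cp, rec_q - cq)
    lig_moved = rot.apply(q.ligand.coords("CA") - cq) + cp
    diff = lig_moved - p.ligand.coords("CA")
    return float(np.sqrt((diff**2).sum(axis=1).mean()))


def oracle_greedy(
    poses: Sequence[Pose], diversity_rmsd: float = 2.0, max_kept: int = 50
) -> list[str]:
    """Brute-force greedy diversity selection (ground-truth oracle)."""
    kept: list[Pose] = []
    for pose in sorted(poses, key=lambda p: (p.score, p.pose_id)):
        if len(kept) >= max_kept:
            break
        if all(oracle_ligand_rmsd(pose, k) > diversity_rmsd for k in kept):
            kept.append(pose)
    return [p.pose_id for p in kept]


def make_pose_deck(cfg: FixtureConfig | None = None) -> tuple[list[Pose], list[str]]:
    """Toy two-mini-protein docking deck with known greedy ground truth.

    The reference pose puts the ligand helix in contact with the receptor
    helix; every other pose is a random rigid perturbation of the ligand,
    and the whole frame (receptor + ligand) of each pose is additionally
    moved by a random rigid transform to exercise receptor superposition.
    Scores follow -20/(1 + L-RMSD-to-reference) plus optional noise, so the
    reference is the energetic optimum by construction.

    Returns the deck and the ground-truth kept ids from the brute-force
    greedy oracle.
    """
    cfg = cfg or FixtureConfig()
    rng = np.random.default_rng(cfg.seed + 2)
    receptor = _helix("ACDEFGHIKLMNPQRSTVWY", "R", np.zeros(3))
    ref_ligand = _helix("MQIFVKTLTGKT", "L", np.array([8.0, 0.0, 5.0]))
    ref = Pose("pose_000", receptor, ref_ligand, -20.0)
    poses = [ref]
    for i in range(1, cfg.pose_deck_size):
        R, t = _rigid(rng, max_angle_deg=25.0, max_shift=8.0)
        ligand = ref_ligand.transformed(R, t)
        pose = Pose(f"pose_{i:03d}", receptor, ligand, 0.0)
        lrmsd = oracle_ligand_rmsd(ref, pose)
        score = -20.0 / (1.0 + lrmsd)
        if cfg.score_noise > 0:
            score += rng.normal(0.0, cfg.score_noise)
        # optional whole-frame move: L-RMSD must be invariant to it
        Rf, tf = _rigid(rng, max_angle_deg=180.0, max_shift=20.0)
        poses.append(
            Pose(
                pose.pose_id,
                receptor.transformed(Rf, tf),
                ligand.transformed(Rf, tf),
                float(score),
            )
        )
    return poses, oracle_greedy(poses)


# ---------------------------------------------------------------------------
# Energetics fixtures


def make_decomposition(
    cfg: FixtureConfig | None = None,
    n_ligand_residues: int = 12,
    n_receptor_residues: int = 20,
) -> tuple[DecompositionTable, np.ndarray, set[ResidueKey]]:
    """Decomposition table built from an explicit pairwise energy matrix.

    ``planted_hotspot_count`` ligand residues get row sums in
    [-8, -3] kcal/mol (hotspots); all others land in [-1.5, 0.5] (mutable).
    Returns (table over ligand residues, pairwise matrix, planted hotspot
    keys); the table is exactly the matrix row sums.
    """
    cfg = cfg or FixtureConfig()
    if cfg.planted_hotspot_count > n_ligand_residues:
        raise ValueError("more planted hotspots than ligand residues")
    rng = np.random.default_rng(cfg.seed + 3)
    hot = set(
        int(i) + 1
        for i in rng.permutation(n_ligand_residues)[: cfg.planted_hotspot_count]
    )
    matrix = np.zeros((n_ligand_residues, n_receptor_residues))
    for i in range(n_ligand_residues):
        total = (
            rng.uniform(-8.0, -3.0) if (i + 1) in hot else rng.uniform(-1.5, 0.5)
        )
        weights = rng.dirichlet(np.ones(n_receptor_residues))
        matrix[i] = total * weights
    table = DecompositionTable(
        tuple((("L", i + 1), float(matrix[i].sum())) for i in range(n_ligand_residues))
    )
    return table, matrix, {("L", i) for i in hot}


def make_energy_frames(
    n_frames: int = 500,
    mean_dg: float = -25.0,
    sigma: float = 3.0,
    seed: int = 0,
) -> list[EnergyFrame]:
    """Snapshot energies whose per-frame ΔG is Normal(mean_dg, sigma)."""
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        e_rec = rng.normal(-1500.0, 20.0)
        e_lig = rng.normal(-600.0, 10.0)
        dg = rng.normal(mean_dg, sigma)
        frames.append(EnergyFrame(i, e_rec + e_lig + dg, e_rec, e_lig))
    return frames
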