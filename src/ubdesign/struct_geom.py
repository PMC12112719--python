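"""Structure handling and RMSD metrics.

Two RMSD notions drive the design funnel:

* **Aligned Cα-RMSD** between homologous proteins: the sequences are
  globally aligned (BLOSUM62, gap open -10, extend -0.5), Cα pairs are taken
  at aligned non-gap columns, and the pairs are optimally superposed
  (Kabsch) before computing the RMSD.
* **Ligand-RMSD (L-RMSD)** between two poses of the same complex: the two
  receptor copies are superposed, the resulting transform is applied to the
  second pose's ligand, and the plain (no re-superposition) Cα-RMSD between
  the ligand copies is returned.  This measures how far the mobile binding
  partner moved in the receptor frame.

Coordinates are in Å; residues use 1-based author numbering; alternate
locations keep the first occurrence.  PDB files are read and written
through biotite (ATOM records only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from .seq_filters import AlignmentParams, align_pair

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


class DegenerateAlignmentError(ValueError):
    """Raised when fewer than 3 residue pairs survive the alignment."""


@dataclass(frozen=True)
class Residue:
    """One residue: name, author index and at least a Cα coordinate."""

    name: str
    index: int
    atoms: dict[str, tuple[float, float, float]]
    confidence: float | None = None

    def __post_init__(self) -> None:
        if "CA" not in self.atoms:
            raise ValueError(f"residue {self.name}{self.index} lacks a CA atom")

    @property
    def ca(self) -> np.ndarray:
        return np.asarray(self.atoms["CA"], dtype=float)


@dataclass(frozen=True)
class StructureModel:
    """Ordered chains of residues with Cα (optionally backbone) coordinates."""

    chains: tuple[tuple[str, tuple[Residue, ...]], ...]

    def __post_init__(self) -> None:
        for chain_id, residues in self.chains:
            idx = [r.index for r in residues]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(
                    f"residue indices must be strictly increasing in chain {chain_id}"
                )

    @property
    def residues(self) -> tuple[Residue, ...]:
        return tuple(r for _, rs in self.chains for r in rs)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def coords(self, selection: Literal["CA", "backbone"] = "CA") -> np.ndarray:
        """Concatenated coordinates over chains in chain order."""
        if selection == "CA":
            return np.array([r.ca for r in self.residues], dtype=float)
        pts = [
            r.atoms[a]
            for r in self.residues
            for a in BACKBONE_ATOMS
            if a in r.atoms
        ]
        return np.asarray(pts, dtype=float)

    def sequence(self) -> str:
        return "".join(_THREE_TO_ONE.get(r.name, "X") for r in self.residues)

    def confidence_track(self) -> list[float] | None:
        track = [r.confidence for r in self.residues]
        return None if any(c is None for c in track) else track

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "StructureModel":
        """Return a copy with every atom mapped through x -> R x + t."""
        def mv(p):
            return tuple((R @ np.asarray(p, dtype=float) + t).tolist())

        return StructureModel(
            tuple(
                (
                    cid,
                    tuple(
                        Residue(r.name, r.index, {a: mv(p) for a, p in r.atoms.items()}, r.confidence)
                        for r in rs
                    ),
                )
                for cid, rs in self.chains
            )
        )


@dataclass(frozen=True)
class Pose:
    """One docking pose: a (shared) receptor, a moved ligand copy and its
    binding-energy score (lower = better)."""

    pose_id: str
    receptor: StructureModel
    ligand: StructureModel
    score: float


def kabsch_superpose(
    mobile: np.ndarray, fixed: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``fixed``.

    Returns ``(R, t, rmsd)`` with proper rotation R (no reflection) and
    translation t such that ``mobile @ R.T + t`` best fits ``fixed``; the
    RMSD is minimal over all rigid transforms.
    """
    mobile = np.asarray(mobile, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if mobile.shape != fixed.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (N, 3) with equal N")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 points to superpose")
    cm, cf = mobile.mean(axis=0), fixed.mean(axis=0)
    H = (mobile - cm).T @ (fixed - cf)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(((moved - fixed) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def plain_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD without superposition."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("point sets must have equal shapes")
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def aligned_ca_rmsd(
    a: StructureModel,
    b: StructureModel,
    params: AlignmentParams | None = None,
    identical_only: bool = False,
) -> float:
    """Sequence-alignment-guided Cα-RMSD between two homologous structures.

    Residues are paired at aligned non-gap columns (with
    ``identical_only=True``, only identical-residue columns), superposed with
    Kabsch and the minimal RMSD over the paired Cα atoms is returned.
    """
    row_a, row_b = align_pair(a.sequence(), b.sequence(), params)
    res_a, res_b = a.residues, b.residues
    ia = ib = 0
    pa, pb = [], []
    for ca_, cb_ in zip(row_a, row_b):
        if ca_ != "-" and cb_ != "-":
            if not identical_only or ca_ == cb_:
                pa.append(res_a[ia].ca)
                pb.append(res_b[ib].ca)
        ia += ca_ != "-"
        ib += cb_ != "-"
    if len(pa) < 3:
        raise DegenerateAlignmentError(
            f"only {len(pa)} matched residue pairs after alignment"
        )
    return kabsch_superpose(np.array(pa), np.array(pb))[2]


def ligand_rmsd(
    p: Pose, q: Pose, selection: Literal["CA", "backbone"] = "CA"
) -> float:
    """L-RMSD between two poses of the same complex.

    Superposes q's receptor onto p's receptor (Kabsch on receptor Cα),
    applies that transform to q's ligand and returns the plain RMSD between
    the ligand copies on the chosen atom selection.
    """
    if q.ligand.n_residues != p.ligand.n_residues:
        raise ValueError("poses have different ligand residue counts")
    R, t, _ = kabsch_superpose(q.receptor.coords("CA"), p.receptor.coords("CA"))
    moved = q.ligand.coords(selection) @ R.T + t
    return plain_rmsd(moved, p.ligand.coords(selection))


def trajectory_lrmsd(
    frames: Sequence[tuple[StructureModel, StructureModel]],
    reference: tuple[StructureModel, StructureModel],
    selection: Literal["CA", "backbone"] = "CA",
) -> tuple[list[float], float, float]:
    """Per-frame L-RMSD of (receptor, ligand) frames against a reference.

    Returns the series plus its mean and max.
    """
    ref_pose = Pose("ref", reference[0], reference[1], 0.0)
    series = []
    for i, (rec, lig) in enumerate(frames):
        if lig.n_residues != reference[1].n_residues or rec.n_residues != reference[0].n_residues:
            raise ValueError(f"frame {i} topology does not match the reference")
        series.append(ligand_rmsd(ref_pose, Pose(f"f{i}", rec, lig, 0.0), selection))
    if not series:
        raise ValueError("no frames supplied")
    return series, float(np.mean(series)), float(np.max(series))


# ---------------------------------------------------------------------------
# PDB IO (ATOM records only; HETATM ignored; first altloc kept)


def read_structure(path: str | Path) -> StructureModel:
    pdb = bpdb.PDBFile.read(str(path))
    arr = pdb.get_structure(model=1, altloc="first", extra_fields=["b_factor"])
    arr = arr[~arr.hetero]
    chains: list[tuple[str, tuple[Residue, ...]]] = []
    for cid in np.unique(arr.chain_id).tolist():
        sub = arr[arr.chain_id == cid]
        residues = []
        for res_id in np.unique(sub.res_id).tolist():
            rsub = sub[sub.res_id == res_id]
            atoms = {}
            conf = None
            for i in range(len(rsub)):
                name = rsub.atom_name[i]
                if name in BACKBONE_ATOMS and name not in atoms:
                    atoms[name] = tuple(float(x) for x in rsub.coord[i])
                    if name == "CA":
                        conf = float(rsub.b_factor[i])
            if "CA" in atoms:
                residues.append(
                    Residue(str(rsub.res_name[0]), int(res_id), atoms, conf)
                )
        if residues:
            chains.append((str(cid), tuple(residues)))
    return StructureModel(tuple(chains))


def write_structure(model: StructureModel, path: str | Path) -> None:
    n_atoms = sum(len(r.atoms) for r in model.residues)
    arr = bst.AtomArray(n_atoms)
    i = 0
    for cid, residues in model.chains:
        for r in residues:
            for name in BACKBONE_ATOMS:
                if name not in r.atoms:
                    continue
                arr.chain_id[i] = cid
                arr.res_id[i] = r.index
                arr.res_name[i] = r.name
                arr.atom_name[i] = name
                arr.element[i] = name[0]
                arr.coord[i] = r.atoms[name]
                i += 1
    arr.set_annotation(
        "b_factor",
        np.array(
            [
                r.confidence if r.confidence is not None else 0.0
                for _, rs in model.chains
                for r in rs
                for a in BACKBONE_ATOMS
                if a in r.atoms
            ]
        ),
    )
    pdb = bpdb.PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def chain_from_sequence(
    sequence: str,
    coords: np.ndarray,
    chain_id: str = "A",
    confidence: Sequence[float] | None = None,
) -> StructureModel:
    """Build a single-chain Cα-only model from a sequence and coordinates."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(sequence), 3):
        raise ValueError("coords must be (len(sequence), 3)")
    residues = tuple(
        Residue(
            _ONE_TO_THREE.get(aa, "GLY"),
            i + 1,
            {"CA": tuple(coords[i])},
            None if confidence is None else float(confidence[i]),
        )
        for i, aa in enumerate(sequence)
    )
    return StructureModel(((chain_id, residues),))


# ---------------------------------------------------------------------------
# Pose-deck IO: a directory of ligand PDB files + receptor.pdb + manifest.tsv


def write_pose_deck(poses: Sequence[Pose], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_structure(poses[0].receptor, directory / "receptor.pdb")
    rows = []
    for pose in poses:
        fname = f"{pose.pose_id}.pdb"
        write_structure(pose.ligand, directory / fname)
        rows.append({"pose_id": pose.pose_id, "file": fname, "score": pose.score})
    pd.DataFrame(rows).to_csv(directory / "manifest.tsv", sep="\t", index=False)


def read_pose_deck(directory: str | Path) -> list[Pose]:
    directory = Path(directory)
    receptor = read_structure(directory / "receptor.pdb")
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    return [
        Pose(
            str(row.pose_id),
            receptor,
            read_structure(directory / row.file),
            float(row.score),
        )
        for row in manifest.itertuples()
    ]
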