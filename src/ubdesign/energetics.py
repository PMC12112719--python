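"""MM-GB(PB)SA-style energetic post-processing.

Binding free energies are estimated from end-state snapshots: per frame
ΔG_t = E_complex − E_receptor − E_ligand (each component already includes
its implicit-solvation term; conformational entropy is excluded by
construction).  The per-residue decomposition assigns each interface
residue the sum of its pairwise interaction energies over all residues in
the system; residues contributing below −2 kcal/mol are binding hotspots,
interface residues at or above −2 kcal/mol are candidate positions for
mutagenesis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import math
import numpy as np
import pandas as pd

ResidueKey = tuple[str, int]  # (chain, author index)

HOTSPOT_THRESHOLD_KCAL = -2.0


@dataclass(frozen=True)
class EnergyFrame:
    """One snapshot's component energies (kcal/mol, solvation included)."""

    frame: int
    e_complex: float
    e_receptor: float
    e_ligand: float

    def __post_init__(self) -> None:
        for v in (self.e_complex, self.e_receptor, self.e_ligand):
            if not math.isfinite(v):
                raise ValueError("energy components must be finite")

    @property
    def dg(self) -> float:
        return self.e_complex - self.e_receptor - self.e_ligand


@dataclass(frozen=True)
class DecompositionTable:
    """Per-residue interaction-energy sums ΔGres for a complex interface."""

    dg_res: tuple[tuple[ResidueKey, float], ...]

    def __post_init__(self) -> None:
        keys = [k for k, _ in self.dg_res]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate residues in decomposition table")
        if any(not math.isfinite(v) for _, v in self.dg_res):
            raise ValueError("ΔGres values must be finite")

    def as_dict(self) -> dict[ResidueKey, float]:
        return dict(self.dg_res)

    @classmethod
    def from_dict(cls, d: Mapping[ResidueKey, float]) -> "DecompositionTable":
        return cls(tuple(d.items()))


@dataclass(frozen=True)
class EnergeticsConfig:
    hotspot_threshold: float = HOTSPOT_THRESHOLD_KCAL
    n_snapshots: int = 500
    #: cumulative band fractions for (NB/WB, MB, SB), weakest first
    band_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if self.n_snapshots < 1:
            raise ValueError("n_snapshots must be positive")
        if abs(sum(self.band_fractions) - 1.0) > 1e-9 or min(self.band_fractions) < 0:
            raise ValueError("band_fractions must be non-negative and sum to 1")


def binding_dg(frames: Sequence[EnergyFrame]) -> tuple[float, float]:
    """Snapshot-averaged binding energy.

    Returns the mean over frames of ΔG_t = E_complex − E_receptor − E_ligand
    and the standard error of that mean (0 for a single frame).
    """
    if not frames:
        raise ValueError("no energy frames supplied")
    dgs = np.array([f.dg for f in frames])
    mean = float(dgs.mean())
    se = float(dgs.std(ddof=1) / np.sqrt(len(dgs))) if len(dgs) > 1 else 0.0
    return mean, se


def ddg(variant_dg: float, original_dg: float) -> float:
    """Relative binding energy ΔΔG = ΔG_variant − ΔG_original.

    Negative values predict improved affinity of the variant.
    """
    if not (math.isfinite(variant_dg) and math.isfinite(original_dg)):
        raise ValueError("ΔG values must be finite")
    return variant_dg - original_dg


def hotspots(
    table: DecompositionTable, cfg: EnergeticsConfig | None = None
) -> set[ResidueKey]:
    """Residues contributing strongly to binding: ΔGres strictly below the
    threshold (−2 kcal/mol by default; exactly −2 is *not* a hotspot)."""
    cfg = cfg or EnergeticsConfig()
    return {k for k, v in table.dg_res if v < cfg.hotspot_threshold}


def mutable_positions(
    table: DecompositionTable,
    interface_residues: Iterable[ResidueKey],
    cfg: EnergeticsConfig | None = None,
) -> set[ResidueKey]:
    """Interface residues free to mutate: ΔGres at or above the hotspot
    threshold.  Together with `hotspots` (restricted to the interface) this
    partitions the interface set."""
    cfg = cfg or EnergeticsConfig()
    d = table.as_dict()
    interface = set(interface_residues)
    missing = interface - d.keys()
    if missing:
        raise ValueError(f"interface residues missing from table: {sorted(missing)}")
    return {k for k in interface if d[k] >= cfg.hotspot_threshold}


def band_candidates(
    dg_by_candidate: Mapping[str, float], cfg: EnergeticsConfig | None = None
) -> dict[str, str]:
    """Band candidates into {NB/WB, MB, SB} by ranked binding energy.

    Candidates are sorted by ΔG (ties broken by candidate id); the
    strongest (most negative) fraction becomes SB, the middle fraction MB
    and the weakest NB/WB, with fractions from the config (terciles by
    default).  Order of the input mapping does not matter.
    """
    cfg = cfg or EnergeticsConfig()
    if len(dg_by_candidate) < 3:
        raise ValueError("need at least 3 candidates to band")
    ranked = sorted(dg_by_candidate.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(ranked)
    n_sb = int(round(cfg.band_fractions[2] * n))
    n_mb = int(round(cfg.band_fractions[1] * n))
    n_sb = min(n_sb, n)
    n_mb = min(n_mb, n - n_sb)
    bands: dict[str, str] = {}
    for pos, (cand, _) in enumerate(ranked):
        if pos < n_sb:
            bands[cand] = "SB"
        elif pos < n_sb + n_mb:
            bands[cand] = "MB"
        else:
            bands[cand] = "NB/WB"
    return bands


# ---------------------------------------------------------------------------
# CSV contracts


def read_energy_frames(path: str | Path) -> list[EnergyFrame]:
    """Frames CSV: columns frame, E_complex, E_receptor, E_ligand."""
    df = pd.read_csv(path)
    return [
        EnergyFrame(int(r.frame), float(r.E_complex), float(r.E_receptor), float(r.E_ligand))
        for r in df.itertuples()
    ]


def write_energy_frames(frames: Sequence[EnergyFrame], path: str | Path) -> None:
    pd.DataFrame(
        {
            "frame": [f.frame for f in frames],
            "E_complex": [f.e_complex for f in frames],
            "E_receptor": [f.e_receptor for f in frames],
            "E_ligand": [f.e_ligand for f in frames],
        }
    ).to_csv(path, index=False, float_format="%.6f")


def read_decomposition(path: str | Path) -> DecompositionTable:
    """Decomposition CSV: columns chain, resid, resname, dGres."""
    df = pd.read_csv(path)
    return DecompositionTable(
        tuple(((str(r.chain), int(r.resid)), float(r.dGres)) for r in df.itertuples())
    )


def write_decomposition(
    table: DecompositionTable, path: str | Path, resnames: Mapping[ResidueKey, str] | None = None
) -> None:
    rows = [
        {
            "chain": chain,
            "resid": resid,
            "resname": (resnames or {}).get((chain, resid), "UNK"),
            "dGres": v,
        }
        for (chain, resid), v in table.dg_res
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
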