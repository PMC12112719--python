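"""Post-generation sequence filtration.

Generated scaffold candidates are kept only if they stay close to — but not
identical with — the ubiquitin wild type (identity window 75-90%), fall in
the 72-84 residue length window, and have confidently predicted structures
(no residue with pLDDT below 50).

Identity between two sequences is defined on the optimal global alignment
under BLOSUM62 with gap open -10 and gap extend -0.5: the number of
identical aligned columns divided by the total number of alignment columns,
gap columns included.  This makes the measure symmetric and penalises
length differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import edlib
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .constants import UBIQUITIN_WT
from .seq_data import InvalidSequenceError, validate_sequence


class AlignmentGapError(ValueError):
    """Raised when the optimal alignment needs a longer gap than allowed."""


@dataclass(frozen=True)
class AlignmentParams:
    """Global-alignment scoring used throughout the package."""

    matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5
    max_gap: int = 50

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.max_gap < 1:
            raise ValueError("max_gap must be positive")


@dataclass(frozen=True)
class FilterConfig:
    """Identity / length windows for generated sequences (inclusive bounds)."""

    identity_min: float = 0.75
    identity_max: float = 0.90
    length_min: int = 72
    length_max: int = 84
    plddt_floor: float = 50.0
    reference: str = UBIQUITIN_WT

    def __post_init__(self) -> None:
        if not 0 <= self.identity_min < self.identity_max <= 1:
            raise ValueError("need 0 <= identity_min < identity_max <= 1")
        if self.length_min > self.length_max:
            raise ValueError("length_min must be <= length_max")


@dataclass(frozen=True)
class ModelQuality:
    """Per-residue confidence (pLDDT, 0-100) of one predicted structure."""

    id: str
    plddt: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.plddt) == 0:
            raise InvalidSequenceError("pLDDT track is empty")
        if any(not 0 <= p <= 100 for p in self.plddt):
            raise ValueError("pLDDT values must be in [0, 100]")


@lru_cache(maxsize=8)
def _aligner(params: AlignmentParams) -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.substitution_matrix = substitution_matrices.load(params.matrix)
    aln.open_gap_score = params.gap_open
    aln.extend_gap_score = params.gap_extend
    aln.mode = "global"
    return aln


def _check_max_gap(aligned_cols: tuple[str, str], max_gap: int) -> None:
    for row in aligned_cols:
        run = 0
        for ch in row:
            run = run + 1 if ch == "-" else 0
            if run > max_gap:
                raise AlignmentGapError(
                    f"alignment requires a gap longer than max_gap={max_gap}"
                )


def align_pair(
    a: str, b: str, params: AlignmentParams | None = None
) -> tuple[str, str]:
    """Return the two gapped rows of the optimal global alignment of a and b."""
    params = params or AlignmentParams()
    validate_sequence(a)
    validate_sequence(b)
    alignment = _aligner(params).align(a, b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    _check_max_gap((row_a, row_b), params.max_gap)
    return row_a, row_b


def pairwise_identity(a: str, b: str, params: AlignmentParams | None = None) -> float:
    """Fraction of identical columns over all columns of the optimal global
    alignment (gap columns count in the denominator)."""
    row_a, row_b = align_pair(a, b, params)
    matches = sum(x == y and x != "-" for x, y in zip(row_a, row_b))
    return matches / len(row_a)


def identity_upper_bound(a: str, b: str) -> float:
    """Cheap rigorous upper bound on `pairwise_identity`.

    Any alignment with C columns, S substitution and I gap columns has
    identity (C - S - I)/C with S + I >= Levenshtein distance d and
    C <= len(a) + len(b), hence identity <= 1 - d/(len(a)+len(b)).
    """
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / (len(a) + len(b))


def filter_generated(
    sequences: Sequence[tuple[str, str]] | Sequence[str],
    cfg: FilterConfig | None = None,
    params: AlignmentParams | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Apply the identity and length windows to generated sequences.

    Parameters
    ----------
    sequences
        Either ``(id, sequence)`` pairs or bare sequences (ids are then
        ``gen_0001`` style).
    cfg, params
        Filter windows and alignment scoring.

    Returns
    -------
    kept : list of (id, sequence)
        Sequences passing both windows, input order preserved.
    report : pandas.DataFrame
        One row per input with columns ``id, length, identity, kept``.
    """
    cfg = cfg or FilterConfig()
    items: list[tuple[str, str]] = [
        s if isinstance(s, tuple) else (f"gen_{i + 1:04d}", s)
        for i, s in enumerate(sequences)
    ]
    rows = []
    kept = []
    for sid, seq in items:
        try:
            ident = pairwise_identity(seq, cfg.reference, params)
        except AlignmentGapError:
            # so divergent from the reference that the alignment would need
            # a longer gap than allowed -- certain rejection either way
            ident = float("nan")
        ok = (
            cfg.length_min <= len(seq) <= cfg.length_max
            and cfg.identity_min <= ident <= cfg.identity_max
        )
        rows.append(
            {"id": sid, "length": len(seq), "identity": ident, "kept": ok}
        )
        if ok:
            kept.append((sid, seq))
    return kept, pd.DataFrame(rows, columns=["id", "length", "identity", "kept"])


def plddt_filter(
    models: Sequence[ModelQuality], floor: float = 50.0
) -> tuple[list[ModelQuality], float]:
    """Discard models with any residue below the pLDDT floor.

    Returns the surviving models (input order) and the mean over the *input*
    set of each model's mean pLDDT.
    """
    if not models:
        raise InvalidSequenceError("no models to filter")
    kept = [m for m in models if min(m.plddt) >= floor]
    overall = sum(sum(m.plddt) / len(m.plddt) for m in models) / len(models)
    return kept, overall


def read_plddt_csv(path: str | Path, model_id: str | None = None) -> ModelQuality:
    """Read a per-residue confidence track from CSV (residue_index, plddt)."""
    df = pd.read_csv(path)
    track = tuple(float(x) for x in df["plddt"])
    return ModelQuality(id=model_id or Path(path).stem, plddt=track)


def write_filter_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.6f")
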