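"""Scaffold sequence library curation.

Parses and writes annotated FASTA libraries of ubiquitin-scaffold binder
variants, splits dimeric constructs into monomers at their N-terminal start
motifs, deduplicates near-identical sequences and classifies binders by
their dissociation constant K_D (nM):

* SB (strong binder):  K_D < 10 nM
* MB (medium binder):  10 nM <= K_D < 100 nM
* WB (weak binder):    K_D >= 100 nM
* NB (non-binder):     annotation only; never derived from a numeric K_D
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .constants import AA_SET, UBIQUITIN_WT

BINDER_CLASSES = ("SB", "MB", "WB", "NB")

#: K_D thresholds (nM) separating strong / medium / weak binders.
SB_MAX_KD_NM = 10.0
WB_MIN_KD_NM = 100.0


class InvalidSequenceError(ValueError):
    """Raised for empty or non-amino-acid sequences."""


@dataclass(frozen=True)
class SequenceRecord:
    """One scaffold variant with optional affinity annotations.

    Parameters
    ----------
    id : str
        Record identifier.
    sequence : str
        Upper-case amino-acid sequence over the 20-letter alphabet.
    kd_nM : float, optional
        Equilibrium dissociation constant in nM; must be positive.
    target : str, optional
        Target protein label (e.g. ``HER3``).
    binder_class : str, optional
        One of ``SB``, ``MB``, ``WB``, ``NB``.
    """

    id: str
    sequence: str
    kd_nM: float | None = None
    target: str | None = None
    binder_class: str | None = None

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        if self.kd_nM is not None and not self.kd_nM > 0:
            raise InvalidSequenceError(
                f"kd_nM must be positive, got {self.kd_nM!r}"
            )
        if self.binder_class is not None and self.binder_class not in BINDER_CLASSES:
            raise InvalidSequenceError(
                f"binder_class must be one of {BINDER_CLASSES}, got {self.binder_class!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DatasetConfig:
    """Curation parameters.

    ``split_motifs`` are the N-terminal 3-mers that start every monomer of a
    dimeric construct; ``dedup_identity`` is the pairwise-identity fraction
    at or above which a later sequence is considered a duplicate.
    """

    dedup_identity: float = 0.99
    split_motifs: tuple[str, ...] = ("MQI", "MRI", "MAS", "MTI")
    ubiquitin_wt: str = UBIQUITIN_WT

    def __post_init__(self) -> None:
        if not 0 < self.dedup_identity <= 1:
            raise ValueError("dedup_identity must be in (0, 1]")
        if any(len(m) != 3 for m in self.split_motifs):
            raise ValueError("split motifs must be 3-mers")
        if len(self.ubiquitin_wt) != 76:
            raise ValueError("ubiquitin_wt must be the 76-residue scaffold")


def validate_sequence(sequence: str) -> None:
    if not sequence:
        raise InvalidSequenceError("sequence is empty")
    bad = set(sequence) - AA_SET
    if bad:
        raise InvalidSequenceError(
            f"sequence contains non-standard letters: {sorted(bad)}"
        )


def classify_binder(kd_nM: float) -> str:
    """Map a dissociation constant (nM) to a binder class.

    SB for K_D < 10 nM, MB for 10 <= K_D < 100 nM, WB for K_D >= 100 nM.
    """
    if kd_nM is None or not kd_nM > 0:
        raise InvalidSequenceError(f"kd_nM must be a positive number, got {kd_nM!r}")
    if kd_nM < SB_MAX_KD_NM:
        return "SB"
    if kd_nM < WB_MIN_KD_NM:
        return "MB"
    return "WB"


def split_dimer(record: SequenceRecord, cfg: DatasetConfig | None = None) -> list[SequenceRecord]:
    """Split a dimeric construct into two monomers at the leftmost internal
    start motif.

    A motif occurrence at position 0 marks the first monomer's own start and
    is ignored; only occurrences strictly after position 0 trigger a split.
    Monomeric records are returned unchanged (singleton list).  The
    concatenation of the outputs always equals the input sequence.
    """
    cfg = cfg or DatasetConfig()
    seq = record.sequence
    validate_sequence(seq)
    cut = min(
        (pos for m in cfg.split_motifs if (pos := seq.find(m, 1)) != -1),
        default=-1,
    )
    if cut == -1:
        return [record]
    left = replace(record, id=f"{record.id}_m1", sequence=seq[:cut])
    right = replace(record, id=f"{record.id}_m2", sequence=seq[cut:])
    return [left, right]


def deduplicate(
    records: Sequence[SequenceRecord],
    cfg: DatasetConfig | None = None,
) -> list[SequenceRecord]:
    """Greedy single-pass deduplication at ``cfg.dedup_identity``.

    A record is dropped iff its pairwise identity to an already-kept record
    is at or above the threshold; the first occurrence wins and input order
    is preserved.  Identity is the module-wide alignment-based definition
    (`ubdesign.seq_filters.pairwise_identity`); an edit-distance bound skips
    alignments for pairs that provably cannot reach the threshold.
    """
    from .seq_filters import identity_upper_bound, pairwise_identity

    cfg = cfg or DatasetConfig()
    kept: list[SequenceRecord] = []
    for rec in records:
        duplicate = False
        for prev in kept:
            if rec.sequence == prev.sequence:
                duplicate = True
                break
            if identity_upper_bound(rec.sequence, prev.sequence) < cfg.dedup_identity:
                continue
            if pairwise_identity(rec.sequence, prev.sequence) >= cfg.dedup_identity:
                duplicate = True
                break
        if not duplicate:
            kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# FASTA IO: K_D / target / class ride in the description as key=value tokens.

_KV_RE = re.compile(r"(\w+)=(\S+)")


def _description(rec: SequenceRecord) -> str:
    parts = []
    if rec.kd_nM is not None:
        parts.append(f"kd_nM={rec.kd_nM:g}")
    if rec.target is not None:
        parts.append(f"target={rec.target}")
    if rec.binder_class is not None:
        parts.append(f"class={rec.binder_class}")
    return " ".join(parts)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read an annotated library (``kd_nM=`` / ``target=`` / ``class=``
    tokens in the description line are parsed back into record fields)."""
    records = []
    for bio in SeqIO.parse(str(path), "fasta"):
        tokens = dict(_KV_RE.findall(bio.description))
        records.append(
            SequenceRecord(
                id=bio.id,
                sequence=str(bio.seq).upper(),
                kd_nM=float(tokens["kd_nM"]) if "kd_nM" in tokens else None,
                target=tokens.get("target"),
                binder_class=tokens.get("class"),
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA with annotation tokens."""
    bio_records = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=_description(r))
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio_records, fh, "fasta")
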