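"""Affinity-maturation bookkeeping.

Given pools of redesigned variants for a parent hit, this module clusters
each pool at 97.5% sequence identity (greedy centroid clustering with the
first member of each cluster as its representative), decomposes
multi-mutant variants into their constituent single substitutions, and
combines the most improving singles (negative ΔΔG, distinct positions)
into double/triple "consensus" mutants.

Mutations use the standard 1-based notation ``K6R`` (lysine 6 to
arginine); multi-mutants join substitutions with ``+``.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .seq_data import InvalidSequenceError, validate_sequence
from .seq_filters import AlignmentParams, identity_upper_bound, pairwise_identity


class MutantConsistencyError(ValueError):
    """Raised when a mutant spec contradicts its parent sequence."""


@dataclass(frozen=True)
class Substitution:
    position: int  # 1-based
    from_res: str
    to_res: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("positions are 1-based")
        if len(self.from_res) != 1 or len(self.to_res) != 1:
            raise ValueError("residues must be single letters")

    def __str__(self) -> str:
        return f"{self.from_res}{self.position}{self.to_res}"


@dataclass(frozen=True)
class MutantSpec:
    """A set of substitutions applied to one parent sequence."""

    parent_id: str
    substitutions: tuple[Substitution, ...]

    def __post_init__(self) -> None:
        positions = [s.position for s in self.substitutions]
        if len(positions) != len(set(positions)):
            raise MutantConsistencyError("duplicate positions in one mutant spec")

    def __str__(self) -> str:
        return "+".join(str(s) for s in self.substitutions) or "WT"

    @property
    def order(self) -> int:
        return len(self.substitutions)


_MUT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_mutant(text: str, parent_id: str = "parent") -> MutantSpec:
    """Parse ``K6R`` / ``K6R+E7Q`` strings into a spec."""
    subs = []
    if text not in ("", "WT"):
        for token in text.split("+"):
            m = _MUT_RE.match(token.strip())
            if not m:
                raise ValueError(f"malformed mutation token: {token!r}")
            subs.append(Substitution(int(m.group(2)), m.group(1), m.group(3)))
    return MutantSpec(parent_id, tuple(subs))


@dataclass(frozen=True)
class MaturationConfig:
    cluster_identity: float = 0.975
    n_generated_per_hit: int = 100
    max_consensus_order: int = 3
    #: only the best-ranked improving singles enter consensus combinations
    top_improvers: int = 6

    def __post_init__(self) -> None:
        if not 0 < self.cluster_identity <= 1:
            raise ValueError("cluster_identity must be in (0, 1]")
        if self.max_consensus_order < 2:
            raise ValueError("max_consensus_order must be >= 2")
        if self.top_improvers < 2:
            raise ValueError("top_improvers must be >= 2")


def cluster_pool(
    sequences: Sequence[str],
    cfg: MaturationConfig | None = None,
    params: AlignmentParams | None = None,
) -> tuple[list[list[int]], list[int]]:
    """Greedy centroid clustering at ``cluster_identity``.

    Sequences are processed in input order; each joins the first existing
    cluster whose centroid it matches at or above the threshold (inclusive),
    otherwise it founds a new cluster and becomes its centroid.

    Returns ``(clusters, centroids)`` as index lists into the input.
    """
    cfg = cfg or MaturationConfig()
    if not sequences:
        raise InvalidSequenceError("empty sequence pool")
    clusters: list[list[int]] = []
    centroids: list[int] = []
    for i, seq in enumerate(sequences):
        validate_sequence(seq)
        placed = False
        for c, cen in enumerate(centroids):
            cen_seq = sequences[cen]
            if seq != cen_seq and identity_upper_bound(seq, cen_seq) < cfg.cluster_identity:
                continue
            if seq == cen_seq or pairwise_identity(seq, cen_seq, params) >= cfg.cluster_identity:
                clusters[c].append(i)
                placed = True
                break
        if not placed:
            clusters.append([i])
            centroids.append(i)
    return clusters, centroids


def diff_mutations(parent: str, variant: str, parent_id: str = "parent") -> MutantSpec:
    """List every position where the variant differs from the parent.

    Only fixed-length scaffolds are supported; indel-bearing variants are
    rejected.
    """
    validate_sequence(parent)
    validate_sequence(variant)
    if len(parent) != len(variant):
        raise MutantConsistencyError(
            "variant length differs from parent (indels are not supported)"
        )
    subs = tuple(
        Substitution(i + 1, p, v)
        for i, (p, v) in enumerate(zip(parent, variant))
        if p != v
    )
    return MutantSpec(parent_id, subs)


def enumerate_singles(specs: Sequence[MutantSpec]) -> list[MutantSpec]:
    """Union of individual substitutions across multi-mutant specs.

    Each distinct substitution is emitted once as a one-substitution spec,
    ordered by (position, to-residue).
    """
    seen: dict[tuple[int, str, str], MutantSpec] = {}
    for spec in specs:
        for sub in spec.substitutions:
            key = (sub.position, sub.to_res, sub.from_res)
            if key not in seen:
                seen[key] = MutantSpec(spec.parent_id, (sub,))
    return [seen[k] for k in sorted(seen, key=lambda k: (k[0], k[1]))]


def consensus_mutants(
    scored_singles: Mapping[str, float] | Sequence[tuple[MutantSpec, float]],
    cfg: MaturationConfig | None = None,
    parent_id: str = "parent",
) -> list[MutantSpec]:
    """Combine improving single mutants into double/triple consensus mutants.

    Only singles with negative ΔΔG are combinable.  All position-compatible
    combinations of order 2..max_consensus_order are emitted, built from the
    improving singles ranked by ascending ΔΔG (most improving first);
    combinations touching the same position twice are excluded.  Output
    order: by combination order, then by the rank of the components.
    """
    cfg = cfg or MaturationConfig()
    if isinstance(scored_singles, Mapping):
        items = [
            (parse_mutant(text, parent_id), score)
            for text, score in scored_singles.items()
        ]
    else:
        items = list(scored_singles)
    if len(items) < 2:
        raise ValueError("need at least 2 scored singles")
    for spec, _ in items:
        if spec.order != 1:
            raise ValueError(f"{spec} is not a single mutant")
    improving = sorted(
        ((spec, s) for spec, s in items if s < 0), key=lambda kv: (kv[1], str(kv[0]))
    )[: cfg.top_improvers]
    out: list[MutantSpec] = []
    for order in range(2, cfg.max_consensus_order + 1):
        for combo in itertools.combinations(improving, order):
            positions = [c[0].substitutions[0].position for c in combo]
            if len(positions) != len(set(positions)):
                continue
            subs = tuple(
                sorted(
                    (c[0].substitutions[0] for c in combo),
                    key=lambda s: s.position,
                )
            )
            out.append(MutantSpec(combo[0][0].parent_id, subs))
    return out


def apply_mutant(parent: str, spec: MutantSpec) -> str:
    """Apply a mutant spec to the parent sequence (length preserved)."""
    validate_sequence(parent)
    seq = list(parent)
    for sub in spec.substitutions:
        if sub.position > len(seq):
            raise MutantConsistencyError(
                f"position {sub.position} beyond parent length {len(seq)}"
            )
        if seq[sub.position - 1] != sub.from_res:
            raise MutantConsistencyError(
                f"parent has {seq[sub.position - 1]} at {sub.position}, "
                f"spec expects {sub.from_res}"
            )
        seq[sub.position - 1] = sub.to_res
    return "".join(seq)
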