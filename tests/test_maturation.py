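"""Mutant bookkeeping: pool clustering, mutation diffs, consensus design."""

import numpy as np
import pytest

from ubdesign.constants import AA_ALPHABET, UBIQUITIN_WT
from ubdesign.maturation import (
    MaturationConfig,
    MutantConsistencyError,
    MutantSpec,
    Substitution,
    apply_mutant,
    cluster_pool,
    consensus_mutants,
    diff_mutations,
    enumerate_singles,
    parse_mutant,
)
from ubdesign.seq_data import InvalidSequenceError
from ubdesign.seq_filters import pairwise_identity

PARENT = UBIQUITIN_WT + "AAAA"  # 80-mer scaffold


def mutate(seq, positions, to="W"):
    out = list(seq)
    for p in positions:
        out[p - 1] = to if out[p - 1] != to else "Y"
    return "".join(out)


class TestClusterPool:
    def test_identical_pool_single_cluster(self):
        clusters, centroids = cluster_pool([PARENT] * 5)
        assert len(clusters) == 1 and clusters[0] == [0, 1, 2, 3, 4]
        assert centroids == [0]

    def test_four_substitutions_split_into_singletons(self):
        # pairwise identity 76/80 = 0.95 < 0.975
        pool = [PARENT] + [
            mutate(PARENT, ps) for ps in ([5, 15, 25, 35], [45, 55, 65, 75], [6, 16, 26, 36])
        ]
        clusters, _ = cluster_pool(pool)
        assert len(clusters) == 4

    def test_boundary_identity_joins_cluster(self):
        variant = mutate(PARENT, [10, 20])  # identity 78/80 = 0.975 exactly
        assert pairwise_identity(PARENT, variant) == pytest.approx(0.975)
        clusters, centroids = cluster_pool([PARENT, variant])
        assert len(clusters) == 1

    def test_every_member_close_to_its_centroid(self, rng):
        pool = [
            mutate(PARENT, rng.choice(np.arange(1, 81), size=int(rng.integers(1, 4)), replace=False))
            for _ in range(30)
        ]
        cfg = MaturationConfig()
        clusters, centroids = cluster_pool(pool, cfg)
        assert sorted(i for c in clusters for i in c) == list(range(30))
        for cluster, cen in zip(clusters, centroids):
            for member in cluster:
                assert (
                    pairwise_identity(pool[member], pool[cen]) >= cfg.cluster_identity
                )

    def test_empty_pool_rejected(self):
        with pytest.raises(InvalidSequenceError):
            cluster_pool([])


class TestDiffMutations:
    def test_self_diff_is_empty(self):
        assert diff_mutations(PARENT, PARENT).substitutions == ()

    def test_named_substitutions(self):
        variant = apply_mutant(PARENT, parse_mutant("K6R+T7Q"))
        spec = diff_mutations(PARENT, variant)
        assert str(spec) == "K6R+T7Q"

    def test_planted_random_substitutions_recovered(self, rng):
        positions = sorted(rng.choice(np.arange(1, 81), size=10, replace=False))
        variant = mutate(PARENT, positions)
        spec = diff_mutations(PARENT, variant)
        assert [s.position for s in spec.substitutions] == [int(p) for p in positions]

    def test_indel_variant_rejected(self):
        with pytest.raises(MutantConsistencyError):
            diff_mutations(PARENT, PARENT[:-1])


class TestEnumerateSingles:
    def test_three_substitutions_three_singles(self):
        spec = parse_mutant("K6R+E7Q+T9A")
        singles = enumerate_singles([spec])
        assert [str(s) for s in singles] == ["K6R", "E7Q", "T9A"]

    def test_shared_substitution_deduplicated(self):
        specs = [parse_mutant("K6R+E7Q"), parse_mutant("K6R+T9A")]
        singles = enumerate_singles(specs)
        assert [str(s) for s in singles] == ["K6R", "E7Q", "T9A"]

    def test_multi_mutant_fixture_yields_exact_single_count(self, rng):
        # 12 multi-mutants drawing from 27 planted distinct substitutions
        planted = []
        positions = rng.choice(np.arange(1, 77), size=27, replace=False)
        for p in positions:
            frm = UBIQUITIN_WT[p - 1]
            to = next(a for a in AA_ALPHABET if a != frm)
            planted.append(Substitution(int(p), frm, to))
        specs = []
        for i in range(12):
            chunk = planted[i * 2 : i * 2 + 3] or planted[-3:]
            specs.append(MutantSpec("hit", tuple(chunk)))
        singles = enumerate_singles(specs)
        covered = {str(s) for spec in specs for s in spec.substitutions}
        assert {str(s) for s in singles} == covered

    def test_idempotent_under_reapplication(self):
        specs = [parse_mutant("K6R+E7Q"), parse_mutant("T9A")]
        once = enumerate_singles(specs)
        assert enumerate_singles(once) == once


class TestConsensusMutants:
    def test_only_improving_singles_combine(self):
        out = consensus_mutants({"K6R": -2.1, "E7Q": -1.0, "T9A": +0.5})
        assert [str(m) for m in out] == ["K6R+E7Q"]

    def test_same_position_conflict_excluded(self):
        out = consensus_mutants({"K6R": -2.1, "K6N": -1.5})
        assert out == []

    def test_three_improving_distinct_positions(self):
        out = consensus_mutants({"K6R": -3.0, "E7Q": -2.0, "T9A": -1.0})
        assert len(out) == 4  # 3 doubles + 1 triple
        orders = sorted(m.order for m in out)
        assert orders == [2, 2, 2, 3]

    def test_top_improvers_cap(self):
        scored = {f"{UBIQUITIN_WT[p-1]}{p}W": -1.0 - p / 100 for p in range(10, 20)}
        cfg = MaturationConfig(top_improvers=3)
        out = consensus_mutants(scored, cfg)
        assert len(out) == 4

    def test_components_are_position_consistent_and_negative(self):
        scored = {"K6R": -2.0, "E7Q": -1.2, "T9A": -0.3, "L8W": +1.0}
        for m in consensus_mutants(scored):
            positions = [s.position for s in m.substitutions]
            assert len(positions) == len(set(positions))
            for s in m.substitutions:
                assert scored[str(MutantSpec("p", (s,)))] < 0


class TestApplyMutant:
    def test_empty_spec_is_identity(self):
        assert apply_mutant(PARENT, MutantSpec("p", ())) == PARENT

    def test_single_substitution(self):
        out = apply_mutant(PARENT, parse_mutant("K6R"))
        assert out[5] == "R" and out[:5] == PARENT[:5] and out[6:] == PARENT[6:]

    def test_apply_then_diff_round_trip(self, rng):
        positions = rng.choice(np.arange(1, 81), size=5, replace=False)
        spec = diff_mutations(PARENT, mutate(PARENT, positions))
        assert diff_mutations(PARENT, apply_mutant(PARENT, spec)) == spec

    def test_wrong_parent_residue_rejected(self):
        with pytest.raises(MutantConsistencyError):
            apply_mutant(PARENT, parse_mutant("W6R"))
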