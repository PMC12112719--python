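"""Identity computation and the post-generation filtration windows."""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from ubdesign.seq_data import InvalidSequenceError
from ubdesign.seq_filters import (
    AlignmentGapError,
    AlignmentParams,
    FilterConfig,
    ModelQuality,
    filter_generated,
    identity_upper_bound,
    pairwise_identity,
    plddt_filter,
)
from ubdesign.fixtures import FixtureConfig, make_plddt_tracks

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_best_score(a, b, gap_open=-10.0, gap_extend=-0.5):
    """Enumerate every global alignment of two short sequences and return
    the best affine-gap BLOSUM62 score (independent oracle)."""
    best = [-np.inf]

    def recurse(i, j, score, last_gap):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, score + BLOSUM62[a[i], b[j]], None)
        if i < len(a):
            pen = gap_extend if last_gap == "a" else gap_open
            recurse(i + 1, j, score + pen, "a")
        if j < len(b):
            pen = gap_extend if last_gap == "b" else gap_open
            recurse(i, j + 1, score + pen, "b")

    recurse(0, 0, 0.0, None)
    return best[0]


class TestPairwiseIdentity:
    def test_identical_sequences(self, wt):
        assert pairwise_identity(wt, wt) == 1.0

    def test_eight_substitutions_no_indels(self, wt):
        variant = list(wt)
        for pos in (3, 10, 20, 30, 40, 50, 60, 70):
            variant[pos] = "W" if wt[pos] != "W" else "Y"
        ident = pairwise_identity(wt, "".join(variant))
        assert ident == pytest.approx(68 / 76)

    def test_truncation_counts_gap_columns(self, wt):
        # 76-mer vs its first 70 residues: 70 matches over 76 columns
        assert pairwise_identity(wt, wt[:70]) == pytest.approx(70 / 76)

    @pytest.mark.parametrize("seed", range(5))
    def test_alignment_score_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        a = "".join(rng.choice(list(aa), size=int(rng.integers(4, 7))))
        b = "".join(rng.choice(list(aa), size=int(rng.integers(4, 7))))
        from ubdesign.seq_filters import _aligner

        score = _aligner(AlignmentParams()).score(a, b)
        assert score == pytest.approx(brute_force_best_score(a, b))

    def test_symmetry_and_self_identity(self, wt, small_library):
        library, _ = small_library
        seqs = [r.sequence for r in library if len(r.sequence) <= 84][:6]
        for a, b in itertools.combinations(seqs, 2):
            assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))
            assert (pairwise_identity(a, b) == 1.0) == (a == b)

    def test_upper_bound_is_valid(self, small_library):
        library, _ = small_library
        seqs = [r.sequence for r in library if len(r.sequence) <= 84][:8]
        for a, b in itertools.combinations(seqs, 2):
            assert identity_upper_bound(a, b) >= pairwise_identity(a, b) - 1e-12

    def test_empty_sequence_rejected(self, wt):
        with pytest.raises(InvalidSequenceError):
            pairwise_identity("", wt)

    def test_long_gap_raises(self, wt):
        with pytest.raises(AlignmentGapError):
            pairwise_identity(wt, wt + "A" * 60)  # needs a 60-column gap


class TestFilterGenerated:
    def test_wild_type_itself_is_rejected(self, wt):
        kept, report = filter_generated([wt])
        assert kept == []
        assert report.loc[0, "identity"] == 1.0 and not report.loc[0, "kept"]

    def test_short_sequence_rejected(self, wt):
        kept, _ = filter_generated([wt[:70]])
        assert kept == []

    def test_identity_lower_bound_inclusive(self, wt):
        # exactly 19 scattered substitutions: identity 57/76 = 0.75; single
        # mismatches can never be outscored by gap pairs under open -10
        variant = list(wt)
        for pos in range(3, 3 + 19 * 4, 4):
            variant[pos] = "W" if variant[pos] != "W" else "Y"
        seq = "".join(variant)
        assert pairwise_identity(seq, wt) == pytest.approx(57 / 76)
        kept, _ = filter_generated([seq])
        assert len(kept) == 1

    def test_mid_window_variant_kept(self, wt):
        variant = list(wt)
        for pos in (5, 15, 25, 33, 41, 47, 55, 63, 68, 71):
            variant[pos] = "W" if variant[pos] != "W" else "Y"
        seq = "".join(variant)  # identity 66/76 ~ 0.868
        kept, report = filter_generated([seq])
        assert len(kept) == 1
        assert report.loc[0, "length"] == 76

    def test_report_matches_decisions_and_preserves_order(self, wt):
        seqs = [wt, wt[:70], wt[:74] + "WY"]
        kept, report = filter_generated(seqs)
        assert list(report["id"]) == ["gen_0001", "gen_0002", "gen_0003"]
        cfg = FilterConfig()
        for _, row in report.iterrows():
            expected = (
                cfg.length_min <= row["length"] <= cfg.length_max
                and cfg.identity_min <= row["identity"] <= cfg.identity_max
            )
            assert row["kept"] == expected

    def test_widening_windows_is_monotone(self, small_library, wt):
        library, _ = small_library
        seqs = [r.sequence for r in library if len(r.sequence) <= 84][:10]
        narrow, _ = filter_generated(seqs, FilterConfig())
        wide, _ = filter_generated(
            seqs, FilterConfig(identity_min=0.0, identity_max=1.0,
                               length_min=1, length_max=200)
        )
        assert set(s for _, s in narrow) <= set(s for _, s in wide)


class TestPlddtFilter:
    def test_uniformly_confident_model_kept(self):
        kept, mean = plddt_filter([ModelQuality("m", (90.0,) * 76)])
        assert len(kept) == 1 and mean == pytest.approx(90.0)

    def test_single_low_residue_discards_model(self):
        track = (95.0,) * 40 + (49.9,) + (95.0,) * 35
        kept, _ = plddt_filter([ModelQuality("m", track)])
        assert kept == []

    def test_floor_is_inclusive(self):
        kept, _ = plddt_filter([ModelQuality("m", (50.0,) * 76)])
        assert len(kept) == 1

    def test_planted_failures_are_exactly_removed(self):
        models, fail_ids = make_plddt_tracks(FixtureConfig(seed=2))
        kept, _ = plddt_filter(models)
        assert len(kept) == 112 - 11
        assert {m.id for m in models} - {m.id for m in kept} == fail_ids

    def test_empty_track_rejected(self):
        with pytest.raises(Exception):
            ModelQuality("m", ())
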