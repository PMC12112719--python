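"""Superposition and the funnel's RMSD metrics."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ubdesign.struct_geom import (
    DegenerateAlignmentError,
    Pose,
    StructureModel,
    aligned_ca_rmsd,
    chain_from_sequence,
    kabsch_superpose,
    ligand_rmsd,
    plain_rmsd,
    read_pose_deck,
    read_structure,
    trajectory_lrmsd,
    write_pose_deck,
    write_structure,
)


def optimizer_min_rmsd(mobile, fixed):
    """Independent oracle: minimise RMSD over rotation vectors with the
    translation solved analytically (centroid match), multi-start."""
    mobile = np.asarray(mobile, float)
    fixed = np.asarray(fixed, float)
    mc = mobile - mobile.mean(axis=0)
    fc = fixed - fixed.mean(axis=0)

    def cost(rv):
        moved = Rotation.from_rotvec(rv).apply(mc)
        return np.sqrt(((moved - fc) ** 2).sum(axis=1).mean())

    best = np.inf
    rng = np.random.default_rng(0)
    for _ in range(12):
        res = minimize(cost, rng.uniform(-np.pi, np.pi, 3), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        best = min(best, res.fun)
    return best


def helix(n, origin=(0.0, 0.0, 0.0)):
    t = np.arange(n)
    return np.column_stack(
        [2.3 * np.cos(1.745 * t), 2.3 * np.sin(1.745 * t), 1.5 * t]
    ) + np.asarray(origin)


def random_rigid(rng):
    R = Rotation.random(random_state=np.random.RandomState(int(rng.integers(1 << 31)))).as_matrix()
    t = rng.uniform(-10, 10, 3)
    return R, t


class TestKabsch:
    def test_identical_points_zero_rmsd_identity_transform(self):
        pts = helix(8)
        R, t, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, np.zeros(3), atol=1e-9)

    def test_rigid_invariance(self, rng):
        pts = helix(10)
        R0, t0 = random_rigid(rng)
        moved = pts @ R0.T + t0
        _, _, rmsd = kabsch_superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_three_point_toy_matches_optimizer_oracle(self):
        mobile = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        fixed = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 1]])
        _, _, rmsd = kabsch_superpose(mobile, fixed)
        assert rmsd == pytest.approx(optimizer_min_rmsd(mobile, fixed), abs=1e-3)

    def test_no_reflection(self, rng):
        pts = rng.normal(size=(6, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        R, _, _ = kabsch_superpose(mirrored, pts)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_superposed_never_worse_than_raw(self, rng):
        for _ in range(10):
            a, b = rng.normal(size=(7, 3)), rng.normal(size=(7, 3))
            _, _, rmsd = kabsch_superpose(a, b)
            assert rmsd <= plain_rmsd(a, b) + 1e-12

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestAlignedCaRmsd:
    def test_self_is_zero(self, wt):
        model = chain_from_sequence(wt, helix(len(wt)))
        assert aligned_ca_rmsd(model, model) == pytest.approx(0.0, abs=1e-9)

    def test_rigidly_moved_copy_is_zero(self, wt, rng):
        coords = helix(len(wt))
        R0, t0 = random_rigid(rng)
        a = chain_from_sequence(wt, coords)
        b = chain_from_sequence(wt, coords @ R0.T + t0)
        assert aligned_ca_rmsd(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_bent_helix_equals_direct_kabsch_on_matched_pairs(self, wt):
        coords_a = helix(len(wt))
        coords_b = coords_a.copy()
        coords_b[40] += np.array([0.0, 0.0, 1.5])  # one bent residue
        a = chain_from_sequence(wt, coords_a)
        b = chain_from_sequence(wt, coords_b)
        expected = kabsch_superpose(coords_a, coords_b)[2]
        assert aligned_ca_rmsd(a, b) == pytest.approx(expected, abs=1e-9)

    def test_degenerate_alignment_rejected(self):
        a = chain_from_sequence("MQI", helix(3))
        b = chain_from_sequence("MQI", helix(3))
        # 3 residues pair fine; 2-residue structures cannot even align here
        assert aligned_ca_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)
        short_a = chain_from_sequence("MQ", helix(2))
        short_b = chain_from_sequence("MQ", helix(2))
        with pytest.raises(DegenerateAlignmentError):
            aligned_ca_rmsd(short_a, short_b)


def make_pose(pid, rec_coords, lig_coords, score=0.0):
    return Pose(
        pid,
        chain_from_sequence("ACDEFGHIKLMNPQRSTVWY"[: len(rec_coords)], rec_coords, "R"),
        chain_from_sequence("MQIFVKTLTGKT"[: len(lig_coords)], lig_coords, "L"),
        score,
    )


class TestLigandRmsd:
    def setup_method(self):
        self.rec = helix(12)
        self.lig = helix(8, origin=(8.0, 0, 0))

    def test_self_is_zero(self):
        p = make_pose("p", self.rec, self.lig)
        assert ligand_rmsd(p, p) == pytest.approx(0.0, abs=1e-9)

    def test_pure_ligand_translation(self):
        p = make_pose("p", self.rec, self.lig)
        q = make_pose("q", self.rec, self.lig + np.array([3.0, 0, 0]))
        assert ligand_rmsd(p, q) == pytest.approx(3.0, abs=1e-9)

    def test_joint_rigid_move_is_invisible(self, rng):
        p = make_pose("p", self.rec, self.lig)
        R0, t0 = random_rigid(rng)
        q = make_pose("q", self.rec @ R0.T + t0, self.lig @ R0.T + t0)
        assert ligand_rmsd(p, q) == pytest.approx(0.0, abs=1e-6)

    def test_symmetry(self, rng):
        p = make_pose("p", self.rec, self.lig)
        R0, t0 = random_rigid(rng)
        q = make_pose(
            "q", self.rec @ R0.T + t0, (self.lig + rng.normal(size=(8, 3))) @ R0.T + t0
        )
        assert ligand_rmsd(p, q) == pytest.approx(ligand_rmsd(q, p), abs=1e-6)

    def test_mismatched_ligand_size_rejected(self):
        p = make_pose("p", self.rec, self.lig)
        q = make_pose("q", self.rec, helix(5, origin=(8.0, 0, 0)))
        with pytest.raises(ValueError):
            ligand_rmsd(p, q)


class TestTrajectory:
    def test_constant_trajectory_is_zero(self):
        rec, lig = helix(12), helix(8, origin=(8.0, 0, 0))
        ref = (chain_from_sequence("A" * 12, rec, "R"), chain_from_sequence("G" * 8, lig, "L"))
        frames = [ref] * 4
        series, mean, mx = trajectory_lrmsd(frames, ref)
        assert series == pytest.approx([0.0] * 4, abs=1e-9)
        assert mx == pytest.approx(0.0, abs=1e-9)

    def test_linear_drift_matches_closed_form(self):
        rec, lig = helix(12), helix(8, origin=(8.0, 0, 0))
        ref = (chain_from_sequence("A" * 12, rec, "R"), chain_from_sequence("G" * 8, lig, "L"))
        step = np.array([0.5, 0.0, 0.0])
        frames = [
            (ref[0], chain_from_sequence("G" * 8, lig + k * step, "L"))
            for k in range(5)
        ]
        series, mean, mx = trajectory_lrmsd(frames, ref)
        assert series == pytest.approx([0.5 * k for k in range(5)], abs=1e-9)
        assert mx == pytest.approx(2.0, abs=1e-9)
        assert all(b >= a for a, b in zip(series, series[1:]))

    def test_topology_mismatch_rejected(self):
        rec, lig = helix(12), helix(8, origin=(8.0, 0, 0))
        ref = (chain_from_sequence("A" * 12, rec, "R"), chain_from_sequence("G" * 8, lig, "L"))
        bad = (ref[0], chain_from_sequence("G" * 7, helix(7, origin=(8.0, 0, 0)), "L"))
        with pytest.raises(ValueError):
            trajectory_lrmsd([bad], ref)


class TestPdbIO:
    def test_structure_round_trip(self, tmp_path, wt):
        conf = np.linspace(50, 98, len(wt))
        model = chain_from_sequence(wt, helix(len(wt)), "A", confidence=conf)
        path = tmp_path / "model.pdb"
        write_structure(model, path)
        back = read_structure(path)
        assert back.sequence() == wt
        np.testing.assert_allclose(back.coords("CA"), model.coords("CA"), atol=1e-2)
        np.testing.assert_allclose(back.confidence_track(), conf, atol=1e-2)

    def test_pose_deck_round_trip(self, tmp_path, pose_deck):
        deck, _ = pose_deck
        write_pose_deck(deck[:5], tmp_path / "deck")
        back = read_pose_deck(tmp_path / "deck")
        assert [p.pose_id for p in back] == [p.pose_id for p in deck[:5]]
        assert [p.score for p in back] == pytest.approx([p.score for p in deck[:5]])
        np.testing.assert_allclose(
            back[3].ligand.coords("CA"), deck[3].ligand.coords("CA"), atol=1e-2
        )
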