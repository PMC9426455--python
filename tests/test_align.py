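"""Kabsch superposition and geometric correspondence search."""

import numpy as np
import pytest

from capsidphylo.align import (AlignParams, Correspondence, find_correspondence,
                               kabsch, multiple_superpose, pairwise_core_rmsd,
                               superpose, write_correspondence_table)
from capsidphylo.simulate import simulate_backbone
from capsidphylo.structure_io import CoreTrace

from oracles import quaternion_rmsd, random_rotation

ONE_TO_ONE = AlignParams(mode="one_to_one")


def _trace(points, label="t"):
    pts = np.asarray(points, float)
    tags = [("A", i + 1, "", "ALA") for i in range(len(pts))]
    return CoreTrace(label=label, positions=pts, residue_tags=tags)


class TestKabsch:
    def test_identical_sets_give_zero_and_identity(self, rng):
        A = rng.normal(size=(20, 3))
        res = kabsch(A, A)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_rigid_motion_is_recovered_exactly(self, rng):
        A = rng.normal(size=(30, 3))
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        B = A @ Rz.T + np.array([5.0, 5.0, 5.0])
        res = kabsch(A, B)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.rotation, Rz, atol=1e-10)

    def test_single_displaced_point_matches_quaternion_oracle(self):
        A = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        B = A.copy()
        B[3] = [0, 0, 2.0]
        assert kabsch(A, B).rmsd == pytest.approx(quaternion_rmsd(A, B), abs=1e-6)

    @pytest.mark.parametrize("n", [4, 10, 100])
    def test_oracle_agreement_on_random_instances(self, n, rng):
        for _ in range(60):
            A = rng.normal(scale=5.0, size=(n, 3))
            B = rng.normal(scale=5.0, size=(n, 3))
            assert kabsch(A, B).rmsd == pytest.approx(
                quaternion_rmsd(A, B), abs=1e-8)

    def test_rotations_are_always_proper(self, rng):
        # near-planar and mirrored inputs are the reflection-prone cases
        for _ in range(50):
            A = rng.normal(size=(12, 3))
            A[:, 2] *= 1e-4
            B = A.copy()
            B[:, 0] *= -1.0  # mirror image
            res = kabsch(A, B)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-12)

    def test_collinear_input_flagged_degenerate_but_solved(self):
        A = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        res = kabsch(A, A)
        assert res.degenerate
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_invariance_of_rmsd(self, rng):
        A = rng.normal(scale=4.0, size=(40, 3))
        B = rng.normal(scale=4.0, size=(40, 3))
        base = kabsch(A, B).rmsd
        for _ in range(10):
            R = random_rotation(rng)
            t = rng.uniform(-50, 50, 3)
            assert kabsch(A @ R.T + t, B).rmsd == pytest.approx(base, abs=1e-9)
            assert kabsch(A, B @ R.T + t).rmsd == pytest.approx(base, abs=1e-9)


class TestFindCorrespondence:
    def test_self_alignment_is_identity(self):
        a = simulate_backbone(80, 1)
        corr = find_correspondence(a, a)
        assert corr.pairs == tuple((i, i) for i in range(80))

    def test_deletion_is_skipped_and_rmsd_zero(self):
        a = simulate_backbone(90, 2)
        keep = [i for i in range(90) if not (40 <= i < 45)]
        b = _trace(a.positions[keep], "b")
        corr = find_correspondence(a, b)
        matched_a = [i for i, _ in corr.pairs]
        assert set(range(40, 45)).isdisjoint(matched_a)
        assert kabsch(a.positions, b.positions, corr).rmsd < 1e-6

    def test_one_to_one_mode_forces_positional_identity(self, rng):
        a = _trace(rng.normal(size=(50, 3)), "a")
        b = _trace(rng.normal(size=(50, 3)), "b")
        corr = find_correspondence(a, b, ONE_TO_ONE)
        assert corr.pairs == tuple((i, i) for i in range(50))

    def test_register_shift_resistance(self, rng):
        # a rigid copy must align at the true register even though the
        # β-meander repeats: full-length correspondence, zero RMSD
        a = simulate_backbone(120, 9)
        R = random_rotation(rng)
        b = _trace(a.positions @ R.T + rng.uniform(-30, 30, 3), "b")
        corr = find_correspondence(a, b)
        assert len(corr) == 120
        assert kabsch(a.positions, b.positions, corr).rmsd < 1e-9

    def test_crossing_pairs_rejected_by_type(self):
        with pytest.raises(ValueError, match="increasing"):
            Correspondence(((0, 0), (1, 2), (2, 1)))


class TestPairwiseRmsd:
    def test_self_distance_is_zero(self):
        a = simulate_backbone(60, 3)
        assert pairwise_core_rmsd(a, a) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_under_argument_swap(self, rng):
        a = simulate_backbone(70, 4)
        b = _trace(a.positions + rng.normal(0, 0.5, (70, 3)), "zzz")
        assert pairwise_core_rmsd(a, b) == pairwise_core_rmsd(b, a)

    def test_noise_concentration(self, rng):
        # isotropic per-coordinate noise sd σ gives rmsd near σ√3
        a = simulate_backbone(120, 5)
        for sigma in (0.3, 0.8):
            vals = []
            for _ in range(30):
                b = _trace(a.positions + rng.normal(0, sigma, (120, 3)), "b")
                vals.append(pairwise_core_rmsd(a, b, ONE_TO_ONE))
            mean = np.mean(vals)
            assert 0.5 * sigma * np.sqrt(3) < mean < 1.5 * sigma * np.sqrt(3)

    def test_triangle_inequality_in_one_to_one_mode(self, rng):
        # Procrustes distance is a metric under fixed correspondence
        for _ in range(25):
            a, b, c = (
                _trace(rng.normal(scale=3.0, size=(40, 3)), lab)
                for lab in "abc"
            )
            dab = pairwise_core_rmsd(a, b, ONE_TO_ONE)
            dbc = pairwise_core_rmsd(b, c, ONE_TO_ONE)
            dac = pairwise_core_rmsd(a, c, ONE_TO_ONE)
            assert dac <= dab + dbc + 1e-9

    def test_rigid_invariance(self, rng):
        a = simulate_backbone(80, 6)
        b = _trace(a.positions + rng.normal(0, 0.4, (80, 3)), "b")
        base = pairwise_core_rmsd(a, b)
        R = random_rotation(rng)
        b2 = _trace(b.positions @ R.T + rng.uniform(-40, 40, 3), "b")
        assert pairwise_core_rmsd(a, b2) == pytest.approx(base, abs=1e-9)


class TestMultipleSuperpose:
    def test_three_identical_traces(self):
        base = simulate_backbone(60, 7)
        traces = [_trace(base.positions, lab) for lab in ("s1", "s2", "s3")]
        ma = multiple_superpose(traces)
        assert len(ma.common_columns) == 60
        for la in ma.labels:
            for lb in ma.labels:
                if la < lb:
                    r = kabsch(ma.common_coords[la], ma.common_coords[lb]).rmsd
                    assert r == pytest.approx(0.0, abs=1e-9)

    def test_insertion_excluded_from_common_core(self, rng):
        base = simulate_backbone(80, 8)
        a = _trace(base.positions, "a")
        b = _trace(base.positions, "b")
        # c carries a 10-residue inserted excursion after residue 40
        loop = base.positions[40] + np.cumsum(
            rng.normal(0, 1.0, (10, 3)) + np.array([3.0, 1.0, 0.0]), axis=0)
        c_pts = np.concatenate([base.positions[:41], loop, base.positions[41:]])
        c = _trace(c_pts, "c")
        ma = multiple_superpose([a, b, c])
        assert len(ma.common_columns) <= 80
        r_ab = kabsch(ma.common_coords["a"], ma.common_coords["b"]).rmsd
        assert r_ab == pytest.approx(0.0, abs=1e-9)

    def test_fewer_than_three_traces_rejected(self):
        a = simulate_backbone(40, 1)
        b = _trace(a.positions, "b")
        with pytest.raises(ValueError, match=">= 3"):
            multiple_superpose([a, b])


class TestReports:
    def test_correspondence_table_shape(self):
        a = simulate_backbone(50, 1)
        b = _trace(a.positions, "b")
        res = superpose(a, b)
        text = write_correspondence_table(a, b, res.correspondence, res)
        lines = text.strip().splitlines()
        assert lines[0].split("\t") == ["label_a", "res_a", "label_b", "res_b",
                                        "distance_A"]
        assert len(lines) == len(res.correspondence) + 1

    def test_short_alignment_flagged_low_confidence(self, rng):
        a = simulate_backbone(30, 2)
        b = _trace(a.positions[:20], "b")
        res = superpose(a, b)
        assert len(res.correspondence) < 30
        assert res.low_confidence
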