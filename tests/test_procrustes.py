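"""Symmetric Procrustes statistic and PROTEST permutation test.

Oracles: an angle-grid brute-force search over all planar rotations and
reflections (for 2-column configurations), exhaustive n! enumeration of the
permutation null, and scipy's independent Procrustes disparity.
"""

import math

import numpy as np
import pytest
from scipy.spatial import procrustes as scipy_procrustes

from concord import (
    DegenerateConfigurationError,
    exhaustive_protest,
    procrustes_fit,
    protest,
)


def _cfg(a):
    """Center and unit-scale (re-stated here so oracles share no code path
    with the implementation's SVD step)."""
    c = np.asarray(a, float) - np.asarray(a, float).mean(axis=0)
    return c / math.sqrt((c**2).sum())


def angle_grid_r(x, y, step=1e-5):
    """Brute-force Procrustes correlation for 2-column matrices: grid-search
    the rotation angle (and the reflection family) maximizing the
    cross-configuration inner product."""
    m = _cfg(y).T @ _cfg(x)
    theta = np.arange(0.0, 2 * np.pi, step)
    ct, st = np.cos(theta), np.sin(theta)
    rotations = (m[0, 0] + m[1, 1]) * ct + (m[0, 1] - m[1, 0]) * st
    reflections = (m[0, 0] - m[1, 1]) * ct + (m[0, 1] + m[1, 0]) * st
    return max(rotations.max(), reflections.max())


class TestProcrustesFit:
    def test_self_congruence(self, rng):
        x = rng.normal(size=(8, 3))
        res = procrustes_fit(x, x)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.m2 == pytest.approx(0.0, abs=1e-12)

    def test_rigid_rotation_gives_r_one(self, rng):
        x = rng.normal(size=(6, 2))
        rot90 = np.array([[0.0, -1.0], [1.0, 0.0]])
        res = procrustes_fit(x, (x - x.mean(0)) @ rot90.T)
        assert res.r == pytest.approx(1.0, abs=1e-10)

    def test_invariances(self, rng):
        """r is unchanged by rotation/reflection, translation and positive
        rescaling of either matrix."""
        x = rng.normal(size=(15, 4))
        y = rng.normal(size=(15, 4))
        base = procrustes_fit(x, y).r
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))  # orthogonal, det +/-1
        assert procrustes_fit(x, y @ q) .r == pytest.approx(base, abs=1e-8)
        assert procrustes_fit(x + rng.normal(size=4), y).r == pytest.approx(base, abs=1e-8)
        assert procrustes_fit(3.7 * x, 0.02 * y).r == pytest.approx(base, abs=1e-8)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=(12, 5)), rng.normal(size=(12, 3))
        assert procrustes_fit(x, y).r == pytest.approx(procrustes_fit(y, x).r, abs=1e-10)

    def test_square_example_matches_angle_grid_oracle(self):
        x = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        y = x.copy()
        y[3] = [2.0, 2.0]
        assert procrustes_fit(x, y).r == pytest.approx(angle_grid_r(x, y), abs=1e-4)

    def test_random_2col_instances_match_angle_grid_oracle(self, rng):
        for _ in range(25):
            x = rng.normal(size=(7, 2))
            y = rng.normal(size=(7, 2))
            assert procrustes_fit(x, y).r == pytest.approx(angle_grid_r(x, y), abs=1e-4)

    def test_orthogonal_configurations_give_r_zero(self, rng):
        """If y's centered columns are orthogonal to x's, all singular values
        vanish."""
        x = np.zeros((6, 4))
        y = np.zeros((6, 4))
        x[:, :2] = rng.normal(size=(6, 2))
        y[:, 2:] = rng.normal(size=(6, 2))
        x -= x.mean(0)
        y -= y.mean(0)
        y[:, 2:] -= (
            x[:, :2] @ np.linalg.lstsq(x[:, :2], y[:, 2:], rcond=None)[0]
        )  # project out any accidental overlap in row space
        res = procrustes_fit(x, y)
        assert res.r == pytest.approx(0.0, abs=1e-10)
        assert res.m2 == pytest.approx(1.0, abs=1e-10)

    def test_rotation_is_orthogonal(self, rng):
        res = procrustes_fit(rng.normal(size=(10, 5)), rng.normal(size=(10, 5)))
        np.testing.assert_allclose(
            res.rotation.T @ res.rotation, np.eye(5), atol=1e-8
        )

    def test_matches_scipy_disparity(self, rng):
        """scipy computes the same symmetric superimposition; its disparity is
        1 - r**2 after optimal scaling."""
        for _ in range(5):
            x, y = rng.normal(size=(9, 4)), rng.normal(size=(9, 4))
            _, _, disparity = scipy_procrustes(x, y)
            assert procrustes_fit(x, y).r == pytest.approx(
                math.sqrt(1.0 - disparity), abs=1e-10
            )

    def test_width_mismatch_is_padded(self, rng):
        x, y = rng.normal(size=(8, 3)), rng.normal(size=(8, 6))
        assert procrustes_fit(x, y).n_dims == 6

    def test_degenerate_configuration_error(self, rng):
        flat = np.ones((5, 3))
        with pytest.raises(DegenerateConfigurationError, match="degenerate"):
            procrustes_fit(flat, rng.normal(size=(5, 3)))


class TestProtest:
    def test_p_floor_for_identical_matrices(self, rng):
        x = rng.normal(size=(10, 2))
        res = protest(x, x, permutations=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_reproducible_under_seed(self, rng):
        x, y = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        a = protest(x, y, permutations=99, seed=42, keep_draws=True)
        b = protest(x, y, permutations=99, seed=42, keep_draws=True)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.permutation_r, b.permutation_r)

    def test_agrees_with_exhaustive_enumeration(self, rng):
        """Monte-Carlo p within 3 MCSE of the exact n! p-value on tiny pairs."""
        for _ in range(3):
            x, y = rng.normal(size=(4, 2)), rng.normal(size=(4, 2))
            p_exact = exhaustive_protest(x, y)
            B = 4999
            p_mc = protest(x, y, permutations=B, seed=7).p_value
            mcse = math.sqrt(p_exact * (1 - p_exact) / B)
            assert abs(p_mc - p_exact) <= 3 * mcse + 2 / (B + 1)

    def test_null_r_decreases_with_n(self, rng):
        """Small-n upward bias: under independence the mean permutation r
        shrinks as the number of sites grows."""
        means = []
        for n in (10, 20, 40):
            vals = []
            for _ in range(8):
                x, y = rng.normal(size=(n, 3)), rng.normal(size=(n, 3))
                res = protest(x, y, permutations=60, seed=rng, keep_draws=True)
                vals.append(res.permutation_r.mean())
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_json_record(self, rng):
        x = rng.normal(size=(6, 2))
        rec = protest(x, x, permutations=9, seed=3).to_json()
        assert set(rec) == {"r", "m2", "p", "B", "seed", "n", "dims"}
        assert rec["B"] == 9 and rec["n"] == 6


class TestExhaustiveProtest:
    def test_scalene_triangle_only_identity_ties(self):
        x = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        assert exhaustive_protest(x, x) == pytest.approx(1 / 6)

    def test_reversal_symmetry_counts_ties(self):
        """Equally spaced collinear points: the reversal permutation is a
        reflection of the configuration, so two of 3! permutations tie."""
        x = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        assert exhaustive_protest(x, x) == pytest.approx(2 / 6)

    def test_refuses_large_n(self, rng):
        with pytest.raises(ValueError, match="n = 9"):
            exhaustive_protest(rng.normal(size=(9, 2)), rng.normal(size=(9, 2)))
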