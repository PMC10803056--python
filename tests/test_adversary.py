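"""Localization attack, privacy scores, and equivalence-class geometry."""

import numpy as np
import pytest

from fedrff.adversary import (
    bandwidth_overlap_period,
    equivalence_class_points,
    find_local_maxima,
    kept_maxima,
    privacy_score_system,
    privacy_score_user,
    zero_feature_score,
)
from fedrff.grid import GridSpec, Surface
from fedrff.kernels import RFFBasis, rff_projection, sample_frequencies, user_basis
from fedrff.protocol import user_surface_exact, user_surface_rff

GRID2 = GridSpec((-3.0, 3.0), 25, (-3.0, 3.0), 25)


def brute_force_maxima(values):
    """Oracle: direct neighbor scan + plateau dedup by flood fill."""
    values = np.atleast_2d(values)
    P, Q = values.shape
    is_max = np.ones((P, Q), dtype=bool)
    for p in range(P):
        for q in range(Q):
            for dp in (-1, 0, 1):
                for dq in (-1, 0, 1):
                    pp, qq = p + dp, q + dq
                    if (dp, dq) != (0, 0) and 0 <= pp < P and 0 <= qq < Q:
                        if values[p, q] < values[pp, qq]:
                            is_max[p, q] = False
    # plateau: connected equal-valued maxima -> lowest linear index
    seen = np.zeros((P, Q), dtype=bool)
    reps = []
    for p in range(P):
        for q in range(Q):
            if is_max[p, q] and not seen[p, q]:
                stack, comp = [(p, q)], []
                seen[p, q] = True
                while stack:
                    a, b = stack.pop()
                    comp.append(a * Q + b)
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            aa, bb = a + da, b + db
                            if (
                                0 <= aa < P and 0 <= bb < Q and is_max[aa, bb]
                                and not seen[aa, bb] and values[aa, bb] == values[a, b]
                            ):
                                seen[aa, bb] = True
                                stack.append((aa, bb))
                reps.append(min(comp))
    return sorted(reps)


class TestFindLocalMaxima:
    def test_unimodal_exact_surface_single_maximum(self):
        d = np.array([0.4, -1.1])
        idx, coords, vals = find_local_maxima(user_surface_exact(d, GRID2, h=0.6))
        assert len(idx) == 1
        nearest = np.argmin(np.linalg.norm(GRID2.nodes() - d, axis=1))
        assert idx[0] == nearest

    def test_constant_plateau_single_representative(self):
        idx, _, _ = find_local_maxima(Surface(np.ones(GRID2.shape), GRID2))
        assert list(idx) == [0]

    def test_1d_cosine_maxima(self):
        grid = GridSpec((0.0, 3.0), 301)
        surf = Surface(np.cos(2 * np.pi * grid.xs), grid)
        idx, coords, _ = find_local_maxima(surf)
        assert np.allclose(sorted(coords[:, 0]), [0.0, 1.0, 2.0, 3.0], atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_on_random_surfaces(self, seed):
        rng = np.random.default_rng(seed)
        grid = GridSpec((0.0, 1.0), 12, (0.0, 1.0), 11)
        vals = np.round(rng.normal(size=grid.shape), 1)  # rounding forces plateaus
        idx, _, _ = find_local_maxima(Surface(vals, grid))
        assert list(idx) == brute_force_maxima(vals)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_bruteforce_1d(self, seed):
        rng = np.random.default_rng(seed)
        grid = GridSpec((0.0, 1.0), 40)
        vals = np.round(rng.normal(size=40), 1)
        idx, _, _ = find_local_maxima(Surface(vals, grid))
        oracle = brute_force_maxima(vals[None, :])  # row vector: same neighbor logic
        assert list(idx) == oracle


class TestPrivacyScoreUser:
    def test_single_maximum_at_truth_scores_zero(self):
        d = GRID2.nodes()[88]
        rep = privacy_score_user(user_surface_exact(d, GRID2, h=0.6), d)
        assert rep.z == 0.0 and rep.K == 1 and not rep.fallback

    def test_equal_maxima_average_distances(self):
        # two equal kept maxima at distances 1 and 3 -> Z = 2
        grid = GridSpec((-4.0, 4.0), 81)
        vals = np.zeros(81)
        vals[np.argmin(np.abs(grid.xs - 1.0))] = 1.0
        vals[np.argmin(np.abs(grid.xs + 3.0))] = 1.0
        rep = privacy_score_user(Surface(vals, grid), np.array([0.0]))
        assert rep.z == pytest.approx(2.0, abs=1e-9)
        assert rep.weights[rep.kept].sum() == pytest.approx(1.0)

    def test_filter_drops_weak_maxima(self):
        grid = GridSpec((-4.0, 4.0), 81)
        vals = np.zeros(81)
        vals[10] = 1.0
        vals[70] = 0.5  # below 1/1.1: filtered out
        rep = privacy_score_user(Surface(vals, grid), np.array([grid.xs[10]]))
        assert rep.kept.sum() >= 1 and rep.z == pytest.approx(0.0, abs=1e-9)
        # literal double-normalized variant divides by the kept count
        rep2 = privacy_score_user(Surface(vals, grid), np.zeros(1), double_normalize=True)
        rep1 = privacy_score_user(Surface(vals, grid), np.zeros(1))
        assert rep2.z == pytest.approx(rep1.z / rep1.kept.sum())

    def test_nonpositive_surface_falls_back_flagged(self):
        rep = privacy_score_user(Surface(-np.ones(GRID2.shape), GRID2), np.zeros(2))
        assert rep.fallback and rep.z > 0

    def test_epsilon_below_one_rejected(self):
        with pytest.raises(ValueError):
            privacy_score_user(Surface(np.ones(GRID2.shape), GRID2), np.zeros(2), 0.9)

    def test_exact_kde_attack_recovers_user_within_grid_spacing(self):
        rng = np.random.default_rng(1)
        for d in rng.uniform(-2.5, 2.5, size=(10, 2)):
            rep = privacy_score_user(user_surface_exact(d, GRID2, h=0.55), d)
            assert rep.z <= max(GRID2.spacing)

    def test_score_invariant_under_simultaneous_translation(self):
        basis = user_basis(3, 0, B=2, h0=0.5)
        d = np.array([0.25, 0.5])
        t = np.array([1.25, -0.75])
        moved = GridSpec(
            (GRID2.x_range[0] + t[0], GRID2.x_range[1] + t[0]), GRID2.P,
            (GRID2.y_range[0] + t[1], GRID2.y_range[1] + t[1]), GRID2.Q,
        )
        z0 = privacy_score_user(user_surface_rff(d, basis, 0.5, GRID2), d).z
        z1 = privacy_score_user(user_surface_rff(d + t, basis, 0.5, moved), d + t).z
        assert z0 == pytest.approx(z1, abs=1e-9)


class TestSystemScore:
    def test_mean_and_permutation_invariance(self):
        assert privacy_score_system([0.0, 2.0]) == 1.0
        assert privacy_score_system([3.0, 3.0, 3.0]) == 3.0
        assert privacy_score_system([1.0, 5.0, 2.0]) == privacy_score_system([5.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            privacy_score_system([])


class TestZeroFeatureScore:
    def test_matches_direct_summation(self):
        d = np.array([0.7, -0.2])
        direct = np.mean([np.linalg.norm(g - d) for g in GRID2.nodes()])
        assert zero_feature_score(GRID2, d) == pytest.approx(direct)

    def test_two_point_1d_grid(self):
        assert zero_feature_score(GridSpec((-1.0, 1.0), 2), np.zeros(1)) == pytest.approx(1.0)

    def test_corner_user_scores_higher_than_center(self):
        assert zero_feature_score(GRID2, np.array([3.0, 3.0])) > zero_feature_score(
            GRID2, np.zeros(2)
        )


class TestEquivalenceClass:
    def test_anchor_is_member(self):
        ec = equivalence_class_points(np.array([1.0, 2.0]), np.array([0.5, 0.5]), GRID2)
        pts = ec.sample_points(5, np.random.default_rng(0))
        assert np.min(np.linalg.norm(pts - np.array([0.5, 0.5]), axis=1)) < ec.spacing

    def test_members_indistinguishable_from_anchor(self):
        rng = np.random.default_rng(2)
        g = rng.uniform(-3, 3, size=(100, 2))
        for _ in range(20):
            omega = rng.normal(size=2) / 0.5
            x = rng.uniform(-2, 2, size=2)
            basis = RFFBasis(h0=0.5, omegas=omega[None, :])
            ref = rff_projection(basis, 0.5, x, g)
            members = equivalence_class_points(omega, x, GRID2).sample_points(3, rng)
            for y in members:
                assert np.max(np.abs(rff_projection(basis, 0.5, y, g) - ref)) < 1e-9

    def test_1d_integer_lattice(self):
        bbox = GridSpec((-3.0, 4.0), 100)
        ec = equivalence_class_points(np.array([2 * np.pi]), np.array([0.3]), bbox)
        assert ec.spacing == pytest.approx(1.0)
        members = np.sort(ec.points[:, 0])
        assert np.allclose(members, np.arange(-2.7, 3.4, 1.0), atol=1e-9)
        assert np.any(np.isclose(members, 0.3, atol=1e-9))
        with pytest.raises(ValueError):
            equivalence_class_points(np.zeros(2), np.zeros(2), GRID2)

    def test_line_spacing_along_frequency_direction(self):
        omega = np.array([3.0, 0.0])
        ec = equivalence_class_points(omega, np.zeros(2), GRID2)
        xs = sorted(line[0][0] for line in ec.lines)
        assert np.allclose(np.diff(xs), 2 * np.pi / 3.0, atol=1e-9)

    @pytest.mark.parametrize("B", [1, 2, 3])
    def test_argmax_lies_in_equivalence_intersection(self, B):
        # for an on-grid user the surface argmax attains every feature's peak
        rng = np.random.default_rng(10 + B)
        for trial in range(5):
            d = GRID2.nodes()[rng.integers(GRID2.n_nodes)]
            basis = sample_frequencies(B, 0.5, dim=2, seed=int(rng.integers(1 << 30)))
            surf = user_surface_rff(d, basis, 0.5, GRID2)
            gstar = GRID2.nodes()[np.argmax(surf.flat)]
            for row in basis.omegas:
                single = RFFBasis(h0=0.5, omegas=row[None, :])
                assert rff_projection(single, 0.5, d, gstar) > 1 - 1e-9


class TestMultiBandwidthResistance:
    """What a server learns by querying one user at several bandwidths."""

    def _kept_1d(self, basis, h, grid, d):
        return np.sort(kept_maxima(user_surface_rff(d, basis, h, grid))[:, 0])

    def test_policy_compliant_rescaling_keeps_many_invariant_bands(self):
        h0 = 0.5
        basis = RFFBasis(h0=h0, omegas=np.array([[2 * np.pi / 1.5]]))  # base period 1.5
        grid = GridSpec((-20.0, 20.0), 4001)
        d = np.array([0.3])
        base = self._kept_1d(basis, h0, grid, d)
        resc = self._kept_1d(basis, 5 * h0, grid, d)
        m = len(base)
        matched = sum(np.min(np.abs(base - c)) < 0.05 for c in resc)
        assert matched == len(resc)  # every rescaled band overlaps a base band
        assert matched >= m // 5

    def test_off_policy_bandwidth_exposes_shifted_bands(self):
        h0 = 0.5
        basis = RFFBasis(h0=h0, omegas=np.array([[2 * np.pi / 1.5]]))
        grid = GridSpec((-20.0, 20.0), 4001)
        d = np.array([0.3])
        base = self._kept_1d(basis, h0, grid, d)
        resc = self._kept_1d(basis, 2.5 * h0, grid, d)  # h = 1.25: not (4n+1) h0
        unmatched = sum(np.min(np.abs(base - c)) > 0.05 for c in resc)
        assert unmatched > 0  # these bands betray themselves by shifting

    def test_irrational_ratio_collapses_intersection_to_true_band(self):
        h0 = 0.5
        basis = RFFBasis(h0=h0, omegas=np.array([[2 * np.pi / 1.5]]))
        grid = GridSpec((-20.0, 20.0), 4001)
        d = np.array([0.3])
        base = self._kept_1d(basis, h0, grid, d)
        resc = self._kept_1d(basis, np.sqrt(2) * h0, grid, d)
        common = [c for c in resc if np.min(np.abs(base - c)) < 0.05]
        assert len(common) == 1
        assert abs(common[0] - 0.3) < 0.05  # ... and it is the user's band

    def test_overlap_period_matches_policy_factor(self):
        for n, expected in [(1, 5), (2, 9)]:
            basis = sample_frequencies(1, 0.5, dim=1, seed=3)
            assert bandwidth_overlap_period(basis, n=n) == expected
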