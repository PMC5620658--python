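import numpy as np
import pytest

from support import simplex_grid_min

from csvh.errors import ConfigError, DegenerateModelError
from csvh.kernels import KernelSpec, ShiftedKernelRef, gram_matrix, shifted_gram
from csvh.hypersphere import (
    compute_eta,
    extract_oset,
    fit_health_hypersphere,
    fit_patient_hypersphere,
    kkt_report,
    penalty_c1,
    penalty_c2,
    penalty_weights,
    solve_furthest_hypersphere,
    solve_weighted_svdd,
    support_tau,
)

SPEC = KernelSpec(width=1.0)


def _two_points():
    X = np.array([[0.0, 0.0], [1.0, 0.0]])
    return X, gram_matrix(X, X, SPEC)


class TestPenalties:
    def test_c1_duplicate_point(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        c1 = penalty_c1(X, SPEC)
        assert c1[0] == pytest.approx(1.0)

    def test_c1_half_similarity(self):
        # place the only neighbor so that k = 0.5 exactly
        d = np.sqrt(2 * np.log(2.0))  # exp(-d^2/2) = 1/2 at width 1
        X = np.array([[0.0, 0.0], [d, 0.0]])
        np.testing.assert_allclose(penalty_c1(X, SPEC), np.exp(-1.0), rtol=1e-12)

    def test_c1_isolated_limit(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [100.0, 0.0]])
        c1 = penalty_c1(X, SPEC)
        assert c1[2] == pytest.approx(np.exp(-2.0), rel=1e-9)
        assert (c1 > np.exp(-2.0) - 1e-12).all()

    def test_c1_needs_two_points(self):
        with pytest.raises(ConfigError):
            penalty_c1(np.array([[0.0, 0.0]]), SPEC)

    def test_c2_pure_own_neighborhood(self):
        Xp = np.random.default_rng(0).normal(size=(8, 2)) * 0.1
        Xh = np.full((5, 2), 50.0)
        np.testing.assert_allclose(penalty_c2(Xp, Xh, 5, SPEC), 1.0)

    def test_c2_balanced_neighborhood(self):
        # target patient surrounded by 2 patient + 2 health at equal distance
        Xp = np.array([[0.0, 0.0], [0.1, 0.0], [-0.1, 0.0], [30.0, 30.0], [30.2, 30.0]])
        Xh = np.array([[0.0, 0.1], [0.0, -0.1]])
        c2 = penalty_c2(Xp, Xh, 4, SPEC)
        assert c2[0] == pytest.approx(np.exp(-1.0))

    def test_c2_own_empty_guard(self):
        # lone patient inside a health cluster, its 5 neighbors all health
        Xp = np.array([[0.0, 0.0], [100.0, 100.0]])
        Xh = np.vstack([0.05 * np.eye(2), -0.05 * np.eye(2), [[0.03, 0.03]]])
        c2 = penalty_c2(Xp, Xh, 5, SPEC)
        assert c2[0] == pytest.approx(np.exp(-5.0))

    def test_c2_monotone_in_other_class(self):
        """More other-class neighbors strictly decreases the overlap penalty."""
        rng = np.random.default_rng(1)
        Xp = rng.normal(size=(10, 2)) * 0.2
        far = np.full((10, 2), 20.0) + rng.normal(size=(10, 2)) * 0.2
        near = np.vstack([[[0.05, 0.0]], far[1:]])
        c_far = penalty_c2(np.vstack([[[0.0, 0.0]], Xp[1:]]), far, 5, SPEC)[0]
        c_near = penalty_c2(np.vstack([[[0.0, 0.0]], Xp[1:]]), near, 5, SPEC)[0]
        assert c_near < c_far

    def test_combined_average_and_outlier_ranking(self, blob_dataset):
        ds = blob_dataset
        spec = KernelSpec(1.0)
        pw = penalty_weights(ds.patient_X, ds.health_X, 5, spec)
        np.testing.assert_allclose(pw.c, 0.5 * (pw.c1 + pw.c2))
        assert (pw.c > 0).all() and (pw.c <= 1).all()
        planted = ds.meta["outlier_indices"]
        inliers = [i for i in range(len(pw.c))
                   if i not in planted and i not in ds.meta["overlap_indices"]]
        assert pw.c[planted].max() < np.median(pw.c[inliers])


class TestWeightedSVDD:
    def test_two_point_symmetric(self):
        X, K = _two_points()
        beta, _ = solve_weighted_svdd(K, np.array([1.0, 1.0]))
        np.testing.assert_allclose(beta, [0.5, 0.5], atol=1e-9)

    def test_two_point_clipped(self):
        X, K = _two_points()
        beta, _ = solve_weighted_svdd(K, np.array([0.3, 1.0]))
        np.testing.assert_allclose(beta, [0.3, 0.7], atol=1e-9)

    def test_two_point_radius(self):
        X, K = _two_points()
        sphere = fit_patient_hypersphere(X, np.full((3, 2), 30.0), SPEC, k_nn=2)
        k12 = np.exp(-0.5)
        assert sphere.r_squared == pytest.approx((1 - k12) / 2, rel=1e-6)

    def test_feasibility_rescale_warns(self):
        X, K = _two_points()
        with pytest.warns(UserWarning, match="rescal"):
            beta, _ = solve_weighted_svdd(K, np.array([0.3, 0.3]))
        assert beta.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_matches_grid_oracle(self, n, rng):
        """Solver objective within 1e-4 of dense simplex-grid enumeration."""
        step = 1e-3 if n < 4 else 5e-3
        for trial in range(3):
            X = rng.normal(size=(n, 2))
            K = gram_matrix(X, X, SPEC)
            c = rng.uniform(0.4, 1.0, size=n)
            if c.sum() < 1:
                c = c / c.sum() * 1.1
            beta, obj = solve_weighted_svdd(K, c)
            oracle = simplex_grid_min(K, np.diag(K), c, step=step)
            assert obj <= oracle + 1e-4

    def test_feasibility_invariants(self, rng):
        X = rng.normal(size=(20, 3))
        K = gram_matrix(X, X, SPEC)
        c = rng.uniform(0.1, 1.0, size=20)
        beta, _ = solve_weighted_svdd(K, c)
        assert beta.sum() == pytest.approx(1.0, abs=1e-8)
        assert (beta >= -1e-12).all() and (beta <= c + 1e-8).all()


class TestGeometry:
    def test_free_svs_equidistant(self, blob_model):
        p = blob_model.patient
        tau = support_tau(p.penalties.c)
        free = (p.beta > tau) & (p.beta < p.penalties.c - tau)
        assert free.any()
        np.testing.assert_allclose(p.train_dist_sq[free], p.r_squared, atol=1e-6)

    def test_interior_points_inside(self, blob_model):
        p = blob_model.patient
        tau = support_tau(p.penalties.c)
        interior = p.beta <= tau
        assert (p.train_dist_sq[interior] <= p.r_squared + 1e-6).all()

    def test_distance_unimodal_toward_center(self):
        """Distance to the kernel center decreases along a scan toward it."""
        rng = np.random.default_rng(11)
        X = rng.normal(size=(25, 2)) * 0.3  # compact symmetric blob at origin
        p = fit_patient_hypersphere(X, np.full((5, 2), 40.0), KernelSpec(2.0), k_nn=5)
        centroid = p.X.T @ p.beta
        far = centroid + np.array([5.0, 0.0])
        ts = np.linspace(0, 1, 20)
        line = far[None, :] * (1 - ts[:, None]) + centroid[None, :] * ts[:, None]
        d = p.distance_sq(line)
        assert (np.diff(d) < 1e-9).all()

    def test_distance_matches_shifted_diag(self, blob_model):
        """||phi(q)-a||^2 computed directly equals k'(q,q) under the same beta."""
        from csvh.kernels import shifted_diag
        p = blob_model.patient
        ref = ShiftedKernelRef(kernel=blob_model.kernel, anchor_points=p.X,
                               anchor_weights=p.beta)
        Q = np.random.default_rng(7).normal(size=(30, 2)) * 3
        np.testing.assert_allclose(p.distance_sq(Q), shifted_diag(Q, ref), atol=1e-10)

    def test_oset_empty_for_enclosed_data(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 2)) * 0.2
        sphere = fit_patient_hypersphere(X, np.full((6, 2), 40.0), KernelSpec(2.0), k_nn=5)
        assert sphere.oset_p.size == 0
        assert sphere.p_squared == 0.0

    def test_oset_subset_of_bounded(self, blob_model):
        p = blob_model.patient
        tau = support_tau(p.penalties.c)
        bounded = np.flatnonzero(p.beta >= p.penalties.c - tau)
        assert set(p.oset_p) <= set(bounded)

    def test_extract_oset_requires_positive_slack(self):
        beta = np.array([0.5, 0.5])
        c = np.array([0.5, 1.0])
        dist = np.array([1.0, 0.5])
        oset = extract_oset(beta, c, dist, r_squared=0.9)
        assert list(oset) == [0]


class TestEta:
    def test_single_point_literal_value(self):
        # single anchor: k'(x,x) = 2 - 2k = 0.8 at k = 0.6, so s = 2 - 2*0.8 = 0.4
        d = np.sqrt(-2 * np.log(0.6))
        ref = ShiftedKernelRef(kernel=SPEC, anchor_points=[[0.0, 0.0]], anchor_weights=[1.0])
        eta = compute_eta(np.array([[d, 0.0]]), ref, mode="literal")
        assert eta == pytest.approx(1 / 1.4, rel=1e-9)

    def test_degenerate_scatter_clamps_high(self):
        ref = ShiftedKernelRef(kernel=SPEC, anchor_points=[[0.0, 0.0]], anchor_weights=[1.0])
        eta = compute_eta(np.array([[0.0, 0.0]]), ref, mode="pairwise")
        assert eta == pytest.approx(1 - 1e-6)

    def test_eta_decreases_with_spread(self):
        ref = ShiftedKernelRef(kernel=SPEC, anchor_points=[[0.0, 0.0]], anchor_weights=[1.0])
        rng = np.random.default_rng(5)
        base = rng.normal(size=(10, 2))
        etas = [compute_eta(scale * base + 4.0, ref, mode="pairwise")
                for scale in (0.2, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(etas, etas[1:]))

    def test_eta_in_open_interval(self, rng):
        ref = ShiftedKernelRef(kernel=SPEC, anchor_points=rng.normal(size=(4, 2)),
                               anchor_weights=np.full(4, 0.25))
        for mode in ("literal", "pairwise"):
            eta = compute_eta(rng.normal(size=(8, 2)) * 2, ref, mode=mode)
            assert 0.0 < eta < 1.0


class TestFurthestHypersphere:
    @pytest.fixture()
    def ref(self):
        return ShiftedKernelRef(kernel=SPEC, anchor_points=[[0.0, 0.0]],
                                anchor_weights=[1.0])

    def test_two_point_symmetric(self, ref):
        Xh = np.array([[4.0, 1.0], [4.0, -1.0]])  # symmetric about the anchor axis
        Kp = shifted_gram(Xh, Xh, ref)
        gamma = solve_furthest_hypersphere(0.5 * (Kp + Kp.T), C=1.0, eta=0.3)
        np.testing.assert_allclose(gamma, [0.5, 0.5], atol=1e-8)

    def test_small_eta_recovers_plain_svdd(self, ref, rng):
        Xh = rng.normal(size=(6, 2)) + 3.0
        Kp = shifted_gram(Xh, Xh, ref)
        Kp = 0.5 * (Kp + Kp.T)
        gamma = solve_furthest_hypersphere(Kp, C=1.0, eta=1e-6)
        beta, _ = solve_weighted_svdd(Kp, np.ones(6))
        np.testing.assert_allclose(gamma, beta, atol=1e-5)

    def test_matches_grid_oracle(self, ref, rng):
        for n in (2, 3):
            Xh = rng.normal(size=(n, 2)) + 2.0
            Kp = shifted_gram(Xh, Xh, ref)
            Kp = 0.5 * (Kp + Kp.T)
            eta = 0.4
            gamma = solve_furthest_hypersphere(Kp, C=1.0, eta=eta)
            obj = gamma @ (Kp / (1 - eta)) @ gamma - np.diag(Kp) @ gamma
            oracle = simplex_grid_min(Kp / (1 - eta), np.diag(Kp), np.ones(n), step=1e-3)
            assert obj <= oracle + 1e-4

    def test_free_svs_equidistant_and_b_norm(self, blob_model):
        h = blob_model.health
        n = h.gamma.shape[0]
        upper = np.full(n, max(h.penalty_c, (1 + 1e-6) / n))
        tau = support_tau(upper)
        free = (h.gamma > tau) & (h.gamma < upper - tau)
        if free.any():
            np.testing.assert_allclose(h.train_dist_sq[free], h.z_squared, atol=1e-6)
        assert h.b_norm_squared >= 0
        assert h.z_squared >= 0

    def test_b_norm_grows_with_eta(self, ref, rng):
        from csvh.hypersphere import health_geometry
        Xh = rng.normal(size=(5, 2)) + 3.0
        Kp = shifted_gram(Xh, Xh, ref)
        Kp = 0.5 * (Kp + Kp.T)
        gamma = np.full(5, 0.2)
        norms = [health_geometry(gamma, Kp, eta)[0] for eta in (0.1, 0.5, 0.9)]
        assert norms[0] < norms[1] < norms[2]

    def test_infeasible_cap_rescaled(self, ref):
        Xh = np.array([[3.0, 0.0], [3.5, 0.0]])
        Kp = shifted_gram(Xh, Xh, ref)
        with pytest.warns(UserWarning, match="rescal"):
            gamma = solve_furthest_hypersphere(0.5 * (Kp + Kp.T), C=0.1, eta=0.3)
        assert gamma.sum() == pytest.approx(1.0, abs=1e-8)


class TestKKTReport:
    def test_fitted_models_within_tolerance(self, blob_model):
        for sphere in (blob_model.patient, blob_model.health):
            rep = kkt_report(sphere)
            assert rep.attrs["max_residual"] <= 1e-6
            assert len(rep) == sphere.X.shape[0]

    def test_corrupted_multipliers_flagged(self, blob_model):
        import copy
        bad = copy.deepcopy(blob_model.patient)
        bad.beta = np.roll(bad.beta, 3)
        rep = kkt_report(bad)
        assert rep.attrs["max_residual"] > 1e-6

    def test_status_partition(self, blob_model):
        rep = kkt_report(blob_model.patient)
        assert set(rep["status"]) <= {"interior", "boundary", "outside"}
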