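"""Split Bregman solver pieces against dense-matrix and numeric-prox oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize

from picdl.geometry import Image2D, Sinogram, fbp_reconstruct, forward_project, parallel_geometry
from picdl.l2piccs import (
    Hyperparameters,
    SplitBregmanState,
    apply_K,
    build_rhs,
    grad_x,
    grad_x_T,
    grad_y,
    grad_y_T,
    preset,
    project_positive,
    reconstruct_l2piccs,
    sart_reconstruct,
    shrink_gradients,
    solve_u_subproblem,
    update_bregman,
)
from picdl.metrics import psnr
from picdl.polysim import (
    PriorSpec,
    SamplingScheme,
    fabricate_prior,
    project_monochromatic,
    subsample_projections,
    toy_spectrum,
)


# ---------------------------------------------------------------------------
# independent dense operators (built from first principles, not via grad_x)
# ---------------------------------------------------------------------------


def dense_diff_matrices(nr, nc):
    """Forward-difference matrices with replicate (Neumann) boundary."""
    n = nr * nc
    Dx = np.zeros((n, n))
    Dy = np.zeros((n, n))
    for r in range(nr):
        for c in range(nc):
            i = r * nc + c
            if c < nc - 1:
                Dx[i, i] = -1.0
                Dx[i, i + 1] = 1.0
            if r < nr - 1:
                Dy[i, i] = -1.0
                Dy[i, i + nc] = 1.0
    return Dx, Dy


@pytest.fixture
def dense_setup(micro_geom, rng):
    A = micro_geom.system_matrix().toarray()
    Dx, Dy = dense_diff_matrices(6, 6)
    hp = Hyperparameters(mu=0.7, lam=1.3, alpha=0.4, gamma=0.9,
                         krylov_tol=1e-12, krylov_maxiter=500)
    K = (hp.mu * A.T @ A + hp.lam * (Dx.T @ Dx + Dy.T @ Dy)
         + (2 * hp.alpha + hp.gamma) * np.eye(36))
    return A, Dx, Dy, K, hp


def random_state(rng, geom):
    shp = (geom.n_rows, geom.n_cols)
    return SplitBregmanState(
        u=rng.normal(size=shp),
        dx=rng.normal(size=shp),
        dy=rng.normal(size=shp),
        v=np.abs(rng.normal(size=shp)),
        bx=rng.normal(size=shp),
        by=rng.normal(size=shp),
        bv=rng.normal(size=shp),
        f_k=rng.normal(size=(geom.n_angles, geom.n_det)),
    )


class TestGradients:
    def test_gradient_transposes_are_exact_adjoints(self, rng):
        u = rng.normal(size=(9, 7))
        g = rng.normal(size=(9, 7))
        assert np.vdot(grad_x(u), g) == pytest.approx(np.vdot(u, grad_x_T(g)), rel=1e-12)
        assert np.vdot(grad_y(u), g) == pytest.approx(np.vdot(u, grad_y_T(g)), rel=1e-12)

    def test_neumann_consistency_on_constants(self):
        const = np.full((8, 8), 4.2)
        assert np.all(grad_x(const) == 0)
        assert np.all(grad_x_T(grad_x(const)) == 0)


class TestApplyK:
    def test_identity_limit(self, micro_geom, rng):
        # mu and lam at machine-negligible weight, 2*alpha + gamma = 1
        hp = Hyperparameters(mu=1e-300, lam=1e-300, alpha=0.25, gamma=0.5)
        u = rng.normal(size=(6, 6))
        out = apply_K(Image2D(u), micro_geom, hp).values
        np.testing.assert_allclose(out, u, rtol=1e-10)

    def test_symmetry_dot_product(self, rng):
        g = parallel_geometry(12, angles=np.linspace(0, 360, 10, endpoint=False))
        hp = Hyperparameters(mu=0.8, lam=0.3, alpha=0.2, gamma=1.1)
        worst = 0.0
        for _ in range(100):
            u, w = rng.normal(size=(12, 12)), rng.normal(size=(12, 12))
            ku = apply_K(Image2D(u), g, hp).values
            kw = apply_K(Image2D(w), g, hp).values
            worst = max(worst, abs(np.vdot(ku, w) - np.vdot(u, kw))
                        / (np.linalg.norm(ku) * np.linalg.norm(w)))
        assert worst < 1e-6

    def test_matches_dense_assembly(self, dense_setup, micro_geom, rng):
        A, Dx, Dy, K, hp = dense_setup
        u = rng.normal(size=(6, 6))
        out = apply_K(Image2D(u), micro_geom, hp).values.ravel()
        np.testing.assert_allclose(out, K @ u.ravel(), atol=1e-8)


class TestBuildRhs:
    def test_zero_state_zero_prior_gives_zero(self, micro_geom):
        hp = Hyperparameters()
        z = np.zeros((6, 6))
        state = SplitBregmanState(z, z, z, z, z, z, z, np.zeros((8, micro_geom.n_det)))
        out = build_rhs(state, Image2D(z), micro_geom, hp)
        assert np.all(out.values == 0)

    def test_prior_term_isolation(self, micro_geom, rng):
        # with mu, lam, gamma negligible, r reduces to 2*alpha*u_p
        hp = Hyperparameters(mu=1e-300, lam=1e-300, alpha=0.35, gamma=1e-300)
        state = random_state(rng, micro_geom)
        state.v = np.zeros((6, 6))
        state.bv = np.zeros((6, 6))
        prior = Image2D(rng.normal(size=(6, 6)))
        out = build_rhs(state, prior, micro_geom, hp).values
        np.testing.assert_allclose(out, 2 * 0.35 * prior.values, atol=1e-12)

    def test_matches_dense_recomputation(self, dense_setup, micro_geom, rng):
        A, Dx, Dy, K, hp = dense_setup
        state = random_state(rng, micro_geom)
        prior = Image2D(rng.normal(size=(6, 6)))
        expected = (hp.mu * A.T @ state.f_k.ravel()
                    + 2 * hp.alpha * prior.values.ravel()
                    + hp.lam * Dx.T @ (state.dx - state.bx).ravel()
                    + hp.lam * Dy.T @ (state.dy - state.by).ravel()
                    + hp.gamma * (state.v - state.bv).ravel())
        out = build_rhs(state, prior, micro_geom, hp).values.ravel()
        np.testing.assert_allclose(out, expected, atol=1e-10)


class TestUSubproblem:
    def test_diagonal_closed_form(self, micro_geom, rng):
        # lam = mu -> 0: u = 2*alpha*u_p / (2*alpha + gamma)
        hp = Hyperparameters(mu=1e-300, lam=1e-300, alpha=0.3, gamma=0.8,
                             krylov_tol=1e-12, krylov_maxiter=200)
        z = np.zeros((6, 6))
        state = SplitBregmanState(z.copy(), z, z, z.copy(), z, z, z.copy(),
                                  np.zeros((8, micro_geom.n_det)))
        prior = Image2D(rng.normal(size=(6, 6)))
        u = solve_u_subproblem(state, prior, micro_geom, hp).values
        np.testing.assert_allclose(u, 2 * 0.3 * prior.values / (2 * 0.3 + 0.8), atol=1e-8)

    def test_recovers_manufactured_solution(self, dense_setup, micro_geom, rng):
        A, Dx, Dy, K, hp = dense_setup
        u_star = rng.normal(size=(6, 6))
        # choose a state whose rhs equals K @ u_star: easiest via dense solve
        state = random_state(rng, micro_geom)
        prior = Image2D(rng.normal(size=(6, 6)))
        r = build_rhs(state, prior, micro_geom, hp).values.ravel()
        u_dense = np.linalg.solve(K, r)
        u = solve_u_subproblem(state, prior, micro_geom, hp).values.ravel()
        np.testing.assert_allclose(u, u_dense, atol=1e-6)

    def test_nonfinite_rhs_rejected(self, micro_geom):
        hp = Hyperparameters()
        z = np.zeros((6, 6))
        state = SplitBregmanState(z, z, z, z, z, z, z,
                                  np.full((8, micro_geom.n_det), np.nan))
        with pytest.raises(ValueError):
            solve_u_subproblem(state, Image2D(z), micro_geom, hp)


class TestShrinkage:
    def test_zero_threshold_is_identity(self, rng):
        gx, gy = rng.normal(size=(5, 5)), rng.normal(size=(5, 5))
        dx, dy = shrink_gradients(gx, gy, 0.0)
        np.testing.assert_allclose(dx, gx)
        np.testing.assert_allclose(dy, gy)

    def test_full_shrinkage_below_threshold(self, rng):
        gx, gy = 0.01 * rng.normal(size=(5, 5)), 0.01 * rng.normal(size=(5, 5))
        dx, dy = shrink_gradients(gx, gy, 10.0)
        assert np.all(dx == 0) and np.all(dy == 0)

    def test_three_four_one_example(self):
        dx, dy = shrink_gradients(np.array([[3.0]]), np.array([[4.0]]), 1.0)
        assert dx[0, 0] == pytest.approx(2.4)
        assert dy[0, 0] == pytest.approx(3.2)

    def test_matches_numeric_prox_minimisation(self):
        """Per-pixel oracle: argmin_d t*||d||_2 + 0.5*||d - g||^2."""
        cases = [(3.0, 4.0, 1.0), (0.5, -0.2, 0.0), (0.1, 0.1, 5.0),
                 (-2.0, 1.5, 0.8), (1e-3, 0.0, 2.0), (4.0, -3.0, 2.5)]
        for gx, gy, t in cases:
            def obj(d):
                return t * np.hypot(*d) + 0.5 * ((d[0] - gx) ** 2 + (d[1] - gy) ** 2)

            best = min(
                (minimize(obj, x0, method="Nelder-Mead",
                          options={"xatol": 1e-12, "fatol": 1e-14})
                 for x0 in ([gx, gy], [0.0, 0.0], [0.1, -0.1])),
                key=lambda r: r.fun,
            )
            dx, dy = shrink_gradients(np.array([[gx]]), np.array([[gy]]), t)
            assert obj([dx[0, 0], dy[0, 0]]) <= best.fun + 1e-9
            if np.hypot(gx, gy) > t:  # unique interior minimum
                assert dx[0, 0] == pytest.approx(best.x[0], abs=1e-5)
                assert dy[0, 0] == pytest.approx(best.x[1], abs=1e-5)

    def test_negative_threshold_amplifies(self):
        dx, _ = shrink_gradients(np.array([[3.0]]), np.array([[4.0]]), -5.0)
        assert dx[0, 0] == pytest.approx(3.0 * 2.0)  # (5+5)/5


class TestPositivity:
    def test_projector(self):
        out = project_positive(np.array([-1.0, 2.0]))
        np.testing.assert_array_equal(out, [0.0, 2.0])


class TestBregmanUpdate:
    def test_fixed_point_leaves_iterators_unchanged(self, micro_geom, rng):
        u = np.abs(rng.normal(size=(6, 6)))
        f = forward_project(Image2D(u), micro_geom)
        state = SplitBregmanState(
            u=u.copy(), dx=grad_x(u), dy=grad_y(u), v=u.copy(),
            bx=rng.normal(size=(6, 6)), by=rng.normal(size=(6, 6)),
            bv=rng.normal(size=(6, 6)), f_k=f.values.copy(),
        )
        out = update_bregman(state, Image2D(u), f, micro_geom)
        np.testing.assert_allclose(out.bx, state.bx, atol=1e-12)
        np.testing.assert_allclose(out.by, state.by, atol=1e-12)
        np.testing.assert_allclose(out.bv, state.bv, atol=1e-12)
        np.testing.assert_allclose(out.f_k, state.f_k, atol=1e-10)

    def test_data_addback_term_isolation(self, micro_geom, rng):
        z = np.zeros((6, 6))
        f = Sinogram(rng.normal(size=(8, micro_geom.n_det)), micro_geom.angles)
        f_prev = rng.normal(size=(8, micro_geom.n_det))
        state = SplitBregmanState(z.copy(), z, z, z, z, z, z, f_prev.copy())
        out = update_bregman(state, Image2D(z), f, micro_geom)
        np.testing.assert_allclose(out.f_k, f_prev + f.values, atol=1e-12)


def test_one_outer_iteration_matches_dense_reference(dense_setup, micro_geom, rng):
    """A full Split Bregman cycle agrees with an explicit dense-matrix
    reference in every state member to 1e-6."""
    A, Dx, Dy, K, hp = dense_setup
    prior = Image2D(np.abs(rng.normal(size=(6, 6))))
    f = rng.normal(size=(8, micro_geom.n_det))
    u0 = np.abs(rng.normal(size=(6, 6)))

    # --- reference: dense matrices and explicit formulas only
    ur = u0.ravel().copy()
    dxr = dyr = bxr = byr = bvr = np.zeros(36)
    vr = np.maximum(ur, 0.0)
    fkr = f.ravel().copy()
    r = (hp.mu * A.T @ fkr + 2 * hp.alpha * prior.values.ravel()
         + hp.lam * Dx.T @ (dxr - bxr) + hp.lam * Dy.T @ (dyr - byr)
         + hp.gamma * (vr - bvr))
    u1 = np.linalg.solve(K, r)
    gx, gy = Dx @ u1 + bxr, Dy @ u1 + byr
    s = np.hypot(gx, gy)
    thr = (1 - hp.alpha) / hp.lam
    factor = np.where(s > 0, np.maximum(s - thr, 0.0) / np.where(s > 0, s, 1.0), 0.0)
    dx1, dy1 = factor * gx, factor * gy
    v1 = np.maximum(u1 + bvr, 0.0)
    bx1, by1 = bxr + Dx @ u1 - dx1, byr + Dy @ u1 - dy1
    bv1 = bvr + u1 - v1
    fk1 = fkr + f.ravel() - A @ u1

    # --- implementation: one outer cycle via the public pieces
    state = SplitBregmanState.initial(u0, f)
    u_next = solve_u_subproblem(state, prior, micro_geom, hp)
    ggx = grad_x(u_next.values) + state.bx
    ggy = grad_y(u_next.values) + state.by
    state.dx, state.dy = shrink_gradients(ggx, ggy, thr)
    state.v = project_positive(u_next.values + state.bv)
    state = update_bregman(state, u_next, Sinogram(f, micro_geom.angles), micro_geom)

    for got, want in [
        (state.u, u1), (state.dx, dx1), (state.dy, dy1), (state.v, v1),
        (state.bx, bx1), (state.by, by1), (state.bv, bv1), (state.f_k, fk1),
    ]:
        np.testing.assert_allclose(got.ravel(), want.ravel(), atol=1e-6)


@pytest.fixture(scope="module")
def lnp_case(shell_setup):
    ph, target, geom_full = shell_setup
    sino = subsample_projections(
        project_monochromatic(ph, geom_full, 0, toy_spectrum(1)),
        SamplingScheme("LNP", count_range=(45, 45), seed=1),
    )
    return target, sino, geom_full.with_angles(sino.angles)


class TestReconstruction:
    def test_full_data_with_true_prior_beats_fbp(self, shell_setup):
        ph, target, geom = shell_setup
        sino = project_monochromatic(ph, geom, 0, toy_spectrum(1))
        rec, _ = reconstruct_l2piccs(sino, geom, target, preset("synthetic", n_outer=20))
        assert psnr(rec, target) >= psnr(fbp_reconstruct(sino, geom), target)

    def test_sparse_views_with_degraded_prior_beats_fbp_by_3db(self, lnp_case):
        target, sino, geom = lnp_case
        prior = fabricate_prior(target, PriorSpec(blur_sigma=1.0, seed=1))
        rec, history = reconstruct_l2piccs(sino, geom, prior)
        gain = psnr(rec, target) - psnr(fbp_reconstruct(sino, geom), target)
        assert gain >= 3.0
        # data-consistency pull across outer iterations
        assert history[min(9, len(history) - 1)]["data_residual"] < history[0]["data_residual"]

    def test_prior_hallucination_is_suppressed(self, lnp_case):
        target, sino, geom = lnp_case
        amp = 0.015
        clean = fabricate_prior(target, PriorSpec(blur_sigma=1.0, seed=1))
        hall = fabricate_prior(target, PriorSpec(
            blur_sigma=1.0, hallucinations=[((40, 40), 6.0, amp, "add")], seed=1))
        rec, _ = reconstruct_l2piccs(sino, geom, hall)
        bump = hall.values - clean.values
        footprint = bump > 0.1 * amp
        residual = rec.values - target.values
        assert residual[footprint].max() < 0.5 * bump.max()

    def test_alpha_zero_makes_prior_irrelevant(self, lnp_case, rng):
        target, sino, geom = lnp_case
        hp = preset("synthetic", alpha=0.0, n_outer=10)
        p1 = fabricate_prior(target, PriorSpec(blur_sigma=2.0, seed=3))
        p2 = Image2D(rng.normal(size=target.shape) * 0.01, target.pixel_size)
        r1, _ = reconstruct_l2piccs(sino, geom, p1, hp)
        r2, _ = reconstruct_l2piccs(sino, geom, p2, hp)
        assert np.abs(r1.values - r2.values).max() <= 1e-10

    def test_final_iterate_is_nonnegative(self, lnp_case):
        target, sino, geom = lnp_case
        prior = fabricate_prior(target, PriorSpec(blur_sigma=1.0, seed=1))
        rec, _ = reconstruct_l2piccs(sino, geom, prior, preset("synthetic", n_outer=15))
        assert rec.values.min() >= -1e-8

    def test_prior_pull_is_weakly_monotone_in_alpha(self, shell_setup):
        ph, target, geom = shell_setup
        sino = project_monochromatic(ph, geom, 0, toy_spectrum(1))
        prior = fabricate_prior(target, PriorSpec(blur_sigma=1.0, seed=0))
        dists = []
        for alpha in (0.0, 0.5, 0.9):
            rec, _ = reconstruct_l2piccs(sino, geom, prior,
                                         preset("synthetic", alpha=alpha, n_outer=20))
            dists.append(np.linalg.norm(rec.values - prior.values))
        assert dists[1] <= dists[0] * 1.01
        assert dists[2] <= dists[1] * 1.01

    def test_seed_robustness_of_fabricated_priors(self, lnp_case):
        """Reconstructions from two equally degraded priors are mutually
        closer than either is to its own prior."""
        target, sino, geom = lnp_case
        recs, priors = [], []
        for seed in (33, 42):
            srng = np.random.default_rng(seed)
            hall = [((int(srng.integers(30, 98)), int(srng.integers(30, 98))),
                     float(srng.uniform(4, 7)), 0.01, "add") for _ in range(2)]
            prior = fabricate_prior(target, PriorSpec(blur_sigma=1.0,
                                                      hallucinations=hall, seed=seed))
            rec, _ = reconstruct_l2piccs(sino, geom, prior)
            recs.append(rec)
            priors.append(prior)
        rng_ref = float(np.ptp(target.values))
        mutual = psnr(recs[0].values, recs[1].values, rng_ref)
        own = [psnr(r.values, p.values, rng_ref) for r, p in zip(recs, priors)]
        assert mutual > max(own)


class TestSART:
    def test_zero_data_zero_init_stays_zero(self, micro_geom):
        f = Sinogram(np.zeros((8, micro_geom.n_det)), micro_geom.angles)
        assert np.all(sart_reconstruct(f, micro_geom, n_iter=5).values == 0)

    def test_residual_decreases_monotonically(self, shell_setup):
        ph, target, geom = shell_setup
        f = project_monochromatic(ph, geom, 0, toy_spectrum(1))
        A = geom.system_matrix()
        u = Image2D(np.zeros(target.shape), target.pixel_size)
        resids = []
        for _ in range(10):
            u = sart_reconstruct(f, geom, n_iter=1, relax=1.0, u0=u)
            resids.append(np.linalg.norm(A @ u.values.ravel() - f.values.ravel()))
        assert all(a > b for a, b in zip(resids, resids[1:]))

    def test_full_view_quality_close_to_fbp(self, shell_setup):
        ph, target, geom = shell_setup
        f = project_monochromatic(ph, geom, 0, toy_spectrum(1))
        sart_psnr = psnr(sart_reconstruct(f, geom, n_iter=40, relax=1.0), target)
        fbp_psnr = psnr(fbp_reconstruct(f, geom), target)
        assert sart_psnr >= fbp_psnr - 3.0

    def test_invalid_relaxation_rejected(self, micro_geom):
        f = Sinogram(np.zeros((8, micro_geom.n_det)), micro_geom.angles)
        with pytest.raises(ValueError):
            sart_reconstruct(f, micro_geom, relax=2.5)
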