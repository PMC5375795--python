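"""ADMM solver correctness: RPCA decomposition, exact quadratic subproblem
solutions, the non-convex reconstruction and its convex/zero-filled
baselines."""

import numpy as np
import pytest

from ktnc.metrics import ser
from ktnc.operators import (
    KTMeasurements,
    SamplingMask,
    adjoint_sample,
    forward_sample,
    temporal_ft,
)
from ktnc.phantom import PhantomSpec, generate_phantom, simulate_measurements
from ktnc.sampling import radial_mask
from ktnc.solvers import (
    SolverConfig,
    kt_ncrpca,
    kt_rpca_convex,
    rpca_admm,
    solve_L_quadratic,
    solve_S_quadratic,
    stopping_check,
    zf_idft,
)


class TestStoppingCheck:
    def test_no_change_stops(self):
        f = np.ones((4, 4, 2))
        assert stopping_check(f, f, eps=1e-12, k=1, kmax=100)

    def test_change_above_eps_continues(self):
        f = np.ones((4, 4, 2))
        assert not stopping_check(f * 1.001, f, eps=1e-4, k=1, kmax=100)

    def test_iteration_budget_stops_regardless(self):
        f = np.ones((4, 4, 2))
        assert stopping_check(f * 2.0, f, eps=1e-4, k=101, kmax=100)

    def test_zero_previous_iterate_continues(self):
        assert not stopping_check(np.ones((2, 2, 2)), np.zeros((2, 2, 2)), 1e-4, 1, 10)


class TestRpcaAdmm:
    def test_pure_rank_one_goes_to_L(self, rng):
        x = np.outer(rng.standard_normal(50), rng.standard_normal(40))
        L, S = rpca_admm(x, rho=10.0)
        assert np.linalg.norm(L - x) / np.linalg.norm(x) < 1e-3
        assert np.linalg.norm(S) / np.linalg.norm(x) < 1e-3

    def test_rank2_plus_sparse_recovery(self, rng):
        """Exact-recovery regime: rank-2 plus 5% sparse corruption, separated
        to <= 1e-2 relative error with the balanced weight 1/sqrt(max(m,n))."""
        m, n = 50, 40
        L0 = rng.standard_normal((m, 2)) @ rng.standard_normal((2, n)) / np.sqrt(2)
        S0 = np.zeros((m, n))
        idx = rng.random((m, n)) < 0.05
        S0[idx] = rng.uniform(-2, 2, idx.sum())
        L, S = rpca_admm(L0 + S0, rho=1.0 / np.sqrt(m))
        assert np.linalg.norm(L - L0) / np.linalg.norm(L0) <= 1e-2
        assert np.linalg.norm(S - S0) / np.linalg.norm(S0) <= 1e-2

    def test_zero_matrix(self):
        L, S = rpca_admm(np.zeros((10, 8)))
        assert np.all(L == 0) and np.all(S == 0)

    def test_rejects_nonfinite(self):
        x = np.ones((5, 5))
        x[0, 0] = np.inf
        with pytest.raises(ValueError):
            rpca_admm(x)


def _random_setup(rng, shape=(16, 16, 4), density=0.3):
    sup = rng.random(shape) < density
    sup[shape[0] // 2, shape[1] // 2, :] = True
    mask = SamplingMask(sup)
    d = rng.standard_normal(mask.n_samples) + 1j * rng.standard_normal(mask.n_samples)
    return KTMeasurements(d, mask)


def _cplx(rng, shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


class TestQuadraticSolves:
    def test_L_solution_satisfies_normal_equations(self, rng):
        """(A^H A + a1 I) L == A^H d + a1 P - Z1 - A^H A S to 1e-8."""
        meas = _random_setup(rng)
        shape = meas.image_shape
        S, P, Z1 = _cplx(rng, shape), _cplx(rng, shape), _cplx(rng, shape)
        a1 = 0.37
        L = solve_L_quadratic(S, P, Z1, a1, meas)
        lhs = adjoint_sample(forward_sample(L, meas.mask)).data + a1 * L
        rhs = (
            adjoint_sample(meas).data
            + a1 * P
            - Z1
            - adjoint_sample(forward_sample(S, meas.mask)).data
        )
        assert np.linalg.norm(lhs - rhs) / np.linalg.norm(rhs) < 1e-8

    def test_S_solution_satisfies_normal_equations(self, rng):
        meas = _random_setup(rng)
        shape = meas.image_shape
        L, Q, Z2 = _cplx(rng, shape), _cplx(rng, shape), _cplx(rng, shape)
        a2 = 1.21
        S = solve_S_quadratic(L, Q, Z2, a2, meas)
        lhs = adjoint_sample(forward_sample(S, meas.mask)).data + a2 * S
        from ktnc.operators import temporal_ift

        rhs = (
            adjoint_sample(meas).data
            + temporal_ift(a2 * Q - Z2)
            - adjoint_sample(forward_sample(L, meas.mask)).data
        )
        assert np.linalg.norm(lhs - rhs) / np.linalg.norm(rhs) < 1e-8

    def test_L_consistent_data_recovers_P(self, rng):
        """d = A(P), S = 0, Z1 = 0 -> L = P exactly, for any alpha."""
        shape = (16, 16, 4)
        P = _cplx(rng, shape)
        sup = rng.random(shape) < 0.4
        sup[8, 8, :] = True
        mask = SamplingMask(sup)
        meas = forward_sample(P, mask)
        for a1 in (1e-3, 1.0, 50.0):
            L = solve_L_quadratic(np.zeros(shape), P, np.zeros(shape), a1, meas)
            np.testing.assert_allclose(L, P, atol=1e-8)

    def test_L_penalty_dominated_limit(self, rng):
        """Fully sampled, huge alpha: L -> P - Z1/alpha."""
        shape = (8, 8, 2)
        mask = SamplingMask(np.ones(shape, dtype=bool))
        meas = forward_sample(_cplx(rng, shape), mask)
        P, Z1 = _cplx(rng, shape), _cplx(rng, shape)
        a1 = 1e8
        L = solve_L_quadratic(np.zeros(shape), P, Z1, a1, meas)
        np.testing.assert_allclose(L, P - Z1 / a1, atol=1e-6)

    def test_S_consistent_data_recovers_truth(self, rng):
        shape = (16, 16, 4)
        S_true, Lk1, Z2 = _cplx(rng, shape), _cplx(rng, shape), _cplx(rng, shape)
        sup = rng.random(shape) < 0.4
        sup[8, 8, :] = True
        mask = SamplingMask(sup)
        meas = forward_sample(Lk1 + S_true, mask)
        a2 = 0.9
        Q = temporal_ft(S_true) + Z2 / a2
        S = solve_S_quadratic(Lk1, Q, Z2, a2, meas)
        np.testing.assert_allclose(S, S_true, atol=1e-8)

    def test_zero_rhs_gives_zero(self, rng):
        meas = _random_setup(rng)
        z = np.zeros(meas.image_shape, complex)
        meas0 = KTMeasurements(np.zeros(meas.mask.n_samples, complex), meas.mask)
        S = solve_S_quadratic(z, z, z, 1.0, meas0)
        assert np.abs(S).max() < 1e-14

    def test_rejects_zero_alpha(self, rng):
        meas = _random_setup(rng)
        z = np.zeros(meas.image_shape, complex)
        with pytest.raises(ValueError):
            solve_L_quadratic(z, z, z, 0.0, meas)


class TestKtNcrpca:
    def test_output_sum_identity(self, small_meas):
        res = kt_ncrpca(small_meas)
        assert np.array_equal(res.F_star.data, res.L_star.data + res.S_star.data)

    def test_deterministic(self, small_meas):
        a = kt_ncrpca(small_meas)
        b = kt_ncrpca(small_meas)
        assert np.array_equal(a.F_star.data, b.F_star.data)
        assert a.iterations == b.iterations

    def test_convex_limit_matches_independent_solver(self, small_meas):
        """p = q = 1 reproduces the separately coded convex reconstruction."""
        cfg = SolverConfig(p=1.0, q=1.0)
        a = kt_ncrpca(small_meas, cfg)
        b = kt_rpca_convex(small_meas, cfg)
        rel = np.linalg.norm(a.F_star.data - b.F_star.data) / np.linalg.norm(b.F_star.data)
        assert rel <= 1e-8

    def test_fully_sampled_weak_regularization_near_exact(self, small_phantom, full_mask):
        F, _, _ = small_phantom
        meas = simulate_measurements(F, full_mask)
        res = kt_ncrpca(meas, SolverConfig(mu1=1e-6))
        assert ser(res.F_star, F) >= 50.0

    def test_beats_zero_filling_by_3db(self, small_phantom, small_meas):
        F, _, _ = small_phantom
        res = kt_ncrpca(small_meas, truth=F)
        assert ser(res.F_star, F) >= ser(zf_idft(small_meas), F) + 3.0

    def test_ser_rises_then_plateaus(self, small_phantom, small_meas):
        F, _, _ = small_phantom
        h = kt_ncrpca(small_meas, truth=F).history["ser_db"]
        assert len(h) >= 10
        assert h[-1] >= h[0]
        assert max(h[-10:]) - min(h[-10:]) < 0.5

    def test_more_rays_never_hurt_on_average(self):
        """Mean SER over 3 seeds is nondecreasing across 8 -> 16 -> 32 rays."""
        means = []
        for rays in (8, 16, 32):
            vals = []
            for seed in (1, 2, 3):
                F, _, _ = generate_phantom(PhantomSpec(Nx=32, Ny=32, Nt=16, seed=seed))
                meas = simulate_measurements(F, radial_mask(32, 32, 16, rays, seed=seed))
                vals.append(ser(kt_ncrpca(meas).F_star, F))
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]

    def test_iteration_cap_respected(self, small_meas):
        res = kt_ncrpca(small_meas, SolverConfig(eps=1e-16, kmax=7))
        assert res.iterations == 7


class TestZfIdft:
    def test_fully_sampled_exact(self, small_phantom, full_mask):
        F, _, _ = small_phantom
        rec = zf_idft(simulate_measurements(F, full_mask))
        np.testing.assert_allclose(rec.data, F.data, atol=1e-10)

    def test_zero_data_zero_image(self, full_mask):
        meas = KTMeasurements(np.zeros(full_mask.n_samples, complex), full_mask)
        assert np.all(zf_idft(meas).data == 0)
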