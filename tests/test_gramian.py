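import numpy as np
import pytest
from scipy.linalg import expm

import netctrl as nc

from conftest import make_ec, stable_random_matrix


def quadrature_gramian(A, B, t_max=200.0, dt=0.01):
    """Independent oracle: composite Simpson quadrature of the Gramian
    integrand e^{At} B B' e^{A't} on a fine grid."""
    n = A.shape[0]
    P = expm(A * dt)
    M = B.copy()
    W = np.zeros((n, n))
    steps = int(round(t_max / dt))
    assert steps % 2 == 0
    for k in range(steps + 1):
        w = 1.0 if k in (0, steps) else (4.0 if k % 2 else 2.0)
        W += w * (M @ M.T)
        M = P @ M
    return W * dt / 3.0


class TestControllabilityGramian:
    def test_scalar_closed_form(self, scalar_ec):
        g = nc.controllability_gramian(scalar_ec, nc.DriverSet((0,)))
        np.testing.assert_allclose(g.W, [[1.0]], atol=1e-12)
        assert g.practically_controllable

    def test_quadrature_oracle(self):
        A = stable_random_matrix(4, seed=1, margin=0.3)
        ec = make_ec(A)
        g = nc.controllability_gramian(ec, nc.DriverSet((0,)))
        B = np.zeros((4, 1))
        B[0, 0] = 1.0
        W_or = quadrature_gramian(A, B)
        rel = np.linalg.norm(g.W - W_or) / np.linalg.norm(W_or)
        assert rel < 1e-6

    def test_broadcast_column_not_practically_controllable(self, big_cohort):
        ec = big_cohort.subjects[0]
        g = nc.gramian_from_input_matrix(ec, np.ones((ec.n, 1)))
        assert g.lambda_min < 1e-12
        assert not g.practically_controllable

    def test_unstable_rejected(self):
        with pytest.raises(nc.StabilityError):
            nc.gramian_from_input_matrix(np.array([[0.1]]), np.ones((1, 1)))

    def test_empty_driver_set_rejected(self):
        with pytest.raises(nc.ParameterError):
            nc.DriverSet(())

    def test_symmetry_and_psd(self, small_cohort):
        g = nc.controllability_gramian(small_cohort.subjects[0],
                                       nc.DriverSet((0, 3, 7)))
        np.testing.assert_allclose(g.W, g.W.T, atol=1e-8)
        assert g.eigenvalues.min() >= -1e-8
        assert g.lambda_min == g.eigenvalues.min()


class TestObservabilityGramian:
    def test_scalar(self, scalar_ec):
        m = nc.observability_gramian(scalar_ec, nc.TargetSet((0,)))
        np.testing.assert_allclose(m.W, [[1.0]], atol=1e-12)

    def test_duality_with_transpose(self):
        A = stable_random_matrix(5, seed=2)
        obs = nc.observability_gramian(A, nc.TargetSet((2,)))
        ctrl = nc.controllability_gramian(A.T, nc.DriverSet((2,)))
        np.testing.assert_allclose(obs.W, ctrl.W, atol=1e-10)

    def test_quadrature_oracle(self):
        A = stable_random_matrix(5, seed=3)
        m = nc.observability_gramian(A, nc.TargetSet((1,)))
        C = np.zeros((5, 1))
        C[1, 0] = 1.0
        M_or = quadrature_gramian(A.T, C)
        rel = np.linalg.norm(m.W - M_or) / np.linalg.norm(M_or)
        assert rel < 1e-6


class TestTargetGramian:
    def test_all_targets_is_identity_projection(self, small_cohort):
        ec = small_cohort.subjects[0]
        g = nc.controllability_gramian(ec, nc.DriverSet((0, 1, 2)))
        wc = nc.target_gramian(g, nc.TargetSet(tuple(range(ec.n))))
        np.testing.assert_array_equal(wc.W, g.W)

    def test_single_target_scalar(self, small_cohort):
        g = nc.controllability_gramian(small_cohort.subjects[0], nc.DriverSet((0,)))
        wc = nc.target_gramian(g, nc.TargetSet((4,)))
        assert wc.W.shape == (1, 1)
        assert wc.W[0, 0] == g.W[4, 4]

    def test_interlacing(self):
        for seed in range(20):
            A = stable_random_matrix(6, seed=seed)
            g = nc.controllability_gramian(A, nc.DriverSet((0, 1)))
            wc = nc.target_gramian(g, nc.TargetSet((2, 3, 4)))
            assert wc.lambda_min >= g.lambda_min - 1e-10

    def test_requires_controllability_kind(self, scalar_ec):
        m = nc.observability_gramian(scalar_ec, nc.TargetSet((0,)))
        with pytest.raises(nc.ParameterError):
            nc.target_gramian(m, nc.TargetSet((0,)))

    def test_out_of_range_target(self, scalar_ec):
        g = nc.controllability_gramian(scalar_ec, nc.DriverSet((0,)))
        with pytest.raises(IndexError):
            nc.target_gramian(g, nc.TargetSet((5,)))


class TestWorstCaseEnergy:
    def test_scalar(self, scalar_ec):
        g = nc.controllability_gramian(scalar_ec, nc.DriverSet((0,)))
        assert nc.worst_case_energy(g).energy == pytest.approx(1.0)

    def test_tiny_lambda_min_is_infinite(self):
        from netctrl.gramian import _gramian_result
        g = _gramian_result(np.diag([1.0, 1e-13]), "controllability")
        e = nc.worst_case_energy(g)
        assert e.energy == np.inf and e.log10_energy == np.inf

    def test_driver_monotonicity(self):
        # Loewner monotonicity: adding a driver never increases the energy
        rng = np.random.default_rng(0)
        for trial in range(50):
            A = stable_random_matrix(6, seed=trial + 100)
            base = tuple(rng.choice(6, size=2, replace=False))
            extra = int(rng.choice([i for i in range(6) if i not in base]))
            e1 = nc.worst_case_energy(
                nc.controllability_gramian(A, nc.DriverSet(base))).energy
            e2 = nc.worst_case_energy(
                nc.controllability_gramian(A, nc.DriverSet(base + (extra,)))).energy
            assert e2 <= e1 * (1 + 1e-8)


class TestPairwiseEnergies:
    def test_decoupled_closed_form(self):
        ec = make_ec(-0.5 * np.eye(3))
        E = nc.pairwise_energies(ec).E
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(np.diag(E), 1.0)  # 2a with a = 0.5
        assert np.all(np.isinf(E[off]))

    def test_chain_closed_form(self, chain_ec):
        # int c^2 t^2 e^{-2t} dt = c^2/4 = 1 for c = 2
        E = nc.pairwise_energies(chain_ec).E
        assert E[0, 1] == pytest.approx(1.0, rel=1e-10)

    def test_matches_general_gramian_path(self, small_cohort):
        ec = small_cohort.subjects[0]
        E = nc.pairwise_energies(ec).E
        rng = np.random.default_rng(1)
        for _ in range(30):
            i, j = rng.integers(0, ec.n, size=2)
            g = nc.controllability_gramian(ec, nc.DriverSet((int(i),)))
            wc = nc.target_gramian(g, nc.TargetSet((int(j),)))
            e = nc.worst_case_energy(wc).energy
            if np.isfinite(e):
                assert E[i, j] == pytest.approx(e, rel=1e-8)

    def test_accessibility_scaling(self, small_cohort):
        # driver weight beta multiplies the Gramian by beta^2 exactly
        ec = small_cohort.subjects[0]
        g1 = nc.controllability_gramian(ec, nc.DriverSet((2,)))
        gb = nc.controllability_gramian(ec, nc.DriverSet((2,), weights=(0.5,)))
        np.testing.assert_allclose(gb.W, 0.25 * g1.W, atol=1e-12)


class TestFiniteHorizonGramian:
    def test_scalar_closed_form(self):
        ec = make_ec(np.array([[-0.5]]))
        g = nc.finite_horizon_gramian(ec, nc.DriverSet((0,)), t_f=20.0, dt=0.001)
        assert g.W[0, 0] == pytest.approx(1 - np.exp(-20), abs=1e-6)

    def test_converges_to_lyapunov(self):
        A = stable_random_matrix(4, seed=5)
        ec = make_ec(A)
        winf = nc.controllability_gramian(ec, nc.DriverSet((0, 1))).W
        errs = [np.linalg.norm(
            nc.finite_horizon_gramian(ec, nc.DriverSet((0, 1)), tf, 0.01).W - winf)
            for tf in (10.0, 20.0, 50.0)]
        assert errs[0] > errs[1] > errs[2]

    def test_psd_increment(self):
        A = stable_random_matrix(4, seed=6)
        ec = make_ec(A)
        g1 = nc.finite_horizon_gramian(ec, nc.DriverSet((0,)), 5.0, 0.005)
        g2 = nc.finite_horizon_gramian(ec, nc.DriverSet((0,)), 10.0, 0.005)
        assert np.linalg.eigvalsh(g2.W - g1.W).min() > -1e-8

    def test_bad_dt(self, scalar_ec):
        with pytest.raises(nc.ParameterError):
            nc.finite_horizon_gramian(scalar_ec, nc.DriverSet((0,)), 1.0, 2.0)


class TestMinEnergyInput:
    def test_nothing_to_steer(self):
        A = stable_random_matrix(4, seed=7)
        ec = make_ec(A)
        tg = nc.TargetSet((1, 2))
        x0 = np.zeros(4)
        ci = nc.min_energy_input(ec, nc.DriverSet((0, 3)), tg, x0,
                                 np.zeros(2), t_f=20.0)
        assert ci.realized_energy == pytest.approx(0.0, abs=1e-12)
        assert np.abs(ci.u).max() == pytest.approx(0.0, abs=1e-12)

    def test_forward_simulation_reaches_target(self):
        rng = np.random.default_rng(3)
        A = stable_random_matrix(6, seed=8)
        ec = make_ec(A)
        dr, tg = nc.DriverSet((0, 1)), nc.TargetSet((3, 4))
        x0 = rng.normal(size=6)
        yf = np.array([1.0, 1.0])
        ci = nc.min_energy_input(ec, dr, tg, x0, yf, t_f=30.0, dt=0.005)
        traj = nc.simulate_controlled(ec, dr, ci, x0)
        assert np.linalg.norm(traj[-1][[3, 4]] - yf) < 1e-4

    def test_energy_quadratic_form_identity(self):
        A = stable_random_matrix(5, seed=9)
        ec = make_ec(A)
        ci = nc.min_energy_input(ec, nc.DriverSet((0, 2)), nc.TargetSet((1, 4)),
                                 np.zeros(5), np.array([0.5, -1.0]), t_f=40.0)
        assert ci.realized_energy == pytest.approx(ci.predicted_energy, rel=0.01)

    def test_worst_case_bound(self):
        rng = np.random.default_rng(11)
        for trial in range(30):
            A = stable_random_matrix(5, seed=trial + 400)
            ec = make_ec(A)
            dr, tg = nc.DriverSet((0, 1, 2)), nc.TargetSet((3, 4))
            yf = rng.normal(size=2)
            yf /= np.linalg.norm(yf)
            ci = nc.min_energy_input(ec, dr, tg, np.zeros(5), yf, t_f=60.0,
                                     dt=0.02)
            from netctrl.gramian import _exact_finite_gramian
            B = dr.b_matrix(5)
            C = tg.c_matrix(5)
            Wc = C @ _exact_finite_gramian(A, B, 60.0) @ C.T
            bound = 1.0 / np.linalg.eigvalsh(Wc).min()
            assert ci.realized_energy <= bound * 1.01 + 1e-9

    def test_singular_target_gramian_reports_lambda(self):
        # decoupled nodes: driver 0 cannot reach node 1 at all
        ec = make_ec(-np.eye(2))
        with pytest.raises(nc.NotTargetControllableError) as exc:
            nc.min_energy_input(ec, nc.DriverSet((0,)), nc.TargetSet((1,)),
                                np.zeros(2), np.array([1.0]), t_f=10.0)
        assert exc.value.lambda_min <= 1e-12


class TestSimulateControlled:
    def test_zero_input_free_response(self):
        A = stable_random_matrix(4, seed=10)
        ec = make_ec(A)
        t = np.arange(0.0, 5.0001, 0.01)
        ci = nc.ControlInput(time_grid=t, u=np.zeros((len(t), 1)),
                             realized_energy=0.0, x0=np.ones(4),
                             yf=np.zeros(1))
        traj = nc.simulate_controlled(ec, nc.DriverSet((0,)), ci, np.ones(4))
        expected = np.array([expm(A * tk) @ np.ones(4) for tk in t[::100]])
        np.testing.assert_allclose(traj[::100], expected, atol=1e-8)

    def test_scalar_constant_input(self):
        ec = make_ec(np.array([[-1.0]]))
        t = np.arange(0.0, 4.0001, 0.001)
        ci = nc.ControlInput(time_grid=t, u=np.ones((len(t), 1)),
                             realized_energy=4.0, x0=np.array([2.0]),
                             yf=np.zeros(1))
        traj = nc.simulate_controlled(ec, nc.DriverSet((0,)), ci, np.array([2.0]))
        closed = 2.0 * np.exp(-t) + (1 - np.exp(-t))
        np.testing.assert_allclose(traj[:, 0], closed, atol=1e-9)

    def test_shape_mismatch(self, scalar_ec):
        t = np.arange(0.0, 1.001, 0.1)
        ci = nc.ControlInput(time_grid=t, u=np.zeros((len(t), 2)),
                             realized_energy=0.0, x0=np.zeros(1),
                             yf=np.zeros(1))
        with pytest.raises(nc.ParameterError):
            nc.simulate_controlled(scalar_ec, nc.DriverSet((0,)), ci, np.zeros(1))


class TestTargetMonotonicity:
    def test_growing_targets_never_decrease_energy(self):
        for seed in range(10):
            A = stable_random_matrix(7, seed=seed + 600)
            g = nc.controllability_gramian(A, nc.DriverSet((0, 1, 2)))
            prev = 0.0
            for size in (1, 2, 4, 6):
                wc = nc.target_gramian(g, nc.TargetSet(tuple(range(size))))
                e = nc.worst_case_energy(wc).energy
                assert e >= prev * (1 - 1e-10)
                prev = e
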