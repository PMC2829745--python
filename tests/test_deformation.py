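"""Multiplicative-integral solvers for dF/dt = L F and material tracking."""

import numpy as np
import pytest
from scipy.linalg import expm

from tagstrain import deformation as dfm
from tagstrain.phantom import (ImageGrid, PhantomModel, analytic_deformation,
                               analytic_velocity_fields, default_annulus_model)


class TestSteps:
    def test_linear_step_examples(self):
        np.testing.assert_array_equal(dfm.step_linear(np.eye(2), np.zeros((2, 2)), 0.3), np.eye(2))
        F = dfm.step_linear(np.eye(2), np.array([[0.0, 0.5], [0.0, 0.0]]), 1.0)
        np.testing.assert_array_equal(F, [[1.0, 0.5], [0.0, 1.0]])

    def test_linear_step_determinant_identity(self, rng):
        """det(I + L dt) = 1 + dt tr L + dt^2 det L for 2x2 matrices."""
        for _ in range(50):
            L = rng.uniform(-1, 1, (2, 2))
            dt = rng.uniform(0.01, 0.5)
            lhs = np.linalg.det(dfm.step_linear(np.eye(2), L, dt))
            rhs = 1.0 + dt * np.trace(L) + dt**2 * np.linalg.det(L)
            assert abs(lhs - rhs) < 1e-12

    def test_exponential_of_nilpotent_truncates_exactly(self):
        L = np.array([[0.0, 0.5], [0.0, 0.0]])
        F = dfm.step_exponential(np.eye(2), L, 1.0)
        np.testing.assert_array_equal(F, [[1.0, 0.5], [0.0, 1.0]])

    def test_exponential_of_spin_is_rotation(self):
        omega = 0.7
        L = np.array([[0.0, -omega], [omega, 0.0]])
        F = dfm.step_exponential(np.eye(2), L, 1.0)
        c, s = np.cos(omega), np.sin(omega)
        np.testing.assert_allclose(F, [[c, -s], [s, c]], atol=1e-14)
        assert np.abs(F @ F.T - np.eye(2)).max() < 1e-12

    def test_exponential_preserves_volume_for_trace_free(self, rng):
        """det exp(A) = exp tr A, so trace-free steps keep det F fixed."""
        for _ in range(50):
            a, b, c = rng.uniform(-1, 1, 3)
            L = np.array([[a, b], [c, -a]])
            F_prev = rng.uniform(-1, 1, (2, 2)) + 2 * np.eye(2)
            F = dfm.step_exponential(F_prev, L, 0.2)
            assert abs(np.linalg.det(F) - np.linalg.det(F_prev)) < 1e-12

    def test_closed_form_matches_scipy_expm(self, rng):
        """Cayley-Hamilton 2x2 exponential vs the general-purpose oracle."""
        for _ in range(100):
            A = rng.uniform(-2, 2, (2, 2))
            np.testing.assert_allclose(dfm.expm2(A), expm(A), atol=1e-12)
        # near-degenerate discriminant exercises the series branch
        A = np.array([[1.0, 1e-8], [0.0, 1.0 + 1e-9]])
        np.testing.assert_allclose(dfm.expm2(A), expm(A), atol=1e-12)


class TestCompose:
    def test_identity_neutral(self, rng):
        F = rng.uniform(-1, 1, (2, 2))
        np.testing.assert_array_equal(dfm.compose(F, np.eye(2)), F)

    def test_rotations_add(self):
        def R(a):
            return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])

        np.testing.assert_allclose(dfm.compose(R(0.3), R(0.5)), R(0.8), atol=1e-14)


def _constant_fields(L_by_interval, n_seeds=1, shape=(8, 8), spacing=1.0, dt=0.05):
    """Spatially uniform velocity-gradient fields (v = 0) for solver tests."""
    from tagstrain.motion import VelocityGradientField

    fields = []
    for k, L in enumerate(L_by_interval):
        fields.append(VelocityGradientField(
            v=np.zeros(shape + (2,)),
            L=np.broadcast_to(L, shape + (2, 2)).copy(),
            selected_scale=np.zeros(shape),
            condition_number=np.ones(shape),
            validity=np.ones(shape, dtype=bool),
            time=(k + 0.5) * dt,
            spacing=spacing,
        ))
    return fields


def _center_traj(n_intervals, n_seeds=1):
    pos = np.broadcast_to(np.array([3.0, 3.0]), (n_intervals + 1, n_seeds, 2)).copy()
    return dfm.MaterialTrajectory(positions=pos, in_domain=np.ones((n_intervals + 1, n_seeds), bool))


class TestIntegration:
    def test_zero_gradient_keeps_identity(self):
        grid = dfm.TimeGrid.uniform(0.0, 0.05, 5)
        fields = _constant_fields([np.zeros((2, 2))] * 5)
        out = dfm.integrate_deformation(fields, _center_traj(5), grid)
        np.testing.assert_array_equal(out.F, np.broadcast_to(np.eye(2), out.F.shape))

    @pytest.mark.parametrize("method", ["exp_product"])
    def test_stationary_flow_closed_form(self, method):
        """Constant L0: the ordered exponential collapses to exp((t - t0) L0)."""
        L0 = np.array([[0.1, -0.3], [0.2, -0.05]])
        n, dt = 12, 0.05
        grid = dfm.TimeGrid.uniform(0.0, dt, n)
        fields = _constant_fields([L0] * n, dt=dt)
        out = dfm.integrate_deformation(fields, _center_traj(n), grid, method=method)
        for k in range(n + 1):
            np.testing.assert_allclose(out.F[k, 0], expm(k * dt * L0), atol=1e-10)

    def test_split_and_compose_reproduces_product_bitwise(self, rng):
        """Continuing the ordered product from F(t1, t0) equals the unsplit run."""
        n, dt = 10, 0.05
        Ls = [rng.uniform(-0.5, 0.5, (2, 2)) for _ in range(n)]
        grid = dfm.TimeGrid.uniform(0.0, dt, n)
        fields = _constant_fields(Ls, dt=dt)
        full = dfm.integrate_deformation(fields, _center_traj(n), grid, method="linear_product")
        for split in (3, 7):
            # same partition points as the full run (not re-derived arithmetic)
            grid2 = dfm.TimeGrid(t0=grid.all_times[split],
                                 frame_times=grid.frame_times[split:])
            rest = dfm.integrate_deformation(
                fields[split:], _center_traj(n - split), grid2,
                method="linear_product", F0=full.F[split],
            )
            np.testing.assert_array_equal(rest.F[-1], full.F[-1])

    def test_volume_identity_trace_free(self, rng):
        """Trace-free L: exp product keeps det F = 1 exactly; the linear
        product's det error shrinks linearly with dt."""
        n = 20
        Ls = [np.array([[a, b], [c, -a]])
              for a, b, c in rng.uniform(-0.5, 0.5, (n, 3))]

        def run(method, refine):
            dt = 0.05 / refine
            Lr = [L for L in Ls for _ in range(refine)]
            grid = dfm.TimeGrid.uniform(0.0, dt, n * refine)
            fields = _constant_fields(Lr, dt=dt)
            out = dfm.integrate_deformation(fields, _center_traj(n * refine), grid, method=method)
            return np.abs(np.linalg.det(out.F[:, 0]) - 1.0).max()

        assert run("exp_product", 1) < 1e-10
        errs = [run("linear_product", r) for r in (1, 2, 4)]
        assert errs[0] > errs[1] > errs[2]
        assert errs[0] / errs[2] > 2.5  # ~first-order in dt

    def test_linear_and_exponential_converge_together(self):
        """On the annulus driven by exact L, both products approach the
        analytic F as dt shrinks, at first order or better."""
        model = default_annulus_model(grid_size=64, r_inner=12.0, r_outer=22.0,
                                      lam_end=-40.0, phi_end=0.15)
        grid_img = ImageGrid((64, 64), 1.0)
        X = np.array([[31.5 + 17.0, 31.5], [31.5, 31.5 - 15.0]])
        F_true = analytic_deformation(model, X, model.time_span[1])
        errs = {}
        for n_frames in (11, 21, 41):
            fields = analytic_velocity_fields(model, grid_img, n_frames)
            dt = (model.time_span[1] - model.time_span[0]) / (n_frames - 1)
            tg = dfm.TimeGrid.uniform(0.0, dt, n_frames - 1)
            traj = dfm.track_material_points(fields, X, tg)
            for method in ("linear_product", "exp_product"):
                out = dfm.integrate_deformation(fields, traj, tg, method=method)
                errs[(method, n_frames)] = np.abs(out.F[-1] - F_true).max()
        for method in ("linear_product", "exp_product"):
            e = [errs[(method, n)] for n in (11, 21, 41)]
            assert e[0] > e[1] > e[2]
        # the two products agree ever more closely as dt -> 0
        gap = [abs(errs[("linear_product", n)] - errs[("exp_product", n)]) for n in (11, 41)]
        assert gap[1] < gap[0]

    def test_annulus_ground_truth_recovery(self):
        """Driven by exact L, end-systolic F matches the analytic oracle to
        ~2% (median Frobenius) at the default frame count."""
        model = default_annulus_model()
        grid_img = ImageGrid((128, 128), 1.0)
        fields = analytic_velocity_fields(model, grid_img, 21)
        dt = 0.4 / 20
        tg = dfm.TimeGrid.uniform(0.0, dt, 20)
        rng = np.random.default_rng(5)
        ang = rng.uniform(0, 2 * np.pi, 200)
        R = rng.uniform(27.0, 43.0, 200)
        X = np.stack([63.5 + R * np.cos(ang), 63.5 + R * np.sin(ang)], axis=-1)
        traj = dfm.track_material_points(fields, X, tg)
        out = dfm.integrate_deformation(fields, traj, tg, method="linear_product")
        F_true = analytic_deformation(model, X, 0.4)
        rel = (np.linalg.norm(out.F[-1] - F_true, axis=(-1, -2))
               / np.linalg.norm(F_true, axis=(-1, -2)))
        assert np.median(rel) < 0.02


class TestMatricant:
    def test_order_one_of_zero_gradient_is_identity(self):
        grid = dfm.TimeGrid.uniform(0.0, 0.1, 4)
        fields = _constant_fields([np.zeros((2, 2))] * 4, dt=0.1)
        out = dfm.matricant_series(fields, _center_traj(4), grid, order=1)
        np.testing.assert_array_equal(out.F, np.broadcast_to(np.eye(2), out.F.shape))

    def test_order_three_matches_exponential_for_small_exposure(self):
        """|L| T = 0.1: the truncation remainder is below 1e-5."""
        L0 = 0.1 * np.array([[0.3, -1.0], [0.8, -0.3]])
        L0 *= 0.1 / (np.linalg.norm(L0, 2) * 1.0)  # ||L0|| * T = 0.1 with T = 1
        n, dt = 20, 0.05
        grid = dfm.TimeGrid.uniform(0.0, dt, n)
        fields = _constant_fields([L0] * n, dt=dt)
        traj = _center_traj(n)
        series = dfm.matricant_series(fields, traj, grid, order=3)
        product = dfm.integrate_deformation(fields, traj, grid, method="exp_product")
        assert np.abs(series.F[-1] - product.F[-1]).max() < 1e-5

    def test_time_ordering_matters_beyond_order_two(self):
        """Non-commuting time-varying L: successive truncation orders differ."""
        A = np.array([[0.0, 1.0], [0.0, 0.0]])
        B = np.array([[0.0, 0.0], [1.0, 0.0]])
        Ls = [A, B] * 5
        grid = dfm.TimeGrid.uniform(0.0, 0.1, 10)
        fields = _constant_fields(Ls, dt=0.1)
        traj = _center_traj(10)
        f2 = dfm.matricant_series(fields, traj, grid, order=2)
        f3 = dfm.matricant_series(fields, traj, grid, order=3)
        assert np.abs(f2.F[-1] - f3.F[-1]).max() > 0

    def test_rejects_bad_order(self):
        with pytest.raises(ValueError):
            dfm.matricant_series(_constant_fields([np.eye(2)]),
                                 _center_traj(1), dfm.TimeGrid.uniform(0, 0.1, 1), order=4)


class TestTracking:
    def test_zero_velocity_keeps_seeds(self):
        grid = dfm.TimeGrid.uniform(0.0, 0.05, 6)
        fields = _constant_fields([np.zeros((2, 2))] * 6)
        traj = dfm.track_material_points(fields, np.array([[3.0, 2.0]]), grid)
        np.testing.assert_array_equal(traj.positions,
                                      np.broadcast_to([3.0, 2.0], (7, 1, 2)))

    def test_uniform_translation_is_exact(self):
        from tagstrain.motion import VelocityGradientField

        v = np.array([1.5, -1.0])
        shape = (16, 16)
        fields = [VelocityGradientField(
            v=np.broadcast_to(v, shape + (2,)).copy(),
            L=np.zeros(shape + (2, 2)),
            selected_scale=np.zeros(shape),
            condition_number=np.ones(shape),
            validity=np.ones(shape, bool), time=0.5, spacing=1.0)
            for _ in range(4)]
        grid = dfm.TimeGrid.uniform(0.0, 0.5, 4)
        traj = dfm.track_material_points(fields, np.array([[4.0, 8.0]]), grid)
        for k in range(5):
            np.testing.assert_allclose(traj.positions[k, 0],
                                       [4.0, 8.0] + v * 0.5 * k, atol=1e-12)

    def test_rotation_radius_drift_is_small(self):
        """Explicit Euler on a circle grows the radius by < 0.5% over systole."""
        omega = 0.5
        model = PhantomModel("rigid_rotation", {"omega": omega},
                             center=(31.5, 31.5), time_span=(0.0, 0.4))
        fields = analytic_velocity_fields(model, ImageGrid((64, 64), 1.0), 21)
        grid = dfm.TimeGrid.uniform(0.0, 0.02, 20)
        X = np.array([[31.5 + 20.0, 31.5]])
        traj = dfm.track_material_points(fields, X, grid)
        r_end = np.linalg.norm(traj.positions[-1, 0] - [31.5, 31.5])
        assert abs(r_end - 20.0) / 20.0 < 0.005

    def test_midpoint_scheme_reduces_rotation_drift(self):
        omega = 0.5
        model = PhantomModel("rigid_rotation", {"omega": omega},
                             center=(31.5, 31.5), time_span=(0.0, 0.4))
        fields = analytic_velocity_fields(model, ImageGrid((64, 64), 1.0), 21)
        grid = dfm.TimeGrid.uniform(0.0, 0.02, 20)
        X = np.array([[31.5 + 20.0, 31.5]])
        drift = {}
        for scheme in ("euler", "midpoint"):
            traj = dfm.track_material_points(fields, X, grid, scheme=scheme)
            drift[scheme] = abs(np.linalg.norm(traj.positions[-1, 0] - [31.5, 31.5]) - 20.0)
        assert drift["midpoint"] < 0.2 * drift["euler"]

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValueError):
            dfm.track_material_points([], np.empty((0, 2)),
                                      dfm.TimeGrid.uniform(0.0, 0.1, 0))

    def test_exit_is_flagged_and_frozen(self):
        """A trajectory leaving the valid grid freezes (never extrapolates)."""
        from tagstrain.motion import VelocityGradientField

        shape = (8, 8)
        fields = [VelocityGradientField(
            v=np.broadcast_to([10.0, 0.0], shape + (2,)).copy(),
            L=np.zeros(shape + (2, 2)),
            selected_scale=np.zeros(shape),
            condition_number=np.ones(shape),
            validity=np.ones(shape, bool), time=0.5, spacing=1.0)
            for _ in range(4)]
        grid = dfm.TimeGrid.uniform(0.0, 0.5, 4)
        traj = dfm.track_material_points(fields, np.array([[5.0, 4.0]]), grid)
        assert not traj.in_domain[-1, 0]
        frozen = traj.positions[traj.in_domain[:, 0].argmin():, 0]
        assert (frozen == frozen[0]).all()
        out = dfm.integrate_deformation(fields, traj, grid)
        assert not out.valid[-1, 0]
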