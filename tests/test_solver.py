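"""Finite-volume discretisation: conservation, positivity, consistency, order."""

import numpy as np
import pytest
from scipy.stats import norm

import burstpide as bp
from burstpide.solver import (
    AxisJump,
    DiscretePIDE,
    ResolutionError,
    StabilityError,
    _DilationRemap,
    build_jump_operator_1d,
    transport_divergence_1d,
)

from conftest import make_grid


class TestJumpOperator:
    def test_recurrence_matches_dense(self, rng):
        axis = bp.Axis(x_max=60.0, n=240)
        jump = AxisJump(axis, b=7.0)
        M = jump.dense()
        v = rng.random(240)
        assert np.abs(jump.apply(v) - M @ v).max() < 1e-12
        assert np.abs(jump.apply_transpose(v) - M.T @ v).max() < 1e-12

    def test_columns_sum_to_one(self):
        axis = bp.Axis(x_max=60.0, n=240)
        M = AxisJump(axis, b=7.0).dense()
        assert np.abs(M.sum(axis=0) - 1.0).max() < 1e-13

    def test_mass_neutral_on_any_density(self, fig4_model, fig4_grid512, rng):
        axis, _ = fig4_grid512
        op = DiscretePIDE(fig4_model, (axis,))
        p = rng.random(axis.n)
        assert abs(op.jump_rhs(p).sum() * axis.dx) < 1e-12 * p.sum() * axis.dx

    def test_gain_from_point_mass_is_cell_integrated_kernel(self):
        """With c == 1, the gain column of a point source reproduces the
        shifted exponential kernel averaged over target cells (independent
        quadrature oracle)."""
        from scipy.integrate import dblquad, quad

        m = bp.Model1D(a=3.0, b=7.0)
        axis = bp.Axis(x_max=60.0, n=60)
        L = build_jump_operator_1d(m, axis)
        gain = L + np.diag(3.0 * np.ones(axis.n))  # c == 1 loss is a*I
        j = 10
        for i in (j, j + 1, j + 4):
            # smooth integrand: the inner (y) upper limit follows x on the
            # diagonal cell instead of clipping the kernel at zero
            upper = (lambda x: x) if i == j else (lambda x: axis.faces[j + 1])
            ref, _ = dblquad(
                lambda y, x: np.exp(-(x - y) / 7.0) / 7.0,
                axis.faces[i], axis.faces[i + 1],
                lambda x: axis.faces[j], upper,
            )
            ref *= 3.0 / axis.dx**2  # a * double cell integral / (dx * dx)
            # column renormalisation compensates the truncated tail beyond
            # x_max: divide by (1/dx) int_cell_j (1 - e^-(x_max-y)/b) dy
            colsum, _ = quad(
                lambda y: 1.0 - np.exp(-(axis.x_max - y) / 7.0),
                axis.faces[j], axis.faces[j + 1],
            )
            ref /= colsum / axis.dx
            assert gain[i, j] * axis.dx == pytest.approx(ref * axis.dx, rel=5e-7)

    def test_resolution_guard(self):
        with pytest.raises(ResolutionError):
            AxisJump(bp.Axis(x_max=100.0, n=10), b=5.0)


class TestTransport:
    def test_divergence_is_mass_neutral(self, rng):
        axis = bp.Axis(x_max=50.0, n=128)
        p = rng.random(128)
        div = transport_divergence_1d(p, axis)
        assert abs(div.sum() * axis.dx) < 1e-13 * p.sum()

    def test_divergence_matches_analytic_derivative(self):
        # gamma(5, 4) profile: d/dx (x p) has a closed form
        from scipy.stats import gamma as sgamma

        a_, b_ = 5.0, 4.0
        axis = bp.Axis(x_max=80.0, n=2000)
        x = axis.centers
        p = sgamma.pdf(x, a_, scale=b_)
        exact = sgamma.pdf(x, a_, scale=b_) * (a_ - x / b_)  # d(xp)/dx
        div = transport_divergence_1d(p, axis)
        interior = slice(5, -5)
        assert np.abs(div - exact)[interior].max() < 0.05  # O(dx) upwind

    def test_dilation_remap_matches_exact_dilation(self):
        """Transporting with the jump disabled is the dilation
        (X_t # p0)(x) = p0(x e^t) e^t; compare against the closed form for
        a Gaussian profile."""
        axis = bp.Axis(x_max=200.0, n=2000)
        mu, sd = 80.0, 8.0
        p0 = np.diff(norm.cdf(axis.faces, mu, sd)) / axis.dx
        t = 0.3
        op = DiscretePIDE(bp.ModelND(km=(1e-12,), b=(10.0,)), (axis,))
        values = p0.copy()
        for _ in range(30):
            values = op._dilate_all(values, t / 30)
        exact = norm.pdf(axis.centers * np.exp(t), mu, sd) * np.exp(t)
        assert np.abs(values - exact).sum() * axis.dx < 2e-3

    def test_remap_conserves_mass_and_positivity(self, rng):
        axis = bp.Axis(x_max=100.0, n=256)
        p = rng.random(256)
        rm = _DilationRemap(axis, stretch=np.exp(0.05))
        out = rm.apply(p)
        assert out.sum() * axis.dx == pytest.approx(p.sum() * axis.dx, rel=1e-14)
        assert out.min() >= 0.0


class TestStepping:
    def test_cfl_violation_raises(self, fig4_model, fig4_grid512):
        axis, pinf = fig4_grid512
        state = bp.DensityGrid((axis,), pinf)
        with pytest.raises(StabilityError):
            bp.step(state, fig4_model, dt=10.0, method="split")
        with pytest.raises(StabilityError):
            bp.step(state, fig4_model, dt=0.1, method="rk4")

    def test_mass_conserved_over_many_steps(self, fig4_model, fig4_grid512):
        axis, _ = fig4_grid512
        p0 = bp.gaussian_initial_condition([60.0], [15.0], (axis,))
        rep = bp.simulate(fig4_model, p0, 5.0, method="split", dt=0.02,
                          save_times=np.arange(1.0, 6.0), save_states=False)
        assert np.abs(np.asarray(rep.mass_history) - 1.0).max() < 1e-10

    def test_stationary_data_stays_stationary(self, fig4_model, fig4_grid512):
        axis, pinf = fig4_grid512
        p0 = bp.DensityGrid((axis,), pinf.copy())
        rep = bp.simulate(fig4_model, p0, 1.0, method="split", dt=0.01,
                          save_states=False)  # 100 steps
        drift = np.abs(rep.final().values - pinf).sum() * axis.dx
        assert drift < 5e-3  # bounded by the spatial truncation error at N=512

    def test_open_loop_gamma_is_fixed_point(self):
        m = bp.Model1D(a=5.0, b=10.0)
        dens = bp.normalise(m)
        axis, pinf = make_grid(dens, 512)
        p0 = bp.DensityGrid((axis,), pinf.copy())
        rep = bp.simulate(m, p0, 2.0, method="split", dt=0.01, save_states=False)
        assert np.abs(rep.final().values - pinf).sum() * axis.dx < 1e-3

    def test_positivity_preserved(self, fig4_model, fig4_grid512):
        axis, _ = fig4_grid512
        p0 = bp.gaussian_initial_condition([2.0], [0.1], (axis,))
        rep = bp.simulate(fig4_model, p0, 3.0, method="split", dt=0.01, save_states=False)
        assert rep.final().values.min() >= 0.0
        assert rep.clipped_mass < 1e-10

    def test_l1_distance_between_solutions_contracts(self, fig4_model, fig4_grid512):
        axis, _ = fig4_grid512
        p0 = bp.gaussian_initial_condition([60.0], [15.0], (axis,))
        q0 = bp.gaussian_initial_condition([120.0], [20.0], (axis,))
        times = np.arange(0.5, 4.0, 0.5)
        ra = bp.simulate(fig4_model, p0, 3.5, save_times=times, method="split", dt=0.01)
        rb = bp.simulate(fig4_model, q0, 3.5, save_times=times, method="split", dt=0.01)
        dists = [np.abs(a.values - b.values).sum() * axis.dx
                 for a, b in zip(ra.states, rb.states)]
        assert all(np.diff(dists) <= 1e-12)

    def test_maximum_principle_monitored(self, fig4_model, fig4_grid512):
        axis, pinf = fig4_grid512
        # discrete fixed point as reference so the principle is exact
        pfix = bp.simulate(fig4_model, bp.DensityGrid((axis,), pinf.copy()),
                           40.0, method="split", dt=0.02, save_states=False).final()
        w = 1.0 + 0.5 * np.sin(axis.centers / 40.0)
        p0 = bp.DensityGrid((axis,), pfix.values * w).normalised()
        rep = bp.simulate(fig4_model, p0, 3.0, method="split", dt=0.01,
                          pinf_values=pfix.values, save_states=False)
        ok = pfix.values > 1e-10 * pfix.values.max()
        u = rep.final().values[ok] / pfix.values[ok]
        u0 = p0.values[ok] / pfix.values[ok]
        assert u.max() <= u0.max() * (1 + 1e-8)
        assert u.min() >= u0.min() * (1 - 1e-8) - 1e-12

    def test_integrators_agree_under_refinement(self, fig4_model, fig4_density):
        diffs = []
        for n in (256, 512, 1024):
            axis, _ = make_grid(fig4_density, n)
            p0 = bp.gaussian_initial_condition([60.0], [15.0], (axis,))
            r1 = bp.simulate(fig4_model, p0, 1.0, method="split", dt=0.002,
                             save_states=False)
            r2 = bp.simulate(fig4_model, p0, 1.0, method="rk4", save_states=False)
            diffs.append(np.abs(r1.final().values - r2.final().values).sum() * axis.dx)
        assert diffs[2] < diffs[1] < diffs[0]
        assert diffs[0] / diffs[2] > 2.5  # observed order ~1 (upwind limited)

    def test_rk4_conserves_mass_and_positivity(self, fig4_model, fig4_density):
        axis, _ = make_grid(fig4_density, 256)
        p0 = bp.gaussian_initial_condition([60.0], [15.0], (axis,))
        rep = bp.simulate(fig4_model, p0, 1.0, method="rk4", save_states=False)
        assert rep.final().mass() == pytest.approx(1.0, abs=1e-12)
        assert rep.final().values.min() > -1e-12


class TestConsistencyOrder:
    def test_rhs_residual_order_on_smooth_stationary_laws(self):
        """RK4 right-hand side applied to a smooth analytic stationary
        density: the L2 residual decreases at observed order >= 1."""
        fb = bp.HillFeedback1D(H=-4, K=45.0, epsilon=0.15)
        for model in (bp.Model1D(a=15.0, b=20.0, feedback=fb), bp.Model1D(a=5.0, b=10.0)):
            dens = bp.normalise(model)
            res = []
            for n in (512, 1024, 2048):
                axis, pinf = make_grid(dens, n)
                op = DiscretePIDE(model, (axis,))
                r = op.rhs(pinf)
                res.append(np.sqrt((r**2).sum() * axis.dx))
            orders = np.log2(np.array(res[:-1]) / np.array(res[1:]))
            assert np.all(orders >= 0.9)

    def test_split_operator_residual_order_on_singular_law(self, fig4_density, fig4_model):
        """The splitting evolution operator's stationarity defect on the
        singular analytic law also vanishes at first-or-better order."""
        res = []
        for n in (512, 1024, 2048):
            axis, pinf = make_grid(fig4_density, n)
            op = DiscretePIDE(fig4_model, (axis,))
            defect = (op.step_split(pinf.copy(), 0.01) - pinf) / 0.01
            res.append(np.sqrt((defect**2).sum() * axis.dx))
        orders = np.log2(np.array(res[:-1]) / np.array(res[1:]))
        assert np.all(orders >= 1.0)


@pytest.fixture(scope="module")
def toggle():
    preset = bp.get_preset("fig11")
    axes = bp.default_axes(preset.model, 128)
    p0 = bp.gaussian_initial_condition(preset.ic_means, preset.ic_sds, axes)
    return preset.model, axes, p0


class TestTwoDimensions:
    def test_symmetric_network_stays_symmetric(self, toggle):
        model, axes, p0 = toggle
        rep = bp.simulate(model, p0, 1.0, method="split", save_states=False)
        v = rep.final().values
        assert np.abs(v - v.T).max() < 1e-14

    def test_mass_and_positivity_to_t10(self, toggle):
        model, axes, p0 = toggle
        rep = bp.simulate(model, p0, 10.0, method="split", save_states=False)
        assert rep.final().mass() == pytest.approx(1.0, abs=1e-10)
        assert rep.final().values.min() >= 0.0

    def test_boundary_mass_stays_negligible(self, toggle):
        model, axes, p0 = toggle
        rep = bp.simulate(model, p0, 5.0, method="split", save_states=False)
        assert rep.boundary_mass() < 1e-8
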