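"""Relative entropies, production, and decay-rate fitting."""

import numpy as np
import pytest
from scipy.stats import gamma as sgamma

import burstpide as bp
from burstpide.entropy import (
    EntropyTrace,
    SupportMismatchError,
    fit_decay_rate,
    production_D2,
)

from conftest import make_grid


def _gamma_cell_averages(axis, shape, scale):
    return np.diff(sgamma.cdf(axis.faces, shape, scale=scale)) / axis.dx


class TestGeneralEntropy:
    def test_zero_at_equilibrium_for_any_H(self, fig4_grid512):
        axis, pinf = fig4_grid512
        p = bp.DensityGrid((axis,), pinf)
        for Hfun in (lambda u: (u - 1) ** 2, lambda u: np.abs(u - 1),
                     lambda u: u * np.log(np.maximum(u, 1e-300)) - u + 1):
            assert abs(bp.general_entropy(p, pinf, Hfun)) < 1e-12

    def test_absolute_H_on_step_densities(self):
        # p = 2/9 on (0,3], 1/9 on (3,6]; P uniform 1/6 on (0,6].  By hand:
        # int |p - P| = 3|2/9 - 1/6| + 3|1/9 - 1/6| = 1/6 + 1/6 = 1/3.
        axis = bp.Axis(x_max=6.0, n=6)
        p = np.where(axis.centers <= 3.0, 2.0 / 9.0, 1.0 / 9.0)
        P = np.full(6, 1.0 / 6.0)
        pg = bp.DensityGrid((axis,), p)
        val = bp.general_entropy(pg, P, lambda u: np.abs(u - 1.0))
        assert val == pytest.approx(1.0 / 3.0, rel=1e-14)

    def test_quadratic_H_reproduces_G2(self, fig4_grid512):
        axis, pinf = fig4_grid512
        p = bp.DensityGrid((axis,), _gamma_cell_averages(axis, 6.0, 12.0))
        g2 = bp.entropy_G2(p, pinf)
        gen = bp.general_entropy(p, pinf, lambda u: (u - 1.0) ** 2)
        assert g2 == pytest.approx(gen, rel=1e-12)

    def test_support_mismatch_reported(self):
        axis = bp.Axis(x_max=10.0, n=10)
        p = bp.DensityGrid((axis,), np.full(10, 0.1))
        pinf = np.full(10, 0.1)
        pinf[7:] = 0.0
        with pytest.raises(SupportMismatchError):
            bp.entropy_G2(p, pinf)


class TestG2:
    def test_gamma_pair_closed_form(self):
        # p ~ gamma(2,1), Pinf ~ gamma(3,1):
        # int p^2/Pinf = Gamma(2*2-3) Gamma(3) / Gamma(2)^2 = 2, so G2 = 1.
        # Midpoint values keep the ratio p/Pinf exact pointwise; the
        # remaining quadrature error is O(dx^2).
        axis = bp.Axis(x_max=60.0, n=6000)
        p = bp.DensityGrid((axis,), sgamma.pdf(axis.centers, 2.0, scale=1.0))
        pinf = sgamma.pdf(axis.centers, 3.0, scale=1.0)
        assert bp.entropy_G2(p, pinf) == pytest.approx(1.0, abs=1e-3)

    def test_nonnegative_and_zero_iff_equal(self, fig4_grid512):
        axis, pinf = fig4_grid512
        assert bp.entropy_G2(bp.DensityGrid((axis,), pinf), pinf) < 1e-13
        p = bp.DensityGrid((axis,), _gamma_cell_averages(axis, 6.0, 12.0))
        assert bp.entropy_G2(p, pinf) > 0.0


class TestD2:
    def test_zero_at_equilibrium_positive_otherwise(self, fig4_model, fig4_grid512):
        axis, pinf = fig4_grid512
        assert production_D2(bp.DensityGrid((axis,), pinf), pinf, fig4_model) < 1e-12
        p = bp.DensityGrid((axis,), _gamma_cell_averages(axis, 6.0, 12.0))
        assert production_D2(p, pinf, fig4_model) > 0.0

    def test_matches_brute_force_double_sum(self, fig4_model, fig4_density):
        axis, pinf = make_grid(fig4_density, 200)
        p = bp.DensityGrid((axis,), _gamma_cell_averages(axis, 6.0, 12.0))
        fast = production_D2(p, pinf, fig4_model)
        from burstpide.solver import DiscretePIDE

        op = DiscretePIDE(fig4_model, (axis,))
        W = op.jumps[0].dense()
        u = p.values / pinf
        du2 = (u[:, None] - u[None, :]) ** 2
        brute = fig4_model.a * np.sum(W * du2 * (op.cfields[0] * pinf)[None, :]) * axis.dx
        assert fast == pytest.approx(brute, rel=1e-12)


class TestFit:
    def test_recovers_exact_exponential(self):
        t = np.linspace(0.0, 8.0, 60)
        trace = EntropyTrace(times=t, G2=3.5 * np.exp(-2 * 0.7 * t))
        fit_decay_rate(trace)
        assert trace.fitted_rate == pytest.approx(0.7, rel=1e-10)
        assert trace.entropy_rate == pytest.approx(1.4, rel=1e-10)
        assert trace.fit_r_squared == pytest.approx(1.0, abs=1e-12)

    def test_rejects_increasing_trace(self):
        t = np.linspace(0.0, 5.0, 30)
        g = np.exp(-t)
        g[10] = g[9] * 1.5  # bump well before the minimum
        with pytest.raises(ValueError, match="increases"):
            fit_decay_rate(EntropyTrace(times=t, G2=g))

    def test_too_few_samples_rejected(self):
        t = np.linspace(0.0, 1.0, 5)
        with pytest.raises(ValueError, match="samples"):
            fit_decay_rate(EntropyTrace(times=t, G2=np.exp(-t)))


class TestExperiments:
    def test_monotone_trace_and_fit(self, fig4_model, fig4_grid512):
        axis, pinf = fig4_grid512
        p0 = bp.gaussian_initial_condition([2.0], [0.1], (axis,))
        tr = bp.entropy_experiment(fig4_model, p0, 8.0, pinf, n_save=80, dt=0.005)
        k = int(np.argmin(tr.G2))
        assert np.all(np.diff(tr.G2[: k + 1]) <= 1e-10 * tr.G2[:k])
        assert tr.fit_r_squared > 0.99
        assert tr.fitted_rate > 0.0

    def test_equilibrium_start_gives_null_trace(self, fig4_model, fig4_grid512):
        axis, pinf = fig4_grid512
        p0 = bp.DensityGrid((axis,), pinf.copy())
        tr = bp.entropy_experiment(fig4_model, p0, 1.0, pinf, n_save=20, fit=False,
                                   dt=0.01)
        assert np.all(tr.G2 < 1e-4)

    def test_h_theorem_identity_along_trajectory(self, fig4_model, fig4_density):
        axis, pinf = make_grid(fig4_density, 512)
        p0 = bp.gaussian_initial_condition([60.0], [15.0], (axis,))
        tr = bp.entropy_experiment(fig4_model, p0, 3.0, pinf, n_save=60,
                                   d2_every=1, dt=0.002)
        t, g, d2 = tr.times, tr.G2, tr.D2
        dg = (g[2:] - g[:-2]) / (t[2:] - t[:-2])
        rel = np.abs(dg + d2[1:-1]) / d2[1:-1]
        sel = (t[1:-1] >= 0.5) & (t[1:-1] <= 2.5)
        assert rel[sel].max() < 0.02

    def test_product_network_factorisation(self):
        """For two independent genes the joint L2 entropy satisfies
        1 + G2_2D = (1 + G2_a)(1 + G2_b) on exact product densities."""
        fb = bp.HillFeedback1D(H=-4, K=45.0, epsilon=0.15)
        m1 = bp.Model1D(a=5.0, b=10.0, feedback=fb)
        dens = bp.normalise(m1)
        axis = bp.Axis(x_max=dens.x_max, n=256)
        pinf1 = dens.cell_averages(axis.faces)
        pa = _gamma_cell_averages(axis, 6.0, 12.0)
        pb = _gamma_cell_averages(axis, 4.0, 15.0)
        g2a = bp.entropy_G2(bp.DensityGrid((axis,), pa), pinf1)
        g2b = bp.entropy_G2(bp.DensityGrid((axis,), pb), pinf1)
        joint = bp.DensityGrid((axis, axis), np.multiply.outer(pa, pb))
        g2_joint = bp.entropy_G2(joint, np.multiply.outer(pinf1, pinf1))
        assert 1.0 + g2_joint == pytest.approx((1.0 + g2a) * (1.0 + g2b), rel=1e-6)

    def test_nd_reference_stationary_converges(self):
        preset = bp.get_preset("fig11")
        axes = bp.default_axes(preset.model, 128)
        p0 = bp.gaussian_initial_condition(preset.ic_means, preset.ic_sds, axes)
        ref = bp.reference_stationary(preset.model, p0, t_max=80.0, tol=1e-8)
        assert ref.mass() == pytest.approx(1.0, abs=1e-8)
        tr = bp.entropy_experiment(preset.model, p0, 6.0, ref.values, n_save=60,
                                   fit=False)
        k = int(np.argmin(tr.G2))
        assert np.all(np.diff(tr.G2[: k + 1]) <= 1e-10 * tr.G2[:k] + 1e-300)
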