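import numpy as np
import pytest

from phantomflow.errors import DataError, ParameterError, StagnationError
from phantomflow.fields import ScanGrid, VelocityField2D
from phantomflow.pressure import (
    InviscidPressureDropModel,
    PathSpec,
    apply_tq_threshold,
    estimate_delta_p,
    integrate_along_path,
    pressure_gradient,
    trace_streamline,
    velocity_derivatives,
)
from phantomflow.pressure import PressureGradientField
from phantomflow.synthetic import AnalyticFieldSpec, BsiDegradationSpec, emulate_bsi, exact_pressure_drop, sample_analytic_field
from phantomflow.units import pa_to_mmhg


def make_field(grid, ux, uy, tq=None, valid=None):
    return VelocityField2D(grid=grid, ux=ux, uy=uy, tq=tq, valid=valid)


class TestTqThreshold:
    def test_all_good_tq_keeps_mask(self, stagnation_field):
        out = apply_tq_threshold(stagnation_field, 0.4)
        assert np.all(out.valid)

    def test_all_zero_tq_invalidates(self, stagnation_field):
        f = stagnation_field.copy()
        f.tq = np.zeros_like(f.tq)
        assert not np.any(apply_tq_threshold(f, 0.4).valid)

    def test_count_matches_direct_count(self, stagnation_field):
        rng = np.random.default_rng(0)
        f = stagnation_field.copy()
        f.tq = rng.uniform(0, 1, f.tq.shape)
        out = apply_tq_threshold(f, 0.4)
        assert out.valid.sum() == np.sum(f.tq > 0.4)

    def test_monotone_in_threshold(self, stagnation_field):
        rng = np.random.default_rng(1)
        f = stagnation_field.copy()
        f.tq = rng.uniform(0, 1, f.tq.shape)
        counts = [apply_tq_threshold(f, th).valid.sum() for th in (0.1, 0.4, 0.7, 0.95)]
        assert counts == sorted(counts, reverse=True)


class TestDerivatives:
    def test_linear_fields_exact(self, small_grid):
        xx, yy = small_grid.meshgrid()
        ux = np.broadcast_to(3.0 * xx + 1.0 * yy, small_grid.shape).copy()
        uy = np.broadcast_to(-2.0 * yy, small_grid.shape).copy()
        d = velocity_derivatives(make_field(small_grid, ux, uy))
        assert np.allclose(d["duxdx"][d["valid"]], 3.0)
        assert np.allclose(d["duxdy"][d["valid"]], 1.0)
        assert np.allclose(d["duydy"][d["valid"]], -2.0)

    def test_linear_in_time_exact(self, small_grid):
        t = small_grid.t[:, None, None]
        ux = np.broadcast_to(0.7 * t, small_grid.shape).copy()
        d = velocity_derivatives(make_field(small_grid, ux, np.zeros(small_grid.shape)))
        assert np.allclose(d["duxdt"][d["valid"]], 0.7)

    def test_quadratic_convergence_order(self):
        # Interior error of central differences on ux = x^2 scales as h^2.
        errs = []
        for n in (17, 33, 65):
            g = ScanGrid(x=np.linspace(-1, 1, n), y=np.linspace(-1, 1, 5), t=np.linspace(0, 1, 3))
            xx, _ = g.meshgrid()
            ux = np.broadcast_to(xx**2, g.shape).copy()
            d = velocity_derivatives(make_field(g, ux, np.zeros(g.shape)))
            interior = d["duxdx"][:, :, 1:-1]
            errs.append(np.max(np.abs(interior - 2 * xx[None, :, 1:-1])))
        errs = np.array(errs)
        # Central differencing is exact on quadratics at interior nodes; the
        # boundary one-sided stencils carry the O(h) error.
        assert np.all(errs < 1e-12)
        full_errs = []
        for n in (17, 33, 65):
            g = ScanGrid(x=np.linspace(-1, 1, n), y=np.linspace(-1, 1, 5), t=np.linspace(0, 1, 3))
            xx, _ = g.meshgrid()
            ux = np.broadcast_to(xx**3, g.shape).copy()
            d = velocity_derivatives(make_field(g, ux, np.zeros(g.shape)))
            full_errs.append(np.max(np.abs(d["duxdx"][0, 0, 1:-1] - 3 * g.x[1:-1] ** 2)))
        order = np.log2(full_errs[0] / full_errs[1])
        assert order == pytest.approx(2.0, abs=0.3)

    def test_single_frame_rejected(self):
        with pytest.raises(Exception):
            g = ScanGrid(x=np.linspace(0, 1, 3), y=np.linspace(0, 1, 3), t=np.array([0.0, 1.0]))
            velocity_derivatives(make_field(g, np.zeros(g.shape), np.zeros(g.shape)))
            raise DataError("grid built")  # ScanGrid itself needs >= 3 t samples

    def test_masked_nodes_fall_back_to_one_sided(self, small_grid):
        xx, _ = small_grid.meshgrid()
        ux = np.broadcast_to(2.0 * xx, small_grid.shape).copy()
        valid = np.ones(small_grid.shape, bool)
        valid[:, :, 10] = False  # a masked column
        d = velocity_derivatives(make_field(small_grid, ux, np.zeros(small_grid.shape), valid=valid))
        # Neighbours of the masked column remain valid via one-sided stencils
        # and stay exact for a linear field.
        assert np.all(d["valid"][:, :, 9])
        assert np.allclose(d["duxdx"][:, :, 9], 2.0)
        assert not np.any(d["valid"][:, :, 10])


class TestPressureGradient:
    def test_steady_uniform_flow_zero_gradient(self, small_grid, bmf):
        f = sample_analytic_field(AnalyticFieldSpec(kind="uniform_unsteady", parameters={"u0": 0.4}), small_grid)
        g = pressure_gradient(f, bmf)
        assert np.allclose(g.dpdx[g.valid], 0.0)
        assert np.allclose(g.dpdy[g.valid], 0.0)

    def test_uniform_acceleration_gives_rho_a(self, small_grid, bmf):
        alpha = 2.5
        f = sample_analytic_field(AnalyticFieldSpec(kind="uniform_unsteady", parameters={"accel": alpha}), small_grid)
        g = pressure_gradient(f, bmf)
        assert np.allclose(g.dpdx[g.valid], -bmf.rho * alpha)
        assert np.allclose(g.dpdy[g.valid], 0.0)

    def test_stagnation_gradient_closed_form(self, stagnation_field, small_grid, bmf):
        g = pressure_gradient(stagnation_field, bmf)
        xx, yy = small_grid.meshgrid()
        expected_x = -bmf.rho * 20.0**2 * xx
        expected_y = -bmf.rho * 20.0**2 * yy
        interior = np.zeros(small_grid.shape, bool)
        interior[:, 1:-1, 1:-1] = True
        m = g.valid & interior
        assert np.allclose(g.dpdx[m], np.broadcast_to(expected_x, small_grid.shape)[m], rtol=1e-10)
        assert np.allclose(g.dpdy[m], np.broadcast_to(expected_y, small_grid.shape)[m], rtol=1e-10)


class TestPathIntegral:
    def _const_grad(self, small_grid, gx, gy):
        shape = small_grid.shape
        return PressureGradientField(
            grid=small_grid,
            dpdx=np.full(shape, gx),
            dpdy=np.full(shape, gy),
            valid=np.ones(shape, bool),
        )

    def test_zero_gradient_zero_drop(self, small_grid):
        s = integrate_along_path(self._const_grad(small_grid, 0.0, 0.0), PathSpec(points=[(-0.01, 0), (0.01, 0)]))
        assert np.allclose(s.dp, 0.0)

    def test_constant_gradient_gl(self, small_grid):
        g = 500.0  # Pa/m along +x
        s = integrate_along_path(self._const_grad(small_grid, g, 0.0), PathSpec(points=[(-0.01, 0.0), (0.01, 0.0)]))
        # dP = P(a) - P(b) = -g * L: pressure rises along +x, so a is lower.
        assert np.allclose(s.dp, pa_to_mmhg(-g * 0.02), rtol=1e-10)

    def test_reversal_flips_sign(self, small_grid):
        grad = self._const_grad(small_grid, 300.0, -200.0)
        p = PathSpec(points=[(-0.012, -0.007), (0.011, 0.013)])
        s1 = integrate_along_path(grad, p)
        s2 = integrate_along_path(grad, p.reversed())
        assert np.allclose(s1.dp, -s2.dp)

    def test_path_outside_grid_rejected(self, small_grid):
        with pytest.raises(ParameterError):
            integrate_along_path(self._const_grad(small_grid, 0, 0), PathSpec(points=[(-1.0, 0.0), (0.01, 0.0)]))


class TestEstimateDeltaP:
    def test_stagnation_matches_oracle(self, stagnation_field, stagnation_spec, small_grid, bmf):
        a, b = (-0.015, -0.01), (0.015, 0.012)
        s = estimate_delta_p(stagnation_field, PathSpec(points=[a, b]), bmf)
        exact = pa_to_mmhg(exact_pressure_drop(stagnation_spec, a, b, small_grid.t))
        assert np.allclose(s.dp, exact, atol=1e-10)

    def test_rotation_matches_oracle_and_path_independent(self, rotation_field, rotation_spec, small_grid, bmf):
        a, b = (-0.012, 0.0), (0.015, 0.005)
        s1 = estimate_delta_p(rotation_field, PathSpec(points=[a, b]), bmf)
        s2 = estimate_delta_p(rotation_field, PathSpec(points=[a, (0.0, 0.015), b]), bmf)
        exact = pa_to_mmhg(exact_pressure_drop(rotation_spec, a, b, small_grid.t))
        assert np.allclose(s1.dp, exact, atol=1e-9)
        assert np.allclose(s1.dp, s2.dp, atol=1e-9)

    def test_dropout_at_endpoint_invalidates_frames(self, stagnation_field, bmf):
        a, b = (-0.015, -0.01), (0.015, 0.012)
        deg = BsiDegradationSpec(
            noise_sd=0.0, v_reject=0.0, dropout_regions=((-0.02, -0.008, -0.02, -0.003),), seed=0
        )
        degraded = emulate_bsi(stagnation_field, deg)
        s = estimate_delta_p(degraded, PathSpec(points=[a, b]), bmf, min_coverage=0.95)
        assert not np.any(s.frame_valid)
        clean = estimate_delta_p(stagnation_field, PathSpec(points=[a, b]), bmf, min_coverage=0.95)
        assert np.all(clean.frame_valid)

    def test_deterministic(self, rotation_field, bmf):
        p = PathSpec(points=[(-0.012, 0.0), (0.015, 0.005)])
        s1 = estimate_delta_p(rotation_field, p, bmf)
        s2 = estimate_delta_p(rotation_field, p, bmf)
        assert np.array_equal(s1.dp, s2.dp)


class TestModelResults:
    def test_summary_and_extrema(self, stagnation_field, bmf):
        res = InviscidPressureDropModel(stagnation_field, [(-0.015, -0.01), (0.015, 0.012)], bmf).fit()
        mx, tmx, mn, tmn = res.extrema()
        assert mx >= mn
        text = res.summary()
        assert "max dP" in text and "mmHg" in text
        df = res.to_dataframe()
        assert set(df.columns) == {"t", "dp_mmHg", "coverage", "valid"}


class TestStreamline:
    def test_uniform_flow_straight_line(self, small_grid):
        f = sample_analytic_field(AnalyticFieldSpec(kind="uniform_unsteady", parameters={"u0": 0.5}), small_grid)
        p = trace_streamline(f, 0, (-0.015, 0.002), step=1e-3, max_steps=100)
        assert np.allclose(p.points[:, 1], 0.002, atol=1e-12)
        assert p.points[-1, 0] > p.points[0, 0]

    def test_rotation_gives_circle(self, rotation_field):
        r0 = 0.01
        p = trace_streamline(rotation_field, 0, (r0, 0.0), step=2e-4, max_steps=400)
        radii = np.hypot(p.points[:, 0], p.points[:, 1])
        assert np.max(np.abs(radii - r0)) < 5e-5

    def test_stagnation_point_seed_rejected(self, stagnation_field):
        with pytest.raises(StagnationError):
            trace_streamline(stagnation_field, 0, (0.0, 0.0), step=1e-3, speed_floor=1e-6)
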