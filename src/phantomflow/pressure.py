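"""Relative-pressure estimation from masked 2-D velocity fields.

The estimator implements the inviscid momentum balance: for incompressible
flow with viscosity neglected,

    dP/dx = -rho (du_x/dt + u_x du_x/dx + u_y du_x/dy)
    dP/dy = -rho (du_y/dt + u_x du_y/dx + u_y du_y/dy)

and the pressure drop between an inlet point a and an outlet point b is the
line integral of the gradient along a path kept fixed across frames:

    dP = P(a) - P(b) = - int_a^b grad P . dl

Derivatives are second-order central differences where the full stencil is
valid, first-order one-sided next to boundaries or masked samples; the path
integral uses validity-aware bilinear sampling and the trapezoid rule.
Frames whose path coverage falls below a minimum are flagged invalid rather
than silently extrapolated. Output pressure drops are reported in mmHg.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParameterError, StagnationError
from .fields import FluidProperties, ScanGrid, VelocityField2D
from .units import pa_to_mmhg

__all__ = [
    "PathSpec",
    "PressureGradientField",
    "DeltaPSeries",
    "apply_tq_threshold",
    "velocity_derivatives",
    "pressure_gradient",
    "integrate_along_path",
    "estimate_delta_p",
    "trace_streamline",
    "InviscidPressureDropModel",
    "PressureDropResults",
]


@dataclass(frozen=True)
class PathSpec:
    """Ordered polyline from the inlet point a to the outlet point b (metres)."""

    points: np.ndarray  # (n, 2) of (x, y)
    mode: str = "fixed_polyline"
    truncated: bool = False

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[0] < 2 or pts.shape[1] != 2:
            raise ParameterError(f"path needs >= 2 (x, y) points, got shape {pts.shape}")
        object.__setattr__(self, "points", pts)
        if self.mode not in ("fixed_polyline", "streamline"):
            raise ParameterError(f"unknown path mode {self.mode!r}")

    @property
    def a(self) -> np.ndarray:
        return self.points[0]

    @property
    def b(self) -> np.ndarray:
        return self.points[-1]

    def reversed(self) -> "PathSpec":
        return PathSpec(points=self.points[::-1].copy(), mode=self.mode, truncated=self.truncated)

    def resample(self, ds: float) -> np.ndarray:
        """Points spaced <= ds along the polyline (vertices preserved)."""
        out = [self.points[0]]
        for p0, p1 in zip(self.points[:-1], self.points[1:]):
            seg = np.linalg.norm(p1 - p0)
            n = max(1, int(np.ceil(seg / ds)))
            for i in range(1, n + 1):
                out.append(p0 + (p1 - p0) * i / n)
        return np.asarray(out)


@dataclass
class PressureGradientField:
    """Inviscid pressure-gradient field with propagated validity."""

    grid: ScanGrid
    dpdx: np.ndarray
    dpdy: np.ndarray
    valid: np.ndarray


@dataclass
class DeltaPSeries:
    """Pressure-drop time series between two fixed points, in mmHg."""

    time: np.ndarray
    dp: np.ndarray  # mmHg; NaN where frame invalid
    coverage: np.ndarray
    frame_valid: np.ndarray
    path: PathSpec = None
    meta: dict = field(default_factory=dict)


def apply_tq_threshold(field_: VelocityField2D, threshold: float = 0.4) -> VelocityField2D:
    """Keep only samples with tracking quality above ``threshold``.

    The scanner-recommended cut is TQ > 0.4. Velocities are untouched; the
    validity mask becomes (tq > threshold) AND the previous mask.
    """
    if not 0 <= threshold <= 1:
        raise ParameterError(f"threshold must lie in [0, 1], got {threshold}")
    return field_.with_valid((field_.tq > threshold) & field_.valid)


def _masked_diff(f: np.ndarray, valid: np.ndarray, axis: int, h: float):
    """Finite difference along ``axis`` honouring the validity mask.

    Central (second order) where both neighbours are valid, one-sided (first
    order) otherwise; nodes with no usable stencil become invalid.
    """
    fp = np.roll(f, -1, axis=axis)
    fm = np.roll(f, 1, axis=axis)
    vp = np.roll(valid, -1, axis=axis)
    vm = np.roll(valid, 1, axis=axis)
    # roll wraps around; kill the wrapped ends
    sl_first = [slice(None)] * f.ndim
    sl_last = [slice(None)] * f.ndim
    sl_first[axis] = 0
    sl_last[axis] = -1
    vm[tuple(sl_first)] = False
    vp[tuple(sl_last)] = False

    central = valid & vp & vm
    fwd = valid & vp & ~vm
    bwd = valid & vm & ~vp
    out = np.full_like(f, np.nan, dtype=float)
    out[central] = (fp[central] - fm[central]) / (2 * h)
    out[fwd] = (fp[fwd] - f[fwd]) / h
    out[bwd] = (f[bwd] - fm[bwd]) / h
    return out, central | fwd | bwd


def velocity_derivatives(field_: VelocityField2D):
    """Spatial and temporal derivatives of both velocity components.

    Returns a dict with keys ``duxdx, duxdy, duydx, duydy`` (1/s),
    ``duxdt, duydt`` (m/s^2) and ``valid`` (nodes where every derivative
    could be formed).
    """
    g = field_.grid
    if g.t.size < 2:
        raise DataError("temporal derivatives require at least 2 frames")
    v = field_.valid
    out = {}
    masks = []
    for name, arr in (("ux", field_.ux), ("uy", field_.uy)):
        d_dx, m1 = _masked_diff(arr, v, axis=2, h=g.dx)
        d_dy, m2 = _masked_diff(arr, v, axis=1, h=g.dy)
        d_dt, m3 = _masked_diff(arr, v, axis=0, h=g.dt)
        out[f"d{name}dx"] = d_dx
        out[f"d{name}dy"] = d_dy
        out[f"d{name}dt"] = d_dt
        masks += [m1, m2, m3]
    out["valid"] = np.logical_and.reduce(masks)
    return out


def pressure_gradient(field_: VelocityField2D, fluid: FluidProperties) -> PressureGradientField:
    """Inviscid pressure gradient at every node with a complete stencil."""
    d = velocity_derivatives(field_)
    rho = fluid.rho
    ux, uy = field_.ux, field_.uy
    dpdx = -rho * (d["duxdt"] + ux * d["duxdx"] + uy * d["duxdy"])
    dpdy = -rho * (d["duydt"] + ux * d["duydx"] + uy * d["duydy"])
    valid = d["valid"]
    dpdx = np.where(valid, dpdx, np.nan)
    dpdy = np.where(valid, dpdy, np.nan)
    return PressureGradientField(grid=field_.grid, dpdx=dpdx, dpdy=dpdy, valid=valid)


def _bilinear(grid: ScanGrid, frame_vals: np.ndarray, frame_valid: np.ndarray, pts: np.ndarray):
    """Validity-aware bilinear sampling of one frame at points (n, 2).

    Weights of invalid corner nodes are dropped and the remainder
    renormalised; a point with no valid corner support returns NaN.
    """
    x, y = pts[:, 0], pts[:, 1]
    ix = np.clip(np.searchsorted(grid.x, x) - 1, 0, grid.x.size - 2)
    iy = np.clip(np.searchsorted(grid.y, y) - 1, 0, grid.y.size - 2)
    fx = (x - grid.x[ix]) / grid.dx
    fy = (y - grid.y[iy]) / grid.dy
    fx = np.clip(fx, 0.0, 1.0)
    fy = np.clip(fy, 0.0, 1.0)
    num = np.zeros(pts.shape[0])
    den = np.zeros(pts.shape[0])
    for dy_, dx_, w in (
        (0, 0, (1 - fx) * (1 - fy)),
        (0, 1, fx * (1 - fy)),
        (1, 0, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        vals = frame_vals[iy + dy_, ix + dx_]
        ok = frame_valid[iy + dy_, ix + dx_] & np.isfinite(vals)
        num += np.where(ok, w * vals, 0.0)
        den += np.where(ok, w, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den <= 1e-12] = np.nan
    return out


def integrate_along_path(
    grad: PressureGradientField,
    path: PathSpec,
    min_coverage: float = 0.9,
    ds: float | None = None,
) -> DeltaPSeries:
    """Trapezoid line integral of the gradient along the path, per frame.

    Sign convention: higher pressure at a than at b gives positive dP
    (inlet minus outlet), i.e. dP = -int_a^b grad P . dl. Output in mmHg.
    """
    if not 0 < min_coverage <= 1:
        raise ParameterError(f"min_coverage must lie in (0, 1], got {min_coverage}")
    g = grad.grid
    for px, py in path.points:
        if not g.contains(px, py):
            raise ParameterError(f"path point ({px}, {py}) outside the grid bounding box")
    if ds is None:
        ds = 0.5 * min(g.dx, g.dy)
    pts = path.resample(ds)
    seg = np.diff(pts, axis=0)  # (m-1, 2) tangential steps
    n_frames = g.t.size
    dp = np.full(n_frames, np.nan)
    coverage = np.zeros(n_frames)
    for k in range(n_frames):
        gx = _bilinear(g, grad.dpdx[k], grad.valid[k], pts)
        gy = _bilinear(g, grad.dpdy[k], grad.valid[k], pts)
        ok = np.isfinite(gx) & np.isfinite(gy)
        coverage[k] = ok.mean()
        if ok.sum() < 2:
            continue
        # Trapezoid over valid samples; gaps are bridged linearly by simply
        # integrating between consecutive valid samples.
        p_ok = pts[ok]
        gx_ok, gy_ok = gx[ok], gy[ok]
        d = np.diff(p_ok, axis=0)
        integrand = 0.5 * ((gx_ok[:-1] + gx_ok[1:]) * d[:, 0] + (gy_ok[:-1] + gy_ok[1:]) * d[:, 1])
        dp[k] = -np.sum(integrand)
    frame_valid = (coverage >= min_coverage) & np.isfinite(dp)
    if not np.any(np.isfinite(dp)):
        raise DataError("path has no valid gradient support at any frame")
    dp_mmhg = np.where(frame_valid, pa_to_mmhg(dp), np.nan)
    return DeltaPSeries(
        time=g.t.copy(),
        dp=dp_mmhg,
        coverage=coverage,
        frame_valid=frame_valid,
        path=path,
        meta={"min_coverage": min_coverage, "ds": ds, "n_path_samples": pts.shape[0]},
    )


def estimate_delta_p(
    field_: VelocityField2D,
    path: PathSpec,
    fluid: FluidProperties,
    tq_threshold: float = 0.4,
    min_coverage: float = 0.9,
    ds: float | None = None,
) -> DeltaPSeries:
    """Full pipeline: TQ masking -> derivatives -> inviscid gradient -> path integral."""
    masked = apply_tq_threshold(field_, tq_threshold)
    grad = pressure_gradient(masked, fluid)
    series = integrate_along_path(grad, path, min_coverage=min_coverage, ds=ds)
    series.meta["tq_threshold"] = tq_threshold
    return series


def trace_streamline(
    field_: VelocityField2D,
    frame: int,
    seed_point,
    step: float,
    max_steps: int = 2000,
    target=None,
    target_radius: float | None = None,
    speed_floor: float = 1e-9,
) -> PathSpec:
    """Trace an instantaneous streamline with fixed-step RK4.

    Integrates the unit-tangent direction field of the chosen frame by a
    classical fourth-order scheme with validity-aware bilinear interpolation,
    stopping at the target neighbourhood, the domain boundary, an invalid
    region (the returned path is then flagged truncated), or ``max_steps``.
    """
    g = field_.grid
    p = np.asarray(seed_point, dtype=float)
    if not g.contains(*p):
        raise ParameterError(f"seed point {tuple(p)} outside the grid")
    if target_radius is None:
        target_radius = max(g.dx, g.dy)
    ux_k, uy_k, v_k = field_.ux[frame], field_.uy[frame], field_.valid[frame]

    def direction(pt):
        pts = pt[None, :]
        vx = _bilinear(g, ux_k, v_k, pts)[0]
        vy = _bilinear(g, uy_k, v_k, pts)[0]
        if not (np.isfinite(vx) and np.isfinite(vy)):
            return None
        s = np.hypot(vx, vy)
        if s < speed_floor:
            return np.zeros(2)
        return np.array([vx, vy]) / s

    d0 = direction(p)
    if d0 is None or not np.any(d0):
        raise StagnationError(f"speed below floor ({speed_floor} m/s) at seed point {tuple(p)}")

    pts = [p.copy()]
    truncated = False
    for _ in range(max_steps):
        k1 = direction(p)
        if k1 is None:
            truncated = True
            break
        k2 = direction(np.clip(p + 0.5 * step * k1, [g.x[0], g.y[0]], [g.x[-1], g.y[-1]]))
        k3 = direction(np.clip(p + 0.5 * step * (k2 if k2 is not None else k1), [g.x[0], g.y[0]], [g.x[-1], g.y[-1]]))
        k4 = direction(np.clip(p + step * (k3 if k3 is not None else k1), [g.x[0], g.y[0]], [g.x[-1], g.y[-1]]))
        if k2 is None or k3 is None or k4 is None:
            truncated = True
            break
        d = (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        if np.hypot(*d) < 1e-12:
            break  # reached a stagnation point
        p = p + step * d
        if not g.contains(*p):
            break
        pts.append(p.copy())
        if target is not None and np.hypot(p[0] - target[0], p[1] - target[1]) <= target_radius:
            break
    if len(pts) < 2:
        raise StagnationError("streamline could not advance from the seed point")
    return PathSpec(points=np.asarray(pts), mode="streamline", truncated=truncated)


# ---------------------------------------------------------------------------
# Model/Results presentation of the estimator.
# ---------------------------------------------------------------------------


class InviscidPressureDropModel:
    """Pressure-drop estimator between two fixed points of a velocity field.

    Parameters
    ----------
    field : VelocityField2D
        Time-resolved 2-D velocity data with tracking quality.
    path : PathSpec or array of (x, y)
        Integration path from the inlet point a to the outlet point b.
    fluid : FluidProperties
        Density (and viscosity, unused by the inviscid balance) of the fluid.

    Examples
    --------
    >>> model = InviscidPressureDropModel(field, [(0.0, 0.0), (0.04, 0.0)], fluid)
    >>> res = model.fit()
    >>> res.summary()
    """

    def __init__(self, field_: VelocityField2D, path, fluid: FluidProperties):
        self.field = field_
        self.path = path if isinstance(path, PathSpec) else PathSpec(points=np.asarray(path, float))
        self.fluid = fluid

    def fit(self, tq_threshold: float = 0.4, min_coverage: float = 0.9, ds: float | None = None):
        series = estimate_delta_p(
            self.field, self.path, self.fluid, tq_threshold=tq_threshold, min_coverage=min_coverage, ds=ds
        )
        return PressureDropResults(self, series)


class PressureDropResults:
    """Results of :class:`InviscidPressureDropModel`.

    Attributes
    ----------
    series : DeltaPSeries
        Per-frame pressure drop (mmHg), coverage and validity.
    """

    def __init__(self, model: InviscidPressureDropModel, series: DeltaPSeries):
        self.model = model
        self.series = series

    @property
    def dp(self) -> np.ndarray:
        return self.series.dp

    @property
    def time(self) -> np.ndarray:
        return self.series.time

    @property
    def n_valid_frames(self) -> int:
        return int(self.series.frame_valid.sum())

    def extrema(self):
        """(max dP, t of max, min dP, t of min) over valid frames, mmHg/s."""
        dp = self.series.dp
        ok = self.series.frame_valid
        if not np.any(ok):
            raise DataError("no valid frames")
        t = self.series.time
        i_max = np.flatnonzero(ok)[np.nanargmax(dp[ok])]
        i_min = np.flatnonzero(ok)[np.nanargmin(dp[ok])]
        return float(dp[i_max]), float(t[i_max]), float(dp[i_min]), float(t[i_min])

    def summary(self) -> str:
        s = self.series
        lines = [
            "Inviscid pressure-drop estimate",
            "===============================",
            f"frames: {s.time.size}  valid: {self.n_valid_frames}",
            f"tq_threshold: {s.meta.get('tq_threshold')}  min_coverage: {s.meta.get('min_coverage')}",
            f"path: {s.path.mode}, {s.path.points.shape[0]} vertices, a={tuple(s.path.a)}, b={tuple(s.path.b)}",
        ]
        if self.n_valid_frames:
            mx, tmx, mn, tmn = self.extrema()
            lines.append(f"max dP: {mx:+.3f} mmHg at t={tmx:.4f} s")
            lines.append(f"min dP: {mn:+.3f} mmHg at t={tmn:.4f} s")
            lines.append(f"mean coverage (valid frames): {s.coverage[s.frame_valid].mean():.3f}")
        return "\n".join(lines)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.series.time,
                "dp_mmHg": self.series.dp,
                "coverage": self.series.coverage,
                "valid": self.series.frame_valid,
            }
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.series.time, self.series.dp, lw=1.5)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("pressure drop (mmHg)")
        return ax
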