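"""Synthetic velocity/pressure fields, the pump waveform, and scanner-style
degradation.

These generators stand in for the physical flow loop and the ultrasound
scanner: every analytic field kind exposes a closed-form velocity *and*
pressure so the downstream pressure-drop estimator can be checked against a
known ground truth, and :func:`emulate_bsi` reproduces the two dominant
artifacts of speckle-tracking velocimetry — additive velocity noise and the
PRF-dependent rejection of low velocities (21 cm/s and 13 cm/s in the
phantom experiments this package models).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, UnsupportedOracleError
from .fields import BLOOD_MIMICKING_FLUID, FluidProperties, ScanGrid, VelocityField2D
from . import womersley as _wom

__all__ = [
    "PulseWaveform",
    "make_pulse_waveform",
    "AnalyticFieldSpec",
    "sample_analytic_field",
    "exact_pressure_drop",
    "BsiDegradationSpec",
    "emulate_bsi",
]

#: Pump defaults: ~2.5 L/min plateau, 0.2 s pulse, 1.5 s inter-pulse delay.
DEFAULT_PEAK_FLOW = 2.5 / 60_000.0  # m^3/s
DEFAULT_PULSE_DURATION = 0.2  # s
DEFAULT_PERIOD = 1.7  # s
DEFAULT_RAMP_FRACTION = 0.25


@dataclass(frozen=True)
class PulseWaveform:
    """One period of the pump's volumetric flow waveform.

    A square pulse with half-cosine ("sine-like") ramps: the flow rises from
    zero over ``ramp_fraction * pulse_duration``, holds ``peak_flow``, ramps
    back to zero, then stays zero for the inter-pulse delay.
    """

    period: float
    pulse_duration: float
    ramp_fraction: float
    peak_flow: float
    time: np.ndarray
    flow: np.ndarray

    @property
    def ramp_duration(self) -> float:
        return self.ramp_fraction * self.pulse_duration

    @property
    def stroke_volume(self) -> float:
        """Closed-form integral of Q over one period, m^3.

        Plateau contributes ``Qp (pulse - 2 ramp)``; each half-cosine ramp
        integrates to ``Qp ramp / 2``.
        """
        return self.peak_flow * self.pulse_duration * (1.0 - self.ramp_fraction)

    def flow_rate(self, t):
        """Periodic closed-form Q(t), m^3/s."""
        s = np.mod(np.asarray(t, dtype=float), self.period)
        tr = self.ramp_duration
        tp = self.pulse_duration
        q = np.zeros_like(s)
        up = s < tr
        q[up] = 0.5 * self.peak_flow * (1 - np.cos(np.pi * s[up] / tr)) if tr > 0 else self.peak_flow
        plat = (s >= tr) & (s <= tp - tr)
        q[plat] = self.peak_flow
        down = (s > tp - tr) & (s < tp)
        if tr > 0:
            q[down] = 0.5 * self.peak_flow * (1 - np.cos(np.pi * (tp - s[down]) / tr))
        return q

    def dflow_dt(self, t):
        """Closed-form dQ/dt, m^3/s^2 (piecewise; zero on plateau and delay)."""
        s = np.mod(np.asarray(t, dtype=float), self.period)
        tr = self.ramp_duration
        tp = self.pulse_duration
        dq = np.zeros_like(s)
        if tr > 0:
            up = s < tr
            dq[up] = 0.5 * self.peak_flow * np.pi / tr * np.sin(np.pi * s[up] / tr)
            down = (s > tp - tr) & (s < tp)
            dq[down] = -0.5 * self.peak_flow * np.pi / tr * np.sin(np.pi * (tp - s[down]) / tr)
        return dq


def make_pulse_waveform(
    peak_flow: float = DEFAULT_PEAK_FLOW,
    pulse_duration: float = DEFAULT_PULSE_DURATION,
    period: float = DEFAULT_PERIOD,
    ramp_fraction: float = DEFAULT_RAMP_FRACTION,
    dt: float = 1e-3,
) -> PulseWaveform:
    """Build the sampled pump waveform over one period."""
    if not pulse_duration > 0:
        raise ParameterError(f"pulse_duration must be positive, got {pulse_duration}")
    if not period > pulse_duration:
        raise ParameterError(f"period ({period}) must exceed pulse_duration ({pulse_duration})")
    if not 0 < ramp_fraction <= 0.5:
        raise ParameterError(f"ramp_fraction must be in (0, 0.5], got {ramp_fraction}")
    if not dt > 0:
        raise ParameterError(f"dt must be positive, got {dt}")
    if peak_flow < 0:
        raise ParameterError(f"peak_flow must be non-negative, got {peak_flow}")
    n = round(period / dt)
    if abs(n * dt - period) > 1e-9 * period:
        raise ParameterError(f"dt ({dt}) does not divide period ({period})")
    t = np.arange(n + 1) * dt
    wf = PulseWaveform(
        period=period,
        pulse_duration=pulse_duration,
        ramp_fraction=ramp_fraction,
        peak_flow=peak_flow,
        time=t,
        flow=np.empty(0),
    )
    object.__setattr__(wf, "flow", wf.flow_rate(t))
    return wf


# ---------------------------------------------------------------------------
# Analytic field kinds: closed-form velocity and pressure oracles.
# ---------------------------------------------------------------------------

_KINDS = ("uniform_unsteady", "stagnation", "solid_body_rotation", "poiseuille_channel", "womersley_axial")


@dataclass(frozen=True)
class AnalyticFieldSpec:
    """An analytic flow with closed-form velocity and pressure.

    Kinds and parameters
    --------------------
    uniform_unsteady : ``u0`` (m/s), ``accel`` (m/s^2)
        u = (u0 + accel*t, 0);  p = -rho*accel*x (inviscid balance).
    stagnation : ``k`` (1/s), ``p0`` (Pa)
        u = (k x, -k y);  p = p0 - rho k^2 (x^2+y^2)/2 (Bernoulli).
    solid_body_rotation : ``omega`` (rad/s), ``p0`` (Pa)
        u = omega (-y, x);  p = p0 + rho omega^2 r^2 / 2 (radial balance).
    poiseuille_channel : ``u_max`` (m/s), ``half_width`` (m)
        u = (u_max (1-(y/h)^2), 0);  p = -2 mu u_max x / h^2 (viscous).
    womersley_axial : ``radius`` (m), ``k0`` (Pa/m), ``harmonics`` tuple of (omega, K)
        x is axial, y is the radial offset from the centreline; the axial
        velocity is the Womersley profile at r=|y| and p = p0 - G(t) x with
        G the driving gradient (viscous, fully developed).
    """

    kind: str
    parameters: dict = field(default_factory=dict)
    fluid: FluidProperties = BLOOD_MIMICKING_FLUID

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ParameterError(f"unknown analytic field kind {self.kind!r}; choose from {_KINDS}")

    def _p(self, name, default=None):
        if default is None and name not in self.parameters:
            raise ParameterError(f"{self.kind} requires parameter {name!r}")
        return self.parameters.get(name, default)

    def _womersley_objects(self):
        radius = self._p("radius")
        hs = _wom.HarmonicSet(k0=self._p("k0", 0.0), harmonics=tuple(self._p("harmonics", ())))
        tube = _wom.TubeSpec(radius=radius, length=1.0, fluid=self.fluid)
        return tube, hs

    def velocity(self, x, y, t):
        """Closed-form (ux, uy) broadcast over x, y, t."""
        x, y, t = np.broadcast_arrays(np.asarray(x, float), np.asarray(y, float), np.asarray(t, float))
        k = self.kind
        if k == "uniform_unsteady":
            ux = self._p("u0", 0.0) + self._p("accel", 0.0) * t
            return ux * np.ones_like(x), np.zeros_like(x)
        if k == "stagnation":
            kk = self._p("k")
            return kk * x, -kk * y
        if k == "solid_body_rotation":
            om = self._p("omega")
            return -om * y, om * x
        if k == "poiseuille_channel":
            h = self._p("half_width")
            ux = self._p("u_max") * (1 - (y / h) ** 2)
            return ux, np.zeros_like(x)
        if k == "womersley_axial":
            tube, hs = self._womersley_objects()
            ux = _wom.womersley_velocity(tube, hs, np.abs(y), t)
            return ux, np.zeros_like(x)
        raise ParameterError(f"unknown kind {k!r}")  # pragma: no cover

    def pressure(self, x, y, t):
        """Closed-form pressure consistent with the governing balance, Pa."""
        x, y, t = np.broadcast_arrays(np.asarray(x, float), np.asarray(y, float), np.asarray(t, float))
        rho = self.fluid.rho
        k = self.kind
        if k == "uniform_unsteady":
            return -rho * self._p("accel", 0.0) * x
        if k == "stagnation":
            return self._p("p0", 0.0) - 0.5 * rho * self._p("k") ** 2 * (x**2 + y**2)
        if k == "solid_body_rotation":
            return self._p("p0", 0.0) + 0.5 * rho * self._p("omega") ** 2 * (x**2 + y**2)
        if k == "poiseuille_channel":
            return -2 * self.fluid.mu * self._p("u_max") / self._p("half_width") ** 2 * x
        if k == "womersley_axial":
            _, hs = self._womersley_objects()
            return self._p("p0", 0.0) - hs.gradient(t) * x
        raise UnsupportedOracleError(f"kind {k!r} has no closed-form pressure")  # pragma: no cover


def sample_analytic_field(spec: AnalyticFieldSpec, grid: ScanGrid) -> VelocityField2D:
    """Evaluate the closed-form velocity on every grid node and frame.

    The result has tq = 1 and valid everywhere.
    """
    tt = grid.t[:, None, None]
    yy = grid.y[None, :, None]
    xx = grid.x[None, None, :]
    ux, uy = spec.velocity(xx, yy, tt)
    return VelocityField2D(
        grid=grid,
        ux=np.broadcast_to(ux, grid.shape).copy(),
        uy=np.broadcast_to(uy, grid.shape).copy(),
        meta={"kind": spec.kind, "parameters": dict(spec.parameters)},
    )


def exact_pressure_drop(spec: AnalyticFieldSpec, a, b, times) -> np.ndarray:
    """Ground-truth pressure drop P(a, t) - P(b, t), Pa.

    Follows the inlet-minus-outlet sign convention: a is the inlet point.
    """
    times = np.asarray(times, dtype=float)
    return spec.pressure(a[0], a[1], times) - spec.pressure(b[0], b[1], times)


# ---------------------------------------------------------------------------
# Scanner-style degradation.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BsiDegradationSpec:
    """Parameters of the speckle-tracking emulation.

    ``v_reject`` models the scanner's low-velocity rejection (0.21 m/s for
    the swell phantoms, 0.13 m/s for the LV phantoms at their respective
    PRFs); rejected samples receive ``tq_bad`` so the downstream TQ > 0.4
    threshold removes them. Tracking quality is binary (good/bad) because
    only the threshold behaviour matters downstream.
    """

    noise_sd: float = 0.02
    v_reject: float = 0.21
    tq_good: float = 0.95
    tq_bad: float = 0.1
    dropout_regions: tuple = ()  # ((x0, x1, y0, y1), ...)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if self.v_reject < 0:
            raise ParameterError(f"v_reject must be non-negative, got {self.v_reject}")
        for name, v in (("tq_good", self.tq_good), ("tq_bad", self.tq_bad)):
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if not self.tq_good > self.tq_bad:
            raise ParameterError("tq_good must exceed tq_bad")


def emulate_bsi(field: VelocityField2D, deg: BsiDegradationSpec) -> VelocityField2D:
    """Degrade a velocity field the way the scanner would.

    Independent Gaussian noise (sd ``noise_sd``) is added to each velocity
    component, reproducibly from ``seed``. Samples whose *noisy* speed falls
    below ``v_reject``, or that lie inside a dropout rectangle, get
    ``tq_bad``; all others get ``tq_good``. The validity mask is inherited
    unchanged — masking on TQ is the downstream estimator's job.
    """
    rng = np.random.default_rng(deg.seed)
    out = field.copy()
    if deg.noise_sd > 0:
        out.ux = out.ux + rng.normal(0.0, deg.noise_sd, size=out.ux.shape)
        out.uy = out.uy + rng.normal(0.0, deg.noise_sd, size=out.uy.shape)
    speed = np.hypot(out.ux, out.uy)
    tq = np.where(speed < deg.v_reject, deg.tq_bad, deg.tq_good)
    if deg.dropout_regions:
        xx, yy = field.grid.meshgrid()
        for (x0, x1, y0, y1) in deg.dropout_regions:
            box = (xx >= x0) & (xx <= x1) & (yy >= y0) & (yy <= y1)
            tq[:, box] = deg.tq_bad
    out.tq = tq
    out.meta = dict(field.meta)
    out.meta["bsi_degradation"] = {
        "noise_sd": deg.noise_sd,
        "v_reject": deg.v_reject,
        "tq_good": deg.tq_good,
        "tq_bad": deg.tq_bad,
        "dropout_regions": [list(r) for r in deg.dropout_regions],
        "seed": deg.seed,
    }
    return out
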