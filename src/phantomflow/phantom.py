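"""Lumped-parameter surrogate of the compliant phantom + flow loop.

The gel cavity is reduced to an R-L-C-R-L network: the pump prescribes the
inflow q_in; the cavity is a single compliant node (compliance c); the
outlet branch discharges through a resistance/inertance pair into a
reservoir held at p_down. Catheter-style pressures are read where the
physical catheters sat — upstream of the inlet constriction and at the
reservoir side of the outlet:

    p_in(t)  = P_c + r_in q_in + l_in dq_in/dt
    p_out(t) = p_down

so that in the stiff-cavity, inertance-free limit the pressure drop reduces
to (r_in + r_out) q_in, and with inertance the drop shows the measured
shape: a positive peak during ramp-up and a negative undershoot at
ramp-down.

The default parameter set is illustrative (chosen so peak drops are a few
mmHg, the magnitude range of the phantom experiments), not fitted to any
physical phantom.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson, solve_ivp

from .errors import IntegrationError, ParameterError
from .synthetic import PulseWaveform

__all__ = ["RCRPhantom", "PhantomSimResult", "simulate_phantom", "mass_balance_check", "DEFAULT_PHANTOM"]


@dataclass(frozen=True)
class RCRPhantom:
    """Lumped network constants of the phantom loop (SI units)."""

    r_in: float = 2.5e6  # Pa*s/m^3
    r_out: float = 2.5e6  # Pa*s/m^3
    c: float = 1.0e-8  # m^3/Pa
    l_in: float = 3.0e5  # Pa*s^2/m^3
    l_out: float = 1.0e5  # Pa*s^2/m^3
    p_down: float = 1000.0  # Pa (reservoir head)

    def __post_init__(self):
        if not self.r_in > 0:
            raise ParameterError(f"r_in must be positive, got {self.r_in}")
        if not self.r_out > 0:
            raise ParameterError(f"r_out must be positive, got {self.r_out}")
        if not self.c > 0:
            raise ParameterError(f"c must be positive, got {self.c}")
        if self.l_in < 0 or self.l_out < 0:
            raise ParameterError("inertances must be non-negative")


DEFAULT_PHANTOM = RCRPhantom()


@dataclass
class PhantomSimResult:
    """Sampled traces of a phantom-loop simulation (SI units)."""

    time: np.ndarray
    p_in: np.ndarray
    p_out: np.ndarray
    q_in: np.ndarray
    q_out: np.ndarray
    v_chamber: np.ndarray
    phantom: RCRPhantom = None
    seed: int | None = None


def simulate_phantom(
    phantom: RCRPhantom,
    waveform: PulseWaveform,
    n_pulses: int = 1,
    dt: float = 1e-3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PhantomSimResult:
    """Integrate the network ODEs over ``n_pulses`` repetitions of the waveform.

    The chamber obeys ``c dP_c/dt = q_in - q_out``; the outlet branch obeys
    ``l_out dq_out/dt = P_c - p_down - r_out q_out`` (algebraic when
    l_out = 0). Adaptive RK45 stepping with a maximum step of 5 ms; traces
    are sampled on a uniform grid of spacing ``dt``. Optional Gaussian
    measurement noise (sd ``noise_sd`` Pa) is added to the reported
    pressures, reproducibly from ``seed``.
    """
    if n_pulses < 1:
        raise ParameterError(f"n_pulses must be >= 1, got {n_pulses}")
    if not 0 < dt <= waveform.period / 100:
        raise ParameterError(f"dt must satisfy 0 < dt <= period/100, got {dt}")

    t_end = n_pulses * waveform.period
    t_eval = np.linspace(0.0, t_end, round(t_end / dt) + 1)

    q_in = waveform.flow_rate
    has_lout = phantom.l_out > 0

    def rhs(t, y):
        p_c = y[0]
        if has_lout:
            q_out = y[1]
            dq_out = (p_c - phantom.p_down - phantom.r_out * q_out) / phantom.l_out
        else:
            q_out = (p_c - phantom.p_down) / phantom.r_out
            dq_out = 0.0
        dp_c = (float(q_in(t)) - q_out) / phantom.c
        return [dp_c, dq_out] if has_lout else [dp_c]

    y0 = [phantom.p_down, 0.0] if has_lout else [phantom.p_down]
    # LSODA switches automatically between non-stiff and stiff stepping: the
    # chamber time constant c*r can be driven arbitrarily small (rigid limit)
    # without stalling the integration.
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method="LSODA",
        t_eval=t_eval,
        max_step=5e-3,
        rtol=1e-9,
        atol=1e-12,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        bad = np.flatnonzero(~np.all(np.isfinite(sol.y), axis=0))
        t_fail = float(sol.t[bad[0]]) if bad.size else float(sol.t[-1])
        raise IntegrationError(f"phantom integration failed near t = {t_fail:.4g} s", t_fail=t_fail)

    p_c = sol.y[0]
    if has_lout:
        q_out = sol.y[1]
    else:
        q_out = (p_c - phantom.p_down) / phantom.r_out
    qi = q_in(t_eval)
    p_in = p_c + phantom.r_in * qi + phantom.l_in * waveform.dflow_dt(t_eval)
    p_out = np.full_like(t_eval, phantom.p_down)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        p_in = p_in + rng.normal(0.0, noise_sd, p_in.shape)
        p_out = p_out + rng.normal(0.0, noise_sd, p_out.shape)
    return PhantomSimResult(
        time=t_eval,
        p_in=p_in,
        p_out=p_out,
        q_in=qi,
        q_out=q_out,
        v_chamber=phantom.c * (p_c - phantom.p_down),
        phantom=phantom,
        seed=seed,
    )


def mass_balance_check(
    result: PhantomSimResult,
    cycle: tuple[float, float],
    rho: float = 1037.0,
    method: str = "simpson",
) -> float:
    """Relative mass residual over a cycle:

        (accumulated mass + mass out - mass in) / mass out

    with masses taken as rho times the time integrals of the flows and the
    accumulation read from the chamber-volume trace. The density cancels in
    the ratio but is kept for dimensional clarity.

    ``method`` selects the flow quadrature: "simpson" (default; the residual
    is then limited by the ODE solver tolerance) or "trapezoid" (second
    order; the residual then scales as the sampling interval squared, which
    makes refinement behaviour visible).
    """
    t0, t1 = cycle
    t = result.time
    if t0 < t[0] - 1e-12 or t1 > t[-1] + 1e-12 or t1 <= t0:
        raise ParameterError(f"cycle {cycle} outside simulated span [{t[0]}, {t[-1]}]")
    if method not in ("simpson", "trapezoid"):
        raise ParameterError(f"unknown quadrature method {method!r}")
    m = (t >= t0 - 1e-12) & (t <= t1 + 1e-12)
    tt = t[m]
    quad = simpson if method == "simpson" else (lambda y, x: np.trapezoid(y, x))
    mass_in = rho * quad(result.q_in[m], x=tt)
    mass_out = rho * quad(result.q_out[m], x=tt)
    accumulated = rho * (result.v_chamber[m][-1] - result.v_chamber[m][0])
    if mass_out == 0:
        raise ParameterError("net mass out over the cycle is zero; residual undefined")
    return float((accumulated + mass_out - mass_in) / mass_out)
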