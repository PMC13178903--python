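"""Constitutive models of the tissue-mimicking gel.

Two laws are implemented:

* Yeoh hyperelastic, uniaxial incompressible loading. With principal
  stretch lambda and the isochoric first invariant I1 = lambda^2 + 2/lambda,
  the first Piola-Kirchhoff stress is

      T = 2 (lambda - lambda^-2) [c1 + 2 c2 (I1 - 3) + 3 c3 (I1 - 3)^2]

  The shipped parameters (c1, c2, c3) = (7.3, 9.4, 0) kPa are the gel fit
  used by the phantom simulations.

* Simplified Kelvin-Voigt viscoelasticity, sigma = E eps + eta deps/dt,
  with retardation time tau = eta / E (about 0.01 s for the gel).

Fitting the Yeoh law is linear in (c1, c2, c3) once the common factor
2(lambda - lambda^-2) is taken out, so recovery is an ordinary least-squares
solve with exact noiseless behaviour.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import FitError, ParameterError

__all__ = [
    "YeohParams",
    "KelvinVoigtParams",
    "StrainHistory",
    "yeoh_uniaxial_stress",
    "kelvin_voigt_stress",
    "retardation_time",
    "simulate_creep",
    "fit_yeoh",
    "YeohUniaxialModel",
    "YeohFitResults",
    "DEFAULT_YEOH",
    "DEFAULT_KELVIN_VOIGT",
]


@dataclass(frozen=True)
class YeohParams:
    """Yeoh coefficients, Pa. c1 must be positive; c2, c3 non-negative."""

    c1: float = 7300.0
    c2: float = 9400.0
    c3: float = 0.0

    def __post_init__(self):
        if not self.c1 > 0:
            raise ParameterError(f"c1 must be positive, got {self.c1}")
        if self.c2 < 0 or self.c3 < 0:
            raise ParameterError("c2 and c3 must be non-negative")


DEFAULT_YEOH = YeohParams()


@dataclass(frozen=True)
class KelvinVoigtParams:
    """Kelvin-Voigt constants: elastic modulus E (Pa) and viscosity eta (Pa*s)."""

    e_mod: float
    eta: float

    def __post_init__(self):
        if not self.e_mod > 0:
            raise ParameterError(f"e_mod must be positive, got {self.e_mod}")
        if not self.eta > 0:
            raise ParameterError(f"eta must be positive, got {self.eta}")

    @property
    def tau(self) -> float:
        """Retardation time tau = eta / E, s."""
        return self.eta / self.e_mod


#: Gel viscoelastic constants giving the reported retardation time of 0.01 s.
DEFAULT_KELVIN_VOIGT = KelvinVoigtParams(e_mod=100e3, eta=1e3)


@dataclass
class StrainHistory:
    """Uniaxial strain history with its rate and (optionally) stress."""

    time: np.ndarray
    strain: np.ndarray
    strain_rate: np.ndarray = None
    stress: np.ndarray = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        if self.time.ndim != 1 or np.any(np.diff(self.time) <= 0):
            raise ParameterError("time must be 1-D and strictly increasing")
        if self.strain.shape != self.time.shape:
            raise ParameterError("strain must match time in shape")
        if self.strain_rate is None:
            self.strain_rate = np.gradient(self.strain, self.time)
        self.strain_rate = np.asarray(self.strain_rate, dtype=float)
        if self.strain_rate.shape != self.time.shape:
            raise ParameterError("strain_rate must match time in shape")


def _i1_uniaxial(lam):
    return lam**2 + 2.0 / lam


def yeoh_uniaxial_stress(params: YeohParams, lam):
    """First Piola-Kirchhoff stress T(lambda), Pa, for uniaxial loading."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ParameterError("stretch must be positive")
    i1 = _i1_uniaxial(lam)
    return 2 * (lam - lam**-2) * (
        params.c1 + 2 * params.c2 * (i1 - 3) + 3 * params.c3 * (i1 - 3) ** 2
    )


def kelvin_voigt_stress(params: KelvinVoigtParams, history: StrainHistory) -> np.ndarray:
    """Pointwise sigma = E eps + eta deps/dt, Pa."""
    return params.e_mod * history.strain + params.eta * history.strain_rate


def retardation_time(e_mod: float, eta: float) -> float:
    """tau = eta / E, s."""
    if e_mod <= 0:
        raise ParameterError(f"e_mod must be positive, got {e_mod}")
    return eta / e_mod


def simulate_creep(params: KelvinVoigtParams, sigma0: float, t_end: float, dt: float = 1e-4) -> StrainHistory:
    """Creep under a constant stress, integrating deps/dt = (sigma0 - E eps)/eta.

    The closed-form response is eps(t) = (sigma0/E)(1 - exp(-t/tau)); this
    routine integrates the ODE numerically so it can serve as the simulation
    side of a dual-route check.
    """
    if t_end <= 0 or dt <= 0:
        raise ParameterError("t_end and dt must be positive")
    t = np.arange(round(t_end / dt) + 1) * dt
    sol = solve_ivp(
        lambda tt, eps: (sigma0 - params.e_mod * eps[0]) / params.eta,
        (0.0, t[-1]),
        [0.0],
        t_eval=t,
        method="RK45",
        rtol=1e-10,
        atol=1e-14,
    )
    eps = sol.y[0]
    rate = (sigma0 - params.e_mod * eps) / params.eta
    return StrainHistory(time=t, strain=eps, strain_rate=rate, stress=np.full_like(t, sigma0))


# ---------------------------------------------------------------------------
# Yeoh fitting (linear in the coefficients).
# ---------------------------------------------------------------------------


class YeohUniaxialModel:
    """Least-squares Yeoh fit to uniaxial stretch/stress data.

    The model is linear in (c1, c2, c3) after factoring 2(lambda - 1/lambda^2),
    so :meth:`fit` is an ordinary least-squares solve with exact recovery on
    noiseless data.

    Parameters
    ----------
    stretch : array
        Principal stretches lambda (dimensionless, > 0, not all equal).
    stress : array
        Measured first Piola-Kirchhoff stresses, Pa.
    """

    def __init__(self, stretch, stress):
        self.stretch = np.asarray(stretch, dtype=float)
        self.stress = np.asarray(stress, dtype=float)
        if self.stretch.shape != self.stress.shape or self.stretch.ndim != 1:
            raise ParameterError("stretch and stress must be 1-D arrays of equal length")
        if np.any(self.stretch <= 0):
            raise ParameterError("stretches must be positive")

    @classmethod
    def from_dataframe(cls, df, stretch_col: str = "lam", stress_col: str = "stress_Pa"):
        return cls(df[stretch_col].to_numpy(), df[stress_col].to_numpy())

    def _design(self, fix_c3_zero: bool):
        lam = self.stretch
        pref = 2 * (lam - lam**-2)
        e = _i1_uniaxial(lam) - 3
        cols = [pref, pref * 2 * e]
        if not fix_c3_zero:
            cols.append(pref * 3 * e**2)
        return np.column_stack(cols)

    def fit(self, fix_c3_zero: bool = False) -> "YeohFitResults":
        n_par = 2 if fix_c3_zero else 3
        lam = self.stretch
        # Points at lam == 1 carry no information (prefactor vanishes).
        informative = np.unique(np.round(lam[np.abs(lam - 1) > 1e-12], 12))
        if informative.size < n_par:
            raise FitError(
                f"need >= {n_par} distinct stretches away from 1 to identify {n_par} parameters"
            )
        x = self._design(fix_c3_zero)
        if np.linalg.matrix_rank(x) < n_par:
            raise FitError("rank-deficient design: stretches do not identify the parameters")
        beta, rss, *_ = np.linalg.lstsq(x, self.stress, rcond=None)
        resid = self.stress - x @ beta
        rss_val = float(resid @ resid)
        dof = self.stretch.size - n_par
        cov = None
        if dof > 0:
            s2 = rss_val / dof
            cov = s2 * np.linalg.inv(x.T @ x)
        if fix_c3_zero:
            beta = np.append(beta, 0.0)
        try:
            params = YeohParams(c1=float(beta[0]), c2=float(max(beta[1], 0.0)), c3=float(max(beta[2], 0.0)))
        except ParameterError:
            params = None  # unphysical estimates; raw_coefficients keep the values
        return YeohFitResults(
            model=self,
            params=params,
            raw_coefficients=beta,
            resid=resid,
            rss=rss_val,
            cov=cov,
            fix_c3_zero=fix_c3_zero,
        )


class YeohFitResults:
    """Estimates, uncertainties and diagnostics of a Yeoh uniaxial fit."""

    def __init__(self, model, params, raw_coefficients, resid, rss, cov, fix_c3_zero):
        self.model = model
        self.params = params
        self.raw_coefficients = raw_coefficients
        self.resid = resid
        self.rss = rss
        self.cov = cov
        self.fix_c3_zero = fix_c3_zero

    @property
    def bse(self):
        """Standard errors of the fitted coefficients (None if dof = 0)."""
        if self.cov is None:
            return None
        return np.sqrt(np.diag(self.cov))

    @property
    def resid_norm(self) -> float:
        return float(np.sqrt(self.rss))

    def predict(self, lam=None):
        lam = self.model.stretch if lam is None else np.asarray(lam, dtype=float)
        return yeoh_uniaxial_stress(
            YeohParams(
                c1=max(self.raw_coefficients[0], np.finfo(float).tiny),
                c2=max(self.raw_coefficients[1], 0.0),
                c3=max(self.raw_coefficients[2], 0.0),
            ),
            lam,
        )

    def summary(self) -> str:
        names = ["c1", "c2", "c3"]
        lines = [
            "Yeoh uniaxial fit (linear least squares)",
            "========================================",
            f"n obs: {self.model.stretch.size}   c3 fixed at 0: {self.fix_c3_zero}",
        ]
        se = self.bse
        for i, name in enumerate(names):
            if self.fix_c3_zero and i == 2:
                lines.append(f"{name}: 0.0 Pa (fixed)")
            elif se is not None and i < len(se):
                lines.append(f"{name}: {self.raw_coefficients[i]:.6g} Pa  (se {se[i]:.3g})")
            else:
                lines.append(f"{name}: {self.raw_coefficients[i]:.6g} Pa")
        lines.append(f"residual norm: {self.resid_norm:.6g} Pa")
        return "\n".join(lines)


def fit_yeoh(stretch, stress, fix_c3_zero: bool = False) -> YeohFitResults:
    """Functional wrapper around :class:`YeohUniaxialModel`."""
    return YeohUniaxialModel(stretch, stress).fit(fix_c3_zero=fix_c3_zero)
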