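"""Core data containers for scan-grid velocity data.

Coordinate convention (fixed package-wide): x rightward, y upward, arrays
indexed ``(frame, y, x)``; metres and seconds internally.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParameterError

__all__ = ["FluidProperties", "ScanGrid", "VelocityField2D", "BLOOD_MIMICKING_FLUID"]


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid constants.

    Parameters
    ----------
    rho : float
        Mass density, kg/m^3. Must be positive.
    mu : float
        Dynamic viscosity, Pa*s. Must be positive.
    """

    rho: float
    mu: float

    def __post_init__(self):
        if not self.rho > 0:
            raise ParameterError(f"rho must be positive, got {self.rho}")
        if not self.mu > 0:
            raise ParameterError(f"mu must be positive, got {self.mu}")

    @property
    def nu(self) -> float:
        """Kinematic viscosity, m^2/s."""
        return self.mu / self.rho


#: Blood-mimicking fluid used throughout the phantom experiments.
BLOOD_MIMICKING_FLUID = FluidProperties(rho=1037.0, mu=4.1e-3)


def _check_axis(name: str, v: np.ndarray, rel_tol: float) -> None:
    if v.ndim != 1 or v.size < 3:
        raise DataError(f"{name} must be 1-D with at least 3 samples, got shape {v.shape}")
    d = np.diff(v)
    if np.any(d <= 0):
        raise DataError(f"{name} must be strictly increasing")
    h = d.mean()
    if np.max(np.abs(d - h)) > rel_tol * abs(h):
        raise DataError(f"{name} spacing is not uniform within rel_tol={rel_tol}")


@dataclass(frozen=True)
class ScanGrid:
    """Uniform rectilinear scan grid: coordinates in metres, frame times in s."""

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    rel_tol: float = 1e-6

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        for name, v in (("x", self.x), ("y", self.y), ("t", self.t)):
            _check_axis(name, v, self.rel_tol)

    @property
    def dx(self) -> float:
        return float(np.diff(self.x).mean())

    @property
    def dy(self) -> float:
        return float(np.diff(self.y).mean())

    @property
    def dt(self) -> float:
        return float(np.diff(self.t).mean())

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape implied by the grid: (n_frames, n_y, n_x)."""
        return (self.t.size, self.y.size, self.x.size)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """2-D coordinate arrays X, Y of shape (n_y, n_x)."""
        return np.meshgrid(self.x, self.y)

    def contains(self, x: float, y: float) -> bool:
        return (self.x[0] <= x <= self.x[-1]) and (self.y[0] <= y <= self.y[-1])


@dataclass
class VelocityField2D:
    """Time-resolved 2-D velocity field with per-sample tracking quality.

    Arrays are indexed ``(frame, y, x)``. ``tq`` is the scanner-style tracking
    quality in [0, 1]; ``valid`` marks samples usable for analysis.
    """

    grid: ScanGrid
    ux: np.ndarray
    uy: np.ndarray
    tq: np.ndarray = None
    valid: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        shape = self.grid.shape
        self.ux = np.asarray(self.ux, dtype=float)
        self.uy = np.asarray(self.uy, dtype=float)
        if self.tq is None:
            self.tq = np.ones(shape)
        if self.valid is None:
            self.valid = np.ones(shape, dtype=bool)
        self.tq = np.asarray(self.tq, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        for name, a in (("ux", self.ux), ("uy", self.uy), ("tq", self.tq), ("valid", self.valid)):
            if a.shape != shape:
                raise DataError(f"{name} has shape {a.shape}, expected {shape} from grid")
        if np.any((self.tq < 0) | (self.tq > 1)):
            raise DataError("tq values must lie in [0, 1]")
        if not np.all(np.isfinite(self.ux[self.valid])) or not np.all(np.isfinite(self.uy[self.valid])):
            raise DataError("velocities must be finite wherever valid is true")

    def speed(self) -> np.ndarray:
        return np.hypot(self.ux, self.uy)

    def copy(self) -> "VelocityField2D":
        return VelocityField2D(
            grid=self.grid,
            ux=self.ux.copy(),
            uy=self.uy.copy(),
            tq=self.tq.copy(),
            valid=self.valid.copy(),
            meta=dict(self.meta),
        )

    def with_valid(self, valid: np.ndarray) -> "VelocityField2D":
        out = self.copy()
        out.valid = np.asarray(valid, dtype=bool)
        if out.valid.shape != self.grid.shape:
            raise DataError("replacement valid mask has wrong shape")
        return out
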