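"""Catheter-trace measurement protocol.

Mirrors how the phantom pressure data were handled: six pump pulses are
recorded, the first three discarded (flow establishment), the next three
averaged pointwise into a representative single-period curve; the pressure
drop is inlet minus outlet; extrema and their times are read off the
averaged curve; replicates are compared across groups with a one-way ANOVA
and pairwise with Welch's t-test at two-sided alpha = 0.05 (the package's
choice of tests — the comparison structure, not the specific test names,
comes from the protocol).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, DataError, ParameterError, ProtocolError, SegmentationError

__all__ = [
    "PressureTrace",
    "PulseEnsemble",
    "MethodSummary",
    "segment_pulses",
    "representative_curve",
    "delta_p",
    "extrema",
    "timing_shift",
    "compare_methods",
]


@dataclass
class PressureTrace:
    """Uniformly sampled pressure signal, mmHg."""

    time: np.ndarray
    pressure: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise DataError("time must be 1-D with >= 2 samples")
        d = np.diff(self.time)
        if np.any(d <= 0):
            raise DataError("time must be strictly increasing")
        if np.max(np.abs(d - d.mean())) > 1e-6 * d.mean():
            raise DataError("time must be uniformly sampled")
        if self.pressure.shape != self.time.shape:
            raise DataError("pressure must match time in shape")
        if not np.all(np.isfinite(self.pressure)):
            raise DataError("pressures must be finite")

    @property
    def dt(self) -> float:
        return float(np.diff(self.time).mean())


@dataclass
class PulseEnsemble:
    """Equal-length, non-overlapping single-period segments of a trace."""

    starts: np.ndarray  # start indices into the source trace
    segments: np.ndarray  # (n_pulses, n_samples)
    dt: float
    source_label: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n_pulses(self) -> int:
        return self.segments.shape[0]


def segment_pulses(trace: PressureTrace, period: float, trigger=None) -> PulseEnsemble:
    """Split a trace into one-period segments.

    ``trigger`` may be None (segments anchored at the trace start, i.e. the
    pump waveform's own time base), a PulseWaveform-like object with a
    ``period`` attribute (same behaviour, with the waveform period checked
    against ``period``), or a float threshold: pulse starts are then upward
    crossings of the threshold with hysteresis (the signal must fall below
    the threshold minus half the hysteresis band before re-triggering).
    """
    if period <= 0:
        raise ParameterError(f"period must be positive, got {period}")
    if trace.time[-1] - trace.time[0] < 2 * period - 1e-9:
        raise DataError("trace must span at least 2 periods")
    n_per = int(round(period / trace.dt))
    if abs(n_per * trace.dt - period) > 1e-6 * period:
        raise ParameterError("period is not an integer number of samples")

    if trigger is None or hasattr(trigger, "period"):
        if trigger is not None and abs(trigger.period - period) > 1e-9:
            raise ParameterError("waveform period disagrees with the requested period")
        starts = np.arange(0, trace.time.size - n_per + 1, n_per)
    else:
        thr = float(trigger)
        p = trace.pressure
        band = 0.5 * (np.percentile(p, 95) - np.percentile(p, 5)) * 0.1
        crossings = []
        armed = True
        for i in range(1, p.size):
            if armed and p[i - 1] < thr <= p[i]:
                crossings.append(i)
                armed = False
            elif not armed and p[i] < thr - band:
                armed = True
        if not crossings:
            raise SegmentationError(f"no upward crossings of threshold {thr}")
        starts = []
        last = None
        jitter = 2  # sampling jitter of the crossing index, samples
        for i in crossings:
            if last is not None and i - last < n_per - jitter:
                continue
            i = i if last is None else max(i, last + n_per)  # keep segments non-overlapping
            if i + n_per <= p.size:
                starts.append(i)
                last = i
        if not starts:
            raise SegmentationError("no complete period fits after the first trigger")
        starts = np.asarray(starts)
    segments = np.stack([trace.pressure[s : s + n_per] for s in starts])
    return PulseEnsemble(
        starts=np.asarray(starts),
        segments=segments,
        dt=trace.dt,
        source_label=trace.label,
        meta={"period": period},
    )


def representative_curve(ensemble: PulseEnsemble, discard: int = 3, use: int = 3) -> PressureTrace:
    """Pointwise mean of pulses discard+1 ... discard+use (protocol default 3/3)."""
    if discard < 0 or use < 1:
        raise ProtocolError(f"invalid protocol counts discard={discard}, use={use}")
    if ensemble.n_pulses < discard + use:
        raise ProtocolError(
            f"ensemble has {ensemble.n_pulses} pulses; protocol needs discard ({discard}) + use ({use})"
        )
    seg = ensemble.segments[discard : discard + use]
    t = np.arange(seg.shape[1]) * ensemble.dt
    return PressureTrace(time=t, pressure=seg.mean(axis=0), label=f"{ensemble.source_label} (representative)")


def delta_p(inlet: PressureTrace, outlet: PressureTrace) -> PressureTrace:
    """Pointwise pressure drop, inlet minus outlet, mmHg.

    The traces must share a time base to within one sample; a sub-sample
    offset is removed by linear interpolation of the outlet onto the inlet
    times.
    """
    if abs(inlet.dt - outlet.dt) > 1e-9 * inlet.dt:
        raise AlignmentError("traces have different sampling intervals")
    t0_off = outlet.time[0] - inlet.time[0]
    if abs(t0_off) > inlet.dt * (1 + 1e-9):
        raise AlignmentError(
            f"time bases offset by {t0_off:.4g} s (> one sample); resample explicitly first"
        )
    lo = max(inlet.time[0], outlet.time[0])
    hi = min(inlet.time[-1], outlet.time[-1])
    if hi <= lo:
        raise AlignmentError("traces have disjoint time ranges")
    m = (inlet.time >= lo - 1e-12) & (inlet.time <= hi + 1e-12)
    t = inlet.time[m]
    p_out = np.interp(t, outlet.time, outlet.pressure)
    return PressureTrace(time=t, pressure=inlet.pressure[m] - p_out, label="dP")


def extrema(curve: PressureTrace):
    """Global extrema of a (typically representative) dP curve.

    Returns (max dP, t of max, min dP, t of min); ties break to the earliest
    time because argmax/argmin return the first occurrence.
    """
    p = curve.pressure
    i_max = int(np.argmax(p))
    i_min = int(np.argmin(p))
    return float(p[i_max]), float(curve.time[i_max]), float(p[i_min]), float(curve.time[i_min])


def timing_shift(curve_a: PressureTrace, curve_b: PressureTrace) -> float:
    """Lag (s) of curve_b behind curve_a, positive when b lags a.

    The lag maximises the normalised cross-correlation of the mean-removed
    curves; the integer-sample peak is refined by parabolic interpolation.
    """
    if abs(curve_a.dt - curve_b.dt) > 1e-9 * curve_a.dt:
        raise AlignmentError("traces have different sampling intervals")
    a = curve_a.pressure - curve_a.pressure.mean()
    b = curve_b.pressure - curve_b.pressure.mean()
    if np.allclose(a, 0) or np.allclose(b, 0):
        raise DataError("zero-variance input: correlation undefined")
    corr = np.correlate(b, a, mode="full")
    lags = np.arange(-(a.size - 1), b.size)
    k = int(np.argmax(corr))
    # Parabolic refinement of the correlation peak.
    if 0 < k < corr.size - 1:
        c_m, c_0, c_p = corr[k - 1 : k + 2]
        denom = c_m - 2 * c_0 + c_p
        frac = 0.0 if denom == 0 else 0.5 * (c_m - c_p) / denom
    else:
        frac = 0.0
    return float((lags[k] + frac) * curve_a.dt + (curve_b.time[0] - curve_a.time[0]))


@dataclass
class MethodSummary:
    """Per-group extrema statistics in the layout of the phantom summary tables."""

    table: pd.DataFrame  # one row per group: n, mean/sd of max and min dP
    pairwise: pd.DataFrame  # Welch t-test p-values per metric and group pair
    anova: dict  # one-way ANOVA p-value per metric (across all groups)
    alpha: float
    notes: list


def compare_methods(extrema_by_group: dict, alpha: float = 0.05) -> MethodSummary:
    """Summarise per-replicate (max dP, min dP) pairs by group.

    Parameters
    ----------
    extrema_by_group : dict
        Mapping group label -> sequence of (max_dp, min_dp) per replicate.

    Groups with a single replicate get no SD and are excluded from tests,
    with an explicit note rather than a silent omission.
    """
    notes = []
    rows = []
    maxs, mins = {}, {}
    for name, vals in extrema_by_group.items():
        arr = np.asarray(vals, dtype=float).reshape(-1, 2)
        if arr.shape[0] < 1:
            raise ParameterError(f"group {name!r} has no replicates")
        maxs[name] = arr[:, 0]
        mins[name] = arr[:, 1]
        row = {
            "group": name,
            "n": arr.shape[0],
            "max_dp_mean": arr[:, 0].mean(),
            "min_dp_mean": arr[:, 1].mean(),
        }
        if arr.shape[0] >= 2:
            row["max_dp_sd"] = arr[:, 0].std(ddof=1)
            row["min_dp_sd"] = arr[:, 1].std(ddof=1)
        else:
            row["max_dp_sd"] = np.nan
            row["min_dp_sd"] = np.nan
            notes.append(f"group {name!r}: single replicate, SD and tests skipped")
        rows.append(row)
    table = pd.DataFrame(rows).set_index("group")

    testable = [g for g in extrema_by_group if len(maxs[g]) >= 2]
    anova = {}
    for metric, data in (("max_dp", maxs), ("min_dp", mins)):
        if len(testable) >= 2:
            anova[metric] = float(stats.f_oneway(*[data[g] for g in testable]).pvalue)
        else:
            anova[metric] = np.nan
            notes.append(f"ANOVA on {metric} skipped: fewer than 2 testable groups")

    pw_rows = []
    for metric, data in (("max_dp", maxs), ("min_dp", mins)):
        for i, g1 in enumerate(testable):
            for g2 in testable[i + 1 :]:
                p = float(stats.ttest_ind(data[g1], data[g2], equal_var=False).pvalue)
                pw_rows.append(
                    {
                        "metric": metric,
                        "group_a": g1,
                        "group_b": g2,
                        "p_value": p,
                        "significant": p < alpha,
                    }
                )
    pairwise = pd.DataFrame(pw_rows, columns=["metric", "group_a", "group_b", "p_value", "significant"])
    return MethodSummary(table=table, pairwise=pairwise, anova=anova, alpha=alpha, notes=notes)
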