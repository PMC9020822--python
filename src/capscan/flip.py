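"""FLIP (fluorescence loss in photobleaching) trace analysis.

A FLIP experiment continuously bleaches one nuclear region while imaging and
follows the fluorescence loss in a target ROI on the nuclear envelope, a
second envelope ROI at equal distance from the bleach point, and an ROI in an
adjacent cell that controls for overall acquisition bleaching. This module
normalizes traces to the last pre-bleach frame, divides out the adjacent-cell
control, summarizes each decay by its interpolated half-time (primary,
model-free) and a constrained exponential rate (secondary), and compares
bleach sites between groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class FlipTrace:
    """Time-stamped ROI mean intensities for one FLIP acquisition."""

    time: np.ndarray  # seconds, strictly increasing
    target: np.ndarray
    control_ne: np.ndarray
    adjacent_cell: np.ndarray
    bleach_onset_frame: int  # index of the first frame affected by bleaching
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        self.control_ne = np.asarray(self.control_ne, dtype=float)
        self.adjacent_cell = np.asarray(self.adjacent_cell, dtype=float)
        n = len(self.time)
        if not (len(self.target) == len(self.control_ne) == len(self.adjacent_cell) == n):
            raise ValidationError("all FLIP series must have equal length")
        if self.bleach_onset_frame < 1 or self.bleach_onset_frame >= n:
            raise ValidationError("bleach_onset_frame must lie in [1, n_frames)")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def series(self) -> dict[str, np.ndarray]:
        return {
            "target": self.target,
            "control_ne": self.control_ne,
            "adjacent_cell": self.adjacent_cell,
        }


def normalize_trace(trace: FlipTrace) -> FlipTrace:
    """Divide each ROI series by its own value at the last pre-bleach frame.

    The normalized value at ``bleach_onset_frame - 1`` is exactly 1 for every
    series; normalization is idempotent and invariant to rescaling the raw
    intensities.
    """
    ref = trace.bleach_onset_frame - 1
    out = {}
    for name, series in trace.series().items():
        v = series[ref]
        if v <= 0:
            raise ValidationError(f"pre-bleach intensity of {name} is not positive")
        out[name] = series / v
    return replace(trace, **out)


def correct_acquisition_bleaching(normalized: FlipTrace) -> FlipTrace:
    """Divide the nuclear ROI series by the adjacent-cell control series.

    Removes global acquisition bleaching shared by all ROIs; the returned
    trace has its adjacent-cell series set to 1.
    """
    adj = normalized.adjacent_cell
    if np.any(adj <= 0):
        raise ValidationError("adjacent-cell series must be positive everywhere")
    return replace(
        normalized,
        target=normalized.target / adj,
        control_ne=normalized.control_ne / adj,
        adjacent_cell=np.ones_like(adj),
    )


def post_bleach(trace: FlipTrace, series: str = "target") -> tuple[np.ndarray, np.ndarray]:
    """Slice a series from the last pre-bleach frame onward, with time
    re-zeroed at that frame (bleach onset)."""
    ref = trace.bleach_onset_frame - 1
    values = trace.series()[series][ref:]
    time = trace.time[ref:] - trace.time[ref]
    return time, values


@dataclass
class DecaySummary:
    half_time: float  # s; inf if the series never crosses 0.5
    rate: float  # /s from A*exp(-k t) + c fit; nan if the fit fails
    amplitude: float
    offset: float


def half_time(series: np.ndarray, time: np.ndarray) -> float:
    """First time (relative to time[0]) at which the linearly interpolated
    series crosses 0.5; inf if it never does."""
    series = np.asarray(series, dtype=float)
    time = np.asarray(time, dtype=float)
    below = np.flatnonzero(series <= 0.5)
    if len(below) == 0:
        return math.inf
    i = below[0]
    if i == 0:
        return 0.0
    s0, s1 = series[i - 1], series[i]
    t0, t1 = time[i - 1], time[i]
    frac = (s0 - 0.5) / (s0 - s1)
    return float(t0 + frac * (t1 - t0) - time[0])


def decay_summary(series: np.ndarray, time: np.ndarray, fit: bool = True) -> DecaySummary:
    """Summarize a normalized decay (starting near 1, decreasing in trend).

    The half-time comes from linear interpolation; the rate from a
    least-squares fit of A*exp(-k*t)+c with A, k, c >= 0. Fit failure leaves
    the rate as NaN while the half-time is still reported.
    """
    series = np.asarray(series, dtype=float)
    time = np.asarray(time, dtype=float)
    if len(series) != len(time) or len(series) < 3:
        raise ValidationError("series and time must be equal-length, >= 3 samples")
    t_half = half_time(series, time)

    rate = amplitude = offset = math.nan
    if fit:
        t_rel = time - time[0]
        c0 = max(float(series.min()), 0.0)
        a0 = max(float(series[0] - c0), 1e-6)
        k0 = math.log(2.0) / t_half if math.isfinite(t_half) and t_half > 0 else 0.1

        def model(t, a, k, c):
            return a * np.exp(-k * t) + c

        try:
            popt, _ = curve_fit(
                model,
                t_rel,
                series,
                p0=(a0, k0, c0),
                bounds=(0.0, np.inf),
                maxfev=10_000,
            )
            amplitude, rate, offset = map(float, popt)
        except (RuntimeError, ValueError):
            logger.warning("exponential decay fit did not converge")
    return DecaySummary(half_time=t_half, rate=rate, amplitude=amplitude, offset=offset)


@dataclass
class SiteComparison:
    """Frame-wise group mean curves and a half-time t-test between sites."""

    time: np.ndarray
    mean_a: np.ndarray
    sem_a: np.ndarray
    mean_b: np.ndarray
    sem_b: np.ndarray
    half_times_a: np.ndarray
    half_times_b: np.ndarray
    t_statistic: float
    p_value: float


def _processed(trace: FlipTrace) -> FlipTrace:
    return correct_acquisition_bleaching(normalize_trace(trace))


def _resample_group(
    traces: Sequence[FlipTrace], grid: np.ndarray
) -> np.ndarray:
    rows = []
    for tr in traces:
        corrected = _processed(tr)
        if len(tr.time) == len(grid) and np.allclose(tr.time, grid):
            rows.append(corrected.target)
        else:
            rows.append(np.interp(grid, tr.time, corrected.target))
    return np.vstack(rows)


def compare_sites(
    cap_traces: Sequence[FlipTrace], control_traces: Sequence[FlipTrace]
) -> SiteComparison:
    """Compare fluorescence loss at the cap site versus the control site.

    Each trace is normalized, corrected for acquisition bleaching and reduced
    to its post-onset half-time; groups are compared with a two-sided pooled
    t-test on half-times. Traces on unequal frame grids are resampled onto
    the coarsest grid by linear interpolation (logged).
    """
    from .metrics import group_test  # local import avoids a module cycle

    if len(cap_traces) < 3 or len(control_traces) < 3:
        raise ValidationError("need at least 3 traces per site")

    all_traces = list(cap_traces) + list(control_traces)
    grids = [tr.time for tr in all_traces]
    if any(len(g) != len(grids[0]) or not np.allclose(g, grids[0]) for g in grids[1:]):
        grid = min(grids, key=len)
        logger.warning("unequal frame grids; resampling to the coarsest grid")
    else:
        grid = grids[0]

    curves_a = _resample_group(cap_traces, grid)
    curves_b = _resample_group(control_traces, grid)

    def halves(traces: Sequence[FlipTrace]) -> np.ndarray:
        hs = []
        for tr in traces:
            t, v = post_bleach(_processed(tr))
            hs.append(half_time(v, t))
        return np.asarray(hs)

    ha, hb = halves(cap_traces), halves(control_traces)
    finite_a, finite_b = ha[np.isfinite(ha)], hb[np.isfinite(hb)]
    if len(finite_a) < 2 or len(finite_b) < 2:
        raise ValidationError("fewer than 2 finite half-times in a group")
    if len(finite_a) < len(ha) or len(finite_b) < len(hb):
        logger.warning(
            "dropped %d traces whose corrected signal never crossed 0.5",
            (len(ha) - len(finite_a)) + (len(hb) - len(finite_b)),
        )
    res = group_test(finite_a, finite_b)

    return SiteComparison(
        time=grid,
        mean_a=curves_a.mean(axis=0),
        sem_a=curves_a.std(axis=0, ddof=1) / math.sqrt(len(curves_a)),
        mean_b=curves_b.mean(axis=0),
        sem_b=curves_b.std(axis=0, ddof=1) / math.sqrt(len(curves_b)),
        half_times_a=ha,
        half_times_b=hb,
        t_statistic=res.t,
        p_value=res.p,
    )


__all__ = [
    "DecaySummary",
    "FlipTrace",
    "SiteComparison",
    "compare_sites",
    "correct_acquisition_bleaching",
    "decay_summary",
    "half_time",
    "normalize_trace",
    "post_bleach",
]
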