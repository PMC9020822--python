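"""Plotting helpers mirroring the standard presentation of each statistic:
per-cohort strip/box plots for colocalization and RA, overlaid survival step
curves with confidence bands, and group-mean FLIP decay curves."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .flip import SiteComparison
from .lifespan import SurvivalCurve


def cohort_strip_plot(
    df: pd.DataFrame, by: str = "cohort", value: str = "r", ax: plt.Axes | None = None, seed: int = 0
) -> plt.Axes:
    """Strip plot of per-cell values by cohort with group mean +/- SEM bars."""
    if ax is None:
        _, ax = plt.subplots()
    rng = np.random.default_rng(seed)
    labels = list(dict.fromkeys(df[by]))
    for i, label in enumerate(labels):
        vals = df.loc[df[by] == label, value].to_numpy(dtype=float)
        x = i + rng.uniform(-0.15, 0.15, len(vals))
        ax.plot(x, vals, "o", alpha=0.5, markersize=4)
        mean = vals.mean()
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        ax.errorbar(i, mean, yerr=sem, fmt="_", color="black", capsize=6, markersize=20)
    ax.set_xticks(range(len(labels)), labels)
    ax.set_ylabel(value)
    return ax


def survival_plot(curves: Sequence[SurvivalCurve], ax: plt.Axes | None = None) -> plt.Axes:
    """Overlaid Kaplan-Meier step curves with 95% confidence bands."""
    if ax is None:
        _, ax = plt.subplots()
    for curve in curves:
        ax.step(curve.times, curve.survival, where="post", label=curve.strain or None)
        ax.fill_between(
            curve.times, curve.ci_low, curve.ci_high, step="post", alpha=0.2
        )
    ax.set_xlabel("divisions")
    ax.set_ylabel("fraction alive")
    ax.set_ylim(0, 1.02)
    if any(c.strain for c in curves):
        ax.legend()
    return ax


def flip_plot(comparison: SiteComparison, labels: tuple[str, str] = ("cap", "control"),
              ax: plt.Axes | None = None) -> plt.Axes:
    """Group-mean corrected FLIP decay curves with SEM ribbons."""
    if ax is None:
        _, ax = plt.subplots()
    for mean, sem, label in (
        (comparison.mean_a, comparison.sem_a, labels[0]),
        (comparison.mean_b, comparison.sem_b, labels[1]),
    ):
        ax.plot(comparison.time, mean, label=label)
        ax.fill_between(comparison.time, mean - sem, mean + sem, alpha=0.2)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("relative intensity")
    ax.legend()
    return ax


__all__ = ["cohort_strip_plot", "flip_plot", "survival_plot"]
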