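"""Replicative-lifespan survival statistics.

Replicative lifespan (RLS) is the number of budding cycles a yeast mother
cell completes before death. Cohorts observed on a microfluidic dissection
platform yield per-cell division counts with right-censoring for cells lost
before death. This module estimates Kaplan-Meier survival curves with 95%
confidence bands (plain Greenwood by default, log-log optional), extracts the
median RLS, and compares cohorts with the two-group log-rank test.

Estimation is delegated to lifelines; confidence bands and the median
convention are computed from the risk table so the exact conventions used
here are explicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import EstimationError, ValidationError


@dataclass
class LifespanCohort:
    """Per-cell division counts with censoring flags for one strain."""

    divisions: np.ndarray  # positive ints; last counted division per cell
    observed: np.ndarray  # True = death observed, False = right-censored
    strain: str = ""

    def __post_init__(self) -> None:
        self.divisions = np.asarray(self.divisions, dtype=int)
        self.observed = np.asarray(self.observed, dtype=bool)
        if len(self.divisions) != len(self.observed):
            raise ValidationError("divisions and observed must have equal length")
        if len(self.divisions) == 0:
            raise ValidationError("cohort is empty")
        if np.any(self.divisions < 1):
            raise ValidationError("divisions must be >= 1")

    @property
    def n(self) -> int:
        return len(self.divisions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.n),
                "strain": self.strain,
                "divisions": self.divisions,
                "observed": self.observed,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, strain: str | None = None) -> "LifespanCohort":
        if strain is not None:
            df = df[df["strain"] == strain]
        return cls(
            divisions=df["divisions"].to_numpy(),
            observed=df["observed"].astype(bool).to_numpy(),
            strain=strain or (str(df["strain"].iloc[0]) if "strain" in df else ""),
        )


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate with 95% confidence bounds.

    ``times`` starts at 0 (S(0) = 1) followed by the distinct event
    divisions; ``at_risk`` and ``n_events`` describe the risk set at each
    event time.
    """

    times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    strain: str = ""

    def survival_at(self, t: float) -> float:
        """Step-function evaluation S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "S": self.survival,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )


def km_estimate(cohort: LifespanCohort, ci_method: str = "greenwood") -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate with a 95% confidence band.

    ``ci_method='greenwood'`` gives the plain-scale Greenwood band clipped to
    [0, 1]; ``'loglog'`` gives the exponential-Greenwood (log-minus-log) band.
    Raises if the cohort contains no observed deaths.
    """
    if not cohort.observed.any():
        raise EstimationError("cannot estimate a survival curve from an all-censored cohort")
    if ci_method not in ("greenwood", "loglog"):
        raise ValidationError("ci_method must be 'greenwood' or 'loglog'")

    kmf = KaplanMeierFitter()
    kmf.fit(cohort.divisions, event_observed=cohort.observed)
    table = kmf.event_table  # indexed by time; includes censoring-only rows

    event_rows = table[table["observed"] > 0]
    times = event_rows.index.to_numpy(dtype=float)
    deaths = event_rows["observed"].to_numpy(dtype=float)
    at_risk = event_rows["at_risk"].to_numpy(dtype=float)

    surv = np.asarray(
        [kmf.survival_function_at_times(t).iloc[0] for t in times], dtype=float
    )

    # Greenwood variance: S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = deaths / (at_risk * (at_risk - deaths))
    terms = np.where(at_risk == deaths, np.nan, terms)  # S hits 0: variance degenerate
    cum = np.nancumsum(terms)
    var = surv**2 * cum
    se = np.sqrt(var)

    z = 1.959963984540054  # two-sided 95% normal quantile
    if ci_method == "greenwood":
        low = np.clip(surv - z * se, 0.0, 1.0)
        high = np.clip(surv + z * se, 0.0, 1.0)
    else:
        # exponential Greenwood on log(-log S)
        with np.errstate(divide="ignore", invalid="ignore"):
            se_ll = np.sqrt(cum) / np.abs(np.log(surv))
            theta = np.log(-np.log(surv))
            low = np.exp(-np.exp(theta + z * se_ll))
            high = np.exp(-np.exp(theta - z * se_ll))
        low = np.where(np.isfinite(low), low, 0.0)
        high = np.where(np.isfinite(high), high, 1.0)
    # where S = 0 the band collapses
    low = np.where(surv == 0.0, 0.0, low)
    high = np.where(surv == 0.0, 0.0, high)

    n0 = cohort.n
    return SurvivalCurve(
        times=np.concatenate(([0.0], times)),
        survival=np.concatenate(([1.0], surv)),
        ci_low=np.concatenate(([1.0], low)),
        ci_high=np.concatenate(([1.0], high)),
        at_risk=np.concatenate(([n0], at_risk)).astype(int),
        n_events=np.concatenate(([0], deaths)).astype(int),
        strain=cohort.strain,
    )


def median_rls(curve: SurvivalCurve) -> float:
    """Median replicative lifespan: the smallest event division t with
    S(t) <= 0.5 (deterministic at an exact-0.5 plateau). Returns ``inf`` when
    survival never reaches 0.5; report such medians as '> max observed'."""
    idx = np.flatnonzero(curve.survival <= 0.5)
    if len(idx) == 0:
        return math.inf
    return float(curve.times[idx[0]])


def format_median(curve: SurvivalCurve) -> str:
    m = median_rls(curve)
    if math.isinf(m):
        return f">{int(curve.times[-1])}"
    return f"{m:g}"


@dataclass
class LogrankResult:
    statistic: float  # chi-square, 1 df
    p: float


def logrank_test(a: LifespanCohort, b: LifespanCohort) -> LogrankResult:
    """Two-group log-rank test (hypergeometric variance, 1-df chi-square).

    Censored records contribute to risk sets only. Group labels are
    exchangeable: the statistic and p-value do not depend on order.
    """
    if not a.observed.any() or not b.observed.any():
        raise ValidationError("both cohorts must contain observed events")
    res = _ll_logrank(
        a.divisions, b.divisions, event_observed_A=a.observed, event_observed_B=b.observed
    )
    return LogrankResult(statistic=float(res.test_statistic), p=float(res.p_value))


def cohort_summary(cohorts: list[LifespanCohort]) -> pd.DataFrame:
    """Per-strain table of n, events, median RLS (as printed in lifespan
    figure legends) and the formatted median."""
    rows = []
    for cohort in cohorts:
        curve = km_estimate(cohort)
        rows.append(
            {
                "strain": cohort.strain,
                "n": cohort.n,
                "events": int(cohort.observed.sum()),
                "median_rls": median_rls(curve),
                "median_label": format_median(curve),
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "LifespanCohort",
    "LogrankResult",
    "SurvivalCurve",
    "cohort_summary",
    "format_median",
    "km_estimate",
    "logrank_test",
    "median_rls",
]
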