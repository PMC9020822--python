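"""Per-cell scalar enrichment statistics and group tests.

The central statistic is the relative accumulation (RA) of a GFP-labeled
nucleoporin in the NPC cap — the envelope region adjacent to the DNA-circle
cluster — in two variants:

* background-corrected: RA = (I_c - I_BG) / (I_R - I_BG), where I_c and I_R
  are the mean envelope intensities over the cap arc and the rest of the
  envelope and I_BG is the extracellular background;
* simple: RA = I_C / I_R (no background term).

Also provided: the tandem-fluorescent-timer red/green ratio (protein age),
the nuclear/cytoplasmic reporter ratio, and the two-sample Student's t-test
used for all group comparisons (pooled variance by default, as reported in
the source analyses; Welch optional). RA values are summarized per strain by
their median and plotted on a log2 scale, so log2(RA) is recorded alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedRatioError, ValidationError
from .simulate import NucleusImage
from .tracing import (
    find_cluster_focus,
    nucleus_mask,
    partition_regions,
    region_means,
    sample_profile,
    trace_envelope,
)


def ra_corrected(i_cap: float, i_rest: float, i_bg: float) -> float:
    """Background-corrected relative accumulation (I_c - I_BG)/(I_R - I_BG).

    Invariant under any joint affine intensity transform (gain > 0) of the
    three inputs. Raises :class:`UndefinedRatioError` when the rest-of-
    envelope signal does not exceed background (the cell is excluded).
    """
    if i_rest <= i_bg:
        raise UndefinedRatioError("rest-of-envelope intensity does not exceed background")
    return (i_cap - i_bg) / (i_rest - i_bg)


def ra_simple(i_cap: float, i_rest: float) -> float:
    """Uncorrected relative accumulation I_C/I_R (gain-invariant; a positive
    offset added to both inputs moves the ratio toward 1)."""
    if i_rest <= 0:
        raise UndefinedRatioError("rest-of-envelope intensity must be positive")
    return i_cap / i_rest


def timer_ratio(
    red_mean: float, green_mean: float, red_bg: float, green_bg: float
) -> float:
    """Tandem-timer mCherry/GFP ratio of background-corrected envelope means.

    mCherry matures slowly, sfGFP fast, so the ratio reports the mean age of
    the tagged protein pool."""
    denom = green_mean - green_bg
    if denom <= 0:
        raise UndefinedRatioError("background-corrected green intensity must be positive")
    return (red_mean - red_bg) / denom


def nc_ratio(
    image_channel: np.ndarray,
    nucleus: np.ndarray,
    cytoplasm: np.ndarray,
    bg: float,
) -> float:
    """Nuclear/cytoplasmic ratio of background-corrected mean intensities for
    an import reporter, from disjoint boolean pixel masks."""
    nucleus = np.asarray(nucleus, dtype=bool)
    cytoplasm = np.asarray(cytoplasm, dtype=bool)
    if not nucleus.any() or not cytoplasm.any():
        raise ValidationError("both masks must be nonempty")
    if (nucleus & cytoplasm).any():
        raise ValidationError("nucleus and cytoplasm masks must be disjoint")
    img = np.asarray(image_channel, dtype=float)
    denom = float(img[cytoplasm].mean()) - bg
    if denom <= 0:
        raise UndefinedRatioError("background-corrected cytoplasmic intensity must be positive")
    return (float(img[nucleus].mean()) - bg) / denom


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


@dataclass
class GroupTestResult:
    t: float
    p: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    degenerate: bool = False


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else math.nan


def group_test(
    values_a: Sequence[float], values_b: Sequence[float], equal_var: bool = True
) -> GroupTestResult:
    """Two-sided two-sample Student's t-test (pooled variance by default,
    ``equal_var=False`` for Welch), with group means and SEMs.

    Zero pooled variance is handled deterministically: equal means give
    t = 0, p = 1; unequal means give p -> 0 and the result is flagged
    degenerate.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 values")

    base = dict(
        n_a=len(a), n_b=len(b), mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=_sem(a), sem_b=_sem(b),
    )
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return GroupTestResult(t=0.0, p=1.0, degenerate=True, **base)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return GroupTestResult(t=sign * math.inf, p=0.0, degenerate=True, **base)

    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupTestResult(t=float(t), p=float(p), **base)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (off by default in all pipelines;
    the group tests report raw p-values)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# per-cell measurements from images
# ---------------------------------------------------------------------------


@dataclass
class CellMeasurement:
    """One scalar statistic for one cell, with cohort metadata."""

    cell_id: str
    metric_name: str
    value: float
    strain: str = ""
    age: int | None = None
    role: str = "n/a"  # mother | daughter | n/a
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "cell_id": self.cell_id,
            "strain": self.strain,
            "age": self.age,
            "role": self.role,
            "metric_name": self.metric_name,
            "value": self.value,
        }
        row.update(self.extras)
        return row


def measurements_to_frame(measurements: Sequence[CellMeasurement]) -> pd.DataFrame:
    return pd.DataFrame([m.to_row() for m in measurements])


def cap_enrichment_from_image(
    image: NucleusImage,
    quantify_channel: int | str = 0,
    cluster_channel: int | str = 1,
    cap_half_width: float = math.radians(30.0),
    linewidth: int = 3,
    n_samples: int = 180,
    cell_id: str = "",
    strain: str = "",
    age: int | None = None,
    role: str = "n/a",
) -> CellMeasurement:
    """Full cap-enrichment pipeline for one image.

    Traces the envelope on the quantified channel, locates the DNA-circle
    cluster focus on the cluster channel, samples matched profiles,
    partitions the cap arc and computes the background-corrected RA; the
    measurement carries log2(RA) and the intermediate intensities as extras.
    """
    if isinstance(quantify_channel, str):
        quantify_channel = image.channel_names.index(quantify_channel)
    if isinstance(cluster_channel, str):
        cluster_channel = image.channel_names.index(cluster_channel)

    contour = trace_envelope(image.data[quantify_channel], n_samples=n_samples)
    focus = find_cluster_focus(image.data[cluster_channel])
    profile = sample_profile(image, contour, linewidth=linewidth)
    partition = partition_regions(
        profile, image, contour, cluster_focus=focus, cap_half_width=cap_half_width
    )
    i_cap, i_rest = region_means(profile, partition, quantify_channel)
    i_bg = float(partition.background[quantify_channel])
    ra = ra_corrected(i_cap, i_rest, i_bg)
    return CellMeasurement(
        cell_id=cell_id,
        metric_name="RA_corrected",
        value=ra,
        strain=strain,
        age=age,
        role=role,
        extras={
            "log2_ra": math.log2(ra) if ra > 0 else -math.inf,
            "I_c": i_cap,
            "I_R": i_rest,
            "I_BG": i_bg,
        },
    )


def timer_ratio_from_image(
    image: NucleusImage,
    green_channel: int | str = 0,
    red_channel: int | str = 1,
    linewidth: int = 3,
    n_samples: int = 180,
    cell_id: str = "",
    strain: str = "",
    age: int | None = None,
    role: str = "n/a",
) -> CellMeasurement:
    """Tandem-timer ratio for one image: trace on the green (fast-maturing)
    channel, average both envelope profiles, correct each by its extracellular
    background, and form the red/green ratio."""
    if isinstance(green_channel, str):
        green_channel = image.channel_names.index(green_channel)
    if isinstance(red_channel, str):
        red_channel = image.channel_names.index(red_channel)

    contour = trace_envelope(image.data[green_channel], n_samples=n_samples)
    profile = sample_profile(image, contour, linewidth=linewidth)
    outside = ~nucleus_mask(contour, image.data.shape[-2:], dilation_px=3)
    bg = [float(np.median(ch[outside])) for ch in image.data]
    ratio = timer_ratio(
        red_mean=float(profile.values[red_channel].mean()),
        green_mean=float(profile.values[green_channel].mean()),
        red_bg=bg[red_channel],
        green_bg=bg[green_channel],
    )
    return CellMeasurement(
        cell_id=cell_id, metric_name="timer_ratio", value=ratio,
        strain=strain, age=age, role=role,
    )


def group_summary(df: pd.DataFrame, by: str = "strain", value: str = "value") -> pd.DataFrame:
    """Per-group summary table (n, median, mean, SEM) of a measurement frame.

    Medians are the headline per-group summary for RA metrics."""
    def agg(g: pd.Series) -> pd.Series:
        return pd.Series(
            {
                "n": len(g),
                "median": g.median(),
                "mean": g.mean(),
                "sem": g.std(ddof=1) / math.sqrt(len(g)) if len(g) > 1 else math.nan,
            }
        )

    return df.groupby(by)[value].apply(agg).unstack().reset_index()


__all__ = [
    "CellMeasurement",
    "GroupTestResult",
    "bh_adjust",
    "cap_enrichment_from_image",
    "group_summary",
    "group_test",
    "measurements_to_frame",
    "nc_ratio",
    "ra_corrected",
    "ra_simple",
    "timer_ratio",
    "timer_ratio_from_image",
]
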