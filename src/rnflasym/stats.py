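"""Group-wise statistical characterization of asymmetry features.

For each feature column (six TSNIT sectors plus G) the healthy and
glaucoma groups are summarised by mean, sample SD (n-1 denominator) and a
two-sided two-sample p-value.  The default test is the Wilcoxon rank-sum
(Mann-Whitney U): the group sizes are unequal and the magnitude metrics
are half-normal-shaped rather than normal, so a rank test is the safer
default; Welch's t is available for comparison.  Because the rank test is
invariant under strictly increasing transforms, columns that are positive
rescalings of one another (e.g. the patient-sum- and cohort-sum-normalised
differences) give identical p-values.

Also here: the half-normal mean law (the mean of |X| for zero-mean normal
X is sigma*sqrt(2/pi)), which explains how group variance differences in
the signed metrics turn into group *mean* differences after taking
magnitudes; and notched-box-plot summaries (quartiles, 1.5*IQR whiskers,
outliers, median notches).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import GLAUCOMA, HEALTHY
from .metrics import FeatureMatrix

#: Sample-size bound below which the rank-sum test uses exact enumeration
#: of the U null distribution rather than the tie-corrected normal
#: approximation.
_EXACT_MAX_N = 25


def compare_groups(healthy_values, glaucoma_values, method: str = "rank_sum") -> float:
    """Two-sided p-value comparing the two diagnosis groups.

    ``rank_sum`` (default): Mann-Whitney U / Wilcoxon rank-sum, exact for
    small samples, tie-corrected normal approximation otherwise.
    ``welch_t``: Welch's unequal-variance t test.
    """
    x = np.asarray(healthy_values, dtype=float)
    y = np.asarray(glaucoma_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "welch_t":
        return float(sps.ttest_ind(x, y, equal_var=False).pvalue)
    if method != "rank_sum":
        raise ValueError(f"unknown method {method!r}")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        warnings.warn("all values tied; rank-sum p-value set to 1", stacklevel=2)
        return 1.0
    mode = "exact" if (x.size + y.size) <= _EXACT_MAX_N else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=mode)
    return float(min(res.pvalue, 1.0))


@dataclass
class GroupSummary:
    """Per-sector two-group summary for one metric (mirrors a report row)."""

    metric: str
    table: pd.DataFrame  # index: sector; columns mean_h, sd_h, n_h, mean_g, sd_g, n_g, p_value

    def to_csv(self, path) -> None:
        self.table.round(6).to_csv(path, index_label="sector")


def summarize_groups(fm: FeatureMatrix, method: str = "rank_sum") -> GroupSummary:
    """Mean, sample SD and two-group p-value per feature column."""
    for label in (HEALTHY, GLAUCOMA):
        n = int(np.sum(fm.labels == label))
        if n < 2:
            raise ValueError(f"group {label!r} has {n} patients; SD undefined")
    rows = {}
    for col in fm.columns:
        h = fm.group_values(col, HEALTHY)
        g = fm.group_values(col, GLAUCOMA)
        rows[col] = {
            "mean_h": float(np.mean(h)),
            "sd_h": float(np.std(h, ddof=1)),
            "n_h": h.size,
            "mean_g": float(np.mean(g)),
            "sd_g": float(np.std(g, ddof=1)),
            "n_g": g.size,
            "p_value": compare_groups(h, g, method=method),
        }
    table = pd.DataFrame.from_dict(rows, orient="index").loc[list(fm.columns)]
    return GroupSummary(metric=fm.metric, table=table)


def half_normal_mean(sigma: float) -> float:
    """Mean of |X| for X ~ Normal(0, sigma^2): ``sigma * sqrt(2/pi)``."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return sigma * math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class BoxSummary:
    """Notched box plot quantities for one sample."""

    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    notch_low: float
    notch_high: float
    outliers: tuple[float, ...]


def box_summary(values) -> BoxSummary:
    """Quartiles, 1.5*IQR whiskers, outliers and median notches.

    Quartiles use linear interpolation between order statistics.  Whiskers
    extend to the most extreme data points within 1.5*IQR of the box
    edges; anything beyond is an outlier.  The notch half-width is
    ``1.57 * IQR / sqrt(n)``, the usual 5%-level median-comparison rule.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 5:
        raise ValueError("box summary needs at least 5 values")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = tuple(float(v) for v in x[(x < lo_fence) | (x > hi_fence)])
    notch = 1.57 * iqr / math.sqrt(x.size)
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=float(inside[0]),
        whisker_high=float(inside[-1]),
        notch_low=float(med - notch),
        notch_high=float(med + notch),
        outliers=outliers,
    )
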