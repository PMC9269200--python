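"""Inter-eye RNFL asymmetry metrics.

All metrics start from the per-sector inter-eye difference of patient *i*

    delta_{S,i} = w_{S,i}^r - w_{S,i}^l          (µm)

and differ only in normalisation:

================  =============================================================
``delta``         raw difference, µm
``abs_delta``     |raw difference|, µm
``Delta``         difference / patient's own sector sum (w^r + w^l), in [-1, 1]
``abs_Delta``     absolute version of ``Delta``, in [0, 1]
``Delta_bar``     difference / cohort-level sector-mean sum (wbar^r + wbar^l)
``abs_Delta_bar`` absolute version of ``Delta_bar``
``Delta_dbar``    difference / patient's own global-thickness sum
                  (w_G^r + w_G^l); coincides with ``Delta`` at sector G
``abs_Delta_dbar`` absolute version of ``Delta_dbar``
``sqrt_abs_Delta`` gamma-compressed sqrt(|Delta|); the power law spreads the
                  half-normal-shaped |Delta| distribution away from zero
================  =============================================================

The cohort-referenced variants (``Delta_bar`` family) need the dataset
mean thickness per sector and eye; by default these are computed over the
whole cohort, healthy and glaucoma pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import FEATURE_COLUMNS, Cohort, PatientRecord

#: The nine metric identifiers, in presentation order.
METRIC_IDS: tuple[str, ...] = (
    "delta",
    "abs_delta",
    "Delta",
    "abs_Delta",
    "Delta_bar",
    "abs_Delta_bar",
    "Delta_dbar",
    "abs_Delta_dbar",
    "sqrt_abs_Delta",
)

#: Metrics whose values are magnitudes (non-negative).
ABSOLUTE_METRICS = frozenset(
    {"abs_delta", "abs_Delta", "abs_Delta_bar", "abs_Delta_dbar", "sqrt_abs_Delta"}
)

#: signed -> absolute counterpart
SIGNED_TO_ABS = {
    "delta": "abs_delta",
    "Delta": "abs_Delta",
    "Delta_bar": "abs_Delta_bar",
    "Delta_dbar": "abs_Delta_dbar",
}

_NEEDS_MEANS = frozenset({"Delta_bar", "abs_Delta_bar"})


@dataclass(frozen=True)
class CohortSectorMeans:
    """Dataset-level mean thickness per sector and eye (µm).

    ``mean_right[S]`` / ``mean_left[S]`` are arithmetic means over all
    ``n`` patients of the cohort, including the global contour G.
    """

    mean_right: Mapping[str, float]
    mean_left: Mapping[str, float]
    n: int

    def sum_for(self, sector: str) -> float:
        return float(self.mean_right[sector]) + float(self.mean_left[sector])


def cohort_sector_means(cohort: Cohort) -> CohortSectorMeans:
    """Arithmetic mean of each sector's thickness per eye over the cohort."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty; sector means undefined")
    right = {c: float(np.mean([r.right.sector(c) for r in cohort])) for c in FEATURE_COLUMNS}
    left = {c: float(np.mean([r.left.sector(c) for r in cohort])) for c in FEATURE_COLUMNS}
    return CohortSectorMeans(right, left, len(cohort))


def normalize_by_reference_sum(value_um: float, mean_right_um: float, mean_left_um: float) -> float:
    """Divide a µm-scale quantity by a cohort reference sum (wbar^r + wbar^l).

    This is the group-level link between the raw-difference statistics and
    the cohort-referenced metric: because the ``Delta_bar`` family divides
    every patient's delta by the same constant, any linear statistic
    (mean, SD) of ``Delta_bar`` equals the corresponding delta statistic
    divided by that constant.
    """
    denom = mean_right_um + mean_left_um
    if denom <= 0:
        raise ValueError("reference thickness sum must be positive")
    return value_um / denom


def compute_metric(
    record: PatientRecord,
    metric: str,
    sector: str,
    means: CohortSectorMeans | None = None,
) -> float:
    """One asymmetry value for one patient and one sector.

    ``means`` is required for the cohort-referenced metrics
    (``Delta_bar``, ``abs_Delta_bar``) and ignored otherwise.
    """
    if metric not in METRIC_IDS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRIC_IDS}")
    if sector not in FEATURE_COLUMNS:
        raise ValueError(f"unknown sector {sector!r}")
    wr = record.right.sector(sector)
    wl = record.left.sector(sector)
    d = wr - wl
    if metric == "delta":
        return d
    if metric == "abs_delta":
        return abs(d)
    if metric in ("Delta", "abs_Delta", "sqrt_abs_Delta"):
        denom = wr + wl
        if denom <= 0:
            raise ValueError(f"non-positive sector sum for patient {record.patient_id}")
        if metric == "Delta":
            return d / denom
        if metric == "abs_Delta":
            return abs(d) / denom
        return math.sqrt(abs(d) / denom)
    if metric in _NEEDS_MEANS:
        if means is None:
            raise ValueError(f"metric {metric!r} requires cohort sector means")
        denom = means.sum_for(sector)
        if denom <= 0:
            raise ValueError("non-positive reference sector-mean sum")
        return d / denom if metric == "Delta_bar" else abs(d) / denom
    # Delta_dbar family: normalised by the patient's own global sum
    denom = record.right.sector("G") + record.left.sector("G")
    if denom <= 0:
        raise ValueError(f"non-positive global sum for patient {record.patient_id}")
    return d / denom if metric == "Delta_dbar" else abs(d) / denom


@dataclass
class FeatureMatrix:
    """n_patients x 7 asymmetry values for one metric, plus row labels.

    Column order is fixed (TS, T, TI, NS, N, NI, G); row order follows the
    cohort.
    """

    metric: str
    values: np.ndarray  # shape (n, 7)
    labels: np.ndarray  # of str
    patient_ids: list[str]
    columns: tuple[str, ...] = FEATURE_COLUMNS

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.columns))
        df.insert(0, "label", self.labels)
        df.insert(0, "patient_id", self.patient_ids)
        return df

    def column(self, sector: str) -> np.ndarray:
        return self.values[:, self.columns.index(sector)]

    def group_values(self, sector: str, label: str) -> np.ndarray:
        return self.column(sector)[self.labels == label]


def feature_matrix(
    cohort: Cohort,
    metric: str,
    means: CohortSectorMeans | None = None,
) -> FeatureMatrix:
    """Apply one metric to every patient and feature column.

    For the cohort-referenced metrics the sector means are computed over
    the whole cohort (both diagnosis groups pooled) unless externally
    supplied reference means are given.
    """
    if metric in _NEEDS_MEANS and means is None:
        means = cohort_sector_means(cohort)
    vals = np.empty((len(cohort), len(FEATURE_COLUMNS)))
    for i, rec in enumerate(cohort):
        for j, col in enumerate(FEATURE_COLUMNS):
            vals[i, j] = compute_metric(rec, metric, col, means)
    labels = np.array([r.label for r in cohort])
    ids = [r.patient_id for r in cohort]
    return FeatureMatrix(metric=metric, values=vals, labels=labels, patient_ids=ids)


def write_feature_csv(fm: FeatureMatrix, path) -> None:
    """Feature CSV with a leading ``# metric=<id>`` comment line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# metric={fm.metric}\n")
        fm.to_frame().to_csv(fh, index=False, float_format="%.6f")


def read_feature_csv(path) -> FeatureMatrix:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith("# metric="):
            raise ValueError("feature CSV must start with a '# metric=' line")
        metric = first.split("=", 1)[1]
        df = pd.read_csv(fh, dtype={"patient_id": str})
    values = df[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    return FeatureMatrix(
        metric=metric,
        values=values,
        labels=df["label"].to_numpy(),
        patient_ids=[str(p) for p in df["patient_id"]],
    )


def feature_labels_binary(labels: Sequence[str]) -> np.ndarray:
    """Labels as 0 (healthy) / 1 (glaucoma) integer array."""
    return np.asarray([1 if l == "glaucoma" else 0 for l in labels], dtype=int)
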