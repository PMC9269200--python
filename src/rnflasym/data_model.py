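"""Core types for paired-eye peripapillary RNFL thickness data.

A peripapillary OCT B-scan is summarised as six angular TSNIT sectors —
temporal-superior (TS), temporal (T), temporal-inferior (TI),
nasal-superior (NS), nasal (N), nasal-inferior (NI) — plus the global
360-degree mean (G).  The temporal and nasal sectors span 90 degrees
each, the remaining four 45 degrees.  All thicknesses are in micrometres.

The atom of the pipeline is :class:`PatientRecord`: one patient's right
and left eye measurements plus a healthy/glaucoma diagnosis that applies
to both eyes (patients with discordant per-eye diagnoses are excluded
upstream, so a single label per patient is an invariant here).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import pandas as pd

#: TSNIT sector names in fixed reporting order (temporal arch first).
SECTORS: tuple[str, ...] = ("TS", "T", "TI", "NS", "N", "NI")

#: Angular extent of each sector in degrees; the six extents tile the
#: 360-degree circumpapillary circle.
SECTOR_EXTENT_DEG: dict[str, float] = {
    "TS": 45.0,
    "T": 90.0,
    "TI": 45.0,
    "NS": 45.0,
    "N": 90.0,
    "NI": 45.0,
}

#: Feature columns used throughout: the six sectors plus the global mean.
FEATURE_COLUMNS: tuple[str, ...] = SECTORS + ("G",)

HEALTHY = "healthy"
GLAUCOMA = "glaucoma"
LABELS = (HEALTHY, GLAUCOMA)

CSV_HEADER = ["patient_id", "eye", "label", *SECTORS, "G"]


class CohortError(ValueError):
    """Raised for malformed cohort data (CSV schema or pairing violations)."""


def angle_weighted_global(thickness_by_sector: Mapping[str, float]) -> float:
    """Global mean thickness over the full circumpapillary contour.

    Each sector mean is weighted by its angular extent:
    ``G = sum_S extent_S * w_S / 360``.

    Parameters
    ----------
    thickness_by_sector
        Mapping with all six sector names to positive thicknesses in µm.
    """
    missing = [s for s in SECTORS if s not in thickness_by_sector]
    if missing:
        raise CohortError(f"missing sector(s) {missing} for global mean")
    total = 0.0
    for s in SECTORS:
        w = float(thickness_by_sector[s])
        if not (w > 0.0) or w != w or w == float("inf"):
            raise CohortError(f"sector {s}: thickness must be finite and > 0, got {w!r}")
        total += SECTOR_EXTENT_DEG[s] * w
    return total / 360.0


@dataclass(frozen=True)
class EyeMeasurement:
    """Per-sector mean RNFL thickness of one eye, in µm.

    ``global_mean`` is the device-reported G when available; if omitted it
    is derived as the angle-weighted sector mean.  Device G values can
    deviate slightly from the angle-weighted mean (the device averages per
    A-scan), so a supplied value is kept verbatim.
    """

    side: str  # "right" | "left"
    thickness_by_sector: Mapping[str, float]
    global_mean: float | None = None

    def __post_init__(self) -> None:
        if self.side not in ("right", "left"):
            raise CohortError(f"eye side must be 'right' or 'left', got {self.side!r}")
        # validates presence + positivity as a side effect
        derived = angle_weighted_global(self.thickness_by_sector)
        if self.global_mean is None:
            object.__setattr__(self, "global_mean", derived)
        elif not self.global_mean > 0.0:
            raise CohortError(f"global mean must be > 0, got {self.global_mean!r}")

    def sector(self, name: str) -> float:
        """Thickness of one feature column; ``G`` maps to ``global_mean``."""
        if name == "G":
            return float(self.global_mean)  # type: ignore[arg-type]
        return float(self.thickness_by_sector[name])


@dataclass(frozen=True)
class PatientRecord:
    """One patient: paired right/left eyes plus diagnosis label."""

    patient_id: str
    right: EyeMeasurement
    left: EyeMeasurement
    label: str
    age: float | None = None
    gender: str | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise CohortError(
                f"patient {self.patient_id}: label must be one of {LABELS}, got {self.label!r}"
            )
        if self.right.side != "right" or self.left.side != "left":
            raise CohortError(f"patient {self.patient_id}: eyes mis-sided")


@dataclass
class Cohort:
    """Ordered collection of patients with unique ids."""

    records: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate patient id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    @property
    def n_healthy(self) -> int:
        return sum(1 for r in self.records if r.label == HEALTHY)

    @property
    def n_glaucoma(self) -> int:
        return sum(1 for r in self.records if r.label == GLAUCOMA)

    def counts(self) -> dict[str, int]:
        return {HEALTHY: self.n_healthy, GLAUCOMA: self.n_glaucoma}


def _record_rows(record: PatientRecord) -> Iterable[dict]:
    for eye in (record.right, record.left):
        row = {
            "patient_id": record.patient_id,
            "eye": eye.side,
            "label": record.label,
        }
        for s in SECTORS:
            row[s] = eye.thickness_by_sector[s]
        row["G"] = eye.global_mean
        yield row


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort in long format: one row per eye, two rows per patient.

    Header is exactly ``patient_id,eye,label,TS,T,TI,NS,N,NI,G``;
    thicknesses are printed with 6 decimals so a read/write round trip is
    the identity to well past reporting precision.
    """
    rows = [row for rec in cohort for row in _record_rows(rec)]
    df = pd.DataFrame(rows, columns=CSV_HEADER)
    df.to_csv(path, index=False, float_format="%.6f")


def read_cohort_csv(path) -> Cohort:
    """Read a long-format cohort CSV and pair rows into patients.

    The ``G`` column may be absent or empty, in which case the global mean
    is computed as the angle-weighted sector mean.  Rows whose partner eye
    is missing are rejected (the analysis is defined only on complete
    pairs), as are duplicate (patient, eye) rows and patients whose two
    rows disagree on the diagnosis label.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = [c for c in CSV_HEADER if c != "G"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise CohortError(f"cohort CSV missing column(s): {missing_cols}")
    has_g = "G" in df.columns

    by_patient: dict[str, dict[str, pd.Series]] = {}
    for idx, row in df.iterrows():
        pid = str(row["patient_id"])
        eye = row["eye"]
        if eye not in ("right", "left"):
            raise CohortError(f"row {idx}: eye must be 'right' or 'left', got {eye!r}")
        if row["label"] not in LABELS:
            raise CohortError(f"row {idx}: bad label {row['label']!r}")
        eyes = by_patient.setdefault(pid, {})
        if eye in eyes:
            raise CohortError(f"duplicate ({pid}, {eye}) row")
        eyes[eye] = row

    unpaired = sorted(p for p, eyes in by_patient.items() if len(eyes) != 2)
    if unpaired:
        raise CohortError(f"patient(s) with a missing partner eye: {unpaired}")

    records = []
    for pid, eyes in by_patient.items():
        r, l = eyes["right"], eyes["left"]
        if r["label"] != l["label"]:
            raise CohortError(f"patient {pid}: mixed diagnosis labels between eyes")
        measurements = {}
        for side, row in (("right", r), ("left", l)):
            try:
                sectors = {s: float(row[s]) for s in SECTORS}
            except (TypeError, ValueError) as exc:
                raise CohortError(f"patient {pid} ({side}): malformed thickness: {exc}") from exc
            g = None
            if has_g and not pd.isna(row["G"]):
                g = float(row["G"])
            measurements[side] = EyeMeasurement(side, sectors, g)
        records.append(
            PatientRecord(
                patient_id=pid,
                right=measurements["right"],
                left=measurements["left"],
                label=str(r["label"]),
            )
        )
    return Cohort(records)


def cohort_to_csv_string(cohort: Cohort) -> str:
    """Cohort CSV as an in-memory string (used for determinism checks)."""
    buf = io.StringIO()
    write_cohort_csv(cohort, buf)
    return buf.getvalue()


def swap_eyes(record: PatientRecord) -> PatientRecord:
    """Mirror a patient: right and left measurements exchanged."""
    new_right = replace(record.left, side="right")
    new_left = replace(record.right, side="left")
    return replace(record, right=new_right, left=new_left)
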