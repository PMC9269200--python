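"""Synthetic paired-eye RNFL cohort generator.

Generates cohorts with the statistical structure the asymmetry analysis
assumes: each patient has a shared bilateral thickness level per sector
(population base level plus a patient-specific offset), and a 6-vector of
inter-eye differences drawn from a multivariate normal whose per-sector
means and SDs match the reference cohort's delta statistics and whose
exchangeable cross-sector correlation rho is calibrated so the *emergent*
SD of the global-contour difference matches the reference value too.
Half the difference is added to the right eye and subtracted from the
left, so both the difference distribution and the per-eye mean levels are
hit by construction.  The global mean G is always computed from the
sectors (angle-weighted), never drawn, so the global-sum normalisers are
internally consistent.

What this emulates: group sizes, per-sector mean levels, per-group
inter-eye difference distributions (the quantities the screening metrics
and classifier actually consume).  What it does not: real cross-sector
level correlations, segmentation artefacts, floor effects of advanced
atrophy, or any per-A-scan structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import calibration as cal
from .data_model import (
    SECTOR_EXTENT_DEG,
    SECTORS,
    Cohort,
    EyeMeasurement,
    PatientRecord,
)

_MAX_REJECTIONS = 1000


def _default_base_levels() -> dict[str, float]:
    return {
        s: (cal.SECTOR_MEAN_RIGHT[s] + cal.SECTOR_MEAN_LEFT[s]) / 2.0 for s in SECTORS
    }


@dataclass
class GroupSimParams:
    """Simulation parameters for one diagnosis group.

    Defaults reproduce the reference cohort: group size, per-sector base
    levels (midpoint of the right/left dataset means), and the per-sector
    inter-eye difference mean/SD.  ``delta_correlation=None`` means
    "calibrate rho so the emergent global-difference SD matches
    ``target_global_delta_sd``".  ``between_patient_sd`` (µm) is the SD of
    the patient-specific level offset shared by both eyes; it controls
    realism of absolute thickness spread but no asymmetry metric depends
    on it strongly.  Its default of 10 µm is a modelling choice — the
    reference summaries do not report level heterogeneity.
    """

    n_patients: int
    delta_mean: dict[str, float]
    delta_sd: dict[str, float]
    base_level: dict[str, float] = field(default_factory=_default_base_levels)
    between_patient_sd: float = 10.0
    delta_correlation: float | None = None
    target_global_delta_sd: float | None = None
    age_mean_sd: tuple[float, float] = (60.0, 12.0)
    male_fraction: float = 0.35

    def resolved_correlation(self) -> float:
        if self.delta_correlation is not None:
            return self.delta_correlation
        if self.target_global_delta_sd is None:
            return 0.0
        return calibrate_correlation(self.target_global_delta_sd, self)


def default_group_params(group: str) -> GroupSimParams:
    """Reference-calibrated parameters for ``healthy`` or ``glaucoma``."""
    n = cal.N_HEALTHY if group == "healthy" else cal.N_GLAUCOMA
    males, females = cal.GENDER_COUNTS[group]
    return GroupSimParams(
        n_patients=n,
        delta_mean={s: cal.DELTA_MEAN[group][s] for s in SECTORS},
        delta_sd={s: cal.DELTA_SD[group][s] for s in SECTORS},
        target_global_delta_sd=cal.DELTA_SD[group]["G"],
        age_mean_sd=cal.AGE_MEAN_SD[group],
        male_fraction=males / (males + females),
    )


@dataclass
class SimConfig:
    """Full cohort simulation configuration; the seed determines output."""

    healthy: GroupSimParams = field(default_factory=lambda: default_group_params("healthy"))
    glaucoma: GroupSimParams = field(default_factory=lambda: default_group_params("glaucoma"))
    seed: int = 0

    def to_yaml(self, path) -> None:
        def flat(p: GroupSimParams) -> dict:
            return {
                "n_patients": p.n_patients,
                "delta_mean": dict(p.delta_mean),
                "delta_sd": dict(p.delta_sd),
                "base_level": dict(p.base_level),
                "between_patient_sd": p.between_patient_sd,
                "delta_correlation": p.delta_correlation,
                "target_global_delta_sd": p.target_global_delta_sd,
                "age_mean_sd": list(p.age_mean_sd),
                "male_fraction": p.male_fraction,
            }

        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {"seed": self.seed, "healthy": flat(self.healthy), "glaucoma": flat(self.glaucoma)},
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)

        def unflat(d: dict) -> GroupSimParams:
            return GroupSimParams(
                n_patients=int(d["n_patients"]),
                delta_mean={k: float(v) for k, v in d["delta_mean"].items()},
                delta_sd={k: float(v) for k, v in d["delta_sd"].items()},
                base_level={k: float(v) for k, v in d["base_level"].items()},
                between_patient_sd=float(d["between_patient_sd"]),
                delta_correlation=None
                if d.get("delta_correlation") is None
                else float(d["delta_correlation"]),
                target_global_delta_sd=None
                if d.get("target_global_delta_sd") is None
                else float(d["target_global_delta_sd"]),
                age_mean_sd=tuple(d["age_mean_sd"]),
                male_fraction=float(d["male_fraction"]),
            )

        return cls(
            healthy=unflat(raw["healthy"]),
            glaucoma=unflat(raw["glaucoma"]),
            seed=int(raw["seed"]),
        )


def calibrate_correlation(target_global_sd: float, params: GroupSimParams) -> float:
    """Exchangeable correlation rho matching a target global-difference SD.

    The global difference is the angle-weighted sector combination
    ``delta_G = sum_S a_S delta_S`` with ``a_S = extent_S/360``, so

        var(delta_G) = sum_S a_S^2 s_S^2
                     + rho * sum_{S != S'} a_S a_S' s_S s_S'

    is linear in rho and inverts in closed form.  Raises when the target
    lies below the rho=0 floor or at/above the rho->1 ceiling.
    """
    a = np.array([SECTOR_EXTENT_DEG[s] / 360.0 for s in SECTORS])
    s = np.array([params.delta_sd[x] for x in SECTORS])
    floor_var = float(np.sum((a * s) ** 2))
    cross = float(np.sum(a * s) ** 2 - floor_var)
    target_var = target_global_sd**2
    rho = (target_var - floor_var) / cross
    if rho < 0:
        raise ValueError(
            f"target global SD {target_global_sd:.4f} below the rho=0 floor "
            f"{np.sqrt(floor_var):.4f}"
        )
    if rho >= 1:
        raise ValueError(
            f"target global SD {target_global_sd:.4f} at or above the rho->1 "
            f"ceiling {np.sqrt(floor_var + cross):.4f}"
        )
    return float(rho)


def _delta_covariance(params: GroupSimParams) -> np.ndarray:
    s = np.array([params.delta_sd[x] for x in SECTORS])
    rho = params.resolved_correlation()
    cov = rho * np.outer(s, s)
    np.fill_diagonal(cov, s**2)
    return cov


def _simulate_group(
    params: GroupSimParams, group: str, prefix: str, rng: np.random.Generator
) -> list[PatientRecord]:
    mean = np.array([params.delta_mean[s] for s in SECTORS])
    cov = _delta_covariance(params)
    base = np.array([params.base_level[s] for s in SECTORS])
    records = []
    for i in range(params.n_patients):
        for attempt in range(_MAX_REJECTIONS + 1):
            level = base + rng.normal(0.0, params.between_patient_sd)
            delta = rng.multivariate_normal(mean, cov, method="cholesky")
            right = level + delta / 2.0
            left = level - delta / 2.0
            if np.all(right > 0) and np.all(left > 0):
                break
        else:
            raise RuntimeError(
                "rejection sampling failed to produce positive thicknesses; "
                "parameters are infeasible"
            )
        age = float(rng.normal(*params.age_mean_sd))
        gender = "male" if rng.random() < params.male_fraction else "female"
        records.append(
            PatientRecord(
                patient_id=f"{prefix}{i + 1:03d}",
                right=EyeMeasurement("right", dict(zip(SECTORS, right))),
                left=EyeMeasurement("left", dict(zip(SECTORS, left))),
                label=group,
                age=age,
                gender=gender,
            )
        )
    return records


def generate_cohort(config: SimConfig | None = None, seed: int | None = None) -> Cohort:
    """Draw a full healthy+glaucoma cohort; the seed fixes the output.

    ``seed`` overrides ``config.seed`` when given.  The two groups consume
    independent child seeds of one seed sequence, so changing one group's
    size does not perturb the other group's draws.
    """
    if config is None:
        config = SimConfig()
    actual_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(actual_seed)
    rng_h, rng_g = (np.random.default_rng(child) for child in ss.spawn(2))
    records = _simulate_group(config.healthy, "healthy", "h", rng_h)
    records += _simulate_group(config.glaucoma, "glaucoma", "g", rng_g)
    return Cohort(records)
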