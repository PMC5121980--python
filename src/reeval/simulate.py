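"""Synthetic hospital cohorts for exercising the validation pipeline.

No patient-level data is distributed with studies of this kind, so the
generator emulates the published cohort description: four BMI classes with
stated proportions, sex and inpatient mix, and age/height/BMI means and
SDs. BMI (not weight) is the sampled variable, truncated to its class
bounds, and weight is derived as BMI·height², which guarantees every
generated patient lands in the intended class. Measured REE is a
configurable truth model (by default the combined study equation) plus
Gaussian noise.

Truncated draws use a location-matched truncated normal: the underlying
location is solved so that the mean AFTER truncation equals the published
group mean (a plain truncated normal would bias the obese BMI mean upward
by >1 kg/m²).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Callable, Optional

import numpy as np
import yaml
from scipy import optimize, stats

from .cohort import Cohort, PatientRecord
from .equations import combined_paper_equation, new_kruizenga_lt25, weijs_vansant_ge25

__all__ = [
    "GroupProfile",
    "CohortProfile",
    "default_profile",
    "generate_cohort",
    "generate_registry",
]

HEIGHT_BOUNDS = (1.40, 2.10)  # m, physiological plausibility
AGE_LOWER = 18.0  # adult cohort
REE_FLOOR = 500.0  # kcal/day


class ProfileValidationError(ValueError):
    """A cohort profile is internally inconsistent."""


@dataclass(frozen=True)
class GroupProfile:
    """Distribution parameters for one BMI class of the cohort."""

    label: str
    proportion: float
    pct_male: float
    pct_inpatient: float
    age_mean: float
    age_sd: float
    height_mean: float  # m
    height_sd: float
    bmi_mean: float
    bmi_sd: float
    bmi_lower: float  # class bounds, kg/m²
    bmi_upper: float
    ree_per_kg_range: tuple[float, float]  # kcal/kg/day, printed range

    def __post_init__(self):
        for name in ("age_sd", "height_sd", "bmi_sd"):
            if getattr(self, name) <= 0:
                raise ProfileValidationError(f"{self.label}: {name} must be > 0")
        if not 0 <= self.proportion <= 1:
            raise ProfileValidationError(f"{self.label}: proportion out of [0,1]")


@dataclass(frozen=True)
class CohortProfile:
    groups: tuple[GroupProfile, GroupProfile, GroupProfile, GroupProfile]
    truth_model: str = "paper_combined"
    noise_sd: float = 200.0  # kcal/day
    seed: int = 0

    def __post_init__(self):
        total = sum(g.proportion for g in self.groups)
        if abs(total - 1.0) > 1e-9:
            raise ProfileValidationError(f"group proportions sum to {total}, not 1")

    def to_yaml(self) -> str:
        doc = asdict(self)
        doc["groups"] = [asdict(g) for g in self.groups]
        for g in doc["groups"]:
            g["ree_per_kg_range"] = list(g["ree_per_kg_range"])
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortProfile":
        doc = yaml.safe_load(text)
        groups = tuple(
            GroupProfile(**{**g, "ree_per_kg_range": tuple(g["ree_per_kg_range"])})
            for g in doc.pop("groups")
        )
        return cls(groups=groups, **doc)


def default_profile() -> CohortProfile:
    """Profile calibrated to the published cohort description: 513 adult
    hospital patients in four BMI classes (27/41/15/17%)."""
    groups = (
        GroupProfile(
            "underweight", 0.27, 44.0, 57.0,
            age_mean=51.3, age_sd=17.0, height_mean=1.72, height_sd=0.10,
            bmi_mean=16.6, bmi_sd=1.5, bmi_lower=0.0, bmi_upper=18.5,
            ree_per_kg_range=(18.0, 43.0),
        ),
        GroupProfile(
            "normal", 0.41, 58.0, 55.0,
            age_mean=54.1, age_sd=15.2, height_mean=1.74, height_sd=0.09,
            bmi_mean=21.3, bmi_sd=1.8, bmi_lower=18.5, bmi_upper=25.0,
            ree_per_kg_range=(14.0, 53.0),
        ),
        GroupProfile(
            "overweight", 0.15, 53.0, 35.0,
            age_mean=55.3, age_sd=15.2, height_mean=1.74, height_sd=0.10,
            bmi_mean=27.3, bmi_sd=1.4, bmi_lower=25.0, bmi_upper=30.0,
            ree_per_kg_range=(12.0, 31.0),
        ),
        GroupProfile(
            "obese", 0.17, 41.0, 17.0,
            age_mean=50.9, age_sd=14.2, height_mean=1.71, height_sd=0.12,
            bmi_mean=36.3, bmi_sd=5.4, bmi_lower=30.0, bmi_upper=float("inf"),
            ree_per_kg_range=(13.0, 29.0),
        ),
    )
    return CohortProfile(groups=groups)


def _truth_fn(profile: CohortProfile) -> Callable[[PatientRecord], float]:
    if profile.truth_model == "paper_combined":
        return combined_paper_equation
    if profile.truth_model == "new_lt25":
        return new_kruizenga_lt25
    if profile.truth_model == "weijs_ge25":
        return weijs_vansant_ge25
    # named registry equation
    from .equations import load_coefficient_table, predict_ree

    registry = load_coefficient_table()
    if profile.truth_model not in registry:
        raise ProfileValidationError(f"unknown truth model {profile.truth_model!r}")
    spec = registry[profile.truth_model]
    return lambda rec: predict_ree(spec, rec).ree_predicted


def _matched_truncnorm(mean: float, sd: float, lower: float, upper: float):
    """Frozen truncated normal on [lower, upper] whose truncated mean equals
    ``mean`` (location solved numerically; scale kept at ``sd``)."""
    if not lower < mean < upper:
        raise ProfileValidationError(
            f"target mean {mean} outside truncation bounds ({lower}, {upper})"
        )

    def trunc_mean(loc: float) -> float:
        a = (lower - loc) / sd
        b = (upper - loc) / sd if np.isfinite(upper) else np.inf
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    lo_br, hi_br = mean - 8 * sd, mean + 8 * sd
    loc = optimize.brentq(lambda m: trunc_mean(m) - mean, lo_br, hi_br, xtol=1e-10)
    a = (lower - loc) / sd
    b = (upper - loc) / sd if np.isfinite(upper) else np.inf
    return stats.truncnorm(a, b, loc=loc, scale=sd)


def generate_cohort(
    profile: Optional[CohortProfile] = None,
    n: int = 513,
    seed: Optional[int] = None,
) -> Cohort:
    """Draw a synthetic cohort of ``n`` patients.

    Per patient: BMI class by the profile proportions; sex and inpatient
    status Bernoulli with the group rates; age truncated normal ≥ 18;
    height truncated normal in [1.40, 2.10] m; BMI truncated normal within
    class bounds; weight derived as BMI·height²; measured REE = truth
    model + N(0, noise_sd), floored at 500 kcal/day. Deterministic under
    ``seed``.
    """
    if profile is None:
        profile = default_profile()
    if n < 1:
        raise ProfileValidationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    truth = _truth_fn(profile)

    props = np.array([g.proportion for g in profile.groups])
    group_idx = rng.choice(len(profile.groups), size=n, p=props)

    # distributions are fixed per group; solve the location match once
    dists = [
        (
            _matched_truncnorm(g.age_mean, g.age_sd, AGE_LOWER, np.inf),
            _matched_truncnorm(g.height_mean, g.height_sd, *HEIGHT_BOUNDS),
            _matched_truncnorm(g.bmi_mean, g.bmi_sd, g.bmi_lower, g.bmi_upper),
        )
        for g in profile.groups
    ]
    # one uniform block per patient keeps draws reproducible and lets the
    # quantile transforms run vectorised per group
    u = rng.random((n, 5))
    noise = rng.normal(0.0, profile.noise_sd, size=n)

    ages = np.empty(n)
    heights = np.empty(n)
    bmis = np.empty(n)
    for gi, (age_d, height_d, bmi_d) in enumerate(dists):
        mask = group_idx == gi
        ages[mask] = age_d.ppf(u[mask, 1])
        heights[mask] = height_d.ppf(u[mask, 2])
        bmis[mask] = bmi_d.ppf(u[mask, 3])

    records: list[PatientRecord] = []
    for i in range(n):
        g = profile.groups[group_idx[i]]
        sex = int(u[i, 0] < g.pct_male / 100.0)
        height = float(heights[i])
        weight = float(bmis[i] * height**2)
        setting = "inpatient" if u[i, 4] < g.pct_inpatient / 100.0 else "outpatient"
        rec = PatientRecord(
            patient_id=f"SYN{i:05d}",
            sex=sex,
            age=float(ages[i]),
            weight=weight,
            height=height,
            setting=setting,
            duration_min=20.0,
            measurement_index=1,
        )
        ree = max(truth(rec) + noise[i], REE_FLOOR)
        records.append(replace(rec, ree_measured=float(ree)))
    return Cohort(records, provenance=f"synthetic(seed={seed}, n={n})", filtered=True)


def generate_registry(
    n_total: int,
    n_incomplete: int = 0,
    n_minor: int = 0,
    n_icu: int = 0,
    n_pregnant: int = 0,
    n_short: int = 0,
    n_repeat: int = 0,
    seed: Optional[int] = None,
    profile: Optional[CohortProfile] = None,
) -> list[PatientRecord]:
    """Raw measurement registry with planted protocol violations.

    Exactly the requested numbers of records are made incomplete (missing
    height), under-age, ICU, pregnant, too short (<15 min) or repeat
    measurements of another patient; all remaining records pass every
    inclusion filter, so filtering retains ``n_total - sum(planted)``.
    """
    planted = n_incomplete + n_minor + n_icu + n_pregnant + n_short + n_repeat
    counts = (n_incomplete, n_minor, n_icu, n_pregnant, n_short, n_repeat)
    if any(c < 0 for c in counts):
        raise ProfileValidationError("planted counts must be non-negative")
    if planted > n_total:
        raise ProfileValidationError(
            f"planted violations ({planted}) exceed n_total ({n_total})"
        )
    n_clean = n_total - planted
    if n_repeat > 0 and n_clean == 0:
        raise ProfileValidationError("repeat measurements need at least one clean record")

    base = generate_cohort(profile, n=n_total, seed=seed).records
    rng = np.random.default_rng(None if seed is None else seed + 1)

    out: list[PatientRecord] = []
    pos = 0

    def take(k: int) -> list[PatientRecord]:
        nonlocal pos
        chunk = base[pos : pos + k]
        pos += k
        return chunk

    clean = take(n_clean)
    out.extend(clean)
    for rec in take(n_incomplete):
        out.append(PatientRecord(**{**_fields(rec), "height": None}))
    for rec in take(n_minor):
        out.append(PatientRecord(**{**_fields(rec), "age": float(rng.uniform(10, 17.9))}))
    for rec in take(n_icu):
        out.append(PatientRecord(**{**_fields(rec), "icu_flag": True}))
    for rec in take(n_pregnant):
        out.append(
            PatientRecord(**{**_fields(rec), "sex": 0, "pregnant_flag": True})
        )
    for rec in take(n_short):
        out.append(PatientRecord(**{**_fields(rec), "duration_min": 10.0}))
    for i, rec in enumerate(take(n_repeat)):
        host = clean[i % n_clean]
        out.append(
            PatientRecord(
                **{
                    **_fields(rec),
                    "patient_id": host.patient_id,
                    "measurement_index": 2 + i // n_clean,
                }
            )
        )
    perm = rng.permutation(len(out))
    return [out[i] for i in perm]


def _fields(rec: PatientRecord) -> dict:
    return {
        "patient_id": rec.patient_id,
        "sex": rec.sex,
        "age": rec.age,
        "weight": rec.weight,
        "height": rec.height,
        "ree_measured": rec.ree_measured,
        "setting": rec.setting,
        "icu_flag": rec.icu_flag,
        "pregnant_flag": rec.pregnant_flag,
        "duration_min": rec.duration_min,
        "measurement_index": rec.measurement_index,
        "weight_self_reported": rec.weight_self_reported,
        "height_self_reported": rec.height_self_reported,
    }
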