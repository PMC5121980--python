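"""Patient data model, BMI classification, inclusion filtering and CSV I/O.

The unit conventions used throughout the package are fixed here: weight in
kg, height in metres, age in years, measured resting energy expenditure
(REE) in kcal/day, sex coded F=0 / M=1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "BMIClass",
    "BMI_CLASSES",
    "Cohort",
    "ExclusionLog",
    "compute_bmi",
    "classify_bmi",
    "apply_inclusion_filters",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
]


class InvalidInputError(ValueError):
    """Raised when a physiological quantity is outside its domain."""


@dataclass(frozen=True)
class PatientRecord:
    """One subject: anthropometry, demographics, measured REE, filter fields.

    Optional fields are ``None`` when missing; completeness is enforced by
    :func:`apply_inclusion_filters`, not at construction, so that raw
    registries with gaps can be represented.
    """

    patient_id: str
    sex: Optional[int] = None  # F=0, M=1
    age: Optional[float] = None  # years
    weight: Optional[float] = None  # kg
    height: Optional[float] = None  # m
    ree_measured: Optional[float] = None  # kcal/day
    setting: Optional[str] = None  # "inpatient" | "outpatient"
    icu_flag: bool = False
    pregnant_flag: bool = False
    duration_min: Optional[float] = None
    measurement_index: int = 1
    weight_self_reported: bool = False
    height_self_reported: bool = False
    weight_adjusted: bool = False

    def __post_init__(self) -> None:
        if self.weight is not None and not self.weight > 0:
            raise InvalidInputError(f"weight must be > 0, got {self.weight}")
        if self.height is not None and not self.height > 0:
            raise InvalidInputError(f"height must be > 0, got {self.height}")
        if self.age is not None and self.age < 0:
            raise InvalidInputError(f"age must be >= 0, got {self.age}")
        if self.ree_measured is not None and not self.ree_measured > 0:
            raise InvalidInputError(
                f"ree_measured must be > 0, got {self.ree_measured}"
            )
        if self.sex is not None and self.sex not in (0, 1):
            raise InvalidInputError(f"sex must be 0 (F) or 1 (M), got {self.sex}")

    @property
    def bmi(self) -> Optional[float]:
        if self.weight is None or self.height is None:
            return None
        return compute_bmi(self.weight, self.height)

    def is_complete(self) -> bool:
        """True when height, weight, age, sex and measured REE are present."""
        return not any(
            v is None
            for v in (self.height, self.weight, self.age, self.sex, self.ree_measured)
        )


@dataclass(frozen=True)
class BMIClass:
    """Half-open BMI interval [lower, upper) in kg/m²."""

    label: str
    lower: float
    upper: float  # exclusive; +inf for obese

    def contains(self, bmi: float) -> bool:
        return self.lower <= bmi < self.upper


#: The four WHO adult BMI classes; lower-inclusive, upper-exclusive.
BMI_CLASSES: tuple[BMIClass, ...] = (
    BMIClass("underweight", 0.0, 18.5),
    BMIClass("normal", 18.5, 25.0),
    BMIClass("overweight", 25.0, 30.0),
    BMIClass("obese", 30.0, float("inf")),
)


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index: weight (kg) divided by height (m) squared.

    No rounding is applied; rounding is a reporting concern.
    """
    if not weight > 0:
        raise InvalidInputError(f"weight must be > 0, got {weight}")
    if not height > 0:
        raise InvalidInputError(f"height must be > 0, got {height}")
    return weight / height**2


def classify_bmi(bmi: float) -> BMIClass:
    """Map a BMI to its class: underweight <18.5, normal [18.5,25),
    overweight [25,30), obese >=30."""
    if not bmi > 0:
        raise InvalidInputError(f"bmi must be > 0, got {bmi}")
    for cls in BMI_CLASSES:
        if cls.contains(bmi):
            return cls
    raise AssertionError("unreachable: classes partition (0, inf)")


@dataclass
class Cohort:
    """Ordered collection of patient records with a provenance tag."""

    records: list[PatientRecord]
    provenance: str = ""
    filtered: bool = False

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def stratum(self, bmi_class: Optional[BMIClass]) -> "Cohort":
        """Sub-cohort for one BMI class (``None`` → the total group)."""
        if bmi_class is None:
            recs = list(self.records)
        else:
            recs = [
                r
                for r in self.records
                if r.bmi is not None and bmi_class.contains(r.bmi)
            ]
        return Cohort(recs, provenance=self.provenance, filtered=self.filtered)


# Rule order fixes the sequential exclusion accounting: a record removed by
# an earlier rule is never re-counted by a later one.
EXCLUSION_RULES: tuple[str, ...] = (
    "incomplete",
    "minor",
    "icu",
    "pregnant",
    "short_measurement",
    "repeat_measurement",
)


@dataclass
class ExclusionLog:
    counts: dict[str, int] = field(
        default_factory=lambda: {rule: 0 for rule in EXCLUSION_RULES}
    )

    @property
    def total_excluded(self) -> int:
        return sum(self.counts.values())

    def to_text(self) -> str:
        lines = [f"{rule}: {self.counts[rule]}" for rule in EXCLUSION_RULES]
        lines.append(f"total_excluded: {self.total_excluded}")
        return "\n".join(lines)


def apply_inclusion_filters(
    records: Iterable[PatientRecord], provenance: str = ""
) -> tuple[Cohort, ExclusionLog]:
    """Apply the study's inclusion criteria to a raw registry.

    Retains adult records with complete height/weight/age/sex/REE, not in
    ICU, not pregnant, with a measurement of at least 15 minutes, keeping
    only the first measurement per patient. Exclusions are counted
    sequentially per rule (completeness → age → ICU → pregnancy → duration
    → repeats).
    """
    log = ExclusionLog()
    survivors: list[PatientRecord] = []
    for rec in records:
        if not rec.is_complete():
            log.counts["incomplete"] += 1
        elif rec.age < 18:
            log.counts["minor"] += 1
        elif rec.icu_flag:
            log.counts["icu"] += 1
        elif rec.pregnant_flag:
            log.counts["pregnant"] += 1
        elif rec.duration_min is not None and rec.duration_min < 15:
            log.counts["short_measurement"] += 1
        else:
            survivors.append(rec)

    # First-measurement rule: minimal measurement_index per patient_id,
    # ties broken by input order.
    best: dict[str, PatientRecord] = {}
    order: list[str] = []
    for rec in survivors:
        prev = best.get(rec.patient_id)
        if prev is None:
            best[rec.patient_id] = rec
            order.append(rec.patient_id)
        elif rec.measurement_index < prev.measurement_index:
            log.counts["repeat_measurement"] += 1
            best[rec.patient_id] = rec
        else:
            log.counts["repeat_measurement"] += 1
    kept = [best[pid] for pid in order]
    return Cohort(kept, provenance=provenance, filtered=True), log


# ---------------------------------------------------------------------------
# CSV I/O

CSV_COLUMNS = [
    "patient_id",
    "sex",
    "age_y",
    "weight_kg",
    "height_m",
    "ree_kcal_d",
    "setting",
    "icu",
    "pregnant",
    "duration_min",
    "measurement_index",
    "weight_self_reported",
    "height_self_reported",
]

_SEX_TO_CODE = {"F": 0, "M": 1}
_CODE_TO_SEX = {0: "F", 1: "M"}
_SETTING_TO_CSV = {"inpatient": "in", "outpatient": "out"}
_CSV_TO_SETTING = {"in": "inpatient", "out": "outpatient"}


class MalformedRowError(ValueError):
    """A CSV row that cannot be parsed; names the row and column."""


def _opt_float(val, row: int, col: str) -> Optional[float]:
    if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
        return None
    try:
        return float(val)
    except (TypeError, ValueError) as exc:
        raise MalformedRowError(f"row {row}, column {col!r}: {val!r}") from exc


def read_cohort(path) -> list[PatientRecord]:
    """Read patient records from CSV; missing cells become missing fields.

    Filtering is a separate stage: incomplete rows are returned as-is.
    Unknown columns raise a warning and are ignored.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "sex": str, "setting": str})
    unknown = [c for c in df.columns if c not in CSV_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown columns: {unknown}", stacklevel=2)
        df = df.drop(columns=unknown)
    records: list[PatientRecord] = []
    for i, row in enumerate(df.to_dict("records"), start=2):  # 1-based + header
        sex_raw = row.get("sex")
        if sex_raw is None or (isinstance(sex_raw, float) and np.isnan(sex_raw)):
            sex = None
        else:
            sex_raw = str(sex_raw).strip().upper()
            if sex_raw == "":
                sex = None
            elif sex_raw in _SEX_TO_CODE:
                sex = _SEX_TO_CODE[sex_raw]
            else:
                raise MalformedRowError(f"row {i}, column 'sex': {sex_raw!r}")
        setting_raw = row.get("setting")
        if setting_raw is None or (
            isinstance(setting_raw, float) and np.isnan(setting_raw)
        ):
            setting = None
        else:
            setting_raw = str(setting_raw).strip()
            if setting_raw == "":
                setting = None
            elif setting_raw in _CSV_TO_SETTING:
                setting = _CSV_TO_SETTING[setting_raw]
            else:
                raise MalformedRowError(f"row {i}, column 'setting': {setting_raw!r}")
        mi = _opt_float(row.get("measurement_index"), i, "measurement_index")
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    sex=sex,
                    age=_opt_float(row.get("age_y"), i, "age_y"),
                    weight=_opt_float(row.get("weight_kg"), i, "weight_kg"),
                    height=_opt_float(row.get("height_m"), i, "height_m"),
                    ree_measured=_opt_float(row.get("ree_kcal_d"), i, "ree_kcal_d"),
                    setting=setting,
                    icu_flag=bool(_opt_float(row.get("icu"), i, "icu") or 0),
                    pregnant_flag=bool(_opt_float(row.get("pregnant"), i, "pregnant") or 0),
                    duration_min=_opt_float(row.get("duration_min"), i, "duration_min"),
                    measurement_index=int(mi) if mi is not None else 1,
                    weight_self_reported=bool(
                        _opt_float(row.get("weight_self_reported"), i, "weight_self_reported") or 0
                    ),
                    height_self_reported=bool(
                        _opt_float(row.get("height_self_reported"), i, "height_self_reported") or 0
                    ),
                )
            )
        except InvalidInputError as exc:
            raise MalformedRowError(f"row {i}: {exc}") from exc
    return records


def write_cohort(cohort: Cohort | Sequence[PatientRecord], path) -> None:
    """Write records to CSV; missing fields become empty cells."""
    records = cohort.records if isinstance(cohort, Cohort) else list(cohort)
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "sex": _CODE_TO_SEX[r.sex] if r.sex is not None else None,
                "age_y": r.age,
                "weight_kg": r.weight,
                "height_m": r.height,
                "ree_kcal_d": r.ree_measured,
                "setting": _SETTING_TO_CSV[r.setting] if r.setting else None,
                "icu": int(r.icu_flag),
                "pregnant": int(r.pregnant_flag),
                "duration_min": r.duration_min,
                "measurement_index": r.measurement_index,
                "weight_self_reported": int(r.weight_self_reported),
                "height_self_reported": int(r.height_self_reported),
            }
        )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Descriptive summary (Table-1 shape)


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Descriptive table for the total group and each BMI class.

    Reports n, % of total, mean/SD of age, weight, height, BMI and measured
    REE, % male, % inpatient, and REE per kg as the mean (and min–max) of
    per-patient ratios ree/weight.
    """
    strata: list[tuple[str, Cohort]] = [("total", cohort)] + [
        (cls.label, cohort.stratum(cls)) for cls in BMI_CLASSES
    ]
    total_n = len(cohort)
    rows = []
    for label, sub in strata:
        n = len(sub)
        row: dict[str, object] = {"stratum": label, "n": n}
        row["pct_of_total"] = 100.0 * n / total_n if total_n else np.nan
        if n == 0:
            for k in (
                "age_mean", "age_sd", "weight_mean", "weight_sd", "height_mean",
                "height_sd", "bmi_mean", "bmi_sd", "ree_mean", "ree_sd",
                "pct_male", "pct_inpatient", "ree_per_kg_mean",
                "ree_per_kg_min", "ree_per_kg_max",
            ):
                row[k] = np.nan
            rows.append(row)
            continue
        arr = lambda f: np.array([f(r) for r in sub], dtype=float)  # noqa: E731
        for name, f in (
            ("age", lambda r: r.age),
            ("weight", lambda r: r.weight),
            ("height", lambda r: r.height),
            ("bmi", lambda r: r.bmi),
            ("ree", lambda r: r.ree_measured),
        ):
            vals = arr(f)
            row[f"{name}_mean"] = float(np.mean(vals))
            row[f"{name}_sd"] = float(np.std(vals, ddof=1)) if n > 1 else np.nan
        row["pct_male"] = 100.0 * float(np.mean(arr(lambda r: r.sex)))
        settings = [r.setting for r in sub if r.setting is not None]
        row["pct_inpatient"] = (
            100.0 * sum(s == "inpatient" for s in settings) / len(settings)
            if settings
            else np.nan
        )
        per_kg = arr(lambda r: r.ree_measured / r.weight)
        row["ree_per_kg_mean"] = float(np.mean(per_kg))
        row["ree_per_kg_min"] = float(np.min(per_kg))
        row["ree_per_kg_max"] = float(np.max(per_kg))
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")


def with_adjusted_weight(record: PatientRecord, new_weight: float) -> PatientRecord:
    """Copy of a record with a replaced weight, flagged as adjusted."""
    return replace(record, weight=new_weight, weight_adjusted=True)
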