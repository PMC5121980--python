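"""Registry of REE predictive equations and the prediction engine.

Each equation is described declaratively (form, units, age/sex bands,
coefficients) and shipped in ``data/equations.yaml``; the engine evaluates
any spec against a patient record and normalises the output to kcal/day.

Forms
-----
linear
    REE = b0 + bW·W + bH·H + bA·A + bS·sex, one coefficient set.
banded_linear
    One linear coefficient set per (sex, age band); covers sex-stratified
    equations (Harris–Benedict, Bernstein) and age-banded ones (WHO,
    Schofield, Henry).
bmi_banded_linear
    One linear coefficient set per BMI interval (Müller's BMI-specific
    equations; the combined study equation that switches at BMI 25).
power
    REE = a·W^p − c·age, sex-specific parameters (Livingston).
per_kg_fixed
    REE = factor · W, with the 1.3 activity/stress divisor applied by
    default (the factor prescribes total energy, not REE).
sex_fixed
    2000 kcal (F) / 2500 kcal (M); the 1.3 divisor is available but off by
    default.

Energy conversion is fixed at 1 kcal = 4.184 kJ, 1 MJ = 1000 kJ.
Sex is coded F=0, M=1 everywhere. Height is stored in metres; equations
quoted in centimetres convert internally.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .cohort import InvalidInputError, PatientRecord, compute_bmi

__all__ = [
    "KJ_PER_KCAL",
    "Coefficients",
    "AgeBand",
    "BMIBand",
    "EquationSpec",
    "EquationRegistry",
    "Prediction",
    "predict_ree",
    "load_coefficient_table",
    "new_kruizenga_lt25",
    "weijs_vansant_ge25",
    "combined_paper_equation",
    "fixed_by_sex",
]

KJ_PER_KCAL = 4.184  # thermochemical calorie, exact by convention here

#: plausibility window for flagging (never clamping) predictions, kcal/day
PLAUSIBLE_RANGE = (500.0, 5000.0)

ADULT_AGE_RANGE = (18.0, 110.0)


class BandingError(ValueError):
    """Patient age falls outside every band of a banded equation."""


class RegistryValidationError(ValueError):
    """Coefficient file fails structural validation."""


class Coefficients(BaseModel):
    """Linear coefficient vector; absent terms default to zero."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    intercept: float = 0.0
    weight: float = 0.0
    height: float = 0.0
    age: float = 0.0
    sex: float = 0.0

    def evaluate(self, *, weight: float, height: float, age: float, sex: int) -> float:
        return (
            self.intercept
            + self.weight * weight
            + self.height * height
            + self.age * age
            + self.sex * sex
        )


class AgeBand(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    sex: Literal[0, 1]
    age: tuple[float, float]  # [lower, upper); upper may be inf
    coefficients: Coefficients


class BMIBand(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    bmi: tuple[float, float]  # [lower, upper)
    coefficients: Coefficients


class PowerParams(BaseModel):
    """REE = a · weight^p − c · age."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    a: float
    p: float
    c: float


class EquationSpec(BaseModel):
    """Declarative description of one predictive equation."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    display_name: str = ""
    form: Literal[
        "linear", "banded_linear", "bmi_banded_linear", "power", "per_kg_fixed", "sex_fixed"
    ]
    output_unit: Literal["kcal/day", "kJ/day", "MJ/day"] = "kcal/day"
    height_unit: Literal["m", "cm", "none"] = "none"
    requires: tuple[str, ...] = ()
    source: str = ""
    coefficients: Optional[Coefficients] = None
    bands: tuple[AgeBand, ...] = ()
    bmi_bands: tuple[BMIBand, ...] = ()
    power: Optional[dict[Literal[0, 1], PowerParams]] = None
    per_kg_factor: Optional[float] = None
    sex_values: Optional[dict[Literal[0, 1], float]] = None
    activity_divisor: float = Field(default=1.0, gt=0)
    apply_divisor_default: bool = True

    @model_validator(mode="after")
    def _check_form(self) -> "EquationSpec":
        if self.form == "linear" and self.coefficients is None:
            raise RegistryValidationError(f"{self.name}: linear form needs coefficients")
        if self.form == "banded_linear":
            if not self.bands:
                raise RegistryValidationError(f"{self.name}: banded form needs bands")
            self._check_band_partition()
        if self.form == "bmi_banded_linear":
            if not self.bmi_bands:
                raise RegistryValidationError(f"{self.name}: needs bmi_bands")
            self._check_bmi_partition()
        if self.form == "power" and not self.power:
            raise RegistryValidationError(f"{self.name}: power form needs parameters")
        if self.form == "per_kg_fixed" and self.per_kg_factor is None:
            raise RegistryValidationError(f"{self.name}: per-kg form needs a factor")
        if self.form == "sex_fixed" and not self.sex_values:
            raise RegistryValidationError(f"{self.name}: sex-fixed form needs values")
        # bmi_banded forms may require height solely to compute BMI
        if (
            self.height_unit == "none"
            and "height" in self.requires
            and self.form in ("linear", "banded_linear")
        ):
            raise RegistryValidationError(f"{self.name}: requires height but unit is none")
        return self

    def _check_band_partition(self) -> None:
        """Per sex, bands must tile the adult age range with no overlap/gap."""
        lo, hi = ADULT_AGE_RANGE
        for sex in (0, 1):
            bands = sorted(
                (b for b in self.bands if b.sex == sex), key=lambda b: b.age[0]
            )
            if not bands:
                raise RegistryValidationError(f"{self.name}: no bands for sex={sex}")
            if bands[0].age[0] > lo:
                raise RegistryValidationError(
                    f"{self.name}: sex={sex} bands start above age {lo}"
                )
            for prev, nxt in zip(bands, bands[1:]):
                if nxt.age[0] < prev.age[1]:
                    raise RegistryValidationError(
                        f"{self.name}: overlapping age bands {prev.age} / {nxt.age}"
                    )
                if nxt.age[0] > prev.age[1]:
                    raise RegistryValidationError(
                        f"{self.name}: gap between age bands {prev.age} / {nxt.age}"
                    )
            if bands[-1].age[1] < hi:
                raise RegistryValidationError(
                    f"{self.name}: sex={sex} bands stop below age {hi}"
                )

    def _check_bmi_partition(self) -> None:
        bands = sorted(self.bmi_bands, key=lambda b: b.bmi[0])
        if bands[0].bmi[0] > 0:
            raise RegistryValidationError(f"{self.name}: BMI bands must start at 0")
        for prev, nxt in zip(bands, bands[1:]):
            if nxt.bmi[0] != prev.bmi[1]:
                raise RegistryValidationError(
                    f"{self.name}: BMI bands not contiguous: {prev.bmi} / {nxt.bmi}"
                )
        if not math.isinf(bands[-1].bmi[1]):
            raise RegistryValidationError(f"{self.name}: BMI bands must reach infinity")


@dataclass(frozen=True)
class Prediction:
    patient_id: str
    equation: str
    ree_predicted: float  # kcal/day
    flags: tuple[str, ...] = ()


def _to_kcal(value: float, unit: str) -> float:
    if unit == "kcal/day":
        return value
    if unit == "kJ/day":
        return value / KJ_PER_KCAL
    if unit == "MJ/day":
        return value * 1000.0 / KJ_PER_KCAL
    raise RegistryValidationError(f"unknown output unit {unit!r}")


def _height_in_unit(height_m: float, unit: str) -> float:
    if unit == "cm":
        return height_m * 100.0
    return height_m  # "m" or "none" (value unused when none)


def _select_age_band(spec: EquationSpec, sex: int, age: float) -> Coefficients:
    bands = sorted((b for b in spec.bands if b.sex == sex), key=lambda b: b.age[0])
    for band in bands:
        if band.age[0] <= age < band.age[1]:
            return band.coefficients
    if bands and age >= bands[-1].age[1]:
        return bands[-1].coefficients  # above top band: highest band applies
    raise BandingError(f"{spec.name}: no age band for sex={sex}, age={age}")


def _require(patient: PatientRecord, spec: EquationSpec) -> None:
    for fieldname in spec.requires:
        attr = {"weight": "weight", "height": "height", "age": "age", "sex": "sex"}[
            fieldname
        ]
        if getattr(patient, attr) is None:
            raise InvalidInputError(
                f"{spec.name}: patient {patient.patient_id} missing {fieldname}"
            )


def predict_ree(
    spec: EquationSpec, patient: PatientRecord, apply_divisor: Optional[bool] = None
) -> Prediction:
    """Evaluate one equation for one patient; result in kcal/day.

    ``apply_divisor`` overrides the equation's default for the 1.3
    activity/stress divisor of the fixed factors; ``None`` keeps the
    default. Negative or implausible values are flagged, never clamped.
    """
    _require(patient, spec)
    w, h, a, s = patient.weight, patient.height, patient.age, patient.sex

    if spec.form == "linear":
        raw = spec.coefficients.evaluate(
            weight=w or 0.0,
            height=_height_in_unit(h, spec.height_unit) if h is not None else 0.0,
            age=a or 0.0,
            sex=s or 0,
        )
    elif spec.form == "banded_linear":
        coef = _select_age_band(spec, s, a)
        raw = coef.evaluate(
            weight=w or 0.0,
            height=_height_in_unit(h, spec.height_unit) if h is not None else 0.0,
            age=a or 0.0,
            sex=s or 0,
        )
    elif spec.form == "bmi_banded_linear":
        bmi = compute_bmi(w, h)
        coef = None
        for band in spec.bmi_bands:
            if band.bmi[0] <= bmi < band.bmi[1]:
                coef = band.coefficients
                break
        if coef is None:  # pragma: no cover - partition validated at load
            raise BandingError(f"{spec.name}: no BMI band for {bmi}")
        raw = coef.evaluate(
            weight=w,
            height=_height_in_unit(h, spec.height_unit),
            age=a or 0.0,
            sex=s or 0,
        )
    elif spec.form == "power":
        params = spec.power[s]
        raw = params.a * w**params.p - params.c * a
    elif spec.form == "per_kg_fixed":
        raw = spec.per_kg_factor * w
    elif spec.form == "sex_fixed":
        raw = spec.sex_values[s]
    else:  # pragma: no cover
        raise RegistryValidationError(f"unknown form {spec.form!r}")

    value = _to_kcal(raw, spec.output_unit)
    use_divisor = spec.apply_divisor_default if apply_divisor is None else apply_divisor
    if use_divisor:
        value /= spec.activity_divisor

    flags: list[str] = []
    if value < 0:
        flags.append("negative")
    if not PLAUSIBLE_RANGE[0] <= value <= PLAUSIBLE_RANGE[1]:
        flags.append("implausible")
    return Prediction(patient.patient_id, spec.name, value, tuple(flags))


class EquationRegistry:
    """Ordered mapping of equation name → :class:`EquationSpec`."""

    def __init__(self, specs: list[EquationSpec], checksum: str = ""):
        self._specs = {s.name: s for s in specs}
        if len(self._specs) != len(specs):
            raise RegistryValidationError("duplicate equation names")
        self.checksum = checksum

    def __getitem__(self, name: str) -> EquationSpec:
        return self._specs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def names(self) -> list[str]:
        return list(self._specs)


def load_coefficient_table(path=None) -> EquationRegistry:
    """Load and validate the equation registry.

    With no argument, loads the coefficient file shipped with the package
    (the full set scored in the analysis: the combined study equation,
    Korth, WHO, Schofield, Henry, Harris–Benedict 1918 and the Roza
    revision, Müller general and BMI-specific, Mifflin, Livingston,
    Bernstein, and the three fixed factors).
    """
    if path is None:
        text = (
            resources.files("reeval").joinpath("data/equations.yaml").read_text("utf-8")
        )
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    checksum = hashlib.sha256(text.encode("utf-8")).hexdigest()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "equations" not in doc:
        raise RegistryValidationError("coefficient file must have an 'equations' list")
    specs = []
    for entry in doc["equations"]:
        try:
            specs.append(EquationSpec(**entry))
        except RegistryValidationError:
            raise
        except (TypeError, ValueError) as exc:
            raise RegistryValidationError(
                f"invalid equation entry {entry.get('name', '?')!r}: {exc}"
            ) from exc
    return EquationRegistry(specs, checksum=checksum)


# ---------------------------------------------------------------------------
# The two equations printed in full in the study, as direct functions.

_KRUIZENGA_LT25 = Coefficients(
    intercept=-137.475, weight=11.355, height=7.224, age=-4.649, sex=135.265
)
_WEIJS_VANSANT_GE25 = Coefficients(
    intercept=-221.631, weight=14.038, height=4.498, age=-0.977, sex=137.566
)


def new_kruizenga_lt25(patient: PatientRecord) -> float:
    """The study's new equation, developed on hospital patients with BMI < 25.

    REE (kcal/day) = 11.355·W(kg) + 7.224·H(cm) − 4.649·age(y)
    + 135.265·sex(F=0, M=1) − 137.475. BMI gating is the caller's concern.
    """
    if patient.weight is None or patient.height is None:
        raise InvalidInputError("weight and height required")
    return _KRUIZENGA_LT25.evaluate(
        weight=patient.weight,
        height=patient.height * 100.0,
        age=patient.age or 0.0,
        sex=patient.sex or 0,
    )


def weijs_vansant_ge25(patient: PatientRecord) -> float:
    """Weijs–Vansant equation for overweight/obese adults (BMI ≥ 25).

    REE (kcal/day) = 14.038·W(kg) + 4.498·H(cm) − 0.977·age(y)
    + 137.566·sex(F=0, M=1) − 221.631.
    """
    if patient.weight is None or patient.height is None:
        raise InvalidInputError("weight and height required")
    return _WEIJS_VANSANT_GE25.evaluate(
        weight=patient.weight,
        height=patient.height * 100.0,
        age=patient.age or 0.0,
        sex=patient.sex or 0,
    )


def combined_paper_equation(patient: PatientRecord) -> float:
    """Dispatch on BMI: the new equation below 25, Weijs–Vansant at or above."""
    bmi = compute_bmi(patient.weight, patient.height)
    if bmi < 25.0:
        return new_kruizenga_lt25(patient)
    return weijs_vansant_ge25(patient)


def fixed_by_sex(sex: int, apply_divisor: bool = False) -> float:
    """Fixed prescription: 2000 kcal (F) / 2500 kcal (M), optional /1.3."""
    if sex not in (0, 1):
        raise InvalidInputError(f"sex must be 0 or 1, got {sex}")
    value = 2500.0 if sex == 1 else 2000.0
    return value / 1.3 if apply_divisor else value
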