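"""Scoring of REE predictions against indirect-calorimetry measurements.

A prediction is *accurate* when it falls within 90–110% of the measured
value (both boundaries inclusive, judged at a 1e-9 relative tolerance);
below that band it under-predicts, above it over-predicts. Per equation
and per BMI stratum the module reports the share of patients in each band,
the bias (mean percentage error) and the root-mean-square error in
kcal/day, i.e. the standard validation summary for energy-expenditure
equations. A weight-adjustment re-evaluation clamps BMI into [18.5, 30]
before prediction and compares accuracy in the underweight and obese
strata against the unadjusted run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    BMI_CLASSES,
    BMIClass,
    Cohort,
    InvalidInputError,
    PatientRecord,
    compute_bmi,
    with_adjusted_weight,
)
from .equations import EquationRegistry, EquationSpec, predict_ree

__all__ = [
    "AccuracyClass",
    "EquationPerformance",
    "classify_prediction",
    "bias_percent",
    "rmse",
    "evaluate_equation",
    "performance_table",
    "adjust_weight",
    "adjusted_weight_comparison",
]

logger = logging.getLogger(__name__)

_RATIO_TOL = 1e-9  # relative tolerance for the 0.90 / 1.10 band boundaries

#: Table-3 stratum order: total first, then ascending BMI classes.
STRATA: tuple[Optional[BMIClass], ...] = (None,) + BMI_CLASSES


class UndefinedStatisticError(ValueError):
    """A summary statistic was requested for an empty collection."""


@dataclass(frozen=True)
class AccuracyClass:
    label: str  # "under" | "accurate" | "over"


UNDER = AccuracyClass("under")
ACCURATE = AccuracyClass("accurate")
OVER = AccuracyClass("over")


def classify_prediction(predicted: float, measured: float) -> AccuracyClass:
    """Classify one prediction as under / accurate / over.

    Accurate means predicted/measured in [0.90, 1.10]; the boundaries count
    as accurate.
    """
    if not measured > 0:
        raise InvalidInputError(f"measured REE must be > 0, got {measured}")
    ratio = predicted / measured
    if ratio < 0.90 * (1 - _RATIO_TOL):
        return UNDER
    if ratio > 1.10 * (1 + _RATIO_TOL):
        return OVER
    return ACCURATE


def bias_percent(pairs: Iterable[tuple[float, float]]) -> float:
    """Mean percentage error, mean over patients of 100·(pred − meas)/meas."""
    pairs = list(pairs)
    if not pairs:
        raise UndefinedStatisticError("bias of an empty collection")
    errs = [100.0 * (p - m) / m for p, m in pairs]
    if any(m <= 0 for _, m in pairs):
        raise InvalidInputError("measured REE must be > 0")
    return float(np.mean(errs))


def rmse(pairs: Iterable[tuple[float, float]]) -> float:
    """Root-mean-square prediction error in kcal/day."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise UndefinedStatisticError("rmse of an empty collection")
    diff = arr[:, 0] - arr[:, 1]
    return float(np.sqrt(np.mean(diff**2)))


@dataclass(frozen=True)
class EquationPerformance:
    """Per-equation summary for one stratum (kcal/day where dimensional)."""

    equation: str
    stratum: str  # "total" or a BMI class label
    n: int
    mean_pred: float
    sd_pred: float
    pct_under: float
    pct_accurate: float
    pct_over: float
    bias: float  # mean percentage error, %
    rmse: float
    n_skipped: int = 0

    def rounded(self) -> dict:
        """Report-precision view: whole % and whole kcal/day."""
        return {
            "equation": self.equation,
            "stratum": self.stratum,
            "n": self.n,
            "mean_pred": round(self.mean_pred) if self.n else None,
            "sd_pred": round(self.sd_pred) if self.n > 1 else None,
            "pct_under": round(self.pct_under) if self.n else None,
            "pct_accurate": round(self.pct_accurate) if self.n else None,
            "pct_over": round(self.pct_over) if self.n else None,
            "bias": round(self.bias) if self.n else None,
            "rmse": round(self.rmse) if self.n else None,
        }


def _score_stratum(
    sub: Cohort, spec: EquationSpec, stratum_label: str, apply_divisor: Optional[bool]
) -> EquationPerformance:
    preds: list[float] = []
    meas: list[float] = []
    n_skipped = 0
    for rec in sub:
        try:
            pred = predict_ree(spec, rec, apply_divisor=apply_divisor)
        except (InvalidInputError, ValueError) as exc:
            logger.warning(
                "skipping patient %s for %s: %s", rec.patient_id, spec.name, exc
            )
            n_skipped += 1
            continue
        preds.append(pred.ree_predicted)
        meas.append(rec.ree_measured)
    n = len(preds)
    if n == 0:
        return EquationPerformance(
            spec.name, stratum_label, 0, np.nan, np.nan, np.nan, np.nan, np.nan,
            np.nan, np.nan, n_skipped,
        )
    classes = [classify_prediction(p, m) for p, m in zip(preds, meas)]
    n_under = sum(c is UNDER for c in classes)
    n_acc = sum(c is ACCURATE for c in classes)
    n_over = sum(c is OVER for c in classes)
    pairs = list(zip(preds, meas))
    return EquationPerformance(
        equation=spec.name,
        stratum=stratum_label,
        n=n,
        mean_pred=float(np.mean(preds)),
        sd_pred=float(np.std(preds, ddof=1)) if n > 1 else np.nan,
        pct_under=100.0 * n_under / n,
        pct_accurate=100.0 * n_acc / n,
        pct_over=100.0 * n_over / n,
        bias=bias_percent(pairs),
        rmse=rmse(pairs),
        n_skipped=n_skipped,
    )


def evaluate_equation(
    cohort: Cohort,
    spec: EquationSpec,
    stratify: bool = True,
    apply_divisor: Optional[bool] = None,
) -> list[EquationPerformance]:
    """Score one equation on a cohort: total group and, optionally, the four
    BMI strata. Patients the equation cannot evaluate are skipped with a
    logged reason and a reduced stratum n."""
    out = [_score_stratum(cohort, spec, "total", apply_divisor)]
    if stratify:
        for cls in BMI_CLASSES:
            out.append(_score_stratum(cohort.stratum(cls), spec, cls.label, apply_divisor))
    return out


def performance_table(
    cohort: Cohort,
    registry: EquationRegistry,
    stratify: bool = True,
    apply_divisor: Optional[bool] = None,
) -> pd.DataFrame:
    """Score every registry equation; rows ordered by descending total
    accuracy (ties broken by equation name), preceded by the measured-REE
    reference row."""
    rows: list[dict] = []
    order_key: dict[str, tuple] = {}
    for spec in registry:
        perfs = evaluate_equation(cohort, spec, stratify=stratify, apply_divisor=apply_divisor)
        total = perfs[0]
        order_key[spec.name] = (-(total.pct_accurate if total.n else -np.inf), spec.name)
        for perf in perfs:
            row = perf.rounded()
            row["n_skipped"] = perf.n_skipped
            rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df["_key"] = df["equation"].map(order_key)
        stratum_order = {"total": 0, **{c.label: i + 1 for i, c in enumerate(BMI_CLASSES)}}
        df["_srt"] = df["stratum"].map(stratum_order)
        df = df.sort_values(["_key", "_srt"]).drop(columns=["_key", "_srt"])
        df = df.reset_index(drop=True)

    meas = [r.ree_measured for r in cohort]
    ref = {
        "equation": "ree_measured",
        "stratum": "total",
        "n": len(meas),
        "mean_pred": round(float(np.mean(meas))) if meas else None,
        "sd_pred": round(float(np.std(meas, ddof=1))) if len(meas) > 1 else None,
        "pct_under": None,
        "pct_accurate": None,
        "pct_over": None,
        "bias": None,
        "rmse": None,
        "n_skipped": 0,
    }
    return pd.concat([pd.DataFrame([ref]), df], ignore_index=True)


def adjust_weight(patient: PatientRecord) -> PatientRecord:
    """Clamp body weight so BMI lies in [18.5, 30].

    Underweight patients get the weight of BMI 18.5 at their height, obese
    patients that of BMI 30; everyone else is returned unchanged. The
    result carries the ``weight_adjusted`` flag; the operation is
    idempotent.
    """
    bmi = compute_bmi(patient.weight, patient.height)
    if bmi < 18.5:
        return with_adjusted_weight(patient, 18.5 * patient.height**2)
    if bmi > 30.0:
        return with_adjusted_weight(patient, 30.0 * patient.height**2)
    return patient


def adjusted_weight_comparison(
    cohort: Cohort,
    registry: EquationRegistry,
    equations: Sequence[str] = ("who_wtht", "harris_benedict_1918"),
) -> pd.DataFrame:
    """Accuracy with actual vs clamped weight in the underweight and obese
    strata (strata defined by the ORIGINAL BMI), for the named equations."""
    rows = []
    for name in equations:
        spec = registry[name]
        for cls in (BMI_CLASSES[0], BMI_CLASSES[3]):  # underweight, obese
            sub = cohort.stratum(cls)
            if len(sub) == 0:
                continue
            actual = _score_stratum(sub, spec, cls.label, None)
            adjusted_sub = Cohort(
                [adjust_weight(r) for r in sub], provenance=sub.provenance, filtered=sub.filtered
            )
            adjusted = _score_stratum(adjusted_sub, spec, cls.label, None)
            rows.append(
                {
                    "equation": name,
                    "stratum": cls.label,
                    "n": actual.n,
                    "pct_accurate_actual": round(actual.pct_accurate),
                    "pct_accurate_adjusted": round(adjusted.pct_accurate),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "equation", "stratum", "n", "pct_accurate_actual", "pct_accurate_adjusted",
        ],
    )


def format_table(df: pd.DataFrame) -> str:
    """Aligned plain-text rendering of a report table."""
    return df.to_string(index=False, na_rep="-")
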