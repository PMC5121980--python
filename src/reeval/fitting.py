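"""Development of a new linear REE equation by ordinary least squares.

Measured REE (kcal/day) is regressed on weight (kg), height (cm), age (y)
and sex (F=0, M=1) within a BMI subgroup. Height enters in centimetres so
the fitted coefficients are directly comparable with published equations
quoted per cm. Plain OLS, no selection or weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import statsmodels.api as sm

from .cohort import Cohort, PatientRecord
from .equations import Coefficients, EquationSpec

__all__ = ["FittedEquation", "fit_linear_ree", "to_equation_spec"]

MIN_N = 10  # guard against degenerate subgroup fits


class SingularDesignError(ValueError):
    """The regressor matrix is rank-deficient (e.g. single-sex, constant age)."""


@dataclass(frozen=True)
class FittedEquation:
    """OLS result: REE = b0 + bW·W(kg) + bH·H(cm) + bA·age(y) + bS·sex."""

    intercept: float
    b_weight: float
    b_height_cm: float
    b_age: float
    b_sex: float
    n: int
    residual_sd: float  # kcal/day
    r_squared: float
    std_errors: tuple[float, float, float, float, float]  # same order as coefs
    subgroup: str = ""

    @property
    def coefficients(self) -> tuple[float, float, float, float, float]:
        return (self.intercept, self.b_weight, self.b_height_cm, self.b_age, self.b_sex)

    def predict(self, patient: PatientRecord) -> float:
        return (
            self.intercept
            + self.b_weight * patient.weight
            + self.b_height_cm * patient.height * 100.0
            + self.b_age * patient.age
            + self.b_sex * patient.sex
        )

    def summary_text(self) -> str:
        names = ("intercept", "weight_kg", "height_cm", "age_y", "sex")
        lines = [f"subgroup: {self.subgroup or 'all'}", f"n: {self.n}"]
        for name, coef, se in zip(names, self.coefficients, self.std_errors):
            lines.append(f"{name}: {coef:.3f} (SE {se:.3f})")
        lines.append(f"R2: {self.r_squared:.4f}")
        lines.append(f"residual_sd_kcal: {self.residual_sd:.1f}")
        return "\n".join(lines)


def fit_linear_ree(
    cohort: Cohort,
    bmi_predicate: Optional[Callable[[float], bool]] = None,
    subgroup_label: str = "",
) -> FittedEquation:
    """Fit measured REE on weight, height (cm), age, sex by OLS.

    ``bmi_predicate`` restricts the fit sample (e.g. ``lambda b: b < 25``);
    ``None`` uses the whole cohort. Requires at least 10 patients and a
    full-rank design.
    """
    records = [
        r
        for r in cohort
        if r.is_complete() and (bmi_predicate is None or bmi_predicate(r.bmi))
    ]
    n = len(records)
    if n < MIN_N:
        raise ValueError(f"need at least {MIN_N} patients for a fit, got {n}")
    X = np.column_stack(
        [
            [r.weight for r in records],
            [r.height * 100.0 for r in records],
            [r.age for r in records],
            [r.sex for r in records],
        ]
    )
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            "regressors are collinear; vary weight/height/age and include both sexes"
        )
    y = np.array([r.ree_measured for r in records], dtype=float)
    res = sm.OLS(y, X).fit()
    b0, bw, bh, ba, bs = res.params
    dof = max(n - X.shape[1], 1)
    return FittedEquation(
        intercept=float(b0),
        b_weight=float(bw),
        b_height_cm=float(bh),
        b_age=float(ba),
        b_sex=float(bs),
        n=n,
        residual_sd=float(np.sqrt(res.ssr / dof)),
        r_squared=float(res.rsquared),
        std_errors=tuple(float(s) for s in res.bse),
        subgroup=subgroup_label,
    )


def to_equation_spec(fitted: FittedEquation, name: Optional[str] = None) -> EquationSpec:
    """Wrap a fitted equation as a registry spec usable by ``predict_ree``."""
    tag = fitted.subgroup.replace(" ", "_") if fitted.subgroup else "all"
    return EquationSpec(
        name=name or f"fitted_{tag}",
        display_name=f"Fitted ({fitted.subgroup or 'all'})",
        form="linear",
        output_unit="kcal/day",
        height_unit="cm",
        requires=("weight", "height", "age", "sex"),
        source=f"OLS fit, n={fitted.n}",
        coefficients=Coefficients(
            intercept=fitted.intercept,
            weight=fitted.b_weight,
            height=fitted.b_height_cm,
            age=fitted.b_age,
            sex=fitted.b_sex,
        ),
    )
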