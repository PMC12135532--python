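"""Kidney-function and body-size covariate equations, KDIGO staging, the
anuria rule, and covariate imputation.

Kidney function is assessed three ways, matching routine intensive-care
practice: the MDRD and CKD-EPI (2009 creatinine) estimated glomerular
filtration rates on the 1.73 m2-normalized scale, and the Cockcroft-Gault
estimated creatinine clearance in absolute mL/min.  The MDRD variant is the
4-variable IDMS-traceable equation (coefficient 175) without a race term;
body surface area uses the Mosteller formula.  Anuria is a 24-hour urine
output below 100 mL and, in the PK model, forces body clearance to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CovariateSet",
    "KDIGO_CATEGORIES",
    "bsa_mosteller",
    "egfr_mdrd",
    "egfr_ckdepi",
    "egfr_relative_to_absolute",
    "ecrcl_cg",
    "classify_kdigo",
    "is_anuric",
    "impute_covariates",
]

ANURIA_THRESHOLD_ML = 100.0

#: KDIGO eGFR categories, printed boundaries; half-open [lower, upper + 1).
KDIGO_CATEGORIES = ("<15", "15-29", "30-44", "45-59", "60-89", ">=90")
_KDIGO_LOWER = (0.0, 15.0, 30.0, 45.0, 60.0, 90.0)


def bsa_mosteller(weight_kg: float, height_cm: float) -> float:
    """Mosteller body surface area: sqrt(weight * height / 3600), m2."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return float(np.sqrt(weight_kg * height_cm / 3600.0))


def _check_sex(sex: str) -> str:
    sex = str(sex).lower()
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    return sex


def egfr_mdrd(scr_mg_dl: float, age_y: float, sex: str) -> float:
    """4-variable IDMS-traceable MDRD eGFR, mL/min/1.73 m2 (no race term):
    175 * Scr^-1.154 * age^-0.203 (* 0.742 if female)."""
    if scr_mg_dl <= 0 or age_y <= 0:
        raise ValueError("serum creatinine and age must be positive")
    out = 175.0 * scr_mg_dl**-1.154 * age_y**-0.203
    if _check_sex(sex) == "female":
        out *= 0.742
    return out


def egfr_ckdepi(scr_mg_dl: float, age_y: float, sex: str) -> float:
    """CKD-EPI 2009 creatinine eGFR, mL/min/1.73 m2 (no race term).

    Carried as the screened-but-unselected alternative kidney-function
    marker; the final PK model uses the MDRD estimate.
    """
    if scr_mg_dl <= 0 or age_y <= 0:
        raise ValueError("serum creatinine and age must be positive")
    if _check_sex(sex) == "female":
        kappa, alpha, sexfac = 0.7, -0.329, 1.018
    else:
        kappa, alpha, sexfac = 0.9, -0.411, 1.0
    r = scr_mg_dl / kappa
    return 141.0 * min(r, 1.0) ** alpha * max(r, 1.0) ** -1.209 * 0.993**age_y * sexfac


def egfr_relative_to_absolute(egfr_rel: float, bsa_m2: float) -> float:
    """De-normalize an eGFR from mL/min/1.73 m2 to absolute mL/min via the
    individual body surface area."""
    if egfr_rel < 0 or bsa_m2 <= 0:
        raise ValueError("egfr must be >= 0 and bsa positive")
    return egfr_rel * bsa_m2 / 1.73


def ecrcl_cg(scr_mg_dl: float, age_y: float, weight_kg: float, sex: str) -> float:
    """Cockcroft-Gault estimated creatinine clearance, mL/min:
    (140 - age) * weight / (72 * Scr), * 0.85 if female."""
    if scr_mg_dl <= 0:
        raise ValueError("serum creatinine must be positive")
    if age_y <= 0 or weight_kg <= 0:
        raise ValueError("age and weight must be positive")
    out = max(0.0, 140.0 - age_y) * weight_kg / (72.0 * scr_mg_dl)
    if _check_sex(sex) == "female":
        out *= 0.85
    return out


def classify_kdigo(egfr: float) -> str:
    """KDIGO eGFR category label for an eGFR in mL/min/1.73 m2."""
    if egfr < 0:
        raise ValueError("egfr must be non-negative")
    idx = int(np.searchsorted(_KDIGO_LOWER, egfr, side="right")) - 1
    return KDIGO_CATEGORIES[idx]


def is_anuric(urine_output_24h_ml: float) -> bool:
    """True iff 24-hour urine output is strictly below 100 mL."""
    if urine_output_24h_ml < 0:
        raise ValueError("urine output must be non-negative")
    return urine_output_24h_ml < ANURIA_THRESHOLD_ML


@dataclass
class CovariateSet:
    """Baseline covariates of one subject, in the units used throughout.

    ``egfr_mdrd``/``egfr_ckdepi`` are on the 1.73 m2-normalized scale;
    ``ecrcl_cg`` is absolute mL/min.  ``qb`` (blood flow) is carried for
    completeness but unused by the final model.
    """

    serum_creatinine: float | None = None  # mg/dL
    age: float | None = None  # years
    sex: str = "male"
    body_weight: float | None = None  # kg
    body_height: float | None = None  # cm
    urine_output_24h: float | None = None  # mL
    qd: float | None = None  # dialysate flow, mL/min
    qb: float | None = None  # blood flow, mL/min
    study_b: bool = False
    egfr_mdrd: float | None = None
    egfr_ckdepi: float | None = None
    ecrcl_cg: float | None = None
    bsa: float | None = None
    anuric: bool = field(default=False)

    def derive(self) -> "CovariateSet":
        """Fill the derived fields (BSA, eGFRs, eCrCL, anuria flag) from the
        measured ones where possible; returns self for chaining."""
        if self.bsa is None and self.body_weight and self.body_height:
            self.bsa = bsa_mosteller(self.body_weight, self.body_height)
        if self.serum_creatinine and self.age:
            if self.egfr_mdrd is None:
                self.egfr_mdrd = egfr_mdrd(self.serum_creatinine, self.age, self.sex)
            if self.egfr_ckdepi is None:
                self.egfr_ckdepi = egfr_ckdepi(self.serum_creatinine, self.age, self.sex)
            if self.ecrcl_cg is None and self.body_weight:
                self.ecrcl_cg = ecrcl_cg(
                    self.serum_creatinine, self.age, self.body_weight, self.sex
                )
        if self.urine_output_24h is not None:
            self.anuric = is_anuric(self.urine_output_24h)
        return self


def impute_covariates(
    table: pd.DataFrame,
    covariate_columns: list[str] | None = None,
    id_column: str = "ID",
    time_column: str = "TIME",
) -> pd.DataFrame:
    """Complete a longitudinal covariate table.

    Within a subject, gaps are filled by last-observation-carried-forward
    (leading gaps by the subject's first recorded value); a characteristic
    missing for an entire subject is replaced by the cohort median of the
    per-subject medians.  Idempotent; raises if a required covariate is
    missing for every subject.
    """
    out = table.copy()
    if covariate_columns is None:
        covariate_columns = [
            c for c in out.columns if c not in (id_column, time_column) and
            pd.api.types.is_numeric_dtype(out[c])
        ]
    out = out.sort_values([id_column, time_column], kind="stable")
    for col in covariate_columns:
        if out[col].isna().all():
            raise ValueError(f"covariate {col!r} is missing for every subject")
        grouped = out.groupby(id_column, sort=False)[col]
        out[col] = grouped.ffill()
        out[col] = out.groupby(id_column, sort=False)[col].bfill()
        if out[col].isna().any():
            cohort_median = (
                out.groupby(id_column, sort=False)[col].median().median()
            )
            out[col] = out[col].fillna(cohort_median)
    return out.sort_index() if out.index.is_monotonic_increasing else out
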