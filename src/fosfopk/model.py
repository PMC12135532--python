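"""Final population-PK model of intravenous fosfomycin: parameters and
covariate/variability relationships.

The structural model is a two-compartment disposition model with zero-order
(infusion) input and two parallel first-order elimination pathways acting on
the central compartment:

* body clearance ``CL_body = theta_cl * (eGFR / 48.4)**theta_kf * exp(eta_CL)``,
  forced to zero for anuric subjects (24-h urine output < 100 mL) and for the
  study-B cohort (no measurable elimination between dialysis sessions);
* dialysis clearance ``CL_KRT = theta_dial * (Q_D / 42)**theta_qd`` while a
  dialysis session is running, zero otherwise (no inter-individual
  variability on the dialysis pathway).

The peripheral volume of anuric subjects grows linearly with time since the
first dose (0.07 %/min at the published estimate), reflecting fluid retention
during severely reduced kidney function; for everyone else it is constant.

Inter-individual variability is lognormal (exponential eta models) on body
clearance and on the two volumes; residual variability is a combined
proportional + additive model on the concentration scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "FixedEffects",
    "RandomEffects",
    "IndividualParams",
    "FULL_DATASET",
    "REDUCED_DATASET",
    "typical_cl_body",
    "typical_cl_krt",
    "vp_at",
    "individual_params",
    "omega2_to_cv",
    "cv_to_omega2",
    "residual_variance",
    "draw_etas",
    "save_params",
    "load_params",
]


def omega2_to_cv(omega2: float) -> float:
    """Convert a lognormal IIV variance to the reported %CV: 100*sqrt(exp(w2)-1)."""
    if omega2 < 0:
        raise ValueError("omega2 must be non-negative")
    return 100.0 * math.sqrt(math.expm1(omega2))


def cv_to_omega2(cv_percent: float) -> float:
    """Inverse of :func:`omega2_to_cv`: ln(1 + (cv/100)^2)."""
    if cv_percent < 0:
        raise ValueError("%CV must be non-negative")
    return math.log1p((cv_percent / 100.0) ** 2)


@dataclass(frozen=True)
class FixedEffects:
    """Typical-value (population) parameters of the final model.

    Units: clearances L/h, volumes L, ``theta_t`` per minute (time-slope of
    the peripheral volume), exponents unitless.  ``egfr_ref`` (mL/min/1.73 m2)
    and ``qd_ref`` (mL/min) are the fixed covariate normalizers of the
    published covariate equations.
    """

    theta_cl: float = 1.6
    theta_kf: float = 0.869
    theta_vc: float = 23.1
    theta_vp: float = 15.4
    theta_t: float = 0.0007
    theta_q: float = 12.0
    theta_dial: float = 2.0
    theta_qd: float = 0.587
    egfr_ref: float = 48.4
    qd_ref: float = 42.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"FixedEffects.{f.name} must be positive, got {v!r}")

    @property
    def vp_slope_per_h(self) -> float:
        """Peripheral-volume growth slope on the internal hour scale."""
        return self.theta_t * 60.0


@dataclass(frozen=True)
class RandomEffects:
    """Variance components: lognormal IIV variances (omega^2, unitless) on
    CL_body / V_C / V_P, plus the combined residual-error parameters
    (proportional SD as a fraction of the prediction, additive SD in mg/L).

    Defaults reproduce the published variability estimates, which are
    reported as %CV and converted through ``ln(1 + (cv/100)^2)``.
    """

    omega2_cl: float = cv_to_omega2(84.6)
    omega2_vc: float = cv_to_omega2(74.8)
    omega2_vp: float = cv_to_omega2(71.1)
    sigma_prop: float = 0.147
    sigma_add: float = 21.9

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"RandomEffects.{f.name} must be >= 0, got {v!r}")

    @property
    def omega2(self) -> np.ndarray:
        return np.array([self.omega2_cl, self.omega2_vc, self.omega2_vp])


#: Estimates from the pooled four-study analysis (n = 45 subjects).
FULL_DATASET = (FixedEffects(), RandomEffects())

#: Sensitivity re-estimation excluding the study-B cohort (n = 37 subjects).
REDUCED_DATASET = (
    FixedEffects(
        theta_cl=1.6,
        theta_kf=0.875,
        theta_vc=25.0,
        theta_vp=14.6,
        theta_t=0.0008,
        theta_q=10.7,
        theta_dial=2.05,
        theta_qd=0.488,
    ),
    RandomEffects(
        omega2_cl=cv_to_omega2(84.7),
        omega2_vc=cv_to_omega2(81.6),
        omega2_vp=cv_to_omega2(51.1),
        sigma_prop=0.150,
        sigma_add=21.9,
    ),
)


@dataclass(frozen=True)
class IndividualParams:
    """Realized subject-level parameters after applying covariates and etas.

    ``cl_krt_at(qd)`` gives the dialysis clearance during a session with
    dialysate flow ``qd`` (mL/min); it is zero outside sessions (handled by
    the simulation engine through the session schedule).  ``vp_slope_per_h``
    is zero unless the subject is anuric.
    """

    cl_body: float
    v_c: float
    v_p0: float
    vp_slope_per_h: float
    q: float
    theta_dial: float
    theta_qd: float
    qd_ref: float = 42.0

    def __post_init__(self) -> None:
        if min(self.v_c, self.v_p0, self.q) <= 0:
            raise ValueError("volumes and intercompartmental clearance must be positive")
        if self.cl_body < 0 or self.vp_slope_per_h < 0:
            raise ValueError("cl_body and vp_slope must be non-negative")

    @property
    def vp_slope_active(self) -> bool:
        return self.vp_slope_per_h > 0

    def cl_krt_at(self, qd: float) -> float:
        return self.theta_dial * (qd / self.qd_ref) ** self.theta_qd

    def vp(self, t_h: float):
        """Peripheral volume (L) at time ``t_h`` hours since first dose."""
        return self.v_p0 * (1.0 + self.vp_slope_per_h * np.asarray(t_h))


def typical_cl_body(
    egfr: float, anuric: bool, study_b: bool, fx: FixedEffects | None = None
) -> float:
    """Typical body clearance (L/h) at a given eGFR (mL/min/1.73 m2).

    Returns exactly 0 for anuric or study-B subjects, regardless of eGFR.
    """
    fx = fx or FULL_DATASET[0]
    if egfr < 0:
        raise ValueError("egfr must be non-negative")
    if anuric or study_b:
        return 0.0
    return fx.theta_cl * (egfr / fx.egfr_ref) ** fx.theta_kf


def typical_cl_krt(qd: float, krt_active: bool, fx: FixedEffects | None = None) -> float:
    """Typical dialysis clearance (L/h) at dialysate flow ``qd`` (mL/min);
    zero when no session is running."""
    fx = fx or FULL_DATASET[0]
    if not krt_active:
        return 0.0
    if qd <= 0:
        raise ValueError("qd must be positive during an active KRT session")
    return fx.theta_dial * (qd / fx.qd_ref) ** fx.theta_qd


def vp_at(tsfd_min: float, anuric: bool, fx: FixedEffects | None = None) -> float:
    """Typical peripheral volume (L) at ``tsfd_min`` minutes since first dose.

    Growth (0.07 %/min at the published slope) applies to anuric subjects
    only; for everyone else the peripheral volume is constant.
    """
    fx = fx or FULL_DATASET[0]
    if tsfd_min < 0:
        raise ValueError("time since first dose must be non-negative")
    if not anuric:
        return fx.theta_vp
    return fx.theta_vp * (1.0 + tsfd_min * fx.theta_t)


def individual_params(fx: FixedEffects, eta, cov) -> IndividualParams:
    """Apply exponential random effects and covariates to the typical values.

    ``eta`` is the (eta_CL, eta_VC, eta_VP) vector; ``cov`` must expose
    ``egfr_mdrd``, ``anuric`` and ``study_b`` attributes (a
    :class:`fosfopk.covariates.CovariateSet` or anything duck-typed).
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (3,) or not np.all(np.isfinite(eta)):
        raise ValueError("eta must be a finite 3-vector")
    cl = typical_cl_body(cov.egfr_mdrd, cov.anuric, getattr(cov, "study_b", False), fx)
    return IndividualParams(
        cl_body=cl * math.exp(eta[0]),
        v_c=fx.theta_vc * math.exp(eta[1]),
        v_p0=fx.theta_vp * math.exp(eta[2]),
        vp_slope_per_h=fx.vp_slope_per_h if cov.anuric else 0.0,
        q=fx.theta_q,
        theta_dial=fx.theta_dial,
        theta_qd=fx.theta_qd,
        qd_ref=fx.qd_ref,
    )


def residual_variance(pred, re: RandomEffects):
    """Variance (mg/L)^2 of the combined residual-error model at prediction
    ``pred``: (sigma_prop*pred)^2 + sigma_add^2.  Accepts arrays."""
    pred = np.asarray(pred, dtype=float)
    if np.any(pred < 0):
        raise ValueError("predictions must be non-negative")
    out = (re.sigma_prop * pred) ** 2 + re.sigma_add**2
    return out if out.ndim else float(out)


def draw_etas(re: RandomEffects, n: int, rng) -> np.ndarray:
    """Draw ``n`` i.i.d. eta vectors (n x 3) with diagonal covariance
    diag(omega2_cl, omega2_vc, omega2_vp).  ``rng`` is a seed or a
    :class:`numpy.random.Generator`."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    sd = np.sqrt(re.omega2)
    return rng.standard_normal((n, 3)) * sd


# ---------------------------------------------------------------------------
# flat key = value serialization (bit-exact roundtrip via repr/float)

_UNITS = {
    "theta_cl": "L/h",
    "theta_kf": "unitless exponent",
    "theta_vc": "L",
    "theta_vp": "L",
    "theta_t": "1/min",
    "theta_q": "L/h",
    "theta_dial": "L/h",
    "theta_qd": "unitless exponent",
    "egfr_ref": "mL/min/1.73m2",
    "qd_ref": "mL/min",
    "omega2_cl": "variance",
    "omega2_vc": "variance",
    "omega2_vp": "variance",
    "sigma_prop": "fraction",
    "sigma_add": "mg/L",
}


def save_params(path, fx: FixedEffects, re: RandomEffects) -> None:
    """Write both parameter sets to a flat ``key = value`` text file."""
    lines = ["# fosfomycin population-PK parameters (one per line)"]
    for obj in (fx, re):
        for f in fields(obj):
            v = getattr(obj, f.name)
            lines.append(f"{f.name} = {v!r}  # {_UNITS.get(f.name, '')}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_params(path) -> tuple[FixedEffects, RandomEffects]:
    """Read a file written by :func:`save_params`; roundtrip is bit-exact."""
    vals: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            vals[key.strip()] = float(raw.strip())
    fx_names = {f.name for f in fields(FixedEffects)}
    re_names = {f.name for f in fields(RandomEffects)}
    fx = FixedEffects(**{k: v for k, v in vals.items() if k in fx_names})
    re_ = RandomEffects(**{k: v for k, v in vals.items() if k in re_names})
    return fx, re_
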