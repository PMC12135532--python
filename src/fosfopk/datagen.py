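"""Synthetic cohort generator emulating the four source studies.

No clinical data are deposited for this analysis, so the package ships a
generator that reproduces the four studies' *designs* — dosing regimens,
infusion durations, dialysis modalities and schedules, printed sampling
schedules, and the covariate distributions summarized for each study — and
simulates observations from the population model at chosen "true"
parameters, adding combined proportional + additive residual error.

Study designs (defaults):

========  ==  =================  =============  ==========================
study      n  regimen            dialysis       sampling anchor
========  ==  =================  =============  ==========================
A         10  5 g q8h, 0.5-1 h   PIKRT 8 h d2   session start + 0..480 min
B          8  5 g q8h, 0.5-1 h   PIKRT 6 h d2   first dose + 30..390 min,
                                                then peri-session samples
C         15  5 g q8h, 2 h       CKRT 0-24 h    one series on, one off CKRT
D         12  4 g q6h (one       none           two series around doses
              subject 6 g q8h)
========  ==  =================  =============  ==========================

Study B contributed no laboratory data (height, creatinine) and its patients
showed no drug elimination between dialysis sessions; its subjects carry the
``STUDYB`` flag, zero true body clearance, and empty EGFR/HT fields (to be
completed by covariate imputation before covariate screening).  Anuric
subject counts per study (A 3, B 0, C 7, D 0) follow the per-category
anuria tallies of the source cohort.  Continuous covariates are sampled
lognormally, parameterized by the published median and interquartile range
(method of quantiles); body-mass index is clamped to a plausible 15-50
kg/m2 by resampling weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import covariates as cov
from .engine import DoseEvent, KRTWindow
from .model import FixedEffects, RandomEffects, typical_cl_body
from .nmio import COLUMNS
from .subjects import SubjectData, predict_conc

__all__ = ["StudySpec", "DEFAULT_SPECS", "generate_cohort"]

_Z75 = 0.6744897501960817  # standard-normal 75th percentile


def _lognormal_from_quantiles(median: float, q25: float, q75: float, rng, n: int):
    """Lognormal sample matched to the printed median and IQR."""
    mu = math.log(median)
    sigma = math.log(q75 / q25) / (2.0 * _Z75) if q75 > q25 > 0 else 0.0
    return np.exp(mu + sigma * rng.standard_normal(n))


@dataclass(frozen=True)
class StudySpec:
    """Design of one source study (see module docstring for the defaults)."""

    label: str
    n_patients: int
    dose_mg: float
    interval_h: float
    infusion_range_h: tuple[float, float]
    krt_mode: str  # "pikrt" | "ckrt" | "none"
    krt_window: tuple[float, float] | None
    qd_quantiles: tuple[float, float, float] | None  # (q25, median, q75) mL/min
    n_anuric: int
    study_b: bool
    male_frac: float
    age: tuple[float, float, float]  # (q25, median, q75)
    weight: tuple[float, float, float]
    height: tuple[float, float, float] | None
    scr: tuple[float, float, float] | None
    uo24: tuple[float, float, float]  # non-anuric subjects; anuric draw U(0,99)
    n_alt_regimen: int = 0
    alt_dose_mg: float = 6000.0
    alt_interval_h: float = 8.0
    krt_anchor_offset_h: float = 0.0  # dose-to-session-start offset (study A)

    def sampling_offsets(self) -> dict:
        """Printed sampling schedules, minutes, per anchor."""
        if self.label == "A":
            return {"krt_start": (0, 15, 30, 60, 120, 240, 480)}
        if self.label == "B":
            return {
                "first_dose": (30, 60, 90, 150, 270, 390),
                "krt_pre": (-3,),
                "krt_start": (30, 120, 240, 360),
            }
        if self.label == "C":
            return {"dose_series": (-5, 15, 30, 60, 90, 180, 240, 300, 360)}
        return {"dose_series": (-5, 30, 45, 60, 90, 120, 240, 360)}


DEFAULT_SPECS = (
    StudySpec(
        label="A", n_patients=10, dose_mg=5000, interval_h=8.0,
        infusion_range_h=(0.5, 1.0), krt_mode="pikrt", krt_window=(24.0, 32.0),
        qd_quantiles=(150.0, 190.0, 240.0), n_anuric=3, study_b=False,
        male_frac=0.9, age=(71.0, 75.5, 79.2), weight=(72.8, 76.5, 79.5),
        height=(173.0, 176.0, 180.0), scr=(0.98, 1.4, 1.6),
        uo24=(150.0, 410.0, 2200.0),
    ),
    StudySpec(
        label="B", n_patients=8, dose_mg=5000, interval_h=8.0,
        infusion_range_h=(0.5, 1.0), krt_mode="pikrt", krt_window=(24.0, 30.0),
        qd_quantiles=(240.0, 250.0, 255.0), n_anuric=0, study_b=True,
        male_frac=0.5, age=(61.5, 64.0, 77.0), weight=(78.8, 99.5, 107.0),
        height=None, scr=None, uo24=(500.0, 700.0, 1000.0),
    ),
    StudySpec(
        label="C", n_patients=15, dose_mg=5000, interval_h=8.0,
        infusion_range_h=(2.0, 2.0), krt_mode="ckrt", krt_window=(0.0, 24.0),
        qd_quantiles=(33.0, 38.0, 42.0), n_anuric=7, study_b=False,
        male_frac=0.87, age=(55.0, 57.0, 62.0), weight=(75.0, 89.0, 105.0),
        height=(172.0, 176.0, 180.0), scr=(1.0, 1.5, 2.2),
        uo24=(150.0, 400.0, 900.0),
    ),
    StudySpec(
        label="D", n_patients=12, dose_mg=4000, interval_h=6.0,
        infusion_range_h=(0.5, 1.0), krt_mode="none", krt_window=None,
        qd_quantiles=None, n_anuric=0, study_b=False,
        male_frac=0.67, age=(57.8, 62.5, 75.0), weight=(69.5, 71.5, 80.0),
        height=(160.0, 166.0, 178.0), scr=(0.6, 0.95, 1.7),
        uo24=(2600.0, 3400.0, 5800.0),
        n_alt_regimen=1,
    ),
)

_DOSING_END_H = 40.0  # doses cover every sampling series with margin


def _obs_times(spec: StudySpec, krt: list[KRTWindow], interval_h: float, rng, jitter: bool):
    """Observation times (h) for one subject from the printed schedules."""
    offs = spec.sampling_offsets()
    times: list[float] = []
    if spec.label == "A":
        anchor = krt[0].start
        times += [anchor + m / 60.0 for m in offs["krt_start"]]
    elif spec.label == "B":
        times += [m / 60.0 for m in offs["first_dose"]]
        anchor = krt[0].start
        times += [anchor + m / 60.0 for m in offs["krt_pre"]]
        times += [anchor + m / 60.0 for m in offs["krt_start"]]
    elif spec.label == "C":
        # one series during CKRT (dose at 8 h) and one after it stops (32 h)
        for anchor in (8.0, 32.0):
            times += [anchor + m / 60.0 for m in offs["dose_series"]]
    else:
        for anchor in (interval_h, 24.0 + interval_h):
            times += [anchor + m / 60.0 for m in offs["dose_series"]]
    times = np.array(sorted(times))
    if jitter:
        times = times + rng.uniform(-2.0, 2.0, size=times.size) / 60.0
        times = np.maximum.accumulate(np.maximum(times, 1.0 / 60.0))
        times += np.arange(times.size) * 1e-6  # keep strictly increasing
    return times


def _sample_covariates(spec: StudySpec, anuric: bool, rng) -> cov.CovariateSet:
    male = rng.random() < spec.male_frac
    age = float(_lognormal_from_quantiles(spec.age[1], spec.age[0], spec.age[2], rng, 1)[0])
    height = (
        float(_lognormal_from_quantiles(spec.height[1], spec.height[0], spec.height[2], rng, 1)[0])
        if spec.height
        else None
    )
    for _ in range(100):
        weight = float(
            _lognormal_from_quantiles(spec.weight[1], spec.weight[0], spec.weight[2], rng, 1)[0]
        )
        if height is None:
            break
        bmi = weight / (height / 100.0) ** 2
        if 15.0 <= bmi <= 50.0:
            break
    scr = (
        float(_lognormal_from_quantiles(spec.scr[1], spec.scr[0], spec.scr[2], rng, 1)[0])
        if spec.scr
        else None
    )
    if anuric:
        uo24 = float(rng.uniform(0.0, 99.0))
    else:
        for _ in range(100):
            uo24 = float(
                _lognormal_from_quantiles(spec.uo24[1], spec.uo24[0], spec.uo24[2], rng, 1)[0]
            )
            if uo24 >= cov.ANURIA_THRESHOLD_ML:
                break
        else:
            uo24 = cov.ANURIA_THRESHOLD_ML
    qd = (
        float(
            _lognormal_from_quantiles(
                spec.qd_quantiles[1], spec.qd_quantiles[0], spec.qd_quantiles[2], rng, 1
            )[0]
        )
        if spec.qd_quantiles
        else None
    )
    c = cov.CovariateSet(
        serum_creatinine=scr,
        age=age,
        sex="male" if male else "female",
        body_weight=weight,
        body_height=height,
        urine_output_24h=uo24,
        qd=qd,
        study_b=spec.study_b,
    )
    return c.derive()


def generate_cohort(
    specs=DEFAULT_SPECS,
    fx: FixedEffects | None = None,
    re: RandomEffects | None = None,
    seed: int | None = None,
    jitter: bool = True,
    residual_error: bool = True,
    egfr_random_walk: float = 0.0,
) -> pd.DataFrame:
    """Generate one synthetic multi-study cohort as an event dataset.

    A seed is required — reproducibility is part of the contract.  Returns a
    dataframe in the :mod:`fosfopk.nmio` column layout (45 subjects under
    the default specs).

    ``egfr_random_walk`` > 0 turns on a stress mode in which the *recorded*
    EGFR column wanders row-to-row as a lognormal random walk with the given
    step SD (e.g. 0.05) around the baseline used for simulation — emulating
    serum-creatinine re-measurements — while the true profile still follows
    the baseline value.
    """
    if seed is None:
        raise ValueError("a seed is required for cohort generation")
    fx = fx or FixedEffects()
    re = re or RandomEffects()
    rng = np.random.default_rng(seed)

    rows: list[dict] = []
    sid = 0
    for spec in specs:
        anuric_flags = np.zeros(spec.n_patients, dtype=bool)
        anuric_flags[: spec.n_anuric] = True
        rng.shuffle(anuric_flags)
        alt_flags = np.zeros(spec.n_patients, dtype=bool)
        alt_flags[: spec.n_alt_regimen] = True
        rng.shuffle(alt_flags)
        for k in range(spec.n_patients):
            sid += 1
            anuric = bool(anuric_flags[k])
            c = _sample_covariates(spec, anuric, rng)
            dose_mg, interval_h = (
                (spec.alt_dose_mg, spec.alt_interval_h)
                if alt_flags[k]
                else (spec.dose_mg, spec.interval_h)
            )
            dur = float(rng.uniform(*spec.infusion_range_h))
            dose_starts = np.arange(0.0, _DOSING_END_H - 1e-9, interval_h)
            krt: list[KRTWindow] = []
            if spec.krt_mode != "none":
                w0, w1 = spec.krt_window
                w0 += spec.krt_anchor_offset_h
                w1 += spec.krt_anchor_offset_h
                krt = [KRTWindow(w0, w1, c.qd)]
            obs_t = _obs_times(spec, krt, interval_h, rng, jitter)

            # true individual parameters and noiseless concentrations
            eta = rng.standard_normal(3) * np.sqrt(re.omega2)
            egfr = c.egfr_mdrd if c.egfr_mdrd is not None else np.nan
            cl_body = (
                typical_cl_body(egfr, anuric, spec.study_b, fx) * math.exp(eta[0])
                if not (anuric or spec.study_b)
                else 0.0
            )
            subj = SubjectData(
                id=sid,
                obs_times=obs_t,
                dv=np.zeros_like(obs_t),
                doses=[DoseEvent(float(t), dose_mg, dur) for t in dose_starts],
                krt_windows=krt,
                egfr=egfr,
                anuric=anuric,
                study_b=spec.study_b,
            )
            ipred = predict_conc(
                subj,
                cl_body,
                fx.theta_vc * math.exp(eta[1]),
                fx.theta_vp * math.exp(eta[2]),
                fx.vp_slope_per_h if anuric else 0.0,
                fx.theta_q,
                fx.theta_dial,
                fx.theta_qd,
                fx.qd_ref,
                chunk=0.1,
            )
            if residual_error:
                sd = np.sqrt((re.sigma_prop * ipred) ** 2 + re.sigma_add**2)
                dv = ipred + sd * rng.standard_normal(ipred.size)
                for i in np.nonzero(dv < 0)[0]:  # redraw the rare negatives
                    for _ in range(100):
                        v = ipred[i] + sd[i] * rng.standard_normal()
                        if v >= 0:
                            dv[i] = v
                            break
                    else:
                        dv[i] = 0.0
            else:
                dv = ipred.copy()

            base = {
                "ID": sid, "CMT": 1,
                "EGFR": egfr, "ANUR": int(anuric),
                "QD": c.qd if c.qd is not None else np.nan,
                "KRTON": 0, "STUDYB": int(spec.study_b),
                "WT": c.body_weight,
                "HT": c.body_height if c.body_height is not None else np.nan,
                "AGE": c.age, "SEX": 0 if c.sex == "male" else 1,
                "UO24": c.urine_output_24h, "STUDY": spec.label,
            }
            events = []
            for t in dose_starts:
                events.append(
                    dict(base, TIME=float(t), AMT=dose_mg, RATE=dose_mg / dur,
                         EVID=1, MDV=1, DV=np.nan)
                )
            for w in krt:
                events.append(dict(base, TIME=w.start, AMT=0.0, RATE=0.0,
                                   EVID=2, MDV=1, DV=np.nan, KRTON=1))
                events.append(dict(base, TIME=w.end, AMT=0.0, RATE=0.0,
                                   EVID=2, MDV=1, DV=np.nan, KRTON=0))
            for t, v in zip(obs_t, dv):
                events.append(dict(base, TIME=float(t), AMT=0.0, RATE=0.0,
                                   EVID=0, MDV=0, DV=float(v)))
            # dialysis state carried onto every row for readability
            events.sort(key=lambda r: (r["TIME"], -r["EVID"]))
            state_on = 0
            for ev in events:
                if ev["EVID"] == 2:
                    state_on = ev["KRTON"]
                ev["KRTON"] = state_on
            if egfr_random_walk > 0 and np.isfinite(egfr):
                walk = np.cumsum(rng.normal(0.0, egfr_random_walk, len(events)))
                for ev, w in zip(events, walk):
                    ev["EGFR"] = egfr * math.exp(w)
            rows.extend(events)
    df = pd.DataFrame(rows)
    return df[COLUMNS]
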