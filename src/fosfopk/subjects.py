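"""Per-subject views of an event dataset and a fast per-subject predictor.

``SubjectData`` pre-compiles one subject's doses, dialysis windows and
observation times into a flat propagation plan (constant-coefficient
intervals with the observation indices attached), so that the likelihood
machinery can evaluate predicted concentrations in microseconds per subject.
For anuric subjects the growing peripheral volume is frozen within chunks of
at most ``chunk`` hours (midpoint value), which keeps the piecewise solution
closed-form; the chunk default of 0.5 h keeps the relative concentration
error well below the residual noise (cross-checked against the reference ODE
integrator in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._propagate import step_scalar
from .engine import DoseEvent, KRTWindow, build_segments

__all__ = ["SubjectData", "compile_subjects", "predict_conc"]


@dataclass
class SubjectData:
    id: int
    obs_times: np.ndarray
    dv: np.ndarray
    doses: list[DoseEvent]
    krt_windows: list[KRTWindow]
    egfr: float
    anuric: bool
    study_b: bool
    covariates: dict = field(default_factory=dict)
    _plans: dict = field(default_factory=dict, repr=False)

    @property
    def n_obs(self) -> int:
        return len(self.obs_times)

    def plan(self, chunk: float):
        """Propagation plan: list of (dt, rate, qd, obs_indices) intervals."""
        key = round(chunk, 6) if self.anuric else 0.0
        if key in self._plans:
            return self._plans[key]
        horizon = float(self.obs_times[-1]) if self.n_obs else 0.0
        if horizon <= 0:
            raise ValueError(f"subject {self.id} has no positive observation times")
        segments = build_segments(self.doses, self.krt_windows, horizon)
        nodes = {0.0, horizon}
        nodes.update(float(t) for t in self.obs_times)
        nodes.update(s.t0 for s in segments)
        if self.anuric and chunk > 0:
            nodes.update(np.arange(0.0, horizon, chunk))
        nodes = sorted(nodes)
        obs_at = {}
        for i, t in enumerate(self.obs_times):
            j = int(np.searchsorted(nodes, float(t)))
            obs_at.setdefault(j, []).append(i)
        plan = []
        seg_i = 0
        for j in range(1, len(nodes)):
            t0, t1 = nodes[j - 1], nodes[j]
            while t0 >= segments[seg_i].t1 - 1e-12:
                seg_i += 1
            s = segments[seg_i]
            plan.append(
                (
                    t1 - t0,
                    0.5 * (t0 + t1),
                    s.rate,
                    s.qd if s.krt_active else 0.0,
                    tuple(obs_at.get(j, ())),
                )
            )
        zero_obs = tuple(obs_at.get(0, ()))
        self._plans[key] = (zero_obs, plan)
        return self._plans[key]


def predict_conc(
    subj: SubjectData,
    cl_body: float,
    v_c: float,
    v_p0: float,
    vp_slope_per_h: float,
    q: float,
    theta_dial: float,
    theta_qd: float,
    qd_ref: float = 42.0,
    chunk: float = 0.5,
) -> np.ndarray:
    """Predicted central concentration (mg/L) at the subject's observation
    times for the given realized parameters.  Pure-Python inner loop."""
    zero_obs, plan = subj.plan(chunk)
    out = np.empty(subj.n_obs)
    for i in zero_obs:
        out[i] = 0.0
    ac = ap = 0.0
    clk_cache: dict[float, float] = {0.0: 0.0}
    for dt, tmid, rate, qd, obs in plan:
        clk = clk_cache.get(qd)
        if clk is None:
            clk = theta_dial * (qd / qd_ref) ** theta_qd
            clk_cache[qd] = clk
        vp = v_p0 * (1.0 + vp_slope_per_h * tmid) if vp_slope_per_h else v_p0
        ac, ap = step_scalar(ac, ap, dt, rate, cl_body + clk, q, v_c, vp)
        if obs:
            c = ac / v_c
            for i in obs:
                out[i] = c
    return out


def _krt_windows_from_rows(g: pd.DataFrame) -> list[KRTWindow]:
    """Reconstruct dialysis sessions from the KRTON/QD columns (carried
    forward between transition rows)."""
    windows = []
    state = 0
    start = qd = None
    for _, row in g.iterrows():
        on = int(row["KRTON"]) if pd.notna(row["KRTON"]) else 0
        if on and not state:
            start, qd = float(row["TIME"]), float(row["QD"])
        elif state and not on:
            windows.append(KRTWindow(start, float(row["TIME"]), qd))
        state = on
    if state:  # session still open at the last record: close it there
        end = float(g["TIME"].iloc[-1])
        if end > start:
            windows.append(KRTWindow(start, end, qd))
    return windows


def compile_subjects(df: pd.DataFrame) -> list[SubjectData]:
    """Split a validated event dataset into per-subject structures."""
    subjects = []
    for sid, g in df.groupby("ID", sort=True):
        g = g.sort_values("TIME", kind="stable")
        obs = g[(g["EVID"] == 0) & (g["MDV"] == 0)]
        dose_rows = g[g["EVID"] == 1]
        doses = [
            DoseEvent(float(r["TIME"]), float(r["AMT"]), float(r["AMT"]) / float(r["RATE"]))
            for _, r in dose_rows.iterrows()
        ]
        first = g.iloc[0]
        covs = {
            k: (float(first[k]) if pd.notna(first[k]) else np.nan)
            for k in ("WT", "HT", "AGE", "SEX", "UO24", "QD", "EGFR")
        }
        subjects.append(
            SubjectData(
                id=int(sid),
                obs_times=obs["TIME"].to_numpy(dtype=float),
                dv=obs["DV"].to_numpy(dtype=float),
                doses=doses,
                krt_windows=_krt_windows_from_rows(g),
                egfr=float(first["EGFR"]) if pd.notna(first["EGFR"]) else np.nan,
                anuric=bool(first["ANUR"]),
                study_b=bool(first["STUDYB"]),
                covariates=covs,
            )
        )
    return subjects
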