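"""Maximum marginal-likelihood estimation of the nonlinear mixed-effects
model via the Laplace approximation, with likelihood-ratio testing, stepwise
covariate search, empirical Bayes estimates and conditional weighted
residuals.

The marginal likelihood of each subject integrates the conditional data
likelihood over the subject's lognormal random effects.  The integral is
approximated by Laplace's method: the conditional -2 log-likelihood is
minimized over eta (the minimizer is the subject's empirical Bayes
estimate), and the curvature of the objective at the mode supplies the
Gaussian correction term,

    -2 log L_i  ~=  m2ll(eta_hat) - d log(2 pi) + log det( 0.5 * H ),

with H the Hessian of m2ll at the mode and d the number of active random
effects.  This stands in for NONMEM's FOCE-I; on the linear-Gaussian cases
where both are exact they coincide, and an adaptive Gauss-Hermite quadrature
oracle bounds the approximation error on small problems in the test suite.

Positive fixed effects and variance components are optimized on the log
scale; covariate-effect exponents and slopes are unbounded.  Finite
differences supply all gradients and Hessians (small dimensions; central
differences for curvature).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .model import FixedEffects, RandomEffects
from .subjects import SubjectData, compile_subjects, predict_conc

__all__ = [
    "CovariateCandidate",
    "ModelSpec",
    "FitResult",
    "conditional_minus2ll",
    "laplace_marginal",
    "fit",
    "lrt",
    "stepwise_covariate_search",
    "weighted_residuals",
]

_LOG2PI = math.log(2.0 * math.pi)
_OMEGA_FLOOR = 1e-10

#: structural parameters in estimation order
BASE_PARAMS = (
    "theta_cl", "theta_kf", "theta_vc", "theta_vp", "theta_t", "theta_q",
    "theta_dial", "theta_qd", "omega2_cl", "omega2_vc", "omega2_vp",
    "sigma_prop", "sigma_add",
)
#: parameters estimated on the log scale (all but the unbounded exponents)
_LOG_SCALE = set(BASE_PARAMS) - {"theta_kf", "theta_qd"}


@dataclass(frozen=True)
class CovariateCandidate:
    """One candidate covariate effect: a multiplicative term on a structural
    parameter, in linear, power or Emax form."""

    parameter: str  # "cl_body" | "v_c" | "v_p0" | "q"
    covariate: str  # dataset column name, e.g. "WT", "AGE", "EGFR"
    form: str  # "linear" | "power" | "emax"

    def __post_init__(self) -> None:
        if self.parameter not in ("cl_body", "v_c", "v_p0", "q"):
            raise ValueError(f"unknown target parameter {self.parameter!r}")
        if self.form not in ("linear", "power", "emax"):
            raise ValueError(f"unknown form {self.form!r}")

    @property
    def df(self) -> int:
        return 2 if self.form == "emax" else 1

    @property
    def param_names(self) -> tuple[str, ...]:
        stem = f"{self.form}_{self.parameter}_{self.covariate}"
        if self.form == "emax":
            return (f"{stem}_emax", f"{stem}_ec50")
        return (f"{stem}_beta",)


@dataclass(frozen=True)
class ModelSpec:
    """Structural switches of the model being estimated.

    The published final model has all three switches on and no extra
    candidates; the covariate search starts from a stripped base model and
    adds candidates.
    """

    egfr_on_cl: bool = True
    qd_on_clkrt: bool = True
    vp_time_slope: bool = True
    candidates: tuple[CovariateCandidate, ...] = ()

    def param_names(self) -> list[str]:
        names = [n for n in BASE_PARAMS]
        if not self.egfr_on_cl:
            names.remove("theta_kf")
        if not self.qd_on_clkrt:
            names.remove("theta_qd")
        if not self.vp_time_slope:
            names.remove("theta_t")
        for cand in self.candidates:
            names.extend(cand.param_names)
        return names


def _cov_effect(form: str, value: float, ref: float, pars: tuple) -> float:
    if not np.isfinite(value):
        return 1.0
    if form == "linear":
        return max(1.0 + pars[0] * (value - ref), 1e-3)
    if form == "power":
        if value <= 0 or ref <= 0:
            return 1.0
        return (value / ref) ** pars[0]
    emax, ec50 = pars
    return max(1.0 + emax * value / (ec50 + value), 1e-3)


def _fd_grad_hess(f, x, f0, h=1e-3):
    """Central-difference gradient and Hessian of ``f`` at ``x``."""
    d = x.size
    g = np.empty(d)
    H = np.empty((d, d))
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        e = np.zeros(d)
        e[i] = h
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        g[i] = (fp[i] - fm[i]) / (2.0 * h)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / (h * h)
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) + f(x - ei - ej)
                - fp[i] - fm[i] - fp[j] - fm[j] + 2.0 * f0
            ) / (2.0 * h * h)
    return g, H


def _newton_minimize(f, x0, gtol=1e-6, maxiter=30):
    """Damped Newton minimization with finite-difference derivatives.

    Built for the 1-3 dimensional inner (eta) problems, where a warm start
    converges in a couple of iterations; returns (x, f(x), Hessian at x).
    The Hessian is regularized toward positive-definiteness when needed.
    """
    x = np.asarray(x0, dtype=float).copy()
    f0 = f(x)
    g, H = _fd_grad_hess(f, x, f0)
    for _ in range(maxiter):
        if np.max(np.abs(g)) < gtol:
            break
        Hreg = H.copy()
        lam = 0.0
        for _try in range(8):
            try:
                L = np.linalg.cholesky(Hreg)
                step = -np.linalg.solve(Hreg, g)
                break
            except np.linalg.LinAlgError:
                lam = max(2.0 * lam, 1e-3 * np.max(np.abs(np.diag(H))), 1e-6)
                Hreg = H + lam * np.eye(x.size)
        else:  # pragma: no cover - pathological curvature
            step = -g
        norm = float(np.linalg.norm(step))
        if norm > 4.0:  # eta steps beyond ~4 SD are never useful
            step *= 4.0 / norm
        # backtracking line search
        t = 1.0
        improved = False
        for _bt in range(10):
            f1 = f(x + t * step)
            if f1 < f0:
                x = x + t * step
                f0 = f1
                improved = True
                break
            t *= 0.5
        if not improved:
            break
        g, H = _fd_grad_hess(f, x, f0)
    return x, f0, H


class _Objective:
    """Total OFV (-2 log marginal likelihood) over a set of subjects."""

    def __init__(self, subjects, spec: ModelSpec, fixed: dict, x0_full: dict,
                 chunk: float = 0.5, egfr_ref: float = 48.4, qd_ref: float = 42.0):
        self.subjects = subjects
        self.spec = spec
        self.fixed = dict(fixed)
        self.chunk = chunk
        self.egfr_ref = egfr_ref
        self.qd_ref = qd_ref
        all_names = spec.param_names()
        self.free_names = [n for n in all_names if n not in self.fixed]
        self.defaults = dict(x0_full)
        # cohort medians as covariate-effect reference values
        self.cov_refs = {}
        for cand in spec.candidates:
            vals = np.array([s.covariates.get(cand.covariate, np.nan) for s in subjects])
            self.cov_refs[cand.covariate] = float(np.nanmedian(vals))
        self.ebe_cache: dict[int, np.ndarray] = {}
        self.n_eval = 0

    # -- parameter vector <-> dict ------------------------------------
    def _is_log(self, name: str) -> bool:
        if name in _LOG_SCALE:
            return True
        return name.endswith("_ec50")  # Emax EC50 must stay positive

    def pack(self, p: dict) -> np.ndarray:
        out = []
        for n in self.free_names:
            v = p[n]
            out.append(math.log(v) if self._is_log(n) else v)
        return np.array(out)

    def unpack(self, x: np.ndarray) -> dict:
        p = dict(self.defaults)
        p.update(self.fixed)
        for n, v in zip(self.free_names, x):
            p[n] = math.exp(v) if self._is_log(n) else v
        if not self.spec.egfr_on_cl:
            p["theta_kf"] = 0.0
        if not self.spec.qd_on_clkrt:
            p["theta_qd"] = 0.0
        if not self.spec.vp_time_slope:
            p["theta_t"] = 0.0
        return p

    # -- model ---------------------------------------------------------
    def typicals(self, p: dict, subj: SubjectData):
        if subj.anuric or subj.study_b:
            tvcl = 0.0
        elif self.spec.egfr_on_cl:
            tvcl = p["theta_cl"] * (subj.egfr / self.egfr_ref) ** p["theta_kf"]
        else:
            tvcl = p["theta_cl"]
        tvvc = p["theta_vc"]
        tvvp = p["theta_vp"]
        tvq = p["theta_q"]
        for cand in self.spec.candidates:
            pars = tuple(p[n] for n in cand.param_names)
            f = _cov_effect(cand.form, subj.covariates.get(cand.covariate, np.nan),
                            self.cov_refs[cand.covariate], pars)
            if cand.parameter == "cl_body":
                tvcl *= f
            elif cand.parameter == "v_c":
                tvvc *= f
            elif cand.parameter == "v_p0":
                tvvp *= f
            else:
                tvq *= f
        slope = p["theta_t"] * 60.0 if (subj.anuric and self.spec.vp_time_slope) else 0.0
        return tvcl, tvvc, tvvp, tvq, slope

    def ipred(self, p: dict, subj: SubjectData, eta: np.ndarray) -> np.ndarray:
        tvcl, tvvc, tvvp, tvq, slope = self.typicals(p, subj)
        return predict_conc(
            subj,
            tvcl * math.exp(eta[0]),
            tvvc * math.exp(eta[1]),
            tvvp * math.exp(eta[2]),
            slope,
            tvq,
            p["theta_dial"],
            p["theta_qd"] if self.spec.qd_on_clkrt else 0.0,
            self.qd_ref,
            chunk=self.chunk,
        )

    def conditional_m2ll(self, p: dict, subj: SubjectData, eta: np.ndarray) -> float:
        pred = self.ipred(p, subj, eta)
        if not np.all(np.isfinite(pred)):
            raise FloatingPointError(f"non-finite prediction for subject {subj.id}")
        var = (p["sigma_prop"] * pred) ** 2 + p["sigma_add"] ** 2
        if np.any(var <= 0):
            raise ValueError(
                "degenerate residual model: zero variance at a prediction "
                f"(subject {subj.id}); set sigma_add > 0"
            )
        resid = subj.dv - pred
        out = float(np.sum(np.log(var) + resid * resid / var)) + subj.n_obs * _LOG2PI
        for k, w in enumerate(
            (p["omega2_cl"], p["omega2_vc"], p["omega2_vp"])
        ):
            if w > _OMEGA_FLOOR:
                out += _LOG2PI + math.log(w) + eta[k] * eta[k] / w
        return out

    def laplace_subject(self, p: dict, subj: SubjectData) -> float:
        omega2 = np.array([p["omega2_cl"], p["omega2_vc"], p["omega2_vp"]])
        active = np.nonzero(omega2 > _OMEGA_FLOOR)[0]
        eta0 = self.ebe_cache.get(subj.id, np.zeros(3))[active]

        def f(x):
            eta = np.zeros(3)
            eta[active] = x
            try:
                v = self.conditional_m2ll(p, subj, eta)
            except (FloatingPointError, OverflowError):
                return np.inf  # absurd trial etas; the line search backs off
            return v if np.isfinite(v) else np.inf

        if active.size == 0:
            return self.conditional_m2ll(p, subj, np.zeros(3))
        mode, f0, H = _newton_minimize(f, eta0)
        if not np.isfinite(f0):
            raise RuntimeError(f"inner optimization failed for subject {subj.id}")
        full = np.zeros(3)
        full[active] = mode
        self.ebe_cache[subj.id] = full
        ev = np.linalg.eigvalsh(0.5 * H)
        ev = np.maximum(ev, 1e-10)
        return f0 - active.size * _LOG2PI + float(np.sum(np.log(ev)))

    def __call__(self, x: np.ndarray) -> float:
        self.n_eval += 1
        p = self.unpack(x)
        try:
            return sum(self.laplace_subject(p, s) for s in self.subjects)
        except (FloatingPointError, OverflowError, np.linalg.LinAlgError):
            return 1e12


# ---------------------------------------------------------------------------
# public functional API


def _params_dict(fx: FixedEffects, re: RandomEffects) -> dict:
    return {
        "theta_cl": fx.theta_cl, "theta_kf": fx.theta_kf, "theta_vc": fx.theta_vc,
        "theta_vp": fx.theta_vp, "theta_t": fx.theta_t, "theta_q": fx.theta_q,
        "theta_dial": fx.theta_dial, "theta_qd": fx.theta_qd,
        "omega2_cl": re.omega2_cl, "omega2_vc": re.omega2_vc,
        "omega2_vp": re.omega2_vp, "sigma_prop": re.sigma_prop,
        "sigma_add": re.sigma_add,
    }


def conditional_minus2ll(
    subj: SubjectData, fx: FixedEffects, re: RandomEffects, eta, chunk: float = 0.5
) -> float:
    """-2 log of the joint density of one subject's data and etas (the inner
    Laplace objective) under the final model structure."""
    obj = _Objective([subj], ModelSpec(), {}, _params_dict(fx, re), chunk,
                     fx.egfr_ref, fx.qd_ref)
    return obj.conditional_m2ll(_params_dict(fx, re), subj, np.asarray(eta, dtype=float))


def laplace_marginal(
    subj: SubjectData, fx: FixedEffects, re: RandomEffects, chunk: float = 0.5
) -> float:
    """One subject's contribution to the OFV (-2 log marginal likelihood)."""
    obj = _Objective([subj], ModelSpec(), {}, _params_dict(fx, re), chunk,
                     fx.egfr_ref, fx.qd_ref)
    return obj.laplace_subject(_params_dict(fx, re), subj)


@dataclass
class FitResult:
    fx: FixedEffects
    re: RandomEffects
    extra: dict
    ofv: float
    rse: dict | None
    ebe: pd.DataFrame
    convergence: dict
    spec: ModelSpec = field(default_factory=ModelSpec)

    def params(self) -> dict:
        out = _params_dict(self.fx, self.re)
        out.update(self.extra)
        return out

    def report(self) -> str:
        lines = [f"OFV: {self.ofv:.3f}", f"converged: {self.convergence}"]
        for k, v in self.params().items():
            r = f"  (RSE {self.rse[k]:.1f}%)" if self.rse and k in self.rse else ""
            lines.append(f"{k} = {v:.6g}{r}")
        return "\n".join(lines)


def fit(
    data,
    fx0: FixedEffects | None = None,
    re0: RandomEffects | None = None,
    spec: ModelSpec | None = None,
    fixed: dict | None = None,
    maxiter: int = 150,
    chunk: float = 0.5,
    compute_rse: bool = False,
    verbose: bool = False,
) -> FitResult:
    """Fit the population model to an event dataset (dataframe) or a list of
    compiled subjects.

    ``fx0``/``re0`` provide initial estimates; ``fixed`` maps parameter
    names to frozen values.  RSEs come from the inverse finite-difference
    Hessian of the OFV at the optimum and are skipped by default (they cost
    ~2 p^2 objective evaluations).
    """
    subjects = data if isinstance(data, list) else compile_subjects(data)
    fx0 = fx0 or FixedEffects(theta_cl=1.0, theta_kf=1.0, theta_vc=30.0,
                              theta_vp=10.0, theta_t=0.0005, theta_q=5.0,
                              theta_dial=1.0, theta_qd=0.5)
    re0 = re0 or RandomEffects(omega2_cl=0.1, omega2_vc=0.1, omega2_vp=0.1,
                               sigma_prop=0.2, sigma_add=10.0)
    spec = spec or ModelSpec()
    x0_full = _params_dict(fx0, re0)
    for cand in spec.candidates:
        for n in cand.param_names:
            x0_full.setdefault(n, 100.0 if n.endswith("_ec50") else 0.0)
    obj = _Objective(subjects, spec, fixed or {}, x0_full, chunk,
                     fx0.egfr_ref, fx0.qd_ref)
    x0 = obj.pack(x0_full)

    trace: list[float] = []

    def cb(xk):
        trace.append(obj(xk))
        if verbose:
            print(f"iter {len(trace)}: OFV {trace[-1]:.3f}")

    res = optimize.minimize(
        obj, x0, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-4, "eps": 1e-4},
        callback=cb if verbose else None,
    )
    p = obj.unpack(res.x)
    ofv = obj(res.x)

    rse = None
    if compute_rse:
        rse = _rse_from_hessian(obj, res.x, p)

    ebe = pd.DataFrame(
        [
            {"ID": s.id, "eta_cl": e[0], "eta_vc": e[1], "eta_vp": e[2]}
            for s in subjects
            for e in [obj.ebe_cache.get(s.id, np.zeros(3))]
        ]
    )
    fx = FixedEffects(
        theta_cl=p["theta_cl"],
        theta_kf=p["theta_kf"] if spec.egfr_on_cl else fx0.theta_kf,
        theta_vc=p["theta_vc"], theta_vp=p["theta_vp"],
        theta_t=p["theta_t"] if spec.vp_time_slope else fx0.theta_t,
        theta_q=p["theta_q"], theta_dial=p["theta_dial"],
        theta_qd=p["theta_qd"] if spec.qd_on_clkrt else fx0.theta_qd,
        egfr_ref=fx0.egfr_ref, qd_ref=fx0.qd_ref,
    )
    re_ = RandomEffects(
        omega2_cl=p["omega2_cl"], omega2_vc=p["omega2_vc"],
        omega2_vp=p["omega2_vp"], sigma_prop=p["sigma_prop"],
        sigma_add=p["sigma_add"],
    )
    extra = {n: p[n] for c in spec.candidates for n in c.param_names}
    conv = {
        "success": bool(res.success),
        "message": str(res.message),
        "nit": int(res.nit),
        "n_eval": obj.n_eval,
        "grad_norm": float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan,
    }
    if not res.success:
        warnings.warn(f"fit did not fully converge: {res.message}")
    return FitResult(fx, re_, extra, float(ofv), rse, ebe, conv, spec)


def _rse_from_hessian(obj: _Objective, x: np.ndarray, p: dict) -> dict:
    """RSE%, from the inverse central-difference Hessian of the OFV on the
    natural scale (cov = 2 * H^-1 for a -2 log-likelihood objective)."""
    names = obj.free_names
    est = np.array([p[n] for n in names])
    h = np.maximum(np.abs(est) * 1e-3, 1e-7)

    def f_nat(v):
        q = dict(p)
        q.update(dict(zip(names, v)))
        return obj(obj.pack(q))

    n = len(names)
    H = np.empty((n, n))
    f0 = f_nat(est)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h[i]
        fp[i] = f_nat(est + e)
        fm[i] = f_nat(est - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f_nat(est + ei + ej) + f_nat(est - ei - ej)
                - fp[i] - fm[i] - fp[j] - fm[j] + 2 * f0
            ) / (2 * h[i] * h[j])
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return {n_: np.nan for n_ in names}
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return {n_: 100.0 * s / abs(e) if e != 0 else np.nan
            for n_, s, e in zip(names, se, est)}


def lrt(ofv_reduced: float, ofv_full: float, df: int = 1, alpha: float = 0.05) -> bool:
    """Likelihood-ratio test between nested models: significant iff the OFV
    drop exceeds the chi-square critical value (3.84 at df=1, alpha=0.05;
    6.63 at alpha=0.01)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    dofv = ofv_reduced - ofv_full
    if dofv < 0:
        warnings.warn("full model has higher OFV than reduced; not significant")
        return False
    return dofv > stats.chi2.ppf(1.0 - alpha, df)


def stepwise_covariate_search(
    data,
    candidates: list[CovariateCandidate],
    base_spec: ModelSpec | None = None,
    fx0: FixedEffects | None = None,
    re0: RandomEffects | None = None,
    alpha_forward: float = 0.05,
    alpha_backward: float = 0.01,
    **fit_kwargs,
):
    """Forward-inclusion / backward-elimination covariate search.

    Forward: repeatedly add the candidate with the largest significant OFV
    drop (chi-square at ``alpha_forward``); backward: drop any retained
    candidate whose removal worsens the OFV by less than the
    ``alpha_backward`` critical value.  Returns (final_spec, final_fit,
    trace); candidates whose fit fails are skipped and logged in the trace.
    """
    subjects = data if isinstance(data, list) else compile_subjects(data)
    spec = base_spec or ModelSpec()
    trace: list[dict] = []
    current = fit(subjects, fx0, re0, spec=spec, **fit_kwargs)
    remaining = list(candidates)
    while remaining:
        best = None
        for cand in remaining:
            cand_spec = replace(spec, candidates=spec.candidates + (cand,))
            try:
                f = fit(subjects, current.fx, current.re, spec=cand_spec, **fit_kwargs)
            except Exception as exc:  # noqa: BLE001 - candidate skipped, logged
                trace.append({"step": "forward", "candidate": cand, "error": str(exc)})
                continue
            dofv = current.ofv - f.ofv
            trace.append({"step": "forward", "candidate": cand, "dofv": dofv})
            crit = stats.chi2.ppf(1.0 - alpha_forward, cand.df)
            if dofv > crit and (best is None or dofv > best[0]):
                best = (dofv, cand, cand_spec, f)
        if best is None:
            break
        _, cand, spec, current = best
        trace.append({"step": "include", "candidate": cand, "dofv": best[0]})
        remaining.remove(cand)
    # backward elimination
    changed = True
    while changed:
        changed = False
        for cand in spec.candidates:
            red_spec = replace(
                spec, candidates=tuple(c for c in spec.candidates if c is not cand)
            )
            f = fit(subjects, current.fx, current.re, spec=red_spec, **fit_kwargs)
            dofv = f.ofv - current.ofv
            trace.append({"step": "backward", "candidate": cand, "dofv": dofv})
            if dofv < stats.chi2.ppf(1.0 - alpha_backward, cand.df):
                spec, current = red_spec, f
                trace.append({"step": "remove", "candidate": cand, "dofv": dofv})
                changed = True
                break
    return spec, current, trace


def weighted_residuals(result: FitResult, data, chunk: float = 0.5) -> pd.DataFrame:
    """Conditional weighted residuals: the observation vector decorrelated by
    the first-order covariance at the empirical Bayes estimates.  Under the
    true model they have approximately zero mean and unit variance."""
    subjects = data if isinstance(data, list) else compile_subjects(data)
    re_ = result.re
    if re_.sigma_prop == 0 and re_.sigma_add == 0:
        raise ValueError("degenerate residual model: cannot weight residuals")
    p = result.params()
    obj = _Objective(subjects, result.spec, {}, p, chunk,
                     result.fx.egfr_ref, result.fx.qd_ref)
    ebe = result.ebe.set_index("ID")
    frames = []
    for s in subjects:
        eta = ebe.loc[s.id].to_numpy(dtype=float) if s.id in ebe.index else np.zeros(3)
        F = obj.ipred(p, s, eta)
        h = 1e-4
        G = np.empty((s.n_obs, 3))
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            G[:, k] = (obj.ipred(p, s, eta + e) - obj.ipred(p, s, eta - e)) / (2 * h)
        omega = np.diag([re_.omega2_cl, re_.omega2_vc, re_.omega2_vp])
        cov = G @ omega @ G.T + np.diag((re_.sigma_prop * F) ** 2 + re_.sigma_add**2)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular observation covariance for subject {s.id}"
            ) from exc
        resid = s.dv - (F - G @ eta)
        cw = solve_triangular(L, resid, lower=True)
        frames.append(pd.DataFrame({"ID": s.id, "TIME": s.obs_times,
                                    "DV": s.dv, "IPRED": F, "CWRES": cw}))
    return pd.concat(frames, ignore_index=True)
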