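"""Diversity-outcome associations.

Cox proportional hazards (Newton-Raphson on the partial likelihood, Breslow
tie handling by default, Efron optional), Kaplan-Meier product-limit curves
with the two-group log-rank test, and logistic regression of binary
treatment response on a (z-normalized) predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import StratifiedCohort
from .io_formats import ClinicalTable

__all__ = ["CoxResult", "LogisticResult", "KMCurve", "fit_cox", "km_logrank",
           "fit_logistic_response", "cox_loglik"]

_Z975 = stats.norm.ppf(0.975)


@dataclass
class CoxResult:
    term: str
    coef: float
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n: int
    n_events: int
    model: str = "univariate"
    converged: bool = True
    flagged: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.hazard_ratio) and self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")


@dataclass
class LogisticResult:
    term: str
    coef: float
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n: int
    normalization: dict = field(default_factory=dict)
    flagged: str = ""


@dataclass
class KMCurve:
    """Product-limit estimates per stratum plus the log-rank comparison."""

    curves: dict  # stratum -> DataFrame(time, survival, at_risk, events)
    logrank_statistic: float
    logrank_p: float


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------


def cox_loglik(beta, times, events, X, ties: str = "breslow") -> float:
    """Breslow/Efron partial log-likelihood (used by the grid-search oracle
    in tests as well as by the fitter's convergence checks)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = X @ beta
    ll = 0.0
    for t in np.unique(times[events == 1]):
        tied = (times == t) & (events == 1)
        risk = times >= t
        d = int(tied.sum())
        theta_risk = np.exp(eta[risk])
        ll += eta[tied].sum()
        if ties == "breslow":
            ll -= d * np.log(theta_risk.sum())
        elif ties == "efron":
            theta_tied = np.exp(eta[tied])
            s_risk = theta_risk.sum()
            s_tied = theta_tied.sum()
            for m in range(d):
                ll -= np.log(s_risk - m / d * s_tied)
        else:
            raise ValueError(f"unknown tie method {ties!r}")
    return float(ll)


def _cox_derivatives(beta, times, events, X, ties):
    n, p = X.shape
    eta = X @ beta
    theta = np.exp(eta)
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for t in np.unique(times[events == 1]):
        tied = (times == t) & (events == 1)
        risk = times >= t
        d = int(tied.sum())
        Xr = X[risk]
        tr = theta[risk]
        grad += X[tied].sum(axis=0)
        if ties == "breslow":
            s0 = tr.sum()
            s1 = Xr.T @ tr
            s2 = (Xr * tr[:, None]).T @ Xr
            mu = s1 / s0
            grad -= d * mu
            hess -= d * (s2 / s0 - np.outer(mu, mu))
        else:  # efron
            Xt = X[tied]
            tt = theta[tied]
            s0r, s1r = tr.sum(), Xr.T @ tr
            s2r = (Xr * tr[:, None]).T @ Xr
            s0t, s1t = tt.sum(), Xt.T @ tt
            s2t = (Xt * tt[:, None]).T @ Xt
            for m in range(d):
                f = m / d
                s0 = s0r - f * s0t
                s1 = s1r - f * s1t
                s2 = s2r - f * s2t
                mu = s1 / s0
                grad -= mu
                hess -= s2 / s0 - np.outer(mu, mu)
    return grad, hess


def _newton_cox(times, events, X, ties, max_iter=50, tol=1e-9):
    p = X.shape[1]
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        grad, hess = _cox_derivatives(beta, times, events, X, ties)
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        # dampen huge steps (monotone-likelihood protection)
        norm = np.linalg.norm(step)
        if norm > 5.0:
            step = step * 5.0 / norm
        beta = beta + step
        if np.abs(grad).max() < tol or np.linalg.norm(step) < tol:
            converged = True
            break
    _, hess = _cox_derivatives(beta, times, events, X, ties)
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
    return beta, se, converged


def _endpoint_columns(clin: ClinicalTable, endpoint: str) -> tuple[str, str]:
    lower = endpoint.lower()
    if f"{lower}_time" in clin.df.columns:
        return f"{lower}_time", f"{lower}_event"
    return "time", "event"


def _design(clin: ClinicalTable, covariates) -> tuple[pd.DataFrame, list[str]]:
    cols = []
    frames = []
    for cov in covariates:
        if isinstance(cov, pd.Series):
            frames.append(cov.reset_index(drop=True).astype(float).rename(cov.name or "x"))
            cols.append(cov.name or "x")
            continue
        series = clin.df[cov]
        if pd.api.types.is_numeric_dtype(series):
            frames.append(series.astype(float))
            cols.append(cov)
        else:
            dummies = pd.get_dummies(series, prefix=cov, drop_first=True, dtype=float)
            frames.append(dummies)
            cols.extend(dummies.columns)
    X = pd.concat(frames, axis=1)
    X.columns = cols
    return X, cols


def fit_cox(
    clin: ClinicalTable,
    covariates,
    endpoint: str = "OS",
    ties: str = "breslow",
) -> list[CoxResult]:
    """Fit a Cox PH model of the endpoint on the given covariates.

    ``covariates`` may name clinical columns (categoricals are one-hot
    encoded, first level dropped) or be pandas Series aligned with the
    table. Returns one :class:`CoxResult` per design term.
    """
    tcol, ecol = _endpoint_columns(clin, endpoint)
    times = clin.df[tcol].to_numpy(dtype=float)
    events = clin.df[ecol].to_numpy(dtype=int)
    n_events = int(events.sum())
    if n_events == 0:
        raise ValueError("no events observed; Cox model undefined")
    if n_events < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    Xdf, names = _design(clin, covariates)
    X = Xdf.to_numpy(dtype=float)
    model_tag = "univariate" if X.shape[1] == 1 else "multivariate"

    keep = X.std(axis=0) > 0
    results: list[CoxResult] = []
    if keep.any():
        Xf = X[:, keep]
        beta, se, converged = _newton_cox(times, events, Xf, ties)
        flagged = "" if converged else "non-convergence (possible monotone likelihood)"
        if np.abs(beta).max() > 15:
            flagged = "extreme coefficient (possible perfect separation)"
            converged = False
    it = iter(range(int(keep.sum())))
    for j, name in enumerate(names):
        if not keep[j]:
            results.append(CoxResult(name, 0.0, 1.0, 0.0, np.inf, 1.0, len(times),
                                     n_events, model_tag, True,
                                     "constant covariate"))
            continue
        i = next(it)
        b, s = float(beta[i]), float(se[i])
        if not np.isfinite(s):
            s = np.inf
        z = b / s if s > 0 and np.isfinite(s) else 0.0
        with np.errstate(over="ignore"):
            lo = float(np.exp(b - _Z975 * s)) if np.isfinite(s) else 0.0
            hi = float(np.exp(b + _Z975 * s)) if np.isfinite(s) else np.inf
        results.append(
            CoxResult(
                term=name,
                coef=b,
                hazard_ratio=float(np.exp(b)),
                ci_lower=lo,
                ci_upper=hi,
                p_value=float(2 * stats.norm.sf(abs(z))),
                n=len(times),
                n_events=n_events,
                model=model_tag,
                converged=converged,
                flagged=flagged,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Kaplan-Meier + log-rank
# ---------------------------------------------------------------------------


def _km_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    order = np.argsort(times, kind="mergesort")
    t, e = times[order], events[order]
    uniq = np.unique(t[e == 1])
    surv = 1.0
    rows = [(0.0, 1.0, len(t), 0)]
    for u in uniq:
        at_risk = int((t >= u).sum())
        d = int(((t == u) & (e == 1)).sum())
        surv *= 1.0 - d / at_risk
        rows.append((float(u), float(surv), at_risk, d))
    return pd.DataFrame(rows, columns=["time", "survival", "at_risk", "events"])


def km_logrank(
    clin: ClinicalTable, strata: StratifiedCohort, endpoint: str = "OS"
) -> KMCurve:
    """Product-limit curves for the high/low strata plus the 1-df log-rank test."""
    tcol, ecol = _endpoint_columns(clin, endpoint)
    df = clin.df.set_index(clin.df["sample_id"].astype(str))
    groups = {}
    for name in ("low", "high"):
        ids = [s for s in getattr(strata, name) if s in df.index]
        if not ids:
            raise ValueError(f"stratum {name!r} is empty after clinical overlap")
        sub = df.loc[ids]
        groups[name] = (sub[tcol].to_numpy(float), sub[ecol].to_numpy(int))
    for name, (t, e) in groups.items():
        if e.sum() < 1:
            raise ValueError(f"stratum {name!r} has no events")
    curves = {name: _km_curve(t, e) for name, (t, e) in groups.items()}

    t1, e1 = groups["high"]
    t2, e2 = groups["low"]
    all_t = np.concatenate([t1, t2])
    all_e = np.concatenate([e1, e2])
    grp = np.concatenate([np.ones(len(t1)), np.zeros(len(t2))])
    o_minus_e = 0.0
    var = 0.0
    for u in np.unique(all_t[all_e == 1]):
        at = all_t >= u
        n = int(at.sum())
        n1 = int((at & (grp == 1)).sum())
        d = int(((all_t == u) & (all_e == 1)).sum())
        d1 = int(((all_t == u) & (all_e == 1) & (grp == 1)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        statistic, p = 0.0, 1.0
    else:
        statistic = o_minus_e**2 / var
        p = float(stats.chi2.sf(statistic, df=1))
    return KMCurve(curves, float(statistic), p)


# ---------------------------------------------------------------------------
# logistic response
# ---------------------------------------------------------------------------


def fit_logistic_response(
    clin: ClinicalTable,
    predictor,
    arm: str | None = None,
    normalize: bool = True,
) -> LogisticResult:
    """Logistic regression of binary response on a single predictor.

    ``predictor`` is a pandas Series indexed by sample ID (e.g. the Shannon
    diversity). When ``normalize`` is true the predictor is z-scored first
    and the odds ratio is per 1-SD unit; normalization constants are stored
    on the result.
    """
    import statsmodels.api as sm

    df = clin.df
    if arm is not None and "arm" in df.columns:
        df = df[df["arm"] == arm]
    if "response" not in df.columns:
        raise ValueError("clinical table has no response column")
    df = df[df["response"].notna()]
    pred = pd.Series(predictor)
    ids = df["sample_id"].astype(str)
    mask = ids.isin(pred.index).to_numpy()
    df = df[mask]
    y = df["response"].astype(int).to_numpy()
    x = pred.loc[df["sample_id"].astype(str)].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("response has a single class; logistic model undefined")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 5:
        warnings.warn(f"fewer than 5 samples in a response class ({counts.tolist()})",
                      stacklevel=2)
    norm: dict = {}
    if normalize:
        mu, sd = float(x.mean()), float(x.std(ddof=0))
        if sd == 0:
            raise ValueError("predictor is constant; cannot normalize")
        x = (x - mu) / sd
        norm = {"mean": mu, "sd": sd}
    X = sm.add_constant(x)
    flagged = ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # perfect separation raises in statsmodels
            raise ValueError(f"logistic fit failed: {exc}") from exc
    b = float(fit.params[1])
    se = float(fit.bse[1])
    if abs(b) > 15 or not np.isfinite(se):
        flagged = "possible complete separation"
    return LogisticResult(
        term="predictor",
        coef=b,
        odds_ratio=float(np.exp(b)),
        ci_lower=float(np.exp(b - _Z975 * se)),
        ci_upper=float(np.exp(b + _Z975 * se)),
        p_value=float(fit.pvalues[1]),
        n=len(y),
        normalization=norm,
        flagged=flagged,
    )
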