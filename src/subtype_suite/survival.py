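"""Kaplan–Meier estimation, log-rank tests and Cox proportional hazards.

Conventions: censoring at an event time is ordered after the event (the
censored subject counts as at risk at that time); the median is the first
time the survival curve reaches 0.5 or below, with infinity as the
not-reached sentinel; log-rank is the standard two-sided non-stratified
O-E chi-square; Cox fitting maximizes the partial likelihood by Newton's
method with step halving, Efron tie handling by default and Breslow as an
option, Wald 95% confidence intervals, and an explicit non-convergence
flag when the likelihood is monotone (complete separation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats_core import TestResult

NOT_REACHED = math.inf


def _validate(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("event indicators must be 0/1")
    return times, events.astype(int)


@dataclass
class SurvivalCurve:
    table: pd.DataFrame  # per distinct time: at_risk, events, censored, survival
    median: float        # NOT_REACHED when the curve never crosses 0.5

    def survival_at(self, t: float) -> float:
        prior = self.table[self.table["time"] <= t]
        return float(prior["survival"].iloc[-1]) if len(prior) else 1.0

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median)


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit survival estimate over the distinct observed times."""
    times, events = _validate(times, events)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times)
    n = times.size
    rows = []
    s = 1.0
    at_risk = n
    for t in uniq:
        here = times == t
        d = int(events[here].sum())
        c = int(here.sum() - d)
        if d > 0:
            s *= 1.0 - d / at_risk
        rows.append({"time": float(t), "at_risk": at_risk, "events": d,
                     "censored": c, "survival": s})
        at_risk -= d + c
    table = pd.DataFrame(rows)
    crossing = table[table["survival"] <= 0.5 + 1e-12]
    crossing = crossing[crossing["events"] > 0]
    median = float(crossing["time"].iloc[0]) if len(crossing) else NOT_REACHED
    return SurvivalCurve(table, median)


def logrank(groups) -> TestResult:
    """Two-sided non-stratified log-rank test across >= 2 groups.

    ``groups`` is a list of ``(times, events)`` pairs. Chi-square has
    (number of groups - 1) degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("log-rank needs at least 2 groups")
    parsed = [_validate(t, e) for t, e in groups]
    k = len(parsed)
    all_times = np.concatenate([t for t, _ in parsed])
    all_events = np.concatenate([e for _, e in parsed])
    group_of = np.concatenate([np.full(t.size, g) for g, (t, _) in enumerate(parsed)])
    if all_events.sum() == 0:
        raise ValueError("no events in any group")
    event_times = np.unique(all_times[all_events == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in event_times:
        at_risk = all_times >= t
        n_t = at_risk.sum()
        d_t = int(((all_times == t) & (all_events == 1)).sum())
        n_g = np.array([(at_risk & (group_of == g)).sum() for g in range(k)], dtype=float)
        d_g = np.array([(((all_times == t) & (all_events == 1)
                          & (group_of == g))).sum() for g in range(k)], dtype=float)
        observed += d_g
        expected += d_t * n_g / n_t
        if n_t > 1:
            frac = n_g / n_t
            scale = d_t * (n_t - d_t) / (n_t - 1)
            cov += scale * (np.diag(frac) - np.outer(frac, frac))
    diff = (observed - expected)[: k - 1]
    v = cov[: k - 1, : k - 1]
    try:
        chi2 = float(diff @ np.linalg.solve(v, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(v) @ diff)
    p = float(sps.chi2.sf(chi2, df=k - 1))
    return TestResult(chi2, min(p, 1.0), "log-rank (non-stratified)",
                      extras={"df": k - 1, "observed": observed.tolist(),
                              "expected": expected.tolist()})


@dataclass
class CoxFit:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool
    ties: str
    n: int
    n_events: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.beta, "se": self.se, "hr": self.hr,
            "hr_ci_lower": self.ci_lower, "hr_ci_upper": self.ci_upper,
        }, index=self.names)


def _cox_loglik_grad_hess(beta, times, events, x, ties):
    """Partial log-likelihood with gradient and Hessian (Efron or Breslow)."""
    n, p = x.shape
    eta = x @ beta
    eta -= eta.max()  # numerical guard; partial likelihood is shift-invariant
    r = np.exp(eta)
    order = np.argsort(-times, kind="stable")  # decreasing time
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        t = times[order[i]]
        j = i
        while j < n and times[order[j]] == t:
            s0 += r[order[j]]
            xi = x[order[j]]
            s1 += r[order[j]] * xi
            s2 += r[order[j]] * np.outer(xi, xi)
            j += 1
        dead = [order[m] for m in range(i, j) if events[order[m]] == 1]
        d = len(dead)
        if d > 0:
            xd = x[dead]
            ll += eta[dead].sum()
            if ties == "breslow" or d == 1:
                for _ in range(d):
                    ll -= math.log(s0)
                    mean = s1 / s0
                    grad -= mean
                    hess -= s2 / s0 - np.outer(mean, mean)
            else:  # Efron
                rd = r[dead].sum()
                s1d = (r[dead, None] * xd).sum(axis=0)
                s2d = np.einsum("i,ij,ik->jk", r[dead], xd, xd)
                for m in range(d):
                    f = m / d
                    denom = s0 - f * rd
                    num1 = s1 - f * s1d
                    num2 = s2 - f * s2d
                    ll -= math.log(denom)
                    mean = num1 / denom
                    grad -= mean
                    hess -= num2 / denom - np.outer(mean, mean)
            grad += xd.sum(axis=0)
        i = j
    return ll, grad, hess


def cox_fit(times, events, covariates, ties: str = "efron",
            max_iter: int = 100, tol: float = 1e-9) -> CoxFit:
    """Cox proportional-hazards regression by Newton's method.

    Monotone likelihood (complete separation) is surfaced as a
    non-convergence flag rather than a silent estimate; constant
    covariates are rejected.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    times, events = _validate(times, events)
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"x{i}" for i in range(x.shape[1])]
    if x.shape[0] != times.size:
        raise ValueError("covariates must align with times")
    if not np.isfinite(x).all():
        raise ValueError("non-finite covariate values")
    const = x.std(axis=0) == 0
    if const.any():
        raise ValueError(f"constant covariate(s): {[names[i] for i in np.flatnonzero(const)]}")
    if events.sum() == 0:
        raise ValueError("no events")

    # center covariates for conditioning; beta is unaffected
    center = x.mean(axis=0)
    xc = x - center
    p = xc.shape[1]
    beta = np.zeros(p)
    ll_null, _, _ = _cox_loglik_grad_hess(beta, times, events, xc, ties)
    ll = ll_null
    converged = False
    for _ in range(max_iter):
        ll_cur, grad, hess = _cox_loglik_grad_hess(beta, times, events, xc, ties)
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        new_beta = beta + step
        ll_new, _, _ = _cox_loglik_grad_hess(new_beta, times, events, xc, ties)
        halvings = 0
        while ll_new < ll_cur and halvings < 30:
            step /= 2
            new_beta = beta + step
            ll_new, _, _ = _cox_loglik_grad_hess(new_beta, times, events, xc, ties)
            halvings += 1
        beta = new_beta
        if abs(ll_new - ll_cur) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if np.abs(beta).max() > 10:
        converged = False  # monotone likelihood: coefficients diverging
    _, _, hess = _cox_loglik_grad_hess(beta, times, events, xc, ties)
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    z = sps.norm.ppf(0.975)
    with np.errstate(over="ignore"):  # CI bounds can overflow under separation
        return CoxFit(names, beta, se, np.exp(beta),
                      np.exp(beta - z * se), np.exp(beta + z * se),
                      float(ll), float(ll_null), converged, ties,
                      int(times.size), int(events.sum()))
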