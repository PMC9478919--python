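"""Survival-analysis statistical core.

Implements the estimators and tests the score pipeline relies on:

* Cox proportional-hazards regression by Newton--Raphson on the partial
  likelihood, with Efron (default) or Breslow handling of tied event times,
  Wald inference throughout.
* Kaplan--Meier product-limit curves with Greenwood variance.
* The (optionally stratified) log-rank test.
* Cumulative-cases / dynamic-controls time-dependent ROC AUC with inverse
  probability of censoring weights (IPCW) from the Kaplan--Meier estimate of
  the censoring distribution.
* Relative risk from 2x2 tables (Katz log-RR interval; Pearson chi-square or
  Fisher's exact p-value).
* Wilcoxon signed-rank (paired) and rank-sum / Mann--Whitney (unpaired) tests.

Everything here is computed directly from the defining formulas; scipy is used
only for reference distributions (normal, chi-square, hypergeometric pmf).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

__all__ = [
    "CoxFit",
    "KMCurve",
    "TestResult",
    "ContingencyResult",
    "TimeDependentROC",
    "fit_cox",
    "cox_derivatives",
    "km_estimate",
    "km_survival_at",
    "logrank_test",
    "td_roc_auc",
    "roc_auc",
    "rr_from_table",
    "rank_test",
]

ALPHA = 0.05  # two-sided significance level used throughout the pipeline


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """Fitted Cox proportional-hazards model (per-covariate arrays)."""

    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    wald_p: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool
    ties_method: str
    names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        names = self.names or [f"x{i}" for i in range(len(self.coef))]
        return {
            "covariates": {
                nm: {
                    "coef": float(c),
                    "se": float(s),
                    "hr": float(h),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "p": float(p),
                }
                for nm, c, s, h, lo, hi, p in zip(
                    names, self.coef, self.se, self.hr,
                    self.ci_low, self.ci_high, self.wald_p,
                )
            },
            "loglik": float(self.loglik),
            "n": self.n,
            "n_events": self.n_events,
            "converged": self.converged,
            "ties_method": self.ties_method,
        }


@dataclass
class KMCurve:
    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # product-limit estimate at each event time
    greenwood_var: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    median: float              # nan when the curve never reaches 0.5


@dataclass
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    method: str


@dataclass
class ContingencyResult:
    rr: float
    ci_low: float
    ci_high: float
    p_value: float
    table: np.ndarray
    method: str
    defined: bool = True


@dataclass
class TimeDependentROC:
    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_cases: int
    n_controls: int
    horizon: float


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------


def _as_2d(x) -> np.ndarray:
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def cox_derivatives(beta, times, events, X, ties_method: str = "efron"):
    """Partial log-likelihood, score vector and Hessian at ``beta``.

    The Hessian returned is the actual (negative-definite) second-derivative
    matrix; the observed information is its negation.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    X = _as_2d(X)
    n, p = X.shape

    order = np.argsort(times, kind="stable")
    t = times[order]
    d = events[order].astype(bool)
    Xs = X[order]

    eta = Xs @ beta
    shift = eta.max() if n else 0.0  # overflow guard; cancels exactly in ll
    w = np.exp(eta - shift)

    # reverse cumulative sums over the risk sets
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    xx = Xs[:, :, None] * Xs[:, None, :]
    S2 = np.cumsum((w[:, None, None] * xx)[::-1], axis=0)[::-1]

    # tie groups of the *time* axis (censored ties stay at risk for the event)
    first = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    dcount = np.add.reduceat(d.astype(int), first)
    wd = w * d
    D0 = np.add.reduceat(wd, first)
    D1 = np.add.reduceat(wd[:, None] * Xs, first, axis=0)
    D2 = np.add.reduceat(wd[:, None, None] * xx, first, axis=0)

    has_event = dcount > 0
    R0, R1, R2 = S0[first][has_event], S1[first][has_event], S2[first][has_event]
    D0, D1, D2 = D0[has_event], D1[has_event], D2[has_event]
    dk = dcount[has_event]

    # expand (group, within-group tie index l) pairs
    gidx = np.repeat(np.arange(dk.size), dk)
    offs = np.repeat(np.concatenate(([0], np.cumsum(dk)[:-1])), dk)
    l = np.arange(dk.sum()) - offs
    if ties_method == "efron":
        frac = l / dk[gidx]
    elif ties_method == "breslow":
        frac = np.zeros(l.size)
    else:
        raise ValueError(f"unknown ties_method: {ties_method!r}")

    phi0 = R0[gidx] - frac * D0[gidx]
    phi1 = R1[gidx] - frac[:, None] * D1[gidx]
    phi2 = R2[gidx] - frac[:, None, None] * D2[gidx]

    loglik = float((eta - shift)[d].sum() - np.log(phi0).sum())
    g = phi1 / phi0[:, None]
    score = (Xs[d].sum(axis=0) - g.sum(axis=0))
    hess = -(phi2 / phi0[:, None, None] - g[:, :, None] * g[:, None, :]).sum(axis=0)
    return loglik, score, hess


def fit_cox(
    times,
    events,
    covariates,
    ties_method: str = "efron",
    max_iter: int = 50,
    tol_score: float = 1e-8,
    tol_loglik: float = 1e-10,
    names: list[str] | None = None,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton--Raphson.

    Convergence when the largest score component falls below ``tol_score`` or
    the relative change in partial log-likelihood falls below ``tol_loglik``;
    steps that do not improve the likelihood are halved (monotone ascent).
    Standard errors come from the inverse observed information; p-values are
    two-sided Wald against the normal reference.

    Raises ``ValueError`` for inputs with no events, non-finite covariates, or
    a covariate column that is constant (degenerate).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    X = _as_2d(covariates)
    n, p = X.shape
    if n == 0 or times.shape[0] != n or events.shape[0] != n:
        raise ValueError("times, events and covariates must share a non-zero length")
    if not np.isfinite(X).all() or not np.isfinite(times).all():
        raise ValueError("non-finite values in covariates or times")
    if not np.isin(events, (0.0, 1.0)).all():
        raise ValueError("events must be 0/1")
    n_events = int(events.sum())
    if n_events == 0:
        raise ValueError("no events")
    for j in range(p):
        if np.ptp(X[:, j]) == 0.0:
            raise ValueError(f"degenerate covariate (constant column {j})")

    beta = np.zeros(p)
    ll, score, hess = cox_derivatives(beta, times, events, X, ties_method)
    converged = False
    for _ in range(max_iter):
        if np.abs(score).max() < tol_score:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, score)
        except np.linalg.LinAlgError:
            break
        alpha, new = 1.0, None
        for _ in range(25):  # monotone step-halving
            cand = beta + alpha * step
            ll_new, s_new, h_new = cox_derivatives(cand, times, events, X, ties_method)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                new = (cand, ll_new, s_new, h_new)
                break
            alpha *= 0.5
        if new is None:
            break
        beta, ll_new, score, hess = new[0], new[1], new[2], new[3]
        if abs(ll_new - ll) <= tol_loglik * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if np.abs(beta).max() > 15:  # runaway estimate: (near-)perfect separation
        converged = False

    info = -hess
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
        converged = False
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    wald_p = 2.0 * _st.norm.sf(np.abs(z))
    wald_p = np.where(se > 0, wald_p, np.nan)
    zcrit = _st.norm.ppf(1 - ALPHA / 2)
    with np.errstate(over="ignore"):  # se=inf on separation -> ci_high=inf
        ci_low = np.exp(beta - zcrit * se)
        ci_high = np.exp(beta + zcrit * se)
    return CoxFit(
        coef=beta,
        se=se,
        hr=np.exp(beta),
        ci_low=ci_low,
        ci_high=ci_high,
        wald_p=wald_p,
        loglik=ll,
        n=n,
        n_events=n_events,
        converged=converged,
        ties_method=ties_method,
        names=list(names) if names else [],
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def km_estimate(times, events) -> KMCurve:
    """Product-limit survival estimate with Greenwood variance.

    Subjects censored at an event time are counted at risk for that event
    (censoring ordered after events at equal times). Median is the smallest
    event time with survival <= 0.5 (nan when never reached).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("negative times")

    order = np.argsort(times, kind="stable")
    t, d = times[order], events[order].astype(bool)
    n = t.size
    first = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    dcount = np.add.reduceat(d.astype(int), first)
    at_risk = n - first
    has_event = dcount > 0
    et = t[first][has_event]
    dk = dcount[has_event]
    nk = at_risk[has_event]

    surv = np.cumprod(1.0 - dk / nk)
    with np.errstate(divide="ignore", invalid="ignore"):
        gterm = np.where(nk > dk, dk / (nk * (nk - dk)), 0.0)
    gvar = surv**2 * np.cumsum(gterm)
    below = np.flatnonzero(surv <= 0.5 + 1e-12)
    median = float(et[below[0]]) if below.size else float("nan")
    return KMCurve(
        times=et, survival=surv, greenwood_var=gvar,
        n_risk=nk, n_event=dk, median=median,
    )


def km_survival_at(curve: KMCurve, t: float, before: bool = False) -> float:
    """Step-function evaluation S(t); ``before=True`` gives the left limit S(t-)."""
    if before:
        idx = np.searchsorted(curve.times, t, side="left") - 1
    else:
        idx = np.searchsorted(curve.times, t, side="right") - 1
    return 1.0 if idx < 0 else float(curve.survival[idx])


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------


def logrank_test(times, events, groups, strata=None) -> TestResult:
    """(Stratified) log-rank test: observed-minus-expected chi-square with
    hypergeometric variance, summed over strata; df = #groups - 1."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k = labels.size
    if k < 2:
        raise ValueError("at least two groups required")
    if events.sum() == 0:
        raise ValueError("no events")
    strata = np.zeros(times.size) if strata is None else np.asarray(strata)

    o_minus_e = np.zeros(k)
    V = np.zeros((k, k))
    for s in np.unique(strata):
        m = strata == s
        t, d, g = times[m], events[m].astype(bool), groups[m]
        if t.size == 0 or not d.any():
            continue
        gi = np.searchsorted(labels, g)
        for et in np.unique(t[d]):
            at = t >= et
            nk = at.sum()
            dk = int(d[t == et].sum())
            nj = np.bincount(gi[at], minlength=k).astype(float)
            dj = np.bincount(gi[(t == et) & d], minlength=k).astype(float)
            ej = dk * nj / nk
            o_minus_e += dj - ej
            if nk > 1:
                c = dk * (nk - dk) / (nk - 1.0)
                V += c * (np.diag(nj) * nk - np.outer(nj, nj)) / nk**2
    z = o_minus_e[:-1]
    Vz = V[:-1, :-1]
    stat = float(z @ np.linalg.pinv(Vz) @ z) if z.size else 0.0
    stat = max(stat, 0.0)
    df = k - 1
    return TestResult(
        statistic=stat, df=df, p_value=float(_st.chi2.sf(stat, df)),
        method="stratified log-rank" if np.unique(strata).size > 1 else "log-rank",
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def _weighted_auc(marker_cases, w_cases, marker_controls, w_controls) -> float:
    """Weighted Mann-Whitney AUC (ties count 1/2), via sorted cumulative sums."""
    vals = np.unique(np.concatenate([marker_cases, marker_controls]))
    cw = np.zeros(vals.size)
    uw = np.zeros(vals.size)
    np.add.at(cw, np.searchsorted(vals, marker_cases), w_cases)
    np.add.at(uw, np.searchsorted(vals, marker_controls), w_controls)
    ubelow = np.concatenate(([0.0], np.cumsum(uw)[:-1]))
    num = float((cw * (ubelow + 0.5 * uw)).sum())
    den = float(cw.sum() * uw.sum())
    return num / den


def roc_auc(marker, labels) -> float:
    """Plain Mann-Whitney ROC AUC of a marker against binary labels (1 = case)."""
    marker = np.asarray(marker, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("need both cases and controls")
    return _weighted_auc(
        marker[labels], np.ones(labels.sum()),
        marker[~labels], np.ones((~labels).sum()),
    )


def td_roc_auc(
    marker, times, events, horizon: float, min_censor_surv: float = 1e-6
) -> TimeDependentROC:
    """Cumulative-cases / dynamic-controls AUC at ``horizon`` with IPCW.

    Cases are subjects with an observed event at or before the horizon,
    weighted 1/G(T-); controls are subjects still under observation past the
    horizon, weighted 1/G(horizon), where G is the Kaplan--Meier estimate of
    the censoring distribution (events and censorings swap roles). G is
    floored at ``min_censor_surv`` so weights cannot blow up. Marker ties
    contribute 1/2. With no censoring this reduces exactly to the empirical
    Mann--Whitney AUC between cases and controls.
    """
    marker = np.asarray(marker, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if not np.isfinite(marker).all():
        raise ValueError("non-finite marker values")

    case = (times <= horizon) & (events == 1)
    control = times > horizon
    if not case.any():
        raise ValueError("no cases at horizon")
    if not control.any():
        raise ValueError("no controls at horizon")

    if (events == 0).any():
        Gkm = km_estimate(times, 1.0 - events)
        g_case = np.array(
            [km_survival_at(Gkm, t, before=True) for t in times[case]]
        )
        g_ctrl = km_survival_at(Gkm, horizon)
    else:
        g_case = np.ones(int(case.sum()))
        g_ctrl = 1.0
    w_case = 1.0 / np.maximum(g_case, min_censor_surv)
    w_ctrl = np.full(int(control.sum()), 1.0 / max(g_ctrl, min_censor_surv))

    mc, mu = marker[case], marker[control]
    auc = _weighted_auc(mc, w_case, mu, w_ctrl)

    thresholds = np.unique(marker)[::-1]  # high marker = test-positive
    cw_tot, uw_tot = w_case.sum(), w_ctrl.sum()
    sens = np.array([w_case[mc >= th].sum() / cw_tot for th in thresholds])
    spec = np.array([w_ctrl[mu < th].sum() / uw_tot for th in thresholds])
    return TimeDependentROC(
        auc=float(auc), thresholds=thresholds, sensitivity=sens,
        specificity=spec, n_cases=int(case.sum()),
        n_controls=int(control.sum()), horizon=float(horizon),
    )


# ---------------------------------------------------------------------------
# 2x2 relative risk
# ---------------------------------------------------------------------------


def _fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    # two-sided Fisher: sum hypergeometric pmf over tables as or less probable
    r1, c1, n = a + b, a + c, a + b + c + d
    kmin = max(0, r1 + c1 - n)
    kmax = min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    pmf = _st.hypergeom.pmf(ks, n, c1, r1)
    p_obs = _st.hypergeom.pmf(a, n, c1, r1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


def rr_from_table(table) -> ContingencyResult:
    """Relative risk of row 1 vs row 2 of a 2x2 [event, no-event] table.

    95% CI by the Katz log-RR normal method; p-value from the Pearson
    chi-square, switching to Fisher's exact test when any expected cell count
    is below 5. A table with zero events in both rows leaves RR undefined
    (flagged, not raised).
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any() or not np.all(tab == np.round(tab)):
        raise ValueError("table must be 2x2 non-negative integer counts")
    a, b = tab[0]
    c, d = tab[1]
    n1, n2 = a + b, c + d
    if n1 == 0 or n2 == 0:
        raise ValueError("zero row total")

    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
    if (expected < 5).any():
        p = _fisher_exact_p(int(a), int(b), int(c), int(d))
        method = "fisher"
    else:
        chi2 = float((((tab - expected) ** 2) / expected).sum())
        p = float(_st.chi2.sf(chi2, 1))
        method = "chi2"

    if a == 0 and c == 0:
        return ContingencyResult(
            rr=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            p_value=p, table=tab.astype(int), method=method, defined=False,
        )
    risk1, risk2 = a / n1, c / n2
    rr = risk1 / risk2 if risk2 > 0 else float("inf")
    if a > 0 and c > 0:
        se = np.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n2)
        zc = _st.norm.ppf(1 - ALPHA / 2)
        lo, hi = float(np.exp(np.log(rr) - zc * se)), float(np.exp(np.log(rr) + zc * se))
    else:
        lo, hi = float("nan"), float("nan")
    return ContingencyResult(
        rr=float(rr), ci_low=lo, ci_high=hi, p_value=p,
        table=tab.astype(int), method=method,
    )


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=float)
    sx = x[order]
    first = np.flatnonzero(np.r_[True, sx[1:] != sx[:-1]])
    counts = np.diff(np.r_[first, sx.size])
    mid = first + (counts - 1) / 2.0 + 1.0
    ranks[order] = np.repeat(mid, counts)
    return ranks


def _signed_rank_exact_p(wplus: float, ranks: np.ndarray) -> float:
    # exact null of W+ by the generating polynomial over sign patterns
    scale = 2  # midranks are multiples of 1/2
    r = np.round(ranks * scale).astype(int)
    total = r.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for ri in r:
        dist[ri:] += dist[: total + 1 - ri]
    dist /= dist.sum()
    w = int(round(wplus * scale))
    p_low = dist[: w + 1].sum()
    p_high = dist[w:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def rank_test(values_a, values_b, paired: bool = False) -> TestResult:
    """Wilcoxon signed-rank (paired) or Mann--Whitney rank-sum (unpaired).

    Paired: zero differences are dropped; exact two-sided null for n <= 25,
    otherwise normal approximation with continuity and tie correction.
    Unpaired: tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input")
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        diff = a - b
        diff = diff[diff != 0]
        n = diff.size
        if n == 0:
            raise ValueError("all differences zero")
        ranks = _midranks(np.abs(diff))
        wplus = float(ranks[diff > 0].sum())
        if n <= 25:
            p = _signed_rank_exact_p(wplus, ranks)
        else:
            mean = n * (n + 1) / 4.0
            _, t_counts = np.unique(np.abs(diff), return_counts=True)
            var = n * (n + 1) * (2 * n + 1) / 24.0 - (
                (t_counts**3 - t_counts).sum() / 48.0
            )
            z = (wplus - mean - 0.5 * np.sign(wplus - mean)) / np.sqrt(var)
            p = float(2.0 * _st.norm.sf(abs(z)))
        return TestResult(statistic=wplus, df=None, p_value=min(p, 1.0),
                          method="wilcoxon signed-rank")

    n1, n2 = a.size, b.size
    N = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mean = n1 * n2 / 2.0
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_adj = (t_counts**3 - t_counts).sum() / (N * (N - 1.0)) if N > 1 else 0.0
    var = n1 * n2 / 12.0 * ((N + 1.0) - tie_adj)
    if var <= 0:
        raise ValueError("degenerate samples (all values tied)")
    z = (u - mean - 0.5 * np.sign(u - mean)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * _st.norm.sf(abs(z))))
    return TestResult(statistic=u, df=None, p_value=p, method="mann-whitney")
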