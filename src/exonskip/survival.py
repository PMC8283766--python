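"""Survival and association statistics, implemented from first principles.

Kaplan–Meier product-limit estimation, the k-group log-rank test, Cox
proportional hazards by Newton iteration on the Efron-tie partial
likelihood, Pearson correlation with a t-distribution p-value, the
tie-corrected Kruskal–Wallis test, and the cohort-level stratified report
(marker x stratum table of log-rank and Cox results).

Only distribution tails (chi-square, normal, t) are taken from scipy; all
estimators and test statistics are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _dists
from scipy.stats import rankdata

MAX_ABS_COEF = 15.0  # |beta| beyond this signals a monotone partial likelihood


class SurvivalError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    """Newton iteration failed to converge; carries diagnostics."""


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate evaluated at the distinct event times."""

    times: np.ndarray      # distinct event times, ascending
    survival: np.ndarray   # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, S = 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMEstimate:
    """Kaplan-Meier product-limit estimator.

    ``events`` uses 1 for an observed event and 0 for censoring.  Subjects
    censored at an event time are kept in the risk set at that time.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if t.size == 0:
        raise SurvivalError("need at least one sample")
    if np.any(t < 0):
        raise SurvivalError("times must be non-negative")
    if not np.all(np.isin(d, (0, 1))):
        raise SurvivalError("events must be 0 or 1")

    event_times = np.unique(t[d == 1])
    surv, at_risk, n_events = [], [], []
    s = 1.0
    for et in event_times:
        n = int(np.sum(t >= et))
        de = int(np.sum((t == et) & (d == 1)))
        s *= 1.0 - de / n
        surv.append(s)
        at_risk.append(n)
        n_events.append(de)
    return KMEstimate(
        times=event_times,
        survival=np.array(surv),
        at_risk=np.array(at_risk, dtype=int),
        events=np.array(n_events, dtype=int),
    )


def km_curve_frame(times, events) -> pd.DataFrame:
    """KM curve coordinates as a table (for export/plotting)."""
    km = km_estimate(times, events)
    return pd.DataFrame({
        "time": km.times, "survival": km.survival,
        "at_risk": km.at_risk, "events": km.events,
    })


# ---------------------------------------------------------------------------
# Log-rank test


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    df: int
    p: float
    observed: np.ndarray
    expected: np.ndarray


def logrank_test(times, events, groups) -> LogrankResult:
    """k-group log-rank test over pooled risk sets.

    At every distinct event time the observed events per group are compared
    with those expected under a common hazard; the quadratic form of O - E
    against the hypergeometric covariance gives a chi-square statistic with
    k - 1 degrees of freedom.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if not (t.size == d.size == g.size):
        raise SurvivalError("times, events and groups must have equal length")
    labels = np.unique(g)
    k = labels.size
    if k < 2:
        raise SurvivalError("log-rank needs at least 2 groups")
    if d.sum() == 0:
        raise SurvivalError("log-rank needs at least one event")
    for lab in labels:
        if np.sum(g == lab) == 0:
            raise SurvivalError(f"group {lab!r} is empty")

    member = np.stack([g == lab for lab in labels], axis=1)  # n x k
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for et in np.unique(t[d == 1]):
        at_risk = t >= et
        n = at_risk.sum()
        n_j = member[at_risk].sum(axis=0).astype(float)
        dead = (t == et) & (d == 1)
        dtot = dead.sum()
        d_j = member[dead].sum(axis=0).astype(float)
        observed += d_j
        p_j = n_j / n
        expected += dtot * p_j
        if n > 1:
            factor = dtot * (n - dtot) / (n - 1)
            cov += factor * (np.diag(p_j) - np.outer(p_j, p_j))
    diff = (observed - expected)[:-1]
    vmat = cov[:-1, :-1]
    chi2 = float(diff @ np.linalg.pinv(vmat) @ diff)
    df = k - 1
    p = float(_dists.chi2.sf(chi2, df))
    return LogrankResult(chi2=chi2, df=df, p=p, observed=observed, expected=expected)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties, Newton iteration)


@dataclass(frozen=True)
class CoxCovariate:
    name: str
    coef: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    z: float
    p: float


@dataclass(frozen=True)
class CoxResult:
    covariates: tuple[CoxCovariate, ...]
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    n_iter: int
    na_reason: str = ""

    @property
    def is_na(self) -> bool:
        return bool(self.na_reason)

    def __getitem__(self, name: str) -> CoxCovariate:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)


def _efron_quantities(beta, x, t, d):
    """Efron-tie partial log-likelihood, gradient and information matrix.

    Expects samples sorted by ascending time.
    """
    n, p = x.shape
    eta = x @ beta
    eta -= eta.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))

    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = n - 1
    while i >= 0:
        ti = t[i]
        j = i
        while j >= 0 and t[j] == ti:
            s0 += w[j]
            s1 += w[j] * x[j]
            s2 += w[j] * np.outer(x[j], x[j])
            j -= 1
        dead = [m for m in range(j + 1, i + 1) if d[m] == 1]
        if dead:
            nd = len(dead)
            d0 = sum(w[m] for m in dead)
            d1 = np.sum([w[m] * x[m] for m in dead], axis=0)
            d2 = np.sum([w[m] * np.outer(x[m], x[m]) for m in dead], axis=0)
            ll += float(np.sum(eta[dead]))
            grad += x[dead].sum(axis=0)
            for ell in range(nd):
                phi = ell / nd
                z0 = s0 - phi * d0
                z1 = s1 - phi * d1
                z2 = s2 - phi * d2
                ll -= np.log(z0)
                grad -= z1 / z0
                info += z2 / z0 - np.outer(z1, z1) / z0**2
        i = j
    return ll, grad, info


def cox_fit(
    times,
    events,
    covariates: Mapping[str, Sequence[float]] | pd.DataFrame,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by maximum partial likelihood.

    Efron approximation for tied event times; Newton iteration; Wald 95%
    confidence intervals and p-values per covariate.

    A monotone partial likelihood (e.g. a binary group whose complement has
    no events — complete separation) is detected when a coefficient diverges
    and is reported as a non-applicable result with ``na_reason`` set rather
    than raised.  Genuine non-convergence raises :class:`ConvergenceError`.
    """
    cov_df = pd.DataFrame(covariates)
    names = list(cov_df.columns)
    x = cov_df.to_numpy(dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    n, p = x.shape
    if not (t.size == d.size == n):
        raise SurvivalError("times, events and covariates must have equal length")
    if d.sum() == 0:
        raise SurvivalError("Cox model needs at least one event")
    for name in names:
        if np.ptp(cov_df[name].to_numpy(dtype=float)) == 0:
            raise SurvivalError(f"covariate {name!r} is constant")

    order = np.argsort(t, kind="stable")
    x, t, d = x[order], t[order], d[order]
    # center for numerical stability; coefficients are unaffected
    x = x - x.mean(axis=0)

    beta = np.zeros(p)
    ll_null, _, _ = _efron_quantities(beta, x, t, d)
    ll = ll_null
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, grad, info = _efron_quantities(beta, x, t, d)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix at iteration {n_iter} (beta={beta})"
            ) from exc
        beta_new = beta + step
        if np.any(np.abs(beta_new) > MAX_ABS_COEF):
            return CoxResult(
                covariates=(), loglik=ll, loglik_null=ll_null,
                n=n, n_events=int(d.sum()), n_iter=n_iter,
                na_reason=(
                    "monotone partial likelihood: a coefficient diverged "
                    "(complete separation, e.g. all cases censored in one group)"
                ),
            )
        converged = np.max(np.abs(step)) < tol
        beta = beta_new
        if converged:
            break
    else:
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations "
            f"(last step {np.max(np.abs(step)):.3g}, beta={beta})"
        )

    ll, grad, info = _efron_quantities(beta, x, t, d)
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    z = beta / se
    results = tuple(
        CoxCovariate(
            name=names[j],
            coef=float(beta[j]),
            se=float(se[j]),
            hr=float(np.exp(beta[j])),
            ci_low=float(np.exp(beta[j] - 1.959963984540054 * se[j])),
            ci_high=float(np.exp(beta[j] + 1.959963984540054 * se[j])),
            z=float(z[j]),
            p=float(2.0 * _dists.norm.sf(abs(z[j]))),
        )
        for j in range(p)
    )
    return CoxResult(
        covariates=results, loglik=float(ll), loglik_null=float(ll_null),
        n=n, n_events=int(d.sum()), n_iter=n_iter,
    )


def cox_score_test(times, events, covariates) -> tuple[float, int, float]:
    """Score test of beta = 0 for the Cox model (chi-square statistic, df, p).

    On tie-free data with a single binary covariate this equals the
    log-rank chi-square exactly.
    """
    cov_df = pd.DataFrame(covariates)
    x = cov_df.to_numpy(dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    order = np.argsort(t, kind="stable")
    x, t, d = x[order], t[order], d[order]
    x = x - x.mean(axis=0)
    _, grad, info = _efron_quantities(np.zeros(x.shape[1]), x, t, d)
    chi2 = float(grad @ np.linalg.solve(info, grad))
    df = x.shape[1]
    return chi2, df, float(_dists.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Association statistics


def pearson_corr(x, y) -> tuple[float, float]:
    """Sample Pearson correlation and its two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise SurvivalError("need two equal-length vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise SurvivalError("values must be finite")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt(np.sum(xd**2) * np.sum(yd**2))
    if denom == 0:
        raise SurvivalError("zero variance in x or y")
    r = float(np.sum(xd * yd) / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = float(2.0 * _dists.t.sf(abs(tstat), n - 2))
    return r, p


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square (df = k - 1)."""
    if len(groups) < 2:
        raise SurvivalError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise SurvivalError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    n = pooled.size
    k = len(arrays)
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start:start + a.size]
        h += a.size * (r.mean() - (n + 1) / 2.0) ** 2
        start += a.size
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    denom = 1.0 - tie_term / (n**3 - n)
    if denom == 0:  # every value identical
        return 0.0, k - 1, 1.0
    h /= denom
    return float(h), k - 1, float(_dists.chi2.sf(h, k - 1))


# ---------------------------------------------------------------------------
# Stratified marker report (the cohort table)


@dataclass(frozen=True)
class SurvivalResult:
    """One cell of the stratified report."""

    marker: str
    subclass: str
    n_low: int
    n_high: int
    events_low: int
    events_high: int
    logrank_chi2: float
    logrank_p: float
    hr: float | None
    ci_low: float | None
    ci_high: float | None
    cox_p: float | None
    significant: bool
    na_reason: str = ""
    skipped_reason: str = ""


def truncate_followup(times, events, horizon: float) -> tuple[np.ndarray, np.ndarray]:
    """Administrative censoring at ``horizon``: later events become censored."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    over = t > horizon
    return np.where(over, horizon, t), np.where(over, 0, d)


def marker_cell(
    marker: str, subclass: str, times, events, high_mask, alpha: float = 0.05
) -> SurvivalResult:
    """Log-rank + univariate Cox for one binary split within one stratum."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    hi = np.asarray(high_mask, dtype=bool)
    n_low, n_high = int((~hi).sum()), int(hi.sum())
    ev_low, ev_high = int(d[~hi].sum()), int(d[hi].sum())
    base = dict(marker=marker, subclass=subclass, n_low=n_low, n_high=n_high,
                events_low=ev_low, events_high=ev_high)
    if n_low < 2 or n_high < 2:
        return SurvivalResult(
            **base, logrank_chi2=float("nan"), logrank_p=float("nan"),
            hr=None, ci_low=None, ci_high=None, cox_p=None, significant=False,
            skipped_reason=f"fewer than 2 samples per group (low={n_low}, high={n_high})",
        )
    if d.sum() == 0:
        return SurvivalResult(
            **base, logrank_chi2=float("nan"), logrank_p=float("nan"),
            hr=None, ci_low=None, ci_high=None, cox_p=None, significant=False,
            skipped_reason="no events in stratum",
        )
    lr = logrank_test(t, d, np.where(hi, "high", "low"))
    cox = cox_fit(t, d, {"high": hi.astype(float)})
    if cox.is_na:
        return SurvivalResult(
            **base, logrank_chi2=lr.chi2, logrank_p=lr.p,
            hr=None, ci_low=None, ci_high=None, cox_p=None,
            significant=lr.p < alpha, na_reason=cox.na_reason,
        )
    c = cox["high"]
    return SurvivalResult(
        **base, logrank_chi2=lr.chi2, logrank_p=lr.p,
        hr=c.hr, ci_low=c.ci_low, ci_high=c.ci_high, cox_p=c.p,
        significant=lr.p < alpha,
    )


def table1_report(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    markers: Mapping[str, str] | None = None,
    subclasses: Sequence[str] | None = None,
    horizon: float | None = 120.0,
    alpha: float = 0.05,
    scope: str = "cohort",
) -> tuple[pd.DataFrame, dict]:
    """Marker x stratum table of median-split survival results.

    ``markers`` maps a report row name to an expression column, with the
    special value ``"signature"`` meaning the dual two-marker signature
    (requires ``wt_expr`` and ``de4_expr`` columns).  Strata are the whole
    cohort plus each requested molecular subclass.  Follow-up is
    administratively censored at ``horizon`` months when given.

    Returns the report table and a metadata dict (medians used, scope,
    horizon, exclusions).
    """
    from . import signature as sig

    if markers is None:
        markers = {"e3": "exon3_expr", "wt": "wt_expr", "de4": "de4_expr",
                   "signature": "signature"}
    if subclasses is None:
        subclasses = list(sig.SUBTYPES)

    expr = expression.copy()
    if "sample_id" in expr.columns:
        expr = expr.set_index("sample_id")
    clin = clinical.copy()
    if "sample_id" in clin.columns:
        clin = clin.set_index("sample_id")
    joined = expr.join(clin, how="inner", lsuffix="", rsuffix="_clin")
    if joined.empty:
        raise SurvivalError("expression and clinical tables share no sample ids")

    subtype = {}
    for sid, row in joined.iterrows():
        try:
            subtype[sid] = sig.assign_subtype(row["er"], row["pr"], row["her2"])
        except (sig.SignatureError, KeyError):
            subtype[sid] = None
    joined["_subtype"] = [subtype[s] for s in joined.index]

    times = joined["rfs_time"].to_numpy(dtype=float)
    events = joined["event"].to_numpy(dtype=int)
    if horizon is not None:
        times, events = truncate_followup(times, events, horizon)
    joined["_time"], joined["_event"] = times, events

    medians_meta: dict = {}

    def _high_mask(stratum_df: pd.DataFrame, column: str) -> pd.Series:
        if scope == "cohort":
            ref = joined[column]
        else:
            ref = stratum_df[column]
        med = float(ref.median())
        medians_meta.setdefault(column, {})[stratum_df.attrs["name"]] = med
        return stratum_df[column] > med

    strata: list[tuple[str, pd.DataFrame]] = [("all", joined)]
    for sc in subclasses:
        strata.append((sc, joined[joined["_subtype"] == sc]))

    cells = []
    for stratum_name, sdf in strata:
        sdf = sdf.copy()
        sdf.attrs["name"] = stratum_name
        for marker_name, column in markers.items():
            if sdf.shape[0] < 4:
                cells.append(SurvivalResult(
                    marker=marker_name, subclass=stratum_name,
                    n_low=0, n_high=0, events_low=0, events_high=0,
                    logrank_chi2=float("nan"), logrank_p=float("nan"),
                    hr=None, ci_low=None, ci_high=None, cox_p=None,
                    significant=False,
                    skipped_reason=f"stratum has only {sdf.shape[0]} samples",
                ))
                continue
            if column == "signature":
                hi_wt = _high_mask(sdf, "wt_expr")
                hi_de4 = _high_mask(sdf, "de4_expr")
                high = (hi_wt | hi_de4)
            else:
                high = _high_mask(sdf, column)
            cells.append(marker_cell(
                marker_name, stratum_name,
                sdf["_time"], sdf["_event"], high.to_numpy(), alpha=alpha,
            ))
    report = pd.DataFrame([vars(c) for c in cells])
    meta = {
        "scope": scope,
        "horizon": horizon,
        "alpha": alpha,
        "medians": medians_meta,
        "n_joined": int(joined.shape[0]),
        "n_missing_subtype": int(sum(v is None for v in subtype.values())),
    }
    return report, meta
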