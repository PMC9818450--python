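"""Censored-survival machinery implemented from first principles.

Kaplan-Meier product-limit estimation, the k-group log-rank test, Cox
proportional-hazards regression (Newton-Raphson on the partial likelihood,
Efron tie handling by default), and cumulative/dynamic time-dependent
ROC/AUC for a continuous marker with inverse-probability-of-censoring
weights (IPCW).

Conventions
-----------
* times are strictly positive (months), events are 0/1 (1 = event);
* Cox standard errors come from the inverse observed information; per
  covariate we report two-sided Wald tests;
* the time-dependent ROC at horizon ``t`` treats subjects dead by ``t`` as
  cases and subjects observed beyond ``t`` as controls, weighting both by
  the Kaplan-Meier estimate of the censoring distribution.  With zero
  censoring the AUC reduces exactly to the Mann-Whitney concordance of the
  marker against died-by-horizon status.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("survscreen")

NOT_REACHED = float("inf")  # sentinel median when survival never drops to 0.5

# Newton-Raphson controls for the Cox partial likelihood
COX_TOL = 1e-9          # absolute change in log partial likelihood
COX_MAX_ITER = 100
COX_MAX_BETA = 20.0     # |beta| beyond this flags monotone-likelihood separation


class SurvivalError(ValueError):
    """Raised on invalid survival-analysis input."""


def _check_times_events(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise SurvivalError("empty input: no subjects")
    if times.shape != events.shape:
        raise SurvivalError("times and events have different lengths")
    if (times <= 0).any():
        raise SurvivalError("survival times must be strictly positive")
    if not np.isin(events, (0, 1)).all():
        raise SurvivalError("event indicators must be 0 or 1")
    return times, events


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``event_times`` are the distinct times with at least one event,
    ascending; ``survival[k]`` is S(t) just after ``event_times[k]``.
    ``median`` is the earliest time with survival <= 0.5, or
    ``NOT_REACHED`` (inf).
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    median: float

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation S(t); S(t)=1 before the first event."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.event_times.size == 0:
            out = np.ones_like(t)
        else:
            idx = np.searchsorted(self.event_times, t, side="right") - 1
            out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out if out.size > 1 else float(out[0])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function.

    Censored-only times do not change the curve (they only shrink the risk
    set).  By convention censored subjects tied with an event time remain
    at risk at that time.
    """
    times, events = _check_times_events(times, events)
    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    uniq, first = np.unique(t_sorted, return_index=True)
    n = times.size
    at_risk_all = n - first                               # subjects with t >= uniq
    d_all = np.add.reduceat(e_sorted, first)              # events at each unique time
    mask = d_all > 0
    event_times = uniq[mask]
    at_risk = at_risk_all[mask]
    d = d_all[mask]
    surv = np.cumprod(1.0 - d / at_risk)
    below = np.nonzero(surv <= 0.5)[0]
    median = float(event_times[below[0]]) if below.size else NOT_REACHED
    return KMCurve(event_times, surv, at_risk, d, median)


def censoring_km(times, events) -> KMCurve:
    """KM estimate of the censoring distribution G (event flags flipped).

    Events are treated as censorings of the censoring process and vice
    versa.  Used for IPCW weighting in the time-dependent ROC.
    """
    times, events = _check_times_events(times, events)
    return km_estimate(times, 1 - events)


# ---------------------------------------------------------------------------
# log-rank


@dataclass
class LogRankResult:
    """Observed-vs-expected chi-square comparison of k survival curves."""

    statistic: float
    dof: int
    p_value: float
    group_labels: list


def logrank_test(times, events, groups) -> LogRankResult:
    """k-group log-rank test over the pooled distinct event times.

    At each event time the events observed per group are compared with the
    expectation under the hypergeometric model given the risk sets; the
    quadratic form over the first k-1 groups uses the full covariance.
    """
    times, events = _check_times_events(times, events)
    groups = np.asarray(groups)
    labels, gidx = np.unique(groups, return_inverse=True)
    k = labels.size
    if k < 2:
        raise SurvivalError("log-rank needs at least two non-empty groups")
    event_times = np.unique(times[events == 1])
    obs = np.zeros(k)
    exp = np.zeros(k)
    cov = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n_t = at_risk.sum()
        dying = at_risk & (times == t) & (events == 1)
        d_t = dying.sum()
        if n_t == 0 or d_t == 0:
            continue
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gidx[dying], minlength=k).astype(float)
        obs += d_g
        exp += d_t * n_g / n_t
        if n_t > 1:
            frac = n_g / n_t
            scale = d_t * (n_t - d_t) / (n_t - 1)
            cov += scale * (np.diag(frac) - np.outer(frac, frac))
    diff = (obs - exp)[: k - 1]
    vmat = cov[: k - 1, : k - 1]
    try:
        stat = float(diff @ np.linalg.solve(vmat, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(vmat) @ diff)
    stat = max(stat, 0.0)
    from scipy.stats import chi2

    p = float(chi2.sf(stat, k - 1))
    return LogRankResult(stat, k - 1, p, list(labels))


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    """Cox partial-likelihood fit.

    Hazard ratios are exp(coefficients); p-values are two-sided Wald.
    ``converged`` False marks a fit downstream filters must treat as
    unusable (non-convergence or monotone-likelihood separation).
    """

    covariates: list[str]
    coef: np.ndarray
    se: np.ndarray
    log_likelihood: float
    iterations: int
    converged: bool
    tie_method: str
    n: int
    n_events: int

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coef / self.se

    @property
    def p_values(self) -> np.ndarray:
        from scipy.stats import norm

        return 2.0 * norm.sf(np.abs(self.z))

    def confidence_intervals(self, alpha: float = 0.05) -> np.ndarray:
        """(lower, upper) HR bounds per covariate, Wald-based."""
        from scipy.stats import norm

        zq = norm.ppf(1 - alpha / 2)
        return np.exp(np.stack([self.coef - zq * self.se, self.coef + zq * self.se], axis=1))


def _efron_quantities(X, times, events, beta, tie_method="efron"):
    """Log partial likelihood, gradient and Hessian at ``beta``.

    Vectorized over tied event times: within a tie group of size d the
    Efron correction subtracts l/d of the tied subjects' own contribution
    from the risk-set sums for l = 0..d-1; Breslow uses the raw risk set
    for every tied event.
    """
    n, p = X.shape
    order = np.argsort(times, kind="stable")
    Xs = X[order]
    ts = times[order]
    es = events[order]
    eta = Xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)

    # reverse cumulative risk-set sums: entry i covers subjects with t >= ts[i]
    # (ties share the value at their first index)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    S2 = np.cumsum((w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]))[::-1], axis=0)[::-1]

    ev = np.nonzero(es == 1)[0]
    if ev.size == 0:
        raise SurvivalError("no events: partial likelihood undefined")
    t_ev = ts[ev]
    # first sorted index of each event's time -> correct risk-set row
    first_idx = np.searchsorted(ts, t_ev, side="left")
    # tie groups among events sharing a time
    _, grp, counts = np.unique(t_ev, return_inverse=True, return_counts=True)
    d = counts[grp].astype(float)
    # within-group rank l = 0..d-1
    l_rank = np.arange(ev.size) - np.concatenate(([0], np.cumsum(counts)))[grp]
    if tie_method == "efron":
        frac = l_rank / d
    elif tie_method == "breslow":
        frac = np.zeros(ev.size)
    else:
        raise SurvivalError(f"unknown tie method {tie_method!r}")

    w_ev = w[ev]
    x_ev = Xs[ev]
    s0_D = np.bincount(grp, weights=w_ev)[grp]
    s1_D = np.zeros((ev.size, p))
    s2_D = np.zeros((ev.size, p, p))
    wx = w_ev[:, None] * x_ev
    wxx = w_ev[:, None, None] * (x_ev[:, :, None] * x_ev[:, None, :])
    for j in range(p):
        s1_D[:, j] = np.bincount(grp, weights=wx[:, j])[grp]
        for kk in range(p):
            s2_D[:, j, kk] = np.bincount(grp, weights=wxx[:, j, kk])[grp]

    denom = S0[first_idx] - frac * s0_D
    num1 = S1[first_idx] - frac[:, None] * s1_D
    num2 = S2[first_idx] - frac[:, None, None] * s2_D

    loglik = float(eta[ev].sum() - np.log(denom).sum())
    m1 = num1 / denom[:, None]
    grad = x_ev.sum(axis=0) - m1.sum(axis=0)
    hess = -(num2 / denom[:, None, None] - m1[:, :, None] * m1[:, None, :]).sum(axis=0)
    return loglik, grad, hess


def cox_fit(
    X,
    times,
    events,
    covariates: list[str] | None = None,
    tie_method: str = "efron",
    tol: float = COX_TOL,
    max_iter: int = COX_MAX_ITER,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Maximizes the partial likelihood (Efron tie correction by default,
    Breslow available) with step-halving on overshoot; convergence when
    the log partial likelihood changes by less than ``tol``.  A constant
    covariate is an error; monotone-likelihood separation yields
    ``converged=False`` rather than a silent result.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(times).size > 1:
        X = X.T
    times, events = _check_times_events(times, events)
    if X.shape[0] != times.size:
        raise SurvivalError("covariate rows must match the number of subjects")
    if not np.isfinite(X).all():
        raise SurvivalError("covariates must be finite")
    n, p = X.shape
    if covariates is None:
        covariates = [f"x{j}" for j in range(p)]
    if events.sum() == 0:
        raise SurvivalError("at least one event is required")
    const = np.nonzero(X.std(axis=0) == 0)[0]
    if const.size:
        raise SurvivalError(f"constant covariate: {covariates[const[0]]!r}")

    # center and scale for numerical stability; transform back afterwards
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Z = (X - mu) / sd

    beta = np.zeros(p)
    loglik, grad, hess = _efron_quantities(Z, times, events, beta, tie_method)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        new_beta = beta + step
        new_ll, new_grad, new_hess = _efron_quantities(Z, times, events, new_beta, tie_method)
        halvings = 0
        while new_ll < loglik and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _efron_quantities(Z, times, events, new_beta, tie_method)
            halvings += 1
        delta = new_ll - loglik
        beta, loglik, grad, hess = new_beta, new_ll, new_grad, new_hess
        if abs(delta) < tol:
            converged = True
            break

    if np.abs(beta / sd).max() > COX_MAX_BETA:
        converged = False  # monotone-likelihood separation: beta diverging

    try:
        cov = np.linalg.inv(-hess)
        se_z = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_z = np.full(p, np.nan)
        converged = False

    return CoxFit(
        covariates=list(covariates),
        coef=beta / sd,
        se=se_z / sd,
        log_likelihood=loglik,
        iterations=iterations,
        converged=converged,
        tie_method=tie_method,
        n=n,
        n_events=int(events.sum()),
    )


def cox_score_test(X, times, events, tie_method: str = "efron") -> tuple[float, float]:
    """Score (Rao) test of beta = 0: statistic and two-sided chi-square p.

    For a two-group indicator with no tied event times this equals the
    log-rank chi-square exactly (classical identity).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    times, events = _check_times_events(times, events)
    _, grad, hess = _efron_quantities(X, times, events, np.zeros(X.shape[1]), tie_method)
    stat = float(grad @ np.linalg.solve(-hess, grad))
    from scipy.stats import chi2

    return stat, float(chi2.sf(stat, X.shape[1]))


# ---------------------------------------------------------------------------
# time-dependent ROC


@dataclass
class TdROC:
    """Cumulative/dynamic ROC of a marker at a fixed horizon.

    Cases are subjects dead by the horizon, controls subjects observed
    beyond it; both are IPCW-weighted by the censoring-distribution KM so
    that informative loss to follow-up does not bias the curve.
    ``thresholds`` descend so sensitivity ascends along the curve arrays;
    at threshold c a subject is marker-positive when marker > c.
    """

    horizon: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_cases: int
    n_controls: int


def td_roc(marker, times, events, horizon: float) -> TdROC:
    """Time-dependent ROC with inverse-probability-of-censoring weights.

    Cases: event by ``horizon`` (weight 1/G(T_i^-)); controls: follow-up
    beyond ``horizon`` (weight 1/G(horizon)); G is the Kaplan-Meier
    estimate of the censoring survival function.  Subjects censored before
    the horizon contribute only through G.  The AUC is the weighted
    probability that a random case's marker exceeds a random control's,
    ties counted half.
    """
    marker = np.asarray(marker, dtype=float)
    times, events = _check_times_events(times, events)
    if marker.shape != times.shape:
        raise SurvivalError("marker and times have different lengths")
    if horizon <= 0 or horizon > times.max():
        raise SurvivalError(
            f"horizon {horizon} outside the observed follow-up range (0, {times.max()}]"
        )

    case = (times <= horizon) & (events == 1)
    control = times > horizon
    if case.sum() == 0:
        raise SurvivalError(f"no cases: no deaths observed by horizon {horizon}")
    if control.sum() == 0:
        raise SurvivalError(f"no controls: no subjects followed beyond horizon {horizon}")

    G = censoring_km(times, events)
    # left limit G(t-): evaluate just below each case's event time
    g_case = np.asarray(G.survival_at(times[case] - 1e-9 * max(1.0, times.max())), dtype=float)
    g_ctrl = float(np.asarray(G.survival_at(horizon)))
    g_case = np.where(g_case <= 0, np.nan, g_case)
    if not np.isfinite(g_case).all() or g_ctrl <= 0:
        # G hitting zero means no information left; drop those cases
        keep = np.isfinite(g_case)
        if not keep.any() or g_ctrl <= 0:
            raise SurvivalError("censoring distribution vanishes before the horizon")
        g_case = g_case[keep]
        case_idx = np.nonzero(case)[0][keep]
    else:
        case_idx = np.nonzero(case)[0]
    w_case = 1.0 / g_case
    w_ctrl = np.full(int(control.sum()), 1.0 / g_ctrl)

    m_case = marker[case_idx]
    m_ctrl = marker[control]
    thresholds = np.unique(marker)[::-1]  # descending
    # positive test: marker > threshold
    sens = np.array([w_case[m_case > c].sum() for c in thresholds]) / w_case.sum()
    spec = np.array([w_ctrl[m_ctrl <= c].sum() for c in thresholds]) / w_ctrl.sum()

    # weighted pairwise concordance (ties count half)
    diff = m_case[:, None] - m_ctrl[None, :]
    conc = (diff > 0) + 0.5 * (diff == 0)
    auc = float((w_case[:, None] * w_ctrl[None, :] * conc).sum() / (w_case.sum() * w_ctrl.sum()))

    return TdROC(
        horizon=float(horizon),
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        n_cases=int(m_case.size),
        n_controls=int(m_ctrl.size),
    )


def auc_trajectory(marker, times, events, horizons) -> list[tuple[float, float]]:
    """td_roc AUC per horizon; invalid horizons are skipped with a warning."""
    horizons = list(horizons)
    if any(b < a for a, b in zip(horizons, horizons[1:])):
        raise SurvivalError("horizons must be ascending")
    out = []
    for h in horizons:
        try:
            out.append((float(h), td_roc(marker, times, events, h).auc))
        except SurvivalError as exc:
            warnings.warn(f"horizon {h} skipped: {exc}", stacklevel=2)
            logger.warning("auc_trajectory: horizon %s skipped: %s", h, exc)
    if not out:
        raise SurvivalError("all horizons invalid for time-dependent ROC")
    return out
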