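"""Survival statistics: Kaplan-Meier, log-rank, Cox proportional hazards.

These primitives are implemented directly (product-limit estimator,
observed-minus-expected log-rank tabulation, Newton-Raphson maximisation of
the stratified partial likelihood with Efron or Breslow tie handling)
because they are the computational core of the consensus-signature method
and are exercised in shapes — thousands of median-split fits per cohort —
where we need full control over the numerics.  Reference implementations
(e.g. lifelines) are used only as independent cross-checks in the test
suite.

Conventions
-----------
* Times are in months; the code never rescales them.
* Observations censored exactly at an event time are counted as at risk
  through that event time (the standard product-limit convention).
* Confidence intervals are 95% Wald intervals on the log-hazard scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge; carries the iteration trace."""


class SeparationError(RuntimeError):
    """Monotone partial likelihood (perfect separation) for a covariate."""


# ---------------------------------------------------------------------------
# input validation helpers
# ---------------------------------------------------------------------------

def validate_outcomes(time, event) -> tuple[np.ndarray, np.ndarray]:
    """Validate and coerce survival times and event indicators."""
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).ravel()
    if time.size == 0:
        raise ValueError("no survival outcomes provided")
    if time.size != event.size:
        raise ValueError("time and event must have equal length")
    if np.any(~np.isfinite(time)) or np.any(time < 0):
        raise ValueError("survival times must be finite and non-negative")
    ev = event.astype(float)
    if not np.all(np.isin(ev, (0.0, 1.0))):
        bad = np.unique(ev[~np.isin(ev, (0.0, 1.0))])
        raise ValueError(f"event indicator must be 0/1, found {bad[:5]}")
    return time, ev.astype(np.int64)


def _unpack_y(y) -> tuple[np.ndarray, np.ndarray]:
    """Accept (n,2) arrays, DataFrames with time/event columns, or structured arrays."""
    if isinstance(y, pd.DataFrame):
        if not {"time", "event"} <= set(y.columns):
            raise ValueError("y DataFrame must have 'time' and 'event' columns")
        return validate_outcomes(y["time"], y["event"])
    arr = np.asarray(y)
    if arr.dtype.names:  # structured, e.g. scikit-survival style
        names = arr.dtype.names
        return validate_outcomes(arr[names[1]], arr[names[0]])
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("y must be an (n, 2) array of [time, event]")
    return validate_outcomes(arr[:, 0], arr[:, 1])


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve.

    ``survival[k]`` is the estimate just after ``times[k]``; the curve is 1
    before the first event time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function lookup S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier estimate of the survival function.

    Censored observations tied with an event time remain at risk through
    that time.
    """
    time, event = validate_outcomes(time, event)
    n = time.size
    ev_times = np.unique(time[event == 1])
    at_risk = np.array([np.sum(time >= t) for t in ev_times], dtype=np.int64)
    d = np.array([np.sum((time == t) & (event == 1)) for t in ev_times], dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(times=ev_times, survival=surv, at_risk=at_risk, events=d)


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------

class LogRankResult(NamedTuple):
    statistic: float
    p: float


def logrank_test(time, event, group) -> LogRankResult:
    """Two-group log-rank test.

    Chi-square statistic with 1 df from the observed-minus-expected event
    counts over the pooled event times, with the hypergeometric variance.
    With zero total events the statistic is undefined (0/0); it is returned
    as 0 with p = 1 and a warning.
    """
    time, event = validate_outcomes(time, event)
    group = np.asarray(group).ravel()
    if group.size != time.size:
        raise ValueError("group labels must align with outcomes")
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError(f"exactly two non-empty groups required, found {labels.size}")
    in1 = group == labels[1]

    if event.sum() == 0:
        warnings.warn("no events in either group; log-rank statistic undefined, returning 0")
        return LogRankResult(0.0, 1.0)

    ev_times = np.unique(time[event == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in ev_times:
        at_risk = time >= t
        nk = at_risk.sum()
        n1k = (at_risk & in1).sum()
        dk = ((time == t) & (event == 1)).sum()
        d1k = ((time == t) & (event == 1) & in1).sum()
        o_minus_e += d1k - dk * n1k / nk
        if nk > 1:
            var += dk * (n1k / nk) * (1 - n1k / nk) * (nk - dk) / (nk - 1)
    if var <= 0:
        return LogRankResult(0.0, 1.0)
    statistic = o_minus_e**2 / var
    return LogRankResult(float(statistic), float(stats.chi2.sf(statistic, df=1)))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxFitResult:
    """Result of a Cox proportional-hazards fit.

    All per-covariate fields are arrays aligned with ``names``.  ``score_p``
    is the p-value of the score test at beta = 0, which for a single binary
    covariate coincides with the log-rank test.
    """

    names: tuple
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    score_chi2: float
    score_p: float
    n: int
    n_events: int
    loglik: float
    n_iter: int
    ties: str

    @property
    def logrank_p(self) -> float:
        """Alias: the score-test p (log-rank equivalent for one binary covariate)."""
        return self.score_p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hr": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            },
            index=list(self.names),
        )

    def single(self) -> dict:
        """Flatten a one-covariate fit to a scalar record (Table-style row)."""
        if len(self.names) != 1:
            raise ValueError("single() requires a one-covariate fit")
        return {
            "coef": float(self.coef[0]),
            "se": float(self.se[0]),
            "hr": float(self.hr[0]),
            "ci_low": float(self.ci_low[0]),
            "ci_high": float(self.ci_high[0]),
            "p": float(self.p[0]),
            "score_p": self.score_p,
            "n": self.n,
            "n_events": self.n_events,
        }


def _partial_loglik_terms(beta, blocks, ties):
    """Log-likelihood, gradient, and information of the stratified partial likelihood.

    ``blocks`` holds, per stratum, covariates/times/events sorted by
    ascending time.  Risk-set sums are accumulated over decreasing time.
    """
    p = blocks[0][0].shape[1]
    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for Xs, ts, es in blocks:
        eta = Xs @ beta
        w = np.exp(eta)
        n = ts.size
        rs0 = 0.0
        rs1 = np.zeros(p)
        rs2 = np.zeros((p, p))
        i = n - 1
        while i >= 0:
            t = ts[i]
            j = i
            while j >= 0 and ts[j] == t:
                j -= 1
            sl = slice(j + 1, i + 1)
            Wi = w[sl]
            Xi = Xs[sl]
            rs0 += Wi.sum()
            rs1 += Wi @ Xi
            rs2 += (Xi * Wi[:, None]).T @ Xi
            ev = es[sl] == 1
            d = int(ev.sum())
            if d > 0:
                Xe = Xi[ev]
                We = Wi[ev]
                s0 = We.sum()
                s1 = We @ Xe
                s2 = (Xe * We[:, None]).T @ Xe
                loglik += float(eta[sl][ev].sum())
                grad += Xe.sum(axis=0)
                fracs = np.arange(d) / d if ties == "efron" else np.zeros(d)
                for f in fracs:
                    phi = rs0 - f * s0
                    a = rs1 - f * s1
                    b = rs2 - f * s2
                    loglik -= np.log(phi)
                    grad -= a / phi
                    info += b / phi - np.outer(a, a) / phi**2
            i = j
    return loglik, grad, info


_SEPARATION_BOUND = 20.0  # |coef| on the standardized scale; e^20 per SD is separation


def cox_fit(
    X,
    time=None,
    event=None,
    *,
    strata=None,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 100,
    names: Sequence[str] | None = None,
) -> CoxFitResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Parameters
    ----------
    X : array-like or DataFrame, shape (n, p)
        Covariates, row-aligned with the outcomes.
    time, event : array-like
        Survival time and 0/1 event indicator.
    strata : array-like, optional
        Stratum labels; each stratum gets its own baseline hazard.
    ties : {"efron", "breslow"}
        Tie-handling approximation (they coincide when no event times tie).

    Covariates are standardized internally for conditioning; reported
    coefficients are on the original scale.  Convergence requires
    max |delta coef| < tol (standardized scale) within ``max_iter``
    iterations.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    if isinstance(X, pd.DataFrame):
        if names is None:
            names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = tuple(names)
    time, event = validate_outcomes(time, event)
    if time.size != n:
        raise ValueError("covariates must be row-aligned with outcomes")
    if event.sum() == 0:
        raise ValueError("no events observed; partial likelihood is empty")

    if strata is None:
        codes = np.zeros(n, dtype=np.int64)
    else:
        strata = np.asarray(strata).ravel()
        if strata.size != n:
            raise ValueError("strata must align with outcomes")
        codes = pd.factorize(strata)[0]

    # each covariate must vary within at least one stratum
    for j in range(p):
        varies = any(
            np.ptp(X[codes == s, j]) > 0 for s in np.unique(codes) if np.any(codes == s)
        )
        if not varies:
            raise ValueError(
                f"covariate {names[j]!r} is constant within every stratum; not identifiable"
            )

    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # cannot happen after the variability check, but be safe
    Z = (X - center) / scale

    blocks = []
    for s in np.unique(codes):
        m = codes == s
        order = np.argsort(time[m], kind="stable")
        blocks.append((Z[m][order], time[m][order], event[m][order]))

    beta = np.zeros(p)
    loglik, grad, info = _partial_loglik_terms(beta, blocks, ties)
    # score test at beta = 0
    try:
        score_chi2 = float(grad @ np.linalg.solve(info, grad))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular information matrix at beta=0") from exc
    score_p = float(stats.chi2.sf(score_chi2, df=p))

    trace = [(0, loglik, float(np.abs(grad).max()))]
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            # a flattening likelihood with a drifting coefficient is monotone,
            # not merely ill-conditioned
            if np.abs(beta).max() > 5.0:
                j = int(np.abs(beta).argmax())
                raise SeparationError(
                    f"monotone partial likelihood: covariate {names[j]!r} separates the data"
                ) from exc
            raise ConvergenceError(f"singular information matrix; trace={trace}") from exc
        # step-halving to guarantee likelihood ascent
        new_beta = beta + step
        new = _partial_loglik_terms(new_beta, blocks, ties)
        halvings = 0
        while new[0] < loglik - 1e-12 and halvings < 30:
            step = step / 2.0
            new_beta = beta + step
            new = _partial_loglik_terms(new_beta, blocks, ties)
            halvings += 1
        beta = new_beta
        loglik, grad, info = new
        trace.append((n_iter, loglik, float(np.abs(step).max())))
        if np.any(np.abs(beta) > _SEPARATION_BOUND):
            j = int(np.abs(beta).argmax())
            raise SeparationError(
                f"monotone partial likelihood: covariate {names[j]!r} separates the data"
            )
        if np.abs(step).max() < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations; trace={trace}"
        )

    cov = np.linalg.inv(info)
    se_z = np.sqrt(np.diag(cov))
    coef = beta / scale
    se = se_z / scale
    z_crit = stats.norm.ppf(0.975)
    hr = np.exp(coef)
    ci_low = np.exp(coef - z_crit * se)
    ci_high = np.exp(coef + z_crit * se)
    wald_p = 2.0 * stats.norm.sf(np.abs(coef) / se)
    return CoxFitResult(
        names=names,
        coef=coef,
        se=se,
        hr=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        p=wald_p,
        score_chi2=score_chi2,
        score_p=score_p,
        n=n,
        n_events=int(event.sum()),
        loglik=float(loglik),
        n_iter=n_iter,
        ties=ties,
    )


class CoxPH(BaseEstimator):
    """Cox proportional-hazards model with a scikit-learn estimator surface.

    ``fit(X, y)`` takes ``y`` as an (n, 2) array of ``[time, event]``, a
    DataFrame with ``time``/``event`` columns, or a structured array.
    ``predict`` returns the linear predictor (log relative hazard).

    Attributes ending in ``_`` are set on fit: ``coef_``, ``se_``,
    ``hazard_ratios_``, ``ci_``, ``p_``, ``score_p_``, ``result_``.
    """

    def __init__(self, ties: str = "efron", tol: float = 1e-9, max_iter: int = 100):
        self.ties = ties
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, strata=None):
        time, event = _unpack_y(y)
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        res = cox_fit(
            X, time, event, strata=strata, ties=self.ties, tol=self.tol, max_iter=self.max_iter
        )
        self.result_ = res
        self.coef_ = res.coef
        self.se_ = res.se
        self.hazard_ratios_ = res.hr
        self.ci_ = np.column_stack([res.ci_low, res.ci_high])
        self.p_ = res.p
        self.score_p_ = res.score_p
        self.n_features_in_ = res.coef.size
        self._center = np.asarray(X, dtype=float).reshape(len(time), -1).mean(axis=0)
        return self

    def predict(self, X):
        """Linear predictor (log relative hazard, centered covariates)."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("CoxPH instance is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return (X - self._center) @ self.coef_


def weighted_mean_hr(hrs, weights) -> float:
    """Size-weighted mean of per-cohort hazard ratios: sum(hr*w) / sum(w).

    Used to aggregate a signature's per-cohort HRs with cohort sizes as
    weights.  Full precision is returned; round to 1 decimal for reporting.
    """
    hrs = np.asarray(hrs, dtype=float).ravel()
    weights = np.asarray(weights, dtype=float).ravel()
    if hrs.size == 0 or weights.size == 0:
        raise ValueError("empty hazard-ratio or weight list")
    if hrs.size != weights.size:
        raise ValueError("hrs and weights must have equal length")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    return float(np.sum(hrs * weights) / np.sum(weights))
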