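"""Consensus probe selection across survival cohorts.

Each probe is dichotomised at its within-cohort median; the high and low
groups are compared with a two-group Cox model (hazard ratio, direction)
and a log-rank test (significance).  A probe is called prognostic when its
effect direction is identical in every cohort and its log-rank p-value
falls below alpha in at least ``min_significant`` of the cohorts.  The
module also provides the analytic per-probe type-I error rate of this vote
and a Monte-Carlo check of it.

The log-rank p feeds the significance vote (it is the designated test of
the two groups); the Wald p of the Cox fit is retained in the grid for
reporting.  Direction is the sign of the unrounded log hazard ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from . import _twogroup
from .matrix import ExpressionMatrix
from .survival import validate_outcomes, _unpack_y

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# median split
# ---------------------------------------------------------------------------

def median_split(values) -> np.ndarray:
    """Label samples high (True) iff strictly above the median; ties go low.

    Raises if either side of the split would be empty (e.g. a constant
    vector) or if fewer than 4 values are supplied.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 4:
        raise ValueError("median split needs at least 4 values")
    med = np.median(values)
    high = values > med
    if high.all() or not high.any():
        raise ValueError("median split impossible: one side would be empty")
    return high


# ---------------------------------------------------------------------------
# per-probe, per-cohort testing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeCohortResult:
    """One cell of the probe x cohort grid: HR (high vs low), log-rank p, direction."""

    probe_id: str
    cohort_id: str
    hr: float
    p: float           # log-rank p-value
    direction: int     # sign of log(hr), computed from the unrounded coefficient
    p_wald: float = np.nan
    coef: float = np.nan
    se: float = np.nan


def probe_cohort_grid(
    expression,
    time,
    event,
    *,
    cohort_id: str = "cohort",
    ties: str = "efron",
) -> pd.DataFrame:
    """Median-split test of every probe in a matrix against one cohort's outcomes.

    Returns a DataFrame with one row per probe: ``probe_id, cohort_id, hr,
    p`` (log-rank), ``direction, p_wald, coef, se``.  Probes whose median
    split is infeasible (constant within the cohort) are dropped with a
    warning.  Probes with a monotone partial likelihood get ``hr`` 0 or
    inf, direction from the score sign, and the log-rank p.
    """
    if isinstance(expression, ExpressionMatrix):
        vals = expression.values
    else:
        vals = pd.DataFrame(expression)
    time, event = validate_outcomes(time, event)
    if vals.shape[1] != time.size:
        raise ValueError("expression samples must align with outcomes")
    arr = vals.to_numpy(dtype=float)
    meds = np.median(arr, axis=1, keepdims=True)
    labels = arr > meds
    feasible = labels.any(axis=1) & (~labels).any(axis=1)
    if not feasible.all():
        dropped = vals.index[~feasible].tolist()
        warnings.warn(
            f"{len(dropped)} probe(s) dropped: median split infeasible "
            f"(first: {dropped[:5]})"
        )
        logger.info("dropped probes with infeasible median split: %s", dropped)
        labels = labels[feasible]
    probe_ids = vals.index[feasible]

    tables = _twogroup.two_group_tables(time, event, labels)
    lr = _twogroup.logrank_grid(tables)
    cox = _twogroup.cox_two_group_grid(tables, ties=ties)
    direction = np.sign(cox.coef).astype(int)
    with np.errstate(over="ignore"):
        hr = np.exp(cox.coef)
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "cohort_id": cohort_id,
            "hr": hr,
            "p": lr.p,
            "direction": direction,
            "p_wald": cox.p,
            "coef": cox.coef,
            "se": cox.se,
        }
    ).reset_index(drop=True)


def probe_cohort_test(
    expression_vector, time, event, *, probe_id: str = "probe", cohort_id: str = "cohort"
) -> ProbeCohortResult:
    """Median-split HR, log-rank p, and direction for a single probe."""
    values = np.asarray(expression_vector, dtype=float).ravel()
    median_split(values)  # validates feasibility; grid path recomputes the labels
    df = probe_cohort_grid(
        pd.DataFrame([values], index=[probe_id]), time, event, cohort_id=cohort_id
    )
    row = df.iloc[0]
    return ProbeCohortResult(
        probe_id=probe_id,
        cohort_id=cohort_id,
        hr=float(row["hr"]),
        p=float(row["p"]),
        direction=int(row["direction"]),
        p_wald=float(row["p_wald"]),
        coef=float(row["coef"]),
        se=float(row["se"]),
    )


# ---------------------------------------------------------------------------
# consensus vote
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsensusCriteria:
    """Vote thresholds: same direction everywhere, p < alpha in >= min_significant cohorts."""

    alpha: float = 0.05
    min_significant: int = 6
    n_cohorts: int = 7
    require_all_same_direction: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.min_significant <= self.n_cohorts:
            raise ValueError("min_significant must be between 0 and n_cohorts")
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be positive")


def consensus_select(grid: pd.DataFrame, criteria: ConsensusCriteria) -> list[str]:
    """Apply the consensus vote to a complete probe x cohort grid.

    ``grid`` is a long DataFrame with columns ``probe_id, cohort_id, hr, p,
    direction`` (as produced by :func:`probe_cohort_grid` over each cohort).
    Every probe must be measured in every cohort; an incomplete grid is an
    error listing the missing cells.  The returned probe ids are sorted.
    """
    required = {"probe_id", "cohort_id", "p", "direction"}
    if not required <= set(grid.columns):
        raise ValueError(f"grid must have columns {sorted(required)}")
    cohorts = pd.unique(grid["cohort_id"])
    if len(cohorts) != criteria.n_cohorts:
        raise ValueError(
            f"grid has {len(cohorts)} cohorts but criteria expect {criteria.n_cohorts}"
        )
    pmat = grid.pivot(index="probe_id", columns="cohort_id", values="p")
    dmat = grid.pivot(index="probe_id", columns="cohort_id", values="direction")
    missing = pmat.isna() | dmat.isna()
    if missing.to_numpy().any():
        cells = [
            (probe, cohort)
            for probe, row in missing.iterrows()
            for cohort, miss in row.items()
            if miss
        ]
        raise ValueError(f"incomplete grid: {len(cells)} missing cells, first {cells[:10]}")

    n_sig = (pmat.to_numpy() < criteria.alpha).sum(axis=1)
    ok = n_sig >= criteria.min_significant
    if criteria.require_all_same_direction:
        darr = dmat.to_numpy()
        same = (darr == darr[:, [0]]).all(axis=1) & (darr[:, 0] != 0)
        ok &= same
    return sorted(pmat.index[ok].tolist())


class ConsensusSelector(SelectorMixin, BaseEstimator):
    """Consensus feature selector over multiple survival cohorts.

    scikit-learn style: ``fit(X, y, groups=...)`` with ``X`` of shape
    (n_samples, n_probes) pooled over cohorts, ``y`` the survival outcome
    ((n, 2) ``[time, event]`` array, DataFrame, or structured array), and
    ``groups`` the cohort label of each sample.  ``transform`` keeps the
    selected probes.

    Attributes
    ----------
    results_ : DataFrame
        The long probe x cohort grid of HR / log-rank p / direction.
    selected_ids_ : list of str
        Probes passing the consensus vote, sorted.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        min_significant: int = 6,
        require_all_same_direction: bool = True,
        ties: str = "efron",
    ):
        self.alpha = alpha
        self.min_significant = min_significant
        self.require_all_same_direction = require_all_same_direction
        self.ties = ties

    def fit(self, X, y, groups=None):
        if groups is None:
            raise ValueError("ConsensusSelector requires per-sample cohort labels (groups=)")
        time, event = _unpack_y(y)
        if isinstance(X, pd.DataFrame):
            probe_ids = [str(c) for c in X.columns]
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            probe_ids = [f"x{j}" for j in range(Xa.shape[1])]
        groups = np.asarray(groups).ravel()
        if groups.size != Xa.shape[0]:
            raise ValueError("groups must align with samples")
        cohort_ids = pd.unique(groups)
        frames = []
        for cid in cohort_ids:
            m = groups == cid
            frames.append(
                probe_cohort_grid(
                    pd.DataFrame(Xa[m].T, index=probe_ids),
                    time[m],
                    event[m],
                    cohort_id=str(cid),
                    ties=self.ties,
                )
            )
        self.results_ = pd.concat(frames, ignore_index=True)
        criteria = ConsensusCriteria(
            alpha=self.alpha,
            min_significant=self.min_significant,
            n_cohorts=len(cohort_ids),
            require_all_same_direction=self.require_all_same_direction,
        )
        self.criteria_ = criteria
        self.selected_ids_ = consensus_select(self.results_, criteria)
        self.n_features_in_ = Xa.shape[1]
        self.feature_names_in_ = np.asarray(probe_ids, dtype=object)
        sel = set(self.selected_ids_)
        self.support_ = np.array([p in sel for p in probe_ids])
        return self

    def _get_support_mask(self):
        if not hasattr(self, "support_"):
            raise RuntimeError("ConsensusSelector instance is not fitted")
        return self.support_


# ---------------------------------------------------------------------------
# type-I error calculus
# ---------------------------------------------------------------------------

def analytic_type1(
    n_cohorts: int,
    min_significant: int,
    alpha: float,
    *,
    require_all_same_direction: bool = False,
) -> float:
    """Per-probe type-I error rate of the consensus vote.

    The significance-count component is the binomial tail
    P(X >= min_significant) with X ~ Binomial(n_cohorts, alpha): under the
    null each cohort's two-sided test rejects independently with
    probability alpha.  With ``require_all_same_direction`` the rate is
    additionally multiplied by P(all n signs equal) = 2^(1 - n) under an
    independent, symmetric-sign null (sign and |statistic| of a symmetric
    two-sided test are independent under the null, so the product is exact
    for that model).
    """
    crit = ConsensusCriteria(
        alpha=alpha, min_significant=min_significant, n_cohorts=n_cohorts
    )
    rate = float(stats.binom.sf(crit.min_significant - 1, crit.n_cohorts, crit.alpha))
    if require_all_same_direction:
        rate *= 2.0 ** (1 - crit.n_cohorts)
    return rate


def bonferroni_fwer(per_test_rate: float, n_tests: int) -> float:
    """Bonferroni family-wise error bound: min(1, n_tests * per_test_rate)."""
    if n_tests < 1 or not 0 <= per_test_rate <= 1:
        raise ValueError("need n_tests >= 1 and a rate in [0, 1]")
    return min(1.0, n_tests * per_test_rate)


@dataclass(frozen=True)
class MonteCarloType1Result:
    estimate: float
    ci_low: float
    ci_high: float
    n_hits: int
    n_replicates: int
    analytic: float


def monte_carlo_type1(
    criteria: ConsensusCriteria,
    n_replicates: int,
    cohort_sizes,
    seed: int,
    *,
    baseline_hazard: float = 0.01,
    censoring_rate: float = 0.005,
    admin_cutoff: float = 120.0,
    confidence: float = 0.95,
) -> MonteCarloType1Result:
    """Empirical per-probe type-I error of the consensus vote on null cohorts.

    For each replicate a fresh set of null cohorts is simulated (expression
    independent of outcome; exponential event times with exponential plus
    administrative censoring), the median-split log-rank p and effect
    direction are computed per cohort, and the vote is applied.  Refuses to
    run when the analytic rate predicts fewer than 10 hits, since the
    estimate would be uninformative.

    Returns the hit fraction with a Wilson binomial confidence interval and
    the analytic rate for the same criteria.
    """
    cohort_sizes = [int(s) for s in cohort_sizes]
    if len(cohort_sizes) != criteria.n_cohorts:
        raise ValueError("cohort_sizes length must equal criteria.n_cohorts")
    if any(s < 4 for s in cohort_sizes):
        raise ValueError("cohort sizes must be >= 4 for a median split")
    if baseline_hazard <= 0 or censoring_rate < 0 or admin_cutoff < 0:
        raise ValueError("rates must be positive and cutoff non-negative")
    analytic = analytic_type1(
        criteria.n_cohorts,
        criteria.min_significant,
        criteria.alpha,
        require_all_same_direction=criteria.require_all_same_direction,
    )
    expected_hits = analytic * n_replicates
    if expected_hits < 10:
        raise ValueError(
            f"expected hit count {expected_hits:.2f} < 10 under the analytic rate "
            f"{analytic:.3g}; relax the criteria or raise n_replicates"
        )

    children = np.random.SeedSequence(seed).spawn(criteria.n_cohorts)
    R = int(n_replicates)
    p_all = np.empty((criteria.n_cohorts, R))
    dir_all = np.empty((criteria.n_cohorts, R))
    for c, (n, ss) in enumerate(zip(cohort_sizes, children)):
        rng = np.random.default_rng(ss)
        t_event = rng.exponential(1.0 / baseline_hazard, size=(R, n))
        if censoring_rate > 0:
            t_cens = rng.exponential(1.0 / censoring_rate, size=(R, n))
        else:
            t_cens = np.full((R, n), np.inf)
        t_cens = np.minimum(t_cens, admin_cutoff)
        time = np.minimum(t_event, t_cens)
        event = t_event <= t_cens
        expr = rng.standard_normal((R, n))
        labels = expr > np.median(expr, axis=1, keepdims=True)

        order = np.argsort(time, axis=1)
        ev = np.take_along_axis(event, order, axis=1).astype(float)
        lab = np.take_along_axis(labels, order, axis=1).astype(float)
        # event times are continuous, hence untied a.s.; at-risk count at sorted
        # position j is n - j and each event contributes d = 1
        nk = (n - np.arange(n)).astype(float)
        n1 = np.cumsum(lab[:, ::-1], axis=1)[:, ::-1]
        frac = n1 / nk
        score = (ev * (lab - frac)).sum(axis=1)
        # with d = 1 the tie correction (nk - d)/(nk - 1) is 1 (and the term
        # vanishes at nk = 1), so the hypergeometric variance is frac*(1-frac)
        var = (ev * frac * (1 - frac)).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(var > 0, score**2 / var, 0.0)
        p_all[c] = np.where(var > 0, stats.chi2.sf(chi2, df=1), 1.0)
        dir_all[c] = np.sign(score)

    n_sig = (p_all < criteria.alpha).sum(axis=0)
    hits = n_sig >= criteria.min_significant
    if criteria.require_all_same_direction:
        same = (dir_all == dir_all[[0]]).all(axis=0) & (dir_all[0] != 0)
        hits &= same
    n_hits = int(hits.sum())
    ci = stats.binomtest(n_hits, R).proportion_ci(confidence_level=confidence, method="wilson")
    return MonteCarloType1Result(
        estimate=n_hits / R,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n_hits=n_hits,
        n_replicates=R,
        analytic=analytic,
    )
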