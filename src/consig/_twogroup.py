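"""Vectorised two-group survival statistics for probe grids.

A probe screen evaluates tens of thousands of median splits against one
cohort's fixed outcomes.  For a binary covariate the partial likelihood
depends on the data only through per-event-time at-risk and event counts
in the high group, so both the log-rank test and the two-group Cox fit can
be evaluated for a whole (probes x samples) label matrix at once with
cumulative-sum tricks.  Agreement with the scalar implementations in
:mod:`consig.survival` is enforced by tests to 1e-8.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats

_SEPARATION_BOUND = 30.0


class TwoGroupTables(NamedTuple):
    """Per-event-time risk/event tables for a batch of binary labelings."""

    event_times: np.ndarray  # (K,)
    n_at_risk: np.ndarray    # (K,) total at risk
    n1: np.ndarray           # (P, K) at risk in group 1 (label True)
    d: np.ndarray            # (K,) events
    d1: np.ndarray           # (P, K) events in group 1


def two_group_tables(time, event, labels) -> TwoGroupTables:
    """Tabulate at-risk and event counts per unique event time.

    ``labels`` is a (P, n) boolean matrix; each row is one grouping of the
    same n samples.  Ties between censored and event times keep the
    censored observation at risk (time >= t convention).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=np.int64)
    labels = np.atleast_2d(np.asarray(labels, dtype=bool))
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    L = labels[:, order]
    ev_pos = np.flatnonzero(e == 1)
    if ev_pos.size == 0:
        empty = np.zeros((labels.shape[0], 0))
        z = np.zeros(0)
        return TwoGroupTables(z, z, empty, z, empty)
    t_ev = t[ev_pos]
    event_times, first = np.unique(t_ev, return_index=True)
    start = np.searchsorted(t, event_times, side="left")
    n_at_risk = (t.size - start).astype(float)
    suffix = np.cumsum(L[:, ::-1], axis=1)[:, ::-1].astype(float)
    n1 = suffix[:, start]
    d = np.add.reduceat(np.ones(ev_pos.size), first)
    d1 = np.add.reduceat(L[:, ev_pos].astype(float), first, axis=1)
    return TwoGroupTables(event_times, n_at_risk, n1, d, d1)


class LogRankGrid(NamedTuple):
    statistic: np.ndarray  # (P,) chi-square
    p: np.ndarray          # (P,)
    score: np.ndarray      # (P,) observed - expected in group 1 (signed)


def logrank_grid(tables: TwoGroupTables) -> LogRankGrid:
    """Log-rank chi-square and p for every labeling in the batch."""
    nk, n1, d, d1 = tables.n_at_risk, tables.n1, tables.d, tables.d1
    P = n1.shape[0]
    if d.size == 0:
        return LogRankGrid(np.zeros(P), np.ones(P), np.zeros(P))
    frac = n1 / nk
    score = (d1 - d * frac).sum(axis=1)
    denom = np.where(nk > 1, nk - 1, 1.0)
    var = (d * frac * (1 - frac) * (nk - d) / denom).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(var > 0, score**2 / var, 0.0)
    p = np.where(var > 0, stats.chi2.sf(chi2, df=1), 1.0)
    return LogRankGrid(chi2, p, score)


class CoxTwoGroupGrid(NamedTuple):
    coef: np.ndarray       # (P,) log HR, group 1 (True) vs group 0; +/-inf when separated
    se: np.ndarray         # (P,) nan when separated
    p: np.ndarray          # (P,) Wald p; nan when separated
    separated: np.ndarray  # (P,) bool


def cox_two_group_grid(
    tables: TwoGroupTables,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 60,
) -> CoxTwoGroupGrid:
    """Two-group Cox fits for every labeling in the batch.

    Scalar Newton-Raphson per probe, run in parallel across probes.  With
    a binary covariate the Efron (or Breslow) partial likelihood reduces to
    sums over (event time, tie index) pairs of log(A0 + e^b * A1) with
    constant A0, A1, which vectorises cleanly.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    nk, n1, d, d1 = tables.n_at_risk, tables.n1, tables.d, tables.d1
    P, K = n1.shape
    if K == 0:
        nan = np.full(P, np.nan)
        return CoxTwoGroupGrid(np.zeros(P), nan, nan, np.zeros(P, dtype=bool))

    d_int = d.astype(np.int64)
    M = int(d_int.sum())
    idx = np.repeat(np.arange(K), d_int)
    ell = np.arange(M) - np.repeat(np.cumsum(d_int) - d_int, d_int)
    frac = (ell / d[idx]) if ties == "efron" else np.zeros(M)

    n0 = nk - n1
    d0 = d - d1
    A1 = n1[:, idx] - frac * d1[:, idx]  # (P, M)
    A0 = n0[:, idx] - frac * d0[:, idx]
    D1 = d1.sum(axis=1)  # (P,)

    beta = np.zeros(P)
    active = np.ones(P, dtype=bool)
    separated = np.zeros(P, dtype=bool)
    info = np.full(P, np.nan)
    for _ in range(max_iter):
        r = np.exp(beta)
        w = (r[:, None] * A1) / (A0 + r[:, None] * A1)
        grad = D1 - w.sum(axis=1)
        cur_info = (w * (1.0 - w)).sum(axis=1)
        info = cur_info
        bad = active & (cur_info <= 1e-12)
        separated |= bad
        active &= ~bad
        step = np.zeros(P)
        np.divide(grad, cur_info, out=step, where=active)
        np.clip(step, -2.0, 2.0, out=step)  # guard rare Newton overshoot; inert near optimum
        beta = np.where(active, beta + step, beta)
        newly_sep = active & (np.abs(beta) > _SEPARATION_BOUND)
        separated |= newly_sep
        active &= ~newly_sep
        active &= np.abs(step) >= tol
        if not active.any():
            break

    se = np.where(~separated & (info > 0), 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.nan)
    coef = beta.copy()
    # separated probes: report the sign via the score at 0, magnitude as +/-inf
    if separated.any():
        w0 = A1 / (A0 + A1)
        score0 = D1 - w0.sum(axis=1)
        coef[separated] = np.where(score0[separated] >= 0, np.inf, -np.inf)
    with np.errstate(invalid="ignore"):
        wald = 2.0 * stats.norm.sf(np.abs(coef) / se)
    wald = np.where(separated, np.nan, wald)
    return CoxTwoGroupGrid(coef, se, wald, separated)
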