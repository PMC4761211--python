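"""Per-cohort and aggregate evaluation of a signature.

For each cohort: Kaplan-Meier curves and a two-group Cox fit on the
median-split score, a Cox fit on the continuous score, a multivariate fit
adjusting for stage and age and stratifying by gender, and quartile
curves.  Per-cohort hazard ratios are aggregated into a forest table whose
summary row is the cohort-size-weighted mean HR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .scoring import ScoreVector, SignatureDef, signature_score, stratify
from .survival import (
    CoxFitResult,
    KMCurve,
    cox_fit,
    km_estimate,
    logrank_test,
    weighted_mean_hr,
)

logger = logging.getLogger(__name__)

FIT_TYPES = ("median_split", "continuous", "multivariate")


def apply_inclusion(
    clinical: pd.DataFrame,
    stages=("I", "II"),
    require_untreated: bool = True,
) -> pd.DataFrame:
    """Filter a clinical table to the included stages and, optionally, untreated patients.

    ``treated`` (0/1 or boolean column), when present, flags patients who
    received adjuvant/neoadjuvant therapy; with ``require_untreated`` those
    rows are removed.  Counts removed per criterion are logged.
    """
    stages = set(stages)
    if not stages:
        raise ValueError("inclusion stage set must be non-empty")
    if "stage" not in clinical.columns:
        raise ValueError("clinical table has no 'stage' column")
    kept = clinical[clinical["stage"].isin(stages)]
    logger.info("inclusion: %d of %d rows pass the stage filter", len(kept), len(clinical))
    if require_untreated:
        if "treated" in kept.columns:
            n_before = len(kept)
            kept = kept[~kept["treated"].astype(bool)]
            logger.info("inclusion: removed %d treated rows", n_before - len(kept))
        else:
            warnings.warn("no 'treated' column; keeping all stage-passing rows")
    if kept.empty:
        raise ValueError("no samples pass the inclusion criteria")
    return kept.reset_index(drop=True)


def censor_at_treatment(clinical: pd.DataFrame) -> pd.DataFrame:
    """Censor follow-up at the initiation of treatment.

    Rows whose ``treatment_start`` precedes the observed time get their
    time replaced by ``treatment_start`` and their event set to 0, creating
    a subcohort unexposed to treatment during follow-up.  Missing
    ``treatment_start`` values leave rows unchanged.
    """
    if "treatment_start" not in clinical.columns:
        raise ValueError("clinical table has no 'treatment_start' column")
    ts = pd.to_numeric(clinical["treatment_start"], errors="coerce")
    if (ts.dropna() < 0).any():
        raise ValueError("negative treatment_start")
    out = clinical.copy()
    mask = ts.notna() & (ts < out["time"])
    out.loc[mask, "time"] = ts[mask]
    out.loc[mask, "event"] = 0
    return out


@dataclass
class CohortEvaluation:
    """All per-cohort results for one signature, on one included-sample set."""

    cohort_id: str
    n: int
    n_events: int
    score: ScoreVector
    groups: np.ndarray                      # 1 = low, 2 = high (median split)
    hr_median_split: CoxFitResult
    logrank_stat: float
    logrank_p: float
    hr_continuous: CoxFitResult
    hr_multivariate: CoxFitResult | None
    km_curves: dict = field(default_factory=dict)        # "low"/"high" -> KMCurve
    quartile_curves: dict = field(default_factory=dict)  # "q1".."q4" -> KMCurve


def evaluate_cohort(
    expression: ExpressionMatrix,
    clinical: pd.DataFrame,
    signature: SignatureDef,
    *,
    cohort_id: str = "cohort",
    multivariate_continuous: bool = False,
    ties: str = "efron",
) -> CohortEvaluation:
    """Full evaluation of one signature in one cohort.

    All fits use the identical included-sample set (the intersection of
    expression and clinical samples, in clinical order).  The multivariate
    fit uses the median-split group indicator (or the continuous score if
    ``multivariate_continuous``), a stage II-vs-I indicator, and age, and
    stratifies by gender; it is skipped with a warning when a covariate is
    constant or a required column is absent.
    """
    shared = [s for s in clinical["sample_id"] if s in set(expression.sample_ids)]
    if not shared:
        raise ValueError("no shared samples between expression and clinical tables")
    clin = clinical.set_index("sample_id").loc[shared].reset_index()
    expr = expression.subset_samples(shared)
    time = clin["time"].to_numpy(dtype=float)
    event = clin["event"].to_numpy()

    sv = signature_score(expr, signature)
    values = sv.score.to_numpy(dtype=float)
    groups = stratify(values, 2)
    high = groups == 2

    hr_split = cox_fit(
        high.astype(float)[:, None], time, event, ties=ties, names=["score_high"]
    )
    lr = logrank_test(time, event, high.astype(int))
    km_curves = {
        "low": km_estimate(time[~high], event[~high]),
        "high": km_estimate(time[high], event[high]),
    }

    hr_cont = cox_fit(values[:, None], time, event, ties=ties, names=["score"])

    hr_multi = None
    needed = {"stage", "age", "gender"}
    if needed <= set(clin.columns):
        score_term = values if multivariate_continuous else high.astype(float)
        term_name = "score" if multivariate_continuous else "score_high"
        X = np.column_stack(
            [score_term, (clin["stage"] == "II").to_numpy(float), clin["age"].to_numpy(float)]
        )
        try:
            hr_multi = cox_fit(
                X,
                time,
                event,
                strata=clin["gender"].to_numpy(),
                ties=ties,
                names=[term_name, "stage_II", "age"],
            )
        except ValueError as exc:
            warnings.warn(f"multivariate fit skipped for {cohort_id}: {exc}")
    else:
        warnings.warn(
            f"multivariate fit skipped for {cohort_id}: missing columns "
            f"{sorted(needed - set(clin.columns))}"
        )

    quartiles = stratify(values, 4)
    quartile_curves = {
        f"q{q}": km_estimate(time[quartiles == q], event[quartiles == q])
        for q in (1, 2, 3, 4)
        if (quartiles == q).any()
    }

    return CohortEvaluation(
        cohort_id=cohort_id,
        n=len(shared),
        n_events=int(np.asarray(event, dtype=float).sum()),
        score=sv,
        groups=groups,
        hr_median_split=hr_split,
        logrank_stat=lr.statistic,
        logrank_p=lr.p,
        hr_continuous=hr_cont,
        hr_multivariate=hr_multi,
        km_curves=km_curves,
        quartile_curves=quartile_curves,
    )


def aggregate(evaluations: list[CohortEvaluation]) -> pd.DataFrame:
    """Forest table: per-cohort HR rows plus a weighted-mean summary row per fit type.

    Weights are the included cohort sizes.  The summary row carries the
    full-precision weighted mean in ``hr`` and the 1-decimal rounding in
    ``hr_rounded``; cohorts whose multivariate fit was skipped are omitted
    from that fit type's rows and weights.
    """
    if not evaluations:
        raise ValueError("need at least one cohort evaluation")
    rows = []
    for fit_type in FIT_TYPES:
        hrs, weights, events = [], [], []
        for ev in evaluations:
            res = {
                "median_split": ev.hr_median_split,
                "continuous": ev.hr_continuous,
                "multivariate": ev.hr_multivariate,
            }[fit_type]
            if res is None:
                continue
            rec = res.single() if len(res.names) == 1 else _first_covariate(res)
            rows.append(
                {
                    "fit": fit_type,
                    "cohort_id": ev.cohort_id,
                    "hr": rec["hr"],
                    "hr_rounded": round(rec["hr"], 1),
                    "ci_low": rec["ci_low"],
                    "ci_high": rec["ci_high"],
                    "p": rec["p"],
                    "n": ev.n,
                    "n_events": ev.n_events,
                }
            )
            hrs.append(rec["hr"])
            weights.append(ev.n)
            events.append(ev.n_events)
        if hrs:
            wm = weighted_mean_hr(hrs, weights)
            rows.append(
                {
                    "fit": fit_type,
                    "cohort_id": "weighted_mean",
                    "hr": wm,
                    "hr_rounded": round(wm, 1),
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p": np.nan,
                    "n": int(np.sum(weights)),
                    "n_events": int(np.sum(events)),
                }
            )
    return pd.DataFrame(rows)


def _first_covariate(res: CoxFitResult) -> dict:
    """Score-term row of a multivariate fit (the score enters first)."""
    return {
        "hr": float(res.hr[0]),
        "ci_low": float(res.ci_low[0]),
        "ci_high": float(res.ci_high[0]),
        "p": float(res.p[0]),
    }


def normalize_by_sample_mean(expression: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample's values by that sample's mean (linear-scale data).

    Intended for RNA-seq style gene-normalized abundance values; each
    normalized sample has mean exactly 1, and the operation is invariant to
    per-sample scale factors.  The output stays flagged linear — log2(x+1)
    is applied at scoring time.
    """
    vals = expression.values
    if expression.scale != "linear":
        raise ValueError("per-sample mean normalization expects linear-scale values")
    if (vals.to_numpy() < 0).any():
        raise ValueError("negative values in a linear-scale matrix")
    means = vals.mean(axis=0)
    zero = means[means == 0]
    if len(zero):
        raise ValueError(f"zero-mean sample(s): {list(zero.index[:5])}")
    return ExpressionMatrix(vals / means, scale="linear")
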