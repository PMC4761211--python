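"""Signature scores and score-based risk stratification.

A signature is an ordered list of probe identifiers; the per-sample score
is the unweighted mean of the log2 expression of the signature probes.
Stratification cuts the score at empirical quantiles, with ties at a cut
point assigned to the lower group — the same "<= median goes low"
convention as the per-probe median split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.base import BaseEstimator, TransformerMixin

from .matrix import ExpressionMatrix
from .selection import median_split


@dataclass(frozen=True)
class SignatureDef:
    """Named, ordered list of probe identifiers defining a score."""

    name: str
    probe_ids: tuple

    def __post_init__(self) -> None:
        if len(self.probe_ids) == 0:
            raise ValueError("signature must contain at least one probe id")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("signature probe ids must be unique")
        object.__setattr__(self, "probe_ids", tuple(str(p) for p in self.probe_ids))


def load_signature(path, name: str | None = None) -> SignatureDef:
    """Read a signature file: one probe id per line.

    A first line starting with ``>`` names the signature (FASTA-like);
    ``#`` lines are comments.  ``name`` overrides any name in the file.
    """
    probes: list[str] = []
    file_name = None
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                if probes:
                    raise ValueError("signature name line must come first")
                file_name = line[1:].strip()
                continue
            probes.append(line.split("\t")[0])
    sig_name = name or file_name or "signature"
    return SignatureDef(name=sig_name, probe_ids=tuple(probes))


def esla7_signature() -> SignatureDef:
    """The packaged ESLA-7 probe-set signature (seven HG-U133A probe sets)."""
    ref = resources.files("consig.signatures").joinpath("esla7.txt")
    with resources.as_file(ref) as path:
        return load_signature(path)


@dataclass(frozen=True)
class ScoreVector:
    """Per-sample signature scores with provenance metadata."""

    score: pd.Series          # index: sample ids
    signature: str
    n_probes_used: int

    @property
    def sample_ids(self) -> pd.Index:
        return self.score.index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.score.index, "score": self.score.to_numpy()})


def signature_score(expression, signature: SignatureDef) -> ScoreVector:
    """Per-sample mean log2 expression over the signature probes.

    Probes absent from the matrix are skipped with a warning and reflected
    in ``n_probes_used``; zero overlap is an error.  Matrices flagged as
    linear scale are transformed with log2(x + 1) first.
    """
    if not isinstance(expression, ExpressionMatrix):
        expression = ExpressionMatrix(pd.DataFrame(expression))
    vals = expression.values
    if expression.scale == "linear":
        vals = np.log2(vals + 1.0)
    present = [p for p in signature.probe_ids if p in vals.index]
    if not present:
        raise ValueError(
            f"no probe of signature {signature.name!r} is present in the matrix"
        )
    missing = len(signature.probe_ids) - len(present)
    if missing:
        warnings.warn(
            f"signature {signature.name!r}: {missing} probe(s) absent from the matrix; "
            f"scoring over the {len(present)} present"
        )
    score = vals.loc[present].mean(axis=0)
    score.name = signature.name
    return ScoreVector(score=score, signature=signature.name, n_probes_used=len(present))


def _score_values(scores) -> np.ndarray:
    if isinstance(scores, ScoreVector):
        return scores.score.to_numpy(dtype=float)
    if isinstance(scores, pd.Series):
        return scores.to_numpy(dtype=float)
    return np.asarray(scores, dtype=float).ravel()


def stratify(scores, n_groups: int = 2) -> np.ndarray:
    """Quantile groups of (nearly) equal size; label 1 = lowest scores.

    Cut points are the empirical quantiles at k/n_groups; a score exactly
    equal to a cut point goes to the lower group.  Raises when ties leave
    any group empty.
    """
    if n_groups not in (2, 4):
        raise ValueError("n_groups must be 2 (median split) or 4 (quartiles)")
    values = _score_values(scores)
    if np.unique(values).size < n_groups:
        raise ValueError(f"need at least {n_groups} distinct score values")
    cuts = np.quantile(values, [k / n_groups for k in range(1, n_groups)])
    labels = 1 + np.sum(values[:, None] > cuts[None, :], axis=1)
    counts = np.bincount(labels, minlength=n_groups + 1)[1:]
    if (counts == 0).any():
        raise ValueError("too many tied scores to form non-empty groups")
    if n_groups == 2:
        # must agree with the probe-level median-split convention
        assert np.array_equal(labels == 2, median_split(values))
    return labels


def score_correlation(a, b) -> float:
    """Pearson correlation of two score vectors over their shared samples."""
    sa = a.score if isinstance(a, ScoreVector) else pd.Series(a)
    sb = b.score if isinstance(b, ScoreVector) else pd.Series(b)
    shared = sa.index.intersection(sb.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    x = sa.loc[shared].to_numpy(dtype=float)
    y = sb.loc[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the score vectors")
    return float(sp_stats.pearsonr(x, y).statistic)


class SignatureScorer(TransformerMixin, BaseEstimator):
    """Transformer computing a signature score from samples x probes data.

    ``transform(X)`` with a DataFrame (samples as rows, probes as columns)
    returns an (n, 1) array of scores.  ``assume_log2`` mirrors the matrix
    scale flag for plain arrays.
    """

    def __init__(self, signature: SignatureDef | None = None, assume_log2: bool = True):
        self.signature = signature
        self.assume_log2 = assume_log2

    def fit(self, X, y=None):
        if self.signature is None:
            raise ValueError("SignatureScorer requires a signature")
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        if self.signature is None:
            raise ValueError("SignatureScorer requires a signature")
        if not isinstance(X, pd.DataFrame):
            raise ValueError("SignatureScorer needs a DataFrame with probe-id columns")
        em = ExpressionMatrix(X.T, scale="log2" if self.assume_log2 else "linear")
        sv = signature_score(em, self.signature)
        return sv.score.to_numpy(dtype=float)[:, None]

    def get_feature_names_out(self, input_features=None):
        name = self.signature.name if self.signature else "score"
        return np.asarray([name], dtype=object)


class QuantileStratifier(TransformerMixin, BaseEstimator):
    """Quantile-group transformer; fit learns cut points, transform labels.

    ``fit_transform`` on one cohort reproduces :func:`stratify` exactly.
    Labels are 1..n_groups with 1 = lowest; ties at a cut point go low.
    """

    def __init__(self, n_groups: int = 2):
        self.n_groups = n_groups

    def fit(self, X, y=None):
        if self.n_groups not in (2, 4):
            raise ValueError("n_groups must be 2 or 4")
        values = np.asarray(X, dtype=float).ravel()
        if np.unique(values).size < self.n_groups:
            raise ValueError(f"need at least {self.n_groups} distinct values")
        self.cutpoints_ = np.quantile(
            values, [k / self.n_groups for k in range(1, self.n_groups)]
        )
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        if not hasattr(self, "cutpoints_"):
            raise RuntimeError("QuantileStratifier instance is not fitted")
        values = np.asarray(X, dtype=float).ravel()
        labels = 1 + np.sum(values[:, None] > self.cutpoints_[None, :], axis=1)
        return labels
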