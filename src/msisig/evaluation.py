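"""Binary-classifier evaluation of signature scores against MSI labels.

The empirical AUC is the Mann–Whitney statistic: the fraction of
(positive, negative) score pairs won by the positive, ties counting one
half.  Its sampling variance comes from DeLong's nonparametric estimator
built on per-observation structural components, giving normal-approximation
confidence intervals.  MSI-high is always the positive class and a higher
score always argues for it — there is no automatic direction flipping, so
an inverted signature shows up as AUC < 0.5 rather than being hidden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .expression import ExpressionMatrix, quantile_normalize
from .pcr import MSIStatus
from .signatures import (
    AdditiveSignature,
    DanaherSignature,
    ScoreVector,
    builtin_signatures,
    score_signature,
)


class EvaluationError(ValueError):
    """Raised for cohorts that cannot support the requested estimate."""


@dataclass(frozen=True)
class LabeledCohort:
    """Sample → MSI status map; MSI-high is the positive class."""

    labels: Mapping[str, MSIStatus]

    @classmethod
    def from_series(cls, s: pd.Series) -> "LabeledCohort":
        return cls({str(k): MSIStatus(v) for k, v in s.items()})

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels)

    @property
    def n_pos(self) -> int:
        return sum(v is MSIStatus.MSI_HIGH for v in self.labels.values())

    @property
    def n_neg(self) -> int:
        return sum(v is MSIStatus.MSI_LOW_MSS for v in self.labels.values())

    def to_series(self) -> pd.Series:
        return pd.Series({k: v.value for k, v in self.labels.items()}, name="status")


@dataclass(frozen=True)
class ROCResult:
    """Empirical AUC with DeLong variance and confidence interval."""

    auc: float
    variance: float
    ci_low: float
    ci_high: float
    alpha: float
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.auc <= 1.0
        assert self.variance >= 0.0
        assert self.ci_low <= self.auc <= self.ci_high


def _split_scores(scores: ScoreVector | pd.Series, cohort: LabeledCohort):
    s = scores.scores if isinstance(scores, ScoreVector) else scores
    unlabeled = [sid for sid in s.index if sid not in cohort.labels]
    if unlabeled:
        raise EvaluationError(f"scored samples without labels: {unlabeled}")
    pos = np.asarray(
        [s[sid] for sid in s.index if cohort.labels[sid] is MSIStatus.MSI_HIGH],
        dtype=float,
    )
    neg = np.asarray(
        [s[sid] for sid in s.index if cohort.labels[sid] is MSIStatus.MSI_LOW_MSS],
        dtype=float,
    )
    return pos, neg


def _psi_matrix(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Pairwise Mann–Whitney kernel: 1 if pos > neg, 0.5 if tied, else 0."""
    diff = pos[:, None] - neg[None, :]
    return np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))


def roc_auc(scores: ScoreVector | pd.Series, cohort: LabeledCohort) -> float:
    """Empirical AUC in the Mann–Whitney form; higher score = MSI-high."""
    pos, neg = _split_scores(scores, cohort)
    if len(pos) == 0 or len(neg) == 0:
        raise EvaluationError("AUC needs at least one sample in each class")
    return float(_psi_matrix(pos, neg).mean())


def delong_ci(
    scores: ScoreVector | pd.Series,
    cohort: LabeledCohort,
    alpha: float = 0.05,
) -> ROCResult:
    """AUC with DeLong variance and a (1−alpha) normal-approximation CI.

    Structural components: V10_i = mean_j psi(x_i, y_j) over negatives,
    V01_j = mean_i psi(x_i, y_j) over positives; the variance is
    S10/m + S01/n with S10, S01 the n−1 sample variances of V10, V01 and
    m, n the positive and negative counts.  The CI is clipped to [0, 1].
    """
    pos, neg = _split_scores(scores, cohort)
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise EvaluationError(
            "DeLong variance needs >= 2 samples per class; use roc_auc alone"
        )
    psi = _psi_matrix(pos, neg)
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # one per positive
    v01 = psi.mean(axis=0)  # one per negative
    variance = float(v10.var(ddof=1) / m + v01.var(ddof=1) / n)
    z = norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(variance)
    return ROCResult(
        auc=auc,
        variance=variance,
        ci_low=float(np.clip(auc - half, 0.0, 1.0)),
        ci_high=float(np.clip(auc + half, 0.0, 1.0)),
        alpha=alpha,
        n_pos=m,
        n_neg=n,
    )


def evaluate_cohort(
    matrix: ExpressionMatrix,
    cohort: LabeledCohort,
    signatures: tuple[AdditiveSignature | DanaherSignature, ...] | None = None,
    normalize: bool = True,
    pseudocount: float = 1.0,
    alpha: float = 0.05,
    missing_policy: str = "error",
) -> tuple[pd.DataFrame, dict[str, ScoreVector]]:
    """Score all signatures on a labeled cohort and tabulate AUC + CI.

    Returns the report table (one row per signature: auc, ci_low, ci_high,
    variance, n_pos, n_neg) and the per-signature score vectors for
    downstream plotting of class-wise score distributions.
    """
    unlabeled = [sid for sid in matrix.sample_ids if sid not in cohort.labels]
    if unlabeled:
        raise EvaluationError(f"samples without labels: {unlabeled}")
    if signatures is None:
        signatures = builtin_signatures()
    if normalize:
        matrix = quantile_normalize(matrix)
    rows = []
    score_vectors: dict[str, ScoreVector] = {}
    for sig in signatures:
        sv = score_signature(matrix, sig, pseudocount, missing_policy)
        res = delong_ci(sv, cohort, alpha)
        score_vectors[sig.name] = sv
        rows.append(
            {
                "signature": sig.name,
                "auc": res.auc,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "variance": res.variance,
                "n_pos": res.n_pos,
                "n_neg": res.n_neg,
            }
        )
    return pd.DataFrame(rows), score_vectors


def score_histograms(
    score_vectors: Mapping[str, ScoreVector],
    cohort: LabeledCohort,
    bins: int = 20,
) -> pd.DataFrame:
    """Class-wise score histogram data (long format) for each signature."""
    rows = []
    for name, sv in score_vectors.items():
        values = sv.scores.to_numpy(dtype=float)
        edges = np.histogram_bin_edges(values, bins=bins)
        for status in MSIStatus:
            members = [
                sid for sid in sv.scores.index if cohort.labels[sid] is status
            ]
            counts, _ = np.histogram(sv.scores[members], bins=edges)
            for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                rows.append(
                    {
                        "signature": name,
                        "status": status.value,
                        "bin_low": lo,
                        "bin_high": hi,
                        "count": int(c),
                    }
                )
    return pd.DataFrame(rows)
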