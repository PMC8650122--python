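"""Model/Results surface over the MSI-signature evaluation pipeline.

``MSISignatureModel`` binds an expression cohort to its MSI labels;
``fit()`` runs normalization (optional), scores the three signatures and
estimates each one's AUC with DeLong uncertainty, returning an
``MSISignatureResults`` that carries the estimates, their confidence
intervals, the per-sample scores, and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .evaluation import LabeledCohort, ROCResult, delong_ci, evaluate_cohort
from .expression import ExpressionMatrix, quantile_normalize
from .pcr import MSIStatus
from .signatures import (
    AdditiveSignature,
    DanaherSignature,
    ScoreVector,
    builtin_signatures,
)


class MSISignatureModel:
    """Evaluate RNA-seq MSI signatures as binary classifiers on one cohort.

    Parameters
    ----------
    expression
        Gene × sample matrix, raw space.
    labels
        Per-sample MSI status; MSI-high is the positive class.
    signatures
        Signature definitions; defaults to the three built-ins
        (Li, Pacinkova–Popovici, Danaher).
    normalize
        Quantile-normalize the cohort before scoring (default True).
    pseudocount
        Added to expression before log transforms (default 1.0).
    alpha
        1 − confidence level of the DeLong intervals (default 0.05).

    Examples
    --------
    >>> from msisig import MSISignatureModel, simulate
    >>> expr, labels = simulate.simulate_expression_cohort(
    ...     simulate.SyntheticCohortSpec(seed=7))
    >>> res = MSISignatureModel(expr, labels).fit()
    >>> print(res.summary())          # doctest: +SKIP
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        labels: LabeledCohort | Mapping[str, MSIStatus] | pd.Series,
        signatures: tuple[AdditiveSignature | DanaherSignature, ...] | None = None,
        normalize: bool = True,
        pseudocount: float = 1.0,
        alpha: float = 0.05,
        missing_policy: str = "error",
    ):
        self.expression = expression
        if isinstance(labels, LabeledCohort):
            self.labels = labels
        elif isinstance(labels, pd.Series):
            self.labels = LabeledCohort.from_series(labels)
        else:
            self.labels = LabeledCohort(
                {k: MSIStatus(v) for k, v in dict(labels).items()}
            )
        self.signatures = signatures if signatures is not None else builtin_signatures()
        self.normalize = normalize
        self.pseudocount = pseudocount
        self.alpha = alpha
        self.missing_policy = missing_policy

    @classmethod
    def from_dataframe(
        cls,
        expression: pd.DataFrame,
        labels: pd.Series,
        **kwargs,
    ) -> "MSISignatureModel":
        """Build from a gene × sample DataFrame and a status Series."""
        return cls(ExpressionMatrix(expression), labels, **kwargs)

    def fit(self) -> "MSISignatureResults":
        """Score every signature and estimate AUC with DeLong uncertainty."""
        report, score_vectors = evaluate_cohort(
            self.expression,
            self.labels,
            signatures=self.signatures,
            normalize=self.normalize,
            pseudocount=self.pseudocount,
            alpha=self.alpha,
            missing_policy=self.missing_policy,
        )
        roc = {
            row["signature"]: ROCResult(
                auc=row["auc"],
                variance=row["variance"],
                ci_low=row["ci_low"],
                ci_high=row["ci_high"],
                alpha=self.alpha,
                n_pos=int(row["n_pos"]),
                n_neg=int(row["n_neg"]),
            )
            for _, row in report.iterrows()
        }
        return MSISignatureResults(self, report, score_vectors, roc)


class MSISignatureResults:
    """Fitted signature evaluation: AUC estimates, CIs, scores, diagnostics."""

    def __init__(
        self,
        model: MSISignatureModel,
        report: pd.DataFrame,
        score_vectors: Mapping[str, ScoreVector],
        roc: Mapping[str, ROCResult],
    ):
        self.model = model
        self.report = report.set_index("signature")
        self.score_vectors = dict(score_vectors)
        self.roc = dict(roc)

    @property
    def auc(self) -> pd.Series:
        return self.report["auc"]

    @property
    def conf_int(self) -> pd.DataFrame:
        return self.report[["ci_low", "ci_high"]]

    @property
    def scores(self) -> pd.DataFrame:
        """Per-sample scores, one column per signature."""
        return pd.DataFrame({n: sv.scores for n, sv in self.score_vectors.items()})

    def summary(self) -> str:
        """Table-style text summary (one row per signature)."""
        lines = [
            "MSI signature evaluation",
            "=" * 72,
            f"samples: {self.model.expression.n_samples}   "
            f"MSI-high: {self.model.labels.n_pos}   "
            f"MSI-low/MSS: {self.model.labels.n_neg}   "
            f"normalize: {self.model.normalize}   "
            f"alpha: {self.model.alpha}",
            "-" * 72,
            f"{'signature':<12}{'AUC':>8}  {'95% CI':>19}{'DeLong var':>14}",
            "-" * 72,
        ]
        for name, r in self.roc.items():
            lines.append(
                f"{name:<12}{r.auc:>8.4f}  "
                f"({r.ci_low:.4f}-{r.ci_high:.4f})".rjust(21)
                + f"{r.variance:>14.3e}"
            )
        lines.append("=" * 72)
        return "\n".join(lines)

    def plot_score_distributions(self, bins: int = 20):
        """Histogram of scores by MSI class, one panel per signature."""
        import matplotlib.pyplot as plt

        names = list(self.score_vectors)
        fig, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 3))
        axes = np.atleast_1d(axes)
        labels = self.model.labels.labels
        for ax, name in zip(axes, names):
            s = self.score_vectors[name].scores
            pos = [s[i] for i in s.index if labels[i] is MSIStatus.MSI_HIGH]
            neg = [s[i] for i in s.index if labels[i] is MSIStatus.MSI_LOW_MSS]
            edges = np.histogram_bin_edges(s.to_numpy(), bins=bins)
            ax.hist(neg, bins=edges, alpha=0.6, label="MSI-low/MSS")
            ax.hist(pos, bins=edges, alpha=0.6, label="MSI-high")
            ax.set_title(name)
            ax.set_xlabel("score")
        axes[0].set_ylabel("samples")
        axes[-1].legend()
        fig.tight_layout()
        return fig
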