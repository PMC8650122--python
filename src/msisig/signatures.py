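"""The three published RNA-seq MSI signatures and their per-sample scores.

Two signatures (Li; Pacinkova–Popovici) are additive: the score of a sample
is the sum of log10-transformed expression of "plus"-genes minus the sum
over "minus"-genes.  The Danaher signature is a pair of cohort-relative
scores — the MMR loss score (MLS), an affine transform of the minimum
Z-score of the four mismatch-repair genes, and the hypermutation predictor
score (HPS), a Z-scored weighted sum of ten genes — combined into the
non-negative MSI predictor score sqrt(min(MLS,0)^2 + max(HPS,0)^2).

For every signature the orientation is: higher score predicts MSI-high.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

ORIENTATION = "higher score predicts MSI-high"

#: Centering and scale of the Danaher MLS transform: magnitude of the
#: expectation (1.03) and the standard deviation (0.69) of the minimum of
#: four independent standard normal variables.
MLS_MU_MIN = 1.03
MLS_SIGMA_MIN = 0.69


class SignatureError(ValueError):
    """Raised for invalid signature definitions or unscorable input."""


class MissingGenesError(SignatureError):
    """Raised when signature genes are absent from the matrix."""

    def __init__(self, signature: str, missing: Iterable[str]):
        self.missing = sorted(missing)
        super().__init__(
            f"signature {signature!r}: genes missing from matrix: {self.missing}"
        )


@dataclass(frozen=True)
class AdditiveSignature:
    """A signed gene set scored as Σ log10(plus) − Σ log10(minus)."""

    name: str
    plus_genes: frozenset[str]
    minus_genes: frozenset[str]
    log_base: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "plus_genes", frozenset(self.plus_genes))
        object.__setattr__(self, "minus_genes", frozenset(self.minus_genes))
        if not self.plus_genes or not self.minus_genes:
            raise SignatureError(f"{self.name}: plus and minus sets must be non-empty")
        overlap = self.plus_genes & self.minus_genes
        if overlap:
            raise SignatureError(f"{self.name}: genes in both sets: {sorted(overlap)}")

    @property
    def genes(self) -> frozenset[str]:
        return self.plus_genes | self.minus_genes


@dataclass(frozen=True)
class DanaherSignature:
    """MMR-loss + hypermutation double signature of Danaher et al."""

    name: str
    mls_genes: tuple[str, ...]
    hps_genes: tuple[str, ...]
    hps_coefficients: Mapping[str, float]
    mu_min: float = MLS_MU_MIN
    sigma_min: float = MLS_SIGMA_MIN
    log_base: int = 2

    def __post_init__(self) -> None:
        if len(self.mls_genes) != 4 or len(set(self.mls_genes)) != 4:
            raise SignatureError(f"{self.name}: MLS needs exactly 4 distinct MMR genes")
        if len(self.hps_genes) != 10 or len(set(self.hps_genes)) != 10:
            raise SignatureError(f"{self.name}: HPS needs exactly 10 distinct genes")
        missing_coeff = [g for g in self.hps_genes if g not in self.hps_coefficients]
        if missing_coeff:
            raise SignatureError(f"{self.name}: missing HPS coefficients: {missing_coeff}")
        if not (self.mu_min > 0 and self.sigma_min > 0):
            raise SignatureError(f"{self.name}: mu_min and sigma_min must be positive")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.mls_genes) | frozenset(self.hps_genes)


@dataclass(frozen=True)
class ScoreVector:
    """Per-sample scores for one signature on one cohort."""

    signature_name: str
    scores: pd.Series
    orientation: str = ORIENTATION

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise SignatureError(f"{self.signature_name}: non-finite score produced")

    @property
    def sample_ids(self) -> list[str]:
        return self.scores.index.tolist()


# --- built-in definitions ---------------------------------------------------

LI_PLUS = ("LYG1", "MSH4", "RPL22L1")
LI_MINUS = (
    "DDX27", "EPM2AIP1", "HENMT1", "MLH1", "NHLRC1", "NOL4L",
    "RNLS", "RTFDC1", "SHROOM4", "SMAP1", "TTC30A", "ZSWIM3",
)

PACINKOVA_PLUS = ("AGR2", "TNNT1", "VNN2", "TNFSF9", "TRIM7", "RPL22L1")
PACINKOVA_MINUS = (
    "ACSL6", "ARID3A", "ASCL2", "AXIN2", "EPDR1", "GGT7", "GNG4",
    "KHDRBS3", "KRT23", "MLH1", "NKD1", "PLAGL2", "PRR15", "RUBCNL",
    "SHROOM2", "SHROOM4", "TFCP2L1", "TNNC2", "VAV3",
)

DANAHER_MLS_GENES = ("MLH1", "MSH2", "MSH6", "PMS2")
DANAHER_HPS_GENES = (
    "EPM2AIP1", "TTC30A", "SMAP1", "RNLS", "WNT11",
    "SFXN1", "SREBF1", "TYMS", "EIF5AL1", "WDR76",
)

_DEFAULT_COEFF_RESOURCE = "danaher_hps_coefficients_synthetic.yaml"


def load_hps_coefficients(path: str | Path | None = None) -> dict[str, float]:
    """Load HPS gene weights from a YAML mapping.

    With no path, loads the packaged synthetic stand-in weights (unit
    magnitudes with biologically oriented signs); replace with the weights
    from the original Danaher publication for faithful absolute scores.
    """
    if path is None:
        text = (
            resources.files("msisig").joinpath(f"data/{_DEFAULT_COEFF_RESOURCE}").read_text()
        )
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    coeffs = doc["coefficients"] if isinstance(doc, dict) and "coefficients" in doc else doc
    return {str(g): float(c) for g, c in coeffs.items()}


def builtin_signatures(
    hps_coefficients: Mapping[str, float] | None = None,
) -> tuple[AdditiveSignature, AdditiveSignature, DanaherSignature]:
    """The Li, Pacinkova–Popovici and Danaher definitions.

    ``hps_coefficients`` overrides the packaged Danaher HPS weights.
    """
    li = AdditiveSignature("li", frozenset(LI_PLUS), frozenset(LI_MINUS))
    pacinkova = AdditiveSignature(
        "pacinkova", frozenset(PACINKOVA_PLUS), frozenset(PACINKOVA_MINUS)
    )
    coeffs = dict(hps_coefficients) if hps_coefficients else load_hps_coefficients()
    danaher = DanaherSignature(
        "danaher", DANAHER_MLS_GENES, DANAHER_HPS_GENES, coeffs
    )
    return li, pacinkova, danaher


def all_signature_genes(
    sigs: Iterable[AdditiveSignature | DanaherSignature] | None = None,
) -> frozenset[str]:
    """Union of all gene symbols used by the given (default: built-in) signatures."""
    if sigs is None:
        sigs = builtin_signatures()
    out: frozenset[str] = frozenset()
    for s in sigs:
        out |= s.genes
    return out


# --- scoring ----------------------------------------------------------------


def _gene_submatrix(
    matrix: ExpressionMatrix,
    genes: Iterable[str],
    signature: str,
    missing_policy: str,
) -> pd.DataFrame:
    genes = list(genes)
    present = [g for g in genes if g in matrix.data.index]
    missing = [g for g in genes if g not in matrix.data.index]
    if missing:
        if missing_policy == "error":
            raise MissingGenesError(signature, missing)
        if missing_policy != "skip":
            raise ValueError(f"unknown missing-gene policy {missing_policy!r}")
        logger.warning(
            "signature %s: skipping %d missing gene(s): %s",
            signature, len(missing), sorted(missing),
        )
    if not present:
        raise MissingGenesError(signature, missing)
    return matrix.data.loc[present]


def _log_transform(df: pd.DataFrame, base: int, pseudocount: float) -> pd.DataFrame:
    if pseudocount < 0:
        raise SignatureError("pseudocount must be non-negative")
    if pseudocount == 0 and (df.to_numpy() <= 0).any():
        raise SignatureError(
            "zero expression with pseudocount 0 would produce log(0); "
            "use a positive pseudocount"
        )
    return np.log(df + pseudocount) / np.log(base)


def score_additive(
    matrix: ExpressionMatrix,
    sig: AdditiveSignature,
    pseudocount: float = 1.0,
    missing_policy: str = "error",
) -> ScoreVector:
    """Sum of signed log10-transformed expression over the signature genes.

    score(s) = Σ_{g∈plus} log10(x_gs + pc) − Σ_{g∈minus} log10(x_gs + pc)
    """
    plus = _gene_submatrix(matrix, sorted(sig.plus_genes), sig.name, missing_policy)
    minus = _gene_submatrix(matrix, sorted(sig.minus_genes), sig.name, missing_policy)
    logp = _log_transform(plus, sig.log_base, pseudocount)
    logm = _log_transform(minus, sig.log_base, pseudocount)
    scores = logp.sum(axis=0) - logm.sum(axis=0)
    scores.name = sig.name
    return ScoreVector(sig.name, scores)


def _zscore_rows(df: pd.DataFrame, context: str) -> pd.DataFrame:
    """Row-wise Z-scores across samples, n−1 SD; zero-variance rows → 0."""
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%s: zero variance across samples for %s; Z-scores set to 0",
            context, df.index[degenerate].tolist(),
        )
    sd = sd.where(~degenerate, 1.0)
    z = df.sub(mean, axis=0).div(sd, axis=0)
    z.loc[degenerate] = 0.0
    return z


def score_danaher_mls(
    matrix: ExpressionMatrix,
    sig: DanaherSignature,
    pseudocount: float = 1.0,
) -> pd.Series:
    """MMR loss score: (Zmin + mu_min) / sigma_min per sample.

    Each MMR gene's log2 expression is Z-scored across the cohort; Zmin is
    the per-sample minimum over the four genes.  Cohort-relative: needs
    at least two samples.
    """
    if matrix.n_samples < 2:
        raise SignatureError("MLS is cohort-relative and needs >= 2 samples")
    sub = _gene_submatrix(matrix, sig.mls_genes, sig.name, "error")
    logx = _log_transform(sub, sig.log_base, pseudocount)
    z = _zscore_rows(logx, f"{sig.name} MLS")
    zmin = z.min(axis=0)
    mls = (zmin + sig.mu_min) / sig.sigma_min
    mls.name = f"{sig.name}_mls"
    return mls


def score_danaher_hps(
    matrix: ExpressionMatrix,
    sig: DanaherSignature,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Hypermutation predictor score: cohort Z-score of Σ coeff·log2(x + pc)."""
    if matrix.n_samples < 2:
        raise SignatureError("HPS is cohort-relative and needs >= 2 samples")
    sub = _gene_submatrix(matrix, sig.hps_genes, sig.name, "error")
    logx = _log_transform(sub, sig.log_base, pseudocount)
    coeffs = pd.Series({g: sig.hps_coefficients[g] for g in sig.hps_genes})
    raw = logx.mul(coeffs, axis=0).sum(axis=0)
    sd = raw.std(ddof=1)
    if sd == 0:
        logger.warning("%s HPS: raw score has zero variance; HPS set to 0", sig.name)
        hps = pd.Series(0.0, index=raw.index)
    else:
        hps = (raw - raw.mean()) / sd
    hps.name = f"{sig.name}_hps"
    return hps


def score_danaher_msi(mls: pd.Series, hps: pd.Series) -> ScoreVector:
    """MSI predictor score sqrt(min(MLS,0)^2 + max(HPS,0)^2).

    Non-negative; raised by MMR loss (negative MLS) and by hypermutation
    (positive HPS); zero iff MLS >= 0 and HPS <= 0.
    """
    if set(mls.index) != set(hps.index):
        raise SignatureError("MLS and HPS cover different samples")
    hps = hps.reindex(mls.index)
    score = np.sqrt(np.minimum(mls, 0.0) ** 2 + np.maximum(hps, 0.0) ** 2)
    score.name = "danaher"
    return ScoreVector("danaher", score)


def score_danaher(
    matrix: ExpressionMatrix,
    sig: DanaherSignature,
    pseudocount: float = 1.0,
) -> ScoreVector:
    """Convenience: MLS + HPS + combined MSI predictor score."""
    mls = score_danaher_mls(matrix, sig, pseudocount)
    hps = score_danaher_hps(matrix, sig, pseudocount)
    return score_danaher_msi(mls, hps)


def score_signature(
    matrix: ExpressionMatrix,
    sig: AdditiveSignature | DanaherSignature,
    pseudocount: float = 1.0,
    missing_policy: str = "error",
) -> ScoreVector:
    """Score any built-in signature type on a cohort."""
    if isinstance(sig, AdditiveSignature):
        return score_additive(matrix, sig, pseudocount, missing_policy)
    return score_danaher(matrix, sig, pseudocount)


# --- gene-set comparison ----------------------------------------------------


def signature_overlap(
    sigs: Iterable[AdditiveSignature | DanaherSignature] | None = None,
) -> dict[str, frozenset[str]]:
    """Pairwise and triple gene-symbol intersections between signatures.

    Keys are '&'-joined signature names ("li&danaher", "li&pacinkova&danaher", ...).
    """
    if sigs is None:
        sigs = builtin_signatures()
    sigs = list(sigs)
    out: dict[str, frozenset[str]] = {}
    for i in range(len(sigs)):
        for j in range(i + 1, len(sigs)):
            out[f"{sigs[i].name}&{sigs[j].name}"] = sigs[i].genes & sigs[j].genes
    if len(sigs) >= 3:
        key = "&".join(s.name for s in sigs)
        inter = sigs[0].genes
        for s in sigs[1:]:
            inter &= s.genes
        out[key] = inter
    return out
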