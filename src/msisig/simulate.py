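"""Synthetic labeled cohorts with the structure the MSI analysis assumes.

The expression generator plants the biology the signatures detect: a
minority MSI-high class in which mismatch-repair and other minus-set genes
are shifted down and plus-set genes up on a log-normal expression
background.  Gene roles are derived from the signature definitions
themselves, one shift per gene regardless of how many signatures use it.
The marker generator draws per-locus instability calls with
class-conditional probabilities so the PCR rule can be exercised against
known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, RAW
from .evaluation import LabeledCohort
from .pcr import (
    ADDITIONAL_LOCI,
    MAIN_LOCI,
    MSIStatus,
    MarkerPanelProfile,
    STABLE,
    UNSTABLE,
)
from .signatures import (
    AdditiveSignature,
    DanaherSignature,
    builtin_signatures,
)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of the synthetic expression cohort.

    Defaults emulate a colorectal-like cohort: a minority MSI-high class
    (30%), log2 baselines around 8 (several hundred normalized counts)
    with 2 log2 units of between-gene spread, per-observation log2 noise
    of 1, and planted class shifts of 2 log2 units (a fourfold change)
    on the signature genes.
    """

    n_samples: int = 200
    msi_high_fraction: float = 0.3
    background_genes: int = 200
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    effect_size_down: float = 2.0
    effect_size_up: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if not 0.0 < self.msi_high_fraction < 1.0:
            raise ValueError("msi_high_fraction must lie in (0, 1)")
        if self.background_genes < 0:
            raise ValueError("background_genes must be non-negative")
        if self.baseline_log2_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if self.effect_size_down < 0 or self.effect_size_up < 0:
            raise ValueError("effect sizes must be non-negative")


def _gene_roles(
    signatures: tuple[AdditiveSignature | DanaherSignature, ...],
) -> tuple[list[str], set[str], set[str]]:
    """Signature gene union plus the down- and up-shifted subsets.

    Down: every minus-set gene and every MMR gene.  Up: plus-set genes and
    HPS genes whose configured coefficient is positive.  A gene claimed by
    both directions is shifted down — MMR loss is the primary biology.
    """
    down: set[str] = set()
    up: set[str] = set()
    genes: set[str] = set()
    for sig in signatures:
        genes |= sig.genes
        if isinstance(sig, AdditiveSignature):
            down |= set(sig.minus_genes)
            up |= set(sig.plus_genes)
        else:
            down |= set(sig.mls_genes)
            up |= {g for g in sig.hps_genes if sig.hps_coefficients[g] > 0}
    up -= down
    return sorted(genes), down, up


def simulate_expression_cohort(
    spec: SyntheticCohortSpec,
    signatures: tuple[AdditiveSignature | DanaherSignature, ...] | None = None,
) -> tuple[ExpressionMatrix, LabeledCohort]:
    """Draw a labeled expression cohort with planted signature effects.

    Genes are the union of the signature gene sets plus unshifted
    background genes.  log2 expression of gene g in sample s is
    Normal(baseline_g + shift_{g,class(s)}, noise_sd), exponentiated to
    the linear scale so the pipeline's own log transforms are exercised.
    """
    if signatures is None:
        signatures = builtin_signatures()
    rng = np.random.default_rng(spec.seed)
    sig_genes, down, up = _gene_roles(signatures)
    genes = sig_genes + [f"BG{i:04d}" for i in range(spec.background_genes)]
    samples = [f"S{i:04d}" for i in range(spec.n_samples)]

    is_high = rng.random(spec.n_samples) < spec.msi_high_fraction
    baseline = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, len(genes))
    shift = np.zeros(len(genes))
    for i, g in enumerate(sig_genes):
        if g in down:
            shift[i] = -spec.effect_size_down
        elif g in up:
            shift[i] = spec.effect_size_up
    log2x = (
        baseline[:, None]
        + shift[:, None] * is_high[None, :]
        + rng.normal(0.0, spec.noise_sd, (len(genes), spec.n_samples))
    )
    data = pd.DataFrame(np.exp2(log2x), index=genes, columns=samples)
    matrix = ExpressionMatrix(data, space=RAW)
    labels = LabeledCohort(
        {
            s: MSIStatus.MSI_HIGH if h else MSIStatus.MSI_LOW_MSS
            for s, h in zip(samples, is_high)
        }
    )
    return matrix, labels


def simulate_marker_profiles(
    n: int,
    msi_high_fraction: float,
    p_unstable_given_high: float,
    p_unstable_given_low: float,
    seed: int = 0,
) -> tuple[list[MarkerPanelProfile], dict[str, MSIStatus]]:
    """Draw marker panels with class-conditional per-locus instability.

    Each of the seven loci is independently unstable with the probability
    of the sample's true class; the true labels are returned alongside so
    classifier recovery can be measured.
    """
    if n < 1:
        raise ValueError("n must be positive")
    for p in (msi_high_fraction, p_unstable_given_high, p_unstable_given_low):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    profiles: list[MarkerPanelProfile] = []
    truth: dict[str, MSIStatus] = {}
    for i in range(n):
        sid = f"S{i:04d}"
        high = rng.random() < msi_high_fraction
        p = p_unstable_given_high if high else p_unstable_given_low
        calls = {
            locus: (UNSTABLE if rng.random() < p else STABLE)
            for locus in MAIN_LOCI + ADDITIONAL_LOCI
        }
        profiles.append(
            MarkerPanelProfile(
                sample_id=sid,
                main_calls={l: calls[l] for l in MAIN_LOCI},
                additional_calls={l: calls[l] for l in ADDITIONAL_LOCI},
            )
        )
        truth[sid] = MSIStatus.MSI_HIGH if high else MSIStatus.MSI_LOW_MSS
    return profiles, truth


def marker_profiles_to_frame(profiles: list[MarkerPanelProfile]) -> pd.DataFrame:
    """Flatten profiles to the TSV layout (sample_id + one column per locus)."""
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id}
        row.update(p.main_calls)
        row.update(p.additional_calls)
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", *MAIN_LOCI, *ADDITIONAL_LOCI])
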