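"""Gold-standard MSI classification from the 7-locus PCR marker panel.

Five "main" mononucleotide loci (BAT25, BAT26, NR21, NR24, NR27) are
scored first: two or more unstable loci call MSI-high outright.  A single
unstable main locus triggers reflex testing of the two additional loci
(BAT40, CAT25); any instability there also calls MSI-high.  Everything
else is pooled as MSI-low/MSS, the negative class of this analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

MAIN_LOCI = ("BAT25", "BAT26", "NR21", "NR24", "NR27")
ADDITIONAL_LOCI = ("BAT40", "CAT25")
ALL_LOCI = MAIN_LOCI + ADDITIONAL_LOCI

STABLE = "stable"
UNSTABLE = "unstable"
MISSING = "missing"
_CALLS = frozenset({STABLE, UNSTABLE, MISSING})


class MSIStatus(str, enum.Enum):
    MSI_HIGH = "MSI-high"
    MSI_LOW_MSS = "MSI-low/MSS"


class MarkerPanelError(ValueError):
    """Raised for malformed or insufficient marker panels."""


class AdditionalTestingRequired(MarkerPanelError):
    """One unstable main marker but the reflex additional calls are missing."""


@dataclass(frozen=True)
class MarkerPanelProfile:
    """Per-sample stability calls for the 5 main + 2 additional loci."""

    sample_id: str
    main_calls: Mapping[str, str]
    additional_calls: Mapping[str, str]

    def __post_init__(self) -> None:
        if set(self.main_calls) != set(MAIN_LOCI):
            raise MarkerPanelError(
                f"{self.sample_id}: main calls must cover exactly {MAIN_LOCI}"
            )
        if set(self.additional_calls) != set(ADDITIONAL_LOCI):
            raise MarkerPanelError(
                f"{self.sample_id}: additional calls must cover exactly {ADDITIONAL_LOCI}"
            )
        bad = {
            locus: call
            for locus, call in {**self.main_calls, **self.additional_calls}.items()
            if call not in _CALLS
        }
        if bad:
            raise MarkerPanelError(f"{self.sample_id}: invalid calls {bad}")


def classify_msi_pcr(profile: MarkerPanelProfile) -> MSIStatus:
    """Apply the stepwise panel rule to one sample.

    >=2 unstable main loci -> MSI-high; exactly 1 unstable main locus and
    >=1 unstable additional locus -> MSI-high; otherwise MSI-low/MSS.
    With 0 unstable main loci the additional loci are never consulted.
    """
    missing_main = [l for l in MAIN_LOCI if profile.main_calls[l] == MISSING]
    if missing_main:
        raise MarkerPanelError(
            f"{profile.sample_id}: missing main marker call(s): {missing_main}"
        )
    n_unstable_main = sum(profile.main_calls[l] == UNSTABLE for l in MAIN_LOCI)
    if n_unstable_main >= 2:
        return MSIStatus.MSI_HIGH
    if n_unstable_main == 0:
        return MSIStatus.MSI_LOW_MSS
    # exactly one unstable main marker: reflex to the additional loci
    missing_add = [l for l in ADDITIONAL_LOCI if profile.additional_calls[l] == MISSING]
    if missing_add:
        raise AdditionalTestingRequired(
            f"{profile.sample_id}: one unstable main marker but additional "
            f"marker call(s) missing: {missing_add}"
        )
    if any(profile.additional_calls[l] == UNSTABLE for l in ADDITIONAL_LOCI):
        return MSIStatus.MSI_HIGH
    return MSIStatus.MSI_LOW_MSS


def read_marker_table(path: str | Path) -> list[MarkerPanelProfile]:
    """Read a TSV with a sample_id column plus one column per locus."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", *ALL_LOCI}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise MarkerPanelError(f"marker table missing columns: {sorted(missing_cols)}")
    profiles = []
    for _, row in df.iterrows():
        profiles.append(
            MarkerPanelProfile(
                sample_id=row["sample_id"],
                main_calls={l: row[l] for l in MAIN_LOCI},
                additional_calls={l: row[l] for l in ADDITIONAL_LOCI},
            )
        )
    return profiles


def classify_marker_table(profiles: list[MarkerPanelProfile]) -> pd.DataFrame:
    """Classify a batch of profiles; returns sample_id, status columns."""
    return pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in profiles],
            "status": [classify_msi_pcr(p).value for p in profiles],
        }
    )
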