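"""Expression-matrix handling: I/O, gene-identifier mapping, quantile normalization.

Expression matrices are dense gene × sample tables of non-negative values.
A matrix carries an explicit normalization ``space`` ("raw" or
"quantile_normalized") so downstream scoring can record what it was fed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RAW = "raw"
QUANTILE_NORMALIZED = "quantile_normalized"

Orientation = Literal["genes-in-rows", "samples-in-rows"]
CollisionPolicy = Literal["error", "sum", "first"]


class ExpressionMatrixError(ValueError):
    """Raised for malformed expression input (duplicates, negatives, empties)."""


@dataclass
class ExpressionMatrix:
    """Dense gene × sample expression matrix.

    Parameters
    ----------
    data
        DataFrame indexed by gene symbol with one column per sample.
        All values must be finite and non-negative; no missing cells.
    space
        Normalization state, ``"raw"`` or ``"quantile_normalized"``.
    """

    data: pd.DataFrame
    space: str = RAW

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ExpressionMatrixError("expression matrix is empty")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ExpressionMatrixError(f"duplicate gene identifiers: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ExpressionMatrixError(f"duplicate sample identifiers: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ExpressionMatrixError("expression values must be numeric")
        if np.isnan(values).any():
            gene, sample = self._first_offender(np.isnan(values))
            raise ExpressionMatrixError(f"missing value at gene {gene!r}, sample {sample!r}")
        if (values < 0).any():
            gene, sample = self._first_offender(values < 0)
            raise ExpressionMatrixError(
                f"negative expression value at gene {gene!r}, sample {sample!r}"
            )
        if self.space not in (RAW, QUANTILE_NORMALIZED):
            raise ExpressionMatrixError(f"unknown normalization space {self.space!r}")

    def _first_offender(self, mask: np.ndarray) -> tuple[str, str]:
        i, j = np.argwhere(mask)[0]
        return str(self.data.index[i]), str(self.data.columns[j])

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV with a leading ``gene_id`` column."""
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


def load_expression_matrix(
    path: str | Path, orientation: Orientation = "genes-in-rows"
) -> ExpressionMatrix:
    """Read a TSV expression matrix.

    The file has one header row and one leading identifier column
    (``gene_id`` then sample IDs for ``genes-in-rows``; transposed for
    ``samples-in-rows``). Values must parse as non-negative reals.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if orientation == "samples-in-rows":
        df = df.T
    elif orientation != "genes-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        numeric = df.astype(float)
    except ValueError:
        for gene in df.index:
            for sample in df.columns:
                cell = df.loc[gene, sample]
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ExpressionMatrixError(
                        f"non-numeric value {cell!r} at gene {gene!r}, sample {sample!r}"
                    ) from None
        raise
    return ExpressionMatrix(numeric, space=RAW)


def load_gene_id_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (``source_id<TAB>hgnc_symbol``, header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("gene ID map needs two columns: source_id, hgnc_symbol")
    src, dst = df.columns[:2]
    if df[src].duplicated().any():
        dups = df.loc[df[src].duplicated(), src].unique().tolist()
        raise ValueError(f"duplicate source IDs in gene map: {dups}")
    return dict(zip(df[src], df[dst]))


def map_gene_identifiers(
    matrix: ExpressionMatrix,
    id_map: Mapping[str, str],
    collision_policy: CollisionPolicy = "error",
) -> ExpressionMatrix:
    """Rename gene identifiers (e.g. Ensembl → HGNC symbols).

    Unmapped genes are dropped with a logged count.  When several source
    IDs map to one target symbol the ``collision_policy`` decides:
    ``"error"`` raises listing the colliding sources, ``"sum"`` adds their
    rows, ``"first"`` keeps the first occurrence in matrix order.
    """
    mapped = matrix.data.index.map(lambda g: id_map.get(g))
    keep = mapped.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("map_gene_identifiers: dropped %d unmapped gene(s)", n_dropped)
    df = matrix.data.loc[keep].copy()
    new_index = pd.Index(mapped[keep], name=matrix.data.index.name)
    if df.shape[0] == 0:
        raise ExpressionMatrixError("no genes remain after identifier mapping")
    if new_index.has_duplicates:
        if collision_policy == "error":
            collided = new_index[new_index.duplicated(keep=False)]
            sources = df.index[new_index.duplicated(keep=False)].tolist()
            raise ExpressionMatrixError(
                f"gene ID collisions onto {sorted(set(collided))}: sources {sources}"
            )
        df.index = new_index
        if collision_policy == "sum":
            df = df.groupby(level=0, sort=False).sum()
        elif collision_policy == "first":
            df = df[~df.index.duplicated(keep="first")]
        else:
            raise ValueError(f"unknown collision policy {collision_policy!r}")
    else:
        df.index = new_index
    return ExpressionMatrix(df, space=matrix.space)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Classic quantile normalization across samples.

    Each sample's values are replaced by the reference distribution — the
    across-sample mean of each order statistic — assigned by within-sample
    rank.  Ties within a sample receive the mean of the reference values of
    their tied ranks (the "average" tie dialect).
    """
    values = matrix.data.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    # reference distribution: mean of the r-th smallest value over samples
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_genes)
        assigned[order] = reference
        # tied input values share the mean of their ranks' reference values
        if np.unique(col).size < n_genes:
            assigned = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
        out[:, j] = assigned
    df = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(df, space=QUANTILE_NORMALIZED)
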