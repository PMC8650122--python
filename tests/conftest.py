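import numpy as np
import pandas as pd
import pytest

from msisig.expression import ExpressionMatrix
from msisig.signatures import builtin_signatures


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes × 2 samples with hand-checkable values."""
    df = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["G1", "G2", "G3"],
        columns=["S1", "S2"],
    )
    return ExpressionMatrix(df)


@pytest.fixture(scope="session")
def signatures():
    return builtin_signatures()


def signature_matrix(values_by_gene, samples=("S1", "S2")):
    """Matrix over the full signature gene union with per-gene constants
    or per-gene per-sample lists."""
    li, pac, dan = builtin_signatures()
    genes = sorted(li.genes | pac.genes | dan.genes)
    rows = []
    for g in genes:
        v = values_by_gene(g)
        rows.append([v] * len(samples) if np.isscalar(v) else list(v))
    return ExpressionMatrix(
        pd.DataFrame(rows, index=genes, columns=list(samples))
    )


@pytest.fixture
def uniform_signature_matrix():
    """Every signature gene at expression 1.0 in two samples."""
    return signature_matrix(lambda g: 1.0)
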