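import numpy as np
import pandas as pd
import pytest

from thyromarker.datatypes import LOG2, ExpressionMatrix, SampleAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def make_matrix(values, genes=None, samples=None, scale=LOG2):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{i + 1}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale=scale)


def make_annotation(n_ftc, n_fta, oncocytic=None, samples=None):
    n = n_ftc + n_fta
    samples = samples or [f"s{i + 1}" for i in range(n)]
    table = pd.DataFrame({"diagnosis": ["FTC"] * n_ftc + ["FTA"] * n_fta},
                         index=pd.Index(samples, name="sample_id"))
    if oncocytic is not None:
        table["oncocytic"] = list(oncocytic)
    return SampleAnnotation(table)


@pytest.fixture
def two_group_matrix(rng):
    """15 samples x 8 genes, genes 1-2 shifted between the groups."""
    values = rng.normal(8.0, 0.7, (8, 15))
    values[0, :7] += 2.0
    values[1, :7] -= 1.5
    matrix = make_matrix(values)
    annot = make_annotation(7, 8)
    return matrix, annot
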