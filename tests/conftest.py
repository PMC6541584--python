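import numpy as np
import pandas as pd
import pytest

from telodiff import ExpressionMatrix, GenomeAnnotation


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 transcripts x 4 samples, 2 case / 2 control."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [0.5, 0.5, 0.5, 0.5], [10.0, 11.0, 9.0, 12.0]],
        index=["tA", "tB", "tC"],
        columns=["c1", "c2", "k1", "k2"],
    )
    groups = {"c1": "case", "c2": "case", "k1": "control", "k2": "control"}
    return ExpressionMatrix(values, groups)


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    return GenomeAnnotation(
        chrom_lengths={"chr1": 100_000_000, "chr2": 50_000_000},
        gene_start_of={
            "tA": ("chr1", 5_000_000),
            "tB": ("chr1", 50_000_000),
            "tC": ("chr2", 45_000_000),
        },
    )


def make_matrix(values: np.ndarray, n_case: int, n_control: int) -> ExpressionMatrix:
    """Helper: wrap an array as a matrix with generic ids."""
    n, m = values.shape
    assert m == n_case + n_control
    samples = [f"c{i}" for i in range(n_case)] + [f"k{i}" for i in range(n_control)]
    groups = {s: ("case" if s.startswith("c") else "control") for s in samples}
    df = pd.DataFrame(values, index=[f"t{i}" for i in range(n)], columns=samples)
    return ExpressionMatrix(df, groups)
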