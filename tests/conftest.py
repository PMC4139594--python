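import numpy as np
import pytest

from cortexseek.matrix import SampleAnnotation, matrix_from_arrays


@pytest.fixture
def tiny_matrix():
    """2 genes x 3 samples, hand-written values."""
    annotations = [
        SampleAnnotation("s1", "VZ", "E15.5", "mouse", "target"),
        SampleAnnotation("s2", "CP", "E15.5", "mouse"),
        SampleAnnotation("s3", "GE", "E15.5", "mouse"),
    ]
    values = np.array([[12.0, 2.0, 2.0], [3.0, 3.0, 3.0]])
    return matrix_from_arrays(["Cdon", "Dbi"], annotations, values, species="mouse")


def make_matrix(values, structures, ages=None, species="mouse", genes=None):
    """Matrix helper: one sample per (structure, age) pair, row-major genes."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    ages = ages or ["E15.5"] * n
    annotations = [
        SampleAnnotation(f"s{i}", structures[i], ages[i], species)
        for i in range(n)
    ]
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    return matrix_from_arrays(genes, annotations, values, species=species,
                              canonicalize_genes=False)
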