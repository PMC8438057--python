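import numpy as np
import pandas as pd
import pytest

from subtype_suite.io_core import AnalyteMatrix, GeneSet, GeneSetCollection, SegmentTable
from subtype_suite.synthetic import default_genome, make_signature_matrix


@pytest.fixture
def tiny_matrix() -> AnalyteMatrix:
    data = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["G1", "G2", "G3"], columns=["S1", "S2"],
    )
    return AnalyteMatrix(data)


@pytest.fixture
def genome():
    return default_genome()


@pytest.fixture
def signature_matrix():
    # synthetic stand-in signature catalog (not COSMIC)
    return make_signature_matrix(5, seed=42)


@pytest.fixture
def two_block_matrix() -> AnalyteMatrix:
    """Two blocks of duplicated sample profiles (plus distinct gene noise)."""
    rng = np.random.default_rng(0)
    a = rng.normal(size=30)
    b = rng.normal(size=30)
    cols = {f"A{i}": a + rng.normal(scale=1e-6, size=30) for i in range(4)}
    cols.update({f"B{i}": b + rng.normal(scale=1e-6, size=30) for i in range(4)})
    data = pd.DataFrame(cols, index=[f"G{i}" for i in range(30)])
    return AnalyteMatrix(data)


def make_segment_table(rows) -> SegmentTable:
    """rows of (sample, chrom, start, end, n_markers, seg_mean), internal coords."""
    return SegmentTable(pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_markers", "seg_mean"]))


@pytest.fixture
def gene_sets():
    return GeneSetCollection({
        "SET_A": GeneSet("SET_A", "first", ("G1", "G2")),
        "SET_B": GeneSet("SET_B", "second", ("G3",)),
    })
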