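import numpy as np
import pandas as pd
import pytest

from concorddeg import CountMatrix, NormalizedMatrix
from concorddeg.io_core import DEG_COLUMNS


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """4 genes x 4 cells, two heart and two blood cells."""
    counts = np.array(
        [
            [5, 0, 3, 1],
            [0, 2, 0, 4],
            [1, 1, 1, 1],
            [0, 0, 0, 0],
        ]
    )
    return CountMatrix(
        genes=["MS4A1", "CD19", "ACTB", "SILENT"],
        cells=["c1", "c2", "c3", "c4"],
        counts=counts,
        cell_group=np.array(["heart", "heart", "blood", "blood"], dtype=object),
        cell_cluster=np.array(["0", "0", "1", "1"], dtype=object),
        dataset_id="toy",
    )


def make_normalized(values, groups, clusters=None, genes=None) -> NormalizedMatrix:
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    return NormalizedMatrix(
        genes=genes or [f"g{i}" for i in range(n_genes)],
        cells=[f"c{j}" for j in range(n_cells)],
        values=values,
        cell_group=np.asarray(groups, dtype=object),
        cell_cluster=None if clusters is None else np.asarray(clusters, dtype=object),
        dataset_id="toy",
    )


def make_deg_table(genes, log2fc, p_value, dataset_id="ds") -> pd.DataFrame:
    n = len(genes)
    df = pd.DataFrame(
        {
            "gene": genes,
            "log2fc": log2fc,
            "stat": np.zeros(n),
            "p_value": p_value,
            "mean_heart": np.zeros(n),
            "mean_blood": np.zeros(n),
            "n_heart": 10,
            "n_blood": 10,
            "dataset_id": dataset_id,
        }
    )
    return df[DEG_COLUMNS]


@pytest.fixture
def toy_deg_trio():
    """The canonical worked example: three datasets, four genes.

    g1 significant everywhere with direction (+,+,+); g2 significant with
    (+,-,+); g3 with (-,-,-); g4 significant in only two of three tables.
    """
    t1 = make_deg_table(["g1", "g2", "g3", "g4"], [1.0, 0.5, -2.0, 1.0],
                        [0.01, 0.02, 0.001, 0.04], "ds0")
    t2 = make_deg_table(["g1", "g2", "g3", "g4"], [0.3, -0.8, -0.1, -1.0],
                        [0.03, 0.01, 0.04, 0.5], "ds1")
    t3 = make_deg_table(["g1", "g2", "g3", "g4"], [2.0, 1.5, -0.7, 0.2],
                        [0.002, 0.03, 0.01, 0.01], "ds2")
    return [t1, t2, t3]
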