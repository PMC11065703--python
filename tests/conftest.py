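import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from senescape import ExpressionDataset, GeneSetCollection


@pytest.fixture
def tiny_dataset():
    """6 genes x 4 cells with simple integer counts."""
    counts = np.array(
        [
            [5, 0, 2, 1],
            [3, 1, 0, 0],
            [1, 4, 0, 2],
            [0, 2, 3, 0],
            [0, 0, 1, 5],
            [2, 2, 2, 2],
        ],
        dtype=float,
    )
    meta = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(4)],
            "sample_id": ["s1", "s1", "s2", "s2"],
            "diagnosis": ["AD", "AD", "NDC", "NDC"],
            "cell_type": ["Micro", "Micro", "Micro", "Astro"],
        }
    ).set_index("cell_id")
    return ExpressionDataset(
        matrix=sp.csr_matrix(counts),
        gene_ids=np.array([f"g{i}" for i in range(6)], dtype=object),
        cell_ids=np.array([f"c{i}" for i in range(4)], dtype=object),
        cell_meta=meta,
    )


@pytest.fixture
def small_collection():
    return GeneSetCollection(sets={"setA": ["g0", "g1"], "setB": ["g2", "g4", "g5"]})


def brute_force_auc(ranks_of_set_genes, k_eff, max_rank):
    """Independent recovery-curve enumeration oracle for the AUC score.

    Walks i = 1..max_rank counting set genes at rank <= i and sums the
    curve; normalises by the top-packed maximum.
    """
    area = 0
    for i in range(1, max_rank + 1):
        area += sum(1 for r in ranks_of_set_genes if r <= i)
    max_area = sum(min(i, k_eff) for i in range(1, max_rank + 1))
    return area / max_area if max_area else 0.0


@pytest.fixture
def auc_oracle():
    return brute_force_auc
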