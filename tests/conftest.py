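import numpy as np
import pandas as pd
import pytest

from factorialtx.containers import DESIGN_CELLS, ExpressionMatrix


def make_matrix(cell_values: dict, gene_ids=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from per-cell replicate values.

    ``cell_values`` maps (strain, copper) -> array-like of shape
    (n_genes, r) of linear-scale values.
    """
    blocks, columns, meta = [], [], []
    for strain, cu in DESIGN_CELLS:
        arr = np.atleast_2d(np.asarray(cell_values[(strain, cu)], dtype=float))
        blocks.append(arr)
        for rep in range(1, arr.shape[1] + 1):
            columns.append(f"{strain}_{cu}_{rep}")
            meta.append({"strain": strain, "copper": cu, "replicate": rep})
    values = np.concatenate(blocks, axis=1)
    genes = gene_ids or [f"G{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=columns),
        pd.DataFrame(meta, index=columns),
    )


@pytest.fixture
def two_gene_matrix() -> ExpressionMatrix:
    """Two genes, 2 replicates per design cell, simple integer intensities."""
    return make_matrix(
        {
            ("REF", "DEFICIENT"): [[100.0, 110.0], [50.0, 52.0]],
            ("REF", "HIGH"): [[95.0, 105.0], [49.0, 51.0]],
            ("DEL", "DEFICIENT"): [[48.0, 52.0], [50.0, 50.0]],
            ("DEL", "HIGH"): [[47.0, 53.0], [50.0, 50.0]],
        },
        gene_ids=["GA", "GB"],
    )
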