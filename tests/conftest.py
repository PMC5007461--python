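"""Shared fixtures: small synthetic panels generated at test time."""

import numpy as np
import pandas as pd
import pytest

from protstrat import preprocess
from protstrat.simulate import PanelConfig, generate_panel


@pytest.fixture(scope="session")
def small_panel():
    """A compact 3-group panel (600 proteins, 5 lines/group, triplicates)."""
    config = PanelConfig(n_proteins=600, lines_per_group=5, seed=11)
    matrix, meta, annotations, survival, truth = generate_panel(config)
    return {"config": config, "matrix": matrix, "meta": meta,
            "annotations": annotations, "survival": survival, "truth": truth}


@pytest.fixture(scope="session")
def processed_panel(small_panel):
    """The small panel taken through the standard preprocessing chain."""
    matrix = preprocess.remove_flagged(small_panel["matrix"])
    matrix = preprocess.filter_replicates(matrix, small_panel["meta"])
    matrix, line_meta = preprocess.average_replicates(matrix,
                                                      small_panel["meta"])
    matrix = preprocess.filter_min_valid(matrix, min(10, matrix.n_samples))
    imputed = preprocess.impute_downshifted(
        matrix, preprocess.ImputationParams(seed=11))
    zscored = preprocess.zscore(imputed, by="rows")
    return {"line_matrix": matrix, "line_meta": line_meta,
            "imputed": imputed, "zscored": zscored,
            "truth": small_panel["truth"]}


def toy_matrix(values, samples=None, proteins=None, **kwargs):
    """Build a ProteinMatrix from a plain nested list (log2 scale)."""
    from protstrat.containers import ProteinMatrix

    arr = np.asarray(values, dtype=float)
    proteins = proteins or [f"P{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j}" for j in range(arr.shape[1])]
    frame = pd.DataFrame(arr, index=pd.Index(proteins, name="protein"),
                         columns=samples)
    return ProteinMatrix(values=frame, **kwargs)
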