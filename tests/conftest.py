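import logging

import numpy as np
import pandas as pd
import pytest

import leatsubtype as L

logging.getLogger("leatsubtype").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (seed 0) with batch correction applied."""
    expr, clinical, truth = L.generate_cohort(L.CohortConfig(seed=0))
    corrected, model = L.combat_correct(expr)
    return {
        "expr": expr,
        "clinical": clinical,
        "truth": truth,
        "corrected": corrected,
        "batch_model": model,
        "scaled": L.scale_genes(corrected),
    }


@pytest.fixture(scope="session")
def default_ranking(default_cohort):
    """NSC CV ranking on the default cohort with planted labels."""
    bundle = default_cohort
    return L.nsc_cv_rank(bundle["scaled"], bundle["truth"].subgroup, n_folds=5, seed=0)


@pytest.fixture()
def toy_matrix():
    """Tiny deterministic expression matrix helper."""

    def make(values, batch=None, genes=None, samples=None):
        values = np.asarray(values, dtype=float)
        genes = genes or [f"G{i}" for i in range(values.shape[0])]
        samples = samples or [f"S{j}" for j in range(values.shape[1])]
        b = pd.Series(batch, index=samples) if batch is not None else None
        return L.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), b)

    return make


@pytest.fixture()
def points_1d():
    """The 1-D toy {0, 1, 10, 11} as a Euclidean distance matrix."""
    pts = np.array([0.0, 1.0, 10.0, 11.0])
    d = np.abs(pts[:, None] - pts[None, :])
    return L.DistanceMatrix(d, pd.Index(["a", "b", "c", "d"]), "euclidean")
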