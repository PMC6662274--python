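import numpy as np
import pandas as pd
import pytest

from agingaccel import ExpressionMatrix, SimulationSpec, generate_cohort


def make_matrix(values: np.ndarray, genes=None, samples=None, ages=None,
                diagnosis=None, tissue=None, **extra) -> ExpressionMatrix:
    """Small helper to build a matrix with minimal metadata."""
    g, n = np.asarray(values).shape
    genes = genes or [f"G{i}" for i in range(1, g + 1)]
    samples = samples or [f"S{i}" for i in range(1, n + 1)]
    meta = pd.DataFrame({
        "age": ages if ages is not None else np.linspace(30, 80, n),
        "diagnosis": diagnosis if diagnosis is not None else ["normal"] * n,
        "tissue": tissue if tissue is not None else ["cortex"] * n,
        **extra,
    }, index=pd.Index(samples, name="sample_id"))
    vals = pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples)
    return ExpressionMatrix(vals, meta)


@pytest.fixture(scope="session")
def small_cohort():
    """100 genes, 60+60 samples, planted structure; shared across tests."""
    spec = SimulationSpec(n_genes=100, n_samples_normal=60, n_samples_ad=60,
                          n_aging_markers=10, n_ad_markers=10, n_planted_edges=5,
                          seed=42)
    return generate_cohort(spec)
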