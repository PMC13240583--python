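import numpy as np
import pytest
import scipy.sparse as sp

from lesionmap.io_formats import CountMatrix
from lesionmap.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def desk_run(tmp_path_factory):
    """One full desk-scale pipeline run shared across the suite."""
    out = tmp_path_factory.mktemp("desk")
    report = run_pipeline(RunConfig(out_dir=str(out), scale="desk", seed=1))
    return {"dir": out, "report": report}


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny")
    report = run_pipeline(RunConfig(out_dir=str(out), scale="tiny", seed=3))
    return {"dir": out, "report": report}


def random_count_matrix(rng, n_genes=40, n_cols=30, density=0.3, max_count=50):
    vals = rng.integers(1, max_count, size=(n_genes, n_cols)) * (
        rng.random((n_genes, n_cols)) < density
    )
    return CountMatrix(
        sp.csr_matrix(vals.astype(np.int64)),
        [f"G{i:04d}" for i in range(n_genes)],
        [f"C{j:04d}" for j in range(n_cols)],
    )
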