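import numpy as np
import pytest

from tcalign.config import PipelineConfig
from tcalign.pipeline import baseline_report, run_pipeline
from tcalign.simulate import generate

FIXTURE_SEED = 3


@pytest.fixture(scope="session")
def default_fixture():
    """The standard synthetic dataset: 2000 genes, 6 types (one tumor-only,
    one cell-line-only), 60 cell lines, 600 tumors, purity Beta(4,2),
    rank-3 contamination."""
    tumors, cell_lines, truth = generate(seed=FIXTURE_SEED)
    return tumors, cell_lines, truth


@pytest.fixture(scope="session")
def pipeline_run(default_fixture):
    """Full pipeline result on the default fixture (shared across tests)."""
    tumors, cell_lines, truth = default_fixture
    cfg = PipelineConfig(rng_seed=FIXTURE_SEED)
    result = run_pipeline(
        tumors, cell_lines, cfg,
        truth.tumor_annotation(), truth.cell_line_annotation(),
    )
    return result


@pytest.fixture(scope="session")
def baseline_run(default_fixture):
    tumors, cell_lines, truth = default_fixture
    cfg = PipelineConfig(rng_seed=FIXTURE_SEED)
    return baseline_report(
        tumors, cell_lines, cfg,
        truth.tumor_annotation(), truth.cell_line_annotation(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
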