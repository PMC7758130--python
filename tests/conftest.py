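import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from mircrosstalk import pipeline, synthdata  # noqa: E402


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full synthetic-mode pipeline run (seed 1), shared across tests."""
    outdir = tmp_path_factory.mktemp("run") / "out"
    cfg = pipeline.PipelineConfig(mode="synthetic", seed=1, outdir=str(outdir))
    result = pipeline.run_pipeline(cfg)
    return cfg, result


@pytest.fixture(scope="session")
def default_truth():
    """Ground truth matching the default_run seed."""
    cfg = synthdata.SynthConfig(seed=1)
    _, truth = synthdata.generate_study(cfg)
    return truth


@pytest.fixture(scope="session")
def small_study_truth():
    """A fast small-scale synthetic study for structural tests."""
    cfg = synthdata.SynthConfig(
        n_genes=300, n_mirnas=60, n_de_genes_ctx1=30, n_de_genes_ctx2=40,
        n_shared_concordant_genes=8, n_shared_discordant_genes=2,
        n_de_mirnas_ctx1=9, n_de_mirnas_ctx2=6, n_shared_mirnas=2,
        n_drugs=6, n_chemicals=8, n_pathways=10, n_bp_terms=12, seed=11,
    )
    bundle, truth = synthdata.generate_study(cfg)
    ann = synthdata.generate_annotations(cfg, truth)
    return cfg, bundle, truth, ann
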