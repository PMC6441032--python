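import warnings
from pathlib import Path

import pytest

from bioscen.pipeline import ExperimentConfig, run_all

ROOT = Path(__file__).resolve().parents[1]


@pytest.fixture(scope="session")
def demo_config() -> ExperimentConfig:
    return ExperimentConfig.from_yaml(ROOT / "configs" / "demo.yaml")


@pytest.fixture(scope="session")
def demo_run(demo_config, tmp_path_factory):
    """One full desk-scale pipeline run shared by the end-to-end tests."""
    outdir = tmp_path_factory.mktemp("demo_run")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        counts = run_all(demo_config, outdir)
    return outdir, counts
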