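import numpy as np
import pytest

from focalamp.pipeline import make_config, run_pipeline
from focalamp.simulate import make_toy_genes, make_toy_genome


@pytest.fixture(scope="session")
def genome():
    return make_toy_genome()


@pytest.fixture(scope="session")
def genes(genome):
    return make_toy_genes(genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fhcc_run(tmp_path_factory):
    """One FHCC-design pipeline run shared by read-only tests."""
    outdir = tmp_path_factory.mktemp("fhcc_run")
    manifest = run_pipeline(make_config("fhcc", 1), outdir)
    return outdir, manifest
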