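import numpy as np
import pytest

from spotfusion import pipeline
from spotfusion.synthetic import SyntheticSpec, generate_slice


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_slice():
    """A small but non-trivial synthetic slice shared by read-only tests."""
    spec = SyntheticSpec(grid_shape=(6, 8), n_genes=60, latent_dim=3, rng_seed=11)
    slc, z = generate_slice(spec)
    return slc, z


@pytest.fixture(scope="session")
def tiny_trained(tmp_path_factory):
    """Stage-1 alignment trained at desk scale: 256 training spots, 64 held
    out, encoders of depth 2 / width 64, 300 steps.  Shared by the recovery
    tests because it is the expensive fixture."""
    outdir = tmp_path_factory.mktemp("tiny-run")
    cfg = pipeline.tiny_config()
    cfg["seed"] = 1
    pipeline.run_pipeline(cfg, outdir, stages=["simulate", "preprocess", "train-align"])
    return cfg, outdir
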