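import numpy as np
import pytest

from chipshift.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One compact end-to-end pipeline run shared by integration-level
    tests (half-size genome, three antibodies, few shuffles)."""
    cfg = RunConfig(
        seed=11,
        chrom_lengths={"chr1": 1_200_000},
        n_genes=60,
        n_enhancers=12,
        antibodies=("Smarca4", "Ezh2", "H3K27ac"),
        n_permutations=2000,
    )
    out = tmp_path_factory.mktemp("small_run")
    return run_pipeline(cfg, out), out


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
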