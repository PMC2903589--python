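import numpy as np
import pandas as pd
import pytest

from pdacsig import SimConfig, simulate_derivation_sets


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_matrix(rng):
    """A 30-gene x 8-sample complete expression matrix."""
    genes = [f"g{i:03d}" for i in range(30)]
    samples = [f"s{i}" for i in range(8)]
    return pd.DataFrame(rng.standard_normal((30, 8)), index=genes, columns=samples)


@pytest.fixture
def spiked_study():
    """Derivation study with a clear 6-gene signal and no batch confound."""
    cfg = SimConfig(
        n_genes=400,
        n_de_genes=6,
        effect_size=1.5,
        noise_sd=0.5,
        batch_shift=0.0,
        missing_rate=0.0,
        seed=11,
    )
    return simulate_derivation_sets(cfg)


@pytest.fixture
def tumor_labels():
    def _get(study):
        tum = study.annotation.query("tissue == 'tumor'")
        return study.expression[tum.sample_id], tum.outcome.to_list()

    return _get
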