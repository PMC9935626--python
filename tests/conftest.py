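import numpy as np
import pytest

from jdr import AjiveConfig, mean_center_genes, run_ajive, simulate_joint_blocks, snr_to_signal_sd

# Study conditions reused across tests: a small strong-signal block pair
# with planted joint rank 3 and per-block individual rank 2.
PAIR_PARAMS = dict(
    n_samples_a=60,
    n_samples_b=70,
    n_genes=200,
    joint_rank=3,
    individual_ranks=(2, 2),
    noise_sd=1.0,
    seed=11,
)


@pytest.fixture(scope="session")
def small_pair():
    params = dict(PAIR_PARAMS)
    params["signal_sd"] = snr_to_signal_sd(5.0, params["n_samples_a"], params["n_genes"], params["noise_sd"])
    a, b, truth = simulate_joint_blocks(**params)
    return mean_center_genes(a), mean_center_genes(b), truth


@pytest.fixture(scope="session")
def fitted(small_pair):
    a, b, _ = small_pair
    return run_ajive(a, b, 5, 5, config=AjiveConfig(n_random_draws=200, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
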