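import numpy as np
import pandas as pd
import pytest

from psynet.simulate import (
    GSES_ITEMS,
    equal_probability_thresholds,
    make_true_network,
    pcor_to_covariance,
    sample_likert,
)

FAST_ESTIMATOR = {"n_lambda": 25}


@pytest.fixture(scope="session")
def chain3():
    """3-node chain with both edge weights 0.5 (hand-computable paths)."""
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 0.5
    W[1, 2] = W[2, 1] = 0.5
    return W


@pytest.fixture(scope="session")
def planted_net10():
    """Planted 10-node self-efficacy-like network."""
    return make_true_network(
        labels=GSES_ITEMS,
        communities={s: "self-efficacy" for s in GSES_ITEMS},
        density=0.3,
        seed=0,
    )


@pytest.fixture(scope="session")
def likert600(planted_net10):
    """600 ordinal rows sampled from the planted 10-node network."""
    cov = pcor_to_covariance(planted_net10)
    thr = [equal_probability_thresholds(4)] * 10
    return sample_likert(cov, thr, 600, seed=42, labels=GSES_ITEMS).frame


def random_signed_weights(p, density=0.5, seed=0, scale=0.3):
    """Random symmetric signed weight matrix (not necessarily a valid GGM)."""
    rng = np.random.default_rng(seed)
    W = np.zeros((p, p))
    iu, ju = np.triu_indices(p, 1)
    mask = rng.random(len(iu)) < density
    vals = rng.uniform(-scale, scale, len(iu)) * mask
    W[iu, ju] = vals
    W[ju, iu] = vals
    return W


@pytest.fixture(scope="session")
def study_csv(tmp_path_factory):
    """Small simulated two-group study written in the input CSV dialect."""
    from psynet.simulate import GeneratorConfig, generate_two_group_study, write_study

    cfg = GeneratorConfig(n_control=300, n_depressed=120, seed=5)
    study = generate_two_group_study(cfg)
    outdir = tmp_path_factory.mktemp("study")
    paths = write_study(study, outdir)
    return paths["data"]
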