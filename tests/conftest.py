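import numpy as np
import pytest

import ecgstream as es


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_stream():
    """6 individuals, 3 chunks — quick end-to-end material."""
    spec = es.StreamSpec(
        n_individuals=6, chunk_sizes=(24, 24, 24), d=12, class_separation=8,
        within_sd=0.1, seed=7,
    )
    return es.simulate_feature_stream(spec)


@pytest.fixture(scope="session")
def small_hyper():
    return es.Hyperparams(r=8, T=4, seed=7)


@pytest.fixture(scope="session")
def trained_small(small_stream, small_hyper):
    trace = []
    state, bank, codebook, states = es.train_stream(
        small_stream.chunks, small_hyper, trace=trace
    )
    return {
        "state": state, "bank": bank, "codebook": codebook,
        "states": states, "trace": trace, "stream": small_stream,
        "hyper": small_hyper,
    }
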