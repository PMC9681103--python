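"""Shared fixtures: small synthetic corpora generated at test time."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from egowords import ego_structure, preprocess

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from egowords.synthetic_data import SyntheticConfig, generate_ego, generate_study


@pytest.fixture(scope="session")
def stopwords():
    return preprocess.load_stopwords()


@pytest.fixture(scope="session")
def small_ego(stopwords):
    """One fully processed synthetic ego: (net, stream, assignments, truth)."""
    config = SyntheticConfig()
    timeline, assignments, truth = generate_ego(config, seed=42, ego_id="egoA")
    windowed = preprocess.window_timeline(timeline, config.T)
    stream = preprocess.process_timeline(windowed, stopwords)
    net = ego_structure.ego_network_from_stream(stream, config.T)
    return net, stream, assignments, truth


@pytest.fixture(scope="session")
def small_study(stopwords):
    """Ten processed egos for cross-ego statistics."""
    config = SyntheticConfig(n_egos=10)
    out = []
    for timeline, assignments, truth in generate_study(config, seed=7):
        stream = preprocess.process_timeline(
            preprocess.window_timeline(timeline, config.T), stopwords
        )
        net = ego_structure.ego_network_from_stream(stream, config.T)
        out.append((net, stream, assignments, truth))
    return out


@pytest.fixture(scope="session")
def topic_ids():
    return SyntheticConfig().topic_ids()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
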