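import numpy as np
import pytest

import igsom


def make_map(weights: dict[tuple[int, int], list[float]]) -> igsom.GrowingMap:
    """Build a GrowingMap with hand-chosen node weights (tests only)."""
    dim = len(next(iter(weights.values())))
    m = igsom.GrowingMap(dim)
    for pos, w in weights.items():
        m._add_node(pos, np.asarray(w, dtype=float))
    return m


def random_connected_map(rng: np.random.Generator, n_nodes: int, dim: int) -> igsom.GrowingMap:
    """A random 4-connected occupied region with random weights."""
    m = igsom.GrowingMap(dim)
    m._add_node((0, 0), rng.random(dim))
    frontier = set(igsom.adjacent_positions((0, 0)))
    while len(m) < n_nodes:
        pos = sorted(frontier)[rng.integers(len(frontier))]
        frontier.discard(pos)
        m._add_node(pos, rng.random(dim))
        frontier.update(p for p in igsom.adjacent_positions(pos) if p not in m)
    return m


TINY = dict(
    n_syllables=10,
    n_words=10,
    n_semantic_categories=3,
    time_frames=20,
    features_per_category=5,
    features_per_word=3,
)


@pytest.fixture(scope="session")
def tiny_corpus() -> igsom.SyntheticCorpus:
    """10 syllables x 3 realizations, 3 semantic categories, 24x20 activations."""
    return igsom.generate_corpus(igsom.SyntheticConfig(seed=11, **TINY))


@pytest.fixture(scope="session")
def tiny_schedule() -> igsom.ScheduleConfig:
    return igsom.ScheduleConfig(fundamental_cycles=5, experiment_cycles=5, seed=11)


@pytest.fixture(scope="session")
def trained_tiny_model(tiny_corpus, tiny_schedule):
    """A model fundamentally trained on the tiny corpus (5 cycles, 11 steps)."""
    model = igsom.IGsomModel.initialize(
        tiny_corpus.audio_dimension, tiny_corpus.semantic_dimension, tiny_schedule.seed
    )
    reports = igsom.run_fundamental_training(model, tiny_corpus.tokens, tiny_schedule)
    return model, reports
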