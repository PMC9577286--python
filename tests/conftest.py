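import numpy as np
import pytest

import groundlex as gl
from groundlex.synthetic import default_net_config


@pytest.fixture(scope="session")
def tiny_world():
    """80-word world, fast enough for per-test pipeline runs."""
    cfg = gl.SynthConfig(n_words=80, seed=7)
    return gl.generate_world(cfg)


@pytest.fixture(scope="session")
def tiny_pipeline(tiny_world):
    """Partition + visual + grounded space for the tiny world at theta=3."""
    world = tiny_world
    visual = world.visual_space()
    partition = gl.partition_vocabulary(world.lexicon, world.ratings, 3.0)
    grounded = gl.build_grounded_space(
        world.lexicon, world.textual, visual, partition, gl.NeighborConfig(N=40, k=5)
    )
    return world, visual, partition, grounded


@pytest.fixture(scope="session")
def tiny_net_cfg(tiny_world):
    return default_net_config(tiny_world.config, epochs=10)


def random_embedding_space(rng, n_words, dim, label="textual"):
    words = [f"x{i}" for i in range(n_words)]
    return gl.EmbeddingSpace(label, {w: rng.standard_normal(dim) for w in words})
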