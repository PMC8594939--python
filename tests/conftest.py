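import numpy as np
import pytest

from quiescell.config import PipelineConfig, SimulationConfig
from quiescell.pipeline import build_movie, segment_and_track


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim():
    """A small full life cycle with divisions (one founder colony)."""
    return SimulationConfig(n_founders=1, t_end=44.0, frame_interval=60.0,
                            image_height=256, image_width=256, seed=5)


@pytest.fixture(scope="session")
def population_run():
    """A division-free 16-cell rendered movie with its analysis primitives,
    shared across tests that only read from it."""
    sim = SimulationConfig(n_founders=16, divisions_enabled=False,
                           t_end=48.0, frame_interval=60.0,
                           image_height=96, image_width=96, seed=21)
    cfg = PipelineConfig(simulation=sim, seed=21)
    lineage, series, stack = build_movie(cfg)
    masks, tracks, features = segment_and_track(stack, cfg)
    return dict(cfg=cfg, lineage=lineage, series=series, stack=stack,
                masks=masks, tracks=tracks, features=features)
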