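import numpy as np
import pytest

from pkaproz import synthetic


@pytest.fixture(scope="session")
def fixtures():
    return synthetic.fixture_suite(seed=0)


@pytest.fixture(scope="session")
def fsk_movie():
    """Saturating-stimulation dish movie, 12 cells, default noise."""
    sc = synthetic.Scenario(kind="fsk_ibmx_saturating", n_cells=12,
                            duration_min=16, seed=7)
    movie, gt = synthetic.render_movie(sc)
    return sc, movie, gt


@pytest.fixture(scope="session")
def dish100_movie():
    """Uniform 100 nM translocation dish movie (1-min frames)."""
    sc = synthetic.Scenario(kind="dish_uniform", dose_nM=100.0, n_cells=6,
                            duration_min=12, seed=5)
    movie, gt = synthetic.render_movie(sc)
    return sc, movie, gt


@pytest.fixture(scope="session")
def chip_movie():
    """Steep-gradient chip movie with migrating nuclei."""
    sc = synthetic.Scenario(kind="chip_gradient", c_source=20.0, c_sink=0.0,
                            n_cells=6, duration_min=60,
                            frame_interval_min=4, seed=3)
    movie, gt = synthetic.render_movie(sc)
    return sc, movie, gt
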