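import numpy as np
import pytest

from placecode import info, maps, synthetic


@pytest.fixture(scope="session")
def small_config():
    """A reduced population keeps the shared fixtures fast; everything else
    follows the study defaults (1.6 m track, 30 fps, 12 trials)."""
    return synthetic.SessionConfig(n_neurons=250, seed=1234)


@pytest.fixture(scope="session")
def bundle(small_config):
    rng = np.random.default_rng(42)
    tuning = synthetic.simulate_tuning(small_config, rng=rng)
    session = synthetic.simulate_trajectory(small_config, rng=rng)
    raster = synthetic.simulate_events(session, tuning, rng=rng)
    return synthetic.SessionBundle(session, raster, tuning)


@pytest.fixture(scope="session")
def binning():
    return maps.BinningSpec()


@pytest.fixture(scope="session")
def speed(bundle):
    return maps.compute_speed(bundle.session)


@pytest.fixture(scope="session")
def lr_map(bundle, binning, speed):
    return maps.place_field_map(bundle.session, bundle.raster, binning, "LR", speed=speed)


@pytest.fixture(scope="session")
def lr_scores(bundle, binning, speed):
    return info.score_direction(
        bundle.session, bundle.raster, binning, "LR",
        n_shuffles=500, seed=7, speed=speed,
    )
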