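import numpy as np
import pytest

from wormvib import BehaviourConfig, PlateConfig, StimulusSchedule, simulate_condition


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_plate():
    return PlateConfig(n_worms=6, image_size=(192, 192))


@pytest.fixture
def clean_plate():
    """Plate with no shadow zones and no sensor noise."""
    return PlateConfig(
        n_worms=6, image_size=(192, 192), shadow_zone_fraction=0.0, noise_pixel_rate=0.0
    )


@pytest.fixture
def clean_behaviour():
    """Every live worm moves every day; no habituation."""
    return BehaviourConfig(no_move_probs=(0.0, 0.0, 0.0, 0.0), habituation_rate=0.0)


@pytest.fixture(scope="session")
def clean_nv_simulation():
    """Shared zero-error-limit simulation: 2 plates, daily acquisition."""
    plate = PlateConfig(
        n_worms=10, image_size=(224, 224), shadow_zone_fraction=0.0, noise_pixel_rate=0.0
    )
    behaviour = BehaviourConfig(no_move_probs=(0.0, 0.0, 0.0, 0.0), habituation_rate=0.0)
    return simulate_condition(
        plate, behaviour, StimulusSchedule.none(), 2, list(range(1, 17)), seed=7
    )
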