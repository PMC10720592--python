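import numpy as np
import pytest

from audisal import (
    PlantedEvent,
    ResponseSpec,
    SceneSpec,
    make_response_set,
    make_scene,
)


@pytest.fixture(scope="session")
def tone_scene():
    """30 s scene with four planted tone-family events over a noise background."""
    spec = SceneSpec(
        "tones",
        duration=30.0,
        planted_events=[
            PlantedEvent(onset=5.0, duration=2.0, kind="tone", carrier=500.0),
            PlantedEvent(onset=11.0, duration=2.0, kind="am-tone", carrier=800.0, mod_rate=8.0),
            PlantedEvent(onset=17.0, duration=2.0, kind="noise-burst"),
            PlantedEvent(onset=23.0, duration=2.0, kind="ripple", carrier=700.0, mod_rate=4.0),
        ],
    )
    waveform, truth = make_scene(spec, seed=11)
    return spec, waveform, truth


@pytest.fixture(scope="session")
def clean_cohort(tone_scene):
    """High-consensus, lapse-free cohort responding to the tone scene."""
    spec, _, truth = tone_scene
    rspec = ResponseSpec(n_participants=80, consensus=0.6, lapse_rate=0.0, seed=7)
    return make_response_set(truth, rspec, spec.duration, scene_id=spec.scene_id)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
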