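import numpy as np
import pytest

from jawdio import features as ft
from jawdio import models
from jawdio import synthetic as syn
from jawdio.audio_io import AudioSegment


@pytest.fixture(scope="session")
def default_specs():
    return syn.default_specs()


@pytest.fixture(scope="session")
def spec_by_condition(default_specs):
    return {
        (s.behavior, s.forage_species, s.forage_height): s for s in default_specs
    }


def tone_segment(freq_hz: float, duration_s: float = 1.0, amplitude: int = 16000,
                 rate: int = 22050) -> AudioSegment:
    t = np.arange(int(duration_s * rate)) / rate
    return AudioSegment((amplitude * np.sin(2 * np.pi * freq_hz * t)).astype(np.int16))


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The default synthetic study dataset: 12 conditions x 50 segments."""
    from jawdio.pipeline import synthesize_default_dataset

    data_dir = tmp_path_factory.mktemp("synthetic_default")
    manifest = synthesize_default_dataset(data_dir, seed=11, counts_per_condition=50)
    return data_dir, manifest


@pytest.fixture(scope="session")
def default_features(default_dataset):
    """Featurized default dataset (filtered pipeline) with encoded labels."""
    from jawdio.pipeline import RunConfig, _featurize

    data_dir, manifest = default_dataset
    cfg = RunConfig()
    x, y, kept = _featurize(manifest, data_dir, cfg)
    return x, y, kept
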