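import numpy as np
import pytest

from dancebeat import AudioSignal
from dancebeat.synthetic import ClickTrackSpec, generate_click_track


@pytest.fixture(scope="session")
def click_120bpm_10s():
    """Clean 120-BPM click track, 10 s, with its ground-truth beat times."""
    return generate_click_track(ClickTrackSpec(bpm=120.0, duration=10.0))


@pytest.fixture(scope="session")
def click_120bpm_30s():
    return generate_click_track(ClickTrackSpec(bpm=120.0, duration=30.0))


@pytest.fixture()
def tone_440(request):
    """1 s of a 440 Hz tone at 8 kHz."""
    t = np.arange(8000) / 8000.0
    return AudioSignal(0.5 * np.sin(2 * np.pi * 440.0 * t), 8000)
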