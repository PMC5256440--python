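import numpy as np
import pytest

from loombias.acoustics import SceneConfig, synthesize
from loombias.trajectory import (
    DIRECTIONS,
    DISTANCE_CLASSES,
    PathSpec,
    make_trajectory,
)

ALL_CONDITIONS = [
    (d, g, v)
    for d in DISTANCE_CLASSES
    for g in DIRECTIONS
    for v in (15.0, 20.0, 25.0)
]


@pytest.fixture(scope="session")
def scene():
    return SceneConfig()

@pytest.fixture(scope="session")
def bare_scene():
    """Scene with absorption, reflection and head shadow disabled (pure
    Doppler + spreading), for envelope checks against the 1/r law."""
    return SceneConfig(air_absorption=False, ground_reflection=False,
                       head_shadow=False)


@pytest.fixture(scope="session")
def rendered_conditions(scene):
    """All 12 factorial conditions rendered (right side) with the full scene."""
    out = {}
    for d, g, v in ALL_CONDITIONS:
        p = PathSpec(d, g, "right", v)
        out[(d, g, v)] = synthesize(make_trajectory(p), scene)
    return out


def short_time_rms(signal, fs, win_s=0.05, hop_s=0.025, lo=0.1, hi=0.9):
    """Windowed RMS over the [lo, hi] fraction of a signal; returns
    (window-center times, rms values)."""
    n = len(signal)
    win = int(win_s * fs)
    hop = int(hop_s * fs)
    starts = np.arange(int(lo * n), int(hi * n) - win, hop)
    times = (starts + win / 2) / fs
    rms = np.array([np.sqrt(np.mean(signal[s:s + win] ** 2)) for s in starts])
    return times, rms


def short_time_fundamental(signal, fs, f_lo=300.0, f_hi=520.0,
                           win_s=0.05, hop_s=0.025, lo=0.1, hi=0.9, pad=8):
    """Track the fundamental by padded-FFT peak picking per window."""
    n = len(signal)
    win = int(win_s * fs)
    hop = int(hop_s * fs)
    window = np.hanning(win)
    freqs = np.fft.rfftfreq(pad * win, 1.0 / fs)
    band = (freqs > f_lo) & (freqs < f_hi)
    starts = np.arange(int(lo * n), int(hi * n) - win, hop)
    times = (starts + win / 2) / fs
    est = []
    for s in starts:
        spec = np.abs(np.fft.rfft(signal[s:s + win] * window, pad * win))
        est.append(freqs[band][np.argmax(spec[band])])
    return times, np.array(est)
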