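import numpy as np
import pytest

from chairkit import beat_outliers as bo
from chairkit import ecg as ecgmod
from chairkit import synthgen
from chairkit.chairio import ChairGeometry

FS_ECG = 500.0


@pytest.fixture(scope="session")
def geometry():
    return ChairGeometry()


@pytest.fixture(scope="session")
def stats():
    return synthgen.PostureStats.default()


@pytest.fixture(scope="session")
def clean_ecg():
    """Noise-free 60 bpm, 60 s trace with ground-truth R indices."""
    sig, r_idx, r_amp = synthgen.gen_ecg(FS_ECG, 60.0, hr_bpm=60.0, hr_sd=0.0, seed=3)
    return sig, r_idx, r_amp


@pytest.fixture(scope="session")
def burst_fixture():
    """The standard artifact-burst fixture: mildly noisy 70 bpm trace with
    high-amplitude broadband bursts, run through filter + detection.

    Frozen seed; returns everything the outlier-method tests need.
    """
    clean, r_idx, r_amp = synthgen.gen_ecg(
        FS_ECG, 180.0, hr_bpm=70.0, hr_sd=0.02, noise=(0.05, 0.02, 0.05), seed=42
    )
    noisy, bursts = synthgen.inject_artifacts(clean, burst_rate=6.0, burst_amp=4.0, seed=43, r_amplitude=r_amp)
    filtered = ecgmod.bandpass_fir(noisy)
    rpeaks = ecgmod.detect_rpeaks(filtered)
    beats = ecgmod.segment_beats(filtered, rpeaks, (200.0, 400.0))
    return {
        "clean": clean,
        "noisy": noisy,
        "filtered": filtered,
        "true_rpeaks": r_idx,
        "bursts": bursts,
        "beats": beats,
    }


def make_beats(arr, fs=FS_ECG, window=(200.0, 400.0), r_indices=None):
    """Assemble a BeatMatrix directly from a 2-D array of waveforms."""
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    if r_indices is None:
        r_indices = np.arange(len(arr)) * 500 + 1000
    return ecgmod.BeatMatrix(arr, np.asarray(r_indices), window, fs)


@pytest.fixture
def template_beat():
    """A plausible single-beat waveform on the default 600 ms window."""
    n = int(0.6 * FS_ECG)
    t = np.arange(n) / FS_ECG - 0.2
    beat = np.zeros(n)
    for off, amp, width in synthgen.BEAT_WAVES.values():
        beat += 0.8 * amp * np.exp(-0.5 * ((t - off) / width) ** 2)
    return beat
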