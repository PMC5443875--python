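import numpy as np
import pytest

from sepsishrv.datatypes import BeatSeries
from sepsishrv.simulate import (
    ECGTemplate,
    ModulationSpec,
    simulate_ecg,
    simulate_rr_ipfm,
)


@pytest.fixture(scope="session")
def metronome_beats() -> BeatSeries:
    """Unmodulated IPFM: constant 140 ms RR over 60 s."""
    spec = ModulationSpec(mean_rr=140.0, components=[], duration=60.0)
    return simulate_rr_ipfm(spec, seed=0)


@pytest.fixture(scope="session")
def modulated_beats() -> BeatSeries:
    """LF + HF modulated beat series, 6 min, with broadband noise."""
    spec = ModulationSpec(
        mean_rr=140.0,
        components=[(0.4, 0.03), (1.5, 0.03)],
        broadband_sd=0.01,
        duration=360.0,
    )
    return simulate_rr_ipfm(spec, seed=1)


@pytest.fixture(scope="session")
def clean_ecg(modulated_beats):
    """Noise-free 1 kHz ECG rendered from the modulated beat series."""
    return simulate_ecg(modulated_beats, ECGTemplate(noise_sd=0.0), seed=2)


@pytest.fixture(scope="session")
def noisy_ecg(modulated_beats):
    """Same beats at 20 dB SNR (QRS amplitude 1 mV, noise SD 0.1 mV)."""
    return simulate_ecg(modulated_beats, ECGTemplate(noise_sd=0.1), seed=3)


def match_beats(detected: np.ndarray, truth: np.ndarray, tol: float):
    """Greedy one-to-one nearest matching; returns (tp, sens, ppv)."""
    used = np.zeros(detected.size, dtype=bool)
    tp = 0
    for t in truth:
        i = int(np.argmin(np.abs(detected - t)))
        if not used[i] and abs(detected[i] - t) < tol:
            used[i] = True
            tp += 1
    return tp, tp / truth.size, tp / detected.size
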