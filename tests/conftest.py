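import numpy as np
import pytest
from scipy.signal import find_peaks

from ecgsynth.preprocess import FilterConfig, preprocess_record
from ecgsynth.sim import default_presets, simulate_cohort


def detect_r_peaks(lead_ii: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Threshold local-maximum R-peak detector (test oracle)."""
    height = 0.5 * lead_ii.max()
    peaks, _ = find_peaks(lead_ii, height=height, distance=int(0.2 * sampling_rate))
    return peaks


@pytest.fixture(scope="session")
def presets():
    return default_presets()


@pytest.fixture(scope="session")
def noiseless_cohort(presets):
    """Small noiseless µV-scale cohort (short records for speed)."""
    return simulate_cohort(
        presets, 3, seed=11, sampling_rate=125, duration=4, noise_sd=0.0
    )


@pytest.fixture(scope="session")
def noisy_cohort(presets):
    return simulate_cohort(
        presets, 3, seed=12, sampling_rate=125, duration=4, noise_sd=8.0
    )


@pytest.fixture(scope="session")
def normalized_cohort(noisy_cohort):
    config = FilterConfig(high_cutoff=40.0)
    return [preprocess_record(r, config)[0] for r in noisy_cohort]
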