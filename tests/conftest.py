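import numpy as np
import pytest

from gaitpac import TrialScenario, generate_trial
from gaitpac.pac_core import BandGrid

FS = 1000.0


@pytest.fixture(scope="session")
def micro_grid():
    """2 x 2 beta-gamma grid: cheap but inside the averaging rectangle."""
    return BandGrid(phase_bands=((18.0, 20.0), (20.0, 22.0)),
                    amp_bands=((90.0, 100.0), (100.0, 110.0)))


@pytest.fixture(scope="session")
def single_cell_grid():
    return BandGrid(phase_bands=((19.0, 21.0),), amp_bands=((95.0, 105.0),))


@pytest.fixture(scope="session")
def fogneg_trial():
    return generate_trial(TrialScenario(fog_status=False, seed=11,
                                        patient_id="P1", trial_id="T1"))


@pytest.fixture(scope="session")
def fogpos_trial():
    return generate_trial(TrialScenario(fog_status=True, seed=12,
                                        patient_id="P2", trial_id="T2"))


def mi_oracle(phase, amplitude, n_bins=18):
    """Independent brute-force MI: explicit loop over bins, direct entropy."""
    width = 2 * np.pi / n_bins
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    for ph, am in zip(phase, amplitude):
        j = int((ph + np.pi) // width)
        if j == n_bins:   # ph == +pi lands in the last bin
            j = n_bins - 1
        sums[j] += am
        counts[j] += 1
    means = [s / c if c else 0.0 for s, c in zip(sums, counts)]
    total = sum(means)
    P = [m / total for m in means]
    H = -sum(p * np.log(p) for p in P if p > 0)
    return (np.log(n_bins) - H) / np.log(n_bins)
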