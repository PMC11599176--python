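"""Unit and property tests for the PAC estimator chain."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitpac as g
from gaitpac.exceptions import (
    DegenerateAmplitudeError,
    DegenerateSurrogateError,
    NyquistError,
)
from gaitpac.pac_core import FIXED_WINDOW_STARTS, BandGrid
from gaitpac.recording import EEGRecording, TrialRecord

from conftest import FS, mi_oracle


# ---------------------------------------------------------------------------
# band grid
# ---------------------------------------------------------------------------

def test_default_grid_is_60_by_40():
    grid = BandGrid.default()
    assert grid.shape == (60, 40)
    # contiguous tiling of the stated ranges
    assert grid.phase_bands[0] == (10.0, 10.5)
    assert grid.phase_bands[-1] == (39.5, 40.0)
    assert grid.amp_bands[0] == (50.0, 52.0)
    assert grid.amp_bands[-1] == (128.0, 130.0)


def test_grid_rejects_gaps_and_malformed_bands():
    with pytest.raises(ValueError):
        BandGrid(phase_bands=((10.0, 11.0), (12.0, 13.0)),
                 amp_bands=((50.0, 52.0),))
    with pytest.raises(ValueError):
        BandGrid(phase_bands=((11.0, 10.0),), amp_bands=((50.0, 52.0),))


# ---------------------------------------------------------------------------
# bandpass + Hilbert
# ---------------------------------------------------------------------------

def test_phase_of_pure_tone_advances_at_carrier_rate():
    t = np.arange(int(10 * FS)) / FS
    x = np.sin(2 * np.pi * 20.0 * t)
    ph = g.bandpass_hilbert(x, FS, (19.0, 21.0), "phase")
    interior = slice(int(0.1 * t.size), int(0.9 * t.size))
    slope = np.polyfit(t[interior], np.unwrap(ph)[interior], 1)[0]
    assert abs(slope - 2 * np.pi * 20.0) / (2 * np.pi * 20.0) < 1e-3


def test_envelope_of_pure_tone_is_flat():
    t = np.arange(int(10 * FS)) / FS
    x = np.sin(2 * np.pi * 100.0 * t)
    env = g.bandpass_hilbert(x, FS, (95.0, 105.0), "amplitude")
    interior = env[int(0.1 * env.size):int(0.9 * env.size)]
    assert interior.std() / interior.mean() < 0.01


def test_band_above_nyquist_rejected():
    x = np.zeros(20000)
    with pytest.raises(NyquistError):
        g.bandpass_hilbert(x, FS, (480.0, 520.0), "amplitude")


def test_too_short_signal_rejected():
    # phase filters are the long ones (sharp transitions)
    with pytest.raises(ValueError, match="filter lengths"):
        g.bandpass_hilbert(np.zeros(3000), FS, (19.0, 21.0), "phase")


# ---------------------------------------------------------------------------
# modulation index
# ---------------------------------------------------------------------------

def test_mi_zero_for_phase_independent_amplitude():
    rng = np.random.default_rng(0)
    phase = rng.uniform(-np.pi, np.pi, 18 * 500)
    mi, dist = g.modulation_index(phase, np.ones_like(phase))
    assert mi == pytest.approx(0.0, abs=1e-12)
    assert dist.P == pytest.approx(np.full(18, 1 / 18), abs=1e-12)


def test_mi_one_when_all_amplitude_in_single_bin():
    rng = np.random.default_rng(1)
    phase = rng.uniform(-np.pi, np.pi, 9000)
    width = 2 * np.pi / 18
    amp = np.where((phase > -np.pi) & (phase <= -np.pi + width), 1.0, 0.0)
    mi, _ = g.modulation_index(phase, amp)
    assert mi == pytest.approx(1.0, abs=1e-12)


def test_mi_matches_entropy_formula_for_three_bin_distribution():
    # bin means 2:1:1 -> P = [0.5, 0.25, 0.25], H = 1.0397, MI = 0.05364
    width = 2 * np.pi / 3
    phase = np.array([-np.pi + 0.5 * width, -np.pi + 1.5 * width,
                      -np.pi + 2.5 * width])
    amp = np.array([2.0, 1.0, 1.0])
    mi, _ = g.modulation_index(phase, amp, n_bins=3)
    expected = (np.log(3) - 1.0397207708399179) / np.log(3)
    assert mi == pytest.approx(expected, abs=1e-12)
    assert mi == pytest.approx(0.0536, abs=1e-4)


def test_mi_error_contracts():
    phase = np.linspace(-3, 3, 100)
    with pytest.raises(DegenerateAmplitudeError):
        g.modulation_index(phase, np.zeros(100))
    with pytest.raises(ValueError):
        g.modulation_index(phase, np.ones(99))
    with pytest.raises(ValueError):
        g.modulation_index(phase, np.ones(100), n_bins=1)
    with pytest.raises(ValueError):
        g.modulation_index(phase, -np.ones(100))


def test_empty_phase_bin_contributes_zero_not_error():
    phase = np.full(100, 0.1)       # single occupied bin
    amp = np.ones(100)
    mi, dist = g.modulation_index(phase, amp)
    assert mi == pytest.approx(1.0)
    assert np.count_nonzero(dist.P) == 1


def test_mi_agrees_with_bruteforce_oracle_on_random_inputs():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = rng.integers(50, 400)
        phase = rng.uniform(-np.pi, np.pi, n)
        amp = rng.gamma(2.0, 1.0, n)
        mi, _ = g.modulation_index(phase, amp)
        assert abs(mi - mi_oracle(phase, amp)) < 1e-12


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.01, 100.0))
def test_mi_scale_invariant_in_amplitude(seed, scale):
    rng = np.random.default_rng(seed)
    phase = rng.uniform(-np.pi, np.pi, 300)
    amp = rng.gamma(2.0, 1.0, 300)
    mi1, _ = g.modulation_index(phase, amp)
    mi2, _ = g.modulation_index(phase, scale * amp)
    assert mi2 == pytest.approx(mi1, abs=1e-10)
    assert 0.0 <= mi1 <= 1.0


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 10_000), st.integers(1, 17))
def test_mi_invariant_under_phase_bin_rotation(seed, shift):
    rng = np.random.default_rng(seed)
    phase = rng.uniform(-np.pi, np.pi, 300)
    amp = rng.gamma(2.0, 1.0, 300)
    width = 2 * np.pi / 18
    rotated = np.angle(np.exp(1j * (phase + shift * width)))
    mi1, _ = g.modulation_index(phase, amp)
    mi2, _ = g.modulation_index(rotated, amp)
    assert mi2 == pytest.approx(mi1, abs=1e-10)


# ---------------------------------------------------------------------------
# surrogate z
# ---------------------------------------------------------------------------

def test_surrogate_z_deterministic_under_seed():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 30_000)
    ph = g.bandpass_hilbert(x, FS, (19.0, 21.0), "phase")
    am = g.bandpass_hilbert(x, FS, (95.0, 105.0), "amplitude")
    z1 = g.surrogate_z(ph, am, FS, n_surrogates=50, seed=7)
    z2 = g.surrogate_z(ph, am, FS, n_surrogates=50, seed=7)
    assert z1 == z2


def test_surrogate_z_constant_amplitude_is_distinct_error():
    phase = np.random.default_rng(0).uniform(-np.pi, np.pi, 5000)
    with pytest.raises(DegenerateSurrogateError):
        g.surrogate_z(phase, np.ones(5000), FS, n_surrogates=20, seed=0)


def test_strong_coupling_gives_large_z():
    profile = g.CouplingProfile.constant(0.9)
    s = g.generate_pac_signal(60.0, FS, profile, seed=123)
    ph = g.bandpass_hilbert(s, FS, (19.5, 20.5), "phase")
    am = g.bandpass_hilbert(s, FS, (98.0, 102.0), "amplitude")
    z = g.surrogate_z(ph, am, FS, n_surrogates=200, seed=0)
    assert z > 5.0


# ---------------------------------------------------------------------------
# comodulogram + band average
# ---------------------------------------------------------------------------

def test_comodulogram_shape_and_determinism(micro_grid):
    s = g.generate_pac_signal(12.0, FS, g.CouplingProfile.constant(0.5), seed=5)
    c1 = g.comodulogram(s, FS, grid=micro_grid, n_surrogates=16, seed=9)
    c2 = g.comodulogram(s, FS, grid=micro_grid, n_surrogates=16, seed=9)
    assert c1.z.shape == micro_grid.shape
    assert np.array_equal(c1.z, c2.z)
    assert np.all((c1.raw_mi >= 0) & (c1.raw_mi <= 1))


def test_band_average_of_constant_comodulogram():
    grid = BandGrid.default()
    com = g.Comodulogram(z=np.full(grid.shape, 2.5),
                         raw_mi=np.zeros(grid.shape), grid=grid)
    assert g.band_average(com) == pytest.approx(2.5)


def test_band_average_selects_exactly_the_beta_gamma_rectangle():
    # midpoint rule on the default tiling: phase mids 13.25..29.75 are
    # indices 6..39 (34 bands); amplitude mids 81..119 are 15..34 (20 bands)
    grid = BandGrid.default()
    z = np.zeros(grid.shape)
    z[6:40, 15:35] = 1.0
    com = g.Comodulogram(z=z, raw_mi=np.zeros(grid.shape), grid=grid)
    assert g.band_average(com) == pytest.approx(1.0)
    assert z.sum() == 34 * 20


def test_band_average_empty_selection_errors(micro_grid):
    com = g.Comodulogram(z=np.zeros(micro_grid.shape),
                         raw_mi=np.zeros(micro_grid.shape), grid=micro_grid)
    with pytest.raises(ValueError):
        g.band_average(com, phase_range=(35.0, 39.0))


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def test_fixed_windows_layout(fogneg_trial, micro_grid):
    series = g.fixed_windows(fogneg_trial, "C3", grid=micro_grid,
                             n_surrogates=8, seed=0)
    assert np.array_equal(series.times, np.array(FIXED_WINDOW_STARTS))
    assert series.values.shape == (5,)


def test_fixed_windows_insufficient_prewalk_errors(micro_grid):
    rng = np.random.default_rng(0)
    rec = EEGRecording(rng.normal(0, 1, (1, 45_000)), FS, ("C3",))
    trial = TrialRecord(recording=rec, walk_start=10.0, walk_end=45.0)
    with pytest.raises(g.CoverageError):
        g.fixed_windows(trial, "C3", grid=micro_grid, n_surrogates=8, seed=0)


def test_sliding_window_counts(single_cell_grid):
    rng = np.random.default_rng(1)
    rec = EEGRecording(rng.normal(0, 5, (1, 60_000)), FS, ("C3",))
    trial = TrialRecord(recording=rec, walk_start=20.0, walk_end=60.0)
    series = g.sliding_mi(trial, "C3", grid=single_cell_grid, n_surrogates=8,
                          seed=0)
    assert series.times.size == 251          # (60 - 10) / 0.2 + 1
    rec10 = EEGRecording(rng.normal(0, 5, (1, 10_000)), FS, ("C3",))
    trial10 = TrialRecord(recording=rec10, walk_start=1.0, walk_end=10.0)
    one = g.sliding_mi(trial10, "C3", grid=single_cell_grid, n_surrogates=8,
                       seed=0)
    assert one.times.size == 1


def test_sliding_step_must_be_positive(fogneg_trial, single_cell_grid):
    with pytest.raises(ValueError):
        g.sliding_mi(fogneg_trial, "C3", step_s=0.0, grid=single_cell_grid)
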