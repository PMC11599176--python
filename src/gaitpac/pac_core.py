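"""Phase-amplitude coupling core.

The estimator chain is: zero-phase FIR bandpass -> Hilbert analytic signal
-> phase / amplitude series -> Kullback-Leibler modulation index (MI) ->
time-lag surrogate z-score -> comodulogram over a band grid -> beta-gamma
band average -> gait-aligned windowing (five fixed 10-s windows, or a
sliding 10-s window advancing 0.2 s).

MI definition: partition (-pi, pi] into N equal phase bins, let P_j be the
mean high-frequency amplitude observed in bin j normalized to sum 1, and
H(P) the Shannon entropy (natural log, 0*log 0 = 0).  Then

    MI = (log N - H(P)) / log N = D_KL(P || uniform) / log N,

which is 0 iff P is uniform (no coupling) and 1 when all amplitude mass
falls in a single bin.

Surrogate normalization: circularly time-shifting the amplitude series
relative to phase destroys coupling while preserving both spectra; the
observed MI is expressed as a z-score against 200 such shifts.  Note this
null is only meaningful for signals whose rhythms have finite coherence
time (true of EEG; a strictly periodic lab signal keeps its coupling under
any circular shift).

Filter design (zero-phase, forward-backward "two-way" FIR, Hamming):

* phase bands get a sharp filter whose transition half-width is
  max(1.5 Hz, band width) -- a strong beta rhythm must not leak into
  neighbouring 0.5-Hz bands, or the comodulogram phase axis smears;
* amplitude bands get a short filter (3 cycles of the band's low edge).
  Its wide transition is deliberate: the amplitude modulation of a
  gamma carrier by an f_p-Hz phase rhythm lives in sidebands at
  +/- f_p around the carrier, and a filter narrower than that removes
  the coupling it is supposed to measure.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.signal import firwin, hilbert, oaconvolve

from .exceptions import (
    CoverageError,
    DegenerateAmplitudeError,
    DegenerateSurrogateError,
    NyquistError,
)
from .recording import TrialRecord

__all__ = [
    "BandGrid",
    "PhaseAmplitudeDistribution",
    "Comodulogram",
    "MISeries",
    "bandpass_hilbert",
    "modulation_index",
    "surrogate_z",
    "comodulogram",
    "band_average",
    "fixed_windows",
    "sliding_mi",
    "FIXED_WINDOW_STARTS",
]

#: Fig-1B style fixed window layout: [-20,-10], [-10,0], [0,10], [10,20], [20,30].
FIXED_WINDOW_STARTS = (-20.0, -10.0, 0.0, 10.0, 20.0)

_BETA_RANGE = (13.0, 30.0)
_GAMMA_RANGE = (80.0, 120.0)


# ---------------------------------------------------------------------------
# band grid
# ---------------------------------------------------------------------------

def _tile(lo: float, hi: float, step: float) -> tuple[tuple[float, float], ...]:
    edges = np.arange(lo, hi + step / 2, step)
    return tuple((float(a), float(b)) for a, b in zip(edges[:-1], edges[1:]))


@dataclass(frozen=True)
class BandGrid:
    """Contiguous, non-overlapping (low, high) band tilings for the phase
    and amplitude axes of a comodulogram.

    The default tiles 10-40 Hz in 0.5-Hz-wide bands (60 bands) and
    50-130 Hz in 2-Hz-wide bands (40 bands).
    """

    phase_bands: tuple[tuple[float, float], ...]
    amp_bands: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for bands, name in ((self.phase_bands, "phase"), (self.amp_bands, "amplitude")):
            if not bands:
                raise ValueError(f"{name} bands empty")
            for (lo, hi) in bands:
                if not lo < hi:
                    raise ValueError(f"malformed {name} band ({lo}, {hi})")
            for (a, b), (c, _) in zip(bands[:-1], bands[1:]):
                if abs(b - c) > 1e-9:
                    raise ValueError(f"{name} bands must tile without gaps or overlap")

    @classmethod
    def default(cls) -> "BandGrid":
        return cls(_tile(10.0, 40.0, 0.5), _tile(50.0, 130.0, 2.0))

    @classmethod
    def from_steps(cls, phase_range=(10.0, 40.0), phase_step=0.5,
                   amp_range=(50.0, 130.0), amp_step=2.0) -> "BandGrid":
        return cls(_tile(*phase_range, phase_step), _tile(*amp_range, amp_step))

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.phase_bands), len(self.amp_bands))

    @property
    def phase_mids(self) -> np.ndarray:
        return np.array([(a + b) / 2 for a, b in self.phase_bands])

    @property
    def amp_mids(self) -> np.ndarray:
        return np.array([(a + b) / 2 for a, b in self.amp_bands])


# ---------------------------------------------------------------------------
# filtering + Hilbert
# ---------------------------------------------------------------------------

@lru_cache(maxsize=512)
def _fir_taps(fs: float, lo: float, hi: float, mode: str) -> np.ndarray:
    if mode == "phase":
        half_width = max(1.5, hi - lo)
        numtaps = int(3.3 * fs / half_width) | 1
    else:
        numtaps = max(int(3 * fs / lo) | 1, 9)
    return firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)


def _apply_fir_twoway(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward application of a (symmetric, odd-length) FIR via
    FFT convolution, with odd-reflection edge padding.  Numerically the
    same two-way filter as filtfilt, at O(n log n) instead of O(n taps)."""
    edge = min(3 * taps.size, x.size - 1)
    left = 2 * x[0] - x[edge:0:-1]
    right = 2 * x[-1] - x[-2:-edge - 2:-1]
    ext = np.concatenate([left, x, right])
    for h in (taps, taps[::-1]):
        ext = oaconvolve(ext, h, mode="same")
    return ext[edge:edge + x.size]


def bandpass_hilbert(signal: np.ndarray, fs: float, band: tuple[float, float],
                     mode: str) -> np.ndarray:
    """Zero-phase FIR bandpass then Hilbert phase or amplitude.

    ``mode="phase"`` returns instantaneous phase in (-pi, pi];
    ``mode="amplitude"`` the nonnegative envelope.  Output length equals
    input length.
    """
    lo, hi = band
    x = np.asarray(signal, dtype=float)
    if not 0 < lo < hi < fs / 2:
        raise NyquistError(f"band ({lo}, {hi}) Hz outside (0, fs/2) at fs={fs}")
    if mode not in ("phase", "amplitude"):
        raise ValueError("mode must be 'phase' or 'amplitude'")
    taps = _fir_taps(float(fs), float(lo), float(hi), mode)
    if x.size <= 3 * taps.size:
        raise ValueError(
            f"signal ({x.size} samples) must exceed 3 filter lengths "
            f"({3 * taps.size} samples) for band ({lo}, {hi}) Hz"
        )
    filtered = _apply_fir_twoway(x, taps)
    analytic = hilbert(filtered)
    return np.angle(analytic) if mode == "phase" else np.abs(analytic)


# ---------------------------------------------------------------------------
# modulation index
# ---------------------------------------------------------------------------

@dataclass
class PhaseAmplitudeDistribution:
    """Phase-binned mean-amplitude distribution P over N equal bins."""

    N: int
    P: np.ndarray

    def entropy(self) -> float:
        nz = self.P[self.P > 0]
        return float(-(nz * np.log(nz)).sum())


def _bin_phase(phase: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    width = 2 * np.pi / n_bins
    idx = np.minimum(((phase + np.pi) // width).astype(np.intp), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return idx, counts


def _mi_binned(idx: np.ndarray, counts: np.ndarray, amplitude: np.ndarray,
               n_bins: int) -> tuple[float, np.ndarray]:
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    total = means.sum()
    if total <= 0:
        raise DegenerateAmplitudeError(
            "amplitude is identically zero; phase-amplitude distribution undefined"
        )
    P = means / total
    nz = P[P > 0]
    H = -(nz * np.log(nz)).sum()
    logN = np.log(n_bins)
    return float((logN - H) / logN), P


def modulation_index(phase: np.ndarray, amplitude: np.ndarray, n_bins: int = 18
                     ) -> tuple[float, PhaseAmplitudeDistribution]:
    """Raw Tort MI in [0, 1] plus the phase-amplitude distribution."""
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape or phase.ndim != 1:
        raise ValueError("phase and amplitude must be equal-length 1-D series")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if amplitude.size and amplitude.min() < 0:
        raise ValueError("amplitude must be nonnegative")
    idx, counts = _bin_phase(phase, n_bins)
    mi, P = _mi_binned(idx, counts, amplitude, n_bins)
    return mi, PhaseAmplitudeDistribution(N=n_bins, P=P)


# ---------------------------------------------------------------------------
# time-lag surrogate z
# ---------------------------------------------------------------------------

def _surrogate_stats(idx: np.ndarray, counts: np.ndarray, amplitude: np.ndarray,
                     n_bins: int, lags: np.ndarray) -> tuple[float, float, float]:
    mi_obs, _ = _mi_binned(idx, counts, amplitude, n_bins)
    sur = np.empty(lags.size)
    for k, lag in enumerate(lags):
        sur[k], _ = _mi_binned(idx, counts, np.roll(amplitude, -int(lag)), n_bins)
    sd = sur.std(ddof=1)
    # ptp == 0 catches bit-identical surrogates whose std is pure
    # mean-roundoff (e.g. a constant amplitude envelope)
    if sd == 0 or np.ptp(sur) == 0:
        raise DegenerateSurrogateError(
            "surrogate MI distribution has zero spread; z-score undefined"
        )
    return mi_obs, float(sur.mean()), float(sd)


def _draw_lags(rng: np.random.Generator, n: int, fs: float, min_lag_s: float,
               n_surrogates: int) -> np.ndarray:
    lo = int(round(min_lag_s * fs))
    hi = n - lo
    if not lo < hi:
        raise ValueError(
            f"series too short for min_lag_s={min_lag_s}: need > {2 * lo} samples"
        )
    return rng.integers(lo, hi, size=n_surrogates)


def surrogate_z(phase: np.ndarray, amplitude: np.ndarray, fs: float,
                n_surrogates: int = 200, min_lag_s: float = 1.0,
                seed: int | np.random.Generator | None = 0,
                n_bins: int = 18) -> float:
    """Surrogate-normalized MI: z = (MI_obs - mean_surr) / sd_surr.

    Each surrogate circularly shifts the amplitude series by a lag drawn
    uniformly from [min_lag_s * fs, n - min_lag_s * fs] samples.  Sample
    standard deviation (ddof=1).  Deterministic given ``seed``.
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lags = _draw_lags(rng, phase.size, fs, min_lag_s, n_surrogates)
    idx, counts = _bin_phase(phase, n_bins)
    mi_obs, mu, sd = _surrogate_stats(idx, counts, amplitude, n_bins, lags)
    return (mi_obs - mu) / sd


# ---------------------------------------------------------------------------
# comodulogram
# ---------------------------------------------------------------------------

@dataclass
class Comodulogram:
    """Grid of surrogate-z-scored (and raw) MI over a BandGrid."""

    z: np.ndarray          # (n_phase_bands, n_amp_bands)
    raw_mi: np.ndarray     # same shape, entries in [0, 1]
    grid: BandGrid
    meta: dict = field(default_factory=dict)


def comodulogram(signal: np.ndarray, fs: float, grid: BandGrid | None = None,
                 n_surrogates: int = 200, seed: int | None = 0,
                 n_bins: int = 18, min_lag_s: float = 1.0,
                 meta: dict | None = None) -> Comodulogram:
    """z-scored MI for every (phase band, amplitude band) pair.

    One seeded generator drives all surrogate lags; lags are drawn per
    (cell, surrogate) iterating cells row-major (phase outer, amplitude
    inner), so results are exactly reproducible.
    """
    grid = grid or BandGrid.default()
    x = np.asarray(signal, dtype=float)
    rng = np.random.default_rng(seed)
    phases = [_bin_phase(bandpass_hilbert(x, fs, b, "phase"), n_bins)
              for b in grid.phase_bands]
    amps = [bandpass_hilbert(x, fs, b, "amplitude") for b in grid.amp_bands]
    n_p, n_a = grid.shape
    z = np.empty((n_p, n_a))
    raw = np.empty((n_p, n_a))
    for i, (idx, counts) in enumerate(phases):
        for j, amp in enumerate(amps):
            lags = _draw_lags(rng, x.size, fs, min_lag_s, n_surrogates)
            mi_obs, mu, sd = _surrogate_stats(idx, counts, amp, n_bins, lags)
            raw[i, j] = mi_obs
            z[i, j] = (mi_obs - mu) / sd
    m = {"n_surrogates": n_surrogates, "seed": seed, "n_bins": n_bins}
    if meta:
        m.update(meta)
    return Comodulogram(z=z, raw_mi=raw, grid=grid, meta=m)


def band_average(com: Comodulogram, phase_range: tuple[float, float] = _BETA_RANGE,
                 amp_range: tuple[float, float] = _GAMMA_RANGE) -> float:
    """Unweighted mean z over cells whose band midpoints fall inside both
    closed ranges.  This scalar is "the beta-gamma PAC MI" downstream."""
    pm = com.grid.phase_mids
    am = com.grid.amp_mids
    psel = (pm >= phase_range[0]) & (pm <= phase_range[1])
    asel = (am >= amp_range[0]) & (am <= amp_range[1])
    if not psel.any() or not asel.any():
        raise ValueError(
            f"no grid cells with midpoints inside phase {phase_range} / "
            f"amplitude {amp_range} Hz"
        )
    return float(com.z[np.ix_(psel, asel)].mean())


# ---------------------------------------------------------------------------
# gait-aligned windowing
# ---------------------------------------------------------------------------

@dataclass
class MISeries:
    """Band-averaged z-MI per window; each time stamps the window's first
    point (gait-relative seconds)."""

    times: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size > 1:
            steps = np.diff(self.times)
            if steps.min() <= 0 or not np.allclose(steps, steps[0], atol=1e-9):
                raise ValueError("times must increase with a uniform step")


def _windowed_zmi(trial: TrialRecord, channel: str, window_starts: np.ndarray,
                  window_s: float, grid: BandGrid, n_surrogates: int,
                  seed: int | None, n_bins: int, min_lag_s: float,
                  phase_range: tuple[float, float],
                  amp_range: tuple[float, float]) -> np.ndarray:
    """Shared engine: filter the whole channel once per band, slice windows,
    z-score MI per (window, cell), beta-gamma band average per window."""
    fs = trial.recording.fs
    x = trial.recording.channel(channel)
    # coverage check up front so the error names the missing span
    span = trial.gait_slice(float(window_starts.min()),
                            float(window_starts.max()) + window_s)
    # filter only the needed span plus a margin of 3 filter lengths so the
    # windows are free of boundary transients
    max_taps = max(_fir_taps(float(fs), float(lo), float(hi), m).size
                   for bands, m in ((grid.phase_bands, "phase"),
                                    (grid.amp_bands, "amplitude"))
                   for lo, hi in bands)
    i0 = max(0, span[0] - 3 * max_taps)
    i1 = min(trial.recording.n_samples, span[-1] + 1 + 3 * max_taps)
    x = x[i0:i1]
    phases = [_bin_phase(bandpass_hilbert(x, fs, b, "phase"), n_bins)[0]
              for b in grid.phase_bands]
    amps = [bandpass_hilbert(x, fs, b, "amplitude") for b in grid.amp_bands]
    pm, am = grid.phase_mids, grid.amp_mids
    psel = np.where((pm >= phase_range[0]) & (pm <= phase_range[1]))[0]
    asel = np.where((am >= amp_range[0]) & (am <= amp_range[1]))[0]
    if psel.size == 0 or asel.size == 0:
        raise ValueError("grid has no cells inside the averaging ranges")
    rng = np.random.default_rng(seed)
    nwin = int(round(window_s * fs))
    out = np.empty(window_starts.size)
    for w, t0 in enumerate(window_starts):
        sl = trial.gait_slice(float(t0), float(t0) + window_s) - i0
        zsum = 0.0
        for i in psel:
            idx = phases[i][sl]
            counts = np.bincount(idx, minlength=n_bins)
            for j in asel:
                lags = _draw_lags(rng, nwin, fs, min_lag_s, n_surrogates)
                mi_obs, mu, sd = _surrogate_stats(
                    idx, counts, amps[j][sl], n_bins, lags)
                zsum += (mi_obs - mu) / sd
        out[w] = zsum / (psel.size * asel.size)
    return out


def fixed_windows(trial: TrialRecord, channel: str, grid: BandGrid | None = None,
                  n_surrogates: int = 200, seed: int | None = 0,
                  window_starts: tuple[float, ...] = FIXED_WINDOW_STARTS,
                  window_s: float = 10.0, n_bins: int = 18,
                  min_lag_s: float = 1.0,
                  phase_range: tuple[float, float] = _BETA_RANGE,
                  amp_range: tuple[float, float] = _GAMMA_RANGE) -> MISeries:
    """Band-averaged z-MI in the five fixed gait-aligned 10-s windows
    [-20,-10], [-10,0], [0,10], [10,20], [20,30] (starts configurable)."""
    grid = grid or BandGrid.default()
    starts = np.asarray(window_starts, dtype=float)
    values = _windowed_zmi(trial, channel, starts, window_s, grid, n_surrogates,
                           seed, n_bins, min_lag_s, phase_range, amp_range)
    return MISeries(times=starts, values=values,
                    meta={"channel": channel, "window_s": window_s,
                          "patient_id": trial.patient_id, "trial_id": trial.trial_id,
                          "fog": trial.fog, "n_surrogates": n_surrogates,
                          "seed": seed})


def sliding_mi(trial: TrialRecord, channel: str, window_s: float = 10.0,
               step_s: float = 0.2, t_start: float | None = None,
               t_stop: float | None = None, grid: BandGrid | None = None,
               n_surrogates: int = 200, seed: int | None = 0, n_bins: int = 18,
               min_lag_s: float = 1.0,
               phase_range: tuple[float, float] = _BETA_RANGE,
               amp_range: tuple[float, float] = _GAMMA_RANGE) -> MISeries:
    """Continuous band-averaged z-MI: a 10-s window advancing by 0.2 s,
    each value stamped at the window's first point.

    ``t_start`` / ``t_stop`` bound the window *start* times (gait-relative
    seconds); by default the windows tile the whole recording, giving
    floor((duration - window_s) / step_s) + 1 values.
    """
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    grid = grid or BandGrid.default()
    rec = trial.recording
    if rec.duration < window_s - 1e-9:
        raise CoverageError(f"recording shorter than one {window_s}-s window")
    lo = -trial.walk_start if t_start is None else t_start
    hi = (rec.duration - trial.walk_start - window_s) if t_stop is None else t_stop
    n_steps = int(np.floor((hi - lo) / step_s + 1e-9)) + 1
    if n_steps < 1:
        raise CoverageError("no sliding window fits the requested span")
    starts = lo + step_s * np.arange(n_steps)
    values = _windowed_zmi(trial, channel, starts, window_s, grid, n_surrogates,
                           seed, n_bins, min_lag_s, phase_range, amp_range)
    return MISeries(times=starts, values=values,
                    meta={"channel": channel, "window_s": window_s,
                          "step_s": step_s, "patient_id": trial.patient_id,
                          "trial_id": trial.trial_id, "fog": trial.fog,
                          "n_surrogates": n_surrogates, "seed": seed})
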