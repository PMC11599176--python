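"""Recording cleanup and the mastoid cross-correlation exclusion rule.

All filters are zero-phase (forward-backward), so preprocessing never
shifts gait-relative timing.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import filtfilt, iirnotch, welch

from .exceptions import IcaConvergenceError, NyquistError
from .recording import EEGRecording

__all__ = ["ExclusionReport", "notch_dbs", "remove_line_noise", "artifact_exclusion"]

#: mean |r| over the four scalp-mastoid pairs at or above this excludes a trial
EXCLUSION_THRESHOLD = 0.8
_PAIRS = (("C3", "M1"), ("C3", "M2"), ("C4", "M1"), ("C4", "M2"))


@dataclass
class ExclusionReport:
    """Outcome of the mastoid contamination check for one trial."""

    mean_correlation: float
    excluded: bool
    pair_correlations: dict = field(default_factory=dict)
    threshold: float = EXCLUSION_THRESHOLD


def notch_dbs(rec: EEGRecording, stim_freq: float, harmonics: bool = True,
              bandwidth: float = 2.0) -> EEGRecording:
    """Notch out the DBS stimulation tone (and, by default, its harmonics
    below Nyquist) on every channel.  Zero-phase IIR notch; output length
    equals input length."""
    nyq = rec.fs / 2
    if not 0 < stim_freq < nyq:
        raise NyquistError(f"stim_freq={stim_freq} Hz outside (0, {nyq}) Hz")
    freqs = [stim_freq]
    if harmonics:
        k = 2
        while k * stim_freq < nyq:
            freqs.append(k * stim_freq)
            k += 1
    out = rec.samples.copy()
    for f0 in freqs:
        b, a = iirnotch(f0, f0 / bandwidth, fs=rec.fs)
        out = filtfilt(b, a, out, axis=-1)
    return rec.copy_with(out)


def _line_power_fraction(x: np.ndarray, fs: float, line_freq: float,
                         half_width: float = 1.0) -> float:
    freqs, psd = welch(x, fs=fs, nperseg=min(int(2 * fs), x.size))
    total = np.trapezoid(psd, freqs)
    if total <= 0:
        return 0.0
    sel = (freqs >= line_freq - half_width) & (freqs <= line_freq + half_width)
    return float(np.trapezoid(psd[sel], freqs[sel]) / total)


def remove_line_noise(rec: EEGRecording, line_freq: float = 60.0,
                      method: str = "ica", threshold: float = 0.5,
                      seed: int = 0) -> EEGRecording:
    """Remove mains noise.

    ``method="ica"`` decomposes the channels with FastICA, zeroes the
    components whose Welch power fraction within line_freq +/- 1 Hz
    exceeds ``threshold``, and reconstructs.  Non-convergence raises
    :class:`IcaConvergenceError`; callers may fall back to
    ``method="notch"``, the deterministic fallback: a one-Fourier-bin
    spectral notch realised by least-squares projection of the
    line-frequency sine/cosine pair out of each channel (exact for a
    phase-stable line, and touching only 2 of n degrees of freedom when
    no line is present).
    """
    if not 0 < line_freq < rec.fs / 2:
        raise NyquistError(f"line_freq={line_freq} Hz outside (0, Nyquist)")
    if method == "notch":
        t = np.arange(rec.n_samples) / rec.fs
        basis = np.column_stack([np.sin(2 * np.pi * line_freq * t),
                                 np.cos(2 * np.pi * line_freq * t)])
        coef, *_ = np.linalg.lstsq(basis, rec.samples.T, rcond=None)
        return rec.copy_with(rec.samples - (basis @ coef).T)
    if method != "ica":
        raise ValueError("method must be 'ica' or 'notch'")
    if rec.n_channels < 2:
        raise ValueError("ICA line removal requires at least 2 channels")
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    ica = FastICA(n_components=rec.n_channels, whiten="unit-variance",
                  max_iter=500, random_state=seed)
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=ConvergenceWarning)
        try:
            sources = ica.fit_transform(rec.samples.T)   # (samples, comps)
        except ConvergenceWarning as exc:
            raise IcaConvergenceError(
                "FastICA did not converge; fall back to method='notch'"
            ) from exc
    reject = [k for k in range(sources.shape[1])
              if _line_power_fraction(sources[:, k], rec.fs, line_freq) > threshold]
    sources[:, reject] = 0.0
    cleaned = ica.inverse_transform(sources).T
    return rec.copy_with(cleaned)


def artifact_exclusion(rec: EEGRecording, threshold: float = EXCLUSION_THRESHOLD
                       ) -> ExclusionReport:
    """Mastoid contamination rule: mean |zero-lag Pearson r| over the four
    (C3/C4, M1/M2) pairs, computed over the full trial; at or above 0.8
    the trial is excluded (boundary inclusive).

    The absolute value is taken because the sign of a scalp-mastoid
    correlation depends on referencing.
    """
    pair_r = {}
    for scalp, mastoid in _PAIRS:
        a = rec.channel(scalp)
        b = rec.channel(mastoid)
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(a, b)[0, 1]
        pair_r[(scalp, mastoid)] = float(r) if np.isfinite(r) else 0.0
    mean_abs = float(np.mean([abs(v) for v in pair_r.values()]))
    return ExclusionReport(mean_correlation=mean_abs,
                           excluded=mean_abs >= threshold,
                           pair_correlations=pair_r, threshold=threshold)
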