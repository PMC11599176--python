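"""Synthetic gait-EEG generator.

Produces multichannel walking trials and whole cohorts with known,
controllable beta-gamma coupling dynamics, so the entire analysis chain is
testable without patient recordings.

Generative model for the coupled channels (C3, C4):

    s(t) = [1 - chi(t) + chi(t) * (1 + sin th_p(t)) / 2] * g(t)
           + b(t) * sin th_p(t) + eps(t)

where ``th_p(t) = 2 pi f_phase t + W(t)`` is the phase of the modulating
beta rhythm, ``g(t)`` the gamma carrier (a pure tone ``sin(2 pi f_amp t +
W'(t))`` or, when ``amp_bandwidth > 0``, band-limited unit-power noise),
``chi(t)`` in [0, 1] the time-varying coupling strength, ``b(t)`` the beta
carrier gain and ``eps`` white Gaussian noise.  ``W`` and ``W'`` are
independent Wiener phase walks (variance ``phase_diffusion`` rad^2 per
second): real EEG rhythms have finite coherence time, and without this the
time-lag surrogate null is degenerate (circularly shifting a strictly
periodic envelope leaves its phase-amplitude coupling intact).  Setting
``phase_diffusion = 0`` and ``amp_bandwidth = 0`` recovers the
deterministic two-tone form exactly.

Cohort-level coupling dynamics relative to gait onset (t = 0):

* FOG- trials: chi ramps down linearly from 0.6 across [-20 s, 0 s] to
  0 and stays low (coupling releases as walking is prepared);
* FOG+ trials: chi flat at 0.15 before onset, ramping up to 0.6 across
  [0 s, +20 s] (coupling fails to release and builds during gait).

The levels sit on the steep part of the surrogate-z response to chi
(the z-MI saturates above chi ~ 0.6 because the surrogate spread grows
with modulation depth), so the injected contrasts are measurable at the
10-s analysis window length.  The ``effect`` parameter interpolates these
profiles toward the common flat level 0.3 (``effect = 0`` makes every
trial's coupling identical and clinical scores independent of it -- the
null cohort).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import NyquistError
from .recording import (
    DEFAULT_CHANNELS,
    EEGRecording,
    TrialRecord,
)

__all__ = [
    "CouplingProfile",
    "ArtifactSpec",
    "TrialScenario",
    "generate_pac_signal",
    "generate_trial",
    "generate_cohort",
    "fog_neg_profile",
    "fog_pos_profile",
    "COHORT_COLUMNS",
]

# amplitude scales, microvolts (synthetic; chosen for a clearly detectable
# but noise-limited coupling at scalp-plausible magnitudes)
PAC_GAIN_UV = 10.0
BACKGROUND_SD_UV = 5.0
LINE_AMP_UV = 20.0
DBS_AMP_UV = 15.0
MOTION_SD_UV = 30.0

COHORT_COLUMNS = ["patient_id", "trial_id", "dataset_count", "LEDD", "DBS_Hz",
                  "UPDRS3", "BBS", "PIGD", "fog_flag", "include_flag"]


def _piecewise(breakpoints: tuple[tuple[float, float], ...], t: np.ndarray
               ) -> np.ndarray:
    """Piecewise-linear profile with flat extrapolation outside the knots."""
    ts = np.array([b[0] for b in breakpoints])
    vs = np.array([b[1] for b in breakpoints])
    return np.interp(t, ts, vs)


@dataclass(frozen=True)
class CouplingProfile:
    """Time-varying beta-gamma coupling description.

    ``chi`` is a piecewise-linear function of time relative to gait onset,
    given as ((t_s, value), ...) knots with flat extrapolation; a constant
    profile is a single knot.  ``beta_gain`` scales the additive beta
    carrier the same way (used to emulate post-onset beta-power drops).
    """

    f_phase: float = 20.0            # Hz, modulating rhythm
    f_amp: float = 100.0             # Hz, modulated fast rhythm
    chi: tuple[tuple[float, float], ...] = ((0.0, 0.0),)
    noise_sd: float = 0.5            # signal units (pre-scaling)
    phase_diffusion: float = 1.0     # rad^2 / s Wiener phase noise
    amp_bandwidth: float = 0.0       # Hz; 0 = pure-tone gamma carrier
    beta_gain: tuple[tuple[float, float], ...] = ((0.0, 1.0),)

    def __post_init__(self) -> None:
        if self.f_amp <= 2 * self.f_phase:
            raise ValueError("f_amp must exceed 2 * f_phase")
        vals = np.array([v for _, v in self.chi])
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("chi values must lie in [0, 1]")
        if self.noise_sd < 0 or self.phase_diffusion < 0 or self.amp_bandwidth < 0:
            raise ValueError("noise_sd, phase_diffusion, amp_bandwidth must be >= 0")

    @classmethod
    def constant(cls, chi: float, **kwargs) -> "CouplingProfile":
        return cls(chi=((0.0, float(chi)),), **kwargs)

    def chi_at(self, t: np.ndarray) -> np.ndarray:
        return _piecewise(self.chi, t)

    def beta_gain_at(self, t: np.ndarray) -> np.ndarray:
        return _piecewise(self.beta_gain, t)


def fog_neg_profile(effect: float = 1.0, **kwargs) -> CouplingProfile:
    """FOG- dynamics: coupling ramps down across [-20 s, 0 s] and stays
    low; beta carrier gain drops across [0, 10 s] (beta desynchronizes
    with walking)."""
    chi = tuple((t, 0.3 + effect * (v - 0.3)) for t, v in ((-20.0, 0.6), (0.0, 0.0)))
    bg = tuple((t, 1.0 + effect * (v - 1.0)) for t, v in ((0.0, 1.0), (10.0, 0.6)))
    return CouplingProfile(chi=chi, beta_gain=bg, **kwargs)


def fog_pos_profile(effect: float = 1.0, **kwargs) -> CouplingProfile:
    """FOG+ dynamics: coupling flat before onset, ramping up across
    [0 s, +20 s]; beta gain unchanged."""
    chi = tuple((t, 0.3 + effect * (v - 0.3)) for t, v in ((0.0, 0.15), (20.0, 0.6)))
    return CouplingProfile(chi=chi, **kwargs)


def generate_pac_signal(duration: float, fs: float, profile: CouplingProfile,
                        seed: int | np.random.Generator | None = 0,
                        t_offset: float = 0.0) -> np.ndarray:
    """Single-channel coupled signal of ``duration`` seconds.

    ``t_offset`` positions the signal on the gait-relative time axis the
    chi profile is defined on (the first sample sits at ``t_offset``).
    Deterministic given ``seed``.
    """
    n = duration * fs
    if n <= 0 or abs(n - round(n)) > 1e-9:
        raise ValueError("duration * fs must be a positive integer")
    n = int(round(n))
    if profile.f_amp >= fs / 2:
        raise NyquistError(f"f_amp={profile.f_amp} Hz >= Nyquist ({fs / 2} Hz)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(n) / fs
    t_rel = t + t_offset
    chi = profile.chi_at(t_rel)
    if profile.phase_diffusion > 0:
        step = np.sqrt(profile.phase_diffusion / fs)
        w_p = np.cumsum(rng.normal(0.0, step, n))
        w_a = np.cumsum(rng.normal(0.0, step, n))
    else:
        w_p = w_a = 0.0
    beta = np.sin(2 * np.pi * profile.f_phase * t + w_p)
    if profile.amp_bandwidth > 0:
        carrier = _bandlimited_noise(rng, n, fs, profile.f_amp,
                                     profile.amp_bandwidth)
    else:
        carrier = np.sin(2 * np.pi * profile.f_amp * t + w_a)
    env = 1.0 - chi + chi * (1.0 + beta) / 2.0
    s = env * carrier + profile.beta_gain_at(t_rel) * beta
    if profile.noise_sd > 0:
        s = s + rng.normal(0.0, profile.noise_sd, n)
    return s


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       center: float, bandwidth: float) -> np.ndarray:
    """Gaussian-spectrum noise carrier at ``center`` Hz, unit peak scale."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    spec = np.fft.rfft(rng.normal(0.0, 1.0, n))
    spec *= np.exp(-0.5 * ((freqs - center) / (bandwidth / 2)) ** 2)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return np.sqrt(2.0) * x / sd if sd > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, fs: float, sd: float,
                exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent background: spectrally shaped white noise, flattened
    below 1 Hz to avoid unbounded drift, scaled to standard deviation sd."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shaping = np.maximum(freqs, 1.0) ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(np.fft.rfft(rng.normal(0.0, 1.0, n)) * shaping, n)
    s = x.std()
    return sd * x / s if s > 0 else x


@dataclass(frozen=True)
class ArtifactSpec:
    """Optional trial artifacts: mains line, DBS stimulation tone and a
    low-frequency motion component shared between mastoids and C3/C4."""

    line_hz: float | None = None          # e.g. 60
    dbs_hz: float | None = None           # stimulation frequency
    mastoid_motion_gain: float = 0.0      # fraction of the motion signal
    #   mixed into C3/C4 (mastoids receive it at gain 1)


@dataclass(frozen=True)
class TrialScenario:
    """Everything needed to synthesize one walking trial."""

    fog_status: bool = False
    pre_walk_s: float = 22.0
    walk_s: float = 32.0
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    updrs3: int = 26
    pigd: int = 5
    bbs: int = 52
    ledd: float = 800.0
    seed: int = 0
    effect: float = 1.0
    patient_id: str = "P0"
    trial_id: str = "T0"
    chi_profile: CouplingProfile | None = None   # overrides the group default
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if self.pre_walk_s < 20:
            raise ValueError("pre_walk_s must be >= 20 s (full pre-gait windows)")
        if self.walk_s < 30:
            raise ValueError("walk_s must be >= 30 s (full post-onset windows)")
        if not 0 <= self.pigd <= 20:
            raise ValueError("PIGD must lie in 0-20")

    @property
    def profile(self) -> CouplingProfile:
        if self.chi_profile is not None:
            return self.chi_profile
        maker = fog_pos_profile if self.fog_status else fog_neg_profile
        return maker(effect=self.effect)


def generate_trial(scenario: TrialScenario) -> TrialRecord:
    """Synthesize one 8-channel trial at 1,000 Hz.

    C3/C4 carry independent realizations of the coupled signal; F3, F4,
    Fz, Cz carry uncoupled 1/f noise; mastoids carry independent noise
    plus, when requested, a motion component mixed into C3/C4 at the
    stated gain.  Line / DBS tones are added to every channel.  Gait
    events sit at the scenario boundaries.
    """
    fs = scenario.fs
    duration = scenario.pre_walk_s + scenario.walk_s
    n = int(round(duration * fs))
    rng = np.random.default_rng(scenario.seed)
    t = np.arange(n) / fs
    profile = scenario.profile
    data = np.empty((len(DEFAULT_CHANNELS), n))
    for ch_i, label in enumerate(DEFAULT_CHANNELS):
        if label in ("C3", "C4"):
            pac = generate_pac_signal(duration, fs, profile, seed=rng,
                                      t_offset=-scenario.pre_walk_s)
            data[ch_i] = PAC_GAIN_UV * pac + _pink_noise(rng, n, fs,
                                                         BACKGROUND_SD_UV)
        else:
            data[ch_i] = _pink_noise(rng, n, fs, BACKGROUND_SD_UV)
    art = scenario.artifacts
    # motion is always drawn so toggling its gain does not shift the rng
    # stream of otherwise-identical scenarios
    motion = _pink_noise(rng, n, fs, MOTION_SD_UV, exponent=2.0)
    if art.mastoid_motion_gain:
        for label in ("M1", "M2"):
            data[DEFAULT_CHANNELS.index(label)] += motion
        for label in ("C3", "C4"):
            data[DEFAULT_CHANNELS.index(label)] += art.mastoid_motion_gain * motion
    if art.line_hz:
        data += LINE_AMP_UV * np.sin(2 * np.pi * art.line_hz * t
                                     + rng.uniform(0, 2 * np.pi))
    if art.dbs_hz:
        if art.dbs_hz >= fs / 2:
            raise NyquistError(f"DBS tone {art.dbs_hz} Hz >= Nyquist")
        data += DBS_AMP_UV * np.sin(2 * np.pi * art.dbs_hz * t
                                    + rng.uniform(0, 2 * np.pi))
    rec = EEGRecording(samples=data, fs=fs, labels=DEFAULT_CHANNELS)
    return TrialRecord(
        recording=rec, walk_start=scenario.pre_walk_s, walk_end=duration,
        patient_id=scenario.patient_id, trial_id=scenario.trial_id,
        fog=scenario.fog_status, dbs_hz=scenario.artifacts.dbs_hz,
        scores={"UPDRS3": scenario.updrs3, "PIGD": scenario.pigd,
                "BBS": scenario.bbs, "LEDD": scenario.ledd},
    )


def generate_cohort(n_patients: int, trials_per_patient: int = 1,
                    effect: float = 1.0, seed: int = 0,
                    fog_fraction: float = 0.4,
                    pre_walk_s: float = 22.0, walk_s: float = 32.0,
                    ) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Synthesize a cohort of patients with group-dependent coupling
    dynamics and clinical scores tied to the injected post-onset coupling.

    PIGD increases (plus noise) in each trial's mean coupling over
    [20, 30] s after onset, so the correlation stage has a known sign;
    ``effect = 0`` makes coupling identical everywhere and PIGD
    independent of it.  Deterministic given ``seed``.
    """
    if n_patients < 2:
        raise ValueError("need n_patients >= 2 (at least one patient per group)")
    rng = np.random.default_rng(seed)
    n_pos = int(np.clip(round(n_patients * fog_fraction), 1, n_patients - 1))
    fog_flags = rng.permutation(
        np.r_[np.ones(n_pos, bool), np.zeros(n_patients - n_pos, bool)])
    trials: list[TrialRecord] = []
    rows = []
    trial_no = 0
    for p in range(n_patients):
        fog = bool(fog_flags[p])
        ledd = float(np.round(rng.normal(800, 200), 1))
        dbs = rng.choice([130.0, 130.0, 145.0, 90.0, np.nan])
        updrs3 = int(np.clip(round(rng.normal(26, 5) + 2 * fog), 0, 80))
        bbs = int(np.clip(round(rng.normal(52, 3) - 2 * fog), 0, 56))
        for _ in range(trials_per_patient):
            trial_no += 1
            maker = fog_pos_profile if fog else fog_neg_profile
            profile = maker(effect=effect)
            chi_post = float(profile.chi_at(np.linspace(20, 30, 11)).mean())
            pigd = int(np.clip(round(1 + 14 * chi_post + rng.normal(0, 2)), 0, 20))
            scen = TrialScenario(
                fog_status=fog, pre_walk_s=pre_walk_s, walk_s=walk_s,
                updrs3=updrs3, pigd=pigd, bbs=bbs, ledd=ledd,
                seed=int(rng.integers(0, 2**31 - 1)), effect=effect,
                patient_id=f"P{p + 1}", trial_id=f"T{trial_no}",
                artifacts=ArtifactSpec(dbs_hz=None if np.isnan(dbs) else dbs),
            )
            trials.append(generate_trial(scen))
            rows.append({
                "patient_id": scen.patient_id, "trial_id": scen.trial_id,
                "dataset_count": 1, "LEDD": ledd,
                "DBS_Hz": dbs, "UPDRS3": updrs3, "BBS": bbs, "PIGD": pigd,
                "fog_flag": fog, "include_flag": True,
            })
    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return trials, table
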