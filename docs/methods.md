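# Methods

`gaitpac` implements a scalp-EEG analysis of beta–gamma phase-amplitude
coupling (PAC) around gait onset in Parkinson's disease: artifact
handling, surrogate-normalized modulation-index comodulograms,
gait-aligned windowing, Welch beta power, mixed-effects window contrasts,
clinical-score correlations and a patient-grouped FOG (freezing of gait)
classifier — together with a synthetic cohort generator that makes every
stage testable without patient recordings.

## The coupling estimator

For one channel and one window, the signal is bandpass filtered into a
low-frequency band (phase) and a high-frequency band (amplitude), both
with zero-phase (forward–backward, "two-way") Hamming-window FIR filters,
and Hilbert transformed. The instantaneous phase is partitioned into
N = 18 equal bins on (−π, π]; with P_j the bin-mean amplitude normalized
to ΣP = 1 and H(P) the Shannon entropy (natural log, 0·log 0 = 0), the
modulation index is

    MI = (log N − H(P)) / log N = D_KL(P ‖ uniform) / log N ∈ [0, 1].

MI = 0 iff P is uniform; MI = 1 when all amplitude mass lies in one bin.
N = 18 follows the convention of the MI literature and is a parameter.

**Surrogate normalization.** Raw MI is biased by window length, spectra
and binning, so each observed MI is z-scored against 200 surrogates
obtained by circularly shifting the amplitude series relative to phase by
a lag drawn uniformly from [min_lag, n − min_lag] samples (min_lag = 1 s,
avoiding near-identity shifts). The z uses the sample standard deviation
(n − 1). One seeded generator per comodulogram draws lags per
(cell, surrogate) in row-major cell order, so results are exactly
reproducible. A caveat that shaped the synthetic generator: this null is
only valid for signals with finite phase-coherence time. A strictly
periodic lab signal keeps its phase–amplitude relation under any circular
shift (the preferred phase merely rotates, and MI is rotation-invariant),
so its z is ≈ 0 at any true coupling strength. Real EEG rhythms drift;
the generator therefore includes phase diffusion (below).

**Comodulogram and band average.** Phase bands tile 10–40 Hz in 0.5-Hz
steps (60 bands) and amplitude bands 50–130 Hz in 2-Hz steps (40 bands),
contiguous and non-overlapping. The z matrix is averaged over all cells
whose band midpoints lie inside the closed beta (13–30 Hz) × gamma
(80–120 Hz) rectangle — 34 × 20 cells on the default grid; the midpoint
rule makes boundary membership unambiguous. This scalar band-averaged
z-MI is "the MI" of every downstream analysis.

**Filter design.** Phase filters are sharp: transition half-width
max(1.5 Hz, band width), so a strong 20-Hz rhythm cannot leak across
neighbouring 0.5-Hz bands and smear the comodulogram's phase axis.
Amplitude filters are short — 3 cycles of the band's low edge — hence
spectrally wide. That width is not sloppiness but a requirement: the
amplitude modulation of a gamma carrier by an f_p rhythm lives in
sidebands at ±f_p around the carrier, and an amplitude filter narrower
than that removes the coupling it is supposed to measure. A corollary,
verified in simulation, is that the comodulogram's amplitude axis has an
intrinsic resolution of roughly ±f_p: every amplitude band whose filter
admits the carrier–sideband pair shows coupling, so a modulated carrier
at 100 Hz produces a flat-topped plateau spanning ~80–120 Hz rather than
a single-cell peak, and the argmax cell wanders within it. The phase
axis, in contrast, localizes to ±1 band. Tests of "peak recovery" on the
amplitude axis fail for this physical reason and are documented as such
rather than worked around by weakening the estimator.

**Windowing.** Windows are 10 s long, aligned to gait onset (t = 0 at the
first step). The fixed scheme uses five windows starting at −20, −10, 0,
10, 20 s; the sliding scheme advances by 0.2 s and stamps each value at
the window's first point. Filtering is done once over the needed span
(plus a margin of three filter lengths) and windows are sliced from the
filtered series, so windows carry no edge transients.

## Preprocessing

* **DBS notch:** zero-phase IIR notch at the stimulation frequency and
  its harmonics below Nyquist (stimulation artifacts are harmonic-rich;
  harmonics can be disabled), bandwidth 2 Hz.
* **Mains removal:** FastICA across channels; components whose Welch
  power fraction within ±1 Hz of the line frequency exceeds 0.5 are
  zeroed before reconstruction. Non-convergence raises a distinct error.
  The deterministic fallback ("notch") least-squares-projects the
  line-frequency sine/cosine pair out of each channel — exact for a
  phase-stable line and touching only 2 of n degrees of freedom when no
  line is present. (A conventional IIR/FIR notch wide enough to suppress
  mains leaves a >1% RMS footprint on broadband input via edge
  transients, which fails the module's own near-identity contract.)
* **Trial exclusion:** mean of the absolute zero-lag Pearson
  correlations of the four (C3/C4 × mastoid) pairs over the whole trial;
  ≥ 0.8 (inclusive) excludes the trial. Absolute values because the sign
  of a scalp–mastoid correlation is reference-dependent; whole-trial
  support is the default, per-window computation is exposed as an option.

## Beta power

Each 10-s window is lowpass filtered at 150 Hz (zero-phase FIR), Welch
estimated (2-s Hann segments, 50% overlap — the package's segmenting
choice), restricted to 1–150 Hz, z-scored across that support, and the z
values averaged over 13–30 Hz into `beta_z`. Channel outliers can be
removed with an iterative two-sided Smirnov–Grubbs test (α = 0.05,
critical value from the t-quantile formula), applied to per-channel
beta_z within a window group.

## Statistics

Repeated measurements of the same (patient, condition, channel, window)
are averaged first so patients with more recordings do not weigh more.
C3 and C4 are averaged into one value per trial and window before
modelling (channel-as-factor is an option). Window and group contrasts
use a linear mixed-effects model with a random intercept per patient —
the smallest structure honouring repeated measures. The fixed-effect
test takes the REML estimate and standard error with a t reference on
containment degrees of freedom: n_patients − 1 for within-patient
(window) contrasts and n_patients − 2 for between-patient (group)
contrasts. This is exact for the balanced paired case; a normal (Wald)
reference would be anticonservative at ~10 patients and fails type-I
calibration in simulation. The implementation is cross-checked once
against lme4/lmerTest in R on a balanced design, where Satterthwaite and
containment degrees of freedom coincide.

Score associations use the Pearson product-moment correlation between
the C3/C4-averaged z-MI in the window starting 20 s after gait onset and
the clinical score (Spearman is exposed as an option). Group score
comparisons use the two-sided Mann–Whitney U with mid-ranks and no
continuity correction (identical groups give p = 1; 1-vs-1 returns p = 1
rather than an error) or Welch's t-test. No multiple-comparison
correction is applied anywhere, deliberately; p-values are reported as
single tests.

## FOG classifier

Every 0.2-s band-averaged z-MI value from the walking-preparation
interval [−20 s, −10 s] (51 window starts per fully covered series)
becomes one single-feature sample labelled with its trial's FOG flag and
grouped by patient. Evaluation is a grouped 80/20 split (whole patients
on one side), standardization fitted on the training portion only, and a
grid search over {RBF, linear} × C ∈ {0.1, 1, 10, 100} × γ ∈ {scale,
0.01, 0.1, 1} under group 10-fold cross-validation; the winner is refit
on the full training portion and scored on the held-out patients. A
structural no-leakage assertion (train/test patient disjointness, one CV
fold per patient) runs on every evaluation. The reported chance level is
the accuracy of always predicting the training-portion majority class on
the held-out samples — on small grouped test sets this is the only
meaningful baseline, since the test portion's own majority is not
available to a legitimate predictor. The validation control is a
patient-label permutation on a no-signal cohort; note that with a fixed
balanced label pool permuted without replacement, chance accuracy is
*not* 50%: a training-majority predictor expects ~27% (the training
majority is anti-correlated with the held-out labels) while a
label-independent rule expects 50%, so the control asserts that the
permutation distribution sits in that chance region, far below the
observed accuracy, rather than pinning it to one number. Patient
memorization through leakage would lift the permutation distribution
toward 100%. Class weights are unweighted by
default; a balanced-weights flag would change the operating point and is
intentionally not silently enabled.

## Synthetic data generator

Coupled channels (C3, C4) follow an amplitude-modulation construction,

    s(t) = [1 − χ(t) + χ(t)(1 + sin θ_p(t))/2] · g(t) + b(t) sin θ_p(t) + ε(t),

with θ_p(t) = 2π f_p t + W(t) the beta phase (f_p = 20 Hz), g(t) the
gamma carrier (f_a = 100 Hz; a pure tone with its own independent phase
walk, or band-limited noise when a carrier bandwidth is set), χ(t) ∈
[0, 1] the time-varying coupling strength, b(t) the beta carrier gain and
ε white noise (sd 0.5). W, W′ are Wiener processes with diffusion
1 rad²/s — enough phase drift that the time-lag surrogate null behaves as
it does on real EEG, while leaving band spectra essentially unchanged.
Setting the diffusion and noise to zero recovers the deterministic
two-tone form exactly (used by the analytic contracts in the tests).
Trials scale this signal to 10 µV and add a 1/f background (exponent 1,
sd 5 µV, flattened below 1 Hz); F3/F4/Fz/Cz carry background only;
mastoids carry independent background plus, when enabled, a slow motion
component (1/f², sd 30 µV) mixed into C3/C4 at a configurable gain.
Optional mains (60 Hz default, 20 µV) and DBS tones (15 µV) are added to
all channels. Trials are 22 s sitting + 32 s walking at 1,000 Hz so the
full window grid fits.

**Group dynamics.** χ(t) is piecewise linear: FOG− trials ramp from 0.6
at −20 s to 0 at gait onset and stay low; FOG+ trials hold 0.15 before
onset and ramp to 0.6 across [0, 20] s; FOG− trials additionally drop
their beta carrier gain from 1 to 0.6 across [0, 10] s (walking-related
beta desynchronization). The surrogate-z response to χ is compressive —
it rises steeply to χ ≈ 0.4 and saturates above ≈ 0.6 because the
surrogate spread grows with modulation depth — so the group profiles are
placed on the steep part of that response curve; this was fixed at
design time from the measured response to constant χ. An `effect`
parameter linearly interpolates all profiles toward a common flat
χ = 0.3 with clinical scores independent of coupling; `effect = 0` is
the null cohort used for type-I calibration. PIGD is drawn as
1 + 14·χ̄(20–30 s) plus N(0, 2) noise, clipped to 0–20 and rounded, so
the correlation stage has a known positive sign; UPDRS-III, Berg Balance
Scale and LEDD are drawn at clinically plausible levels with mild group
shifts.

**What the generator does not emulate:** volume conduction and shared
backgrounds across channels, eye/EMG artifacts, nonstationary mains,
inter-patient spectral variability, or any biophysical head model.
Passing tests therefore demonstrate that the estimator chain and
inference are correct under a controlled ground truth — not that the
clinical effect sizes of real cohorts would be recovered.

## Problem sizes and numerical choices

The package defaults are the full analysis conditions (60 × 40 grid, 200
surrogates, five 10-s windows, 0.2-s sliding step). The test suite and
the acceptance script run the same code at reduced sizes chosen once for
a single-CPU budget: 2 × 2 beta–gamma grids (the averaging rectangle's
core) with 16–50 surrogates for cohort-level simulations, a 30 × 20 grid
with 60 surrogates for parameter recovery, and the full 200 surrogates
wherever the surrogate calibration itself is under test. Power and
calibration claims use 50 and 200 cohort seeds respectively; medians over
20 seeds are used for recovery claims. Degenerate inputs have distinct
error types: an identically zero amplitude (MI undefined) is separated
from a zero-spread surrogate distribution (z undefined), and bit-identical
surrogate sets are treated as zero-spread. Ties at the (−π, π] bin
boundary go to the first bin (measure zero for continuous phase).

## Known limitations

* The comodulogram amplitude axis cannot localize a modulated carrier
  more finely than ±f_phase (sideband physics, above).
* The z-MI is compressive in true coupling strength; it orders coupling
  levels correctly (monotone in simulation) but is not a linear readout.
* MixedLM occasionally estimates zero patient variance on null data
  (boundary REML solutions); this is expected and reported, not an error.
* The EDF writer quantizes to 16 bits over each channel's observed range;
  round-trip error is below one quantization step but not zero.
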