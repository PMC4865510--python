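# Methods

This package analyses synchronized multimodal recordings of simulated
driving — 64-channel EEG, two EOG and two ECG electrodes at 512 Hz, and an
8-channel two-wavelength (735/850 nm) continuous-wave fNIRS probe on the
forehead at 10 Hz — to quantify and classify driver mental fatigue induced
by total sleep deprivation.  Two sessions per subject are compared: one
*well-rested* (≥ 7 h sleep) and one *sleep-deprived* (no sleep).

## Signal model and feature chain

**Trials.** Each session is cut into consecutive non-overlapping 10-s
trials from the start trigger; a 30-min session yields 180 trials.  The
trial grid is shared by all modalities.

**EEG.** After optional ocular-artifact removal (below), channels are
band-pass filtered 1–50 Hz (zero-phase 4th-order Butterworth).  A Welch
PSD (2-s Hamming segments, 50 % overlap, 0.5 Hz resolution) is computed
per trial and channel, integrated over the five canonical bands — delta
1–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–50 Hz, half-open
intervals with shared edges assigned to the upper band — and each band
power is divided by the summed power of all five bands, giving the
relative power level (RPL; dimensionless, sums to 1).  Two scalar
features are formed by spatial averaging: alpha RPL over the right
centro-parietal region (default CP2, CP4, CP6, P2, P4, P6) and beta RPL
over the fronto-central region (default Fz, FCz, FC1, FC2, Cz).  Sleep
deprivation raises centro-parietal alpha RPL and lowers fronto-central
beta RPL, so the beta/alpha ratio falls when fatigued.

**Ocular artifacts.** Logistic infomax ICA (natural-gradient, full-batch,
constant learning rate 0.1, convergence when the gradient's largest entry
drops below 1e-5) is fitted on 1-Hz-high-passed, PCA-whitened EEG.
Components whose absolute correlation with either EOG channel exceeds 0.7
are zeroed before reconstruction.  The plain logistic nonlinearity
handles super-Gaussian sources (blinks); an extended, kurtosis-sign
adaptive update is available for sub-Gaussian sources.  In the pipeline
the ICA is fitted on 8×-decimated samples with at most 100 iterations —
partial convergence is reported, not raised, because a partially
converged unmixing still screens artifacts.

**ECG.** Both chest leads are band-passed 0.1–30 Hz and linearly
detrended.  R-peaks are local maxima above mean + 2.5·SD separated by a
0.3-s refractory period (≈ 200 bpm ceiling); the statistics-based
threshold makes detection invariant to amplitude scaling.  Heart rate is
the R-peak count per half-open minute window, averaged across the two
leads; the per-trial classification feature is the mean RR interval
within each 10-s trial.

**EOG.** The vertical channel is band-passed 0.1–10 Hz; blinks are
threshold peaks (mean + 3·SD, 0.2-s refractory) counted per minute.  The
blink rate is reported but deliberately excluded from the fatigue index:
it does not separate the conditions reliably (drowsy drivers blink
deliberately to fight sleep).

**fNIRS.** The first 30 s of light intensity define the per-channel,
per-wavelength baseline.  Optical-density changes
OD_λ = log10(I_baseline/I_transient) are inverted through the modified
Beer–Lambert law with extinction coefficients
ε_HbO = (0.4646, 1.1596) and ε_HbR = (1.2959, 0.7861) mM⁻¹cm⁻¹ at
(735, 850) nm, emitter–detector separation d = 3 cm, and DPF = 1 folded
into the unit, so concentration changes carry mM/DPF.  The closed-form
two-wavelength inversion is algebraically identical to solving the 2×2
linear system OD = d·DPF·E·(ΔHbO, ΔHbR); tests verify agreement to
1e-12.  Series are smoothed with 10-s windows at 50 % overlap
(interpolated back to the sample grid) and summarized per trial by the
within-trial mean, averaged over the eight prefrontal channels.

**Drift removal and the session-scale HbO signal.** A zero-phase 0.01 Hz
high-pass removes instrumental drift before the *trial-level*
classification features are computed.  The *index-level* HbO component,
however, uses the baseline-referenced series without that high-pass: the
physiological signal of interest is a monotone oxygenation rise across
the whole 30-min session (≈ 0.0006 Hz), which any practical drift filter
would remove together with the drift.  Keeping both requirements —
drift-filtered features and a session-scale oxygenation index — is only
possible by separating the two paths, which is what the pipeline does.
Residual multiplicative sensor drift (simulated time constant 15 min,
amplitude ≤ 2 %) biases the index-level HbO by well under a tenth of the
condition effect.

## The Driving Condition Level

Per minute of driving, three features are computed: the fronto-central
beta / centro-parietal alpha RPL ratio, the mean ΔHbO, and the heart
rate.  Each is min-max normalized to [0, 1] and summed:

    DCL = norm(beta RPL / alpha RPL) + norm(ΔHbO) + norm(HR),  0 ≤ DCL ≤ 3.

All three components are larger when alert, so a smaller DCL means more
fatigue.  Before normalization, values outside mean ± 2·σ of the feature
set are shrunk to the minimum/maximum of the remaining values (note that
for very small sets — n ≤ 5 — no single point can exceed 2σ, so the rule
is inert there by arithmetic, not by choice).  Normalization bounds are
fitted on the pooled minutes of both conditions of one subject: the
relative index below compares the two conditions and requires them on a
common scale, which per-condition bounds would destroy.  This pooling is
a design choice and is configurable.

The session-level DCL is the mean of the per-minute values, and the
relative DCL compares conditions:

    rDCL (%) = 100 − 100 · DCL_sleep-deprived / DCL_well-rested,

higher rDCL meaning a larger fatigue-induced drop.  The per-modality
contribution to the DCL difference is the difference of mean normalized
components; contributions sum exactly to the DCL difference.  A weighted
variant a·norm(ratio) + b·norm(HbO) + c·norm(HR) is searched exhaustively
on the {0, 0.1, …, 1}³ grid for the largest between-condition difference,
with lexicographic tie-breaking.

If a pooled feature has zero range (possible only in degenerate settings
such as identical sessions), its normalized value is pinned at 1/2 so it
contributes equally to both conditions.

## Classification

Per-trial features (EEG: alpha and beta region RPLs; ECG: mean RR;
fNIRS: ΔHbO and ΔHbR trial amplitudes) are classified with Fisher's
linear discriminant, w = (S_pooled + λI)⁻¹(μ₁ − μ₀) with ridge
λ = 10⁻³·tr(S)/d for numerical stability, boundary at the projected
midpoint of the class means, exact ties resolved to the well-rested
class.

Because trials form a time series, splits respect temporal order: the
first 70 % of trials (126 of 180) train, the remaining 30 % (54) test,
and the last six trials (one minute) of each block are dropped so no
training trial lies within a minute of a test trial — 120 train / 48
test per condition.  The scheme is repeated 30 times, rotating the trial
order by one minute (six trials) per repetition; a non-circular truncated
variant is available by flag.  Reported accuracy is the mean over
repetitions.

Modality fusion is classifier stacking: each modality's FLDA decision
score is a feature of a second-level FLDA.  First-level scores on the
training block are produced out-of-fold with a contiguous 5-fold split
(contiguous, again, because trials are serially dependent); without this
the second-level model trains on optimistically biased scores.  At test
time, first-level models refitted on the whole training block score the
test trials.

Small-sample paired condition comparisons use the exact Wilcoxon
signed-rank test: zero differences dropped, average ranks on ties, and
the null distribution of the positive-rank sum computed exactly by
dynamic programming over all 2ⁿ sign assignments (n ≤ 25).

## The synthetic-data generator

No subject recordings are public, so the generator produces sessions
with known ground truth in the directions the study reports:

| parameter | well-rested | sleep-deprived |
|---|---|---|
| heart rate (bpm) | 70, drifting −0.1/min | 62, flat |
| centro-parietal alpha gain | 1.0 | 1.3 |
| fronto-central beta gain | 1.3 | 1.0 |
| ΔHbO trend (mM/DPF per min) | +0.01 | −0.001 |
| blink rate (min⁻¹) | 10 | 14 |

Magnitudes are not reported by the study (only directions and heart
rates are), so the gains and trends were fixed once at physiologically
plausible values and are not tuned.  EEG channels are sums of five
band-limited noise processes (white noise through 4th-order Butterworth
band-passes, scaled to per-band RMS amplitudes of 20/10/10/6/3 µV with
region gains applied) plus 2 µV sensor noise; ECG is a Mexican-hat QRS
template train (~80 ms support, 1 mV) at the instantaneous rate with
10 ms timing jitter, baseline wander, and noise; blinks are Poisson
events rendered as 300 µV Gaussian deflections on the vertical EOG with
a small stereotyped leak into the frontal EEG channels; fNIRS
intensities are produced by the *forward* Beer–Lambert attenuation model
from a ground-truth hemodynamic time course (flat during the 30-s
baseline window, then linear trend + 0.02 Hz physiological sinusoid +
noise; ΔHbR = −0.3·ΔHbO), with multiplicative exponential drift and
0.2 % sensor noise.  All randomness derives from one seed with fixed
per-modality sub-streams, so identical parameters give bit-identical
sessions.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: volume-conducted source topographies (each
channel's band noise is independent, so the EEG is full-rank and ocular
ICs are only partially recoverable, unlike real low-rank artifacts, which
are tested on explicit low-rank constructions), cardiac/respiratory
pulsation in the optical signals, non-stationary spectra, electrode
artifacts, and realistic inter-subject variability.  Condition separations
are cleaner than the study's (synthetic single-modality accuracies
saturate near 1.0 where real drivers gave 60–67 %), so classification
tests check calibration properties (chance level, d′-matched accuracy,
stacking dominance) on matched Gaussian features rather than absolute
synthetic-session accuracies.

## Numerical choices and edge cases

- Filters are zero-phase (forward–backward) so R-peak and blink timings
  are not shifted; filtering is linear to 1e-9 relative.
- Band integration sums Welch bins on [lo, hi) at 0.5 Hz resolution — no
  double counting at shared edges.
- EDF files are written with per-channel physical ranges taken from the
  data, so 16-bit quantization error is ≤ range/65535; EDF+ annotations
  carry the session start/end triggers, and stream alignment crops both
  acquisition streams to their triggered windows (durations must agree
  within 1 s; overlap under 60 s is an error).
- Trials with fewer than two R-peaks give a missing RR value; minutes
  with no detected beats give a missing heart rate, excluded from means.
- Degenerate inputs raise: zero total band power, non-positive light
  intensity, singular extinction matrix, all-identical normalization
  sets, single-class fits, all paired differences zero.
- Default demo sessions are 600 s (60 trials, 10 minutes); the study's
  1800-s geometry is used wherever counts matter and by passing
  `--duration 1800`.

## Known limitations

- The fatigue index is validated on synthetic sessions only; absolute
  rDCL values depend on the preset effect sizes and pooled normalization
  and should not be compared numerically to the published per-subject
  table (its arithmetic, by contrast, is reproduced exactly).
- Logistic infomax cannot separate sub-Gaussian sources; use
  `extended=True` when strong oscillatory artifacts are expected.
- The EDF writer targets the subset of EDF+ this pipeline produces
  (continuous recordings, 1-s records, one annotation channel).
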