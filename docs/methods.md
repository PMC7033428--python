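# Methods

## The estimation problem

Each trial pairs a 14-channel, 0.5 s pre-cue EEG segment with a scalar
reaction delay (seconds). The pipeline estimates a per-subject regression
from segment to delay and quantifies it with the repeated-split MAE defined
in the README. Everything below documents the concrete conventions, the
synthetic test bed, and the choices made where the design was genuinely open.

## Segmentation conventions

Sample indices are 0-based. A cue at time `t` maps to sample
`floor(t * fs)`; the segment is the half-open window of `n_tsi` samples
ending immediately *before* that index. Flooring (rather than rounding)
guarantees that no sample recorded at or after the physical cue time enters
the predictor, at the cost of at most one sample of jitter. Trials whose
window would start before the recording does are dropped and reported.

Amplitude screening flags an epoch when, on any channel, its peak-to-peak
amplitude exceeds `k = 5` times that channel's median peak-to-peak across
epochs. The default pipeline only reports flags — it drops nothing — so the
default behaviour matches an analysis in which visual inspection found no
epoch worth removing. `drop_flagged=True` turns the screen into a filter.

## Zero-padded FFT band filtering

For a segment of length `n = 64` at `fs = 128` Hz: subtract the segment
mean, append `pad_to − n = 192` zeros, take the FFT (length 256, bin
spacing 0.5 Hz), zero every bin whose |frequency| falls outside the
half-open band `[f_low, f_high)` (the DC bin is always zeroed), invert, and
keep the first `n` samples.

* *Half-open edges.* The bands share edges at 4, 8, 12 … Hz; half-open
  intervals assign each shared-edge bin to exactly one band, which makes
  disjoint-band reconstructions exactly additive. The 28–32 Hz gap between
  high beta and gamma-1 is part of the bank, not an accident.
* *Demeaning + zeroed DC.* The step between a segment's offset and the
  appended zeros would smear energy across low frequencies; removing the
  mean before padding and discarding the DC bin neutralizes it. No band
  extends below 1 Hz, so nothing of interest is lost.
* *Zeros appended at the end only*, and the reconstruction truncated back to
  the first `n` samples, so features never describe the padding.
* *No taper.* The 64-sample rectangular window has a 2 Hz-wide mainlobe.
  Consequences, verified against a direct-summation oracle: a tone at a
  band centre keeps ≳ 87% of its variance, a tone 1 Hz inside a band edge
  keeps ~70%, a tone 1 Hz outside leaks ~5% in, and tones ≥ 2 Hz outside
  leak < 2%. Padding refines the bin spacing; it cannot narrow the
  mainlobe. These bounds are asserted in the tests as properties of this
  filter, not of an ideal one.

## Features and standardization

`logvar = ln` of the population (1/N) variance. The 1/N choice is recorded
for reproducibility of fixtures; it cancels after z-scoring. Columns are
ordered channel-major (all bands of AF3, then F7, …), labelled
`CHANNEL_Band`. Zero variance in any (trial, channel, band) is an error
naming the offender — it signals a dead channel, not a small feature.

Standardization statistics are computed from the training rows of each
repetition only and applied unchanged to the test rows. The alternative
(fit on all rows) leaks test-set scale into training; the leak-free reading
is the default and the only one used in the shipped analyses.

## Tuning and evaluation protocol

`round(0.75 n)` trials (half away from zero) train, the rest test, 11
repetitions, repetition `r` seeded `base_seed + r`. Grid search scores every
hyperparameter combination by the mean MAE over 3 shuffled inner folds of
the training rows; ties resolve to the earlier grid point. For the SVR, the
number of features kept (`k ∈ {5, 10, 20, 40, 140}`) is one more grid axis;
the |Pearson r| ranking is recomputed inside every inner fold so no
validation row influences the selection it is scored with, and the final
refit re-ranks on the full training set.

Default grids (deliberate, overridable defaults — chosen as plausible
log-spaced ranges, not tuned to any dataset): LASSO / LASSO-LARS
α ∈ 10⁻⁴…10¹ (7 log-spaced); kernel ridge α ∈ 10⁻³…10², γ ∈ 10⁻⁴…10¹
(decades); SVR C ∈ 10⁻²…10³, γ ∈ 10⁻⁴…10¹ (decades), ε ∈ {0.01, 0.05, 0.1} s.

The shuffled control permutes the *training* targets of each repetition
(its own seeded stream) before tuning; test targets remain true, so its MAE
measures what the full tuned machinery achieves with no usable
feature-target link — empirically, predict-the-average performance.

`MAE_s` averages per-repetition mean AEs without pooling, so repetitions
with unequal test sizes weigh equally; the AE standard deviation and
maximum are computed over the pooled AEs of all repetitions.

## Statistical layer

* **Robust trend.** Delay vs cue timestamp, line fit by IRLS with Huber's T:
  weights 1 for |r|/scale ≤ c, else c/(|r|/scale), c = 1.345 (≈95% Gaussian
  efficiency), scale = median(|r|)/0.6745 about zero (the intercept centres
  the residuals; this matches the widely used implementations and lets the
  test suite cross-check slopes against one to 10⁻⁴). Iteration stops when
  the largest coefficient change or the relative change of the Huber
  objective drops below 10⁻⁸; cap 5000 iterations (on very small n the
  weight of a borderline point decays geometrically and hundreds of cheap
  iterations are normal). Non-convergence raises with a trace. The slope
  p-value uses the asymptotic normal statistic slope/se; with ~48 events no
  small-sample refinement is attempted.
* **ANOVA.** Classical between/within mean squares over the pooled AEs
  (all repetitions concatenated per algorithm), F on (k−1, N−k) df.
  All-identical data returns (F=0, p=1); zero within-group spread with
  nonzero between-group spread raises (F undefined).
* **Pairwise t-tests.** Welch by default (group sizes can differ when trials
  are dropped); a paired mode exists for matched designs and reports p = 1
  when all differences are zero. Raw p-values by default, mirroring how
  post-hoc tables are usually printed; Holm/Bonferroni are available but off.

## The synthetic test bed

One simulated session emulates: a 7200 s recording at 128 Hz over the
standard 14-channel montage; cue gaps ~ N(150 s, 60 s) truncated below at
10 s by resampling (back-to-back cues are physically implausible; configs
where truncation would discard > 50% of draws are rejected as degenerate);
the schedule stops one segment-plus-response margin (5.5 s) before the
session ends, giving ≈ 47 events per session on average.

Each channel is a sum of ten sinusoids — one per band, carrier at the band
centre, random phase — plus 1/f noise band-limited to 0.16–43 Hz (the
emulated headset's useful bandwidth; an optional 50 Hz mains tone is off by
default because the headset notch-filters it). Oscillation amplitudes sit
at a 10 μV baseline except inside each trial's pre-cue window, where they
take per-trial log-normal draws (σ = 0.6 in log-amplitude), making the
log-variance features approximately Gaussian by construction. The noise rms
is 4 μV: oscillations comparable to, and in the planted band above, the
broadband floor. With these levels the measured log-variance of a planted
band tracks the planted one at r ≈ 0.95; the residual comes from in-band
noise power and from rectangular-window leakage of neighbouring carriers,
both of which a 64-sample window makes irreducible.

Reaction delays are generated as
`delay_i = max(0.25, 0.55 + Σ coupling[c,b] · logvar_icb + ε_i)`,
ε ~ N(0, 0.05 s), where `logvar_icb` is computed from the same sample grid
the synthesized signal places in the window — the generative model and the
extraction pipeline agree exactly by construction. The recovery scenario
plants a single coupling of 0.3 s per logvar unit on (O1, alpha), which
keeps delays in the 0.3–3.3 s range typical of vigilance tasks. Responses
are emitted as `cue + delay` so the event table has the same shape as a
real recording's markers.

What the generator does **not** emulate: ocular/EMG artifacts, non-
stationary background spectra, volume conduction (channels are
independent), or any nonlinear brain-behaviour link. Passing recovery
tests therefore shows the pipeline is correct and sensitive under its own
assumptions — not that real EEG carries this much signal.

## Problem sizes used in the shipped analyses and tests

The analysis scripts and the recovery test run full 2-hour sessions
(~50 trials) with the complete default grids. The null-calibration study
runs 20 full sessions with a reduced SVR grid (C ∈ {1, 10, 100},
γ ∈ {0.003, 0.03}, ε = 0.05, k ∈ {10, 140}) — under a null coupling the
grid's breadth does not change what the control can learn, and the reduced
grid keeps the 40 tuned evaluations proportionate. Unit tests use 10-minute
sessions with 40 s cue gaps, which exercise identical code paths.

## Known limitations

* EDF support writes 16-bit files through a minimal encoder (round-trip
  error bounded by the digitization step and verified against an
  independent reader); physical ranges are per-channel symmetric.
* The band filter's pass/stop behaviour is window-limited (see above); a
  4 Hz band at 0.5 s cannot behave like an ideal filter.
* Hyperparameter grids and the SVR ranking rule are declared defaults, not
  reconstructions of any particular study's settings.
* The slope p-value is asymptotic; with heavy-tailed delays and ~48 points
  it is indicative, not exact.
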