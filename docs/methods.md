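# Methods

## Signal conditioning

EEG is filtered with a 10th-order Butterworth band-pass (0.3–30 Hz),
designed in zero-pole-gain form, converted to second-order sections and
applied forward–backward, so the magnitude response is squared and the phase
response is zero. Forward–backward filtering needs edge padding; we use
odd-reflection padding with a default length of six cycles of the low band
edge (20 s at 0.3 Hz/100 Hz), capped at the signal length. Shorter padding
(e.g. three filter orders, the common library default) leaves visible
low-frequency edge transients several seconds into a record, which the
bundled tests measure; the pad length is an explicit argument for anyone who
prefers the shorter convention. Resampling to the 100 Hz analysis rate uses
a polyphase anti-aliasing filter with the exact rate ratio reduced to lowest
terms.

All downstream processing happens at 100 Hz. Sample *i* covers the
half-open interval `[i/fs, (i+1)/fs)`; events are half-open `[onset,
onset+duration)` and rasterize to `[round(onset·fs), round(end·fs))` with
round-half-even.

## Sampling design

Recordings contribute non-overlapping 115 s blocks of artifact-free N2
sleep. Each block is scored as five 25 s epochs at offsets 0, 22.5, 45,
67.5 and 90 s, so consecutive epochs overlap by 2.5 s and the five epochs
tile the block exactly (25 + 4 × 22.5 = 115). Epoch ids are `b{i}e{j}`.
Viewed-epoch bookkeeping is mandatory: a scorer who viewed an epoch and
marked nothing contributes weight 0 there, while a scorer who never viewed
it is excluded from that epoch's denominator — averaging only makes sense
over viewers.

## Group consensus

Confidence weights are 1 (high), 0.75 (medium), 0.5 (low), 0 (unmarked).
Per scorer and sample, the weight is the maximum over their markings
covering the sample; where two overlapping epochs show the same instant the
scorer's highest score wins. Scores are averaged per sample over that
sample's viewers, and maximal runs strictly above the group-consensus
threshold (GCt) become candidates. "Strictly above" makes GCt = 0 a
meaningful setting (any non-zero agreement passes).

Cleanup runs merge-then-filter: adjacent candidates closer than 0.1 s are
merged when at least one member is shorter than 0.3 s (repeated to a
fixpoint), then events shorter than 0.3 s or longer than 2.5 s are dropped.
The merge rule's quantifier (either vs. both neighbours short) is genuinely
ambiguous; we require *at least one* short member, which is the weaker and
therefore more merge-friendly reading, and it is confined to one function if
a user disagrees.

The expert panel's consensus is the gold standard (GS). Individual scorers
are evaluated against a leave-one-out GS (their tracks removed from
numerator and denominator) to avoid self-agreement bias. The GCt that
maximizes mean individual f1 is found by a full grid scan (default grid
0.05–0.95, step 0.05; ties go to the smallest value).

## Event-level evaluation

Two events match when their interval intersection-over-union reaches the
overlap threshold (default 0.2). Matching is one-to-one and greedy on the
globally greatest IoU; zero-overlap pairs never match, and ties break to the
earlier event onset, then the earlier detection onset (the underlying
"greatest overlap wins, extra detections are false positives" rule does not
fix tie handling; the bundled brute-force oracle implements the same rules
independently and the two agree exactly on 1000+ random instances).
Degenerate conventions keep sweep curves plottable: precision is 0 with no
detections, recall is NaN with no reference events, and f1 is 0 whenever
precision + recall is 0.

The scorers-needed experiment draws n scorers per epoch uniformly without
replacement among that epoch's viewers (three independent draws by
default), builds the partial consensus with a panel-size-dependent GCt, and
scores it against a reference. The GCt schedule is 0.4 for one scorer per
epoch, linearly approaching the subtype optimum at five scorers, constant
beyond; only the two endpoints of this schedule are anchored by prior
results, so the interior is configurable.

## Per-subject characterization

Density is events per minute over the scored time (115 s per block).
Amplitude is the maximum peak-to-peak swing between *consecutive* local
extrema of the 11–16 Hz filtered signal within the event — the oscillatory
peak-to-peak convention, not global max − min (the two agree on a clean
sinusoid, which the tests exploit). Dominant frequency is the arg-max of
the FFT magnitude of the 10–16 Hz filtered event segment zero-padded by
5 s, restricted to 9–17 Hz to guard against filter-skirt leakage; the
frequency resolution is 1/(duration + 5) Hz ≈ 0.17 Hz for a 1 s event. The
amplitude band (11–16 Hz) and frequency band (10–16 Hz) differ by
convention of the underlying protocol; both are arguments.

Cross-method agreement uses squared Pearson correlation of per-subject
vectors (r², the stated statistic of the protocol); group contrasts use the
two-sided Mann–Whitney test with 0.05/0.01/0.001 star coding. Both call
standard scipy routines.

## Automated detectors

All five detectors consume the 100 Hz broad-band signal and apply their
published constants:

| detector         | band (Hz)  | statistic                          | threshold            |
|------------------|-----------|-------------------------------------|----------------------|
| envelope         | 11–15     | Hilbert envelope                    | seed 8×mean, extend 2×mean |
| rms_std          | 11.3–15.7 | RMS, 100 ms windows, 50 ms step     | 1.5 × STD            |
| rms_percentile   | 11–15     | RMS, contiguous 25 ms windows       | 95th percentile      |
| wavelet          | ~10–16    | 13 Hz Morlet power, 0.1 s average   | 4.5 × mean           |
| a7               | 11–16     | four features, 0.3 s win, 0.1 s step| 1.25 µV², 1.6σ, 1.3σ, 0.69 |

Decisions where the published summaries are silent:

- **Baselines.** Record-level means/STDs/percentiles are computed over the
  full artifact-free record; A7 additionally z-scores its relative-power and
  covariance features against a 30 s centred rolling baseline and errors on
  records shorter than that.
- **Sigma filters.** Detector-internal band-passes are 4th-order zero-phase
  Butterworth. The steep 10th-order conditioning filter rings far beyond a
  short burst: a strong 1 s spindle smears into a multi-second
  supra-threshold run and is then discarded by the duration bound. The
  order is an argument.
- **rms_std threshold.** Read literally as 1.5 × STD of the RMS series (no
  mean term); `threshold_mode="mean_plus_std"` provides the alternative
  reading. The literal form is permissive on calm records — its precision is
  the weakest of the five — but detects sparse strong bursts reliably
  because they inflate the STD.
- **A7 transforms.** Absolute sigma power is thresholded on the log10 scale
  (`log10(mean square) > log10(1.25)`), matching the original detector's
  log-scale criterion; the relative-power feature is log10-transformed
  before z-scoring, and the covariance uses a signed `log10(1 + |cov|)` —
  a plain log of near-zero covariances produces extreme outliers that
  inflate the rolling baseline's spread and suppress every z-score.
- **Morlet parameters.** Single scale, centre 13 Hz, Gaussian time width
  chosen so the power response is half-max 3 Hz off-centre (σ_t ≈ 44 ms),
  i.e. half-power points near 10 and 16 Hz.
- **Duration bounds.** 0.3–3.0 s for all detectors (none is published with
  a bound; without one, threshold crossings of a single sample count as
  events).
- A zero-phase band-pass of a pure out-of-band tone is a *rescaled copy* of
  the tone, so the A7 correlation feature stays ≈1 on noiseless periodic
  input; the feature discriminates as intended as soon as any broadband
  background is present. The tests encode the realistic (noisy) case.

## Synthetic data

The generator emulates what the pipeline assumes about its input, not a
full night of sleep:

- **Background**: Gaussian 1/f^α noise (α = 1), band-limited 0.3 Hz–Nyquist,
  scaled to a target RMS (default 15 µV — a plausible broad-band N2 level).
- **Spindles**: Hann-enveloped constant-frequency sinusoids; defaults
  3/min, 0.5–1.5 s, 11–16 Hz, 20–50 µV peak-to-peak — bracketing the
  densities/durations/amplitudes reported for healthy cohorts. Placement is
  a thinned Poisson process with a 0.5 s dead time, 1 s clear of block
  edges, so truth lists always satisfy the matcher's disjointness invariant.
  A `chirp_hz_per_s` flag adds intra-burst frequency drift for users who
  want to stress the constant-frequency assumption.
- **Scorers**: each detects each true event with probability
  `sensitivity × logistic((amplitude − midpoint)/scale)` (defaults make the
  logistic saturate, so the probability is effectively `sensitivity`),
  jitters both boundaries with Gaussian noise, rates confidence by the
  event's amplitude tertile (optionally perturbed one level with a
  configurable probability), and adds Poisson false positives. Overlapping
  marks from one scorer are resolved first-wins so records stay valid.
- All randomness flows from one seed through `SeedSequence` sub-streams;
  identical seeds give bit-identical output.

What passing tests on this generator show: the consensus, evaluation and
characterization machinery is arithmetically correct and recovers known
parameters under the stated noise model. What they do not show: performance
on real N2 EEG, whose background is non-stationary, whose spindles chirp
and deviate from Hann envelopes, and whose scorers have structured biases
no parametric family captures.

The detector checks use a deliberately easy regime (`HIGH_SNR_EEG`:
60–90 µV bursts at 11.5–14.5 Hz on an 8 µV background, 2/min) — mid-band
frequencies keep bursts inside every detector's published pass-band, and
the contrast is high enough that a correct implementation should find
nearly all of them. These are sanity checks of the implementations, not
benchmarks of the algorithms.

## Problem sizes

The bundled tests and the acceptance script run on 2–3 blocks (230–345 s)
per synthetic subject with panels of up to 10 scorers, and 1000+ random
small instances for the matcher oracle — sizes at which every quantity is
stable across seeds while the whole suite stays fast. All sizes are
arguments; nothing in the implementation assumes them.

## Known limitations

- Real-data file support is EDF (via `mne`) and a trivial CSV dialect; the
  annotation TSV dialect is self-defined, and a converter from public
  annotation archives is future work.
- No artifact detection: blocks are assumed artifact-free by design.
- Scorer reliability modelling beyond uniform confidence-weighted averaging
  (e.g. Dawid–Skene) is out of scope, as are sample-level agreement metrics
  and ROC analyses.
- The three-component decomposition detectors that depend on external
  sparse-optimization designs are not reimplemented; their published
  summaries underdetermine them.
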