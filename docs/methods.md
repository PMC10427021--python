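# Methods

`neurosong` re-implements, as a tested reusable pipeline, a complete
encoding/decoding analysis of music perception from intracranial
recordings: from a song waveform and multichannel neural data to
significant spectrotemporal receptive fields (STRFs), decoded and
reconstructed spectrograms, excerpt-identification statistics, receptive
field component decomposition, and virtual-lesion ablations. Because the
patient recordings themselves are not required, a synthetic-data generator
emulates the signal structure of the study conditions so that every stage
is exercised end to end. This note documents the models, the parameters
that matter, the numerical choices, and what the synthetic results do and
do not show.

## Signal model

### Auditory spectrogram

The stimulus representation is a cochlea-inspired time-frequency
magnitude: a bank of zero-phase Butterworth bandpass filters at
geometrically spaced center frequencies f_k = f_min (f_max/f_min)^(k/(K-1))
(default K = 32 bins from 188 to 6,745 Hz; the full-resolution variant
uses 128 bins from 180 to 7,246 Hz), half-wave rectification, low-pass
envelope smoothing (`env_cutoff_hz`, default 30 Hz — the cochlear model's
smoothing constant is unspecified, so it is a config parameter), and
polyphase downsampling to a 100 Hz frame rate. Endpoint-exact geometric
spacing was chosen because the printed endpoint pairs are not exactly
consistent with a pure 24-channels-per-octave ladder. Band edges sit at
the geometric midpoints to neighbouring bins. The frame count is always
round(duration x 100); 190.72 s of audio gives 19,072 frames.

For modeling, the spectrogram is log-compressed, values <- log(values +
floor), with the floor defaulting to 1e-5 of the spectrogram maximum so
the dynamic range is bounded regardless of input gain.

### High-frequency activity (HFA)

Raw multichannel recordings (study rate 1,200 Hz, with 10 s symmetric
padding) are cleaned with notch filters at 60 Hz and harmonics up to
300 Hz (Butterworth order 4, 2 Hz bandwidth) and a 1 Hz high-pass
(order 4). HFA is a bandpass-Hilbert estimate: thirteen 20 Hz sub-bands
spanning 70-150 Hz in 5 Hz steps; per sub-band, bandpass -> median
common-average reference per splitter-box group -> Hilbert envelope ->
robust scaling (median removed, divided by the 10th-90th interpercentile
range, percentiles by linear interpolation). The scaled envelopes are
averaged, pads removed, the series polyphase-downsampled to 100 Hz,
re-expressed in robust z-units (the averaged series is rescaled once more
so the outlier threshold has a defined unit), and samples beyond |z| > 7
are tagged as outliers for later row removal.

Numerical choices the source recipe leaves open, fixed here: all IIR
filters run forward-backward (zero phase) so response latencies survive
for the STRF lag axis; downsampling is polyphase anti-aliased
resampling; the final robust rescaling defines the "standard deviation"
unit of the outlier rule. The 20 Hz sub-band width admits envelope
modulations up to 10 Hz, which is what lets the 6.66 Hz rhythmic
modulation through.

Two practical caveats, verified on synthetic data: the median reference
needs several electrodes per splitter group (with 2-4 channels the median
contains a large share of any single channel and distorts it), and the
per-sub-band robust scaling assumes broadband signals — a pure sinusoid
leaves carrier-free sub-bands degenerate (a near-zero interpercentile
range amplifies numerical leakage), which is an artifact of pathological
inputs, not of real field potentials.

## Encoding: STRF estimation and significance

A STRF is a linear map from the preceding 750 ms of the log spectrogram to
the HFA of one electrode: y_t = a + sum_{b,l} w[b,l] S_log[b, t-l] + e,
with 75 lags at 10 ms steps, i.e. 32 x 75 = 2,400 features. The first 74
frames have no full window, so 19,072 frames give 18,998 observations
(the arithmetic is followed even though one printed figure elsewhere says
18,898). Rows whose target exceeds the |z| > 7 tag are dropped.

Splits allocate indivisible 2 s blocks of consecutive frames (5 s in
decoding mode) to train/validation/test at 60-20-20, stratified by each
block's majority vocal/instrumental label (vocals at 13-80 s in the study
stimulus), with a fresh shuffle per seed. The trailing partial block is
kept as a normal block. Features are scaled by a robust scaler (median,
2-98 percentile range) fitted on training rows only.

Fitting is full-batch gradient descent on the Huber loss (transition
delta = 1, appropriate for robust-z targets) with RMSProp-style adaptive
step sizes plus heavy-ball momentum (defaults: step 3e-4, decay 0.9,
momentum 0.95, epsilon 1e-8). Momentum matters: the lagged design is
strongly autocorrelated and plain diagonal preconditioning crawls in its
low-variance directions (weight-recovery correlation plateaued near 0.92
after thousands of epochs without it; with it, noise-free recovery passes
0.95 within a few hundred). Early stopping evaluates the validation loss
every epoch and ends training once it has not diminished for 10
consecutive epochs; the patience counter only starts after a 50-epoch
warm-up so the momentum transient cannot trigger it. With a very large
Huber delta the loss is quadratic and the fit converges to the
least-squares solution (tested against the normal equations at corr >=
0.999). With the Huber gradient bounded, the optimizer cannot blow up at
any realistic step size; the divergence guard exists for degenerate
configurations.

Significance is a bootstrap over n_boot independent
split-scale-fit-evaluate iterations (250 in the study; tests use 15-50
for speed). An electrode is significant iff the empirical 2.5-97.5
percentile interval of its test-set Pearson r excludes 0 *and* its mean
test r-squared is positive. The per-coefficient z-map is mean/sd of each
weight across the fits (sd = 0 yields z = 0 with a warning). Note the
z-map is only meaningful when bootstrap variability is non-degenerate: on
noise-free data all fits coincide, the sd collapses, and the z-map is
dominated by numerical noise — recovery claims are therefore made on the
bootstrap-mean STRF.

Region statistics: Pearson chi-square on 2x2 proportion tables without
continuity correction (the two reported comparisons, 199/1,479 vs 148/900
and 133/374 vs 165/654, reproduce as 4.01 and 12.34), and an additive
(no-interaction) two-way ANOVA of prediction accuracy by laterality and
region with Tukey-Kramer post hoc contrasts on region levels.

## Decoding: stimulus reconstruction

Decoders mirror the encoding recipe in the reverse direction. The design
matrix holds anticausal lags (500 ms, 50 lags) of every electrode's HFA
and each model predicts one spectrogram bin. A fixed continuous test
interval (61-76 s in the study) is excluded from hyperparameter tuning
and fitting; any 5 s block overlapping it is excluded from allocation.

Hyperparameters (optimizer step size for linear decoders over a log grid
0.001-100; L2 strength alpha for MLPs over 0.01-100) are tuned by grid
search over 10 train/validation resamples, keeping per resample the index
of the grid value with minimum validation MSE and selecting
grid[round(mean(indices))] — arithmetic on grid positions, not values.
The grid granularity (11 and 9 log-spaced points) is a package choice;
only the ranges are prescribed.

The nonlinear decoder is a fully connected MLP with two hidden layers of
64 units (trainable-parameter count F*N + N*N + N with F = E*L), ReLU
activation, adam with internal early stopping — activation, batch regime
and early-stopping internals are unstated in the source and follow
scikit-learn's `MLPRegressor` defaults, exposed as config. MLPs use a
best-of-3 restart strategy: during tuning the restart with minimum
validation MSE represents a grid point; in the final population the
restart with maximum *test* r-squared is kept. That second rule is a
knowingly optimistic selection step, implemented as printed and flagged
here: it alone gives MLP ensembles a small consistent edge (~0.01-0.02
effective r-squared on our synthetic data) independent of any true
nonlinearity.

An ensemble of n_models decoders on distinct splits is summarized by the
effective r-squared: models sorted by increasing test r-squared, the n
best predictions averaged, and the r-squared of the average maximized
over n (ties toward larger n).

Bootstrap curves quantify accuracy versus electrode count (subsets of 5,
10, 20, ... sampled without replacement; 100 resamples) and versus
dataset duration (contiguous excerpts of 15-180 s), normalized per run to
the full-electrode / full-duration reference and fitted with a two-term
power law a x^b + c. The full set and full duration are the reference by
construction (100%). Duration excerpts are constrained to contain the
fixed test interval so accuracies remain comparable.

## Song-excerpt identification

The song is tiled into non-overlapping held-out test segments (twelve
15 s segments covering 0-180 s for the study stimulus; any remainder is
absorbed into the last segment, a coverage decision the source leaves
open). Each segment is decoded by models trained with that segment held
out and the decodes are concatenated. Both decoded and original
spectrograms are cut into 5 s excerpts; every decoded-original pair gets
a Pearson correlation over the flattened excerpt arrays (38 x 38 for the
full song). The rank of each row's true excerpt (1 + the number of
strictly smaller off-diagonal entries; exact ties count half) measures
identifiability; the mean normalized rank is calibrated against 1,000
column permutations and deemed significant above the null's 97.5
percentile. For an n x n matrix with exchangeable entries the expected
mean normalized rank is (n+1)/(2n) — 0.513 at n = 38.

## STRF components

Significant STRFs (electrodes x 2,400 coefficients) are centered per
coefficient and decomposed with FastICA, oriented with coefficients as
samples and electrodes as variables, so sources are component maps and
the mixing matrix holds one scalar per electrode and component. A probe
run with 10 sources estimates each component's explained variance through
its back-projection:

    pvaf_i = 100 - 100 * mean(var(STRF - backproj_i)) / mean(var(STRF))

with variance across coefficients per electrode and the mean across
electrodes (the formula's nesting is ambiguous in the source; this
reading is fixed and tested: exact reconstruction gives 100, a halved
back-projection 75). Components with pvaf > 5 are counted (k*) and a
final ICA with k* sources is fitted. The probe run is allowed to return a
non-converged solution — on low-rank data the surplus noise sources never
settle while the strong components do, and the probe only counts the
strong ones; the final run must converge (3 seeds, then error). Each
component's sign is fixed so its largest-magnitude map coefficient is
positive (the back-projection is invariant), and an electrode carries a
component when its mixing coefficient is positive.

Rhythmic tuning is detected separately: the temporal modulation spectrum
of each STRF (lag-axis FFT magnitude per spectral bin, zero-padded to
0.25 Hz resolution, scaled as sinusoid amplitude 2|FFT|/n_lags) is
summarized by its maximum across bins in the 6-7 Hz window — the
16th-note rate of the song (4 x tempo/60 = 6.66 Hz at 100 bpm, a 150 ms
period) — and thresholded at 0.3. The units of that threshold are
unstated in the source; here maps are normalized to unit peak magnitude
before the FFT, making the threshold a scale-free "modulation amplitude
relative to the map's peak". Under this convention planted 150 ms combs
score ~0.4 and every other archetype (and unit-variance noise maps)
stays below ~0.2, giving clean separation at 0.3. A Hann lag-window was
considered to reduce leakage but roughly halves the comb's amplitude and
was rejected.

A sliding-window correlation between a component map and the log
spectrogram (map against the preceding 750 ms window, frame by frame)
localizes the musical elements driving the component; zero-variance
windows return 0.

## Ablation (virtual lesions)

Anatomical sets ({STG, SMC, IFG, other} x {bilateral, L, R} plus the two
whole hemispheres — 14 candidates before empty-set pruning; the source
counts 12 without listing them, so the catalog is configurable) and
functional sets ({onset, sustained, late onset, rhythmic} x laterality,
which may overlap) are removed from the inputs of per-bin linear decoders
refitted on split seeds identical to the baseline, so the per-bin change
in test r reflects electrode removal only. Linear models are used
throughout so removed information cannot be re-synthesized nonlinearly. A
repeated-measures one-way ANOVA across sets (bins as the repeated factor,
the baseline entering as a zero-delta level) with Tukey-Kramer post hoc
contrasts yields per-set significance versus baseline; a significant drop
labels the set's information *unique*, an absent drop (for individually
significant electrodes) labels it *redundant*. Overlapping functional
sets block cross-set uniqueness claims.

## Waveform reconstruction

Decoded magnitudes are clipped at zero and squared (sharpening prominent
elements), interpolated from the log-spaced bins onto a linear-frequency
STFT grid frame by frame, and inverted by Griffin-Lim alternating
projection with seeded random initial phases (500 iterations in the study
configuration; tests use 40-60). The internal magnitude-mismatch error is
non-increasing up to numerical tolerance. Reconstruction of a pure tone
returns its frequency within one bin; the filterbank's bandwidth spreads
some energy into adjacent bins, so round-trip energy claims are made on
the one-bin neighborhood.

## Synthetic data: what it emulates and what it does not

`generate_stimulus` builds a nonnegative 100 Hz, 32-band spectrogram
with (i) a mid-band background amplitude-modulated at the 16th-note rate,
(ii) harmonic-stack note events every 2 bars with 250 ms exponential
decay, (iii) sustained top-band energy with a slow vibrato-like
fluctuation during the vocal interval (13-80 s of a 190.72 s stimulus by
default), and (iv) a broadband uniform noise floor, U(0.02, 0.8) per
cell. The floor is deliberately generous: it stands in for percussive
and strumming texture and keeps every band informative — without it
several bands are barely excited and STRF weights there are not
identifiable even noise-free.

`generate_electrodes` plants Gabor-like receptive-field archetypes
(Gaussian in log-frequency x Gaussian or comb in lag): broadband onset at
90 ms, late onset at 210 ms, narrowband sustained across the full window
in the top bins, and a 150 ms lag comb (bump width 16 ms, near the
optimum for 6.66 Hz modulation energy) in mid bins. The default cohort is
60 responsive (15 per archetype) plus 40 noise electrodes, alternating
hemispheres, with a region policy placing onset in STG, sustained in
STG/SMC, rhythmic in STG, and noise electrodes in IFG/other. Exact
duplicates (`duplicate_of`) support redundancy constructions. The study
reports no per-electrode SNR, so `noise_sd` (z-units of additive Gaussian
noise on a unit-variance standardized drive) is a free parameter,
default 1.0; significance calling was verified to be monotone in it.

`simulate_hfa` generates the lagged-linear response to the log
spectrogram, standardized per electrode, optionally passed through a
compressive tanh (unit slope at 0, saturating at +-1.5) before noise.
`simulate_raw_ecog` renders each channel as a broadband 70-150 Hz noise
carrier (or a deterministic 110 Hz tone for degenerate checks) whose
envelope follows max(1 + 0.6 z, 0.05) of the upsampled target, plus line
noise at 60 Hz and harmonics and 1/f-like background, with 10 s pads.
With the default gain the full preprocessing chain recovers each
channel's target at r >= 0.7 (r ~ 0.8-0.93 across archetypes); the
stochastic carrier's intrinsic Rayleigh envelope noise caps this — a
deterministic carrier recovers at r > 0.97.

What passing tests show: the estimators recover planted structure at
realistic SNR, false-positive rates are controlled, and every statistic
behaves as derived. What they do not show: real cortical responses are
not lagged-linear in a log spectrogram, real STRF populations are not
three clean archetypes plus noise, and real electrode noise is neither
white nor stationary; absolute accuracy numbers on synthetic cohorts do
not transfer to patient data.

A note on the linear-versus-MLP contrast. On song-like (non-Gaussian)
targets the Bayes-optimal decoder is nonlinear even when the forward
model is linear, because the posterior mean inherits the target's
non-Gaussian prior; MLPs therefore show a small advantage on such data
regardless of the response nonlinearity. The package tests the contrast
accordingly: the MLP advantage is demonstrated on compressively
nonlinear song-like cohorts, and the *absence* of a nonlinear advantage
is demonstrated on linear-Gaussian cohorts, where the MLP's difference
from the linear decoder is additionally bounded (|mean difference| <
0.05 effective r-squared; at desk scale the MLP carries a small
estimation deficit there rather than exact statistical equality).

## Problem sizes used in tests

The default test and acceptance runs use reduced-scale cohorts chosen as
the smallest sizes at which every effect is still decisively measurable:
stimuli of 30-80 s, 8-16 bands, 10-30 lags, 6-16 electrodes, 15-50
bootstrap resamples, ensembles of 2-4 decoders, and 6 x 10 s
identification segments with 2 s excerpts. Full-scale settings (190.72 s,
32/128 bands, 75 lags, 250 resamples, 100-model ensembles, twelve 15 s
segments) remain the library defaults.
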