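# Methods

This note records the scientific and numerical choices behind ictalnet:
what each stage computes, which parameters matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Records, epochs, filtering

A record is a single-channel EEG signal (µV) with a caller-supplied
sampling rate, default 173.61 Hz; the file dialect is one ASCII integer
per line, one directory per class (A, B: healthy eyes open/closed; C, D:
interictal intracranial; E: ictal). Records nominally span 23.6 s, which
at 173.61 Hz is ≈4,097 samples, yet the corpus files carry 4,096 points;
the package treats 4,096 as ground truth and does not reconcile the
off-by-one.

Epoching uses a fixed window with stride equal to the window length
(default 1,024 samples), so 100 records per class become 400
classification instances and any trailing remainder is dropped. The
arithmetic of the published task sample sizes (4 × 100 × classes) forces
the non-overlapping stride.

The band-pass filter is Chebyshev type I, order 4, 0.5 dB passband
ripple, 3–40 Hz, applied forward-backward (`sosfiltfilt`) for zero phase.
Only "Chebyshev, 3–40 Hz" is fixed by the source description; type,
order, ripple, zero-phase application, and filtering per epoch (rather
than per record — `bandpass_record` provides the alternative) are this
package's documented defaults, all exposed as arguments. Forward-backward
application doubles the attenuation in dB; the passband may dip up to
about 1 dB, which the tone-gain tests allow for.

## Features

**FFT.** The full N-point magnitude spectrum (including the redundant
conjugate-symmetric half) is reshaped row-major into an m×n matrix with
m·n = N; default 32×32 for 1,024-sample epochs — square and factor-exact,
the only hard constraint being m·n = N. The full spectrum is kept because
the matrix layout indexes through A_N.

**DWT.** Dyadic decomposition (a₀ = 2, b₀ = 1), db4, 5 levels, so at
173.61 Hz the subband edges (2.71, 5.43, 10.85, 21.70, 43.40 Hz) straddle
the 3–40 Hz analysis band. Boundary handling is **periodization**, not
symmetric extension: with an orthogonal wavelet, periodization makes the
transform an orthonormal change of basis, giving exact reconstruction,
exact energy conservation, and a coefficient count equal to the input
length — three properties the test suite asserts and that symmetric
extension would break (it pads each subband). Symmetric extension remains
available via the `mode` argument. The feature is the concatenated raw
coefficients, coarse→fine; no derived statistics, mirroring the raw
magnitudes of the FFT branch so the comparison is between
representations, not between feature-engineering pipelines.

**EMD.** Sifting with cubic-spline envelopes through the local extrema.
The IMF acceptance rule is the standard two-part check: extrema and
zero-crossing counts within one of each other AND mean-envelope smallness
‖m‖₂/‖h‖₂ < 0.05, with a cap of 100 sifting passes per IMF (the
operational threshold is a package choice; the qualitative conditions are
standard). Envelope splines mirror the two nearest extrema beyond each
signal edge to damp end swings; a plateau counts as one extremum at its
midpoint; decomposition stops when the remainder has fewer than two
maxima or two minima (monotonic-like). A failed initialisation of the
spline (too few extrema) is signalled to the caller, not raised. The
feature is the first five IMFs stacked as channels, zero-padded when
fewer exist — which signal functionals to derive from the IMFs was left
open in the source description, so the IMFs themselves are fed to the
classifier and the choice is recorded here.

All feature kinds are max-magnitude normalised per epoch before the
classifier (the source is silent on scaling); the network therefore sees
spectral/temporal shape, not absolute amplitude.

## Classifier

Three conv+ReLU blocks (the block count is fixed by the architecture
description; kernel lengths 7/5/3, channel counts, strides, hidden
sizes, optimiser, and schedule are package defaults, all in
`ModelConfig`), a nested LSTM over the step axis, a time-distributed
fully connected layer with ReLU, 1-D average pooling over steps, a final
FC layer, and softmax. The nested cell: outer gates i, f, g, o as in a
standard LSTM; the inner LSTM receives i⊙g as input and f⊙c_{t−1} as its
hidden-state context, carries its own cell state, and its hidden output
becomes the outer cell state c_t; h_t = o⊙tanh(c_t). The construction
forces the inner hidden size to equal the outer one (the inner output
*is* the outer cell state); `ModelConfig` validates this. Correctness is
anchored by the reduction property — replacing the inner cell with plain
addition reproduces a textbook LSTM step exactly — checked against an
independently written reference over random weights.

Two input layouts: `matrix_rows_as_steps` (FFT matrices; m steps of n
features) and `flat_sequence` (DWT/EMD/raw vectors or channel stacks).
Whether the classifier should consume the 2-D matrix or a flat sequence
is ambiguous in the source; the matrix-rows-as-steps reading is the
headline configuration and the alternative is one config field away.

The network and its reverse-mode autodiff are implemented in float64
NumPy inside the package; gradients are verified against central finite
differences in the test suite, and all computation is single-threaded, so
a fixed seed yields bit-identical training runs.

Training: Adam (1e-3 default), softmax cross-entropy, batch 32, early
stop on a training-loss plateau. Because a small recurrent network can
occasionally plateau at chance from an unlucky initialisation, training
uses deterministic multi-start: a run whose final loss stays above
`restart_loss_threshold` (0.45; successful runs end far below, chance is
ln 2 ≈ 0.69) is re-initialised with a seed derived from the configured
one, up to `max_restarts` = 2 times. This keeps the procedure a pure
function of (data, config, seed). Prediction is the argmax with ties
broken to the lowest class index. No class weighting is applied, matching
the reported protocol of handling the imbalanced tasks without additional
operations.

Two presets: `default_config` (channels 16/32/32, hidden 64, 100 epochs)
and `small_config` (channels 8/16/16 with strides 1/2/2, hidden 32, 15
epochs), the latter sized so that a 10-fold cross-validation of an
800-epoch task completes in well under a minute on one CPU; the synthetic
experiments and the acceptance script use `small_config`.

## Evaluation

Stratified seeded 10-fold splits: per class, shuffled indices are dealt
so per-class counts per fold differ by at most one (surplus to the
currently smallest folds, ties to the lowest fold index); "evenly split"
is all the source fixes, and stratification is chosen so every fold
carries both classes. Each fold trains a fresh model seeded from the CV
seed and the fold index. Metrics keep full precision internally; display
rounding is half-up to 4 decimals. A zero-denominator sensitivity or
specificity is reported as absent (None), never as 0. Reports serialise
to CSV (rows K1..K10 + Mean; columns Acc/Sen/Spe) and JSON (plus raw
confusion counts).

`compare_tasks` uses a two-sided Welch t-test on the two fold-accuracy
vectors. The statistical test behind the published pairwise comparisons
is not named at the source, so the p-values are a mechanism, not a
reproduction target; when both vectors have zero variance the sentinel is
1.0 for equal means and 0.0 otherwise.

The published per-fold benchmark tables are transcribed in
`ictalnet.benchmarks` and used as aggregation fixtures. Three `C_vs_E`
cells are internally inconsistent at the source (the printed fold values
average to 0.9925/0.9975/0.9875 against printed means of
0.9875/1.0000/0.9750); they are transcribed verbatim, flagged in
`INCONSISTENT_CELLS`, and their fixture tests fail by design. The
source's own mean rounding is also mixed (0.99625→0.9962 but
0.97625→0.9763), so fixture comparisons use half-a-unit-in-the-last-place
tolerance rather than asserting one tie-breaking rule.

## Synthetic generator

Class recipes encode only the qualitative electrophysiology that
distinguishes the corpus classes — eyes-open alpha (8–13 Hz) over pink
noise for A; stronger alpha plus theta for B (eyes closed); sparse
biphasic interictal spikes (~0.7/s and ~1.0/s, ~60 ms, amplitudes
150/180 µV) over an A-like background for C/D; and a high-amplitude
(300 µV) non-sinusoidal 3–7 Hz spike-wave rhythm for E. Records are
integer-quantised µV to stay in the file dialect, deterministic in
(seed, class, index) via independent seed streams.

What passing tests show: that the pipeline detects genuine, large
spectral class differences and degrades when those differences shrink.
What they do not show: performance on real EEG — the generator has no
artifacts (EMG/EOG), no non-stationarity beyond slow amplitude
modulation, no inter-subject variability, and class differences far
cleaner than clinical data. The published-corpus accuracies are therefore
context, not a target, for synthetic runs.

`hard_mode` is the monotonicity probe: the ictal background is matched to
the eyes-open background and the rhythm amplitude is scaled to 5% (15 µV),
chosen so the rhythm's line power (~amp²/2 ≈ 112) sits at the pink-noise
power already present in the 3–7 Hz band (~150) — the classes then
genuinely overlap. Under default conditions the full-scale synthetic
`A_vs_E` cross-validation reaches ≥ 0.95 mean accuracy; under hard mode it
falls markedly (about 0.72–0.74 across seeds).

## Problem sizes

The test suite and acceptance script use the full corpus geometry (5 ×
100 records × 4,096 samples) for bookkeeping and for the end-to-end
`A_vs_E` runs, `small_config` for all trained models, and reduced sizes
(8 records/class, 256-sample epochs) for the unit-level cross-validation
fixtures — sizes chosen so the complete suite runs in a couple of minutes
on one CPU while still exercising every stage at the real data shape.

## Known limitations

- The EMD sifting cap (100) can in principle return a non-IMF candidate;
  it is flagged (`capped`) and has not been observed on the test signals.
- `compare_tasks` assumes approximately normal fold accuracies; with 10
  folds and near-ceiling accuracies this is a rough approximation.
- The default full-size `ModelConfig` is provided for completeness but is
  not exercised at scale by the suite; the synthetic experiments
  deliberately use the small preset.
- Multiclass (>2) heads work through the softmax but are untested beyond
  what the binary tasks need.
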