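# ictalnet

Single-channel EEG seizure classification for the Bonn-style five-class
setting: epoching and Chebyshev band-pass preprocessing, three feature
extractors (FFT magnitude matrices, discrete wavelet subbands, empirical
mode decomposition), a fully convolutional nested-LSTM classifier, and a
stratified 10-fold cross-validation harness over the nine standard binary
tasks. A synthetic EEG generator emulates the corpus shape so the whole
pipeline is testable without downloading any data; the real Bonn corpus is
an optional drop-in.

## Who this is for

Researchers and students working on automated epilepsy detection from
scalp/intracranial EEG who want a self-contained, fully reproducible
reference pipeline: every stage is seeded, every report regenerable, and
the classifier is plain NumPy (no GPU or deep-learning framework needed).

## The data and the tasks

The Bonn corpus has five classes of 100 single-channel records (4,096
samples at 173.61 Hz): **A**/**B** are healthy volunteers with eyes
open/closed, **C**/**D** are interictal intracranial recordings
(contralateral hippocampus / epileptogenic zone), and **E** is ictal
(seizure) activity. Each record is cut into four non-overlapping epochs of
1,024 samples and band-pass filtered (Chebyshev type I, 3–40 Hz,
zero-phase). Nine binary tasks pit class combinations against each other
(`A_vs_E`, `B_vs_E`, `AB_vs_E`, `C_vs_E`, `D_vs_E`, `CD_vs_E`, `AB_vs_CD`,
`AB_vs_CDE`, `ABCD_vs_E`); the epileptic side is always the positive
class, so sensitivity reads as seizure detection rate.

## The model

Per epoch x(n), n = 0..N−1, the headline feature is the DFT magnitude
matrix: X_k = Σₙ x(n)·e^(−i2πkn/N), A_k = |X_k|, laid out row-major as an
m×n matrix (default 32×32 for N = 1,024). The classifier is

```
conv+ReLU ×3  →  nested LSTM over steps  →  time-distributed FC
              →  1-D average pool  →  FC  →  softmax
```

where the matrix rows are the recurrent time steps. The nested LSTM
computes the usual outer gates i, f, g, o but replaces the additive cell
update c_t = f⊙c_{t−1} + i⊙g with an inner LSTM cell that takes i⊙g as
input and f⊙c_{t−1} as hidden context; the inner cell's output becomes
c_t, and h_t = o⊙tanh(c_t). Substituting plain addition for the inner
cell recovers a textbook LSTM exactly — that reduction is the normative
correctness test in the suite.

The comparison branches are a dyadic DWT (db4, 5 levels, periodized, so
the transform is orthonormal) and EMD (cubic-spline envelope sifting; the
first five intrinsic mode functions are the feature channels).

Evaluation is stratified seeded 10-fold cross-validation with per-fold
confusion counts and Sen = TP/(TP+FN), Spe = TN/(TN+FP),
Acc = (TP+TN)/total; tasks are compared by a Welch t-test on fold
accuracies.

## Worked example

```sh
ictalnet synth --out data --seed 7 --n-records 10
printf 'schema_version: 1\nmodel:\n  preset: small\n' > model.yaml
ictalnet evaluate --data data --task A_vs_E --feature fft --out run --seed 7 --config model.yaml
ictalnet report --runs run
```

prints

```
          fft
A_vs_E 1.0000
```

and `run/A_vs_E_fft.csv` holds the per-fold table (rows K1..K10 + Mean,
columns Acc/Sen/Spe) — here every fold is 1.0 because the default
synthetic classes are strongly separated: the ictal class carries a
high-amplitude 3–7 Hz spike-wave rhythm that dominates its spectrum,
which the FFT feature makes plainly visible. Under the generator's hard
mode (ictal rhythm shrunk to the in-band noise floor, background matched
to the eyes-open class) the same full-scale pipeline drops to about 0.72
mean accuracy, demonstrating that performance tracks effect size rather
than an artifact of the harness.

The same pipeline runs on the real corpus by pointing `--data` at a
directory with one subdirectory per class (`A/ B/ C/ D/ E/`) of plain
one-integer-per-line record files.

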