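# Methods

## Problem and model

Worker honeybees and drones differ in body size and wing length, and with
them the wingbeat repetition rate: worker flight buzz carries a harmonic
series on a fundamental near 260 Hz, drones on a lower one. The package
discriminates the two classes from 1-second mono audio segments
(44,100 Hz, 16-bit PCM) in three stages:

1. **Frequency-domain features.** Each segment is summarised by one of
   four representations: a Burg autoregressive power spectral density or a
   MUSIC pseudospectrum (512 coefficients over [0, fs/2)), or MFCC or GTCC
   cepstral coefficients (120, one per auditory filter).
2. **One-class autoencoder.** A bottlenecked feed-forward network is
   trained to reconstruct *worker* feature vectors only. Its per-segment
   reconstruction error `MSE` is small for workers and large for anything
   the network never saw — drones act as anomalies.
3. **Thresholding.** A segment is called drone iff its error exceeds a
   threshold: either a k-sigma rule
   `T_k = mean(MSE_train) + k·std(MSE_train)` (k = 1, 2, 3, worker
   training errors only, sample standard deviation with n−1), or the
   maximum-likelihood threshold `T*` — the intersection of prior-weighted
   Gaussians fitted to the worker and drone error samples, i.e. an
   empirical Bayes boundary minimising misclassification under zero-one
   loss. With unequal variances the intersection is the root of a
   quadratic; only the root between the two class means implements
   "higher error ⇒ drone", so that root is returned (with equal variances
   the closed form `(μ1+μ2)/2 + σ²·ln(p1/p2)/(μ2−μ1)` applies). If no
   root falls between the means — severely overlapping fits — the
   implementation warns and falls back to the real root with the smaller
   prior-weighted misclassification mass, or the midpoint when the
   quadratic has no real root.

Worker is the **positive** class throughout the evaluation module:
TP counts correctly detected workers, TN correctly detected drones,
accuracy = (TP+TN)/total and F1 = 2TP/(2TP+FP+FN). This is deliberate and
opposite to the intuitive "detect the drone" framing; inverting it
silently swaps precision and specificity.

## Spectral estimators

**Burg PSD.** The Burg lattice recursion chooses each reflection
coefficient to minimise the summed forward and backward prediction-error
power, guaranteeing |k| ≤ 1 and hence a stationary AR model; the
coefficients are assembled by the Levinson update. The PSD is the
all-pole spectrum `E_m / |1 + Σ a_m(k) e^{−j2πfk}|²` evaluated on 512
equally spaced frequencies over [0, fs/2). Default order m = 32 — enough
poles for several harmonics below a few kHz while stable on a 1-s frame.
The mean is removed per segment (DC carries no wingbeat information).
Spectra are computed on the full 1-second segment; sub-frame averaging is
not applied.

**MUSIC.** An M×M Toeplitz autocorrelation matrix is built from biased
(divide-by-n) sample autocovariances — the biased estimator keeps the
matrix positive semi-definite — and eigendecomposed. The M−p smallest
eigenvectors span the noise subspace, and the pseudospectrum is
`1 / Σ_k |e(f)ᴴ v_k|²` with the complex steering vector
`e(f) = [1, e^{−j2πf}, …, e^{−j2πf(M−1)}]`. Defaults M = 256, p = 16:
the pseudospectrum's resolving power scales like fs/M, so at 44.1 kHz a
matrix of a few hundred rows is needed before fundamentals a few tens of
Hz apart produce distinct signal subspaces; p = 16 budgets two
eigenvalues per real sinusoid for a fundamental plus seven harmonics.
The O(M³) eigendecomposition is negligible on 1-s frames. Both settings
are exposed in `SpectralConfig`.

Both spectral features are stored as `10·log10(power)` (dB) by default:
raw power spans many decades, and the autoencoder's min-max/sigmoid
pipeline needs a bounded dynamic range. `log_scale=False` disables this.

## Cepstral features

Frames of 2048 samples (~46 ms) with hop 1024 and a Hamming window;
|FFT|² is weighted by a filterbank, the energies are log10-transformed
(floor 1e−12 against silent frames) and cosine-transformed:

    c_i = sqrt(2/M) Σ_{m=1..M} log10 Y(m) · cos((2m−1) i π / (2M)),  i = 1..M.

The full transform is kept — 120 coefficients from 120 filters, no
truncation (unusual relative to speech practice, where the first dozen
coefficients are kept, but deliberate here: the network input is the
whole vector). Log base 10 is honoured exactly. Per-segment vectors are
the mean of per-frame coefficients (median available).

The **mel** filterbank uses triangular filters with centers equally
spaced in `mel(f) = 1127·ln(1 + f/700)` between 50 Hz and 6 kHz — a band
bracketing the wingbeat fundamental and its informative harmonics. The
**gammatone** filterbank samples `|GT(f)|² = |1 + j(f−f0)/BW|^(−2N)`
(order N = 4) on the FFT grid, centers equally spaced on the
Glasberg–Moore ERB-rate scale with per-filter bandwidth
`ERB(f0) = 24.7·(4.37·f0/1000 + 1)`; the frequency-sampled response is
used directly rather than a time-domain IIR cascade.

## Autoencoder

Encoder sizes interpolate geometrically from the input dimension down to
the 8-neuron code (e.g. 512 → 128 → 32 → 8 for two hidden layers); the
decoder mirrors the encoder minus its widest hidden layer, so it is one
layer shorter, ending in a sigmoid output of the input dimension. All
other layers are ReLU. Inputs are min-max normalised to [0, 1] per
dimension on the training set (constant dimensions map to 0.5, unseen
values are clipped), which the sigmoid output range forces. Training is
mini-batch Adam (lr 1e−3, batch 32, 100 epochs by default) on the MSE
loss, fully seeded: the same seed, data and configuration reproduce the
run bit-for-bit in single-threaded execution. The implementation is
plain NumPy — the networks are small enough (≤ 512 units) that a
framework would add nothing but a dependency.

## Split protocol

Workers: 80% train / 10% threshold calibration / 10% evaluation.
Drones: 50% calibration / 50% evaluation; drones never enter training.
k-sigma thresholds use the training errors exactly; T* is fitted on the
calibration split, with priors defaulting to the calibration class
proportions (equal priors are one argument away). `paper_mode=True`
collapses calibration into evaluation, fitting T* on the same errors it
is judged on — a leakier protocol kept for comparability with workflows
that only distinguish "training set" and "test set".

## Synthetic buzz generator

Fixtures are generated, never shipped. A clip is a sum of `n_harmonics`
(default 8) sinusoids at k·f0 with amplitudes decaying by 0.7 per
harmonic, slow frequency jitter (±40 cents, ~4 Hz random control points,
linearly interpolated), sinusoidal amplitude modulation (depth 0.3 at
7 Hz), and white Gaussian noise at SNR 20 dB (clean-field recording
conditions; harder settings available), peak-normalised to 0.9. Worker
fundamental 260 Hz; the drone fixture uses 200 Hz — larger bodies and
longer wings push the wingbeat rate down, but the exact drone value is a
fixture choice, not a measurement. Per-clip seeds derive from a master
`SeedSequence`, and the generator uses NumPy's PCG64 explicitly, so
corpora are platform-reproducible.

The generator does **not** model overlapping bees, flight-path Doppler,
microphone directivity, wind, rain or colony background hum, and its two
classes are separated by construction. Passing tests therefore
demonstrate that the estimators, the network and the thresholds do what
their definitions say — not that field recordings of real hives will
separate as cleanly.

## Problem sizes and numerical choices

The reference experiment (tests and `scripts/acceptance.py`) uses 200
worker + 100 drone 1-s clips — the 2:1 class ratio of a mating-season
corpus — with MUSIC features and the 2-hidden-layer encoder; it
completes in well under a minute on one core. Threshold-theory checks
draw 50,000 Gaussian error samples per class and compare against
closed-form intersections and analytic Bayes accuracy from normal CDFs.

Degenerate inputs: zero-variance signals are rejected before AR fitting,
as are zero-variance error samples before Gaussian fits (spread at the
level of float rounding counts as zero). PSD evaluation clamps to a
floor of 1e−30 and warns if an AR root sits on an evaluation bin.
Classification ties go to worker, the dominant class. Sample standard
deviations use the n−1 convention throughout.

## Known limitations

- Accuracies on the synthetic corpus are optimistic by design; the
  generator's class gap (60 Hz in the fundamental) is wider relative to
  noise than field conditions guarantee.
- The Gaussian model for reconstruction errors is an approximation;
  strongly skewed error distributions would bias T* (the paper-field
  alternative, kernel density estimates, is deliberately out of scope).
- Burg and MUSIC orders are fixed per run, not selected per segment;
  order selection criteria (AIC/MDL) are not implemented.
- Training uses a fixed epoch budget with no early stopping; the
  `validation_fraction` setting reserves data for monitoring only.
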