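# Methods note

## Signal model

A single-channel SSVEP epoch is modelled as a pure sinusoid plus additive
noise:

```
x[t] = A sin(2 pi f t / fs + phi) + n[t],   t = 0 .. N-1
```

with sampling rate `fs = 100` Hz and epoch length `N = 100` samples (1 s).
The five stimulus frequencies come from dividing a 60 Hz display refresh
rate by the integers 10, 9, 8, 7, 6. Synthesis and recognition use the exact
quotients (e.g. `60/9 = 6.666...` Hz); displayed values are rounded to two
decimals (6.00, 6.67, 7.50, 8.57, 10.00 Hz).

Assumptions: the evoked response is stationary within an epoch, dominated by
its fundamental (the generator adds no harmonics), and noise is independent
of the signal. Noise is white Gaussian or pink (`1/sqrt(f)` spectral
shaping, renormalized to unit power), scaled per epoch so that
`10 log10(P_signal / P_noise)` equals the requested SNR. `noise=None`
produces the zero-noise surrogate (infinite SNR).

Per-subject structure: each synthetic subject draws an amplitude factor
uniformly from [0.8, 1.2], applied to every epoch; phases are drawn uniformly
in [0, 2 pi) per epoch (or fixed on request). This is the minimum structure
needed for leave-one-subject-out evaluation to be meaningful: held-out
subjects differ in gain but share the noise model.

### What the generator does and does not emulate

It emulates the frequency-selective, phase-variable, low-SNR character of
single-channel SSVEP epochs and subject-level gain variation. It does **not**
emulate harmonic content of real evoked responses, non-stationary artifacts
(blinks, movement), 1/f-plus-alpha EEG background structure beyond the pink
option, electrode/montage effects, or latency jitter within an epoch.
Conclusions about absolute recognition rates therefore do not transfer to
real EEG; the *relative* ordering of the methods is the object of study.

## Phase estimation

The latent phase is estimated by cross-correlating the epoch with
integer-lag shifted unit sines at the known training frequency and taking
`phi_hat = 2 pi f lag* / fs` for the best lag. Numerical choices:

- **Lag grid of `ceil(fs/f)` lags** (`0 <= lag < ceil(fs/f)`). With a
  floor/round grid the largest gap between adjacent candidate phases can
  exceed one grid step for frequencies where `fs/f` is fractional (e.g.
  7.5 Hz, `fs/f = 13.33`), which would break the error bound below. With
  `ceil` the maximum gap never exceeds `2 pi f / fs`.
- **Whole-cycle correlation window.** The correlation is computed over the
  largest prefix of the epoch containing an integer number of cycles of `f`
  that lands on an integer sample count. Over whole cycles the correlation
  of two unit sines is exactly proportional to `cos(phi - phi_lag)`, so the
  argmax lag is the nearest grid phase. With a fractional-cycle window,
  cross terms bias the scores and can push the error past the bound.
- Ties are resolved toward the smallest lag.

Resulting guarantees (verified in the test suite and the acceptance script):
on-grid phases are recovered exactly; off-grid error is at most
`pi f / fs` radians (half a grid step).

## Affine denoising autoencoder

Encoder `y = W x + b` (hidden size `h`, default 25), decoder
`x' = W' y + b'`; no activation, making the model affine end to end. Inputs
are standardized **per epoch** (zero mean, unit variance), so the clean
target is a sine of amplitude `sqrt(2)` (the amplitude of a unit-variance
sine). Targets:

- `IP`: sine at the epoch's training frequency with the cross-correlation
  phase estimate (phase-matched);
- `AP`: same frequency, zero phase;
- `AE`: the standardized input itself.

Training: mini-batch gradient descent (default learning rate 0.01, 2000
iterations, batch 32, uniform init in [-0.1, 0.1]) on the loss "mean over
epochs of the summed squared reconstruction error over samples". A
non-finite loss raises immediately with the iteration index.

Because the composition of two affine maps is affine of rank at most `h`,
the global optimum is the rank-`h` reduced-rank regression (RRR) solution:
ordinary least squares projected onto the top-`h` right singular vectors of
the fitted values. The test suite computes this closed form independently
and requires trained full-batch loss within 1% of it; reconstruction
de-standardizes back to original units.

## Recognition

- **CCA**: for a single channel, the maximal canonical correlation against a
  sine/cosine reference bank equals the multiple correlation coefficient,
  computed as `sqrt(R^2)` of a centered least-squares regression. Banks use
  up to 4 harmonics; harmonics at or above Nyquist are dropped. Scores lie
  in [0, 1], are amplitude- and phase-invariant, and equal 1.0 exactly on
  clean sines.
- **Euclidean-loss network**: fully connected ReLU layers with an affine
  output, loss `(1/2N) sum ||scores - onehot||^2`, Glorot-uniform init,
  mini-batch SGD with per-epoch permutation. Backpropagation is implemented
  from scratch and verified against central finite differences (relative
  error < 1e-5). The squared form of the Euclidean loss is used (the
  gradient of an unsquared norm is undefined at zero and merely rescales the
  descent direction elsewhere).
- **Baselines**: RBF-kernel SVM (one-vs-rest) and a per-class diagonal
  Gaussian mixture Bayes classifier (4 components per class).

## Evaluation

- **SNR**: `10 log10(sum ref^2 / sum (est - ref)^2)` against the known clean
  component, capped at 300 dB for zero residual.
- **Recognition rate**: percent correct, per-frequency rates and confusion
  matrix; reported values use half-up decimal rounding.
- **Error-reduction rate**: `100 (sys - base) / (100 - base)`, the fraction
  of the baseline's errors removed.
- **LOSO**: one fold per subject; the denoiser and any trainable classifier
  are fitted only on the training subjects of each fold. Per-fold seeds are
  derived deterministically from the experiment seed.
- **Phase diagnostics**: distortion between estimated input and output
  phases measured as the chord distance `2 |sin(delta/2)|`, wraparound-safe.

## Study conditions

Two regimes are used by the tests and the acceptance script; both are
choices of this package's synthetic benchmark:

- **SNR-transfer study** (0 dB input): 5 subjects x 20 epochs per label,
  train on 4 subjects, test on the held-out one, 20 independent datasets.
  The phase-matched denoiser gains about +5 dB on held-out epochs; the
  zero-phase variant loses about 2 dB and is beaten by the phase-matched one
  on every dataset.
- **Recognition study** (-8.5 dB white noise): 8 subjects x 40 epochs per
  label, chosen so that raw CCA sits near 85% under LOSO, leaving headroom
  to measure the denoisers' effect. Denoised CCA and the denoised-feature
  network both exceed raw CCA there.

## Limitations

- **A linear denoiser cannot beat CCA on information grounds alone.** CCA is
  already invariant to amplitude and phase, so the denoiser helps only where
  CCA's estimator wastes degrees of freedom. Under white noise the harmonic
  columns of the reference bank (the synthetic signal has no harmonics)
  collect pure noise, and suppressing that subspace is where the measured
  recognition gain comes from. Under pink noise this headroom largely
  vanishes: the optimal rank-constrained affine map plus CCA ties raw CCA.
- **Sample-size sensitivity.** The 100-dimensional affine map needs roughly
  1000+ training epochs to transfer across subjects; with a few hundred
  epochs even the closed-form optimum overfits and the denoised pipeline can
  fall below raw CCA. The study sizes above were chosen accordingly.
- Single channel only; multi-channel spatial filtering (and with it the full
  generality of CCA) is out of scope.
- Phase estimation assumes the training frequency is known for each training
  epoch; the denoiser therefore needs labelled training data.
- No claims are made about real EEG performance; all reported numbers are
  computed on the synthetic generator described here.
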