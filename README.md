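# ssvepdae

Denoising-autoencoder feature extraction for steady-state visual evoked
potential (SSVEP) brain-computer interfaces, with a full synthetic benchmark:
data generation, phase-matched affine denoising, frequency recognition, and
leave-one-subject-out evaluation.

## The problem

An SSVEP-based speller presents several stimuli flickering at distinct
frequencies. When the user attends one of them, the EEG over visual cortex
contains a small oscillation at that frequency, buried in noise. The decoding
task is: given a one-second single-channel epoch, decide which of the
candidate frequencies drove it.

Each recorded epoch is modelled as

```
x(t) = s(t) + n(t),      s(t) = A sin(2 pi f_i t + phi_i)
```

where `f_i` is one of five flicker frequencies derived from a 60 Hz display
refresh rate divided by integers 10, 9, 8, 7 and 6 — that is, 6.00, 6.67,
7.50, 8.57 and 10.00 Hz — `phi_i` is an unknown phase, and `n(t)` is noise
(white or pink) scaled to a target signal-to-noise ratio (SNR). Epochs are
1 s at 100 Hz (100 samples).

## The method

1. **Phase estimation by cross-correlation.** The latent phase of an epoch is
   estimated by correlating it against integer-lag shifted templates of a
   sine at its training frequency; the best lag gives the phase up to a
   quantization error below `pi * f / fs` radians.

2. **Affine denoising autoencoder (DAE).** A linear encoder `y = W x + b`
   and decoder `x' = W' y + b'` are trained by mini-batch gradient descent to
   map standardized noisy epochs to clean sine targets. Three target modes:
   - `IP` — sine at the epoch's training frequency with the **phase matched**
     to the cross-correlation estimate;
   - `AP` — sine at the training frequency with zero phase;
   - `AE` — the input itself (a plain autoencoder).
   Because the model is affine, its global optimum is the closed-form
   reduced-rank regression solution, which the test suite uses as an oracle.

3. **Recognition.** Either canonical correlation analysis (CCA) against
   sine/cosine reference banks with up to four harmonics, or a from-scratch
   fully connected network trained with a Euclidean (sum-of-squares) loss on
   one-hot targets by backpropagation. SVM and GMM baselines are included.

4. **Evaluation.** Leave-one-subject-out (LOSO) cross-validation reporting
   recognition rate, per-frequency rates and confusion matrix, reconstruction
   SNR against the known clean component, phase-distortion diagnostics, and
   the error-reduction rate `100 * (sys - base) / (100 - base)`.

The key empirical behaviour the package reproduces: phase-matched (`IP`)
targets yield a denoiser that transfers to unseen subjects and raises both
SNR and recognition rate, while zero-phase (`AP`) targets destroy phase
information and lose SNR.

## Worked example

```python
from ssvepdae import (
    ExperimentConfig, NoiseSpec, generate_dataset,
    make_stimulus_frequencies, run_experiment,
)

stim = make_stimulus_frequencies(60.0, [10, 9, 8, 7, 6])
print("flicker frequencies (Hz):", list(stim.frequencies))

table = generate_dataset(stim, n_subjects=8, epochs_per_label=40,
                         noise=NoiseSpec(target_snr_db=-8.5, seed=0), seed=0)
print("epochs:", len(table), " samples/epoch:", table.X.shape[1])

raw, _ = run_experiment(table, ExperimentConfig(denoiser="none",
                                                classifier="CCA", seed=0))
den, diag = run_experiment(table, ExperimentConfig(denoiser="IP",
                                                   classifier="CCA", seed=0))
print(f"raw CCA accuracy:      {raw.recognition_rate_overall:.2f}%")
print(f"denoised CCA accuracy: {den.recognition_rate_overall:.2f}%")
print(f"input SNR:  {den.snr_input_db_mean:+.2f} dB")
print(f"output SNR: {den.snr_db_mean:+.2f} dB")
```

Output (deterministic for the seeds shown; takes ~15 s):

```
flicker frequencies (Hz): [6.0, 6.67, 7.5, 8.57, 10.0]
epochs: 1600  samples/epoch: 100
raw CCA accuracy:      85.81%
denoised CCA accuracy: 89.31%
input SNR:  -8.48 dB
output SNR: -4.29 dB
```

Both experiments are evaluated under LOSO: for each of the 8 subjects the
denoiser (and classifier, where trainable) is fitted on the other 7 and
scored on the held-out one.

## Command line

The `ssvepdae` entry point has five subcommands; every option can also come
from a YAML/JSON file via `--config` (flags override the file):

```bash
ssvepdae simulate --n-subjects 5 --epochs-per-label 20 --snr-db 0 \
    --seed 0 --out epochs.csv
ssvepdae train-denoiser --table epochs.csv --mode IP --hidden-size 25 \
    --seed 0 --out dae.json
ssvepdae denoise --table epochs.csv --model dae.json --out enhanced.csv
ssvepdae train-classifier --table epochs.csv --denoiser dae.json \
    --seed 0 --out dnn.json
ssvepdae evaluate --table epochs.csv --denoiser IP --classifier CCA \
    --seed 0 --out report.json
```

Epoch tables are CSVs (one row per epoch, sample columns `s000..s099`) with a
JSON sidecar carrying sampling rate and stimulus metadata; models and reports
are JSON and round-trip bit-exactly. Each written model/report embeds a
`config_sha256` of the resolved configuration.

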