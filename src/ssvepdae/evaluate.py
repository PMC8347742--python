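"""Evaluation: SNR, recognition rates, LOSO cross-validation, phase diagnostics.

Because the epochs are synthetic, the clean evoked component of every test
epoch is known, so signal-to-noise ratio can be measured directly in the
time domain as signal power over residual power against that reference.
Recognition quality is summarized as an overall and per-frequency percent
rate with a confusion matrix, and improvements over a baseline system as an
error-reduction rate.  Cross-validation is leave-one-subject-out (LOSO):
each fold trains the denoiser and the classifier on all other subjects and
tests on the held-out one, so no subject's data ever leaks into its own fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

from .denoise import (
    DAETrainConfig,
    LinearDenoisingAutoencoder,
    estimate_phase_xcorr,
    standardize_epochs,
)
from .recognize import (
    CCAFrequencyClassifier,
    DNNTrainConfig,
    EuclideanMLPClassifier,
    GMMBayesClassifier,
    svm_baseline,
)
from .synthetic import EpochTable, generate_ideal_sine, SineParams

SNR_CAP_DB = 300.0

DENOISERS = ("none", "AE", "AP", "IP")
CLASSIFIERS = ("CCA", "DNN", "SVM", "GMM")

__all__ = [
    "SNR_CAP_DB",
    "EvalReport",
    "PhaseDiagnostics",
    "ExperimentConfig",
    "snr_db",
    "recognition_rate",
    "error_reduction_rate",
    "loso_split",
    "phase_distortion",
    "run_experiment",
    "round_half_up",
    "write_report",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, the convention used in printed rate tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def snr_db(estimate: np.ndarray, reference: np.ndarray) -> float:
    """Time-domain SNR: ``10 log10(sum ref^2 / sum (est - ref)^2)`` in dB.

    A zero residual returns the documented cap of +300 dB.
    """
    estimate = np.asarray(estimate, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if estimate.shape != reference.shape:
        raise ValueError("estimate and reference must have equal length")
    p_ref = float(np.sum(reference**2))
    if p_ref == 0.0:
        raise ValueError("reference signal is all zero")
    p_res = float(np.sum((estimate - reference) ** 2))
    if p_res == 0.0:
        return SNR_CAP_DB
    return min(10.0 * np.log10(p_ref / p_res), SNR_CAP_DB)


def recognition_rate(predictions, truths, n_classes: int | None = None):
    """Overall percent correct, per-class breakdown, confusion matrix.

    ``predictions`` may be plain label indices or objects with a ``label``
    attribute.  Returns ``(overall_pct, per_class_pct, confusion)`` where
    ``confusion[i, j]`` counts epochs of true class i predicted as j.
    """
    pred = np.asarray(
        [getattr(p, "label", p) for p in predictions], dtype=int
    )
    true = np.asarray(list(truths), dtype=int)
    if pred.shape[0] != true.shape[0]:
        raise ValueError("predictions and truths lengths differ")
    if pred.shape[0] == 0:
        raise ValueError("no predictions to score")
    k = n_classes if n_classes is not None else int(max(pred.max(), true.max())) + 1
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (true, pred), 1)
    overall = 100.0 * float(np.trace(confusion)) / pred.shape[0]
    per_class = {}
    for c in range(k):
        row = confusion[c]
        if row.sum() > 0:
            per_class[c] = 100.0 * float(row[c]) / float(row.sum())
    return overall, per_class, confusion


def error_reduction_rate(rate_baseline: float, rate_system: float) -> float:
    """Percent of the baseline's errors removed by the system.

    ``100 * ((100 - baseline) - (100 - system)) / (100 - baseline)``; negative
    when the system is worse, 100 exactly when the system makes no errors.
    """
    for r in (rate_baseline, rate_system):
        if not (0.0 <= r <= 100.0):
            raise ValueError(f"rates must be percentages in [0, 100], got {r}")
    if rate_baseline == 100.0:
        raise ValueError("baseline has zero error; error reduction undefined")
    return 100.0 * (rate_system - rate_baseline) / (100.0 - rate_baseline)


def loso_split(table: EpochTable) -> list[tuple[list[str], str]]:
    """One fold per subject: (training subjects, held-out test subject)."""
    subjects = table.subjects()
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    return [([s for s in subjects if s != test], test) for test in subjects]


def phase_distortion(target_phase: float, realized_phase: float) -> float:
    """Chord distance on the unit circle between two phases.

    Euclidean distance between ``(cos p, sin p)`` points,
    ``2 |sin((p1 - p2)/2)|`` — wraparound-safe, in [0, 2].
    """
    if not (np.isfinite(target_phase) and np.isfinite(realized_phase)):
        raise ValueError("phases must be finite")
    return float(2.0 * np.abs(np.sin((target_phase - realized_phase) / 2.0)))


# ---------------------------------------------------------------------------
# experiment harness


@dataclass
class PhaseDiagnostics:
    """Target vs realized phase of enhanced signals, and their chord distortions."""

    pairs: list[tuple[float, float]] = field(default_factory=list)
    distortions: list[float] = field(default_factory=list)

    def density(self, n_bins: int = 40) -> tuple[np.ndarray, np.ndarray]:
        counts, edges = np.histogram(
            self.distortions, bins=n_bins, range=(0.0, 2.0), density=True
        )
        return counts, edges


@dataclass
class EvalReport:
    snr_db_mean: float | None
    snr_input_db_mean: float | None
    recognition_rate_overall: float
    recognition_rate_per_freq: dict[float, float]
    confusion: np.ndarray
    n_epochs_evaluated: int
    error_reduction_rate: float | None = None

    def to_dict(self) -> dict:
        return {
            "snr_db_mean": self.snr_db_mean,
            "snr_input_db_mean": self.snr_input_db_mean,
            "recognition_rate_overall": round_half_up(self.recognition_rate_overall),
            "recognition_rate_per_freq": {
                f"{f:.2f}": round_half_up(r)
                for f, r in self.recognition_rate_per_freq.items()
            },
            "confusion": self.confusion.tolist(),
            "error_reduction_rate": (
                None
                if self.error_reduction_rate is None
                else round_half_up(self.error_reduction_rate)
            ),
            "n_epochs_evaluated": self.n_epochs_evaluated,
        }

    def to_text(self) -> str:
        lines = []
        lines.append(f"epochs evaluated      : {self.n_epochs_evaluated}")
        if self.snr_input_db_mean is not None:
            lines.append(f"input SNR (dB, mean)  : {self.snr_input_db_mean:8.3f}")
        if self.snr_db_mean is not None:
            lines.append(f"output SNR (dB, mean) : {self.snr_db_mean:8.3f}")
        lines.append(
            f"recognition rate (%)  : {round_half_up(self.recognition_rate_overall):8.2f}"
        )
        lines.append("per-frequency rates (%):")
        for f, r in sorted(self.recognition_rate_per_freq.items()):
            lines.append(f"  {f:6.2f} Hz : {round_half_up(r):6.2f}")
        if self.error_reduction_rate is not None:
            lines.append(
                f"error reduction (%)   : {round_half_up(self.error_reduction_rate):8.2f}"
            )
        return "\n".join(lines) + "\n"


@dataclass
class ExperimentConfig:
    """One cell of the experiment grid: denoiser mode x classifier."""

    denoiser: str = "IP"  # none | AE | AP | IP
    classifier: str = "CCA"  # CCA | DNN | SVM | GMM
    hidden_size: int = 25
    dae: DAETrainConfig = field(default_factory=DAETrainConfig)
    dnn: DNNTrainConfig = field(default_factory=DNNTrainConfig)
    dnn_input: str = "hidden"  # hidden (autoencoder features) | reconstruction
    gmm_components: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.denoiser not in DENOISERS:
            raise ValueError(f"invalid config key denoiser={self.denoiser!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"invalid config key classifier={self.classifier!r}")
        if self.dnn_input not in ("hidden", "reconstruction"):
            raise ValueError(f"invalid config key dnn_input={self.dnn_input!r}")
        if self.hidden_size < 1:
            raise ValueError(f"invalid config key hidden_size={self.hidden_size}")


def _clean_reference(table: EpochTable, idx: int) -> np.ndarray | None:
    if table.true_freq is None:
        return None
    params = SineParams(
        amplitude=float(table.true_amplitude[idx]),
        frequency=float(table.true_freq[idx]),
        phase=float(table.true_phase[idx]),
    )
    return generate_ideal_sine(params, table.fs, table.X.shape[1])


def _fit_denoiser(cfg: ExperimentConfig, train: EpochTable, fold: int) -> LinearDenoisingAutoencoder:
    est = LinearDenoisingAutoencoder(
        hidden_size=cfg.hidden_size,
        mode=cfg.denoiser,
        fs=train.fs,
        learning_rate=cfg.dae.learning_rate,
        n_iterations=cfg.dae.n_iterations,
        batch_size=cfg.dae.batch_size,
        init_scale=cfg.dae.init_scale,
        seed=(cfg.seed * 1009 + fold) % (2**31),
    )
    return est.fit(train.X, train.label_frequencies)


def _features(cfg: ExperimentConfig, dae, table: EpochTable) -> np.ndarray:
    if dae is None:
        Z, _, _ = standardize_epochs(table.X)
        return Z
    if cfg.dnn_input == "reconstruction":
        return dae.reconstruct(table.X)
    return dae.transform(table.X)


def run_experiment(
    table: EpochTable, config: ExperimentConfig
) -> tuple[EvalReport, PhaseDiagnostics]:
    """LOSO evaluation of one denoiser/classifier combination.

    Per fold the denoiser (if any) and the classifier are fit on the training
    subjects only, then applied to the held-out subject.  The report pools
    predictions over all folds; SNR is averaged over test epochs whenever the
    table carries ground-truth sine parameters.  Fully reproducible from
    ``config.seed``.
    """
    config.validate()
    folds = loso_split(table)
    freqs = list(table.stimulus_set.exact_frequencies)
    n_classes = len(freqs)

    all_pred: list[int] = []
    all_true: list[int] = []
    snr_out: list[float] = []
    snr_in: list[float] = []
    diagnostics = PhaseDiagnostics()

    for fold_idx, (_, test_subject) in enumerate(folds):
        test_mask = table.subject_ids == test_subject
        train = table.subset(~test_mask)
        test = table.subset(test_mask)

        dae = None
        if config.denoiser != "none":
            dae = _fit_denoiser(config, train, fold_idx)

        if config.classifier == "CCA":
            X_eval = test.X if dae is None else dae.reconstruct(test.X)
            clf = CCAFrequencyClassifier(frequencies=freqs, fs=table.fs).fit(X_eval)
            pred = clf.predict(X_eval)
        else:
            F_train = _features(config, dae, train)
            F_test = _features(config, dae, test)
            clf_seed = (config.seed * 9973 + fold_idx) % (2**31)
            if config.classifier == "DNN":
                clf = EuclideanMLPClassifier(
                    hidden_widths=tuple(config.dnn.hidden_widths),
                    learning_rate=config.dnn.learning_rate,
                    n_epochs=config.dnn.n_epochs,
                    batch_size=config.dnn.batch_size,
                    seed=clf_seed,
                )
            elif config.classifier == "SVM":
                clf = svm_baseline(seed=clf_seed)
            else:
                clf = GMMBayesClassifier(
                    n_components=config.gmm_components, seed=clf_seed
                )
            clf.fit(F_train, train.labels)
            pred = clf.predict(F_test)

        all_pred.extend(int(p) for p in pred)
        all_true.extend(int(t) for t in test.labels)

        # SNR and phase diagnostics against the known clean component
        if test.true_freq is not None:
            recon = dae.reconstruct(test.X) if dae is not None else None
            Z_test, _, _ = standardize_epochs(test.X)
            for i in range(len(test)):
                ref = _clean_reference(test, i)
                snr_in.append(snr_db(test.X[i], ref))
                if recon is not None:
                    snr_out.append(snr_db(recon[i], ref))
                    if config.denoiser in ("AP", "IP"):
                        f_lab = float(test.label_frequencies[i])
                        target_phase = (
                            0.0
                            if config.denoiser == "AP"
                            else estimate_phase_xcorr(Z_test[i], f_lab, table.fs)
                        )
                        realized = estimate_phase_xcorr(recon[i], f_lab, table.fs)
                        diagnostics.pairs.append((target_phase, realized))
                        diagnostics.distortions.append(
                            phase_distortion(target_phase, realized)
                        )

    overall, per_class, confusion = recognition_rate(all_pred, all_true, n_classes)
    per_freq = {freqs[c]: r for c, r in per_class.items()}
    report = EvalReport(
        snr_db_mean=float(np.mean(snr_out)) if snr_out else None,
        snr_input_db_mean=float(np.mean(snr_in)) if snr_in else None,
        recognition_rate_overall=overall,
        recognition_rate_per_freq=per_freq,
        confusion=confusion,
        n_epochs_evaluated=len(all_true),
    )
    return report, diagnostics


def write_report(
    report: EvalReport,
    json_path: str | Path,
    text_path: str | Path | None = None,
    diagnostics: PhaseDiagnostics | None = None,
    diagnostics_path: str | Path | None = None,
    extra: dict | None = None,
) -> None:
    doc = report.to_dict()
    if extra:
        doc.update(extra)
    Path(json_path).write_text(json.dumps(doc, indent=2))
    if text_path is not None:
        Path(text_path).write_text(report.to_text())
    if diagnostics is not None and diagnostics_path is not None:
        lines = ["target_phase_rad,realized_phase_rad,distortion"]
        for (tp, rp), d in zip(diagnostics.pairs, diagnostics.distortions):
            lines.append(f"{tp:.17g},{rp:.17g},{d:.17g}")
        Path(diagnostics_path).write_text("\n".join(lines) + "\n")
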