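"""Synthetic single-channel SSVEP epoch generator.

An SSVEP epoch is modelled as ``x(t) = s(t) + n(t)`` where the evoked
component ``s_i(t) = A sin(2*pi*f_i*t + phi_i)`` is a pure sine at one of the
flicker frequencies and ``n(t)`` is additive noise at a controlled
signal-to-noise ratio.  Flicker frequencies are integer divisions of a
monitor refresh rate (a 60 Hz panel can only flicker at 60/k Hz), epochs are
one-second windows at 100 Hz, and every subject contributes epochs for every
frequency so that leave-one-subject-out folds are always well formed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_FS = 100.0
DEFAULT_DURATION_S = 1.0

__all__ = [
    "StimulusSet",
    "SineParams",
    "NoiseSpec",
    "Epoch",
    "EpochTable",
    "make_stimulus_frequencies",
    "generate_ideal_sine",
    "generate_epoch",
    "generate_dataset",
    "write_epoch_table",
    "read_epoch_table",
]


@dataclass(frozen=True)
class StimulusSet:
    """Flicker frequencies realizable on a monitor of a given refresh rate.

    ``frequencies`` holds the display-rounded values (2 decimals, the labels
    users see); ``exact_frequencies`` holds ``refresh_rate / divisor`` at full
    precision and is what the synthesizer and the recognizers use, since a
    60/7 Hz flicker is not exactly 8.57 Hz.
    """

    refresh_rate: float
    divisors: tuple[int, ...]
    frequencies: tuple[float, ...]
    exact_frequencies: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class SineParams:
    """Amplitude, frequency (Hz) and phase (radians in [0, 2pi)) of the carrier."""

    amplitude: float
    frequency: float
    phase: float

    def __post_init__(self):
        if not self.amplitude > 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")
        if not (0.0 <= self.phase < 2.0 * np.pi):
            raise ValueError(f"phase must lie in [0, 2*pi), got {self.phase}")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive-noise model: kind, target SNR in dB relative to the sine, seed."""

    kind: str = "white_gaussian"
    target_snr_db: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("white_gaussian", "pink"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if not np.isfinite(self.target_snr_db):
            raise ValueError("target_snr_db must be finite")


@dataclass(frozen=True)
class Epoch:
    samples: np.ndarray
    fs: float
    subject_id: str
    label: int
    truth: SineParams | None = None

    def __post_init__(self):
        if len(self.samples) != round(self.fs * DEFAULT_DURATION_S):
            raise ValueError(
                f"epoch must hold {round(self.fs * DEFAULT_DURATION_S)} samples, "
                f"got {len(self.samples)}"
            )


@dataclass
class EpochTable:
    """Ordered epoch collection with a shared stimulus set and generator metadata."""

    X: np.ndarray  # (n_epochs, n_samples)
    subject_ids: np.ndarray  # (n_epochs,) str
    labels: np.ndarray  # (n_epochs,) int, index into stimulus_set
    stimulus_set: StimulusSet
    fs: float = DEFAULT_FS
    true_freq: np.ndarray | None = None
    true_phase: np.ndarray | None = None
    true_amplitude: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def label_frequencies(self) -> np.ndarray:
        """Exact flicker frequency (Hz) of each epoch's label."""
        return np.asarray(self.stimulus_set.exact_frequencies)[self.labels]

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subject_ids:
            seen.setdefault(str(s))
        return list(seen)

    def subset(self, mask: np.ndarray) -> "EpochTable":
        mask = np.asarray(mask)
        return EpochTable(
            X=self.X[mask],
            subject_ids=self.subject_ids[mask],
            labels=self.labels[mask],
            stimulus_set=self.stimulus_set,
            fs=self.fs,
            true_freq=None if self.true_freq is None else self.true_freq[mask],
            true_phase=None if self.true_phase is None else self.true_phase[mask],
            true_amplitude=(
                None if self.true_amplitude is None else self.true_amplitude[mask]
            ),
            metadata=dict(self.metadata),
        )


def make_stimulus_frequencies(
    refresh_rate: float, divisors: list[int]
) -> StimulusSet:
    """Derive the flicker-frequency set from a monitor refresh rate.

    Each frequency is ``refresh_rate / divisor`` rounded to 2 decimals for
    display; the exact quotient is kept alongside.  The result is sorted
    ascending.  A 60 Hz refresh with divisors 10..6 yields the classic
    five-target set 6.00, 6.67, 7.50, 8.57, 10.00 Hz.
    """
    if not refresh_rate > 0:
        raise ValueError(f"refresh_rate must be positive, got {refresh_rate}")
    if len(divisors) == 0:
        raise ValueError("divisors must be nonempty")
    divisors = [int(d) for d in divisors]
    if any(d < 1 for d in divisors):
        raise ValueError(f"divisors must all be >= 1, got {divisors}")
    exact = [refresh_rate / d for d in divisors]
    order = np.argsort(exact)
    exact_sorted = tuple(exact[i] for i in order)
    rounded = tuple(float(round(f, 2)) for f in exact_sorted)
    if len(set(rounded)) != len(rounded):
        raise ValueError("duplicate stimulus frequencies after rounding")
    return StimulusSet(
        refresh_rate=float(refresh_rate),
        divisors=tuple(divisors[i] for i in order),
        frequencies=rounded,
        exact_frequencies=exact_sorted,
    )


def generate_ideal_sine(
    params: SineParams, fs: float, n_samples: int
) -> np.ndarray:
    """Sample ``A sin(2*pi*f*t/fs + phi)`` at t = 0..n_samples-1."""
    if not fs > 2.0 * params.frequency:
        raise ValueError(
            f"sampling rate {fs} Hz violates Nyquist for {params.frequency} Hz"
        )
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    t = np.arange(n_samples, dtype=float)
    return params.amplitude * np.sin(
        2.0 * np.pi * params.frequency * t / fs + params.phase
    )


def _unit_power_noise(kind: str, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Noise with expected mean-square power 1 per sample."""
    w = rng.standard_normal(n_samples)
    if kind == "white_gaussian":
        return w
    # pink: shape the spectrum as 1/f (power ~ 1/f), renormalize expected power
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n_samples)
    f[0] = f[1]  # keep DC finite
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n=n_samples)
    return out / np.std(out) if np.std(out) > 0 else out


def generate_epoch(
    params: SineParams,
    noise: NoiseSpec | None,
    fs: float = DEFAULT_FS,
    n_samples: int | None = None,
    subject_id: str = "S00",
    label: int = 0,
    rng: np.random.Generator | None = None,
) -> Epoch:
    """Clean sine plus noise scaled to the target SNR (in expectation).

    The noise is drawn with unit expected power and multiplied by
    ``sqrt(P_sine / 10**(snr_db/10))`` where ``P_sine`` is the realized mean
    square of this epoch's sine, so that ``10 log10(P_sine/P_noise)`` equals
    ``target_snr_db`` in expectation over noise draws.  ``noise=None`` is the
    infinite-SNR surrogate: zero noise amplitude, samples identical to the
    ideal sine.
    """
    if n_samples is None:
        n_samples = round(fs * DEFAULT_DURATION_S)
    s = generate_ideal_sine(params, fs, n_samples)
    if noise is not None:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        p_sine = float(np.mean(s**2))
        sigma = np.sqrt(p_sine / 10.0 ** (noise.target_snr_db / 10.0))
        s = s + sigma * _unit_power_noise(noise.kind, n_samples, rng)
    return Epoch(
        samples=s, fs=fs, subject_id=subject_id, label=label, truth=params
    )


def generate_dataset(
    stimulus_set: StimulusSet,
    n_subjects: int,
    epochs_per_label: int,
    noise: NoiseSpec | None,
    phase_mode: str = "random_uniform",
    seed: int = 0,
    fs: float = DEFAULT_FS,
    amplitude: float = 1.0,
    amplitude_jitter: tuple[float, float] = (0.8, 1.2),
) -> EpochTable:
    """Simulate a multi-subject epoch table.

    Every subject contributes ``epochs_per_label`` one-second epochs per
    flicker frequency.  Phases are drawn uniformly on [0, 2pi) per epoch
    (``random_uniform``) or held at 0 (``fixed``).  Subject heterogeneity is a
    per-subject amplitude multiplier drawn once, uniform on
    ``amplitude_jitter``.  Fully reproducible from ``seed``.
    """
    if len(stimulus_set) == 0:
        raise ValueError("stimulus set is empty")
    if n_subjects < 1 or epochs_per_label < 1:
        raise ValueError("n_subjects and epochs_per_label must be >= 1")
    if phase_mode not in ("random_uniform", "fixed"):
        raise ValueError(f"unknown phase_mode {phase_mode!r}")
    rng = np.random.default_rng(seed)
    n_samples = round(fs * DEFAULT_DURATION_S)
    n_total = n_subjects * len(stimulus_set) * epochs_per_label

    X = np.empty((n_total, n_samples))
    subj = np.empty(n_total, dtype=object)
    labels = np.empty(n_total, dtype=int)
    tf = np.empty(n_total)
    tp = np.empty(n_total)
    ta = np.empty(n_total)

    i = 0
    for s_idx in range(n_subjects):
        sid = f"S{s_idx:02d}"
        amp_s = amplitude * rng.uniform(*amplitude_jitter)
        for lab, f_exact in enumerate(stimulus_set.exact_frequencies):
            for _ in range(epochs_per_label):
                phi = rng.uniform(0.0, 2.0 * np.pi) if phase_mode == "random_uniform" else 0.0
                params = SineParams(amplitude=amp_s, frequency=f_exact, phase=phi)
                ep = generate_epoch(
                    params, noise, fs=fs, n_samples=n_samples,
                    subject_id=sid, label=lab, rng=rng,
                )
                X[i] = ep.samples
                subj[i] = sid
                labels[i] = lab
                tf[i], tp[i], ta[i] = f_exact, phi, amp_s
                i += 1

    return EpochTable(
        X=X,
        subject_ids=np.asarray(subj, dtype=object),
        labels=labels,
        stimulus_set=stimulus_set,
        fs=fs,
        true_freq=tf,
        true_phase=tp,
        true_amplitude=ta,
        metadata={
            "seed": seed,
            "n_subjects": n_subjects,
            "epochs_per_label": epochs_per_label,
            "noise": None if noise is None else dataclasses.asdict(noise),
            "phase_mode": phase_mode,
            "amplitude": amplitude,
            "amplitude_jitter": list(amplitude_jitter),
        },
    )


# ---------------------------------------------------------------------------
# delimited-text persistence


def write_epoch_table(table: EpochTable, path: str | Path) -> None:
    """CSV with one row per epoch plus a JSON sidecar (``<path>.meta.json``)."""
    path = Path(path)
    n_samples = table.X.shape[1]
    cols = {
        "subject_id": table.subject_ids,
        "label": table.labels,
        "true_freq_hz": table.true_freq if table.true_freq is not None else np.nan,
        "true_phase_rad": table.true_phase if table.true_phase is not None else np.nan,
        "true_amplitude": (
            table.true_amplitude if table.true_amplitude is not None else np.nan
        ),
    }
    df = pd.DataFrame(cols)
    sample_cols = pd.DataFrame(
        table.X, columns=[f"s{i:03d}" for i in range(n_samples)]
    )
    df = pd.concat([df, sample_cols], axis=1)
    df.to_csv(path, index=False, float_format="%.17g")

    sidecar = {
        "fs": table.fs,
        "stimulus_set": {
            "refresh_rate": table.stimulus_set.refresh_rate,
            "divisors": list(table.stimulus_set.divisors),
            "frequencies": list(table.stimulus_set.frequencies),
            "exact_frequencies": list(table.stimulus_set.exact_frequencies),
        },
        "metadata": table.metadata,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=2))


def read_epoch_table(path: str | Path) -> EpochTable:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar = json.loads(Path(str(path) + ".meta.json").read_text())
    ss = sidecar["stimulus_set"]
    stimulus_set = StimulusSet(
        refresh_rate=ss["refresh_rate"],
        divisors=tuple(ss["divisors"]),
        frequencies=tuple(ss["frequencies"]),
        exact_frequencies=tuple(ss["exact_frequencies"]),
    )
    sample_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    truth_ok = df["true_freq_hz"].notna().all()
    return EpochTable(
        X=df[sample_cols].to_numpy(),
        subject_ids=df["subject_id"].to_numpy(dtype=object),
        labels=df["label"].to_numpy(dtype=int),
        stimulus_set=stimulus_set,
        fs=float(sidecar["fs"]),
        true_freq=df["true_freq_hz"].to_numpy() if truth_ok else None,
        true_phase=df["true_phase_rad"].to_numpy() if truth_ok else None,
        true_amplitude=df["true_amplitude"].to_numpy() if truth_ok else None,
        metadata=sidecar.get("metadata", {}),
    )
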