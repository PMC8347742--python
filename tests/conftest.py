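import numpy as np
import pytest

from ssvepdae import (
    NoiseSpec,
    generate_dataset,
    make_stimulus_frequencies,
)


@pytest.fixture(scope="session")
def five_target_set():
    """The five-frequency stimulus set of a 60 Hz monitor (divisors 10..6)."""
    return make_stimulus_frequencies(60.0, [10, 9, 8, 7, 6])


@pytest.fixture(scope="session")
def clean_table(five_target_set):
    """Zero-noise table: every epoch is an exact sine with random phase."""
    return generate_dataset(
        five_target_set, n_subjects=3, epochs_per_label=4, noise=None, seed=11
    )


@pytest.fixture(scope="session")
def noisy_table(five_target_set):
    """Small 0 dB white-noise table shared across tests."""
    return generate_dataset(
        five_target_set,
        n_subjects=3,
        epochs_per_label=10,
        noise=NoiseSpec(target_snr_db=0.0, seed=13),
        seed=13,
    )


def clean_sine_reference(table, i):
    """The known noise-free component of epoch ``i`` of a synthetic table."""
    t = np.arange(table.X.shape[1]) / table.fs
    return table.true_amplitude[i] * np.sin(
        2.0 * np.pi * table.true_freq[i] * t + table.true_phase[i]
    )
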