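import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssvepdae import (
    LinearDenoisingAutoencoder,
    build_target,
    dae_decode,
    dae_encode,
    estimate_phase_xcorr,
    generate_dataset,
    load_dae,
    make_stimulus_frequencies,
    save_dae,
    train_dae,
)
from ssvepdae.denoise import DAETrainConfig, TARGET_AMPLITUDE, standardize_epochs


def sine(f, fs, n, phase=0.0, amp=1.0):
    return amp * np.sin(2 * np.pi * f * np.arange(n) / fs + phase)


def brute_force_phase(x, f, fs):
    """Independent lag search oracle: try every integer lag directly."""
    n_lags = int(np.ceil(fs / f))
    best_lag, best_score = 0, -np.inf
    for lag in range(n_lags):
        ref = np.sin(2 * np.pi * f * (np.arange(len(x)) + lag) / fs)
        score = float(ref @ x)
        if score > best_score:
            best_lag, best_score = lag, score
    return (2 * np.pi * f * best_lag / fs) % (2 * np.pi)


class TestPhaseEstimator:
    def test_zero_phase_self_alignment(self):
        assert estimate_phase_xcorr(sine(10, 100, 100), 10, 100) == 0.0

    def test_on_grid_phase_recovered_exactly(self):
        # phase of lag 3 at 10 Hz / 100 Hz: 2*pi*10*3/100
        phi = 2 * np.pi * 10 * 3 / 100
        est = estimate_phase_xcorr(sine(10, 100, 100, phi), 10, 100)
        assert est == pytest.approx(phi, abs=1e-9)

    @pytest.mark.parametrize("f", [6.0, 60 / 9, 7.5, 60 / 7, 10.0])
    def test_matches_brute_force_oracle(self, f):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = sine(f, 100, 100, rng.uniform(0, 2 * np.pi)) + 0.3 * rng.standard_normal(100)
            assert estimate_phase_xcorr(x, f, 100) == pytest.approx(
                brute_force_phase(x, f, 100), abs=1e-12
            )

    @pytest.mark.parametrize("f", [6.0, 60 / 9, 7.5, 60 / 7, 10.0])
    def test_off_grid_error_bounded_by_half_grid_step(self, f):
        fs = 100.0
        bound = np.pi * f / fs
        for phi in np.linspace(0, 2 * np.pi, 97, endpoint=False):
            est = estimate_phase_xcorr(sine(f, fs, 100, phi), f, fs)
            err = abs((est - phi + np.pi) % (2 * np.pi) - np.pi)
            assert err <= bound + 1e-9, f"f={f} phi={phi}: err {err} > {bound}"

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            estimate_phase_xcorr(np.ones(100), -1.0, 100)
        with pytest.raises(ValueError):
            estimate_phase_xcorr(np.ones(100), 10.0, 0.0)

    def test_signal_shorter_than_period_rejected(self):
        with pytest.raises(ValueError):
            estimate_phase_xcorr(np.ones(5), 6.0, 100)


class TestBuildTarget:
    def test_zero_phase_target_starts_at_zero(self):
        x = np.random.default_rng(0).standard_normal(100)
        target = build_target(x, 7.5, 100, "AP")
        assert target[0] == 0.0

    def test_autoencoder_target_is_input(self):
        x = np.random.default_rng(0).standard_normal(100)
        assert np.array_equal(build_target(x, 7.5, 100, "AE"), x)

    def test_phase_matched_target_tracks_on_grid_sine(self):
        phi = 2 * np.pi * 10 * 3 / 100  # on the lag grid
        x = sine(10, 100, 100, phi)
        target = build_target(x, 10, 100, "IP")
        assert np.allclose(target, TARGET_AMPLITUDE * x, atol=1e-9)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            build_target(np.zeros(100), 10, 100, "XX")


class TestAffineMaps:
    @pytest.fixture()
    def small_model(self):
        m = LinearDenoisingAutoencoder(hidden_size=3)
        m.W_ = np.zeros((3, 4))
        m.b_ = np.zeros(3)
        m.W_dec_ = np.zeros((4, 3))
        m.b_dec_ = np.zeros(4)
        m.n_features_in_ = 4
        return m

    def test_zero_maps(self, small_model):
        assert np.array_equal(dae_encode(small_model, np.ones(4)), np.zeros(3))
        assert np.array_equal(dae_decode(small_model, np.ones(3)), np.zeros(4))

    def test_identity_round_trip(self):
        m = LinearDenoisingAutoencoder(hidden_size=4)
        m.W_ = np.eye(4)
        m.b_ = np.zeros(4)
        m.W_dec_ = np.eye(4)
        m.b_dec_ = np.zeros(4)
        m.n_features_in_ = 4
        x = np.array([1.0, -2.0, 3.0, 0.5])
        assert np.array_equal(dae_decode(m, dae_encode(m, x)), x)

    def test_matches_elementwise_arithmetic_oracle(self, small_model):
        rng = np.random.default_rng(5)
        small_model.W_ = rng.standard_normal((3, 4))
        small_model.b_ = rng.standard_normal(3)
        x = rng.standard_normal(4)
        y = dae_encode(small_model, x)
        expected = [
            sum(small_model.W_[i, j] * x[j] for j in range(4)) + small_model.b_[i]
            for i in range(3)
        ]
        assert np.allclose(y, expected, atol=1e-12)

    def test_shape_mismatch_rejected(self, small_model):
        with pytest.raises(ValueError):
            dae_encode(small_model, np.ones(5))
        with pytest.raises(ValueError):
            dae_decode(small_model, np.ones(4))


def rrr_optimum_loss(Z, T, rank):
    """Closed-form reduced-rank-regression optimum of the affine autoencoder.

    Best rank-``rank`` affine map Z -> T in least squares: ordinary
    least-squares coefficients projected onto the top right-singular vectors
    of the fitted values.  Loss convention matches training: mean over
    samples of the squared error summed over features.
    """
    Zc = Z - Z.mean(axis=0)
    Tc = T - T.mean(axis=0)
    B = np.linalg.lstsq(Zc, Tc, rcond=None)[0]
    F = Zc @ B
    _, _, Vt = np.linalg.svd(F, full_matrices=False)
    P = Vt[:rank].T @ Vt[:rank]
    R = Zc @ (B @ P) + T.mean(axis=0)
    return float(np.mean(np.sum((R - T) ** 2, axis=1)))


class TestTraining:
    def test_zero_noise_autoencoder_reaches_perfect_reconstruction(self):
        stim = make_stimulus_frequencies(60, [10, 9, 8, 7, 6])
        tab = generate_dataset(stim, 2, 5, noise=None, seed=5)
        dae = LinearDenoisingAutoencoder(
            hidden_size=100, mode="AE", n_iterations=20000,
            batch_size=len(tab), learning_rate=0.01, seed=0,
        ).fit(tab.X)
        assert dae.final_loss_ < 1e-6

    def test_trained_loss_approaches_reduced_rank_optimum(self):
        # 20-sample epochs at 20 Hz, hidden 5, 200 epochs
        stim = make_stimulus_frequencies(20, [10, 5, 4])
        from ssvepdae import NoiseSpec

        tab = generate_dataset(stim, 2, 34, NoiseSpec(target_snr_db=0.0, seed=2), seed=2, fs=20.0)
        tab = tab.subset(np.arange(len(tab)) < 200)
        dae = LinearDenoisingAutoencoder(
            hidden_size=5, mode="IP", fs=20.0, n_iterations=5000,
            batch_size=200, learning_rate=0.01, seed=0,
        ).fit(tab.X, tab.label_frequencies)
        Z, _, _ = standardize_epochs(tab.X)
        T = np.array([
            build_target(Z[i], tab.label_frequencies[i], 20.0, "IP")
            for i in range(len(tab))
        ])
        opt = rrr_optimum_loss(Z, T, 5)
        assert dae.final_loss_ <= opt * 1.01

    def test_same_seed_identical_parameters(self, noisy_table):
        cfg = DAETrainConfig(n_iterations=200, seed=3)
        a = train_dae(noisy_table, "IP", 10, cfg)
        b = train_dae(noisy_table, "IP", 10, cfg)
        assert np.array_equal(a.W_, b.W_)
        assert np.array_equal(a.W_dec_, b.W_dec_)

    def test_divergence_raises_with_iteration_number(self, noisy_table):
        with pytest.raises(FloatingPointError, match="iteration"):
            LinearDenoisingAutoencoder(
                hidden_size=25, mode="AE", learning_rate=10.0, n_iterations=500, seed=0
            ).fit(noisy_table.X)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            LinearDenoisingAutoencoder().fit(np.empty((0, 100)), np.empty(0))

    def test_sine_target_modes_require_frequencies(self, noisy_table):
        with pytest.raises(ValueError, match="frequencies"):
            LinearDenoisingAutoencoder(mode="IP").fit(noisy_table.X)


class TestPersistence:
    def test_json_round_trip_bit_exact(self, tmp_path, noisy_table):
        model = train_dae(noisy_table, "IP", 8, DAETrainConfig(n_iterations=100, seed=1))
        p = tmp_path / "dae.json"
        save_dae(model, p)
        back = load_dae(p)
        assert np.array_equal(back.W_, model.W_)
        assert np.array_equal(back.b_, model.b_)
        assert np.array_equal(back.W_dec_, model.W_dec_)
        assert np.array_equal(back.b_dec_, model.b_dec_)
        assert back.mode == model.mode
        x = noisy_table.X[:3]
        assert np.array_equal(back.reconstruct(x), model.reconstruct(x))


@given(phi=st.floats(min_value=0, max_value=2 * np.pi, exclude_max=True))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_phase_estimator_error_bound_property(phi):
    f, fs = 7.5, 100.0
    est = estimate_phase_xcorr(sine(f, fs, 100, phi), f, fs)
    err = abs((est - phi + np.pi) % (2 * np.pi) - np.pi)
    assert err <= np.pi * f / fs + 1e-9
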