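import numpy as np
import pytest

from cortconn.io import EpochedEEG, TEST
from cortconn.preprocess import (
    apply_rejection,
    backproject,
    bandpass_filter,
    fit_equivalent_dipole,
    infomax_ica,
    kurtosis_reject,
    rereference_average,
    resample,
    select_cortical_ics,
)


def make_eeg(data: np.ndarray, fs: float = 512.0) -> EpochedEEG:
    C, T, N = data.shape
    gen = np.random.default_rng(0)
    return EpochedEEG(
        data=data,
        fs=fs,
        channel_names=[f"E{i}" for i in range(C)],
        channel_pos=gen.standard_normal((C, 3)) * 0.05,
        condition=np.array([TEST] * N, dtype=object),
    )


def tone(freq: float, fs: float, T: int) -> np.ndarray:
    return np.sin(2 * np.pi * freq * np.arange(T) / fs)


class TestFilter:
    def test_passband_tone_preserved(self):
        fs, T = 512.0, 2048
        x = np.tile(tone(10, fs, T), (2, 1))[:, :, None]
        out = bandpass_filter(make_eeg(x, fs), 1.0, 55.0)
        mid = slice(T // 4, -T // 4)
        ratio = out.data[0, mid, 0].std() / x[0, mid, 0].std()
        assert abs(ratio - 1.0) < 0.05

    def test_stopband_tone_attenuated(self):
        fs, T = 512.0, 2048
        x = np.tile(tone(100, fs, T), (2, 1))[:, :, None]
        out = bandpass_filter(make_eeg(x, fs), 1.0, 55.0)
        mid = slice(T // 4, -T // 4)  # avoid forward-backward edge transients
        assert out.data[:, mid].std() < 0.1 * x[:, mid].std()

    def test_dc_offset_removed(self):
        fs, T = 512.0, 1024
        x = np.full((2, T, 1), 50.0)
        out = bandpass_filter(make_eeg(x, fs), 1.0, 55.0)
        assert np.abs(out.data.mean()) < 1e-9

    def test_band_above_nyquist_rejected(self, toy_eeg):
        with pytest.raises(ValueError):
            bandpass_filter(toy_eeg, 1.0, 70.0)  # fs = 128


class TestRereference:
    def test_two_channel_arithmetic(self):
        x = np.array([[[1.0], [1.0]], [[3.0], [3.0]]]).reshape(2, 2, 1)
        out = rereference_average(make_eeg(x))
        np.testing.assert_allclose(out.data[:, :, 0], [[-1, -1], [1, 1]])

    def test_idempotent_projection(self, toy_eeg):
        once = rereference_average(toy_eeg)
        twice = rereference_average(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)
        np.testing.assert_allclose(once.data.mean(axis=0), 0.0, atol=1e-12)

    def test_rank_reduced(self, toy_eeg):
        out = rereference_average(toy_eeg)
        flat = out.data.reshape(out.n_channels, -1)
        s = np.linalg.svd(flat, compute_uv=False)
        assert s[-1] < 1e-10 * s[0]


class TestKurtosisReject:
    def test_spiky_channel_flagged_alone(self):
        gen = np.random.default_rng(1)
        data = gen.standard_normal((32, 256, 8))
        hits = gen.random((256, 8)) < 0.05
        data[5][hits] += gen.choice([-12.0, 12.0], size=hits.sum())
        flags, trial_flags, report = kurtosis_reject(make_eeg(data), 5.0)
        assert list(np.flatnonzero(flags)) == [5]
        assert report["flagged_channels"] == [5]

    def test_homogeneous_channels_unflagged(self):
        gen = np.random.default_rng(2)
        flags, trial_flags, _ = kurtosis_reject(make_eeg(gen.standard_normal((16, 128, 6))), 5.0)
        assert not flags.any() and not trial_flags.any()

    def test_zero_threshold_invalid(self, toy_eeg):
        with pytest.raises(ValueError):
            kurtosis_reject(toy_eeg, 0.0)

    def test_too_few_trials_raise(self):
        gen = np.random.default_rng(3)
        with pytest.raises(ValueError):
            kurtosis_reject(make_eeg(gen.standard_normal((8, 64, 2))), 5.0)

    def test_override_keeps_flagged_channel(self):
        gen = np.random.default_rng(1)
        data = gen.standard_normal((32, 256, 8))
        hits = gen.random((256, 8)) < 0.05
        data[5][hits] += gen.choice([-12.0, 12.0], size=hits.sum())
        flags, _, _ = kurtosis_reject(make_eeg(data), 5.0, override_keep=[("channel", 5)])
        assert not flags.any()

    def test_apply_rejection_reduces(self):
        gen = np.random.default_rng(4)
        eeg = make_eeg(gen.standard_normal((8, 64, 6)))
        out = apply_rejection(eeg, np.eye(8, dtype=bool)[0], np.zeros(6, bool))
        assert out.n_channels == 7 and out.n_trials == 6


from helpers import amari_index


class TestInfomax:
    def test_recovers_laplacian_mixture(self):
        gen = np.random.default_rng(0)
        S = gen.laplace(size=(2, 8000))
        A = np.array([[1.0, 0.5], [0.5, 1.0]])
        X = (A @ S).reshape(2, 1000, 8)
        decomp = infomax_ica(make_eeg(X, 128.0), seed=0)
        assert amari_index(decomp.unmixing @ A) < 0.1

    def test_deterministic_given_seed(self):
        gen = np.random.default_rng(1)
        X = gen.laplace(size=(3, 400, 5))
        d1 = infomax_ica(make_eeg(X, 128.0), seed=3)
        d2 = infomax_ica(make_eeg(X, 128.0), seed=3)
        np.testing.assert_array_equal(d1.unmixing, d2.unmixing)

    def test_mixing_unmixing_inverse_pair(self):
        gen = np.random.default_rng(2)
        X = gen.laplace(size=(3, 400, 5))
        d = infomax_ica(make_eeg(X, 128.0), seed=0)
        np.testing.assert_allclose(d.mixing @ d.unmixing, np.eye(3), atol=1e-8)

    def test_rank_deficient_raises_with_guidance(self):
        gen = np.random.default_rng(3)
        X = gen.standard_normal((2, 300, 4))
        X3 = np.concatenate([X, X[:1] + X[1:]], axis=0)
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            infomax_ica(make_eeg(X3, 128.0), seed=0)


class TestBackproject:
    @pytest.fixture(scope="class")
    def decomp(self):
        gen = np.random.default_rng(4)
        X = gen.laplace(size=(4, 300, 6))
        return X, infomax_ica(make_eeg(X, 128.0), seed=0)

    def test_retain_all_recovers_input(self, decomp):
        X, d = decomp
        Xc = X - X.reshape(4, -1).mean(axis=1)[:, None, None]
        out = backproject(d, range(4))
        assert np.max(np.abs(out - Xc)) < 1e-8

    def test_single_component_output_rank_one(self, decomp):
        _, d = decomp
        out = backproject(d, [2]).reshape(4, -1)
        s = np.linalg.svd(out, compute_uv=False)
        assert s[1] < 1e-8 * s[0]

    def test_empty_retained_raises(self, decomp):
        _, d = decomp
        with pytest.raises(ValueError):
            backproject(d, [])


class TestDipoleFit:
    def test_exact_leadfield_column(self, small_model):
        fit = fit_equivalent_dipole(small_model.K[:, 17], small_model)
        assert fit.gridpoint == 17
        assert fit.residual_variance < 1e-10

    def test_noisy_column_recovered(self, small_model):
        gen = np.random.default_rng(5)
        col = small_model.K[:, 23]
        noisy = col + gen.standard_normal(col.shape) * np.sqrt(np.mean(col**2) / 100)
        fit = fit_equivalent_dipole(noisy, small_model)
        assert fit.gridpoint == 23

    def test_orthogonal_map_has_high_rv(self, small_model, rng):
        K = small_model.K
        Q, _ = np.linalg.qr(K)
        v = rng.standard_normal(K.shape[0])
        v -= Q[:, : np.linalg.matrix_rank(K)] @ (Q[:, : np.linalg.matrix_rank(K)].T @ v)
        fit = fit_equivalent_dipole(v, small_model)
        assert fit.residual_variance > 0.99

    def test_zero_map_raises(self, small_model):
        with pytest.raises(ValueError):
            fit_equivalent_dipole(np.zeros(small_model.n_channels), small_model)


class TestSelectICs:
    def test_leadfield_component_retained_noise_rejected(self, small_model):
        gen = np.random.default_rng(6)
        C = small_model.n_channels
        from cortconn.preprocess import ICADecomposition

        mixing = np.column_stack([small_model.K[:, 5], gen.standard_normal(C)])
        mixing = np.column_stack([mixing, gen.standard_normal((C, C - 2))])
        decomp = ICADecomposition(
            unmixing=np.linalg.pinv(mixing), mixing=mixing,
            activations=np.zeros((C, 10, 2)), converged=True, iterations=1,
        )
        retained, log = select_cortical_ics(decomp, small_model, rv_threshold=0.15)
        assert 0 in retained and 1 not in retained

    def test_vacuous_threshold_retains_all(self, small_model):
        gen = np.random.default_rng(7)
        C = small_model.n_channels
        from cortconn.preprocess import ICADecomposition

        mixing = gen.standard_normal((C, C))
        decomp = ICADecomposition(
            unmixing=np.linalg.pinv(mixing), mixing=mixing,
            activations=np.zeros((C, 10, 2)), converged=True, iterations=1,
        )
        retained, _ = select_cortical_ics(decomp, small_model, rv_threshold=1.0)
        assert retained == list(range(C))


class TestResample:
    def test_512_to_128_quarters_samples(self):
        gen = np.random.default_rng(8)
        eeg = make_eeg(gen.standard_normal((3, 512, 4)), 512.0)
        out = resample(eeg, 128.0)
        assert out.n_samples == 128 and out.fs == 128.0

    def test_passband_tone_amplitude_preserved(self):
        fs, T = 512.0, 2048
        x = np.tile(tone(10, fs, T), (2, 1))[:, :, None]
        out = resample(make_eeg(x, fs), 128.0)
        assert abs(out.data.std() / x.std() - 1.0) < 0.05

    def test_above_new_nyquist_removed(self):
        fs, T = 512.0, 2048
        x = np.tile(tone(100, fs, T), (2, 1))[:, :, None]
        out = resample(make_eeg(x, fs), 128.0)
        assert out.data.std() < 0.1 * x.std()

    def test_invalid_target_raises(self, toy_eeg):
        with pytest.raises(ValueError):
            resample(toy_eeg, -5.0)
        with pytest.raises(ValueError):
            resample(toy_eeg, 256.0)
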