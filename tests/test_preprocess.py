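"""Filtering, epoching, features, standardization, kernel PCA, channel choice."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nirscgan as ng
from nirscgan.preprocess import FeatureMatrix, kernel_pca_reduce, select_channel
from nirscgan.types import Epoch, Event, Recording, TaskLabel


def _recording_from(series: np.ndarray, fs: float = 10.0, events=()) -> Recording:
    data = np.tile(series, (2, 1))
    return Recording(hbo=data, hbr=data.copy(), sampling_rate=fs,
                     events=list(events), channel_side=["left", "right"])


def butterworth_gain(freq: float, low: float = 0.01, high: float = 0.1,
                     order: int = 3) -> float:
    """Squared analytic band-pass magnitude (forward-backward application)."""
    from scipy import signal as sps

    b, a = sps.butter(order, [low, high], btype="bandpass", fs=10.0)
    _, h = sps.freqz(b, a, worN=[2 * np.pi * freq / 10.0])
    return float(np.abs(h[0]) ** 2)


class TestBandpass:
    def test_dc_removed(self):
        rec = _recording_from(np.full(3000, 5.0))
        out = ng.bandpass(rec)
        assert np.abs(out.hbo).max() < 1e-6 * 5.0

    def test_passband_amplitude_and_phase(self):
        # long record and a central window: the 0.01 Hz poles have a ~16 s
        # time constant, so steady state needs room away from the edges
        t = np.arange(12000) / 10.0
        rec = _recording_from(np.sin(2 * np.pi * 0.05 * t))
        out = ng.bandpass(rec)
        mid = slice(5500, 6500)
        amp = out.hbo[0, mid].max()
        assert 0.9 <= amp <= 1.0
        assert amp == pytest.approx(np.sqrt(butterworth_gain(0.05)), abs=0.02)
        # zero-phase: cross-correlation peak at zero lag
        a, b = rec.hbo[0, mid], out.hbo[0, mid]
        lags = np.arange(-20, 21)
        xc = [np.dot(a, np.roll(b, k)) for k in lags]
        assert lags[np.argmax(xc)] == 0

    def test_cardiac_attenuation(self):
        t = np.arange(12000) / 10.0
        rec = _recording_from(np.sin(2 * np.pi * 1.2 * t))
        out = ng.bandpass(rec)
        amp = np.abs(out.hbo[0, 5500:6500]).max()
        assert amp < 1e-3
        assert butterworth_gain(1.2) < 1e-4  # analytic oracle agrees: > 40 dB

    def test_stopband_attenuation_exceeds_40db(self):
        assert 10 * np.log10(1 / butterworth_gain(1.2)) >= 40
        assert 10 * np.log10(1 / butterworth_gain(0.001)) >= 40

    def test_band_validation(self):
        rec = _recording_from(np.zeros(1000))
        with pytest.raises(ValueError):
            ng.bandpass(rec, low=0.1, high=6.0)
        with pytest.raises(ValueError):
            ng.bandpass(rec, low=0.2, high=0.1)

    def test_short_signal_rejected(self):
        rec = _recording_from(np.zeros(30))
        with pytest.raises(ValueError, match="short"):
            ng.bandpass(rec)


class TestExtractEpochs:
    def _rec(self, onsets, n=2000):
        events = [Event(o, TaskLabel(i % 3), 10.0) for i, o in enumerate(onsets)]
        data = np.tile(np.arange(n, dtype=float), (2, 1))
        return Recording(hbo=data, hbr=data.copy(), sampling_rate=10.0, events=events)

    def test_sample_count(self):
        epochs = ng.extract_epochs(self._rec([50.0]), window=(-2, 28))
        assert len(epochs) == 1 and epochs[0].n_samples == 300

    def test_insufficient_margin_skipped(self, caplog):
        epochs = ng.extract_epochs(self._rec([1.0, 50.0]))
        assert len(epochs) == 1

    def test_labels_preserved_in_order(self):
        epochs = ng.extract_epochs(self._rec([50.0, 90.0, 130.0]))
        assert [e.label for e in epochs] == [TaskLabel.RHT, TaskLabel.LHT, TaskLabel.FT]

    def test_no_events_warns_empty(self):
        rec = self._rec([])
        with pytest.warns(UserWarning):
            assert ng.extract_epochs(rec) == []


class TestBaselineCorrect:
    def _epoch(self, series):
        data = np.tile(series, (2, 1))
        return Epoch(hbo=data, hbr=data.copy(), t0_offset=-2.0,
                     label=TaskLabel.RHT, sampling_rate=10.0)

    def test_constant_maps_to_zero(self):
        out = ng.baseline_correct(self._epoch(np.full(300, 3.2)))
        assert np.abs(out.hbo).max() < 1e-12

    def test_ramp_oracle(self):
        # epoch value equals time in seconds; reference samples cover
        # t = -1.0 .. -0.1 (half-open window), mean -0.55
        t = -2.0 + np.arange(300) / 10.0
        out = ng.baseline_correct(self._epoch(t), ref_interval=(-1, 0))
        ref_mean = np.mean(t[10:20])
        assert ref_mean == pytest.approx(-0.55)
        assert np.allclose(out.hbo[0], t - ref_mean, atol=1e-12)

    def test_reference_mean_zero_and_idempotent(self, benchmark_epochs):
        ep = benchmark_epochs[0]
        sl = slice(10, 20)
        assert np.abs(ep.hbo[:, sl].mean(axis=1)).max() < 1e-9
        again = ng.baseline_correct(ep)
        assert np.allclose(again.hbo, ep.hbo, atol=1e-12)

    def test_bad_reference_rejected(self):
        with pytest.raises(ValueError):
            ng.baseline_correct(self._epoch(np.zeros(300)), ref_interval=(-5, 0))


class TestWindowMeanFeatures:
    def test_feature_count_120(self, benchmark_epochs):
        fm = ng.window_mean_features(benchmark_epochs)
        assert fm.values.shape == (len(benchmark_epochs), 120)

    @given(n_ch=st.integers(1, 8), n_w=st.integers(1, 4))
    @settings(max_examples=20, deadline=None)
    def test_feature_count_property(self, n_ch, n_w):
        data = np.zeros((n_ch, 300))
        ep = Epoch(hbo=data, hbr=data.copy(), t0_offset=-2.0,
                   label=TaskLabel.FT, sampling_rate=10.0)
        windows = tuple((5.0 * k, 5.0 * (k + 1)) for k in range(n_w))
        fm = ng.window_mean_features([ep], windows)
        assert fm.values.shape == (1, n_ch * 2 * n_w)

    def test_constant_channel_value(self):
        data = np.zeros((3, 300))
        data[0] = 2.0
        ep = Epoch(hbo=data, hbr=np.zeros_like(data), t0_offset=-2.0,
                   label=TaskLabel.RHT, sampling_rate=10.0)
        fm = ng.window_mean_features([ep])
        assert fm.feature_names[0] == "ch00:hbo:w0-5"
        assert fm.values[0, 0] == pytest.approx(2.0)
        assert np.abs(fm.values[0, 6:]).max() == 0.0  # other channels all zero


class TestStandardize:
    def test_hand_computed_column(self):
        fm = FeatureMatrix(np.array([[1.0], [2.0], [3.0]]), ["f"], np.zeros(3, int))
        z, params = ng.standardize(fm)
        assert np.allclose(z.values.ravel(), [-1.224744871, 0, 1.224744871], atol=1e-8)
        assert params.sd[0] == pytest.approx(np.sqrt(2.0 / 3.0))  # population sd

    def test_fit_then_apply_roundtrip(self):
        rng = np.random.default_rng(0)
        fm = FeatureMatrix(rng.normal(3, 2, (20, 5)), [f"f{i}" for i in range(5)],
                           np.zeros(20, int))
        z, params = ng.standardize(fm)
        assert np.abs(z.values.mean(axis=0)).max() < 1e-9
        assert np.abs(z.values.std(axis=0) - 1).max() < 1e-9
        back = ng.preprocess.destandardize(z, params)
        assert np.allclose(back.values, fm.values, atol=1e-9)

    def test_apply_uses_given_params(self):
        rng = np.random.default_rng(1)
        fm = FeatureMatrix(rng.normal(0, 1, (10, 3)), list("abc"), np.zeros(10, int))
        _, params = ng.standardize(fm)
        test_row = FeatureMatrix(params.mean[None, :], list("abc"), np.zeros(1, int))
        z, _ = ng.standardize(test_row, params)
        assert np.abs(z.values).max() < 1e-12

    def test_constant_column_floored(self, caplog):
        fm = FeatureMatrix(np.ones((4, 2)), ["a", "b"], np.zeros(4, int))
        _, params = ng.standardize(fm)
        assert np.all(params.sd >= 1e-8)


class TestKernelPCA:
    def _pca_oracle(self, x, k):
        """Covariance eigendecomposition (independent of sklearn)."""
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc / x.shape[0]
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1][:k]
        return xc @ v[:, order]

    def test_linear_kernel_matches_pca_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = rng.normal(size=(10, 6))
            fm = FeatureMatrix(x, [f"f{i}" for i in range(6)], np.zeros(10, int))
            scores, _ = kernel_pca_reduce(fm, kernel="linear", n_components=3)
            oracle = self._pca_oracle(x, 3)
            for j in range(3):
                assert (np.allclose(scores[:, j], oracle[:, j], atol=1e-6)
                        or np.allclose(scores[:, j], -oracle[:, j], atol=1e-6))

    def test_component_bound(self):
        fm = FeatureMatrix(np.random.default_rng(0).normal(size=(5, 6)),
                           [f"f{i}" for i in range(6)], np.zeros(5, int))
        with pytest.raises(ValueError):
            kernel_pca_reduce(fm, n_components=5)
        scores, model = kernel_pca_reduce(fm, n_components=4)
        assert scores.shape == (5, 4)

    def test_rbf_separates_blobs(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 0.1, (15, 4))
        b = rng.normal(5, 0.1, (15, 4))
        fm = FeatureMatrix(np.vstack([a, b]), list("wxyz"),
                           np.r_[np.zeros(15, int), np.ones(15, int)])
        scores, _ = kernel_pca_reduce(fm, kernel="rbf", n_components=2)
        s = scores[:, 0]
        # brute-force threshold search: zero overlap
        assert max(s[:15].max(), s[15:].max()) > min(s[:15].min(), s[15:].min())
        assert (s[:15].max() < s[15:].min()) or (s[15:].max() < s[:15].min())

    def test_transform_new_rows(self):
        rng = np.random.default_rng(3)
        fm = FeatureMatrix(rng.normal(size=(12, 4)), list("abcd"), np.zeros(12, int))
        scores, model = kernel_pca_reduce(fm, n_components=2)
        again, _ = kernel_pca_reduce(fm, model)
        assert np.allclose(scores, again, atol=1e-8)


class TestSelectChannel:
    def _epochs_with_signal(self, channel: int, n_ch: int = 10):
        rng = np.random.default_rng(0)
        epochs = []
        for i in range(30):
            label = TaskLabel(i % 3)
            hbo = rng.normal(0, 0.05, (n_ch, 300))
            hbo[channel] += (int(label) - 1) * 2.0
            epochs.append(Epoch(hbo=hbo, hbr=np.zeros_like(hbo), t0_offset=-2.0,
                                label=label, sampling_rate=10.0))
        return epochs

    def test_finds_informative_channel(self):
        assert select_channel(self._epochs_with_signal(7)) == 7

    def test_tie_breaks_to_lowest_index(self):
        data = np.ones((4, 300))
        epochs = [Epoch(hbo=data * (i % 3), hbr=np.zeros_like(data), t0_offset=-2.0,
                        label=TaskLabel(i % 3), sampling_rate=10.0) for i in range(6)]
        assert select_channel(epochs) == 0

    def test_permutation_invariant(self):
        eps = self._epochs_with_signal(4)
        rev = list(reversed(eps))
        assert select_channel(eps) == select_channel(rev)

    def test_single_class_rejected(self):
        eps = [e for e in self._epochs_with_signal(2) if e.label == TaskLabel.RHT]
        with pytest.raises(ValueError):
            select_channel(eps)
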