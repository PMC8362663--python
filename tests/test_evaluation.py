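"""Metrics, MS-SSIM diagnostics and the augmentation sweep protocol."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nirscgan as ng
from nirscgan.cgan import CGANConfig
from nirscgan.classifier import CNNConfig
from nirscgan.evaluation import relaxation_schedule
from nirscgan.types import GASFImage, ImageDataset, TaskLabel

# Reference confusion matrices for the real-data protocol:
# real-only training and real + 110% generated training (30 test trials).
CM_REAL_ONLY = np.array([[8, 1, 1], [2, 7, 1], [0, 1, 9]])
CM_AUGMENTED = np.array([[9, 1, 0], [0, 10, 0], [0, 0, 10]])


class TestConfusionMatrix:
    def test_diagonal_on_perfect_prediction(self):
        cm = ng.confusion_matrix([0, 1, 2], [0, 1, 2])
        assert np.array_equal(cm, np.eye(3, dtype=int))

    def test_all_predicted_ft(self):
        cm = ng.confusion_matrix([0, 1, 2, 0], [2, 2, 2, 2])
        assert cm[:, :2].sum() == 0 and cm[:, 2].sum() == 4

    def test_random_pair_vs_hand_tally(self):
        rng = np.random.default_rng(0)
        a, p = rng.integers(0, 3, 30), rng.integers(0, 3, 30)
        cm = ng.confusion_matrix(a, p)
        for i in range(3):
            for j in range(3):
                assert cm[i, j] == int(np.sum((a == i) & (p == j)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ng.confusion_matrix([0, 1], [0])


class TestAccuracy:
    def test_real_only_matrix_gives_80(self):
        assert ng.accuracy(CM_REAL_ONLY) == pytest.approx(80.00, abs=1e-12)

    def test_augmented_matrix_gives_9667(self):
        assert ng.accuracy(CM_AUGMENTED) == pytest.approx(96.67, abs=0.005)

    def test_identity_scaled(self):
        assert ng.accuracy(np.eye(3) * 10) == 100.0

    def test_binary_reduction_consistency(self):
        """trace/total is the multi-class reduction of (TP+TN)/(TP+FP+TN+FN):
        the one-vs-rest mean obeys mean_c (TP_c+TN_c)/n = 1/3 + (2/3)·acc,
        so acc = (3·mean − 1)/2 — checked by brute-force per-class tallies."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            cm = rng.integers(0, 10, (3, 3))
            if cm.sum() == 0:
                continue
            n = cm.sum()
            ovr = []
            for c in range(3):
                tp = cm[c, c]
                fp = cm[:, c].sum() - tp
                fn = cm[c, :].sum() - tp
                tn = n - tp - fp - fn
                ovr.append((tp + tn) / n)
            acc = (3 * np.mean(ovr) - 1) / 2
            assert acc * 100 == pytest.approx(ng.accuracy(cm), abs=1e-9)


class TestPrecision:
    def test_augmented_matrix_precisions(self):
        p = ng.precision_per_class(CM_AUGMENTED)
        assert p[TaskLabel.RHT] == pytest.approx(1.0)
        assert p[TaskLabel.FT] == pytest.approx(1.0)
        assert p[TaskLabel.LHT] == pytest.approx(10 / 11, abs=1e-12)

    def test_derangement_all_zero(self):
        # cyclic misprediction: every image assigned the next class over
        p = ng.precision_per_class(np.roll(np.eye(3), 1, axis=1) * 5)
        assert np.allclose(p, 0.0)

    def test_empty_column_is_nan_with_warning(self):
        cm = np.array([[5, 5, 0], [0, 10, 0], [0, 10, 0]])
        with pytest.warns(UserWarning, match="PRECISION_UNDEFINED"):
            p = ng.precision_per_class(cm)
        assert np.isnan(p[2])


def auroc_pairwise_oracle(y, scores, cls):
    """Exhaustive positive-negative pair comparison, ties count 1/2."""
    pos = [s for yy, s in zip(y, scores) if yy == cls]
    neg = [s for yy, s in zip(y, scores) if yy != cls]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p, q in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_ordering(self):
        y = [0, 0, 1, 1, 2, 2]
        p = np.zeros((6, 3))
        for i, c in enumerate(y):
            p[i, c] = 1.0
        per, macro = ng.auroc_ovr(y, p)
        assert np.allclose(per, 1.0) and macro == 1.0

    def test_all_ties_give_half(self):
        y = [0, 1, 2, 0, 1, 2]
        per, macro = ng.auroc_ovr(y, np.full((6, 3), 1 / 3))
        assert np.allclose(per, 0.5) and macro == 0.5

    @given(st.lists(st.tuples(st.integers(0, 2),
                              st.integers(0, 4)), min_size=4, max_size=12))
    @settings(max_examples=80, deadline=None)
    def test_matches_exhaustive_pairwise_oracle(self, rows):
        y = [r[0] for r in rows]
        if len(set(y)) < 2:
            return
        rng = np.random.default_rng(0)
        p = rng.random((len(rows), 3))
        p[:, 0] = [r[1] / 4 for r in rows]  # coarse scores force ties
        per, macro = ng.auroc_ovr(y, p)
        if 0 in y and any(v != 0 for v in y):
            oracle = auroc_pairwise_oracle(y, p[:, 0], 0)
            assert per[0] == pytest.approx(oracle, abs=1e-12)
        vals = per[~np.isnan(per)]
        assert macro == pytest.approx(np.mean(vals))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ng.auroc_ovr([1, 1, 1], np.full((3, 3), 1 / 3))


class TestMsSsim:
    def _img(self, seed, smooth=True):
        rng = np.random.default_rng(seed)
        base = rng.random((28, 28))
        if smooth:
            from scipy.ndimage import gaussian_filter

            base = gaussian_filter(base, 2.0)
            base = (base - base.min()) / (base.max() - base.min())
        return base

    def test_identical_images_score_one(self):
        a = self._img(0)
        assert ng.ms_ssim(a, a) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self):
        a, b = self._img(1), self._img(2)
        assert ng.ms_ssim(a, b) == pytest.approx(ng.ms_ssim(b, a), abs=1e-12)

    def test_single_scale_matches_skimage(self):
        """Contrast-structure × luminance at one scale is plain SSIM; the
        independent reference is scikit-image's implementation."""
        from skimage.metrics import structural_similarity

        from nirscgan.evaluation import ssim_index

        a, b = self._img(3), self._img(4)
        ref = structural_similarity(a, b, win_size=11, gaussian_weights=True,
                                    sigma=1.5, use_sample_covariance=False,
                                    data_range=1.0)
        assert ssim_index(a, b) == pytest.approx(ref, abs=1e-3)

    def test_noise_lowers_similarity(self):
        a = self._img(5)
        noisy = np.clip(a + 0.3 * np.random.default_rng(6).standard_normal(a.shape), 0, 1)
        assert ng.ms_ssim(a, noisy) < ng.ms_ssim(a, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ng.ms_ssim(np.zeros((28, 28)), np.zeros((14, 14)))


class TestDiversityReport:
    def _ds(self, pixel_sets):
        return ImageDataset([GASFImage(p, lab) for lab, p in pixel_sets])

    def test_identical_images_report_one(self):
        p = np.full((28, 28), 0.7)
        ds = self._ds([(TaskLabel.RHT, p.copy()) for _ in range(3)])
        rep = ng.diversity_report(ds)
        assert rep[TaskLabel.RHT] == pytest.approx(1.0, abs=1e-9)

    def test_two_images_equal_single_pair(self):
        rng = np.random.default_rng(0)
        a, b = rng.random((28, 28)), rng.random((28, 28))
        ds = self._ds([(TaskLabel.FT, a), (TaskLabel.FT, b)])
        rep = ng.diversity_report(ds)
        assert rep[TaskLabel.FT] == pytest.approx(ng.ms_ssim(a, b), abs=1e-12)

    def test_five_images_vs_brute_force_mean(self):
        rng = np.random.default_rng(1)
        imgs = [rng.random((28, 28)) for _ in range(5)]
        ds = self._ds([(TaskLabel.LHT, p) for p in imgs])
        rep = ng.diversity_report(ds)
        brute = np.mean([ng.ms_ssim(imgs[i], imgs[j])
                         for i in range(5) for j in range(i + 1, 5)])
        assert rep[TaskLabel.LHT] == pytest.approx(brute, abs=1e-12)

    def test_small_class_skipped_with_warning(self):
        ds = self._ds([(TaskLabel.RHT, np.zeros((28, 28)))])
        with pytest.warns(UserWarning, match="DIVERSITY_SKIPPED"):
            rep = ng.diversity_report(ds)
        assert TaskLabel.RHT not in rep


class TestRelaxationSchedule:
    def test_endpoints_and_monotonicity(self):
        l2_0, dr_0 = relaxation_schedule(0.0)
        l2_f, dr_f = relaxation_schedule(1.1)
        assert (l2_0, dr_0) == (0.5, 0.4)
        assert l2_f == pytest.approx(0.01) and dr_f == pytest.approx(0.2)
        grid = [relaxation_schedule(f)[0] for f in (0, 0.3, 0.6, 0.9, 1.1)]
        assert all(b <= a for a, b in zip(grid, grid[1:]))


class TestSweepStructure:
    @pytest.fixture(scope="class")
    def tiny_report(self, template_train, template_val):
        cgan = CGANConfig(steps=40, g_base_filters=16, d_base_filters=8, batch_size=16)
        cnn = CNNConfig(filters=(4, 8, 8, 8), dense_widths=(16, 8), max_epochs=4,
                        early_stop_patience=2)
        return ng.augmentation_sweep(template_train, template_val, cgan, cnn,
                                     fractions=(0.0, 0.5, 1.1), seed=0)

    def test_row_count_matches_grid(self, tiny_report):
        assert [r["fraction"] for r in tiny_report.rows] == [0.0, 0.5, 1.1]

    def test_fraction_zero_has_no_generated(self, tiny_report):
        assert tiny_report.rows[0]["n_generated"] == 0

    def test_rows_certify_real_only_testing(self, tiny_report):
        assert all(r["test_real_only"] for r in tiny_report.rows)

    def test_regularization_logged_per_row(self, tiny_report):
        l2s = [r["l2"] for r in tiny_report.rows]
        assert l2s[0] == 0.5 and l2s[-1] == pytest.approx(0.01)

    def test_render_table_has_named_rows(self, tiny_report):
        text = tiny_report.render_table()
        assert "Original data set" in text
        assert "Real data + 110% generated data" in text

    def test_generated_images_rejected_as_sweep_input(self, template_train):
        fake = ImageDataset([GASFImage(im.pixels, im.label, "generated")
                             for im in template_train.images])
        with pytest.raises(ValueError):
            ng.augmentation_sweep(fake, template_train, fractions=(0.0,), seed=0)
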