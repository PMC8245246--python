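"""Feature families, the adjacency spatial filter, SVM cross-validation and
the repeated-measures ANOVA."""

import numpy as np
import pytest

from gaitnet.data import EpochSet
from gaitnet.decode import (rm_anova_1way, rm_anova_path_length,
                            train_eval_svm)
from gaitnet.features import (AdjacencySpatialFilter, FeatureTable,
                              TrialNetworks, features_mrcp, features_netattr,
                              features_powerspec_ar, features_hht,
                              per_trial_networks)


def toy_epochs(n_trials=6, n_channels=3, n_samples=400, rate=1000.0, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_trials, n_channels, n_samples))
    labels = ["MCI" if i % 2 == 0 else "IEG" for i in range(n_trials)]
    return EpochSet(data, labels, rate)


class TestMrcpFeatures:
    def test_template_trial_recovers_amplitude(self):
        t = np.arange(1000) / 1000.0
        template = -5.0 * np.exp(-0.5 * ((t - 0.2) / 0.03) ** 2)
        data = np.zeros((1, 2, 1000))
        data[0, 0] = template
        table = features_mrcp(EpochSet(data, ["MCI"], 1000.0))
        assert table.matrix[0, 0] == pytest.approx(-5.0, abs=1e-6)
        assert table.matrix[0, 1] == 0.0

    def test_dimension_is_channel_count(self):
        e = toy_epochs(n_channels=7)
        assert features_mrcp(e).d == 7
        assert features_mrcp(e, include_phase=True).d == 14

    def test_full_montage_is_32_dimensional(self):
        e = toy_epochs(n_trials=4, n_channels=32)
        assert features_mrcp(e).d == 32


class TestPowerspecFeatures:
    def test_ar1_band_power_matches_closed_form_ordering(self):
        """Closed-form oracle: the AR(1) PSD is proportional to
        1/(1 - 2a cos w + a^2). At 1000 Hz with a = 0.9 the half-power point
        is ~17 Hz, so at equal total variance the 8-30 Hz band holds a far
        larger share for the AR(1) channel than for white noise (whose power
        spreads to 500 Hz)."""
        a, fs = 0.9, 1000.0
        f = np.linspace(0.5, fs / 2, 2000)
        w_ang = 2 * np.pi * f / fs
        ar_psd = 1.0 / (1 - 2 * a * np.cos(w_ang) + a**2)
        band = (f >= 8) & (f <= 30)
        frac_ar = np.trapezoid(ar_psd[band], f[band]) / np.trapezoid(ar_psd, f)
        frac_white = (30 - 8) / (fs / 2)
        assert frac_ar > frac_white  # the derived direction

        rng = np.random.default_rng(1)
        n = 4000
        noise = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = noise[0]
        for i in range(1, n):
            x[i] = a * x[i - 1] + noise[i]
        x *= noise.std() / x.std()  # equal variance
        data = np.stack([[x, noise]])
        table = features_powerspec_ar(EpochSet(data, ["MCI"], fs))
        assert table.matrix[0, 0] > table.matrix[0, 1]
        measured_ratio = table.matrix[0, 0] / table.matrix[0, 1]
        assert measured_ratio == pytest.approx(frac_ar / frac_white, rel=0.35)

    def test_zero_channel_zero_feature(self):
        data = np.zeros((1, 2, 500))
        data[0, 1] = np.random.default_rng(2).standard_normal(500)
        table = features_powerspec_ar(EpochSet(data, ["MCI"], 1000.0))
        assert table.matrix[0, 0] == 0.0
        assert table.matrix[0, 1] > 0.0

    def test_quadratic_amplitude_scaling(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((1, 1, 1000))
        e1 = features_powerspec_ar(EpochSet(x, ["MCI"], 1000.0)).matrix[0, 0]
        e2 = features_powerspec_ar(EpochSet(2 * x, ["MCI"], 1000.0)).matrix[0, 0]
        assert e2 / e1 == pytest.approx(4.0, rel=0.05)


class TestHhtFeatures:
    def test_shape_contract(self):
        e = toy_epochs(n_trials=3, n_channels=4, n_samples=600, rate=250.0)
        table = features_hht(e, decimate=2)
        assert table.matrix.shape == (3, 4)
        assert table.family == "timefreq"


class TestNetattrFeatures:
    @staticmethod
    def networks_from(adjs, labels):
        adjs = np.asarray(adjs)
        return TrialNetworks(adjs.astype(float), adjs.astype(int), labels,
                             order=2, band=(8, 30), threshold=0.2)

    def test_complete_graph_gives_all_ones(self):
        a = 1 - np.eye(4, dtype=int)
        table = features_netattr(self.networks_from([a, a], ["MCI", "IEG"]))
        np.testing.assert_array_equal(table.matrix, 1.0)

    def test_empty_graph_imputed_finite(self):
        z = np.zeros((4, 4), dtype=int)
        with pytest.warns(UserWarning, match="empty"):
            table = features_netattr(self.networks_from([z, z], ["MCI", "IEG"]))
        assert np.isfinite(table.matrix).all()

    def test_density_gap_separates_classes(self, two_class_epochs):
        epochs, _ = two_class_epochs
        mask = [lab in ("MCI", "IEG") for lab in epochs.labels]
        sub = EpochSet(epochs.data[mask],
                       [l for l in epochs.labels if l != "REST"], epochs.rate)
        nets = per_trial_networks(sub, order=2)
        table = features_netattr(nets)
        labs = np.asarray(table.labels)
        mci = table.matrix[labs == "MCI"]
        ieg = table.matrix[labs == "IEG"]
        between = np.linalg.norm(mci.mean(0) - ieg.mean(0))
        within = 0.5 * (np.linalg.norm(mci - mci.mean(0), axis=1).mean()
                        + np.linalg.norm(ieg - ieg.mean(0), axis=1).mean())
        assert between > 0  # classes differ in planted density
        assert nets.weights.shape[1:] == (4, 4)


class TestAdjacencySpatialFilter:
    def test_identical_class_means_flat_eigenvalues(self):
        rng = np.random.default_rng(4)
        base = rng.random((6, 6))
        weights = np.stack([base + 1e-6 * rng.random((6, 6)) for _ in range(8)])
        f = AdjacencySpatialFilter(n_components=4).fit(
            weights, ["A"] * 4 + ["B"] * 4
        )
        np.testing.assert_allclose(f.eigvals_, 0.5, atol=0.05)

    def test_planted_block_contrast_separates(self):
        rng = np.random.default_rng(5)
        n = 8
        w_a, w_b = [], []
        for _ in range(20):
            noise = 0.05 * rng.random((n, n))
            a = noise.copy()
            a[:4, :4] += 0.8  # class A: strong front block
            b = noise.copy()
            b[4:, 4:] += 0.8  # class B: strong back block
            w_a.append(a)
            w_b.append(b)
        weights = np.stack(w_a + w_b)
        labels = ["A"] * 20 + ["B"] * 20
        f = AdjacencySpatialFilter(n_components=4).fit(weights, labels)
        assert f.eigvals_.max() > 0.8
        feats_a = f.transform(weights[:20])
        feats_b = f.transform(weights[20:])
        assert np.abs(feats_a.mean(0) - feats_b.mean(0)).max() > 0.5

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        weights = rng.random((10, 5, 5))
        labels = np.array(["A"] * 5 + ["B"] * 5)
        perm = rng.permutation(10)
        f1 = AdjacencySpatialFilter(4).fit(weights, labels)
        f2 = AdjacencySpatialFilter(4).fit(weights[perm], labels[perm])
        np.testing.assert_allclose(f1.transform(weights), f2.transform(weights),
                                   atol=1e-8)

    def test_component_cap_on_small_montage(self):
        rng = np.random.default_rng(7)
        weights = rng.random((8, 4, 4))
        f = AdjacencySpatialFilter(16).fit(weights, ["A"] * 4 + ["B"] * 4)
        assert f.filters_.shape == (4, 4)  # capped at N

    def test_full_montage_gives_16_components(self):
        rng = np.random.default_rng(8)
        weights = rng.random((12, 32, 32))
        f = AdjacencySpatialFilter(16).fit(weights, ["A"] * 6 + ["B"] * 6)
        assert f.transform(weights).shape == (12, 16)


class TestSvm:
    def test_separable_features_perfect(self):
        rng = np.random.default_rng(9)
        x = np.vstack([rng.normal(0, 0.1, (20, 3)),
                       rng.normal(5, 0.1, (20, 3))])
        table = FeatureTable(x, ["MCI"] * 20 + ["IEG"] * 20, "toy")
        rep = train_eval_svm(table, seed=0)
        assert rep.mean_accuracy == 100.0
        assert rep.confusion.sum() == 40

    def test_shuffled_labels_at_chance(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((40, 6))
        accs = []
        for seed in range(20):
            labels = list(rng.permutation(["MCI"] * 20 + ["IEG"] * 20))
            rep = train_eval_svm(FeatureTable(x, labels, "null"), seed=seed)
            accs.append(rep.mean_accuracy)
        assert 40.0 <= np.mean(accs) <= 60.0

    def test_too_few_trials_rejected(self):
        table = FeatureTable(np.zeros((6, 2)), ["MCI"] * 3 + ["IEG"] * 3, "toy")
        with pytest.raises(ValueError):
            train_eval_svm(table, cv_folds=5)

    def test_report_std_is_across_folds(self):
        rng = np.random.default_rng(11)
        x = np.vstack([rng.normal(0, 1.5, (25, 4)),
                       rng.normal(1, 1.5, (25, 4))])
        rep = train_eval_svm(FeatureTable(x, ["MCI"] * 25 + ["IEG"] * 25,
                                          "toy"), seed=1)
        assert rep.std_accuracy == pytest.approx(
            np.std(rep.fold_accuracies, ddof=1))
        assert 0 <= rep.mean_accuracy <= 100


class TestRmAnova:
    def test_identical_conditions_not_significant(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((20, 5)) + 3
        nodal = {"MCI": x, "REST": x.copy()}
        table = rm_anova_path_length(nodal, list("abcde"), ("MCI", "REST"),
                                     channels=list("abcde"))
        diag = np.diag(table.p_values)
        assert (diag > 0.99).all()
        assert not np.diag(table.significant).any()

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(13)
        base = rng.standard_normal((30, 5))
        shifted = base.copy()
        shifted[:, 2] += 3.0  # 3 within-trial SDs on one channel
        nodal = {"MCI": shifted, "REST": base + rng.standard_normal((30, 5)) * 0.0}
        table = rm_anova_path_length(nodal, list("abcde"), ("MCI", "REST"),
                                     channels=list("abcde"))
        assert table.p_values[2, 2] < 0.05

    def test_unpaired_design_rejected(self):
        nodal = {"MCI": np.zeros((10, 3)), "REST": np.zeros((12, 3))}
        with pytest.raises(ValueError, match="unpaired"):
            rm_anova_path_length(nodal, list("abc"), ("MCI", "REST"),
                                 channels=list("abc"))

    def test_matches_statsmodels_anovarm(self):
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(14)
        data = rng.standard_normal((15, 3)) + [0.0, 0.4, 0.1]
        f_ours, p_ours = rm_anova_1way(data)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(15), 3),
            "cond": np.tile(np.arange(3), 15),
            "y": data.ravel(),
        })
        res = AnovaRM(long, "y", "subject", within=["cond"]).fit()
        assert f_ours == pytest.approx(res.anova_table["F Value"].iloc[0],
                                       rel=1e-8)
        assert p_ours == pytest.approx(res.anova_table["Pr > F"].iloc[0],
                                       rel=1e-8)

    def test_two_condition_grid_matches_general_formula(self):
        rng = np.random.default_rng(15)
        x1 = rng.standard_normal((12, 3))
        x2 = rng.standard_normal((12, 3))
        table = rm_anova_path_length({"A": x1, "B": x2}, list("abc"),
                                     ("A", "B"), channels=list("abc"))
        for i in range(3):
            for j in range(3):
                f, p = rm_anova_1way(np.column_stack([x1[:, i], x2[:, j]]))
                assert table.f_values[i, j] == pytest.approx(f, rel=1e-10)
                assert table.p_values[i, j] == pytest.approx(p, rel=1e-10)
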