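import numpy as np
import pandas as pd
import pytest

import methpanel as mp
from methpanel.classify_eval import predict, rose_params
from methpanel.exceptions import ConfigurationError, DesignError, SplitError, ValidationError


class TestStratifiedSplit:
    def test_class_ratios_preserved(self):
        ids = [f"s{i}" for i in range(100)]
        labels = ["tumor"] * 80 + ["normal"] * 20
        train, test = mp.train_test_split_stratified(ids, labels, 0.2, seed=0)
        assert len(train) == 80 and len(test) == 20
        lookup = dict(zip(ids, labels))
        assert sum(lookup[s] == "tumor" for s in test) == 16
        assert set(train) | set(test) == set(ids)
        assert set(train) & set(test) == set()

    def test_same_seed_same_split(self):
        ids = [f"s{i}" for i in range(30)]
        labels = ["tumor"] * 20 + ["normal"] * 10
        assert mp.train_test_split_stratified(ids, labels, seed=5) == \
            mp.train_test_split_stratified(ids, labels, seed=5)

    def test_half_split_of_four_plus_four(self):
        ids = list("abcdefgh")
        labels = ["tumor"] * 4 + ["normal"] * 4
        train, test = mp.train_test_split_stratified(ids, labels, 0.5, seed=1)
        assert len(train) == 4 and len(test) == 4

    def test_tiny_class_rejected(self):
        with pytest.raises(SplitError):
            mp.train_test_split_stratified(["a", "b"], ["tumor", "normal"], 0.5, seed=0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            mp.train_test_split_stratified(["a", "b"], ["tumor", "normal"], 1.5, seed=0)


class TestRoseBandwidth:
    @pytest.mark.parametrize(
        "d,n,sigma,expected",
        [(1, 100, 1.0, 0.4217), (4, 25, 0.5, 0.3179), (3, 10, 0.0, 0.0)],
    )
    def test_closed_form_values(self, d, n, sigma, expected):
        assert mp.rose_bandwidth(d, n, sigma) == pytest.approx(expected, abs=1e-4)

    def test_zero_bandwidth_only_for_zero_sigma(self):
        X = np.array([[0, 1], [0, 0], [0, 1]], dtype=float)
        params = rose_params(X, "normal")
        assert params.h[0] == 0.0 and params.h[1] > 0.0


class TestRoseOversample:
    def _features(self, X):
        return pd.DataFrame(X, index=[f"s{i}" for i in range(len(X))], columns=["f1", "f2"])

    def test_balanced_input_untouched(self):
        X = self._features(np.array([[0, 1], [1, 0], [1, 1], [0, 0]]))
        y = np.array(["tumor", "tumor", "normal", "normal"])
        Xb, yb = mp.rose_oversample(X, y, seed=0)
        assert Xb.equals(X) and list(yb) == list(y)

    def test_top_up_to_exact_balance(self):
        rng = np.random.default_rng(0)
        X = self._features(rng.integers(0, 2, (20, 2)))
        y = np.array(["tumor"] * 15 + ["normal"] * 5)
        Xb, yb = mp.rose_oversample(X, y, seed=1)
        assert len(Xb) == 30
        assert (yb == "normal").sum() == (yb == "tumor").sum() == 15
        # originals preserved verbatim, synthetic rows appended after
        assert Xb.iloc[:20].equals(X)
        assert set(np.unique(Xb.to_numpy())) <= {0, 1}

    def test_synthetic_means_track_minority_means(self):
        rng = np.random.default_rng(3)
        minority = rng.integers(0, 2, (30, 2))
        X = self._features(np.vstack([rng.integers(0, 2, (90, 2)), minority]))
        y = np.array(["tumor"] * 90 + ["normal"] * 30)
        diffs = []
        for seed in range(50):
            Xb, yb = mp.rose_oversample(X, y, seed=seed)
            synth = Xb.iloc[120:].to_numpy()
            diffs.append(synth.mean(axis=0) - minority.mean(axis=0))
        mean_diff = np.abs(np.mean(diffs, axis=0))
        se = np.sqrt(0.25 / (60 * 50))
        assert np.all(mean_diff < 3 * se + 0.02)

    def test_degenerate_single_minority_duplicates(self):
        X = self._features(np.array([[1, 1]] * 5 + [[0, 1]]))
        y = np.array(["tumor"] * 5 + ["normal"])
        with pytest.warns(UserWarning, match="duplication"):
            Xb, yb = mp.rose_oversample(X, y, seed=0)
        synth = Xb.iloc[6:].to_numpy()
        assert np.all(synth == [0, 1])


class TestForestContract:
    def test_separable_training_is_perfect(self):
        X = np.array([[0], [0], [1], [1]])
        y = np.array(["normal", "normal", "tumor", "tumor"])
        forest = mp.train_forest(X, y, trees=20, seed=0)
        assert list(predict(forest, X)) == list(y)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, (60, 4))
        y = np.where(rng.random(60) < 0.5, "tumor", "normal")
        grid = rng.integers(0, 2, (32, 4))
        p1 = predict(mp.train_forest(X, y, trees=50, seed=9), grid)
        p2 = predict(mp.train_forest(X, y, trees=50, seed=9), grid)
        np.testing.assert_array_equal(p1, p2)

    def test_indistinguishable_rows_get_majority_label(self):
        X = np.ones((9, 2))
        y = np.array(["tumor"] * 6 + ["normal"] * 3)
        forest = mp.train_forest(X, y, trees=51, seed=0)
        assert set(predict(forest, X)) == {"tumor"}

    def test_single_class_training_rejected(self):
        with pytest.raises(DesignError):
            mp.train_forest(np.zeros((4, 1)), np.array(["tumor"] * 4))


def kappa_oracle(pred, truth):
    """Direct chance-corrected agreement from the raw label pairs."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    n = len(truth)
    p_o = np.mean(pred == truth)
    p_e = sum(
        np.mean(truth == c) * np.mean(pred == c) for c in ("tumor", "normal")
    )
    return (p_o - p_e) / (1 - p_e) if p_e != 1 else 0.0


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array(["tumor", "normal", "tumor"])
        report = mp.evaluate(y, y)
        assert report.accuracy == 1.0 and report.kappa == 1.0

    def test_hand_computed_confusion(self):
        truth = ["tumor"] * 50 + ["normal"] * 50
        pred = (["tumor"] * 40 + ["normal"] * 10) + (["tumor"] * 5 + ["normal"] * 45)
        report = mp.evaluate(pred, truth)
        assert (report.tp, report.fn, report.fp, report.tn) == (40, 10, 5, 45)
        assert report.accuracy == pytest.approx(0.85)
        assert report.kappa == pytest.approx(0.70)

    def test_one_sided_predictions_zero_kappa(self):
        truth = ["tumor"] * 10 + ["normal"] * 10
        report = mp.evaluate(["tumor"] * 20, truth)
        assert report.kappa == pytest.approx(0.0)
        assert not report.kappa_undefined

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mp.evaluate(["tumor"], ["tumor", "normal"])

    def test_matches_direct_recomputation_and_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(2, 100)
            truth = np.where(rng.random(n) < 0.6, "tumor", "normal")
            pred = np.where(rng.random(n) < 0.5, "tumor", "normal")
            report = mp.evaluate(pred, truth)
            assert report.kappa == pytest.approx(kappa_oracle(pred, truth), abs=1e-12)
            if not report.kappa_undefined and len(set(truth)) == 2 and len(set(pred)) == 2:
                assert report.kappa == pytest.approx(
                    cohen_kappa_score(truth, pred), abs=1e-12
                )


class TestValidateExternal:
    def _separable_setup(self):
        cfg = mp.SimulationConfig(
            n_tumor=60,
            n_normal=60,
            n_probes=30,
            n_signal_blocks=2,
            block_size=2,
            effect_m=4.0,
            shared_noise_m=0.3,
            within_block_noise_m=0.1,
            precision=400.0,
            seed=21,
        )
        matrix, sheet, _ = mp.simulate_cohort(cfg)
        adjusted = mp.beta_to_m(matrix)
        panel = mp.Panel(
            probe_ids=["probe00000", "probe00002"],
            splits={},
            trace=mp.panel_selection.PanelTrace(),
            candidate_order=["probe00000", "probe00002"],
            chosen_size=2,
            config=mp.SelectionConfig(trees=50, seed=0),
        )
        return adjusted, sheet, panel

    def test_balanced_cohort_runs_without_rebalancing(self):
        adjusted, sheet, panel = self._separable_setup()
        report = mp.validate_external(adjusted, sheet, panel, panel.config, seed=0)
        assert report.n_test == 24
        assert report.accuracy > 0.9

    def test_predictions_invariant_to_rose_seed_when_separable(self):
        # imbalanced but cleanly separable cohort: ROSE synthesises samples,
        # yet the learned boundary (and hence test accuracy) must not move
        cfg = mp.SimulationConfig(
            n_tumor=80,
            n_normal=20,
            n_probes=30,
            n_signal_blocks=2,
            block_size=2,
            effect_m=4.0,
            shared_noise_m=0.3,
            within_block_noise_m=0.1,
            precision=400.0,
            seed=22,
        )
        matrix, sheet, _ = mp.simulate_cohort(cfg)
        adjusted = mp.beta_to_m(matrix)
        panel = mp.Panel(
            probe_ids=["probe00000", "probe00002"],
            splits={},
            trace=mp.panel_selection.PanelTrace(),
            candidate_order=["probe00000", "probe00002"],
            chosen_size=2,
            config=mp.SelectionConfig(trees=50, seed=0),
        )
        accs = {
            mp.validate_external(
                adjusted, sheet, panel, panel.config, seed=4, rose_seed=rs
            ).accuracy
            for rs in range(5)
        }
        assert len(accs) == 1

    def test_missing_panel_probe_rejected(self):
        adjusted, sheet, panel = self._separable_setup()
        panel.probe_ids = ["probe00000", "probe99999"]
        with pytest.raises(ValidationError, match="probe99999"):
            mp.validate_external(adjusted, sheet, panel, panel.config)
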