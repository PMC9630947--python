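import numpy as np
import pandas as pd
import pytest

from matchexplain.lime_explainer import (
    Explanation,
    LimeConfig,
    build_training_summary,
    discretize,
    explain_instance,
    perturb,
    similarity,
    summarize_explanations,
)


class TestDiscretize:
    def test_interpolated_quartiles_of_1_to_8(self):
        edges, encoder = discretize(np.arange(1, 9))
        assert np.allclose(edges, [2.75, 4.5, 6.25])
        assert encoder(5) == 3

    def test_below_all_edges_is_bin_one(self):
        edges, encoder = discretize(np.arange(1, 9))
        assert encoder(-100) == 1
        assert encoder(100) == 4

    def test_encoder_monotone(self):
        rng = np.random.default_rng(0)
        edges, encoder = discretize(rng.normal(size=200))
        grid = np.linspace(-4, 4, 101)
        assert np.all(np.diff(encoder(grid)) >= 0)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            discretize(np.ones(50))


class TestPerturb:
    @pytest.fixture
    def summary_and_instance(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(
            {
                "age": rng.integers(60, 95, size=500).astype(float),
                "site": rng.choice(["a", "b"], size=500, p=[0.5, 0.5]),
            }
        )
        cfg = LimeConfig(n_permutations=5000, seed=2)
        return build_training_summary(X, cfg), X.iloc[0], cfg

    def test_first_row_is_instance_with_zero_distance(self, summary_and_instance):
        summary, inst, cfg = summary_and_instance
        raw, design, dist = perturb(inst, summary, cfg)
        assert len(raw) == cfg.n_permutations
        assert np.all(design[0] == 1.0)
        assert dist[0] == 0.0
        assert raw.iloc[0]["age"] == inst["age"]
        assert raw.iloc[0]["site"] == inst["site"]

    def test_deterministic_under_seed(self, summary_and_instance):
        summary, inst, cfg = summary_and_instance
        a = perturb(inst, summary, cfg)
        b = perturb(inst, summary, cfg)
        pd.testing.assert_frame_equal(a[0], b[0])
        assert np.array_equal(a[1], b[1])

    def test_binary_feature_indicator_frequency(self, summary_and_instance):
        summary, inst, cfg = summary_and_instance
        raw, design, _ = perturb(inst, summary, cfg)
        own_level_freq = (raw["site"] == inst["site"]).mean()
        f = summary.features[1]
        train_freq = f.frequencies[f.levels.index(str(inst["site"]))]
        # the indicator resamples from the training marginal (~0.5 here)
        assert abs(design[:, 1].mean() - train_freq) < 3 * 0.5 / np.sqrt(5000)
        assert design[:, 1].mean() == pytest.approx(own_level_freq)


class TestSimilarity:
    def test_reference_points(self):
        assert similarity(np.array([0.0]), 2.0)[0] == 1.0
        assert similarity(np.array([2.0]), 2.0)[0] == pytest.approx(np.exp(-1))

    def test_wide_kernel_limit(self):
        d = np.linspace(0, 3, 10)
        w = similarity(d, 1e9)
        assert np.allclose(w, 1.0)

    def test_default_width_uses_feature_count(self):
        d = np.array([0.75 * np.sqrt(4)])
        assert similarity(d, "default", n_features=4)[0] == pytest.approx(
            np.exp(-1)
        )


class TestExplainInstance:
    def test_linear_black_box_recovered(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(
            {"z1": rng.normal(size=500), "z2": rng.normal(size=500)}
        )
        cfg = LimeConfig(
            n_permutations=5000, kernel_width=1e6, n_features=2,
            discretizer="none", seed=4,
        )
        summary = build_training_summary(X, cfg)
        m1, s1 = summary.features[0].mean, summary.features[0].sd
        m2, s2 = summary.features[1].mean, summary.features[1].sd

        def black_box(rows):
            z1 = (rows["z1"].to_numpy() - m1) / s1
            z2 = (rows["z2"].to_numpy() - m2) / s2
            return 2 * z1 - z2 + 3

        exp = explain_instance(black_box, X.iloc[0], summary, cfg)
        weights = {f["feature"]: f["weight"] for f in exp.features}
        assert weights["z1"] == pytest.approx(2.0, abs=0.05)
        assert weights["z2"] == pytest.approx(-1.0, abs=0.05)
        assert exp.explanation_fit >= 0.99

    def test_constant_black_box_zero_fit(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"x": rng.normal(size=300)})
        cfg = LimeConfig(n_permutations=500, n_features=1, seed=6)
        summary = build_training_summary(X, cfg)
        exp = explain_instance(lambda rows: np.full(len(rows), 0.7),
                               X.iloc[0], summary, cfg)
        assert exp.explanation_fit == 0.0
        assert all(abs(f["weight"]) < 1e-10 for f in exp.features)

    def test_age_dominant_tree_black_box(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(
            {
                "age": rng.integers(60, 95, size=800).astype(float),
                "noise": rng.choice(["p", "q"], size=800),
            }
        )
        cfg = LimeConfig(n_permutations=2000, n_features=2, seed=8)
        summary = build_training_summary(X, cfg)

        def tree_like(rows):
            return np.where(rows["age"].to_numpy() > 80, 0.1, 0.9)

        old = X[X["age"] > 85].iloc[0]
        exp = explain_instance(tree_like, old, summary, cfg)
        assert exp.features[0]["feature"] == "age"
        assert exp.predicted_label == "out"

    def test_deterministic_explanation(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"x": rng.normal(size=200)})
        cfg = LimeConfig(n_permutations=300, n_features=1, seed=10)
        summary = build_training_summary(X, cfg)
        bb = lambda rows: (rows["x"].to_numpy() > 0).astype(float)
        a = explain_instance(bb, X.iloc[3], summary, cfg)
        b = explain_instance(bb, X.iloc[3], summary, cfg)
        assert a.to_dict() == b.to_dict()

    def test_failing_black_box_rows_dropped_then_error(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame({"x": rng.normal(size=100)})
        cfg = LimeConfig(n_permutations=200, n_features=1, seed=12)
        summary = build_training_summary(X, cfg)

        def always_fails(rows):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="half"):
            explain_instance(always_fails, X.iloc[0], summary, cfg)


class TestSummaries:
    @staticmethod
    def _exp(sid, fit, w):
        return Explanation(
            subject_id=sid, predicted_label="in", probability=0.8,
            features=[{"feature": "x", "description": "x", "weight": w,
                       "direction": "supports"}],
            intercept=0.0, explanation_fit=fit,
        )

    def test_group_means(self):
        exps = [self._exp(0, 0.2, 0.5), self._exp(1, 0.4, 0.3)]
        out = summarize_explanations(exps, {0: "in", 1: "in"})
        assert out["in"]["mean_explanation_fit"] == pytest.approx(0.3)
        assert out["in"]["mean_top_weight"] == pytest.approx(0.4)
        assert out["out"] is None

    def test_reorder_invariance(self):
        exps = [self._exp(i, 0.1 * i, 0.2) for i in range(4)]
        labels = {0: "in", 1: "out", 2: "in", 3: "out"}
        assert summarize_explanations(exps, labels) == summarize_explanations(
            exps[::-1], labels
        )
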