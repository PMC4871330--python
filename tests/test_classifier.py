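"""ROC, logistic fits, variable selection and frozen-model scoring."""

import numpy as np
import pandas as pd
import pytest

from gaitwatch import classifier as clf
from gaitwatch.errors import ValidationError

from conftest import oracle_auc


class TestRoc:
    def test_perfect_separation(self):
        roc = clf.roc_analysis([0.9, 0.8, 0.1, 0.2],
                               [True, True, False, False])
        assert roc.auc == 1.0
        assert roc.sensitivity == 100.0 and roc.specificity == 100.0

    def test_all_tied_scores(self):
        roc = clf.roc_analysis([0.5] * 6, [True, True, True, False, False,
                                           False])
        assert roc.auc == pytest.approx(0.5)

    def test_auc_matches_pairwise_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 25))
            scores = rng.integers(0, 10, size=n).astype(float)  # forces ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            roc = clf.roc_analysis(scores, labels)
            assert roc.auc == pytest.approx(oracle_auc(scores, labels),
                                            rel=1e-12)

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.4
        roc = clf.roc_analysis(scores, labels)
        assert roc.auc == pytest.approx(roc_auc_score(labels, scores))

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=40)
        labels = np.concatenate([np.ones(20), np.zeros(20)]).astype(bool)
        a = clf.roc_analysis(scores, labels)
        b = clf.roc_analysis(np.exp(scores * 2.0), labels)
        assert a.auc == pytest.approx(b.auc)
        assert (a.sensitivity + a.specificity
                == pytest.approx(b.sensitivity + b.specificity))

    def test_complement_scores(self, rng):
        scores = rng.permutation(30).astype(float)   # tie-free
        labels = rng.random(30) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        a = clf.roc_analysis(scores, labels)
        b = clf.roc_analysis(-scores, labels)
        assert a.auc + b.auc == pytest.approx(1.0)

    def test_cutoff_tie_prefers_specificity(self):
        # two cutoffs reach sens+spec = 1.5; the high-spec one must win
        scores = [1.0, 3.0, 2.0, 4.0]
        labels = [False, False, True, True]
        roc = clf.roc_analysis(scores, labels)
        assert roc.specificity == 100.0

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            clf.roc_analysis([1.0, 2.0], [True, True])


class TestThresholdClassify:
    def test_directions(self):
        lame = [1.0, 2.0, 3.0]
        ok = [4.0, 5.0]
        out = clf.threshold_classify(lame + ok, 3.5, "below",
                                     [True] * 3 + [False] * 2)
        assert out["sensitivity"] == 100.0 and out["specificity"] == 100.0

    def test_all_below_cutoff(self):
        out = clf.threshold_classify([1.0, 2.0, 3.0], 10.0, "below",
                                     [True, False, False])
        assert out["sensitivity"] == 100.0 and out["specificity"] == 0.0

    def test_tie_on_cutoff_is_nonlame(self):
        out = clf.threshold_classify([5.0, 4.0], 5.0, "below", [True, False])
        assert out["tp"] == 0

    def test_confusion_identity(self, rng):
        """sens*P + spec*N equals the correct count on every fixture."""
        for _ in range(20):
            v = rng.normal(size=30)
            lab = rng.random(30) < 0.5
            if lab.all() or not lab.any():
                continue
            out = clf.threshold_classify(v, float(rng.normal()), "below", lab)
            correct = (out["sensitivity"] / 100 * out["n_pos"]
                       + out["specificity"] / 100 * out["n_neg"])
            assert correct == pytest.approx(
                out["proportion_correct"] / 100 * (out["n_pos"] + out["n_neg"]))


class TestLogistic:
    def test_null_feature_gives_or_near_one(self, rng):
        frame = pd.DataFrame({"x": rng.normal(size=4000)})
        labels = rng.random(4000) < 0.5
        model = clf.fit_logistic(frame, labels, ["x"])
        assert abs(model.coefficients["x"]) < 0.1
        inc = model.or_table.iloc[0]
        assert 0.85 < inc["odds_ratio"] < 1.18

    def test_binary_feature_matches_cross_product_ratio(self):
        """Single 0/1 feature: OR equals (a*d)/(b*c) from the 2x2 table."""
        a, b, c, d = 30, 10, 15, 25      # exposed-lame, exposed-ok, ...
        x = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
        model = clf.fit_logistic(pd.DataFrame({"f": x}), y, ["f"])
        expected = (a * d) / (b * c)
        assert np.exp(model.coefficients["f"]) == pytest.approx(expected,
                                                                rel=1e-4)

    def test_parameter_recovery_from_frozen_model(self, rng):
        """Fitting data simulated from the published two-variable equation
        recovers its coefficients within 10% at n = 5000."""
        fm = clf.FROZEN_MODELS["A"]
        n = 5000
        frame = pd.DataFrame({
            "standing_bouts": rng.normal(108.0, 18.0, size=n),
            "walking_speed_calc": rng.normal(0.63, 0.11, size=n),
        })
        lp = fm.score(frame)
        labels = rng.random(n) < 1.0 / (1.0 + np.exp(-lp))
        model = clf.fit_logistic(frame, labels)
        for name, true in fm.coefficients.items():
            assert abs(model.coefficients[name] - true) < 0.1 * abs(true)
        assert abs(model.intercept - fm.intercept) < 0.1 * abs(fm.intercept)

    def test_separation_flagged_not_silent(self):
        frame = pd.DataFrame({"x": [0.0, 1.0, 2.0, 10.0, 11.0, 12.0]})
        labels = [False, False, False, True, True, True]
        model = clf.fit_logistic(frame, labels, ["x"])
        assert model.separation

    def test_needs_both_classes(self):
        with pytest.raises(ValidationError):
            clf.fit_logistic(pd.DataFrame({"x": [1.0, 2.0, 3.0]}),
                             [True, True, True], ["x"])


class TestSelection:
    def test_correlated_candidates_never_cooccur(self, rng):
        x = rng.normal(size=120)
        frame = pd.DataFrame({
            "a": x, "b": 2 * x + 0.01 * rng.normal(size=120),
            "c": rng.normal(size=120)})
        labels = rng.random(120) < 1 / (1 + np.exp(-(x - 0.2)))
        sel = clf.build_multivariable(frame, ["a", "b", "c"], labels)
        assert not {"a", "b"} <= set(sel.variables)

    def test_single_informative_variable_retained(self, rng):
        n = 800
        signal = rng.normal(size=n)
        frame = pd.DataFrame({"signal": signal,
                              "noise1": rng.normal(size=n),
                              "noise2": rng.normal(size=n)})
        labels = rng.random(n) < 1 / (1 + np.exp(-2.5 * signal))
        sel = clf.build_multivariable(frame, list(frame.columns), labels)
        assert sel.variables == ["signal"]
        assert any("drop" in step["action"] for step in sel.trace)

    def test_no_admissible_pair_returns_univariable(self, rng):
        x = rng.normal(size=100)
        frame = pd.DataFrame({"a": x, "b": x + 0.001 * rng.normal(size=100)})
        labels = rng.random(100) < 1 / (1 + np.exp(-x))
        sel = clf.build_multivariable(frame, ["a", "b"], labels)
        assert len(sel.variables) == 1
        assert "univariable" in sel.note


class TestFrozenModels:
    def test_published_equation_arithmetic(self):
        """Model A at the two group-mean profiles scores -3.09 and +3.17."""
        frame = pd.DataFrame({
            "standing_bouts": [119.63, 97.91],
            "walking_speed_calc": [0.72, 0.54]})
        ev = clf.score_frozen("A", frame, cutoff=-0.06)
        assert ev.scores[0] == pytest.approx(-3.0907, abs=2e-3)
        assert ev.scores[1] == pytest.approx(3.1676, abs=2e-3)
        assert list(ev.predicted_lame) == [False, True]

    def test_model_b_equation(self):
        frame = pd.DataFrame({
            "eating_time": [378.61], "standing_bouts": [119.63],
            "walking_speed_calc": [0.72]})
        ev = clf.score_frozen("B", frame)
        expected = 26.3199 - 0.0091 * 378.61 - 0.1043 * 119.63 - 18.8167 * 0.72
        assert ev.scores[0] == pytest.approx(expected)

    def test_missing_variable_reported(self):
        with pytest.raises(ValidationError, match="standing_bouts"):
            clf.score_frozen("A", pd.DataFrame({"walking_speed_calc": [0.6]}))

    def test_frozen_auc_equals_refit_auc(self, rng):
        """Frozen and refitted two-variable models share the ROC curve family."""
        n = 120
        sb = np.concatenate([rng.normal(119.6, 17.2, 30),
                             rng.normal(97.9, 17.7, 90)])
        ws = np.concatenate([rng.normal(0.72, 0.09, 30),
                             rng.normal(0.54, 0.10, 90)])
        labels = np.array([False] * 30 + [True] * 90)
        frame = pd.DataFrame({"standing_bouts": sb, "walking_speed_calc": ws})
        frozen_auc = clf.score_frozen("A", frame, labels=labels).auc
        refit = clf.fit_logistic(frame, labels)
        refit_auc = clf.roc_analysis(refit.linear_predictor(frame), labels).auc
        assert abs(frozen_auc - refit_auc) < 0.02
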