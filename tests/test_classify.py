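"""Leakage-safe classification: selection, grouped/purged CV, LOSO, transfer
and chance tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import eegdrive as ed
from eegdrive.classify import ClassifierSpec, FoldPlan, task_labels

FAST = ClassifierSpec(n_trees=100, selector_trees=50, k1=10, k2=5, seed=0)


def synth_features(n_subjects=3, laps_per_mode=2, segments=10, n_noise=18,
                   offsets=None, seed=0, subject_shift=0.0):
    """FeatureTable with two informative columns shifted per condition.

    ``offsets`` maps condition -> (f0 offset, f1 offset) in units of the
    unit noise sd.
    """
    rng = np.random.default_rng(seed)
    offsets = offsets or {"MD-Easy": (3, 0), "MD-Hard": (3, 3),
                          "AD-Easy": (0, 0), "AD-Hard": (0, 3)}
    rows, labels, groups = [], [], []
    for s in range(n_subjects):
        shift = rng.normal(0, subject_shift)
        for lap in range(2 * laps_per_mode):
            mode = "MD" if lap < laps_per_mode else "AD"
            for seg in range(segments):
                cond = f"{mode}-{'Easy' if seg % 2 == 0 else 'Hard'}"
                x = rng.standard_normal(n_noise + 2)
                x[0] += offsets[cond][0] + shift
                x[1] += offsets[cond][1] + shift
                rows.append(x)
                labels.append(cond)
                groups.append({"subject": s, "lap": lap, "segment": seg})
    feats = pd.DataFrame(rows, columns=[f"f{i}" for i in range(n_noise + 2)])
    return ed.FeatureTable(features=feats, labels=np.array(labels),
                           groups=pd.DataFrame(groups))


class TestTwoStageSelect:
    def test_separating_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((80, 30))
        y = np.repeat(["a", "b"], 40)
        x[:, 7] = (y == "a") * 5.0 + 0.1 * rng.standard_normal(80)
        sel = ed.two_stage_select(x, y, k1=10, k2=1, seed=0)
        assert list(sel) == [7]

    def test_identity_selection(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((40, 12))
        y = np.repeat(["a", "b"], 20)
        sel = ed.two_stage_select(x, y, k1=12, k2=12, seed=0)
        np.testing.assert_array_equal(sel, np.arange(12))

    def test_k2_exceeding_k1_rejected(self):
        with pytest.raises(ValueError):
            ed.two_stage_select(np.zeros((10, 5)), np.repeat(["a", "b"], 5),
                                k1=3, k2=4)

    def test_permuted_labels_select_at_chance(self):
        rng = np.random.default_rng(2)
        n_features, informative, k2 = 200, set(range(5)), 20
        overlaps = []
        for seed in range(5):
            x = rng.standard_normal((100, n_features))
            y = np.repeat(["a", "b"], 50)
            for i in informative:
                x[:, i] += (y == "a") * 3.0
            y_perm = rng.permutation(y)
            sel = ed.two_stage_select(x, y_perm, k1=50, k2=k2, seed=seed)
            overlaps.append(len(informative & set(sel)))
        # expected overlap under chance = 5 * k2/200 = 0.5 per run
        assert np.mean(overlaps) < 2.0


class TestChanceTest:
    def test_exact_binomial_tail(self):
        # oracle: direct sum of binomial pmf for k >= 25
        expected = sum(sps.binom.pmf(k, 100, 0.25) for k in range(25, 101))
        assert ed.chance_test(25, 100, 0.25) == pytest.approx(expected, rel=1e-10)
        assert ed.chance_test(25, 100, 0.25) == pytest.approx(0.5383, abs=5e-4)

    def test_perfect_score_closed_form(self):
        assert ed.chance_test(100, 100, 0.25) == pytest.approx(0.25 ** 100, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ed.chance_test(0, 0, 0.25)
        with pytest.raises(ValueError):
            ed.chance_test(5, 10, 1.5)

    def test_grouped_permutation_alternative(self):
        rng = np.random.default_rng(3)
        groups = np.repeat(np.arange(20), 5)
        y_true = np.array(["a", "b"])[rng.integers(0, 2, 100)]
        # perfect predictions -> tiny p; random predictions -> large p
        assert ed.grouped_permutation_test(y_true, y_true, groups,
                                           n_perm=200, seed=0) <= 1 / 100
        # random predictions: p-values are uniform-ish, so check the mean
        ps = []
        for k in range(10):
            y_rand = np.array(["a", "b"])[rng.integers(0, 2, 100)]
            ps.append(ed.grouped_permutation_test(y_true, y_rand, groups,
                                                  n_perm=200, seed=k))
        assert np.mean(ps) > 0.2
        with pytest.raises(ValueError, match="equal-sized"):
            ed.grouped_permutation_test(y_true[:99], y_true[:99], groups[:99])


class TestRunCv:
    def test_separable_data_high_accuracy(self):
        ft = synth_features(seed=3)
        rep = ed.run_cv(ft, FoldPlan(seed=0), FAST)
        assert rep.accuracy > 0.7
        assert rep.chance_p < 1e-6

    def test_confusion_rows_sum_to_one(self):
        ft = synth_features(seed=4)
        rep = ed.run_cv(ft, FoldPlan(seed=0), FAST)
        sums = rep.confusion.sum(axis=1)
        np.testing.assert_allclose(sums[np.isfinite(sums)], 1.0, atol=1e-12)
        for i, cls in enumerate(rep.classes):
            assert rep.confusion[i, i] == pytest.approx(rep.recall[cls], abs=1e-12)

    def test_label_permutation_at_chance(self):
        ft = synth_features(seed=5)
        rng = np.random.default_rng(0)
        ft_perm = ed.FeatureTable(features=ft.features,
                                  labels=rng.permutation(ft.labels),
                                  groups=ft.groups)
        rep = ed.run_cv(ft_perm, FoldPlan(seed=0), FAST)
        lo, hi = sps.binom.ppf([0.025, 0.975], rep.n_test, 0.25) / rep.n_test
        assert lo <= rep.accuracy <= hi

    def test_leakage_audit_recorded_and_clean(self):
        ft = synth_features(seed=6)
        plan = FoldPlan(purge_gap=2, seed=0)
        rep = ed.run_cv(ft, plan, FAST)
        assert len(rep.leakage_audit) > 0
        for audit in rep.leakage_audit:
            assert audit["disjoint_groups"]
            assert audit["scaler_train_only"]
            assert audit["min_temporal_gap"] > plan.purge_gap

    def test_deterministic_reports(self):
        ft = synth_features(seed=7)
        r1 = ed.run_cv(ft, FoldPlan(seed=1), FAST)
        r2 = ed.run_cv(ft, FoldPlan(seed=1), FAST)
        assert r1.accuracy == r2.accuracy
        assert r1.fold_accuracies == r2.fold_accuracies
        np.testing.assert_array_equal(r1.confusion, r2.confusion)

    def test_split_sample_scheme(self):
        ft = synth_features(seed=8)
        rep = ed.run_cv(ft, FoldPlan(scheme="split-sample", seed=0), FAST)
        assert rep.accuracy > 0.6


class TestTaskLabels:
    def test_mode_and_difficulty_mapping(self):
        labels = np.array(["MD-Easy", "AD-Hard", "MD-Hard"])
        _, mode = task_labels(labels, "mode")
        assert list(mode) == ["MD", "AD", "MD"]
        mask, diff = task_labels(labels, "difficulty-md")
        assert list(mask) == [True, False, True]
        with pytest.raises(ValueError):
            task_labels(labels, "nonsense")


class TestLoso:
    def test_homogeneous_effect_generalizes(self):
        ft = synth_features(n_subjects=4, seed=9)
        rep = ed.run_loso(ft, "mode", FAST)
        assert rep.mean_accuracy > 0.5
        assert rep.p < 0.05
        assert len(rep.subject_accuracies) == 4

    def test_null_features_near_chance(self):
        ft = synth_features(n_subjects=4, seed=10,
                            offsets=dict.fromkeys(ed.CONDITIONS, (0, 0)))
        rep = ed.run_loso(ft, "difficulty", FAST)
        assert abs(rep.mean_accuracy - 0.5) < 0.15

    def test_subject_heterogeneity_hurts_loso(self):
        """Large subject-specific feature shifts degrade cross-subject
        transfer relative to within-subject validation on the same task."""
        ft = synth_features(n_subjects=4, seed=11, subject_shift=4.0)
        loso = ed.run_loso(ft, "mode", FAST)
        cv = ed.run_cv(ft, FoldPlan(seed=0), FAST, task="mode")
        assert loso.mean_accuracy < cv.accuracy

    def test_needs_three_subjects(self):
        ft = synth_features(n_subjects=2, seed=12)
        with pytest.raises(ValueError):
            ed.run_loso(ft, "mode", FAST)


class TestCrossModeTransfer:
    def test_shared_difficulty_effect_transfers(self):
        offsets = {"MD-Easy": (0, 0), "MD-Hard": (0, 3),
                   "AD-Easy": (0, 0), "AD-Hard": (0, 3)}
        ft = synth_features(seed=13, offsets=offsets)
        out = ed.cross_mode_transfer(ft, FAST)
        assert out["accuracy"] > 0.5
        assert out["chance_p"] < 0.05

    def test_mode_specific_effect_does_not_transfer(self):
        offsets = {"MD-Easy": (0, 0), "MD-Hard": (0, 3),
                   "AD-Easy": (0, 0), "AD-Hard": (0, 0)}
        ft = synth_features(seed=14, offsets=offsets)
        out = ed.cross_mode_transfer(ft, FAST)
        lo, hi = sps.binom.ppf([0.025, 0.975], out["n_test"], 0.5) / out["n_test"]
        assert lo <= out["accuracy"] <= hi

    def test_missing_mode_rejected(self):
        ft = synth_features(seed=15)
        md_only = ft.subset(np.flatnonzero([l.startswith("MD") for l in ft.labels]))
        with pytest.raises(ValueError):
            ed.cross_mode_transfer(md_only, FAST)
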