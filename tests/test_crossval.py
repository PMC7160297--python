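import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectronet.crossval import (auc_wmw, compare_models, fit_propensity,
                                 lpocv_folds, run_lpocv, score_subject)
from spectronet.nets import TrainConfig
from spectronet.synth import ParameterError, SubjectRecord

from oracles import brute_force_auc, closed_form_ttest


def make_subjects(n_adhd, n_hc, ages_adhd=None, ages_hc=None):
    subjects = []
    for i in range(n_adhd):
        age = ages_adhd[i] if ages_adhd else 40.0 + i
        subjects.append(SubjectRecord(f"adhd{i:03d}", "ADHD", age, seed=i))
    for i in range(n_hc):
        age = ages_hc[i] if ages_hc else 30.0 + i
        subjects.append(SubjectRecord(f"hc{i:03d}", "HC", age, seed=100 + i))
    return subjects


class TestFoldEnumeration:
    def test_20v20_gives_400(self):
        assert len(lpocv_folds(make_subjects(20, 20))) == 400

    def test_1v1(self):
        assert len(lpocv_folds(make_subjects(1, 1))) == 1

    def test_2v3_exhaustive(self):
        plans = lpocv_folds(make_subjects(2, 3))
        assert len(plans) == 6
        pairs = {p.held_out for p in plans}
        assert len(pairs) == 6  # all distinct combinations

    def test_no_leakage(self):
        for plan in lpocv_folds(make_subjects(3, 4)):
            assert plan.held_out[0] not in plan.train_ids
            assert plan.held_out[1] not in plan.train_ids
            assert len(plan.train_ids) == 5

    def test_empty_class_rejected(self):
        with pytest.raises(ParameterError):
            lpocv_folds(make_subjects(3, 0))

    @given(st.integers(1, 8), st.integers(1, 8))
    @settings(max_examples=20, deadline=None)
    def test_fold_count_identity(self, na, nh):
        assert len(lpocv_folds(make_subjects(na, nh))) == na * nh


class TestScoreSubject:
    def test_mean_and_class(self):
        score, pred = score_subject([0.6, 0.7, 0.8])
        assert score == pytest.approx(0.7)
        assert pred == "ADHD"

    def test_tie_goes_to_hc(self):
        score, pred = score_subject([0.5, 0.5])
        assert score == 0.5
        assert pred == "HC"

    def test_marginal_majority(self):
        score, pred = score_subject([0.51] * 140)
        assert pred == "ADHD"

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            score_subject([])


class TestAucWmw:
    def test_perfect_separation(self):
        assert auc_wmw([0.9, 0.8, 0.2, 0.1],
                       ["ADHD", "ADHD", "HC", "HC"]) == 1.0

    def test_three_of_four_pairs(self):
        # pos=[0.9, 0.4], neg=[0.6, 0.1]: 3 concordant of 4
        assert auc_wmw([0.9, 0.4, 0.6, 0.1],
                       ["ADHD", "ADHD", "HC", "HC"]) == 0.75

    def test_all_ties(self):
        assert auc_wmw([0.5] * 6, ["ADHD"] * 3 + ["HC"] * 3) == 0.5

    def test_empty_class_rejected(self):
        with pytest.raises(ParameterError):
            auc_wmw([0.1, 0.2], ["ADHD", "ADHD"])

    @given(st.lists(st.tuples(
        st.floats(0, 1, allow_nan=False),
        st.sampled_from(["ADHD", "HC"])), min_size=2, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, pairs):
        scores = [p[0] for p in pairs]
        labels = [p[1] for p in pairs]
        if "ADHD" not in labels or "HC" not in labels:
            return
        assert auc_wmw(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)


class TestPropensity:
    def test_uninformative_covariate(self):
        ages = [30.0, 31.0, 32.0, 30.0, 31.0, 32.0]
        labels = ["ADHD"] * 3 + ["HC"] * 3
        ipw = fit_propensity(ages, labels)
        np.testing.assert_allclose(ipw.propensity, 0.5, atol=0.02)
        np.testing.assert_allclose(ipw.weights, 2.0, atol=0.1)

    def test_younger_adhd_upweighted(self):
        rng = np.random.default_rng(0)
        ages = np.concatenate([rng.normal(45, 10, 50), rng.normal(30, 10, 50)])
        labels = ["ADHD"] * 50 + ["HC"] * 50
        ipw = fit_propensity(ages, labels)
        adhd_ages = ages[:50]
        adhd_w = ipw.weights[:50]
        youngest = adhd_w[np.argsort(adhd_ages)[:10]].mean()
        oldest = adhd_w[np.argsort(adhd_ages)[-10:]].mean()
        assert youngest > oldest

    def test_parameter_recovery(self):
        # labels generated from a known logit; recovered propensities close
        rng = np.random.default_rng(1)
        ages = rng.uniform(20, 60, size=2000)
        beta0, beta1 = -3.0, 0.08
        p_true = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * ages)))
        labels = np.where(rng.random(2000) < p_true, "ADHD", "HC")
        ipw = fit_propensity(ages, labels)
        rmse = np.sqrt(np.mean((ipw.propensity - np.clip(p_true, 0.05, 0.95)) ** 2))
        assert rmse < 0.05

    def test_weights_positive_finite(self):
        # near-separation: clipping keeps weights bounded
        ages = [20.0, 21.0, 22.0, 50.0, 51.0, 52.0]
        labels = ["HC"] * 3 + ["ADHD"] * 3
        with pytest.warns(UserWarning):
            ipw = fit_propensity(ages, labels)
        assert np.all(np.isfinite(ipw.weights))
        assert np.all(ipw.weights > 0)
        assert ipw.weights.max() <= 1.0 / 0.05 + 1e-9

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            fit_propensity([30.0, 40.0], ["ADHD", "ADHD"])


class TestCompareModels:
    def test_identical_vectors(self):
        t, p = compare_models([0.8] * 10, [0.8] * 10)
        assert t == 0.0
        assert p == 1.0

    def test_constant_shift_significant(self):
        rng = np.random.default_rng(2)
        b = rng.normal(70, 3, size=8)
        t, p = compare_models(b + 10, b)
        assert p < 0.05

    def test_matches_closed_form(self):
        rng = np.random.default_rng(3)
        a = rng.normal(85, 5, size=20)
        b = rng.normal(80, 7, size=25)
        t, p = compare_models(a, b)
        t_ref, p_ref = closed_form_ttest(a, b)
        assert t == pytest.approx(t_ref, abs=1e-9)
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_too_few_folds(self):
        with pytest.raises(ParameterError):
            compare_models([1.0], [0.5, 0.6])


@pytest.fixture(scope="module")
def mini_run(tiny_frames):
    subjects, frames = tiny_frames
    cfg = TrainConfig(max_epochs=2, patience=10, seed=0)
    summary, folds = run_lpocv(frames, subjects, "cnn", cfg)
    return subjects, frames, summary, folds


class TestRunLpocv:
    """Structural checks with a 3v3 cohort and a 2-epoch budget."""

    def test_fold_count(self, mini_run):
        _, _, summary, folds = mini_run
        assert summary.n_folds == len(folds) == 9  # 3v3

    def test_subject_scores_in_unit_interval(self, mini_run):
        _, _, _, folds = mini_run
        for r in folds:
            for score in r.subject_scores.values():
                assert 0.0 <= score <= 1.0

    def test_summary_bounds(self, mini_run):
        _, _, summary, _ = mini_run
        assert 0.0 <= summary.accuracy_pct <= 100.0
        assert 0.0 <= summary.pooled_auc_pct <= 100.0

    def test_pair_auc_values(self, mini_run):
        _, _, _, folds = mini_run
        assert all(r.pair_auc in (0.0, 0.5, 1.0) for r in folds)

    def test_missing_frames_rejected(self, mini_run):
        subjects, frames, _, _ = mini_run
        extra = subjects + [SubjectRecord("ghost", "HC", 33.0)]
        with pytest.raises(ParameterError):
            run_lpocv(frames, extra, "cnn", TrainConfig(max_epochs=1, seed=0))

    def test_unknown_channel_rejected(self, mini_run):
        subjects, frames, _, _ = mini_run
        with pytest.raises(ParameterError):
            run_lpocv(frames, subjects, "cnn",
                      TrainConfig(max_epochs=1, seed=0),
                      channel_subset=["Oz"])

    def test_channel_subset_runs(self, mini_run):
        subjects, frames, _, _ = mini_run
        summary, folds = run_lpocv(
            frames, subjects, "cnn", TrainConfig(max_epochs=1, seed=0),
            channel_subset=["F3", "Fz", "F4"])
        assert summary.channels == ("F3", "Fz", "F4")
        assert summary.n_folds == 9


class TestChannelAblationOrdering:
    def test_frontopolar_below_frontal(self):
        # channel gains scale frontopolar effects to ~0; single-channel ACC
        # for Fp1 should fall below Fz (scaled-down mirror, majority of 3
        # seeds)
        from spectronet.ersp import dataset_ersp
        from spectronet.preprocess import bandpass, baseline_correct
        from spectronet.synth import CohortSpec, EffectSpec, simulate_cohort
        from dataclasses import replace

        wins = 0
        for seed in (41, 42, 43):
            effects = replace(
                EffectSpec(seed=7),
                channel_gains=(0.0, 0.0, 1.0, 1.0, 1.0, 1.0, 1.0))
            spec = CohortSpec(n_per_group=3, frames_per_subject=10, seed=seed)
            subjects, epochs = simulate_cohort(spec, effects)
            clean = {sid: baseline_correct(bandpass(es))
                     for sid, es in epochs.items()}
            frames = dataset_ersp(clean, subjects)
            cfg = TrainConfig(max_epochs=60, patience=5, min_delta=5e-3,
                              seed=seed)
            acc = {}
            for ch in ("Fp1", "Fz"):
                summary, _ = run_lpocv(frames, subjects, "cnn", cfg,
                                       channel_subset=[ch])
                acc[ch] = summary.accuracy_pct
            wins += acc["Fp1"] < acc["Fz"]
        assert wins >= 2
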