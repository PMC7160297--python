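import numpy as np
import pytest
from scipy import signal as sg
from scipy import stats

from spectronet.synth import (CHANNELS, CohortSpec, EffectSpec, ParameterError,
                              SubjectRecord, generate_cohort,
                              generate_reaction_times, generate_trial_sequence,
                              simulate_cohort, synthesize_epochs,
                              synthesize_resting)

from oracles import gamma_moments


class TestGenerateCohort:
    def test_default_counts(self):
        subjects = generate_cohort(CohortSpec(seed=0))
        assert sum(s.group == "ADHD" for s in subjects) == 20
        assert sum(s.group == "HC" for s in subjects) == 20

    def test_minimal_cohort(self):
        subjects = generate_cohort(CohortSpec(n_per_group=1, seed=0))
        assert len(subjects) == 2
        assert {s.group for s in subjects} == {"ADHD", "HC"}

    def test_age_sampler_matches_truncated_normal(self):
        # oracle: closed-form truncated-normal mean (truncation at 18)
        spec = CohortSpec(n_per_group=10_000, seed=7)
        ages = np.array([s.age for s in generate_cohort(spec)
                         if s.group == "ADHD"])
        a = (18.0 - spec.age_mean_adhd) / spec.age_sd_adhd
        expected = stats.truncnorm.mean(a, np.inf, loc=spec.age_mean_adhd,
                                        scale=spec.age_sd_adhd)
        se = ages.std(ddof=1) / np.sqrt(ages.size)
        assert abs(ages.mean() - expected) < 3 * se

    def test_ages_truncated_at_adult_floor(self):
        ages = [s.age for s in generate_cohort(CohortSpec(n_per_group=2000, seed=3))]
        assert min(ages) >= 18.0

    def test_deterministic(self):
        a = generate_cohort(CohortSpec(seed=11))
        b = generate_cohort(CohortSpec(seed=11))
        assert a == b

    @pytest.mark.parametrize("kwargs", [
        dict(n_per_group=0), dict(frames_per_subject=0),
        dict(age_sd_adhd=0.0), dict(age_sd_hc=-1.0),
    ])
    def test_invalid_spec(self, kwargs):
        with pytest.raises(ParameterError):
            generate_cohort(CohortSpec(seed=0, **kwargs))


class TestTrialSequence:
    def test_140_trials_ratio_2(self):
        events = generate_trial_sequence(140, 2, seed=0)
        n_inc = sum(e.congruency == "incongruent" for e in events)
        assert n_inc == 47  # round(140/3)
        assert len(events) - n_inc == 93

    def test_exact_ratio(self):
        events = generate_trial_sequence(3, 2, seed=0)
        assert sum(e.congruency == "incongruent" for e in events) == 1

    def test_fixation_grid(self):
        events = generate_trial_sequence(300, 2, seed=5)
        assert set(e.fixation_ms for e in events) <= {200.0, 300.0, 400.0}

    def test_onsets_strictly_increasing(self):
        events = generate_trial_sequence(100, 2, seed=1)
        onsets = [e.onset for e in events]
        assert all(b > a for a, b in zip(onsets, onsets[1:]))

    def test_trial_component_durations_span(self):
        # closest reconstruction from the component grid: 1070..1398 ms
        durations = set()
        for level in range(5):
            events = generate_trial_sequence(60, 2, seed=level, level=level)
            for e in events:
                durations.add(e.flanker_ms + e.target_ms + 500 + 300 + e.fixation_ms)
        assert min(durations) == 1070
        assert max(durations) == 1398

    def test_deterministic(self):
        assert generate_trial_sequence(50, 2, seed=9) == \
            generate_trial_sequence(50, 2, seed=9)

    def test_invalid(self):
        with pytest.raises(ParameterError):
            generate_trial_sequence(0, 2, seed=0)


def _subject(group="ADHD", **kw):
    defaults = dict(subject_id="x1", group=group, age=30.0, seed=5)
    defaults.update(kw)
    return SubjectRecord(**defaults)


class TestSynthesizeEpochs:
    def test_epoch_geometry(self):
        events = generate_trial_sequence(30, 2, seed=0)
        es = synthesize_epochs(_subject(), events, EffectSpec(seed=1))
        n_inc = sum(e.congruency == "incongruent" for e in events)
        assert es.data.shape == (n_inc, 7, 500)
        assert es.time_ms[0] == -200.0
        assert es.time_ms[-1] == 798.0
        assert es.channel_names == CHANNELS

    def test_deterministic(self):
        events = generate_trial_sequence(12, 2, seed=0)
        a = synthesize_epochs(_subject(), events, EffectSpec(seed=1))
        b = synthesize_epochs(_subject(), events, EffectSpec(seed=1))
        np.testing.assert_array_equal(a.data, b.data)

    def test_alpha_attenuation_halves_band_power(self):
        # oracle: direct Welch spectral estimate on the generated signals.
        # High alpha SNR so the band power is dominated by the oscillation.
        # isolate the alpha mechanism: no theta burst or N100 (their spectra
        # leak into the 8-12 Hz band), no between-subject offsets
        effects = EffectSpec(alpha_attenuation=-3.0, alpha_amp=2.5,
                             noise_scale=0.2, subject_sd=0.0,
                             theta_amp=0.0, theta_subject_sd=0.0,
                             n100_amp=0.0, seed=2)
        events = generate_trial_sequence(600, 2, seed=3)
        adhd = synthesize_epochs(_subject("ADHD"), events, effects)
        hc = synthesize_epochs(_subject("HC", subject_id="x2", seed=6),
                               events, effects)

        def band_power(es):
            f, p = sg.welch(es.data[:, 2:, :], fs=500, nperseg=500, axis=-1)
            m = (f >= 8) & (f <= 12)
            return p[..., m].sum(axis=-1).mean()

        ratio = band_power(adhd) / band_power(hc)
        assert abs(ratio - 10 ** (-0.3)) < 0.1 * 10 ** (-0.3)

    def test_resting_has_no_event_locked_structure(self):
        effects = EffectSpec(seed=4)
        subj = _subject()
        rest = synthesize_resting(subj, 300, effects)
        events = generate_trial_sequence(900, 2, seed=8)
        task = synthesize_epochs(subj, events, effects)
        # trial-averaged ERP at ~100 ms: strong negative deflection in task,
        # none at rest (noise and random-phase alpha average out)
        idx = np.argmin(np.abs(rest.time_ms - 100.0))
        erp_rest = rest.data[:, 3, idx].mean()
        erp_task = task.data[:, 3, idx].mean()
        assert erp_task < -2.0
        assert abs(erp_rest) < 1.0

    def test_bad_band_rejected(self):
        with pytest.raises(ParameterError):
            EffectSpec(alpha_band=(8.0, 30.0)).validate()

    def test_null_effects_groups_exchangeable(self):
        # with zero effects a two-sample test on per-subject alpha power
        # should reject at roughly the nominal 5% rate
        rejections = 0
        n_sets = 200
        for k in range(n_sets):
            spec = CohortSpec(n_per_group=3, frames_per_subject=6,
                              age_mean_hc=43.85, age_sd_hc=14.78, seed=k)
            effects = EffectSpec(seed=k + 1).null()
            subjects, epochs = simulate_cohort(spec, effects)
            power = {}
            for s in subjects:
                d = epochs[s.subject_id].data
                f, p = sg.welch(d[:, 2:, :], fs=500, nperseg=250, axis=-1)
                m = (f >= 8) & (f <= 12)
                power.setdefault(s.group, []).append(p[..., m].mean())
            _, pval = stats.ttest_ind(power["ADHD"], power["HC"])
            rejections += pval < 0.05
        # 95% acceptance region for Binomial(200, 0.05): [3, 17]
        assert 3 <= rejections <= 17


class TestFrameCounts:
    @pytest.mark.parametrize("n,frames", [(2, 12), (3, 7)])
    def test_frame_count_conservation(self, n, frames):
        spec = CohortSpec(n_per_group=n, frames_per_subject=frames, seed=0)
        subjects, epochs = simulate_cohort(spec, EffectSpec(seed=1))
        for group in ("ADHD", "HC"):
            total = sum(epochs[s.subject_id].n_trials for s in subjects
                        if s.group == group)
            assert total == n * frames

    def test_resting_frame_count_matches_task(self):
        spec = CohortSpec(n_per_group=2, frames_per_subject=9, seed=0)
        _, task = simulate_cohort(spec, EffectSpec(seed=1))
        _, rest = simulate_cohort(spec, EffectSpec(seed=1), resting=True)
        for sid in task:
            assert rest[sid].n_trials == task[sid].n_trials

    def test_simulation_deterministic(self):
        spec = CohortSpec(n_per_group=2, frames_per_subject=5, seed=3)
        _, a = simulate_cohort(spec, EffectSpec(seed=4))
        _, b = simulate_cohort(spec, EffectSpec(seed=4))
        for sid in a:
            np.testing.assert_array_equal(a[sid].data, b[sid].data)


class TestEffectMonotonicity:
    def test_cnn_accuracy_nondecreasing_in_effect_size(self):
        # scaled-down 3-point grid (3v3, 10 frames, 9 folds), majority of
        # 3 seeds; slack tolerates fold-level granularity
        from spectronet.crossval import run_lpocv
        from spectronet.nets import TrainConfig
        from spectronet.preprocess import bandpass, baseline_correct
        from spectronet.ersp import dataset_ersp
        from dataclasses import replace

        def acc(seed, scale):
            eff = EffectSpec(seed=11)
            eff = replace(eff, alpha_attenuation=-3.0 * scale,
                          theta_boost=3.0 * scale,
                          n100_gain=1.0 + (eff.n100_gain - 1.0) * scale)
            spec = CohortSpec(n_per_group=3, frames_per_subject=10, seed=seed)
            subjects, epochs = simulate_cohort(spec, eff)
            clean = {sid: baseline_correct(bandpass(es))
                     for sid, es in epochs.items()}
            frames = dataset_ersp(clean, subjects)
            summary, _ = run_lpocv(
                frames, subjects, "cnn",
                TrainConfig(max_epochs=60, patience=5, min_delta=5e-3,
                            seed=seed))
            return summary.accuracy_pct

        slack = 12.0  # ~2 fold-decisions at 9 folds
        wins = 0
        for seed in (31, 32, 33):
            a0, a1, a2 = (acc(seed, s) for s in (0.0, 0.5, 1.0))
            wins += (a1 >= a0 - slack) and (a2 >= a1 - slack) and (a2 > a0)
        assert wins >= 2


class TestReactionTimes:
    def test_mean_converges(self):
        spec = CohortSpec(seed=0)
        rts = generate_reaction_times("ADHD", 200_000, spec, seed=1)
        assert abs(rts.mean() - 368.0) < 2.0

    def test_empty(self):
        assert len(generate_reaction_times("HC", 0, CohortSpec(seed=0))) == 0

    def test_gamma_moment_identity(self):
        # var = mean^2 / shape, by simulation against the closed form
        spec = CohortSpec(rt_shape=16.0, seed=0)
        rts = generate_reaction_times("HC", 200_000, spec, seed=2)
        mean, var = gamma_moments(16.0, 321.0)
        assert abs(rts.mean() - mean) < 2.0
        assert abs(rts.var() - var) / var < 0.05

    def test_invalid(self):
        with pytest.raises(ParameterError):
            generate_reaction_times("ADHD", -1, CohortSpec(seed=0))
        with pytest.raises(ParameterError):
            generate_reaction_times("bogus", 1, CohortSpec(seed=0))
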