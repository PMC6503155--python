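"""Trial time-course extraction, rating-template removal and AUC statistics."""

import numpy as np
import pytest

import isobold as ib
from isobold.cohort import rating_scan_signal, region_scan_signal
from isobold.timecourse import (TimecourseWindow, compute_auc,
                                condition_average, extract_trial_courses,
                                rating_template, rating_template_removal)


def _single_session_subject(**overrides):
    kw = dict(n_subjects=1, grid_shape=(4, 4, 4), n_regions=1,
              region_effects=[ib.RegionEffect(1, amp_pain=1.0, amp_tactile=0.6,
                                              intensity_slope=0.0)],
              noise=ib.NoiseModel.silent(), sessions=2, seed=13)
    kw.update(overrides)
    cfg = ib.CohortConfig(**kw)
    parc = ib.simulate_parcellation(cfg)
    subj = ib.simulate_subject(cfg, parc, 0)
    return cfg, parc, subj


class TestExtraction:
    def test_constant_signal_gives_zero_courses(self):
        vol = ib.Volume4D(data=np.full((3, 3, 3, 100), 7.0), tr=0.8)
        ev = ib.EventTable([ib.TrialEvent("t0", 1, "pain", "low", 10.0, 5.0, 25.0)])
        courses = extract_trial_courses({1: vol}, np.ones((3, 3, 3), bool), ev)
        assert len(courses) == 1
        np.testing.assert_allclose(courses[0].samples, 0.0, atol=1e-12)

    def test_noiseless_course_matches_forward_model(self):
        """Extracted single-trial course equals the generator's HRF response
        sampled on the volume grid (baseline window precedes the response)."""
        cfg, parc, subj = _single_session_subject(rating_amp=0.0)
        window = TimecourseWindow()
        ev_all = subj.events
        first = ev_all.session_events(1)[0]
        courses = extract_trial_courses(subj.bold, parc.region_mask(1),
                                        ib.EventTable([first]), window, region_id=1)
        assert len(courses) == 1
        sig = region_scan_signal(cfg, ev_all, cfg.effect(1), 1)
        c = int(round(first.stim_onset_s / cfg.tr_s))
        n_pre, n_post = window.n_pre(cfg.tr_s), window.n_post(cfg.tr_s)
        want = sig[c - n_pre: c + n_post + 1] - sig[c - n_pre: c].mean()
        np.testing.assert_allclose(courses[0].samples, want, atol=1e-9)

    def test_trial_near_session_end_dropped(self):
        vol = ib.Volume4D(data=np.zeros((2, 2, 2, 50)), tr=0.8)  # 40 s session
        ev = ib.EventTable([
            ib.TrialEvent("ok", 1, "pain", "low", 5.0, 5.0, 18.0),
            ib.TrialEvent("late", 1, "pain", "low", 35.0, 5.0, 39.0),
        ])
        courses = extract_trial_courses({1: vol}, np.ones((2, 2, 2), bool), ev)
        assert [c.trial_id for c in courses] == ["ok"]

    def test_empty_region_rejected(self):
        vol = ib.Volume4D(data=np.zeros((2, 2, 2, 10)), tr=0.8)
        with pytest.raises(ValueError, match="region"):
            extract_trial_courses({1: vol}, np.zeros((2, 2, 2), bool),
                                  ib.EventTable([]), region_id=3)


class TestTemplateRemoval:
    def test_rating_only_signal_removed(self):
        """When the generator emits only rating-locked responses, template
        removal reduces the stimulus-locked trial-mean course to a small
        residual relative to the template peak. Trials are spaced (long
        lead-in) so consecutive rating responses do not overlap; the
        stimulus-to-rating lag keeps its 3-13 s range."""
        cfg, parc, subj = _single_session_subject(
            region_effects=[ib.RegionEffect(1, amp_pain=0.0, amp_tactile=0.0,
                                            intensity_slope=0.0)],
            rating_amp=0.5, lead_in_s=32.0, trials_per_session=8)
        window = TimecourseWindow()
        tr = cfg.tr_s
        rmask = parc.region_mask(1)
        courses = extract_trial_courses(subj.bold, rmask, subj.events, window,
                                        region_id=1)
        template = rating_template(subj.bold, rmask, subj.events, window)
        corrected = rating_template_removal(courses, template, window, tr)
        mean_course = np.mean([c.samples for c in corrected], axis=0)
        assert np.max(np.abs(mean_course)) < 0.05 * np.max(np.abs(template))

    def test_zero_template_is_identity(self):
        cfg, parc, subj = _single_session_subject(rating_amp=0.0)
        window = TimecourseWindow()
        courses = extract_trial_courses(subj.bold, parc.region_mask(1),
                                        subj.events, window, region_id=1)
        out = rating_template_removal(courses, np.zeros(window.length(cfg.tr_s)),
                                      window, cfg.tr_s)
        for before, after in zip(courses, out):
            np.testing.assert_array_equal(before.samples, after.samples)

    def test_pre_stimulus_samples_untouched(self):
        cfg, parc, subj = _single_session_subject(rating_amp=0.5)
        window = TimecourseWindow()
        tr = cfg.tr_s
        rmask = parc.region_mask(1)
        courses = extract_trial_courses(subj.bold, rmask, subj.events, window,
                                        region_id=1)
        template = rating_template(subj.bold, rmask, subj.events, window)
        corrected = rating_template_removal(courses, template, window, tr)
        n_pre = window.n_pre(tr)
        for before, after in zip(courses, corrected):
            np.testing.assert_array_equal(before.samples[:n_pre],
                                          after.samples[:n_pre])


class TestAUC:
    def test_zero_course(self):
        w = TimecourseWindow()
        assert compute_auc(np.zeros(w.length(0.8)), w, 0.8) == 0.0

    def test_triangle_closed_form(self):
        """Trapezoid AUC of a triangular course equals the polyline area
        computed segment by segment."""
        w = TimecourseWindow(pre_s=0.0, post_s=10.0)
        tr = 0.8
        t = np.arange(w.length(tr)) * tr
        course = np.where(t <= 5, t / 5, np.clip(2 - t / 5, 0, None))
        got = compute_auc(course, w, tr)
        want = sum((course[i] + course[i + 1]) / 2 * tr
                   for i in range(len(course) - 1))
        assert got == pytest.approx(want, abs=1e-12)

    def test_linearity_and_scaling(self, rng):
        w = TimecourseWindow()
        tr = 0.8
        a = rng.normal(size=w.length(tr))
        b = rng.normal(size=w.length(tr))
        assert compute_auc(a + b, w, tr) == pytest.approx(
            compute_auc(a, w, tr) + compute_auc(b, w, tr), abs=1e-10)
        assert compute_auc(3 * a, w, tr) == pytest.approx(
            3 * compute_auc(a, w, tr), abs=1e-10)

    def test_trial_mean_commutes_with_auc(self, rng):
        """Mean of per-trial AUCs equals AUC of the trial-mean course."""
        w = TimecourseWindow()
        tr = 0.8
        trials = rng.normal(size=(12, w.length(tr)))
        per_trial = [compute_auc(t, w, tr) for t in trials]
        assert np.mean(per_trial) == pytest.approx(
            compute_auc(trials.mean(axis=0), w, tr), abs=1e-10)

    def test_non_finite_rejected(self):
        w = TimecourseWindow()
        bad = np.zeros(w.length(0.8))
        bad[5] = np.nan
        with pytest.raises(ValueError):
            compute_auc(bad, w, 0.8)


class TestConditionAverage:
    def test_identical_conditions_zero_t(self, rng):
        course = rng.normal(size=10)
        subs = [{"pain": course, "tactile": course.copy()} for _ in range(5)]
        res = condition_average(subs, ("pain", "tactile"), np.arange(10) * 0.8)
        np.testing.assert_array_equal(res.t, 0.0)

    def test_constant_offset_gives_inf_t(self, rng):
        base = rng.normal(size=8)
        subs = [{"pain": base + 1.0, "tactile": base} for _ in range(6)]
        res = condition_average(subs, ("pain", "tactile"), np.arange(8) * 0.8)
        assert np.all(np.isinf(res.t))
        np.testing.assert_array_equal(res.p, 0.0)

    def test_missing_condition_excluded_pairwise(self, rng):
        subs = [{"pain": rng.normal(size=5), "tactile": rng.normal(size=5)}
                for _ in range(4)]
        subs.append({"pain": rng.normal(size=5)})
        res = condition_average(subs, ("pain", "tactile"), np.arange(5) * 0.8)
        assert res.n_subjects == 4


class TestRegionAnalyses:
    def test_analysis3_recovers_preferential_sign(self):
        """Injected pain/tactile-preferential regions show the matching AUC
        difference sign; relabelling regions permutes results equivariantly."""
        cfg = ib.CohortConfig(n_subjects=8, grid_shape=(8, 8, 8), n_regions=8,
                              noise=ib.NoiseModel(sigma_white=0.3, ar1_rho=0.2,
                                                  drift_amplitudes=()),
                              seed=31)
        parc, subjects = ib.simulate_cohort(cfg)
        res = ib.analysis3(subjects, parc, ib.PermConfig(n_perm=200, seed=1))
        diff = res.results["pain_gt_tactile"].mean_diff
        for eff in cfg.region_effects:
            idx = res.region_ids.index(eff.region_id)
            if eff.preference == "pain":
                assert diff[idx] > 0
            elif eff.preference == "tactile":
                assert diff[idx] < 0

    def test_analysis4_directions(self):
        """Slope 0: the preferred modality keeps a larger response in the
        mismatch comparison; both comparison directions are produced."""
        effects = ib.default_region_effects(8, intensity_slope=0.0)
        cfg = ib.CohortConfig(n_subjects=6, grid_shape=(8, 8, 8), n_regions=8,
                              region_effects=effects,
                              noise=ib.NoiseModel(sigma_white=0.2, ar1_rho=0.0,
                                                  drift_amplitudes=()),
                              seed=17)
        parc, subjects = ib.simulate_cohort(cfg)
        res = ib.analysis4(subjects, parc, [1, 2, 3], [4, 5, 6],
                           ib.PermConfig(n_perm=100, seed=2))
        assert set(res.results) == {"pain_preferential", "tactile_preferential"}
        # pain-preferential: pain_low minus tactile_high stays positive at slope 0
        assert np.all(res.results["pain_preferential"].mean_diff > 0)
        assert np.all(res.results["tactile_preferential"].mean_diff > 0)
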