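"""HRF kernel, design matrices and per-voxel OLS fitting."""

import numpy as np
import pytest
from scipy import stats

import isobold as ib
from isobold.glm import (HRFSpec, build_design_5cond, build_design_parametric,
                         canonical_hrf, contrast_map, dct_drift_basis, fit_glm,
                         sample_regressor)
from isobold.matching import match_trials


class TestCanonicalHRF:
    def test_zero_at_origin_and_peak_location(self):
        """Gamma shapes > 1 vanish at t=0; the kernel mode sits at
        peak_delay - peak_dispersion (gamma mode), checked on a fine grid."""
        h = canonical_hrf(HRFSpec(), dt=0.001)
        assert h[0] == 0.0
        t_peak = np.argmax(h) * 0.001
        assert t_peak == pytest.approx(6.0 - 1.0, abs=0.01)
        assert np.max(h) == pytest.approx(1.0)

    def test_sample_count_scales_with_dt(self):
        n1 = len(canonical_hrf(HRFSpec(), dt=0.05))
        n2 = len(canonical_hrf(HRFSpec(), dt=0.1))
        assert abs(n1 - 2 * n2) <= 1

    def test_bad_dt_rejected(self):
        with pytest.raises(ValueError):
            canonical_hrf(HRFSpec(), dt=0.0)


class TestSampleRegressor:
    def test_impulse_matches_direct_convolution(self):
        """A single impulse regressor equals the HRF evaluated at the scan
        times minus the onset (brute-force oracle)."""
        tr, n_scans, onset = 0.8, 100, 7.3
        spec = HRFSpec()
        x = sample_regressor([onset], [0.0], [2.0], n_scans, tr, spec)
        dt = tr / spec.microtime_bins_per_tr
        h = canonical_hrf(spec, dt)
        t_scan = np.arange(n_scans) * tr + spec.microtime_onset_bin * dt
        want = np.zeros(n_scans)
        i0 = int(round(onset / dt))
        for i, ts in enumerate(t_scan):
            k = int(round(ts / dt)) - i0
            if 0 <= k < len(h):
                want[i] = 2.0 * h[k]
        np.testing.assert_allclose(x, want, atol=1e-9)

    def test_boxcar_is_sum_of_impulse_responses(self):
        """Discretised boxcar = dt-weighted sum of shifted impulse kernels."""
        tr, n_scans = 0.8, 120
        spec = HRFSpec()
        dt = tr / spec.microtime_bins_per_tr
        x_box = sample_regressor([10.0], [4.0], [1.5], n_scans, tr, spec)
        n_bins = int(round(4.0 / dt))
        parts = [sample_regressor([10.0 + j * dt], [0.0], [1.5 * dt], n_scans, tr, spec)
                 for j in range(n_bins)]
        np.testing.assert_allclose(x_box, np.sum(parts, axis=0), atol=1e-8)


class TestDesigns:
    def test_five_condition_column_counts(self, small_cohort):
        """Per session: 5 conditions + 5 derivatives + 6 motion + 9 drift
        (floor(2*600/128)) + 1 mean, provided no condition is empty."""
        _, _, subjects = small_cohort
        subj = subjects[0]
        mres = match_trials(subj.events)
        n_scans = {s: subj.bold[s].n_scans for s in subj.bold}
        d = build_design_5cond(subj.events, mres, n_scans, subj.tr, subj.motion)
        for ses in (1, 2):
            kinds = [k for k, s in zip(d.column_kind, d.session_of_column) if s == ses]
            n_cond = kinds.count("condition")
            assert n_cond + len([nm for s2, nm in d.omitted_conditions if s2 == ses]) == 5
            assert kinds.count("derivative") == n_cond
            assert kinds.count("nuisance") == 6
            assert kinds.count("drift") == 9
            assert kinds.count("session_mean") == 1

    def test_drift_count_formula_against_basis_oracle(self):
        """K = floor(2 T / cutoff) and the columns are orthonormal,
        matching an independently constructed cosine basis."""
        n, tr, cutoff = 750, 0.8, 128.0
        drift = dct_drift_basis(n, tr, cutoff)
        assert drift.shape[1] == int(np.floor(2 * n * tr / cutoff)) == 9
        gram = drift.T @ drift
        np.testing.assert_allclose(gram, np.eye(9), atol=1e-10)
        i = np.arange(n)
        oracle = np.sqrt(2 / n) * np.cos(np.pi * 3 * (2 * i + 1) / (2 * n))
        np.testing.assert_allclose(drift[:, 2], oracle, atol=1e-12)

    def test_zero_events_leaves_nuisance_only(self):
        d = build_design_5cond(
            ib.EventTable([]), ib.MatchResult([], [], []),
            {1: 100}, 0.8, {1: np.zeros((100, 6))})
        assert set(d.column_kind) == {"nuisance", "drift", "session_mean"}
        assert len(d.omitted_conditions) == 5

    def test_constant_ratings_omit_modulator(self, small_cohort):
        _, _, subjects = small_cohort
        subj = subjects[0]
        from dataclasses import replace
        events = ib.EventTable([replace(e, rating=5.0) for e in subj.events])
        n_scans = {s: subj.bold[s].n_scans for s in subj.bold}
        d = build_design_parametric(events, n_scans, subj.tr, subj.motion)
        assert "modulator" not in d.column_kind
        assert all(nm == "intensity_modulator" for _, nm in d.omitted_conditions)

    def test_modulator_linearity(self, small_cohort):
        """Scaling the centered ratings scales the modulator column by the
        same factor (halving keeps every rating on the 0-10 scale)."""
        _, _, subjects = small_cohort
        subj = subjects[0]
        from dataclasses import replace
        n_scans = {s: subj.bold[s].n_scans for s in subj.bold}
        d1 = build_design_parametric(subj.events, n_scans, subj.tr, subj.motion)
        mean_r = {s: np.mean([e.rating for e in subj.events.session_events(s)])
                  for s in (1, 2)}
        halved = ib.EventTable([
            replace(e, rating=mean_r[e.session] + 0.5 * (e.rating - mean_r[e.session]))
            for e in subj.events])
        d2 = build_design_parametric(halved, n_scans, subj.tr, subj.motion)
        for j1 in d1.columns_named("intensity_modulator"):
            np.testing.assert_allclose(d2.matrix[:, j1], 0.5 * d1.matrix[:, j1],
                                       atol=1e-8)


class TestFitGLM:
    def test_exact_linear_recovery(self, rng):
        """bold = X @ beta0 is recovered to 1e-10 with zero residual."""
        n, k, v = 120, 7, 50
        x = rng.normal(size=(n, k))
        design = ib.DesignMatrix(x, [f"c{i}" for i in range(k)], [1] * k,
                                 ["condition"] * k, {1: (0, n)}, 0.8)
        beta0 = rng.normal(size=(k, v))
        data = (x @ beta0).T.reshape(5, 10, 1, n)
        vol = ib.Volume4D(data=data, tr=0.8)
        fit = fit_glm(vol, design)
        np.testing.assert_allclose(fit.beta, beta0, atol=1e-10)
        np.testing.assert_allclose(fit.sigma2, 0.0, atol=1e-18)
        assert fit.dof == n - k

    def test_duplicated_column_uses_pseudoinverse(self, rng):
        n = 60
        base = rng.normal(size=(n, 3))
        x = np.column_stack([base, base[:, 0]])
        design = ib.DesignMatrix(x, ["a", "b", "c", "a2"], [1] * 4,
                                 ["condition"] * 4, {1: (0, n)}, 0.8)
        vol = ib.Volume4D(data=rng.normal(size=(2, 2, 2, n)), tr=0.8)
        fit = fit_glm(vol, design)
        assert fit.rank == 3 and fit.dof == n - 3
        assert np.all(np.isfinite(fit.beta))

    def test_t_null_distribution(self, rng):
        """Per-voxel t statistics on white noise follow Student-t(dof):
        Kolmogorov-Smirnov check on 1e4 voxels."""
        n, v = 60, 10000
        x = np.column_stack([rng.normal(size=(n, 3)), np.ones(n)])
        design = ib.DesignMatrix(x, ["a", "b", "c", "mean"], [1] * 4,
                                 ["condition"] * 3 + ["session_mean"],
                                 {1: (0, n)}, 0.8)
        vol = ib.Volume4D(data=rng.normal(size=(25, 20, 20, n)), tr=0.8)
        fit = fit_glm(vol, design)
        tmap = contrast_map(fit, np.array([1.0, 0, 0, 0]), kind="t")
        tvals = tmap.values[tmap.mask]
        assert tvals.size == v
        p = stats.kstest(tvals, stats.t(df=fit.dof).cdf).pvalue
        assert p > 1e-3

    def test_drift_component_does_not_bias_conditions(self, noiseless_subject):
        """Adding a drift-space signal leaves condition betas unchanged
        (high-pass filter orthogonality)."""
        cfg, parc, subj = noiseless_subject
        mres = match_trials(subj.events)
        n_scans = {s: subj.bold[s].n_scans for s in subj.bold}
        d = build_design_5cond(subj.events, mres, n_scans, subj.tr, subj.motion)
        data = np.concatenate([subj.bold[s].data for s in sorted(subj.bold)], axis=3)
        vol = ib.Volume4D(data=data, tr=subj.tr, mask=subj.bold[1].mask)
        fit0 = fit_glm(vol, d)
        drift_cols = [j for j, k in enumerate(d.column_kind) if k == "drift"]
        bump = d.matrix[:, drift_cols[:3]] @ np.array([5.0, -2.0, 1.0])
        vol2 = ib.Volume4D(data=data + bump.reshape(1, 1, 1, -1), tr=subj.tr,
                           mask=subj.bold[1].mask)
        fit1 = fit_glm(vol2, d)
        cond_cols = [j for j, k in enumerate(d.column_kind) if k == "condition"]
        np.testing.assert_allclose(fit1.beta[cond_cols], fit0.beta[cond_cols],
                                   atol=1e-8)


class TestContrasts:
    def test_zero_weights_rejected(self, rng):
        n = 40
        x = rng.normal(size=(n, 2))
        design = ib.DesignMatrix(x, ["a", "b"], [1, 1], ["condition"] * 2,
                                 {1: (0, n)}, 0.8)
        fit = fit_glm(ib.Volume4D(data=rng.normal(size=(2, 2, 1, n)), tr=0.8), design)
        with pytest.raises(ValueError):
            contrast_map(fit, np.zeros(2))

    def test_scaling_invariance_of_t(self, rng):
        n = 40
        x = rng.normal(size=(n, 2))
        design = ib.DesignMatrix(x, ["a", "b"], [1, 1], ["condition"] * 2,
                                 {1: (0, n)}, 0.8)
        fit = fit_glm(ib.Volume4D(data=rng.normal(size=(2, 2, 1, n)), tr=0.8), design)
        w = np.array([1.0, -1.0])
        eff1 = contrast_map(fit, w, kind="effect").values
        eff3 = contrast_map(fit, 3 * w, kind="effect").values
        np.testing.assert_allclose(eff3, 3 * eff1, rtol=1e-10)
        t1 = contrast_map(fit, w, kind="t").values
        t3 = contrast_map(fit, 3 * w, kind="t").values
        np.testing.assert_allclose(t3, t1, rtol=1e-10)

    def test_contrast_touching_omitted_condition_errors(self):
        d = build_design_5cond(
            ib.EventTable([]), ib.MatchResult([], [], []),
            {1: 100}, 0.8, {1: np.zeros((100, 6))})
        with pytest.raises(ValueError, match="omitted"):
            d.contrast_vector({"matched_pain": 1.0})

    def test_difference_contrast_sign_in_preferential_regions(self, noiseless_subject):
        """Noiseless pain-vs-tactile effect is positive exactly in regions
        whose injected pain amplitude exceeds the tactile amplitude."""
        cfg, parc, subj = noiseless_subject
        fl = ib.first_level_contrasts(subj)
        diff = fl["difference"].values
        for eff in cfg.region_effects:
            if eff.intensity_slope != 0:
                continue  # span mismatch regions checked elsewhere
            region_vals = diff[parc.region_mask(eff.region_id)]
            if eff.amp_pain > eff.amp_tactile:
                assert np.all(region_vals > 0.1)
            elif eff.amp_tactile > eff.amp_pain:
                assert np.all(region_vals < -0.1)
            else:
                np.testing.assert_allclose(region_vals, 0.0, atol=1e-6)
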