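"""Synthetic cohort generator: design structure, rating moments, forward model."""

import numpy as np
import pytest

import isobold as ib
from isobold.cohort import region_scan_signal


class TestEvents:
    def test_trial_counts_and_balance(self, small_config):
        ev = ib.simulate_events(small_config, 0)
        for ses in (1, 2):
            sev = ev.session_events(ses)
            assert len(sev) == 24
            for mod in ("pain", "tactile"):
                mev = [e for e in sev if e.modality == mod]
                assert len(mev) == 12
                assert sum(e.physical_level == "low" for e in mev) == 6
                assert sum(e.physical_level == "high" for e in mev) == 6

    def test_block_structure_alternates(self, small_config):
        """Six blocks of four same-modality trials, alternating, with the
        starting modality flipping between sessions."""
        ev = ib.simulate_events(small_config, 0)
        starts = {}
        for ses in (1, 2):
            sev = ev.session_events(ses)
            mods = [e.modality for e in sev]
            blocks = [mods[i:i + 4] for i in range(0, 24, 4)]
            assert all(len(set(b)) == 1 for b in blocks)
            block_mods = [b[0] for b in blocks]
            assert all(block_mods[i] != block_mods[i + 1] for i in range(5))
            starts[ses] = block_mods[0]
        assert starts[1] != starts[2]

    def test_onsets_inside_stimulation_window(self, small_config):
        """Stimulus onsets obey 25t + 2 <= onset <= 25t + 12; the rating
        period never contains a stimulus."""
        for si in range(3):
            ev = ib.simulate_events(small_config, si)
            for ses in (1, 2):
                for t, e in enumerate(ev.session_events(ses)):
                    assert 25 * t + 2 <= e.stim_onset_s <= 25 * t + 12
                    assert e.rating_onset_s == pytest.approx(25 * t + 15)
                    assert e.stim_onset_s < e.rating_onset_s
                    # lag between stimulus and rating is in [3, 13] s
                    assert 3 - 1e-9 <= e.rating_onset_s - e.stim_onset_s <= 13 + 1e-9

    def test_rating_moments_match_truncation_corrected_target(self):
        """Over 1e4 draws per condition, sample means sit within 3 SE of
        the truncated-Gaussian targets implied by the configured moments."""
        model = ib.RatingModel()
        rng = np.random.default_rng(7)
        for (mod, lev), (mu, sd) in model.moments.items():
            draws = model.draw(mod, lev, rng, size=10000)
            assert np.all((draws >= 0) & (draws <= 10))
            target = model.truncated_mean(mod, lev)
            se = draws.std(ddof=1) / 100.0
            assert abs(draws.mean() - target) < 3 * se

    def test_ratings_within_scale(self, small_config):
        for si in range(4):
            ev = ib.simulate_events(small_config, si)
            assert all(0 <= e.rating <= 10 for e in ev)


class TestParcellation:
    def test_partition_properties(self, small_config):
        parc = ib.simulate_parcellation(small_config)
        sizes = parc.region_sizes()
        assert len(sizes) == small_config.n_regions
        assert all(v >= 8 for v in sizes.values())
        assert sum(sizes.values()) == int(np.prod(small_config.grid_shape))

    def test_single_region_degenerate(self):
        cfg = ib.CohortConfig(n_subjects=1, grid_shape=(6, 6, 6), n_regions=1,
                              region_effects=[ib.RegionEffect(1)], seed=0)
        parc = ib.simulate_parcellation(cfg)
        assert np.all(parc.labels == 1)

    def test_infeasible_count_rejected(self):
        cfg = ib.CohortConfig(n_subjects=1, grid_shape=(6, 6, 6), n_regions=8, seed=0)
        with pytest.raises(ValueError):
            ib.simulate_parcellation(cfg, mask=np.zeros((6, 6, 6), dtype=bool))


class TestForwardModel:
    def test_single_trial_matches_direct_convolution(self):
        """With silent noise and a single pain trial, the region time course
        equals the HRF forward model computed by brute-force discrete
        convolution."""
        eff = [ib.RegionEffect(1, amp_pain=1.0, amp_tactile=0.0, intensity_slope=0.0)]
        cfg = ib.CohortConfig(n_subjects=1, grid_shape=(4, 4, 4), n_regions=1,
                              trials_per_session=8, sessions=1, rating_amp=0.0,
                              region_effects=eff, noise=ib.NoiseModel.silent(),
                              seed=2)
        ev = ib.simulate_events(cfg, 0)
        one_pain = [e for e in ev if e.modality == "pain"][:1]
        table = ib.EventTable(one_pain)
        parc = ib.simulate_parcellation(cfg)
        subj = ib.simulate_bold(cfg, table, parc, 0)
        ts = subj.bold[1].data[parc.region_mask(1)][0] - cfg.baseline
        # oracle: dense convolution of a unit-area impulse with the kernel
        spec = cfg.hrf
        dt = cfg.tr_s / spec.microtime_bins_per_tr
        h = ib.canonical_hrf(spec, dt)
        u = np.zeros(cfg.n_scans * spec.microtime_bins_per_tr)
        u[int(round(one_pain[0].stim_onset_s / dt))] = 1.0 / dt
        fine = np.convolve(u, h)[:len(u)] * dt
        idx = np.arange(cfg.n_scans) * spec.microtime_bins_per_tr + spec.microtime_onset_bin
        np.testing.assert_allclose(ts, fine[idx], atol=1e-9)

    def test_modality_symmetry_in_noiseless_limit(self):
        """Equal amplitudes, no peak shift, no slope: the pain-vs-tactile
        mean time-course difference vanishes up to onset jitter when the
        design is evaluated through the GLM difference contrast."""
        eff = [ib.RegionEffect(r + 1, amp_pain=0.8, amp_tactile=0.8,
                               intensity_slope=0.0) for r in range(8)]
        cfg = ib.CohortConfig(n_subjects=1, grid_shape=(8, 8, 8), n_regions=8,
                              region_effects=eff, noise=ib.NoiseModel.silent(),
                              seed=9)
        parc = ib.simulate_parcellation(cfg)
        subj = ib.simulate_subject(cfg, parc, 0)
        fl = ib.first_level_contrasts(subj)
        np.testing.assert_allclose(fl["difference"].values, 0.0, atol=1e-6)

    def test_rng_stream_contract(self, small_config):
        """Same (seed, subject_index) reproduces data bitwise; different
        subject indices give different noise."""
        parc = ib.simulate_parcellation(small_config)
        a1 = ib.simulate_subject(small_config, parc, 0)
        a2 = ib.simulate_subject(small_config, parc, 0)
        b = ib.simulate_subject(small_config, parc, 1)
        np.testing.assert_array_equal(a1.bold[1].data, a2.bold[1].data)
        assert not np.allclose(a1.bold[1].data, b.bold[1].data)

    def test_noiseless_recovery_of_amplitudes_and_slopes(self, noiseless_subject):
        """End-to-end: injected condition amplitudes and intensity slopes are
        recovered by the GLMs to tight relative error on noiseless data."""
        cfg, parc, subj = noiseless_subject
        fl = ib.first_level_contrasts(subj)
        for eff in cfg.region_effects:
            vals = fl["intensity"].values[parc.region_mask(eff.region_id)]
            if eff.intensity_slope != 0:
                np.testing.assert_allclose(vals, eff.intensity_slope, rtol=1e-6)
            pain_beta = fl["matched_pain"].values[parc.region_mask(eff.region_id)]
            if eff.intensity_slope == 0:
                np.testing.assert_allclose(pain_beta, eff.amp_pain, rtol=1e-6)
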