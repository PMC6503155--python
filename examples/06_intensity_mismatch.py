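"""Intensity-mismatch comparison: does modality preference survive when the
preferred modality is perceived as weaker?

All stimuli are pooled and median-split into high/low perceived intensity
(count-equalized near the median). Pain-preferential regions then compare
low-intensity pain against high-intensity touch. With the default mild
intensity slope the pain preference persists; making the slope dominate the
modality gap reverses the comparison — responses follow intensity, not
modality.
"""

import numpy as np

import isobold as ib

for slope, label in ((0.0, "slope 0 (pure modality coding)"),
                     (0.5, "slope 0.5 (intensity dominates)")):
    effects = ib.default_region_effects(8, intensity_slope=slope)
    cfg = ib.CohortConfig(n_subjects=8, grid_shape=(8, 8, 8), n_regions=8,
                          region_effects=effects, seed=11)
    parc, subjects = ib.simulate_cohort(cfg)
    res = ib.analysis4(subjects, parc, pain_pref_regions=[1, 2, 3],
                       tactile_pref_regions=[4, 5, 6],
                       cfg=ib.PermConfig(n_perm=500, seed=2))
    pp = res.results["pain_preferential"]
    print(label)
    for rid, d, p in zip(pp.region_ids, pp.mean_diff, pp.p_fwe):
        direction = "pain_low > tactile_high" if d > 0 else "REVERSED"
        print(f"  region {rid}: AUC(pain_low) - AUC(tactile_high) = {d:7.2f} "
              f" p_FWE = {p:.3f}  -> {direction}")
# With slope 0 the pain-preferential regions keep larger responses to the
# (weaker-felt) painful stimuli; with a dominant slope the high-intensity
# tactile stimuli win, mirroring intensity-driven coding.
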