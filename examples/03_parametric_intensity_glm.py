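"""Fit the parametric-intensity GLM and read off the intensity slope.

All stimuli are collapsed into one regressor with a mean-centred rating
modulator; in the generator every region gains 0.15 a.u. of response per
rating unit, and on noiseless data the fitted modulator beta returns that
slope exactly.
"""

import numpy as np

import isobold as ib

cfg = ib.CohortConfig(n_subjects=1, grid_shape=(8, 8, 8), n_regions=8,
                      noise=ib.NoiseModel.silent(), seed=5)
parc = ib.simulate_parcellation(cfg)
subj = ib.simulate_subject(cfg, parc, 0)

fl = ib.first_level_contrasts(subj)
slope_map = fl["intensity"].values

print("fitted intensity slope per region (injected: 0.15 a.u./rating unit):")
for rid in parc.region_ids:
    vals = slope_map[parc.region_mask(rid)]
    print(f"  region {rid}: {vals.mean():+.6f}")
# Regions whose responses are pure impulses recover 0.15 to numerical
# precision; pain-preferential regions (1-3) deviate slightly because their
# injected responses are longer and later than the canonical kernel.
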