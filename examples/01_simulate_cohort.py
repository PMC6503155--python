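"""Simulate a small synthetic cohort and inspect its design.

Builds two subjects' worth of events, parcellation and 4-D BOLD, and
prints the trial structure and rating summary. The event layout follows
the emulated study: 2 sessions x 24 trials of 25 s (2 s lead-in, 10 s
stimulation window with one randomly timed stimulus, 3 s gap, 10 s rating
period), TR = 0.8 s.
"""

import numpy as np

import isobold as ib

cfg = ib.CohortConfig(n_subjects=2, grid_shape=(8, 8, 8), n_regions=8, seed=1)
parc, subjects = ib.simulate_cohort(cfg)

subj = subjects[0]
print(f"grid {cfg.grid_shape}, {cfg.n_regions} regions, "
      f"{cfg.n_scans} scans/session at TR {cfg.tr_s} s")
print(f"region sizes: {parc.region_sizes()}")

ev = subj.events
for ses in ev.sessions:
    sev = ev.session_events(ses)
    mods = [e.modality for e in sev]
    blocks = [mods[i] for i in range(0, len(mods), 4)]
    print(f"session {ses}: {len(sev)} trials, block order {blocks}")

for mod in ("pain", "tactile"):
    r = [e.rating for e in ev.by_modality(mod)]
    print(f"{mod:8s} ratings: mean {np.mean(r):.2f}, range "
          f"[{min(r):.2f}, {max(r):.2f}]  (0-10 scale)")
# Expected: alternating pain/tactile blocks of 4, ratings clustered around
# the low/high perceived-intensity means of the emulated study.
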