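"""Synthetic multi-subject cohort generator.

Emulates an event-related pain-vs-touch fMRI study: two sessions of 24
trials each, a trial being 2 s lead-in, a 10-s stimulation window holding a
single brief stimulus at a uniformly random time, a 3-s gap, and a 10-s
rating period (25 s per trial). Trials come in six alternating same-modality
blocks of four (two low + two high physical intensity, randomly ordered);
the starting modality alternates across sessions and subjects. Perceived
intensity ratings are truncated Gaussians on the 0-10 visual-analogue scale
with per-(modality, level) moments.

BOLD is generated from the same canonical-HRF forward model the GLM uses:
each region has pain/tactile response amplitudes, a linear perceived-
intensity gain, and optional pain-specific prolongation (longer neural
duration, delayed peak) mirroring the observation that pain responses are
larger, later and longer-lasting. Rating periods add a common boxcar
response. Noise is AR(1) with slow cosine drifts and optional leakage of
the motion parameters into the signal. All randomness derives from
(seed, subject_index) so subjects are independent but reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .glm import HRFSpec, sample_regressor
from .io import EventTable, Parcellation, SubjectDataset, TrialEvent, Volume4D

__all__ = [
    "RatingModel",
    "RegionEffect",
    "NoiseModel",
    "CohortConfig",
    "default_region_effects",
    "simulate_events",
    "simulate_parcellation",
    "simulate_bold",
    "simulate_subject",
    "simulate_cohort",
]

# Observed perceived-intensity moments (mean, SD) on the 0-10 scale for
# (modality, physical level); used as pre-truncation parameters of a
# Gaussian truncated to [0, 10].
DEFAULT_RATING_MOMENTS = {
    ("pain", "low"): (2.76, 1.54),
    ("pain", "high"): (5.59, 1.51),
    ("tactile", "low"): (3.06, 1.14),
    ("tactile", "high"): (5.65, 1.26),
}


@dataclass(frozen=True)
class RatingModel:
    """Truncated-Gaussian perceived-intensity model per (modality, level)."""

    moments: dict = field(default_factory=lambda: dict(DEFAULT_RATING_MOMENTS))
    lower: float = 0.0
    upper: float = 10.0

    def __post_init__(self) -> None:
        for key, (_, sd) in self.moments.items():
            if sd <= 0:
                raise ValueError(f"SD must be positive for {key}")

    def draw(self, modality: str, level: str, rng: np.random.Generator,
             size=None) -> np.ndarray:
        mu, sd = self.moments[(modality, level)]
        a, b = (self.lower - mu) / sd, (self.upper - mu) / sd
        return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)

    def truncated_mean(self, modality: str, level: str) -> float:
        """Exact mean of the truncated distribution (the moment-check target)."""
        mu, sd = self.moments[(modality, level)]
        a, b = (self.lower - mu) / sd, (self.upper - mu) / sd
        return float(stats.truncnorm.mean(a, b, loc=mu, scale=sd))


@dataclass(frozen=True)
class RegionEffect:
    """Ground-truth response structure of one region.

    ``amp_pain``/``amp_tactile`` are single-event response amplitudes (a.u.)
    at a mid-scale rating of 5; ``intensity_slope`` is the amplitude gain per
    rating unit; ``peak_shift_s`` delays pain responses; ``duration_s``
    prolongs the neural event (0 = impulse). A region is pain-preferential
    iff amp_pain > amp_tactile, tactile-preferential iff the reverse.
    """

    region_id: int
    amp_pain: float = 0.7
    amp_tactile: float = 0.7
    intensity_slope: float = 0.15
    peak_shift_s: float = 0.0
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ValueError("duration_s must be nonnegative")

    @property
    def preference(self) -> str:
        if self.amp_pain > self.amp_tactile:
            return "pain"
        if self.amp_tactile > self.amp_pain:
            return "tactile"
        return "none"


@dataclass(frozen=True)
class NoiseModel:
    """AR(1) voxel noise + slow cosine drifts + motion leakage."""

    sigma_white: float = 1.0   # innovation SD, a.u.
    ar1_rho: float = 0.3
    drift_amplitudes: tuple[float, ...] = (1.0, 0.5)
    motion_leak: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must be in [0, 1)")
        vals = (self.sigma_white, self.ar1_rho, self.motion_leak, *self.drift_amplitudes)
        if not np.all(np.isfinite(vals)):
            raise ValueError("noise parameters must be finite")

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(sigma_white=0.0, ar1_rho=0.0, drift_amplitudes=(), motion_leak=0.0)


def default_region_effects(n_regions: int, n_pain_pref: int = 3,
                           n_tactile_pref: int = 3,
                           intensity_slope: float = 0.15) -> list[RegionEffect]:
    """Default ground truth: the first ``n_pain_pref`` regions prefer pain
    (amplitude 1.0 vs 0.5, with 1-s peak delay and 2-s neural duration
    emulating the later, longer pain response), the next ``n_tactile_pref``
    prefer touch (0.5 vs 1.0), and the rest respond equally (0.7)."""
    if n_pain_pref + n_tactile_pref > n_regions:
        raise ValueError("more preferential regions than regions")
    effects = []
    for i in range(n_regions):
        rid = i + 1
        if i < n_pain_pref:
            effects.append(RegionEffect(rid, amp_pain=1.0, amp_tactile=0.5,
                                        intensity_slope=intensity_slope,
                                        peak_shift_s=1.0, duration_s=2.0))
        elif i < n_pain_pref + n_tactile_pref:
            effects.append(RegionEffect(rid, amp_pain=0.5, amp_tactile=1.0,
                                        intensity_slope=intensity_slope))
        else:
            effects.append(RegionEffect(rid, intensity_slope=intensity_slope))
    return effects


@dataclass
class CohortConfig:
    """Full generative specification of a synthetic study."""

    n_subjects: int = 30
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_regions: int = 10
    tr_s: float = 0.8
    sessions: int = 2
    trials_per_session: int = 24
    lead_in_s: float = 2.0
    stim_window_s: float = 10.0
    gap_s: float = 3.0
    rating_period_s: float = 10.0
    rating_amp: float = 0.5
    baseline: float = 100.0
    rating_model: RatingModel = field(default_factory=RatingModel)
    region_effects: list[RegionEffect] = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    hrf: HRFSpec = field(default_factory=HRFSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_effects is None:
            self.region_effects = default_region_effects(self.n_regions)
        if len(self.region_effects) != self.n_regions:
            raise ValueError("need one RegionEffect per region")
        for name in ("n_subjects", "n_regions", "tr_s", "sessions", "trials_per_session"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("lead_in_s", "stim_window_s", "gap_s", "rating_period_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.trials_per_session % 8 != 0:
            raise ValueError("trials_per_session must be a multiple of 8 "
                             "(blocks of 4, two modalities, two levels)")

    @property
    def trial_length_s(self) -> float:
        return self.lead_in_s + self.stim_window_s + self.gap_s + self.rating_period_s

    @property
    def session_duration_s(self) -> float:
        return self.trial_length_s * self.trials_per_session

    @property
    def n_scans(self) -> int:
        return int(round(self.session_duration_s / self.tr_s))

    def effect(self, region_id: int) -> RegionEffect:
        for e in self.region_effects:
            if e.region_id == region_id:
                return e
        raise KeyError(region_id)


def _rng(config: CohortConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *key])


def simulate_events(config: CohortConfig, subject_index: int) -> EventTable:
    """Generate one subject's event table for all sessions.

    Per session: alternating same-modality blocks of 4 trials (2 low + 2
    high, randomly ordered); the starting modality alternates with both
    session and subject index. The single stimulus of each trial falls
    uniformly inside that trial's stimulation window.
    """
    rng = _rng(config, subject_index, 0)
    events = []
    n_blocks = config.trials_per_session // 4
    for ses in range(1, config.sessions + 1):
        start_pain = (subject_index + ses) % 2 == 0
        for b in range(n_blocks):
            modality = "pain" if (start_pain ^ (b % 2 == 1)) else "tactile"
            levels = ["low", "low", "high", "high"]
            rng.shuffle(levels)
            for j, level in enumerate(levels):
                t = b * 4 + j
                t0 = t * config.trial_length_s
                stim = t0 + config.lead_in_s + rng.uniform(0.0, config.stim_window_s)
                rating_onset = t0 + config.lead_in_s + config.stim_window_s + config.gap_s
                rating = float(config.rating_model.draw(modality, level, rng))
                events.append(TrialEvent(
                    trial_id=f"s{ses}t{t:02d}",
                    session=ses,
                    modality=modality,
                    physical_level=level,
                    stim_onset_s=float(stim),
                    rating=rating,
                    rating_onset_s=float(rating_onset),
                    rating_duration_s=config.rating_period_s,
                ))
    return EventTable(events)


def simulate_parcellation(config: CohortConfig, mask: np.ndarray | None = None) -> Parcellation:
    """Tile the mask into ``n_regions`` compact regions (k-means on voxel
    coordinates; falls back to ordered chunking if k-means leaves a region
    under 8 voxels)."""
    if mask is None:
        mask = np.ones(config.grid_shape, dtype=bool)
    coords = np.argwhere(mask)
    n_vox = len(coords)
    if config.n_regions * 8 > n_vox:
        raise ValueError(
            f"cannot fit {config.n_regions} regions of >= 8 voxels into "
            f"{n_vox} in-mask voxels"
        )
    labels = np.zeros(config.grid_shape, dtype=np.int32)
    if config.n_regions == 1:
        labels[mask] = 1
        return Parcellation(labels=labels, region_ids=(1,))
    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=config.n_regions, n_init=4,
                random_state=int(config.seed) % (2**31))
    assign = km.fit_predict(coords.astype(float))
    counts = np.bincount(assign, minlength=config.n_regions)
    if counts.min() < 8:
        # ordered chunking: lexicographic voxel order split into equal runs
        order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
        assign = np.zeros(n_vox, dtype=int)
        bounds = np.linspace(0, n_vox, config.n_regions + 1).astype(int)
        for r in range(config.n_regions):
            assign[order[bounds[r]:bounds[r + 1]]] = r
    labels[tuple(coords.T)] = assign + 1
    return Parcellation(labels=labels, region_ids=tuple(range(1, config.n_regions + 1)))


def _region_events(config: CohortConfig, events: EventTable,
                   effect: RegionEffect, session: int):
    sev = events.session_events(session)
    onsets, durations, amps = [], [], []
    for e in sev:
        amp_mod = effect.amp_pain if e.modality == "pain" else effect.amp_tactile
        a = amp_mod + effect.intensity_slope * (e.rating - 5.0)
        shift = effect.peak_shift_s if e.modality == "pain" else 0.0
        onsets.append(e.stim_onset_s + shift)
        durations.append(effect.duration_s)
        amps.append(a)
    return np.array(onsets), np.array(durations), np.array(amps)


def region_scan_signal(config: CohortConfig, events: EventTable,
                       effect: RegionEffect, session: int) -> np.ndarray:
    """Noiseless stimulus-driven signal of one region for one session,
    sampled at scan times (excludes rating response, baseline and noise)."""
    onsets, durations, amps = _region_events(config, events, effect, session)
    if len(onsets) == 0:
        return np.zeros(config.n_scans)
    return sample_regressor(onsets, durations, amps,
                            config.n_scans, config.tr_s, config.hrf)


def _all_region_signals(config: CohortConfig, events: EventTable,
                        session: int) -> dict[int, np.ndarray]:
    """Batched equivalent of :func:`region_scan_signal` for every region
    (one FFT convolution for the whole region set)."""
    from scipy.signal import fftconvolve
    from .glm import canonical_hrf
    spec = config.hrf
    bins = spec.microtime_bins_per_tr
    dt = config.tr_s / bins
    n_fine = config.n_scans * bins
    rids = [e.region_id for e in config.region_effects]
    u = np.zeros((len(rids), n_fine))
    for r, eff in enumerate(config.region_effects):
        onsets, durations, amps = _region_events(config, events, eff, session)
        for o, d, a in zip(onsets, durations, amps):
            i0 = int(round(o / dt))
            if i0 >= n_fine or i0 < 0:
                continue
            if d <= 0:
                u[r, i0] += a / dt
            else:
                i1 = min(int(round((o + d) / dt)), n_fine)
                u[r, i0:i1] += a
    h = canonical_hrf(spec, dt)
    x_fine = fftconvolve(u, h[None, :], axes=1)[:, :n_fine] * dt
    idx = np.arange(config.n_scans) * bins + min(spec.microtime_onset_bin, bins - 1)
    return {rid: x_fine[r, idx] for r, rid in enumerate(rids)}


def rating_scan_signal(config: CohortConfig, events: EventTable,
                       session: int) -> np.ndarray:
    """Common rating-period response (10-s boxcar, amplitude rating_amp)."""
    sev = events.session_events(session)
    if not sev or config.rating_amp == 0:
        return np.zeros(config.n_scans)
    ons = np.array([e.rating_onset_s for e in sev])
    dur = np.array([e.rating_duration_s for e in sev])
    return sample_regressor(ons, dur, np.full_like(ons, config.rating_amp),
                            config.n_scans, config.tr_s, config.hrf)


def _simulate_motion(rng: np.random.Generator, n_scans: int) -> np.ndarray:
    """Six smooth random-walk motion parameters (a.u., zero-mean)."""
    steps = rng.normal(0.0, 0.01, size=(n_scans, 6))
    walk = np.cumsum(steps, axis=0)
    from scipy.ndimage import gaussian_filter1d
    walk = gaussian_filter1d(walk, sigma=5.0, axis=0)
    return walk - walk.mean(axis=0)


def simulate_bold(config: CohortConfig, events: EventTable,
                  parcellation: Parcellation, subject_index: int) -> SubjectDataset:
    """Generate one subject's 4-D BOLD (all sessions) plus motion tables."""
    rng = _rng(config, subject_index, 1)
    mask = parcellation.labels > 0
    n_vox = int(mask.sum())
    lab_flat = parcellation.labels[mask]
    t_scan = np.arange(config.n_scans) * config.tr_s
    bold, motion = {}, {}
    for ses in range(1, config.sessions + 1):
        region_sig = _all_region_signals(config, events, ses)
        rating_sig = rating_scan_signal(config, events, ses)
        mot = _simulate_motion(rng, config.n_scans)
        data_flat = np.empty((n_vox, config.n_scans))
        for rid in parcellation.region_ids:
            data_flat[lab_flat == rid] = region_sig[rid] + rating_sig
        nz = config.noise
        if nz.sigma_white > 0:
            white = rng.normal(0.0, nz.sigma_white, size=(n_vox, config.n_scans))
            if nz.ar1_rho > 0:
                noise = sps.lfilter([1.0], [1.0, -nz.ar1_rho], white, axis=1)
            else:
                noise = white
            data_flat += noise
        if nz.drift_amplitudes:
            t_frac = t_scan / config.session_duration_s
            for k, amp in enumerate(nz.drift_amplitudes, start=1):
                phase = rng.uniform(0.0, 2 * np.pi, size=n_vox)
                data_flat += amp * np.cos(np.pi * k * t_frac[None, :] + phase[:, None])
        if nz.motion_leak != 0:
            w = rng.normal(0.0, 1.0, size=(6, n_vox))
            data_flat += nz.motion_leak * (mot @ w).T
        data_flat += config.baseline
        data = np.zeros(config.grid_shape + (config.n_scans,))
        data[mask] = data_flat
        bold[ses] = Volume4D(data=data, tr=config.tr_s, mask=mask.copy())
        motion[ses] = mot
    return SubjectDataset(bold=bold, events=events, motion=motion,
                          subject_id=f"sub-{subject_index + 1:02d}")


def simulate_subject(config: CohortConfig, parcellation: Parcellation,
                     subject_index: int) -> SubjectDataset:
    events = simulate_events(config, subject_index)
    return simulate_bold(config, events, parcellation, subject_index)


def simulate_cohort(config: CohortConfig):
    """Yield (parcellation, list of SubjectDataset) for the whole cohort."""
    parcellation = simulate_parcellation(config)
    subjects = [simulate_subject(config, parcellation, i)
                for i in range(config.n_subjects)]
    return parcellation, subjects
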