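"""Model-free time-course analysis: trial-locked extraction, rating-template
removal, condition averaging, and area-under-the-curve (AUC) statistics.

A trial time course is the spatial mean of a region's raw BOLD over a
window around the stimulus (default 1.6 s before to 20 s after), sampled at
the volume grid nearest each offset (no interpolation), with the mean of
the pre-stimulus samples subtracted as baseline. Because stimulus-evoked
responses can overlap with the response to the rating act (button presses
3-13 s after the stimulus), an average rating-locked course per region is
subtracted from each stimulus-locked course, aligned by that trial's actual
stimulus-to-rating lag. The AUC (trapezoid rule from stimulus onset to the
window end, signed) summarises response magnitude per subject, region and
condition; group inference on AUCs uses the paired sign-flip permutation
test with max-statistic FWE correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EventTable, Parcellation, SubjectDataset, Volume4D
from .matching import equalize_counts, match_trials, median_split
from .perm import PairedPermResult, PermConfig, paired_signflip

logger = logging.getLogger(__name__)

__all__ = [
    "TimecourseWindow",
    "TrialTimecourse",
    "extract_trial_courses",
    "rating_template",
    "rating_template_removal",
    "template_window_for",
    "rating_centers_for",
    "condition_average",
    "compute_auc",
    "analysis3",
    "analysis4",
    "Analysis3Result",
    "Analysis4Result",
]


@dataclass(frozen=True)
class TimecourseWindow:
    """Extraction window: ``pre_s`` before to ``post_s`` after the event."""

    pre_s: float = 1.6
    post_s: float = 20.0

    def __post_init__(self) -> None:
        if self.pre_s < 0:
            raise ValueError("pre_s must be nonnegative")
        if self.post_s <= 0:
            raise ValueError("post_s must be positive")

    def n_pre(self, tr: float) -> int:
        return int(round(self.pre_s / tr))

    def n_post(self, tr: float) -> int:
        return int(round(self.post_s / tr))

    def length(self, tr: float) -> int:
        return self.n_pre(tr) + self.n_post(tr) + 1

    def offsets_s(self, tr: float) -> np.ndarray:
        return (np.arange(self.length(tr)) - self.n_pre(tr)) * tr


@dataclass
class TrialTimecourse:
    region_id: int
    trial_id: str
    session: int
    condition: str
    samples: np.ndarray          # baseline-subtracted, length window.length(tr)
    stim_center: int             # volume index nearest the stimulus onset
    rating_center: int           # volume index nearest the rating onset


def region_timeseries(bold: dict[int, Volume4D], region_mask: np.ndarray) -> dict[int, np.ndarray]:
    """Per-session spatial-mean time series of one region."""
    if int(np.sum(region_mask)) == 0:
        raise ValueError("empty region")
    return {ses: vol.data[region_mask].mean(axis=0) for ses, vol in bold.items()}


def _extract(ts: np.ndarray, center: int, n_pre: int, n_post: int) -> np.ndarray | None:
    if center - n_pre < 0 or center + n_post >= len(ts):
        return None
    seg = ts[center - n_pre: center + n_post + 1].astype(float).copy()
    baseline = seg[:n_pre].mean() if n_pre > 0 else 0.0
    return seg - baseline


def extract_trial_courses(bold: dict[int, Volume4D] | Volume4D,
                          region_mask: np.ndarray,
                          events: EventTable,
                          window: TimecourseWindow = TimecourseWindow(),
                          region_id: int = 0) -> list[TrialTimecourse]:
    """Stimulus-locked, baseline-subtracted courses of one region.

    Trials whose window does not fit inside the session are dropped with a
    logged count. ``bold`` maps session -> Volume4D (a bare Volume4D is
    accepted for single-session tables).
    """
    if isinstance(bold, Volume4D):
        sessions = events.sessions
        if len(sessions) > 1:
            raise ValueError("single Volume4D given for multi-session events")
        bold = {sessions[0] if sessions else 1: bold}
    tr = next(iter(bold.values())).tr
    ts = region_timeseries(bold, region_mask)
    if int(np.sum(region_mask)) == 0:
        raise ValueError(f"empty region {region_id}")
    n_pre, n_post = window.n_pre(tr), window.n_post(tr)
    out, dropped = [], 0
    for e in events:
        c_stim = int(round(e.stim_onset_s / tr))
        seg = _extract(ts[e.session], c_stim, n_pre, n_post)
        if seg is None:
            dropped += 1
            continue
        out.append(TrialTimecourse(
            region_id=region_id, trial_id=e.trial_id, session=e.session,
            condition=e.modality, samples=seg, stim_center=c_stim,
            rating_center=int(round(e.rating_onset_s / tr))))
    if dropped:
        logger.info("region %s: dropped %d trial(s) whose window exceeded the session",
                    region_id, dropped)
    return out


def template_window_for(events: EventTable,
                        window: TimecourseWindow,
                        tr: float) -> TimecourseWindow:
    """Rating-template window for removal purposes.

    The pre-period reaches back past the longest stimulus-to-rating lag so
    the template can be re-referenced to any trial's pre-stimulus baseline,
    and the post-period extends by the largest spacing between consecutive
    rating onsets so the template also describes the tail of the previous
    trial's rating response throughout the stimulus-locked window.
    """
    max_lag = max((e.rating_onset_s - e.stim_onset_s for e in events), default=0.0)
    max_gap = 0.0
    for ses in events.sessions:
        onsets = [e.rating_onset_s for e in events.session_events(ses)]
        gaps = np.diff(sorted(onsets))
        if len(gaps):
            max_gap = max(max_gap, float(gaps.max()))
    return TimecourseWindow(pre_s=window.pre_s + np.ceil(max_lag / tr) * tr,
                            post_s=window.post_s + np.ceil(max_gap / tr) * tr)


def rating_centers_for(events: EventTable, tr: float) -> dict[int, list[int]]:
    """Per session, the sorted volume indices nearest each rating onset."""
    out: dict[int, list[int]] = {}
    for ses in events.sessions:
        out[ses] = sorted(int(round(e.rating_onset_s / tr))
                          for e in events.session_events(ses))
    return out


def rating_template(bold: dict[int, Volume4D] | Volume4D,
                    region_mask: np.ndarray,
                    events: EventTable,
                    window: TimecourseWindow = TimecourseWindow()) -> np.ndarray:
    """Average rating-locked course of a region over all trials (the
    response template of the rating act), baseline-subtracted."""
    if isinstance(bold, Volume4D):
        sessions = events.sessions
        bold = {sessions[0] if sessions else 1: bold}
    tr = next(iter(bold.values())).tr
    ts = region_timeseries(bold, region_mask)
    n_pre, n_post = window.n_pre(tr), window.n_post(tr)
    segs = []
    for e in events:
        c = int(round(e.rating_onset_s / tr))
        seg = _extract(ts[e.session], c, n_pre, n_post)
        if seg is not None:
            segs.append(seg)
    if not segs:
        raise ValueError("no trial has a complete rating-locked window")
    return np.mean(segs, axis=0)


def rating_template_removal(courses: list[TrialTimecourse],
                            template: np.ndarray,
                            window: TimecourseWindow,
                            tr: float,
                            template_window: TimecourseWindow | None = None,
                            rating_centers: dict[int, list[int]] | None = None,
                            ) -> list[TrialTimecourse]:
    """Subtract the rating template from each stimulus-locked course.

    The template's post-onset part (offsets >= 0 from the rating onset) is
    shifted by the trial's actual stimulus-to-rating lag in volumes and
    subtracted where it overlaps the stimulus-locked window; samples before
    the rating onset — in particular all pre-stimulus samples — are
    untouched.

    When the template was extracted on a longer window (see
    :func:`template_window_for`), it is re-referenced before subtraction to
    its value over the trial's own pre-stimulus baseline period, so that the
    subtraction is consistent with the course's baseline even when rating
    responses of neighbouring trials overlap the baseline.

    With ``rating_centers`` (per-session volume indices of all rating
    onsets, see :func:`rating_centers_for`) each post-stimulus sample is
    corrected using the template aligned to the *most recent* rating onset
    at or before that sample. Because rating onsets recur at the fixed
    trial pace, the rating-locked average already contains the tails of the
    surrounding trials' responses at their correct phases, so this single
    subtraction also removes the previous trial's bleed-in between the
    stimulus and the current rating onset. Without ``rating_centers`` only
    the trial's own rating response is subtracted.
    """
    if template_window is None:
        template_window = window
    n_pre = window.n_pre(tr)
    n_pre_t = template_window.n_pre(tr)
    length = window.length(tr)
    t_len = len(template)
    out = []
    for c in courses:
        samples = c.samples.copy()
        centers = (rating_centers or {}).get(c.session)
        if centers is None:
            centers = [c.rating_center]
        # template re-reference value per instance, over this trial's
        # pre-stimulus baseline period
        base_of: dict[int, float] = {}

        def t_base(c_r: int) -> float:
            if c_r not in base_of:
                idx = [jb - n_pre - (c_r - c.stim_center) + n_pre_t
                       for jb in range(n_pre)]
                idx = [k for k in idx if 0 <= k < t_len]
                base_of[c_r] = float(np.mean(template[idx])) if idx else 0.0
            return base_of[c_r]

        for j in range(n_pre, length):
            v = c.stim_center + j - n_pre  # absolute volume index
            recent = [c_r for c_r in centers if c_r <= v]
            if not recent:
                continue  # no rating event has occurred yet
            c_r = max(recent)
            k = j - n_pre - (c_r - c.stim_center) + n_pre_t
            value = template[k] if n_pre_t <= k < t_len else 0.0
            samples[j] -= value - t_base(c_r)
        out.append(TrialTimecourse(region_id=c.region_id, trial_id=c.trial_id,
                                   session=c.session, condition=c.condition,
                                   samples=samples, stim_center=c.stim_center,
                                   rating_center=c.rating_center))
    return out


@dataclass
class ConditionAverage:
    offsets_s: np.ndarray
    conditions: tuple[str, str]
    mean: dict[str, np.ndarray]       # across-subject mean course per condition
    sem: dict[str, np.ndarray]
    t: np.ndarray                     # per-timepoint paired t (descriptive)
    p: np.ndarray                     # uncorrected two-sided p
    n_subjects: int


def condition_average(subject_courses: list[dict[str, np.ndarray]],
                      conditions: tuple[str, str],
                      offsets_s: np.ndarray) -> ConditionAverage:
    """Across-subject mean ± SEM per condition and per-timepoint paired t.

    ``subject_courses[i]`` maps condition name to that subject's mean course
    (trial-averaged). Subjects missing either condition are excluded
    pairwise with a logged count. Zero-variance differences yield t = ±inf
    and p = 0 (flagged, not an error).
    """
    a_name, b_name = conditions
    rows_a, rows_b = [], []
    excluded = 0
    for sc in subject_courses:
        if a_name in sc and b_name in sc:
            rows_a.append(sc[a_name])
            rows_b.append(sc[b_name])
        else:
            excluded += 1
    if excluded:
        logger.info("condition_average: excluded %d subject(s) missing a condition",
                    excluded)
    if len(rows_a) < 1:
        raise ValueError("no subject has both conditions")
    a = np.stack(rows_a)
    b = np.stack(rows_b)
    n = a.shape[0]
    d = a - b
    md = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1) if n > 1 else np.zeros(d.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = md / (sd / np.sqrt(n))
    t = np.where(np.isnan(t), 0.0, t)  # 0/0 -> no effect
    from scipy import stats as _st
    p = np.where(np.isinf(t), 0.0,
                 2 * _st.t.sf(np.abs(np.where(np.isinf(t), 0, t)), max(n - 1, 1)))
    out_mean = {a_name: a.mean(axis=0), b_name: b.mean(axis=0)}
    out_sem = {
        a_name: a.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(md),
        b_name: b.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(md),
    }
    return ConditionAverage(offsets_s=offsets_s, conditions=conditions,
                            mean=out_mean, sem=out_sem, t=t, p=p, n_subjects=n)


def compute_auc(course: np.ndarray, window: TimecourseWindow, tr: float,
                rectified: bool = False) -> float:
    """Signed trapezoidal area of the course from offset 0 to ``post_s``.

    Units are a.u.·s. ``rectified=True`` integrates |course| instead.
    """
    course = np.asarray(course, dtype=float)
    if not np.all(np.isfinite(course)):
        raise ValueError("non-finite samples in course")
    seg = course[window.n_pre(tr):]
    if rectified:
        seg = np.abs(seg)
    return float(np.trapezoid(seg, dx=tr))


# ---------------------------------------------------------------------------
# Region-wise analyses


def _subject_region_mean_courses(subject: SubjectDataset, parcellation: Parcellation,
                                 window: TimecourseWindow,
                                 trial_groups: dict[str, set[str]],
                                 remove_template: bool = True,
                                 ) -> dict[int, dict[str, np.ndarray]]:
    """Per region: the subject's trial-mean course for each named trial group.

    ``trial_groups`` maps a condition label to the set of trial_ids in it;
    groups with no extractable trial are omitted for that region.
    """
    tr = subject.tr
    out: dict[int, dict[str, np.ndarray]] = {}
    for rid in parcellation.region_ids:
        rmask = parcellation.region_mask(rid)
        courses = extract_trial_courses(subject.bold, rmask, subject.events,
                                        window, region_id=rid)
        if remove_template:
            t_win = template_window_for(subject.events, window, tr)
            template = rating_template(subject.bold, rmask, subject.events, t_win)
            centers = rating_centers_for(subject.events, tr)
            courses = rating_template_removal(courses, template, window, tr,
                                              template_window=t_win,
                                              rating_centers=centers)
        by_group: dict[str, list[np.ndarray]] = {}
        for c in courses:
            for gname, ids in trial_groups.items():
                if c.trial_id in ids:
                    by_group.setdefault(gname, []).append(c.samples)
        out[rid] = {g: np.mean(v, axis=0) for g, v in by_group.items() if v}
    return out


@dataclass
class Analysis3Result:
    auc_table: pd.DataFrame              # subject, region, condition, auc
    results: dict[str, PairedPermResult]  # pain_gt_tactile / tactile_gt_pain
    region_ids: list[int]
    mean_courses: dict = field(default_factory=dict)


def analysis3(subjects: list[SubjectDataset], parcellation: Parcellation,
              cfg: PermConfig = PermConfig(),
              window: TimecourseWindow = TimecourseWindow(),
              tolerance: float = 0.5,
              remove_template: bool = True) -> Analysis3Result:
    """Region-wise model-free comparison of intensity-matched pain vs touch.

    Per subject and region the AUC of the matched-pain and matched-tactile
    trial-mean courses (rating template removed) is computed; AUCs are then
    compared across subjects with a paired sign-flip test, max-statistic
    FWE-corrected across regions, in both directions.
    """
    region_ids = list(parcellation.region_ids)
    rows = []
    auc_pain = np.full((len(subjects), len(region_ids)), np.nan)
    auc_tact = np.full_like(auc_pain, np.nan)
    for si, subj in enumerate(subjects):
        mres = match_trials(subj.events, tolerance)
        pain_ids = {p for p, _, _ in mres.pairs}
        tact_ids = {t for _, t, _ in mres.pairs}
        groups = {"pain": pain_ids, "tactile": tact_ids}
        mc = _subject_region_mean_courses(subj, parcellation, window, groups,
                                          remove_template)
        tr = subj.tr
        for ri, rid in enumerate(region_ids):
            for cond, store in (("pain", auc_pain), ("tactile", auc_tact)):
                if cond in mc[rid]:
                    val = compute_auc(mc[rid][cond], window, tr)
                    store[si, ri] = val
                    rows.append({"subject": subj.subject_id, "region": rid,
                                 "condition": cond, "auc": val})
    ok = ~(np.isnan(auc_pain).any(axis=1) | np.isnan(auc_tact).any(axis=1))
    if ok.sum() < len(subjects):
        logger.info("analysis3: excluded %d subject(s) with missing conditions",
                    int(len(subjects) - ok.sum()))
    results = {}
    from dataclasses import replace as _replace
    for name, tail, a, b in (("pain_gt_tactile", "greater", auc_pain, auc_tact),
                             ("tactile_gt_pain", "greater", auc_tact, auc_pain)):
        results[name] = paired_signflip(a[ok], b[ok], _replace(cfg, tail=tail),
                                        region_ids=region_ids)
    return Analysis3Result(auc_table=pd.DataFrame(rows), results=results,
                           region_ids=region_ids)


@dataclass
class Analysis4Result:
    auc_table: pd.DataFrame
    results: dict[str, PairedPermResult]  # pain_preferential / tactile_preferential


def analysis4(subjects: list[SubjectDataset], parcellation: Parcellation,
              pain_pref_regions: list[int], tactile_pref_regions: list[int],
              cfg: PermConfig = PermConfig(),
              window: TimecourseWindow = TimecourseWindow(),
              remove_template: bool = True) -> Analysis4Result:
    """Intensity-mismatch comparison in modality-preferential regions.

    Per subject, all stimuli are pooled and median-split into high/low
    perceived intensity (median ties dropped), and the compared groups are
    count-equalized by removing trials nearest the median from the larger
    group. Pain-preferential regions compare low-intensity pain vs
    high-intensity touch; tactile-preferential regions compare low-intensity
    touch vs high-intensity pain. Subjects with an empty group are excluded
    for that comparison.
    """
    sub_parc = {
        "pain_preferential": pain_pref_regions,
        "tactile_preferential": tactile_pref_regions,
    }
    rows = []
    results: dict[str, PairedPermResult] = {}
    for direction, rids in sub_parc.items():
        if not rids:
            continue
        pref_mod = "pain" if direction == "pain_preferential" else "tactile"
        other_mod = "tactile" if pref_mod == "pain" else "pain"
        cond_a = f"{pref_mod}_low"
        cond_b = f"{other_mod}_high"
        a_mat = np.full((len(subjects), len(rids)), np.nan)
        b_mat = np.full_like(a_mat, np.nan)
        for si, subj in enumerate(subjects):
            split = median_split(subj.events)
            low_pref = [e for e in subj.events
                        if e.modality == pref_mod and split.labels.get(e.trial_id) == "low"]
            high_other = [e for e in subj.events
                          if e.modality == other_mod and split.labels.get(e.trial_id) == "high"]
            low_pref, high_other = equalize_counts(low_pref, high_other,
                                                   split.pooled_median)
            if not low_pref or not high_other:
                logger.info("analysis4 (%s): subject %s excluded (empty split group)",
                            direction, subj.subject_id)
                continue
            groups = {cond_a: {e.trial_id for e in low_pref},
                      cond_b: {e.trial_id for e in high_other}}
            sub_p = Parcellation(
                labels=np.where(np.isin(parcellation.labels, rids),
                                parcellation.labels, 0).astype(np.int32),
                region_ids=tuple(rids))
            mc = _subject_region_mean_courses(subj, sub_p, window, groups,
                                              remove_template)
            tr = subj.tr
            for ri, rid in enumerate(rids):
                if cond_a in mc[rid]:
                    a_mat[si, ri] = compute_auc(mc[rid][cond_a], window, tr)
                    rows.append({"subject": subj.subject_id, "region": rid,
                                 "condition": cond_a, "auc": a_mat[si, ri]})
                if cond_b in mc[rid]:
                    b_mat[si, ri] = compute_auc(mc[rid][cond_b], window, tr)
                    rows.append({"subject": subj.subject_id, "region": rid,
                                 "condition": cond_b, "auc": b_mat[si, ri]})
        ok = ~(np.isnan(a_mat).any(axis=1) | np.isnan(b_mat).any(axis=1))
        if ok.sum() >= 2:
            from dataclasses import replace as _replace
            results[direction] = paired_signflip(a_mat[ok], b_mat[ok],
                                                 _replace(cfg, tail="two"),
                                                 region_ids=rids)
    return Analysis4Result(auc_table=pd.DataFrame(rows), results=results)
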