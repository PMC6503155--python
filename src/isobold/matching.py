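"""Perceived-intensity trial matching and the median-split labelling.

Matching pairs each painful trial with the tactile trial whose rating is
closest, provided the difference lies within the closed interval
[r - tol, r + tol] (tol = 0.5 on the 0-10 rating scale by default). Pairing
is greedy in chronological pain-trial order and one-to-one: a tactile trial
pairs at most once. The median split pools all ratings, labels trials
strictly above the pooled median "high" and strictly below "low" (ties at
the median are dropped), and count equalization removes trials nearest the
median from the larger group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EventTable, TrialEvent

__all__ = ["MatchResult", "SplitLabels", "match_trials", "median_split",
           "equalize_counts", "apply_match_labels"]


@dataclass
class MatchResult:
    pairs: list[tuple[str, str, float]]  # (pain_id, tactile_id, |delta rating|)
    unmatched_pain: list[str]
    unmatched_tactile: list[str]
    tolerance: float = 0.5

    @property
    def matched_ids(self) -> set[str]:
        out = set()
        for p, t, _ in self.pairs:
            out.add(p)
            out.add(t)
        return out

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class SplitLabels:
    labels: dict[str, str]  # trial_id -> high | low | dropped
    pooled_median: float
    counts: dict[tuple[str, str], int] = field(default_factory=dict)  # (modality, label) -> n


def match_trials(events: EventTable, tolerance: float = 0.5) -> MatchResult:
    """Pair painful with tactile trials of near-equal perceived intensity.

    Pain trials are processed in ascending (session, onset) order; each is
    paired with the not-yet-paired tactile trial minimising |Δrating|,
    subject to |Δrating| <= tolerance (closed interval). Ties go to the
    earliest tactile onset. Pain trials with no candidate stay unmatched.
    """
    if tolerance < 0:
        raise ValueError(f"tolerance must be nonnegative, got {tolerance}")
    pain = events.by_modality("pain")  # EventTable keeps (session, onset) order
    tactile = events.by_modality("tactile")
    available = list(tactile)
    pairs: list[tuple[str, str, float]] = []
    unmatched_pain: list[str] = []
    for p in pain:
        best = None
        best_key = None
        for t in available:
            d = abs(t.rating - p.rating)
            if d > tolerance:
                continue
            key = (d, t.session, t.stim_onset_s)
            if best is None or key < best_key:
                best, best_key = t, key
        if best is None:
            unmatched_pain.append(p.trial_id)
        else:
            pairs.append((p.trial_id, best.trial_id, float(best_key[0])))
            available.remove(best)
    return MatchResult(
        pairs=pairs,
        unmatched_pain=unmatched_pain,
        unmatched_tactile=[t.trial_id for t in available],
        tolerance=tolerance,
    )


def apply_match_labels(events: EventTable, result: MatchResult) -> EventTable:
    """Return a copy of ``events`` with matched/pair_id slots filled."""
    out = events.copy()
    pair_of = {}
    for i, (p, t, _) in enumerate(result.pairs):
        pair_of[p] = f"pair{i + 1:02d}"
        pair_of[t] = f"pair{i + 1:02d}"
    for e in out.events:
        e.matched = e.trial_id in pair_of
        e.pair_id = pair_of.get(e.trial_id)
    return out


def median_split(events: EventTable) -> SplitLabels:
    """Pool all ratings, label strictly above the median high, strictly
    below low; trials rating exactly the median are dropped."""
    rated = [e for e in events if e.rating is not None]
    if len(rated) < 2:
        raise ValueError("median split needs at least 2 rated stimuli")
    med = float(np.median([e.rating for e in rated]))
    labels: dict[str, str] = {}
    counts: dict[tuple[str, str], int] = {}
    for e in rated:
        if e.rating > med:
            lab = "high"
        elif e.rating < med:
            lab = "low"
        else:
            lab = "dropped"
        labels[e.trial_id] = lab
        counts[(e.modality, lab)] = counts.get((e.modality, lab), 0) + 1
    return SplitLabels(labels=labels, pooled_median=med, counts=counts)


def equalize_counts(group_a: list[TrialEvent], group_b: list[TrialEvent],
                    median: float) -> tuple[list[TrialEvent], list[TrialEvent]]:
    """Equalize group sizes by removing, from the larger group, the trials
    whose ratings are nearest the pooled median (ties: earliest onset
    removed first). The smaller group is untouched."""
    a, b = list(group_a), list(group_b)
    if len(a) == len(b):
        return a, b
    big, small = (a, b) if len(a) > len(b) else (b, a)
    n_drop = len(big) - len(small)
    order = sorted(big, key=lambda e: (abs(e.rating - median), e.session, e.stim_onset_s))
    drop_ids = {e.trial_id for e in order[:n_drop]}
    big_kept = [e for e in big if e.trial_id not in drop_ids]
    if len(a) > len(b):
        return big_kept, small
    return small, big_kept


def apply_split_labels(events: EventTable, split: SplitLabels) -> EventTable:
    out = events.copy()
    for e in out.events:
        e.split = split.labels.get(e.trial_id)
    return out
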