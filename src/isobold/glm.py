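"""First-level GLM: canonical HRF, design matrices, per-voxel OLS, contrasts.

Two designs are provided. The five-condition design models matched painful,
matched tactile, remaining painful, remaining tactile stimuli and the rating
period, each with a temporal derivative, per session. The parametric design
collapses all stimuli into one regressor with a perceived-intensity
modulator (mean-centered ratings per session). Both add six motion
covariates, a discrete-cosine high-pass drift set (1/128 Hz cut-off by
default) and a per-session mean.

Event regressors are built at microtime resolution (16 bins per TR by
default), convolved with the canonical double-gamma HRF and sampled at the
middle microtime bin of each scan.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import Volume4D

logger = logging.getLogger(__name__)

__all__ = [
    "HRFSpec",
    "DesignMatrix",
    "GLMFit",
    "StatMap",
    "canonical_hrf",
    "sample_regressor",
    "dct_drift_basis",
    "build_design_5cond",
    "build_design_parametric",
    "fit_glm",
    "contrast_map",
    "FIVE_CONDITIONS",
]

FIVE_CONDITIONS = (
    "matched_pain",
    "matched_tactile",
    "remaining_pain",
    "remaining_tactile",
    "rating_period",
)


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma hemodynamic response function parameters.

    The kernel is ``g(t; peak) - undershoot_ratio * g(t; undershoot)`` with
    gamma densities of shape delay/dispersion and scale dispersion, sampled
    over ``kernel_length_s`` and rescaled to peak 1.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel_length_s: float = 32.0
    microtime_bins_per_tr: int = 16
    microtime_onset_bin: int = 8

    def __post_init__(self) -> None:
        for name in ("peak_delay_s", "undershoot_delay_s", "peak_dispersion",
                     "undershoot_dispersion", "kernel_length_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.microtime_bins_per_tr < 1:
            raise ValueError("microtime_bins_per_tr must be >= 1")


def canonical_hrf(spec: HRFSpec = HRFSpec(), dt: float = 0.05) -> np.ndarray:
    """Sample the double-gamma HRF at step ``dt`` seconds, peak-normalised."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    t = np.arange(0.0, spec.kernel_length_s + dt / 2, dt)
    peak = stats.gamma.pdf(t, a=spec.peak_delay_s / spec.peak_dispersion,
                           scale=spec.peak_dispersion)
    under = stats.gamma.pdf(t, a=spec.undershoot_delay_s / spec.undershoot_dispersion,
                            scale=spec.undershoot_dispersion)
    h = peak - spec.undershoot_ratio * under
    return h / np.max(h)


def sample_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    n_scans: int,
    tr: float,
    spec: HRFSpec = HRFSpec(),
    derivative: bool = False,
) -> np.ndarray:
    """HRF-convolved regressor sampled at scan times.

    Neural activity is a sum of boxcars (height = amplitude, length =
    duration); zero-duration events are unit-area impulses scaled by their
    amplitude, so an isolated impulse of amplitude A peaks at A. The
    convolution integral is evaluated on a microtime grid of
    ``spec.microtime_bins_per_tr`` bins per TR and sampled at bin
    ``spec.microtime_onset_bin`` of each scan. With ``derivative=True`` the
    kernel's finite-difference time derivative is used instead.
    """
    bins = spec.microtime_bins_per_tr
    dt = tr / bins
    n_fine = n_scans * bins
    u = np.zeros(n_fine)
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.broadcast_to(np.atleast_1d(np.asarray(durations, dtype=float)),
                                onsets.shape)
    amplitudes = np.broadcast_to(np.atleast_1d(np.asarray(amplitudes, dtype=float)),
                                 onsets.shape)
    for o, d, a in zip(onsets, durations, amplitudes):
        i0 = int(round(o / dt))
        if i0 >= n_fine or i0 < 0:
            continue
        if d <= 0:
            u[i0] += a / dt  # unit-area impulse
        else:
            i1 = min(int(round((o + d) / dt)), n_fine)
            u[i0:i1] += a
    h = canonical_hrf(spec, dt)
    if derivative:
        h = np.gradient(h, dt)
    from scipy.signal import fftconvolve
    x_fine = fftconvolve(u, h)[:n_fine] * dt
    idx = np.arange(n_scans) * bins + min(spec.microtime_onset_bin, bins - 1)
    return x_fine[idx]


def dct_drift_basis(n_scans: int, tr: float, hp_cutoff_s: float) -> np.ndarray:
    """Discrete-cosine high-pass drift columns for periods above the cut-off.

    K = floor(2 * n_scans * tr / hp_cutoff_s) orthonormal DCT-II columns
    (k = 1..K, the constant term excluded).
    """
    if hp_cutoff_s <= 0:
        return np.zeros((n_scans, 0))
    n_k = int(np.floor(2.0 * n_scans * tr / hp_cutoff_s))
    i = np.arange(n_scans)
    cols = [np.sqrt(2.0 / n_scans) * np.cos(np.pi * k * (2 * i + 1) / (2 * n_scans))
            for k in range(1, n_k + 1)]
    return np.column_stack(cols) if cols else np.zeros((n_scans, 0))


@dataclass
class DesignMatrix:
    """T_total x K design with per-column bookkeeping."""

    matrix: np.ndarray
    column_names: list[str]
    session_of_column: list[int]
    column_kind: list[str]  # condition | derivative | modulator | nuisance | drift | session_mean
    session_rows: dict[int, tuple[int, int]]  # session -> (row_start, row_stop)
    tr: float
    omitted_conditions: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("design matrix contains non-finite entries")
        k = self.matrix.shape[1]
        if not (len(self.column_names) == len(self.session_of_column)
                == len(self.column_kind) == k):
            raise ValueError("column bookkeeping length mismatch")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def columns_named(self, base_name: str, kind: str | None = None) -> list[int]:
        """Indices of columns whose name is ``base_name`` (any session)."""
        out = []
        for j, (nm, kd) in enumerate(zip(self.column_names, self.column_kind)):
            if nm == base_name and (kind is None or kd == kind):
                out.append(j)
        return out

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        """Build a K-vector from per-condition weights, averaged over sessions.

        Weights address canonical condition/modulator columns by base name;
        a weight naming an omitted condition raises ``ValueError``.
        """
        w = np.zeros(self.n_columns)
        omitted_names = {nm for _, nm in self.omitted_conditions}
        for name, weight in weights.items():
            if weight == 0:
                continue
            idx = [j for j in self.columns_named(name)
                   if self.column_kind[j] in ("condition", "modulator")]
            if not idx:
                if name in omitted_names:
                    raise ValueError(
                        f"contrast touches omitted condition {name!r} "
                        f"(omitted in sessions {[s for s, nm in self.omitted_conditions if nm == name]})"
                    )
                raise ValueError(f"unknown condition {name!r}")
            for j in idx:
                w[j] += weight / len(idx)
        return w


def _session_design_block(
    condition_events: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    n_scans: int,
    tr: float,
    motion: np.ndarray,
    hp_cutoff_s: float,
    session: int,
    spec: HRFSpec,
    modulator_events: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
    with_derivatives: bool = True,
):
    """Columns for one session; returns (matrix, names, kinds, omitted)."""
    cols, names, kinds = [], [], []
    omitted: list[str] = []
    for name, (onsets, durs, amps) in condition_events.items():
        if len(onsets) == 0:
            logger.warning("session %d: condition %r has no events; column omitted",
                           session, name)
            omitted.append(name)
            continue
        cols.append(sample_regressor(onsets, durs, amps, n_scans, tr, spec))
        names.append(name)
        kinds.append("condition")
        if with_derivatives:
            cols.append(sample_regressor(onsets, durs, amps, n_scans, tr, spec,
                                         derivative=True))
            names.append(name + "_deriv")
            kinds.append("derivative")
    for name, (onsets, durs, amps) in (modulator_events or {}).items():
        if len(onsets) == 0 or np.allclose(amps, 0.0):
            logger.warning("session %d: modulator %r is degenerate; column omitted",
                           session, name)
            omitted.append(name)
            continue
        cols.append(sample_regressor(onsets, durs, amps, n_scans, tr, spec))
        names.append(name)
        kinds.append("modulator")
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (n_scans, 6):
        raise ValueError(f"session {session}: motion shape {motion.shape} != ({n_scans}, 6)")
    for j in range(6):
        cols.append(motion[:, j])
        names.append(f"motion{j + 1}")
        kinds.append("nuisance")
    drift = dct_drift_basis(n_scans, tr, hp_cutoff_s)
    for j in range(drift.shape[1]):
        cols.append(drift[:, j])
        names.append(f"drift{j + 1}")
        kinds.append("drift")
    cols.append(np.ones(n_scans))
    names.append("session_mean")
    kinds.append("session_mean")
    return np.column_stack(cols), names, kinds, omitted


def _assemble(blocks, sessions, tr):
    """Block-diagonal assembly of per-session column sets."""
    total_rows = sum(b[0].shape[0] for b in blocks)
    total_cols = sum(b[0].shape[1] for b in blocks)
    mat = np.zeros((total_rows, total_cols))
    names, kinds, sess_of, omitted = [], [], [], []
    session_rows = {}
    r0 = c0 = 0
    for (block, bnames, bkinds, bomit), ses in zip(blocks, sessions):
        r1, c1 = r0 + block.shape[0], c0 + block.shape[1]
        mat[r0:r1, c0:c1] = block
        names.extend(bnames)
        kinds.extend(bkinds)
        sess_of.extend([ses] * block.shape[1])
        omitted.extend((ses, nm) for nm in bomit)
        session_rows[ses] = (r0, r1)
        r0, c0 = r1, c1
    return DesignMatrix(mat, names, sess_of, kinds, session_rows, tr,
                        omitted_conditions=omitted)


def build_design_5cond(
    events,
    match_result,
    n_scans: dict[int, int],
    tr: float,
    motion: dict[int, np.ndarray],
    hp_cutoff_s: float = 128.0,
    spec: HRFSpec = HRFSpec(),
    stim_duration_s: float = 0.0,
) -> DesignMatrix:
    """Five-condition design: matched/remaining pain and tactile stimuli
    (impulses) and the rating period (boxcars), plus derivatives, motion,
    drift and session means, per session."""
    matched_ids = set()
    for pain_id, tact_id, _ in match_result.pairs:
        matched_ids.add(pain_id)
        matched_ids.add(tact_id)
    blocks = []
    sessions = sorted(n_scans)
    for ses in sessions:
        sev = events.session_events(ses)
        def _sel(pred):
            ons = np.array([e.stim_onset_s for e in sev if pred(e)])
            return ons, np.full_like(ons, stim_duration_s), np.ones_like(ons)
        cond = {
            "matched_pain": _sel(lambda e: e.modality == "pain" and e.trial_id in matched_ids),
            "matched_tactile": _sel(lambda e: e.modality == "tactile" and e.trial_id in matched_ids),
            "remaining_pain": _sel(lambda e: e.modality == "pain" and e.trial_id not in matched_ids),
            "remaining_tactile": _sel(lambda e: e.modality == "tactile" and e.trial_id not in matched_ids),
        }
        r_ons = np.array([e.rating_onset_s for e in sev])
        r_dur = np.array([e.rating_duration_s for e in sev])
        cond["rating_period"] = (r_ons, r_dur, np.ones_like(r_ons))
        blocks.append(_session_design_block(cond, n_scans[ses], tr, motion[ses],
                                            hp_cutoff_s, ses, spec))
    return _assemble(blocks, sessions, tr)


def build_design_parametric(
    events,
    n_scans: dict[int, int],
    tr: float,
    motion: dict[int, np.ndarray],
    hp_cutoff_s: float = 128.0,
    spec: HRFSpec = HRFSpec(),
    stim_duration_s: float = 0.0,
) -> DesignMatrix:
    """Parametric-intensity design: one all-stimuli regressor, one modulator
    whose impulse heights are the session-mean-centered ratings, and the
    rating period, per session, plus nuisance/drift/mean columns."""
    blocks = []
    sessions = sorted(n_scans)
    for ses in sessions:
        sev = events.session_events(ses)
        ons = np.array([e.stim_onset_s for e in sev])
        durs = np.full_like(ons, stim_duration_s)
        ratings = np.array([e.rating for e in sev])
        centered = ratings - ratings.mean() if len(ratings) else ratings
        r_ons = np.array([e.rating_onset_s for e in sev])
        r_dur = np.array([e.rating_duration_s for e in sev])
        cond = {
            "all_stimuli": (ons, durs, np.ones_like(ons)),
            "rating_period": (r_ons, r_dur, np.ones_like(r_ons)),
        }
        mod = {"intensity_modulator": (ons, durs, centered)}
        blocks.append(_session_design_block(cond, n_scans[ses], tr, motion[ses],
                                            hp_cutoff_s, ses, spec,
                                            modulator_events=mod))
    return _assemble(blocks, sessions, tr)


@dataclass
class GLMFit:
    """Per-voxel OLS fit: betas (K x V), residual variances and DoF."""

    beta: np.ndarray
    sigma2: np.ndarray
    dof: int
    design: DesignMatrix
    xtx_pinv: np.ndarray
    mask: np.ndarray
    rank: int


@dataclass
class StatMap:
    """A 3-D statistic image: effect (contrast-of-beta) or t units."""

    values: np.ndarray
    kind: str  # effect | t
    contrast_weights: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("effect", "t"):
            raise ValueError(f"kind must be 'effect' or 't', got {self.kind!r}")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite statistic inside mask")


def fit_glm(bold: Volume4D, design: DesignMatrix) -> GLMFit:
    """Per-voxel ordinary least squares via SVD (pseudoinverse if rank-deficient)."""
    if design.n_rows != bold.n_scans:
        raise ValueError(
            f"design has {design.n_rows} rows but BOLD has {bold.n_scans} scans"
        )
    if not np.any(bold.mask):
        raise ValueError("empty mask")
    y = bold.masked_timeseries()  # (T, V)
    x = design.matrix
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = s.max() * max(x.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if rank < x.shape[1]:
        logger.warning("design is rank-deficient (rank %d < %d columns); "
                       "using pseudoinverse", rank, x.shape[1])
    dof = x.shape[0] - rank
    if dof <= 0:
        raise ValueError(f"non-positive degrees of freedom ({dof})")
    s_inv = np.where(s > tol, 1.0 / s, 0.0)
    pinv = (vt.T * s_inv) @ u.T
    beta = pinv @ y
    resid = y - x @ beta
    sigma2 = np.einsum("tv,tv->v", resid, resid) / dof
    xtx_pinv = (vt.T * s_inv**2) @ vt
    return GLMFit(beta=beta, sigma2=sigma2, dof=dof, design=design,
                  xtx_pinv=xtx_pinv, mask=bold.mask.copy(), rank=rank)


def contrast_map(fit: GLMFit, weights, kind: str = "effect") -> StatMap:
    """Contrast image: effect = w'beta; t = effect / sqrt(sigma2 w'(X'X)^+ w).

    ``weights`` is either a K-vector or a dict of per-condition weights
    resolved via :meth:`DesignMatrix.contrast_vector` (session-averaged).
    """
    if isinstance(weights, dict):
        w = fit.design.contrast_vector(weights)
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (fit.design.n_columns,):
        raise ValueError(f"weight length {w.shape} != K ({fit.design.n_columns})")
    if np.allclose(w, 0.0):
        raise ValueError("contrast weights are all zero")
    effect = w @ fit.beta  # (V,)
    if kind == "effect":
        vals = effect
    elif kind == "t":
        var_w = float(w @ fit.xtx_pinv @ w)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = effect / np.sqrt(fit.sigma2 * var_w)
        vals = np.where(np.isfinite(vals), vals, 0.0)
    else:
        raise ValueError(f"kind must be 'effect' or 't', got {kind!r}")
    grid = np.zeros(fit.mask.shape)
    grid[fit.mask] = vals
    return StatMap(values=grid, kind=kind, contrast_weights=w, mask=fit.mask.copy())
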