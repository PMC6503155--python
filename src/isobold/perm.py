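"""Second-level nonparametric inference by sign-flip permutation.

One-sample tests on subject effect maps generate their null by randomly
negating whole subject maps (valid under symmetric errors); family-wise
error is controlled with the max-statistic distribution, either over voxels
(voxel-level FWE) or over suprathreshold cluster sizes (cluster-level FWE
with a cluster-defining threshold, p < 0.001 one-tailed by default). The
same machinery gives paired tests across regions via sign flips of the
paired differences. p-values use the (b + 1)/(m + 1) estimator, which
includes the observed statistic and is never smaller than 1/(n_perm + 1).
When 2^n_subjects <= n_perm (and n <= 12) all sign assignments are
enumerated exactly instead of sampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "PermConfig",
    "VoxelFWEResult",
    "ClusterFWEResult",
    "PairedPermResult",
    "one_sample_signflip",
    "cluster_signflip",
    "paired_signflip",
    "union_mask",
    "conjunction",
]


@dataclass(frozen=True)
class PermConfig:
    n_perm: int = 5000
    seed: int = 0
    alpha: float = 0.05
    cdt_p: float = 0.001
    connectivity: int = 18  # 6 faces | 18 +edges | 26 +corners
    tail: str = "two"       # two | greater | less
    exhaustive: bool | None = None  # None = automatic when 2^n <= n_perm

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.cdt_p < 1:
            raise ValueError("cdt_p must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.tail not in ("two", "greater", "less"):
            raise ValueError("tail must be 'two', 'greater' or 'less'")


@dataclass
class VoxelFWEResult:
    observed_t: np.ndarray    # 3-D grid, 0 outside mask
    p_fwe: np.ndarray         # 3-D grid, 1 outside mask
    threshold_t: float        # (1 - alpha) quantile of the max-stat null
    sig_mask: np.ndarray
    mask: np.ndarray
    n_perm: int
    exhaustive: bool


@dataclass
class ClusterFWEResult:
    table: list[dict]         # id, size, peak_t, peak_voxel, p_fwe
    cluster_map: np.ndarray   # labeled 3-D grid (0 = no cluster)
    cdt_t: float
    observed_t: np.ndarray
    mask: np.ndarray
    n_perm: int

    def significant(self, alpha: float = 0.05) -> list[dict]:
        return [row for row in self.table if row["p_fwe"] <= alpha]


@dataclass
class PairedPermResult:
    region_ids: list
    mean_diff: np.ndarray
    t: np.ndarray
    p_fwe: np.ndarray
    n_perm: int
    tail: str

    def significant(self, alpha: float = 0.05) -> list:
        return [r for r, p in zip(self.region_ids, self.p_fwe) if p <= alpha]


def _sign_matrix(n_subjects: int, cfg: PermConfig) -> tuple[np.ndarray, bool]:
    """Sign assignments (n_perm x n_subjects); exhaustive when feasible.

    The identity assignment is always the first row of the exhaustive set,
    so the observed statistic is a member of the enumerated null.
    """
    auto = n_subjects <= 12 and 2**n_subjects <= cfg.n_perm
    use_exhaustive = auto if cfg.exhaustive is None else cfg.exhaustive
    if use_exhaustive:
        if n_subjects > 20:
            raise ValueError("exhaustive enumeration infeasible for n > 20")
        bits = np.arange(2**n_subjects)[:, None] >> np.arange(n_subjects)[None, :]
        return 1.0 - 2.0 * (bits & 1), True
    rng = np.random.default_rng(cfg.seed)
    signs = rng.choice([-1.0, 1.0], size=(cfg.n_perm, n_subjects))
    return signs, False


def _one_sample_t(x: np.ndarray) -> np.ndarray:
    """One-sample t per column of (n x V)."""
    n = x.shape[0]
    m = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def _flip_t(x: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t statistics for every sign assignment, vectorised.

    Sign flips leave sum(x^2) unchanged, so only the mean varies:
    t_p = m_p / sqrt((ss/n - m_p^2) / (n - 1) / n) with m_p = (S x)/n.
    """
    n = x.shape[0]
    ss = np.sum(x * x, axis=0)  # (V,)
    m = signs @ x / n           # (P, V)
    var = (ss[None, :] - n * m * m) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    return np.where(np.isfinite(t), t, 0.0)


def _tailed(t: np.ndarray, tail: str) -> np.ndarray:
    if tail == "two":
        return np.abs(t)
    if tail == "greater":
        return t
    return -t


def _stack_maps(maps, mask) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("empty mask")
    x = np.stack([np.asarray(m)[mask] for m in maps], axis=0)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values inside mask")
    return x


def one_sample_signflip(maps, mask, cfg: PermConfig = PermConfig()) -> VoxelFWEResult:
    """Voxel-level FWE one-sample test via the max-statistic sign-flip null.

    ``maps`` is a sequence of per-subject 3-D effect images on a common
    grid. p_fwe(v) = (1 + #{permutation maxima >= t(v)}) / (n_perm + 1).
    """
    mask = np.asarray(mask, dtype=bool)
    x = _stack_maps(maps, mask)
    signs, exhaustive = _sign_matrix(x.shape[0], cfg)
    t_obs = _tailed(_one_sample_t(x), cfg.tail)
    null_max = _tailed(_flip_t(x, signs), cfg.tail).max(axis=1)  # (P,)
    n_perm = len(signs)
    p = (1 + np.sum(null_max[None, :] >= t_obs[:, None], axis=1)) / (n_perm + 1)
    threshold_t = float(np.quantile(null_max, 1 - cfg.alpha))
    t_grid = np.zeros(mask.shape)
    t_grid[mask] = _one_sample_t(x)
    p_grid = np.ones(mask.shape)
    p_grid[mask] = p
    sig = np.zeros(mask.shape, dtype=bool)
    sig[mask] = p <= cfg.alpha
    return VoxelFWEResult(observed_t=t_grid, p_fwe=p_grid,
                          threshold_t=threshold_t, sig_mask=sig, mask=mask,
                          n_perm=n_perm, exhaustive=exhaustive)


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def _cluster_sizes(supra: np.ndarray, structure: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return np.zeros(0, dtype=int)
    return np.bincount(lab.ravel())[1:]


def cluster_signflip(maps, mask, cfg: PermConfig = PermConfig()) -> ClusterFWEResult:
    """Cluster-extent FWE: threshold t maps at the cluster-defining
    threshold, group suprathreshold voxels by ``cfg.connectivity``, and
    compare observed cluster sizes with the max-cluster-size null over
    sign flips."""
    mask = np.asarray(mask, dtype=bool)
    x = _stack_maps(maps, mask)
    n = x.shape[0]
    dof = n - 1
    if cfg.tail == "two":
        cdt_t = float(stats.t.ppf(1 - cfg.cdt_p / 2, dof))
    else:
        cdt_t = float(stats.t.ppf(1 - cfg.cdt_p, dof))
    structure = _structure(cfg.connectivity)
    signs, _ = _sign_matrix(n, cfg)
    n_perm = len(signs)

    t_obs_v = _one_sample_t(x)
    t_grid = np.zeros(mask.shape)
    t_grid[mask] = t_obs_v
    supra = np.zeros(mask.shape, dtype=bool)
    supra[mask] = _tailed(t_obs_v, cfg.tail) >= cdt_t
    lab, n_clust = ndimage.label(supra, structure=structure)

    # null: max cluster size per sign assignment
    null_max = np.zeros(n_perm, dtype=int)
    t_perm = _tailed(_flip_t(x, signs), cfg.tail)  # (P, V)
    grid = np.zeros(mask.shape)
    for p_i in range(n_perm):
        grid[mask] = t_perm[p_i]
        sizes = _cluster_sizes((grid >= cdt_t) & mask, structure)
        null_max[p_i] = sizes.max() if len(sizes) else 0

    table = []
    for cid in range(1, n_clust + 1):
        members = lab == cid
        size = int(members.sum())
        tvals = np.where(members, _tailed(t_grid, cfg.tail), -np.inf)
        peak_idx = np.unravel_index(np.argmax(tvals), tvals.shape)
        p_fwe = (1 + int(np.sum(null_max >= size))) / (n_perm + 1)
        table.append({
            "id": cid,
            "size": size,
            "peak_t": float(t_grid[peak_idx]),
            "peak_voxel": tuple(int(i) for i in peak_idx),
            "p_fwe": float(p_fwe),
        })
    table.sort(key=lambda r: (r["p_fwe"], -r["size"]))
    return ClusterFWEResult(table=table, cluster_map=lab, cdt_t=cdt_t,
                            observed_t=t_grid, mask=mask, n_perm=n_perm)


def paired_signflip(values_a: np.ndarray, values_b: np.ndarray,
                    cfg: PermConfig = PermConfig(),
                    region_ids=None) -> PairedPermResult:
    """Region-wise paired t-test with sign-flip max-|t| FWE correction.

    ``values_a``/``values_b`` are (n_subjects x n_regions) matrices of a
    summary statistic (e.g. AUC) under two conditions; the test is a
    one-sample test on d = a - b with the family-wise null taken as the
    max statistic across regions.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("need (n_subjects x n_regions) with >= 2 subjects")
    d = a - b
    if region_ids is None:
        region_ids = list(range(1, d.shape[1] + 1))
    signs, _ = _sign_matrix(d.shape[0], cfg)
    n_perm = len(signs)
    t_obs = _one_sample_t(d)
    stat_obs = _tailed(t_obs, cfg.tail)
    null_max = _tailed(_flip_t(d, signs), cfg.tail).max(axis=1)
    p = (1 + np.sum(null_max[None, :] >= stat_obs[:, None], axis=1)) / (n_perm + 1)
    return PairedPermResult(region_ids=list(region_ids), mean_diff=d.mean(axis=0),
                            t=t_obs, p_fwe=p, n_perm=n_perm, tail=cfg.tail)


def union_mask(map_a_sig: np.ndarray, map_b_sig: np.ndarray) -> np.ndarray:
    a = np.asarray(map_a_sig, dtype=bool)
    b = np.asarray(map_b_sig, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a | b


def conjunction(map_a_sig: np.ndarray, map_b_sig: np.ndarray) -> np.ndarray:
    a = np.asarray(map_a_sig, dtype=bool)
    b = np.asarray(map_b_sig, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a & b
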