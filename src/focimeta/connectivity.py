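"""Seed-to-voxel resting-state functional connectivity.

First level: the mean BOLD time course of a seed region is correlated
(Pearson) with every voxel's time course and the correlation map is
Fisher-z transformed.  Second level: per-subject z maps for two seeds (or
conditions) are compared with a voxel-wise paired t-test; clusters are
formed at an uncorrected voxel threshold and family-wise error over
clusters is controlled by sign-flip permutation of the subject difference
maps — exact for the paired design under exchangeability, with no
smoothness estimation.  Simple effects are one-sample t-tests against
zero, and their conjunction is the masked voxel-wise minimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import DatasetError, GridMismatchError, ROIError
from .grids import StatMap, VolumeGrid

__all__ = [
    "BoldRun",
    "SeedROI",
    "GroupResult",
    "seed_series",
    "correlation_map",
    "fisher_z",
    "paired_contrast",
    "one_sample_contrast",
    "conjunction_simple_effects",
]

Z_CLIP = 18.0  # keeps maps finite at r = +/-1
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class BoldRun:
    """One subject's preprocessed 4-D BOLD run: series shape = grid.shape + (T,)."""

    grid: VolumeGrid
    series: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        s = np.asarray(self.series, dtype=float)
        if s.shape[:3] != tuple(self.grid.shape):
            raise ValueError("series spatial shape does not match grid")
        if s.shape[-1] < 20:
            raise DatasetError("a BOLD run needs at least 20 volumes")
        if not np.all(np.isfinite(s)):
            raise DatasetError("non-finite values in BOLD series")
        self.series = s


@dataclass(frozen=True)
class SeedROI:
    """A seed region: a sphere (centre + radius, mm) or an explicit voxel set."""

    center: tuple[float, float, float] | None = None
    radius: float = 5.0
    voxels: tuple[tuple[int, int, int], ...] | None = None

    def voxel_indices(self, grid: VolumeGrid) -> np.ndarray:
        if self.voxels is not None:
            idx = np.asarray(self.voxels, dtype=int)
        else:
            if self.center is None:
                raise ROIError("seed needs a centre or an explicit voxel set")
            all_idx = np.argwhere(np.ones(grid.shape, dtype=bool))
            d = np.sqrt(((grid.voxel_to_mm(all_idx) - np.asarray(self.center)) ** 2).sum(axis=1))
            idx = all_idx[d <= self.radius]
        mask = grid.effective_mask()
        inside = [tuple(v) for v in idx if mask[tuple(v)]]
        if not inside:
            raise ROIError("seed region does not intersect the mask")
        return np.asarray(inside, dtype=int)


def seed_series(run: BoldRun, roi: SeedROI) -> np.ndarray:
    """Unweighted mean time course over the seed's voxels."""
    idx = roi.voxel_indices(run.grid)
    return run.series[tuple(idx.T)].mean(axis=0)


def correlation_map(run: BoldRun, seed: np.ndarray) -> StatMap:
    """Voxel-wise Pearson correlation with a seed time course.

    Constant voxels get r = 0; a zero-variance seed is an error.
    """
    seed = np.asarray(seed, dtype=float)
    s = seed - seed.mean()
    ss = np.sqrt((s**2).sum())
    if ss == 0:
        raise ValueError("seed time course has zero variance")
    x = run.series - run.series.mean(axis=-1, keepdims=True)
    xs = np.sqrt((x**2).sum(axis=-1))
    num = (x * s).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(xs > 0, num / (xs * ss), 0.0)
    r = np.clip(r, -1.0, 1.0)
    return StatMap(run.grid, r, "r")


def fisher_z(rmap: StatMap, z_max: float = Z_CLIP) -> StatMap:
    """Fisher transform z = atanh(r), clipped to |z| <= z_max."""
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(rmap.values, -1.0, 1.0))
    return rmap.with_values(np.clip(z, -z_max, z_max), "z")


@dataclass
class GroupResult:
    """Second-level outcome: t/p maps, corrected clusters, permutation null."""

    t_map: StatMap
    p_map: StatMap
    corrected: StatMap  # binary
    clusters: pd.DataFrame
    null_max_sizes: np.ndarray
    df: int
    voxel_p: float
    cluster_fwe: float


def _stack(maps: Sequence[StatMap]) -> tuple[VolumeGrid, np.ndarray]:
    grid = maps[0].grid
    for m in maps[1:]:
        grid.require_same(m.grid)
    return grid, np.stack([m.values for m in maps], axis=0)


def _one_sample_t(data: np.ndarray) -> np.ndarray:
    """Voxel-wise one-sample t across the leading (subject) axis."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def _cluster_sizes(sup: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    lab, n = ndimage.label(sup, structure=_STRUCT26)
    sizes = np.bincount(lab.ravel())[1:] if n else np.zeros(0, dtype=int)
    return lab, n, sizes


def _permutation_group(
    diffs: np.ndarray,
    grid: VolumeGrid,
    voxel_p: float,
    cluster_fwe: float,
    n_perm: int,
    seed: int,
) -> GroupResult:
    n = diffs.shape[0]
    dfree = n - 1
    mask = grid.effective_mask()
    t_obs = np.where(mask, _one_sample_t(diffs), 0.0)
    p_obs = np.where(mask, stats.t.sf(t_obs, dfree), 1.0)
    t_crit = stats.t.isf(voxel_p, dfree)

    lab, ncl, sizes = _cluster_sizes((t_obs > t_crit) & mask)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm, dtype=int)
    flat = diffs.reshape(n, -1)
    for it in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        t_perm = _one_sample_t((flat * signs[:, None]).reshape(diffs.shape))
        _, _, psz = _cluster_sizes((t_perm > t_crit) & mask)
        null_max[it] = psz.max() if psz.size else 0

    rows = []
    keep = np.zeros(grid.shape, dtype=bool)
    for comp in range(1, ncl + 1):
        size = int(sizes[comp - 1])
        p_cl = (1.0 + np.sum(null_max >= size)) / (n_perm + 1.0)
        sig = p_cl <= cluster_fwe
        if sig:
            keep |= lab == comp
        idx = np.argwhere(lab == comp)
        peak = idx[np.argmax(t_obs[tuple(idx.T)])]
        mmp = grid.voxel_to_mm(peak[None, :])[0]
        rows.append(
            {
                "cluster": comp,
                "size_vox": size,
                "volume_mm3": size * grid.voxel_volume,
                "p_fwe": p_cl,
                "significant": sig,
                "peak_t": float(t_obs[tuple(peak)]),
                "peak_x": mmp[0],
                "peak_y": mmp[1],
                "peak_z": mmp[2],
            }
        )
    cols = ["cluster", "size_vox", "volume_mm3", "p_fwe", "significant",
            "peak_t", "peak_x", "peak_y", "peak_z"]
    return GroupResult(
        t_map=StatMap(grid, t_obs, "t"),
        p_map=StatMap(grid, p_obs, "p"),
        corrected=StatMap(grid, keep.astype(float), "binary"),
        clusters=pd.DataFrame(rows, columns=cols),
        null_max_sizes=null_max,
        df=dfree,
        voxel_p=voxel_p,
        cluster_fwe=cluster_fwe,
    )


def paired_contrast(
    zmaps_a: Sequence[StatMap],
    zmaps_b: Sequence[StatMap],
    subjects_a: Sequence[str] | None = None,
    subjects_b: Sequence[str] | None = None,
    voxel_p: float = 0.001,
    cluster_fwe: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> GroupResult:
    """Voxel-wise paired t-test (a > b) with permutation cluster-FWE.

    Per-subject differences a_i - b_i are tested against zero; clusters are
    formed at the one-sided uncorrected ``voxel_p`` threshold and retained
    when their permutation cluster p-value (share of sign-flip max-cluster
    sizes at least as large, add-one corrected) is at most ``cluster_fwe``.
    """
    if len(zmaps_a) != len(zmaps_b):
        raise DatasetError("paired contrast needs the same subjects in both conditions")
    if len(zmaps_a) < 6:
        raise DatasetError("paired contrast needs at least 6 subjects")
    if subjects_a is not None and subjects_b is not None:
        if list(subjects_a) != list(subjects_b):
            raise DatasetError("subject lists differ between conditions")
    grid, a = _stack(list(zmaps_a))
    grid_b, b = _stack(list(zmaps_b))
    grid.require_same(grid_b)
    return _permutation_group(a - b, grid, voxel_p, cluster_fwe, n_perm, seed)


def one_sample_contrast(
    zmaps: Sequence[StatMap],
    voxel_p: float = 0.001,
    cluster_fwe: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> GroupResult:
    """One-sample (simple-effect) t-test against zero, permutation-corrected."""
    if len(zmaps) < 6:
        raise DatasetError("one-sample contrast needs at least 6 subjects")
    grid, data = _stack(list(zmaps))
    return _permutation_group(data, grid, voxel_p, cluster_fwe, n_perm, seed)


def conjunction_simple_effects(group_a: GroupResult, group_b: GroupResult) -> StatMap:
    """Minimum of the two simple-effect t maps, masked to both corrected maps.

    Non-zero only where *both* corrected (cluster-FWE surviving) maps are
    non-zero; the value there is the smaller of the two t statistics.
    """
    group_a.t_map.grid.require_same(group_b.t_map.grid)
    both = (group_a.corrected.values > 0) & (group_b.corrected.values > 0)
    tmin = np.minimum(group_a.t_map.values, group_b.t_map.values)
    return group_a.t_map.with_values(np.where(both, tmin, 0.0), "t")
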