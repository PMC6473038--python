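"""Activation likelihood estimation (ALE) with non-additive modeled activation.

Each experiment (study/contrast) contributes a *modeled activation* (MA)
map: every focus is smoothed with an isotropic 3-D Gaussian kernel and, in
the non-additive convention, overlapping kernels from the same experiment
combine by voxel-wise maximum, so one study never inflates the evidence at
a voxel by reporting many nearby peaks.  The ALE map is then the union
probability across experiments,

    ALE = 1 - prod_i (1 - MA_i),

the probability that at least one experiment activates the voxel.  Kernel
values are scaled as a proper 3-D density integrated per voxel (density x
voxel volume), so MA and ALE live in [0, 1).

Significance is assessed against a Monte-Carlo null in which every
experiment's foci are relocated uniformly at random within the mask;
voxel-wise p-values from the pooled empirical null feed a Benjamini-
Hochberg FDR step (the "pID" variant, valid under positive dependence),
followed by a cluster-extent threshold on 26-connected components.
Conjunction of two ALE analyses is the voxel-wise minimum image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .cluster import ClusterSolution
from .errors import DatasetError
from .grids import StatMap, VolumeGrid

__all__ = [
    "NullDistribution",
    "ma_map",
    "ale_union",
    "mc_null",
    "threshold_uncorrected",
    "threshold_fdr",
    "extent_threshold",
    "conjunction",
    "cluster_report",
    "intersect_with_clusters",
    "ale_conjunction_pipeline",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def ma_map(
    experiment_foci: Sequence[Sequence[float]],
    grid: VolumeGrid,
    fwhm_mm: float = 10.0,
) -> StatMap:
    """Modeled-activation map of one experiment (non-additive).

    Per voxel, the maximum over the experiment's foci of an isotropic
    Gaussian of the given FWHM centred at each focus, scaled as density x
    voxel volume.  Foci outside the grid raise a warning and contribute
    only the part of their kernel that intersects the grid.
    """
    foci = np.atleast_2d(np.asarray(experiment_foci, dtype=float))
    if foci.shape[0] < 1:
        raise DatasetError("an experiment needs at least one focus")
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma = fwhm_mm * _FWHM_TO_SIGMA
    peak = grid.voxel_volume / (2.0 * np.pi * sigma**2) ** 1.5
    support = 4.0 * sigma  # mm; kernel negligible beyond

    vs = grid.voxel_size
    values = np.zeros(grid.shape)
    shape = np.array(grid.shape)
    for f in foci:
        c = grid.mm_to_voxel(f)[0]
        if np.any(c < -0.5) or np.any(c > shape - 0.5):
            warnings.warn(
                f"focus {tuple(np.round(f, 1))} lies outside the grid; "
                "contribution clipped",
                stacklevel=2,
            )
        lo = np.maximum(np.floor(c - support / vs).astype(int), 0)
        hi = np.minimum(np.ceil(c + support / vs).astype(int) + 1, shape)
        if np.any(hi <= lo):
            continue
        ii, jj, kk = np.meshgrid(
            np.arange(lo[0], hi[0]),
            np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        d2 = np.sum((grid.voxel_to_mm(ijk) - f) ** 2, axis=1)
        contrib = peak * np.exp(-d2 / (2.0 * sigma**2))
        block = values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        np.maximum(block, contrib.reshape(block.shape), out=block)
    np.minimum(values, 1.0 - 1e-12, out=values)
    values[~grid.effective_mask()] = 0.0
    return StatMap(grid=grid, values=values, kind="MA")


def ale_union(ma_maps: Sequence[StatMap]) -> StatMap:
    """Union probability across experiments: ALE = 1 - prod(1 - MA)."""
    if len(ma_maps) == 0:
        raise DatasetError("ale_union needs at least one MA map")
    grid = ma_maps[0].grid
    log_comp = np.zeros(grid.shape)
    for m in ma_maps:
        grid.require_same(m.grid)
        log_comp += np.log1p(-m.values)
    return StatMap(grid=grid, values=-np.expm1(log_comp), kind="ALE")


@dataclass
class NullDistribution:
    """Pooled voxel-wise ALE values under uniform spatial randomization."""

    samples: np.ndarray  # sorted ascending
    n_iter: int
    seed: int
    foci_design: tuple[int, ...]  # per-experiment focus counts

    def sf(self, values: np.ndarray) -> np.ndarray:
        """Empirical upper-tail p-values, add-one corrected."""
        n = self.samples.size
        # count of null samples >= v
        ge = n - np.searchsorted(self.samples, values, side="left")
        return (ge + 1.0) / (n + 1.0)

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.samples, q))


def mc_null(
    foci_design: Sequence[int],
    grid: VolumeGrid,
    fwhm_mm: float = 10.0,
    n_iter: int = 500,
    seed: int = 0,
) -> NullDistribution:
    """Monte-Carlo spatial-randomization null for ALE.

    Each iteration relocates every experiment's foci uniformly at random
    among in-mask voxel centres, recomputes the ALE map, and pools the
    in-mask voxel values.  Deterministic given ``seed``.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be at least 100")
    mask = grid.effective_mask()
    mask_idx = np.argwhere(mask)
    if mask_idx.shape[0] == 0:
        raise DatasetError("empty mask")
    rng = np.random.default_rng(seed)
    pooled = np.empty((n_iter, int(mask.sum())))
    for it in range(n_iter):
        mas = []
        for n_f in foci_design:
            pick = mask_idx[rng.integers(0, mask_idx.shape[0], size=n_f)]
            mas.append(ma_map(grid.voxel_to_mm(pick), grid, fwhm_mm))
        ale = ale_union(mas)
        pooled[it] = ale.values[mask]
    samples = np.sort(pooled.ravel())
    return NullDistribution(
        samples=samples, n_iter=n_iter, seed=seed, foci_design=tuple(foci_design)
    )


def threshold_uncorrected(
    ale: StatMap, null: NullDistribution, p: float = 0.05
) -> tuple[StatMap, StatMap]:
    """Voxel-wise uncorrected threshold; returns (thresholded ALE, p map)."""
    pvals = null.sf(ale.values)
    keep = (pvals <= p) & ale.grid.effective_mask()
    out = np.where(keep, ale.values, 0.0)
    return ale.with_values(out, "ALE"), ale.with_values(pvals, "p")


def threshold_fdr(
    ale: StatMap, null: NullDistribution, q: float = 0.05
) -> tuple[StatMap, StatMap]:
    """FDR (pID) voxel threshold from the empirical null.

    Voxel p-values come from the null's pooled upper tail; the
    Benjamini-Hochberg step-up procedure (valid under positive dependence)
    is applied at level ``q`` within the mask.  Returns the binary map of
    surviving voxels and the per-voxel p map.  If nothing survives the
    result is simply empty.
    """
    from statsmodels.stats.multitest import multipletests

    mask = ale.grid.effective_mask()
    pvals = null.sf(ale.values)
    surviving = np.zeros(ale.grid.shape, dtype=bool)
    pm = pvals[mask]
    if pm.size:
        reject, _, _, _ = multipletests(pm, alpha=q, method="fdr_bh")
        surviving[mask] = reject
    return (
        ale.with_values(surviving.astype(float), "binary"),
        ale.with_values(np.where(mask, pvals, 1.0), "p"),
    )


def extent_threshold(
    binary: StatMap, min_volume_mm3: float = 300.0, connectivity: int = 26
) -> StatMap:
    """Drop connected components whose volume does not exceed the threshold.

    A component survives only if voxel_count * voxel_volume is strictly
    greater than ``min_volume_mm3``.  26-neighbour connectivity by default.
    """
    struct = _STRUCT26 if connectivity == 26 else ndimage.generate_binary_structure(3, 1)
    lab, n = ndimage.label(binary.values > 0, structure=struct)
    if n == 0:
        return binary.with_values(np.zeros(binary.grid.shape), "binary")
    counts = np.bincount(lab.ravel())
    vol = counts * binary.grid.voxel_volume
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = vol[1:] > min_volume_mm3
    return binary.with_values(keep[lab].astype(float), "binary")


def conjunction(map_a: StatMap, map_b: StatMap) -> StatMap:
    """Minimum-statistic conjunction image (voxel-wise minimum)."""
    map_a.grid.require_same(map_b.grid)
    return map_a.with_values(np.minimum(map_a.values, map_b.values))


def cluster_report(binary_or_stat: StatMap, ale: StatMap) -> pd.DataFrame:
    """Suprathreshold cluster table: volume, weighted centre, extrema.

    One row per 26-connected component of the (binarised) first map:
    volume in mm^3, the ALE-weighted centroid in mm, the maximum ALE value
    and its mm location.  Empty map -> empty table.
    """
    binary_or_stat.grid.require_same(ale.grid)
    grid = ale.grid
    lab, n = ndimage.label(binary_or_stat.values > 0, structure=_STRUCT26)
    rows = []
    for comp in range(1, n + 1):
        idx = np.argwhere(lab == comp)
        w = ale.values[tuple(idx.T)]
        mm = grid.voxel_to_mm(idx)
        if w.sum() > 0:
            centre = (mm * w[:, None]).sum(axis=0) / w.sum()
        else:
            centre = mm.mean(axis=0)
        imax = int(np.argmax(w))
        rows.append(
            {
                "cluster": comp,
                "volume_mm3": idx.shape[0] * grid.voxel_volume,
                "extrema_value": float(w[imax]),
                "wc_x": centre[0],
                "wc_y": centre[1],
                "wc_z": centre[2],
                "max_x": mm[imax, 0],
                "max_y": mm[imax, 1],
                "max_z": mm[imax, 2],
            }
        )
    cols = ["cluster", "volume_mm3", "extrema_value", "wc_x", "wc_y", "wc_z",
            "max_x", "max_y", "max_z"]
    return pd.DataFrame(rows, columns=cols)


def intersect_with_clusters(
    solution: ClusterSolution,
    validated: StatMap,
    radius_mm: float = 5.0,
) -> pd.Series:
    """Cross-validate HC clusters against a thresholded ALE map.

    A cluster is validated iff any surviving voxel centre lies within
    ``radius_mm`` of its centroid (default: the clustering resolution).
    Returns a boolean Series indexed by cluster id.
    """
    surv = np.argwhere(validated.values > 0)
    cents = solution.centroids()
    if surv.shape[0] == 0:
        return pd.Series(False, index=solution.summaries.index, name="validated")
    mm = validated.grid.voxel_to_mm(surv)
    flags = []
    for c in cents:
        d = np.sqrt(((mm - c) ** 2).sum(axis=1))
        flags.append(bool((d <= radius_mm).any()))
    return pd.Series(flags, index=solution.summaries.index, name="validated")


def ale_conjunction_pipeline(
    experiments_a: Mapping[object, np.ndarray],
    experiments_b: Mapping[object, np.ndarray],
    grid: VolumeGrid,
    fwhm_mm: float = 10.0,
    uncorr_p: float = 0.05,
    q: float = 0.05,
    min_volume_mm3: float = 300.0,
    n_iter: int = 500,
    seed: int = 0,
    order: str = "threshold_first",
) -> dict:
    """Two-dataset ALE conjunction analysis.

    Builds per-experiment MA maps and an ALE map for each dataset, applies
    the per-dataset uncorrected voxel threshold (p < ``uncorr_p``), forms
    the minimum-image conjunction, then applies FDR (pID) at ``q`` and the
    extent threshold to the conjunction.  ``order="min_first"`` instead
    forms the minimum image from the raw ALE maps before any thresholding.
    Returns a dict of intermediate and final maps plus the cluster table.
    """
    ss = np.random.SeedSequence(seed)
    s_a, s_b = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    out: dict = {}
    ales, nulls, ps = {}, {}, {}
    for tag, exps, s in (("a", experiments_a, s_a), ("b", experiments_b, s_b)):
        mas = [ma_map(foci, grid, fwhm_mm) for foci in exps.values()]
        ale = ale_union(mas)
        null = mc_null([len(f) for f in exps.values()], grid, fwhm_mm, n_iter, s)
        thr, pmap = threshold_uncorrected(ale, null, uncorr_p)
        ales[tag], nulls[tag], ps[tag] = ale, null, pmap
        out[f"ale_{tag}"] = ale
        out[f"ale_{tag}_thresholded"] = thr
        out[f"p_{tag}"] = pmap

    if order == "threshold_first":
        conj = conjunction(out["ale_a_thresholded"], out["ale_b_thresholded"])
    elif order == "min_first":
        conj = conjunction(ales["a"], ales["b"])
    else:
        raise ValueError(f"unknown order: {order!r}")
    out["conjunction"] = conj

    # conservative conjunction p-value: the larger of the two dataset p's,
    # restricted to voxels present in the minimum image
    pmax = np.maximum(ps["a"].values, ps["b"].values)
    pmax[conj.values <= 0] = 1.0
    from statsmodels.stats.multitest import multipletests

    mask = grid.effective_mask()
    surviving = np.zeros(grid.shape, dtype=bool)
    pm = pmax[mask]
    if pm.size:
        reject, _, _, _ = multipletests(pm, alpha=q, method="fdr_bh")
        surviving[mask] = reject
    binary = StatMap(grid, surviving.astype(float), "binary")
    binary = extent_threshold(binary, min_volume_mm3)
    out["binary"] = binary
    out["clusters"] = cluster_report(binary, conj)
    return out
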