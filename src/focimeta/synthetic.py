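"""Synthetic foci datasets and preprocessed BOLD runs with planted truth.

The generators emulate the statistical structure the analyses assume — not
real anatomy or scanner physics.  Foci are drawn from axis-aligned
Gaussian blobs (matching the per-axis-sd reporting convention of cluster
tables) around well-separated centres, optionally plus a diffuse uniform
background; with exact per-centre compositions the dataset-wide label
totals (and hence the priors) are reproduced on every seed.  BOLD runs are
generated "already preprocessed": a unit-variance Gaussian seed course,
planted regions correlated with it at a chosen rho, independent noise
elsewhere.  Everything is bit-reproducible given the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import BoldRun, SeedROI
from .foci import Focus, FociDataset
from .grids import VolumeGrid

__all__ = [
    "FociDesign",
    "BoldDesign",
    "PlantedRegion",
    "SyntheticTruth",
    "generate_foci",
    "generate_bold",
    "action_awareness_design",
]


@dataclass(frozen=True)
class FociDesign:
    """Blueprint for a synthetic foci dataset.

    ``centers``: (K, 3) blob centres in mm; ``spreads``: (K, 3) per-axis
    sd in mm; ``sizes``: foci per blob; ``mixtures``: (K, L) label mixture
    per blob over ``labels``; ``background_counts``: exact per-label counts
    of foci scattered uniformly in ``background_box``.
    """

    centers: tuple[tuple[float, float, float], ...]
    spreads: tuple[tuple[float, float, float], ...]
    sizes: tuple[int, ...]
    mixtures: tuple[tuple[float, ...], ...]
    labels: tuple[str, ...]
    background_counts: dict[str, int]
    enriched: tuple[bool, ...] | None = None  # which centres are planted signal
    #: exact per-centre label counts; when given they override random
    #: mixture draws, so dataset-wide totals are reproduced exactly
    compositions: tuple[tuple[int, ...], ...] | None = None
    background_box: tuple[tuple[float, float], ...] = (
        (-88.0, 88.0),
        (-100.0, 88.0),
        (-70.0, 104.0),
    )
    n_studies: int = 31
    n_contrasts: int = 34
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.centers)
        if not (len(self.spreads) == len(self.sizes) == len(self.mixtures) == k):
            raise ValueError("centers, spreads, sizes and mixtures must align")
        if any(s < 1 for s in self.sizes):
            raise ValueError("blob sizes must be >= 1")
        for mix in self.mixtures:
            if len(mix) != len(self.labels) or abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError("each mixture must sum to 1 over the label set")
        if any(c < 0 for c in self.background_counts.values()):
            raise ValueError("negative background count")
        if self.enriched is not None and len(self.enriched) != k:
            raise ValueError("enriched flags must align with centers")
        if self.compositions is not None:
            if len(self.compositions) != k:
                raise ValueError("compositions must align with centers")
            for comp, n in zip(self.compositions, self.sizes):
                if len(comp) != len(self.labels) or sum(comp) != n:
                    raise ValueError("each composition must sum to its blob size")

    @property
    def n_total(self) -> int:
        return sum(self.sizes) + sum(self.background_counts.values())


@dataclass(frozen=True)
class PlantedRegion:
    """A connected sphere of voxels correlated with the seed at strength rho."""

    center: tuple[float, float, float]
    radius: float
    rho: float

    def __post_init__(self) -> None:
        if not (-1.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (-1, 1)")


@dataclass(frozen=True)
class BoldDesign:
    """Blueprint for a group of synthetic preprocessed BOLD runs."""

    grid: VolumeGrid
    t_volumes: int = 212
    n_subjects: int = 32
    seed_roi: SeedROI = field(default_factory=lambda: SeedROI(center=(0.0, 0.0, 0.0)))
    planted: tuple[PlantedRegion, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_volumes < 20:
            raise ValueError("t_volumes must be >= 20")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators for recovery tests."""

    centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    enriched_labels: tuple[str, ...] = ()
    enriched_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    assignment: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    planted_mask: np.ndarray | None = None
    subject_seeds: tuple[int, ...] = ()

    def blob_members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == k)

    def enriched_centers(self) -> np.ndarray:
        return self.centers[self.enriched_mask]


def generate_foci(design: FociDesign) -> tuple[FociDataset, SyntheticTruth]:
    """Draw a labelled foci dataset from a design; deterministic given seed.

    Foci are drawn per centre from axis-aligned Gaussians and labelled from
    the centre's mixture; background foci are uniform in the background box
    with exactly the per-label counts of the design.  The combined list is
    shuffled, then study/contrast ids are assigned round-robin.  The truth
    records which centre (or -1 for background) produced each focus.
    """
    rng = np.random.default_rng(design.seed)
    coords: list[np.ndarray] = []
    labs: list[str] = []
    origin: list[int] = []
    for k, (c, s, n, mix) in enumerate(
        zip(design.centers, design.spreads, design.sizes, design.mixtures)
    ):
        pts = np.asarray(c) + rng.standard_normal((n, 3)) * np.asarray(s)
        if design.compositions is not None:
            blob_labels = [
                lab
                for lab, cnt in zip(design.labels, design.compositions[k])
                for _ in range(cnt)
            ]
            rng.shuffle(blob_labels)
            labs.extend(blob_labels)
        else:
            choice = rng.choice(len(design.labels), size=n, p=np.asarray(mix))
            labs.extend(design.labels[i] for i in choice)
        coords.append(pts)
        origin.extend([k] * n)
    n_bg = sum(design.background_counts.values())
    if n_bg:
        lo = np.array([b[0] for b in design.background_box])
        hi = np.array([b[1] for b in design.background_box])
        coords.append(lo + rng.random((n_bg, 3)) * (hi - lo))
        bg_labels = [
            lab for lab, cnt in design.background_counts.items() for _ in range(cnt)
        ]
        rng.shuffle(bg_labels)
        labs.extend(bg_labels)
        origin.extend([-1] * n_bg)
    xyz = np.vstack(coords)
    origin_arr = np.asarray(origin, dtype=int)

    perm = rng.permutation(xyz.shape[0])
    xyz = xyz[perm]
    labs = [labs[i] for i in perm]
    origin_arr = origin_arr[perm]

    # round-robin experiment bookkeeping: contrasts cycle, studies host them
    pairs = [
        (f"S{(j % design.n_studies) + 1:02d}", f"C{j + 1:02d}")
        for j in range(design.n_contrasts)
    ]
    foci = tuple(
        Focus(
            study_id=pairs[i % design.n_contrasts][0],
            contrast_id=pairs[i % design.n_contrasts][1],
            label=labs[i],
            coord=(float(x), float(y), float(z)),
            space="MNI",
        )
        for i, (x, y, z) in enumerate(xyz)
    )
    ds = FociDataset(foci, tuple(design.labels), provenance=f"synthetic seed={design.seed}")
    k = len(design.centers)
    mask = (
        np.asarray(design.enriched, dtype=bool)
        if design.enriched is not None
        else np.ones(k, dtype=bool)
    )
    truth = SyntheticTruth(
        centers=np.asarray(design.centers, dtype=float),
        enriched_labels=tuple(
            design.labels[int(np.argmax(mix))] for mix in design.mixtures
        ),
        enriched_mask=mask,
        assignment=origin_arr,
    )
    return ds, truth


def generate_bold(design: BoldDesign) -> tuple[list[BoldRun], SyntheticTruth]:
    """Generate per-subject preprocessed runs with planted connectivity.

    Each subject gets an independent child seed (spawned from the design
    seed).  Seed-ROI voxels carry the unit-variance Gaussian seed course
    verbatim; voxels of each planted region follow rho * seed +
    sqrt(1 - rho^2) * noise; everything else is independent noise scaled by
    ``noise_sd``.
    """
    grid = design.grid
    roi_idx = design.seed_roi.voxel_indices(grid)
    planted_mask = np.zeros(grid.shape, dtype=bool)
    rho_map = np.zeros(grid.shape)
    all_idx = np.argwhere(np.ones(grid.shape, dtype=bool))
    mm = grid.voxel_to_mm(all_idx)
    for region in design.planted:
        d = np.sqrt(((mm - np.asarray(region.center)) ** 2).sum(axis=1))
        sel = all_idx[d <= region.radius]
        planted_mask[tuple(sel.T)] = True
        rho_map[tuple(sel.T)] = region.rho
    planted_mask[tuple(roi_idx.T)] = False  # seed voxels carry the seed itself

    children = np.random.SeedSequence(design.seed).spawn(design.n_subjects)
    subject_seeds = tuple(int(c.generate_state(1)[0] % (2**31)) for c in children)
    runs: list[BoldRun] = []
    for si, child in enumerate(children):
        rng = np.random.default_rng(child)
        seed_ts = rng.standard_normal(design.t_volumes)
        noise = rng.standard_normal(grid.shape + (design.t_volumes,)) * design.noise_sd
        series = noise.copy()
        rho = rho_map[planted_mask][:, None]
        series[planted_mask] = rho * seed_ts + np.sqrt(1.0 - rho**2) * noise[planted_mask]
        series[tuple(roi_idx.T)] = seed_ts
        runs.append(BoldRun(grid=grid, series=series, subject_id=f"sub{si + 1:02d}"))
    truth = SyntheticTruth(planted_mask=planted_mask, subject_seeds=subject_seeds)
    return runs, truth


# --- the default, study-mimicking foci design ------------------------------

#: Nine well-separated blob centres (mm, MNI): five enriched for motor
#: intention, four for the sense of self-agency.  Locations loosely follow
#: the mesial-frontal / insular / parietal / occipital / cerebellar layout
#: of action-awareness clusters but are spaced >= 40 mm apart so that blob
#: recovery is a property of the method, not of chance overlap.
_INTENTION_CENTERS = (
    (0.0, 60.0, -15.0),    # ventromedial frontal / anterior cingulate
    (55.0, -5.0, 20.0),    # right anterior insular/opercular
    (-55.0, -75.0, 35.0),  # left superior parietal
    (-55.0, 60.0, 18.0),   # left middle frontal
    (55.0, 60.0, -45.0),   # right inferior frontal / temporal pole
)
_AGENCY_CENTERS = (
    (0.0, -5.0, 75.0),     # caudal mesial frontal (SMA-proper-like)
    (-55.0, -5.0, 20.0),   # left posterior insula
    (55.0, -75.0, 35.0),   # right occipito-parietal
    (10.0, -80.0, -35.0),  # cerebellum
)


def _scatter_sites(
    n_sites: int,
    rng: np.random.Generator,
    fixed: np.ndarray,
    box: tuple[tuple[float, float], ...],
    min_sep: float = 55.0,
    max_tries: int = 20000,
) -> np.ndarray:
    """Rejection-sample site centres >= min_sep from each other and ``fixed``."""
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    placed: list[np.ndarray] = []
    tries = 0
    sep = min_sep
    while len(placed) < n_sites:
        tries += 1
        if tries % 4000 == 0:  # jammed packing: relax gently rather than fail
            sep = max(sep - 2.0, 50.0)
        if tries > max_tries:
            raise RuntimeError("could not place clutter sites; relax min_sep")
        cand = lo + rng.random(3) * (hi - lo)
        others = np.vstack([fixed] + placed) if placed else fixed
        if np.min(np.sqrt(((others - cand) ** 2).sum(axis=1))) >= sep:
            placed.append(cand)
    return np.asarray(placed)


def action_awareness_design(seed: int = 0) -> FociDesign:
    """The default paper-scale design: 342 foci, 246 intention / 96 agency.

    Nine pure enriched blobs (five intention, four agency) at fixed,
    well-separated centres, with per-axis spreads in the 4-5 mm band
    observed for activation-peak clusters.  The remaining foci emulate the
    many non-significant clusters of such datasets: eleven small
    "clutter" sites (tight intention-only blobs whose composition is, by
    construction, never flaggable at alpha = 0.05) scattered at least
    55 mm from every other centre, plus ten diffuse uniform stragglers.
    Enriched blob sizes are chosen so a blob centroid estimates its centre
    to well under 3 mm (spread / sqrt(k)), giving the clustering +
    composition pipeline a recoverable ground truth.
    """
    labels = ("intention", "self_agency")
    int_sizes = (37, 37, 36, 36, 36)        # 182 enriched intention foci
    int_spreads = (4.0, 4.0, 4.1, 4.0, 4.2)
    ag_sizes = (22, 22, 22, 22)             # 88 enriched agency foci
    ag_spreads = (4.0, 4.0, 4.0, 4.0)
    # clutter sites: 8 intention + 1 agency foci each — a composition whose
    # enrichment tails stay above 0.05 even when two sites merge or a site
    # absorbs a couple of extra intention foci
    n_sites = 8
    site_mix = (8.0 / 9.0, 1.0 / 9.0)
    background: dict[str, int] = {}

    fixed = np.asarray(_INTENTION_CENTERS + _AGENCY_CENTERS)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51735]))
    box = ((-85.0, 85.0), (-100.0, 85.0), (-65.0, 100.0))
    sites = _scatter_sites(n_sites, rng, fixed, box, min_sep=62.0)

    centers = tuple(map(tuple, np.vstack([fixed, sites])))
    spreads = tuple(
        (s, s, s) for s in int_spreads + ag_spreads + (4.8,) * n_sites
    )
    sizes = int_sizes + ag_sizes + (9,) * n_sites
    mixtures = tuple([(1.0, 0.0)] * 5 + [(0.0, 1.0)] * 4 + [site_mix] * n_sites)
    compositions = tuple(
        [(n, 0) for n in int_sizes] + [(0, n) for n in ag_sizes] + [(8, 1)] * n_sites
    )
    enriched = tuple([True] * 9 + [False] * n_sites)
    return FociDesign(
        centers=centers,
        spreads=spreads,
        sizes=sizes,
        mixtures=mixtures,
        labels=labels,
        background_counts=background,
        enriched=enriched,
        compositions=compositions,
        seed=seed,
    )
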