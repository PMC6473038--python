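# Methods

## The model

The unit of analysis is an *activation focus*: a 3-D stereotactic
coordinate (mm, MNI) reported as a local maximum by a PET/fMRI study,
carrying a study id, a contrast id and a class label (here:
`intention`, `self_agency`, `external_agency`). The package treats foci
as exchangeable points; it does not model between-study dependence,
sample sizes, or effect magnitudes.

### Coordinate normalisation

Talairach-reported rows are converted at ingestion with the inverse of
the widely used piecewise-linear MNI→Talairach approximation: two linear
maps (superior/inferior of the axial plane) with no translation term, so
the origin is a fixed point and each halfspace is mapped injectively.
Inversion selects the halfspace by the sign of the *output* (MNI) z: the
superior inverse is tried first and the inferior one replaces it when
the result lands strictly below z = 0; a z = 0 tie resolves to the
superior map. Round-trip error is below 1e-6 mm over the brain volume.

### Ward clustering with a spatial-resolution cut

Clusters are grown by greedy agglomeration under Ward's criterion on
squared Euclidean distances: the cost of merging clusters A and B is the
increase in within-cluster sum of squares,
`|A||B|/(|A|+|B|) · ‖c_A − c_B‖²` (mm²). Ward linkage is reducible, so
the greedy sequence is monotone in cost. Exact cost ties (measure-zero
for real data) resolve to the smallest (left, right) creation-index
pair, making the sequence deterministic given input order.

The dendrogram is cut at a **spatial resolution**, default 5 mm: the
coarsest partition (fewest clusters) whose *mean over clusters* of the
per-cluster, per-axis sample standard deviation is at or below the
resolution on each axis separately. The all-singletons partition always
satisfies the constraint, so a cut exists. Per-axis sd uses the n−1
denominator and is defined as 0 for singletons — with that convention
the summary statistic reported for real datasets of this kind (mean sds
just under the 5-mm ceiling on each axis) is reproduced by construction.
A stricter variant (maximum over clusters instead of the mean) is
available via `criterion="max"`. The cut respects dendrogram structure
only; no post-hoc reassignment is performed.

### Cluster-composition inference

Let p be the proportion of a class in the whole dataset (the *prior*,
e.g. 246/342 and 96/342 for a 342-peak dataset split 246/96). For a
cluster holding x of n foci in that class, the one-sided exact binomial
upper tail `P(X ≥ x), X ~ Binomial(n, p)` is computed by direct
term-by-term summation of the pmf in log space (gammaln + logsumexp) —
no normal approximation, no continuity correction, no mid-p adjustment.
The one-sided convention is deliberate: it reproduces the printed
reference P-values (an all-intention cluster of 10 gives 0.037 → 0.04;
a 4-of-5 agency cluster gives 0.024 → 0.02), which a two-sided
convention cannot. A cluster is tagged *enriched* for the label with the
smallest tail when that tail ≤ α (default 0.05, per-cluster,
uncorrected — matching the per-cluster reporting convention); an exact
tie leaves the cluster unclassified. Benjamini–Hochberg correction
across clusters is available behind `correction="bh"`.

### ALE with non-additive modeled activation

Each experiment's foci are smoothed with an isotropic Gaussian kernel
(default FWHM 10 mm; the width is configurable and deliberately
documented rather than hidden — the sample-size-dependent empirical
kernel is out of scope). A focus's contribution at a voxel is the kernel
density times the voxel volume, so a modeled-activation (MA) value is a
small probability; with 10-mm FWHM and 2-mm voxels the central value is
≈ 0.0066, the same order as published ALE extrema (0.005–0.009).
Within one experiment overlapping kernels combine by voxel-wise
**maximum** (the non-additive convention), so duplicating a focus never
changes its MA map. Across experiments,
`ALE = 1 − Π_i (1 − MA_i)` — the probability that at least one
experiment activates the voxel; it dominates every MA map and is
permutation-invariant in experiment order.

Significance uses a Monte-Carlo null: each iteration relocates every
experiment's foci uniformly at random among in-mask voxel centres and
recomputes ALE; in-mask voxel values are pooled across iterations.
Voxel p-values are add-one-corrected empirical upper tails. Voxel-wise
FDR control uses the Benjamini–Hochberg step-up (the "pID" variant,
valid under positive dependence), followed by an extent threshold that
keeps 26-connected components whose volume strictly exceeds 300 mm³
(at 2-mm voxels a 37-voxel component — 296 mm³ — dies and a 38-voxel one
— 304 mm³ — survives). Conjunction of two analyses is the voxel-wise
minimum image. The default pipeline order applies each dataset's
uncorrected p < 0.05 threshold first, then the minimum image, then
FDR + extent on the conjunction (p-values for the conjunction are the
voxel-wise maximum of the two input p-maps, the conservative
minimum-statistic convention); `order="min_first"` forms the minimum
from raw ALE maps instead, since the published order is ambiguous.
HC clusters are cross-validated against a thresholded ALE map by
flagging clusters with any surviving voxel within 5 mm (the clustering
resolution) of their centroid.

### Seed-to-voxel connectivity

First level: the unweighted mean time course over a seed region (default
geometry: a 5-mm sphere around a cluster centroid) is Pearson-correlated
with every voxel's course; constant voxels get r = 0; maps are Fisher
transformed (z = atanh r) and clipped at |z| ≤ 18 so r = ±1 voxels stay
finite. Second level: voxel-wise paired t on per-subject difference
maps, clusters formed at a one-sided uncorrected threshold (default
p < 0.001), and cluster-level FWE control by sign-flip permutation: a
cluster is retained when `(1 + #{perm max-cluster-size ≥ observed}) /
(n_perm + 1) ≤ 0.05`. Sign flipping is exact for the paired design under
exchangeability and replaces random-field-theory correction, whose
smoothness estimation is an SPM internal not reproduced here. Simple
effects are the same machinery applied to one condition's maps;
their conjunction is the voxel-wise minimum of the two t maps masked to
voxels surviving both corrected maps.

## The synthetic-data generators

`action_awareness_design()` emulates the structure of a curated
two-class foci dataset at the published scale: 342 peaks, exactly 246
intention / 96 self-agency (exact per-centre compositions, so the priors
are reproduced on every seed), about 31 studies / 34 contrasts assigned
round-robin, and compact activation sites with per-axis spreads in the
4–5 mm band reported for such clusters.

Nine **enriched blobs** (five pure-intention of 36–37 foci, four
pure-self-agency of 22) sit at fixed centres spaced ≥ 62 mm apart;
blob sizes are set so a blob centroid estimates its centre to well
under 3 mm (spread/√k ≈ 0.7–0.9 mm per axis). The remaining mass is
eight **clutter sites** — tight blobs of 8 intention + 1 agency foci at
seed-dependent random locations ≥ 62 mm from every other centre. The
(8, 1) composition is chosen so that no single site, no pairwise union
of sites, and no site that absorbs a stray focus or two can reach a
0.05 enrichment tail: the non-enriched mass is non-flaggable by
construction, mirroring datasets where most clusters are unclassified.

Two deliberate departures from a naive emulation, made once at design
time: (1) the non-enriched mass is *clustered*, not uniform dust —
sparse uniform points form loose pairs whose per-axis spread (10–25 mm)
interacts badly with the mean-sd resolution cut, either splitting
genuine blobs or letting over-coarse cuts absorb distant points; real
foci datasets are themselves collections of compact sites, which is
what the generator models (a uniform background remains available via
`background_counts`). (2) Enriched blobs are larger and purer than the
published significant clusters (k up to 17 there), trading the observed
size range for identifiable ground truth: recovery failures should
indicate method defects, not unlucky sampling. Consequently, passing
recovery tests shows the pipeline finds well-separated enriched
structure at realistic spreads and class imbalance; it does not show
robustness to overlapping sites, focus-poor clusters, or
between-study correlation, none of which the generator produces.

`generate_bold()` emulates *already preprocessed* resting-state runs
(default 32 subjects, 212 volumes, matching the published acquisition
scale): seed-ROI voxels carry a unit-variance Gaussian seed course
verbatim, planted spherical regions follow `ρ·seed + √(1−ρ²)·noise`
(default ρ = 0.6), and everything else is independent Gaussian noise.
No autocorrelation, drift, motion or physiological structure is
simulated, so calibration results speak to the permutation machinery,
not to fMRI noise modelling.

## Numerical and scale choices

- Binomial tails: log-space summation is exact to ~1e-15; tails are
  clipped into [0, 1].
- Ward: O(n²) memory, O(n³/6) worst-case time via a full cost matrix —
  sized for datasets of hundreds of foci (342 points cluster in well
  under a second), not tens of thousands.
- ALE: kernels are evaluated on a ±4σ support cube; MA is capped below
  1. Default grids in examples/tests are desk-scale boxes (2–8 mm
  voxels); the full MNI bounding box at 2 mm
  ([−90, 90] × [−126, 90] × [−72, 108]) is the default for real use.
- Monte-Carlo nulls pool all in-mask voxel values across iterations
  (hundreds of iterations at desk scale); the empirical p-value is
  (r + 1)/(m + 1).
- Permutation tests use a few hundred sign-flip iterations in tests and
  default to 500–1000 in the CLI; seeds propagate from one run seed via
  `numpy.random.SeedSequence` spawning.
- Acceptance-scale simulation sizes (20 generator seeds for foci
  recovery, 40 null simulations for connectivity calibration) were
  chosen as the package's own desk-scale study conditions.

## Known limitations

- The empirical, sample-size-dependent ALE kernel and the analytic
  histogram null of the reference ALE implementation are not
  reproduced; the Monte-Carlo null is validated only by its own
  calibration properties.
- The mean-criterion resolution cut is a global constraint: a partition
  can satisfy it while containing one spatially wide cluster if many
  tight clusters pull the mean down. The `max` criterion avoids this at
  the cost of finer partitions.
- Foci are treated as independent draws; studies reporting many nearby
  peaks are partially handled by the non-additive MA convention but not
  by the clustering stage.
- The gray-matter mask of the reference implementations is not bundled;
  the default mask is the full bounding box, and user-supplied NIfTI
  masks are honoured.
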