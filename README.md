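# focimeta

Coordinate-based meta-analysis of neuroimaging activation foci, built for
the question of which brain regions are reported together across PET/fMRI
studies and whether those regional clusters are dominated by one class of
experiment (e.g. motor-intention vs sense-of-agency contrasts).

The package implements, as a tested library plus a thin CLI:

- **Foci handling** — delimited and Sleuth/GingerALE foci tables, with
  Talairach→MNI normalisation via the inverse of the standard
  piecewise-linear MNI→Talairach mapping.
- **Hierarchical clustering** — greedy Ward agglomeration on the squared
  Euclidean geometry of the peaks. The merge cost of clusters A, B is the
  within-cluster sum-of-squares increase
  `|A||B|/(|A|+|B|) · ‖c_A − c_B‖²` (mm²). The dendrogram is cut at a
  *spatial resolution* (default 5 mm): the coarsest partition whose mean
  per-cluster, per-axis standard deviation stays at or below the
  resolution on every axis.
- **Cluster-composition inference** — for a cluster with x of n foci in a
  class whose dataset-wide proportion is p, the one-sided exact binomial
  tail `P(X ≥ x), X ~ Binomial(n, p)` measures enrichment relative to the
  prior; clusters are tagged at α = 0.05.
- **ALE (activation likelihood estimation)** — non-additive modeled
  activation maps (within-experiment voxel-wise maximum of Gaussian focus
  kernels), union probability `ALE = 1 − Π(1 − MA_i)` across experiments,
  a seed-controlled Monte-Carlo spatial-randomisation null, FDR (pID =
  Benjamini–Hochberg) and cluster-extent thresholding, minimum-image
  conjunction, and intersection of HC clusters with thresholded ALE maps.
- **Seed-to-voxel resting-state connectivity** — Pearson correlation maps
  against a seed-region mean time course, Fisher z transform, paired
  t-tests with sign-flip permutation cluster-FWE correction, and
  minimum-statistic conjunction of simple effects.
- **Synthetic data** — generators for labelled foci datasets (planted
  enriched blobs plus non-enriched clutter) and preprocessed BOLD runs
  with planted seed-coupled regions, all bit-reproducible from a seed,
  with ground truth for recovery tests.

## Worked example

```python
from focimeta import (
    action_awareness_design, generate_foci, dataset_priors,
    ward_linkage, cut_at_resolution, summarize_clusters, composition_test,
)

ds, truth = generate_foci(action_awareness_design(seed=3))
priors = dataset_priors(ds)          # {'intention': 0.7193, 'self_agency': 0.2807}
merges = ward_linkage(ds.coords)
sol = summarize_clusters(cut_at_resolution(merges, ds.coords, 5.0), ds.labels)
res = composition_test(sol, priors, alpha=0.05)
print(res.classification[res.classification.enriched])
```

On this seed the dataset has 342 foci (246 intention / 96 self-agency),
the 5-mm cut yields 17 clusters with mean per-axis standard deviations of
(4.32, 4.25, 4.35) mm, and nine clusters are flagged as enriched — for
example a cluster of 22 foci at (0.8, −4.5, 74.3) mm tagged
`self_agency` with tail probability 7.3e−13, and one of 37 foci at
(−0.5, 60.3, −15.0) mm tagged `intention` at 5.1e−06. These are exactly
the nine planted blobs of the design; the eight clutter sites and their
near-prior compositions stay unclassified.

The same pipeline is scriptable from a shell:

```bash
focimeta simulate --out run --seed 3
focimeta cluster  --out run --foci run/foci.tsv   # clusters.tsv + manifest
focimeta compose  --out run --foci run/foci.tsv   # composition.tsv
focimeta conjoin  --out run --foci run/foci.tsv   # ALE conjunction maps
```

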