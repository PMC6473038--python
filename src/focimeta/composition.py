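"""Cluster-composition analysis.

Each cluster produced by the hierarchical clustering is tested for
enrichment of each peak class: if a cluster of n foci contains x foci of a
class whose overall proportion in the dataset is p, the one-sided exact
binomial upper tail P(X >= x), X ~ Binomial(n, p), measures how surprising
that concentration is under the null hypothesis that the cluster's
composition matches the dataset-wide prior.  A cluster is tagged *enriched*
for the class with the smallest tail when that tail is at or below alpha;
otherwise it stays *unclassified*.

The tail is computed by direct term-by-term summation of the binomial pmf
in log space — exact up to floating rounding, with no normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .cluster import ClusterSolution
from .foci import PriorTable

__all__ = ["binomial_tail", "composition_test", "CompositionResult", "write_composition_report"]


def binomial_tail(x: int, n: int, p: float) -> float:
    """Exact one-sided upper tail P(X >= x) for X ~ Binomial(n, p).

    Computed by direct summation of the pmf terms k = x..n, accumulated in
    log space (logsumexp) for numerical stability.

    Parameters
    ----------
    x, n : int
        Observed count and cluster size, 0 <= x <= n.
    p : float
        Prior success probability in [0, 1].
    """
    if not (0 <= x <= n):
        raise ValueError(f"x must satisfy 0 <= x <= n, got x={x}, n={n}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if x == 0:
        return 1.0
    if p == 0.0:
        return 0.0  # x >= 1 impossible
    if p == 1.0:
        return 1.0
    k = np.arange(x, n + 1)
    log_terms = (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + k * np.log(p)
        + (n - k) * np.log1p(-p)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


@dataclass
class CompositionResult:
    """Outcome of the composition analysis.

    ``tails`` has one row per (cluster, label): observed count x, cluster
    size n, prior p and the one-sided tail.  ``classification`` has one row
    per cluster with the winning label (smallest tail) and an ``enriched``
    flag at level alpha; equal smallest tails leave the cluster
    unclassified.
    """

    tails: pd.DataFrame
    classification: pd.DataFrame
    alpha: float


def composition_test(
    solution: ClusterSolution,
    priors: PriorTable,
    alpha: float = 0.05,
    correction: str = "none",
) -> CompositionResult:
    """Per-cluster exact binomial enrichment tests against the dataset prior.

    Parameters
    ----------
    solution : ClusterSolution
        Must carry label counts (see ``summarize_clusters``).
    priors : PriorTable
        Dataset-wide proportions; must cover every counted label.
    alpha : float
        Per-cluster significance level (0.05 by default, uncorrected across
        clusters, matching the convention of reporting per-cluster
        P-values).
    correction : {"none", "bh"}
        Optional Benjamini-Hochberg correction of the winning tails across
        clusters.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    count_cols = [c for c in solution.summaries.columns if c.startswith("n_")]
    if not count_cols:
        raise ValueError("solution carries no label counts; run summarize_clusters first")
    labels = [c[2:] for c in count_cols]
    missing = [lab for lab in labels if lab not in priors.counts]
    if missing:
        raise ValueError(f"labels missing from priors: {missing}")

    rows = []
    for cid, row in solution.summaries.iterrows():
        n = int(row["size"])
        for lab in labels:
            x = int(row[f"n_{lab}"])
            p = priors.proportion(lab)
            rows.append(
                {
                    "cluster_id": cid,
                    "label": lab,
                    "x": x,
                    "n": n,
                    "prior": p,
                    "tail": binomial_tail(x, n, p),
                }
            )
    tails = pd.DataFrame(rows)

    cls_rows = []
    for cid, grp in tails.groupby("cluster_id"):
        best = grp["tail"].min()
        winners = grp[grp["tail"] == best]
        if len(winners) > 1:
            cls_rows.append(
                {"cluster_id": cid, "label": None, "tail": best, "enriched": False}
            )
        else:
            w = winners.iloc[0]
            cls_rows.append(
                {"cluster_id": cid, "label": w["label"], "tail": best, "enriched": False}
            )
    classification = pd.DataFrame(cls_rows).set_index("cluster_id")

    crit = classification["tail"].to_numpy(dtype=float)
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(crit, alpha=alpha, method="fdr_bh")
    elif correction == "none":
        reject = crit <= alpha
    else:
        raise ValueError(f"unknown correction: {correction!r}")
    classification["enriched"] = reject & classification["label"].notna()
    classification.loc[classification["label"].isna(), "enriched"] = False
    return CompositionResult(tails=tails, classification=classification, alpha=alpha)


def write_composition_report(result: CompositionResult, target, sep: str = "\t") -> None:
    """Machine-readable TSV: per cluster, n, per-label x and tails, tag."""
    wide = result.tails.pivot(index="cluster_id", columns="label", values=["x", "tail"])
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    n = result.tails.groupby("cluster_id")["n"].first()
    out = pd.concat([n, wide, result.classification[["label", "enriched"]]], axis=1)
    out = out.rename(columns={"label": "enriched_label"})
    out.to_csv(target, sep=sep)
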