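"""k-means clustering of expression patterns and cluster categorisation.

Transcripts are clustered on their log2(FPKM + 1) profiles across the
species x tissue conditions (per-replicate columns by default) with
Lloyd's algorithm, k-means++ initialisation, Euclidean distance, and the
best of several restarts by SSE. Clusters are then categorised from their
centroids: *tissue-dependent* if the between-tissue centroid contrast
(averaged over species) is large while the between-species contrast is
small, *lineage-dependent* in the opposite case, *neither* otherwise.

The implementation orders transcripts canonically (by id) before
clustering and seeds each restart from (seed, restart index), so the
assignment is invariant to the row order of the input matrix. An empty
cluster during Lloyd iterations is re-seeded at the point farthest from
its current centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix

__all__ = [
    "ClusterModel",
    "kmeans_cluster",
    "categorise_clusters",
    "cluster_membership_report",
    "TISSUE_DEPENDENT",
    "LINEAGE_DEPENDENT",
    "NEITHER",
]

TISSUE_DEPENDENT = "TISSUE_DEPENDENT"
LINEAGE_DEPENDENT = "LINEAGE_DEPENDENT"
NEITHER = "NEITHER"


@dataclass
class ClusterModel:
    k: int
    centroids: pd.DataFrame  # k x feature columns, log2 scale
    assignment: pd.Series  # transcript id -> cluster index
    sse: float
    sse_history: list = field(default_factory=list)
    meta: pd.DataFrame = None  # sample metadata for the feature columns
    categories: dict = field(default_factory=dict)  # cluster -> (category, annotation)

    def members(self, cluster: int) -> set:
        return set(self.assignment.index[self.assignment == cluster])


def _kmeanspp(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = x.shape[0]
    centroids = np.empty((k, x.shape[1]))
    centroids[0] = x[rng.integers(n)]
    d2 = ((x - centroids[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centroids[c] = x[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((x - centroids[c]) ** 2).sum(axis=1))
    return centroids


def _lloyd(x: np.ndarray, centroids: np.ndarray, max_iter: int, tol: float):
    """Lloyd iterations; returns (centroids, labels, sse, per-iteration SSE)."""
    history = []
    labels = None
    for _ in range(max_iter):
        d2 = (
            (x**2).sum(axis=1)[:, None]
            + (centroids**2).sum(axis=1)[None, :]
            - 2.0 * x @ centroids.T
        )
        labels = d2.argmin(axis=1)
        sse = float(np.clip(d2[np.arange(len(x)), labels], 0, None).sum())
        history.append(sse)
        new = centroids.copy()
        for c in range(centroids.shape[0]):
            mask = labels == c
            if mask.any():
                new[c] = x[mask].mean(axis=0)
            else:  # empty cluster: re-seed at the farthest point
                far = np.clip(d2[np.arange(len(x)), labels], 0, None).argmax()
                new[c] = x[far]
        shift = float(np.abs(new - centroids).max())
        centroids = new
        if shift <= tol:
            break
    d2 = (
        (x**2).sum(axis=1)[:, None]
        + (centroids**2).sum(axis=1)[None, :]
        - 2.0 * x @ centroids.T
    )
    labels = d2.argmin(axis=1)
    sse = float(np.clip(d2[np.arange(len(x)), labels], 0, None).sum())
    history.append(sse)
    return centroids, labels, sse, history


def kmeans_cluster(
    m: ExpressionMatrix,
    k: int = 15,
    seed: int = 0,
    n_init: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    collapse_replicates: bool = False,
) -> ClusterModel:
    """Cluster transcripts on log-scale expression profiles.

    Features are the per-replicate sample columns (or per-condition
    replicate means with ``collapse_replicates``). Deterministic given
    ``seed``; the returned model is the best of ``n_init`` restarts by SSE.
    """
    if not m.is_log:
        raise ValueError("k-means expects log2(FPKM+1) expression values")
    if k > len(m.transcript_ids):
        raise ValueError(f"k={k} exceeds number of transcripts {len(m.transcript_ids)}")
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(m.transcript_ids)  # canonical ordering for invariance
    if collapse_replicates:
        means = m.replicate_means()
        cols = [f"{sp}.{ti}" for sp, ti in means.columns]
        feats = pd.DataFrame(means.to_numpy(), index=means.index, columns=cols).loc[order]
        meta = pd.DataFrame(
            {
                "species": [sp for sp, _ in means.columns],
                "tissue": [ti for _, ti in means.columns],
                "replicate": 1,
            },
            index=pd.Index(cols, name="sample_id"),
        )
    else:
        feats = m.values.loc[order]
        meta = m.meta
    x = feats.to_numpy()

    best = None
    for restart in range(n_init):
        rng = np.random.default_rng((seed, restart))
        init = _kmeanspp(x, k, rng)
        centroids, labels, sse, history = _lloyd(x, init, max_iter, tol)
        if best is None or sse < best[2]:
            best = (centroids, labels, sse, history)
    centroids, labels, sse, history = best
    return ClusterModel(
        k=k,
        centroids=pd.DataFrame(centroids, columns=feats.columns),
        assignment=pd.Series(labels, index=order),
        sse=sse,
        sse_history=history,
        meta=meta,
    )


def _condition_centroids(cm: ClusterModel) -> pd.DataFrame:
    """Average centroid columns within each (species, tissue) condition."""
    meta = cm.meta
    key = list(zip(meta.loc[cm.centroids.columns, "species"], meta.loc[cm.centroids.columns, "tissue"]))
    out = {}
    for cond in dict.fromkeys(key):
        cols = [c for c, kk in zip(cm.centroids.columns, key) if kk == cond]
        out[cond] = cm.centroids[cols].mean(axis=1)
    df = pd.DataFrame(out)
    df.columns = pd.MultiIndex.from_tuples(dict.fromkeys(key), names=["species", "tissue"])
    return df


def categorise_clusters(
    cm: ClusterModel, t_tissue: float = 2.0, t_lineage: float = 2.0
) -> ClusterModel:
    """Label each cluster tissue-dependent, lineage-dependent, or neither.

    Tissue score = |mean over species of (centroid in tissue A - tissue B)|;
    lineage score = range over species of the tissue-averaged centroid.
    Thresholds are in log2 units. A cluster exceeding both thresholds is
    NEITHER (ambiguous).
    """
    cond = _condition_centroids(cm)
    tissues = list(dict.fromkeys(cond.columns.get_level_values("tissue")))
    if len(tissues) != 2:
        raise ValueError("cluster categorisation needs exactly two tissues")
    species = list(dict.fromkeys(cond.columns.get_level_values("species")))
    a, b = tissues
    diffs = pd.DataFrame({sp: cond[(sp, a)] - cond[(sp, b)] for sp in species})
    tissue_signed = diffs.mean(axis=1)
    tissue_score = tissue_signed.abs()
    sp_avg = pd.DataFrame({sp: cond[sp].mean(axis=1) for sp in species})
    lineage_score = sp_avg.max(axis=1) - sp_avg.min(axis=1)

    categories = {}
    for c in range(cm.k):
        ts, ls = float(tissue_score[c]), float(lineage_score[c])
        if ts >= t_tissue and ls < t_lineage:
            focal = a if tissue_signed[c] > 0 else b
            categories[c] = (TISSUE_DEPENDENT, focal)
        elif ls >= t_lineage and ts < t_tissue:
            mid = (sp_avg.loc[c].max() + sp_avg.loc[c].min()) / 2.0
            high = tuple(sorted(sp for sp in species if sp_avg.loc[c, sp] > mid))
            categories[c] = (LINEAGE_DEPENDENT, "+".join(high))
        else:
            categories[c] = (NEITHER, "")
    cm.categories = categories
    return cm


def cluster_membership_report(cm: ClusterModel) -> pd.DataFrame:
    """Per-cluster size, category, annotation and sorted member ids."""
    if not cm.categories:
        raise ValueError("categorise_clusters must run before the membership report")
    rows = []
    for c in range(cm.k):
        members = sorted(cm.members(c))
        cat, ann = cm.categories[c]
        rows.append(
            {
                "cluster": c,
                "size": len(members),
                "category": cat,
                "annotation": ann,
                "members": ",".join(members),
            }
        )
    report = pd.DataFrame(rows).set_index("cluster")
    assert report["size"].sum() == len(cm.assignment)
    return report
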