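"""Expression-distance phylogenetics and PCA.

Species are compared through their expression profiles: the distance
between two species is 1 - rho (Spearman rank correlation of their
replicate-averaged profiles), trees are built by neighbour joining, and
edge support comes from resampling transcripts with replacement. PCA of
the sample profiles (centred, optionally scaled) summarises the global
structure, with per-group normal-theory confidence ellipses.

Neighbour joining follows Saitou & Nei with the usual refinements: the
pair minimising the Q criterion is joined (deterministic tie-break on
label order), and a negative branch length is clamped to zero with the
deficit moved onto its sibling edge, preserving the pairwise path length.
NJ reconstructs additive distance matrices exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix
from .trees import ExpressionTree

__all__ = [
    "DistanceMatrix",
    "PcaResult",
    "spearman_distance",
    "neighbour_joining",
    "bootstrap_support",
    "pca_with_ellipses",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with ordered labels."""

    labels: list
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        k = len(self.labels)
        if self.d.shape != (k, k):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (self.d < -1e-12).any():
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        self.d = np.clip((self.d + self.d.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.d, 0.0)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def _group_profiles(m: ExpressionMatrix, group_by) -> pd.DataFrame:
    """Replicate-averaged profile per metadata group (transcripts x groups)."""
    group_by = list(group_by)
    keys = [tuple(row) for row in m.meta[group_by].itertuples(index=False)]
    order = list(dict.fromkeys(keys))
    out = {}
    for g in order:
        cols = [s for s, k in zip(m.sample_ids, keys) if k == g]
        label = g[0] if len(g) == 1 else ".".join(str(x) for x in g)
        out[label] = m.values[cols].mean(axis=1)
    return pd.DataFrame(out)


def spearman_distance(m: ExpressionMatrix, group_by=("species",)) -> DistanceMatrix:
    """1 - Spearman rho between replicate-averaged group profiles."""
    if len(m.transcript_ids) < 3:
        raise ValueError("need at least 3 transcripts for a rank correlation")
    prof = _group_profiles(m, group_by)
    for g in prof.columns:
        if prof[g].nunique() == 1:
            raise ValueError(f"constant expression profile for group {g!r}")
    ranks = prof.rank(axis=0, method="average").to_numpy()
    rho = np.corrcoef(ranks.T)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(prof.columns), np.clip(d, 0.0, None))


def neighbour_joining(dm: DistanceMatrix) -> ExpressionTree:
    """Saitou-Nei neighbour joining; exact on additive matrices."""
    labels = list(dm.labels)
    if len(labels) < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    d = dm.d.copy()
    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(lbl)) for lbl in labels]
    active = list(range(len(labels)))

    def _join(i_pos: int, j_pos: int) -> None:
        """Join active entries at positions i_pos < j_pos into a new node."""
        nonlocal d, nodes, active
        n_act = len(active)
        i, j = active[i_pos], active[j_pos]
        r = d[np.ix_(active, active)].sum(axis=1)
        li = 0.5 * d[i, j] + (r[i_pos] - r[j_pos]) / (2.0 * (n_act - 2))
        lj = d[i, j] - li
        if li < 0:  # clamp, moving the deficit to the sibling edge
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = float(li)
        parent.add_child(nodes[j])
        nodes[j].edge.length = float(lj)
        # distances from the new node
        dn = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(dn)] = dn
        d[: len(dn), -1] = dn
        d[-1, -1] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    while len(active) > 3:
        n_act = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n_act - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for a in range(n_act):
            for b in range(a + 1, n_act):
                if best is None or q[a, b] < q[best[0], best[1]] - 1e-15:
                    best = (a, b)
        _join(*best)

    i, j, k = active
    root = dendropy.Node()
    lens = {
        i: 0.5 * (d[i, j] + d[i, k] - d[j, k]),
        j: 0.5 * (d[i, j] + d[j, k] - d[i, k]),
        k: 0.5 * (d[i, k] + d[j, k] - d[i, j]),
    }
    for idx in (i, j, k):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = float(max(lens[idx], 0.0))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    return ExpressionTree(tree)


def bootstrap_support(
    m: ExpressionMatrix, group_by=("species",), n_boot: int = 1000, seed: int = 0
) -> ExpressionTree:
    """NJ tree with transcript-resampling bootstrap supports on internal edges.

    Transcripts are resampled with replacement ``n_boot`` times; the support
    of each internal edge of the point-estimate tree is the percentage of
    replicate trees containing the same bipartition.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    tree = neighbour_joining(spearman_distance(m, group_by))
    targets = tree.bipartitions()
    counts = {b: 0 for b in targets}
    rng = np.random.default_rng(seed)
    n = len(m.transcript_ids)
    values = m.values
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = ExpressionMatrix(
            values.iloc[idx].set_axis(range(n), axis=0), m.meta, m.is_log
        )
        bt = neighbour_joining(spearman_distance(boot, group_by))
        for b in bt.bipartitions():
            if b in counts:
                counts[b] += 1
    tree.set_supports({b: 100.0 * c / n_boot for b, c in counts.items()})
    return tree


@dataclass
class PcaResult:
    """PCA scores plus per-group normal-theory confidence ellipses.

    Each ellipse is (centre, 2x2 covariance of the group's first two
    component scores, radius scale sqrt(chi2_2 quantile at ``confidence``)).
    """

    scores: pd.DataFrame
    explained_variance_fraction: np.ndarray
    ellipses: dict


def pca_with_ellipses(
    m: ExpressionMatrix, group_by=("species", "tissue"), confidence: float = 0.95,
    scale: bool = False,
) -> PcaResult:
    """PCA of sample profiles (centred; unit-variance scaling optional)."""
    from sklearn.decomposition import PCA

    if len(m.sample_ids) < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = m.values.to_numpy().T  # samples x transcripts
    if scale:
        sd = x.std(axis=0, ddof=0)
        x = (x - x.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    pca = PCA()
    scores = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    scores_df = pd.DataFrame(scores, index=m.sample_ids, columns=cols)

    radius = float(np.sqrt(stats.chi2.ppf(confidence, df=2)))
    group_by = list(group_by)
    keys = [tuple(row) for row in m.meta[group_by].itertuples(index=False)]
    ellipses = {}
    for g in dict.fromkeys(keys):
        rows = [s for s, k in zip(m.sample_ids, keys) if k == g]
        label = g[0] if len(g) == 1 else ".".join(str(x) for x in g)
        pts = scores_df.loc[rows, ["PC1", "PC2"]].to_numpy() if scores.shape[1] >= 2 else None
        if pts is None or len(rows) < 3:
            warnings.warn(f"group {label!r} has <3 samples; ellipse omitted")
            continue
        centre = pts.mean(axis=0)
        cov = np.cov(pts.T, ddof=1)
        ellipses[label] = (centre, cov, radius)
    return PcaResult(
        scores=scores_df,
        explained_variance_fraction=pca.explained_variance_ratio_,
        ellipses=ellipses,
    )
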