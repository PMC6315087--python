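"""Synthetic multi-species expression datasets with known ground truth.

Emulates the statistical structure of a five-species, two-tissue (male
accessory gland vs testis), three-replicate FPKM study over a shared
ortholog set:

* a baseline log2 expression level per transcript,
* species effects drifting along a known species tree as Brownian motion
  (branch lengths are drift variances in log2^2 units),
* planted tissue-enriched transcripts (constant log2 offset in one tissue,
  all species), planted lineage-dependent transcripts (offset in every
  tissue of one clade), and planted highly variable transcripts
  (between-species drift variance multiplied by an inflation factor),
* i.i.d. Gaussian replicate noise on the log2 scale,
* per-sample multiplicative scale distortions applied on the linear FPKM
  scale (the technical artefact the weighting-factor normalisation must
  remove),
* per-transcript dN/dS (omega) drawn from a gamma law and tilted so that
  omega co-varies with log2 mean expression with a chosen sign,
* a planted-partition interaction graph whose communities are the planted
  transcript groups.

Everything is deterministic given the seed. The generator produces log2
values first and back-transforms with 2^x - 1, so log2(FPKM + 1) recovers
the latent value exactly when no distortion is applied.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, InteractionGraph, OmegaTable
from .trees import ExpressionTree, read_newick

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_dataset", "worked_toy_dataset"]

#: Species tree of the study system: the recently diverged (gambiae,
#: coluzzii) cherry separated from (arabiensis, (quadriannulatus, merus)).
#: Branch lengths are Brownian drift variances of log2 expression, sized so
#: that the most diverged species pairs differ by ~1.5-fold on average
#: (log2 sd ~0.6-0.7) while the sister pair is nearly identical.
DEFAULT_SPECIES_TREE = (
    "((gambiae:0.08,coluzzii:0.08):0.12,"
    "arabiensis:0.25,(quadriannulatus:0.15,merus:0.15):0.10);"
)

TISSUES = ("MAG", "TESTIS")


@dataclass
class SimulationConfig:
    """Knobs of the generative model; defaults are the study conditions."""

    seed: int = 0
    species_tree: str = DEFAULT_SPECIES_TREE
    n_species: int = 5
    n_replicates: int = 3
    n_transcripts: int = 2000
    frac_tissue_enriched: float = 0.10
    frac_lineage_dependent: float = 0.10
    frac_highly_variable: float = 0.05
    tissue_effect_log2: float = 4.0
    lineage_effect_log2: float = 3.0
    hvg_variance_inflation: float = 10.0
    replicate_noise_sd_log2: float = 0.25
    #: "random" -> log-uniform in [0.5, 2]; "none" -> all 1; or an explicit
    #: mapping sample_id -> factor.
    sample_scale_factors: object = "random"
    omega_shape: float = 0.5
    omega_rate: float = 2.0
    omega_expression_slope: float = -0.05
    #: planted-partition edge probabilities for the interaction graph
    ppi_within_p: float = 0.05
    ppi_between_p: float = 0.005
    baseline_mean_log2: float = 3.0
    baseline_sd_log2: float = 2.0

    def validate(self) -> None:
        fr = self.frac_tissue_enriched + self.frac_lineage_dependent + self.frac_highly_variable
        if fr > 1.0 + 1e-12:
            raise ValueError("planted fractions sum above 1")
        for name in ("tissue_effect_log2", "lineage_effect_log2", "replicate_noise_sd_log2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.hvg_variance_inflation < 1:
            raise ValueError("hvg_variance_inflation must be >= 1")


@dataclass
class SimulationTruth:
    """Ground-truth labels and parameters behind a simulated dataset."""

    labels: pd.DataFrame  # per transcript: tissue_enriched_in, lineage_group, is_hvg, cluster
    scale_factors: pd.Series  # per sample, the applied multiplicative distortion
    species_tree: ExpressionTree
    omegas: pd.Series
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def cluster_members(self) -> dict:
        out = {}
        for cl, grp in self.labels.groupby("cluster"):
            out[cl] = set(grp.index)
        return out


def _parse_tree(newick: str) -> ExpressionTree:
    import dendropy

    t = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True, preserve_underscores=True
    )
    return ExpressionTree(t)


def _brownian_species_effects(
    tree: ExpressionTree, n_transcripts: int, drift_scale: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate Brownian drift along the tree; returns transcripts x species.

    ``drift_scale`` multiplies the drift *variance* per transcript (1 for
    typical transcripts, the inflation factor for planted HVGs).
    """
    dt = tree.dendropy_tree
    values = {id(dt.seed_node): np.zeros(n_transcripts)}
    species = []
    # preorder gives parent before child; edges in a fixed traversal order
    for node in dt.preorder_node_iter():
        if node is dt.seed_node:
            continue
        bl = node.edge.length or 0.0
        step = rng.standard_normal(n_transcripts) * np.sqrt(bl * drift_scale)
        values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            species.append((node.taxon.label, values[id(node)]))
    return pd.DataFrame(dict(species))


def _clades(tree: ExpressionTree) -> list:
    """Non-trivial clades usable as lineage groups, smallest-side convention."""
    sides = sorted(tree.bipartitions(), key=lambda s: tuple(sorted(s)))
    return [tuple(sorted(s)) for s in sides]


def simulate_dataset(cfg: SimulationConfig):
    """Generate (ExpressionMatrix, SimulationTruth, InteractionGraph, OmegaTable)."""
    import networkx as nx

    cfg.validate()
    tree = _parse_tree(cfg.species_tree)
    species = sorted(tree.leaf_labels)
    if len(species) != cfg.n_species:
        raise ValueError(
            f"n_species={cfg.n_species} but species tree has {len(species)} leaves"
        )
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_transcripts
    ids = [f"T{i:05d}" for i in range(n)]

    # -- planted labels (disjoint blocks) ---------------------------------
    n_te = int(round(cfg.frac_tissue_enriched * n))
    n_ld = int(round(cfg.frac_lineage_dependent * n))
    n_hvg = int(round(cfg.frac_highly_variable * n))
    perm = rng.permutation(n)
    te_idx = perm[:n_te]
    ld_idx = perm[n_te : n_te + n_ld]
    hvg_idx = perm[n_te + n_ld : n_te + n_ld + n_hvg]

    tissue_of = np.array([""] * n, dtype=object)
    for j, i in enumerate(te_idx):
        tissue_of[i] = TISSUES[j % 2]
    clades = _clades(tree)
    lineage_of = np.array([""] * n, dtype=object)
    if n_ld and not clades:
        raise ValueError("species tree has no non-trivial clade for lineage effects")
    for j, i in enumerate(ld_idx):
        lineage_of[i] = "+".join(clades[j % len(clades)])
    is_hvg = np.zeros(n, dtype=bool)
    is_hvg[hvg_idx] = True

    cluster = np.array(["background"] * n, dtype=object)
    cluster[tissue_of == "MAG"] = "MAG_enriched"
    cluster[tissue_of == "TESTIS"] = "TESTIS_enriched"
    for j, i in enumerate(ld_idx):
        cluster[i] = f"lineage_{lineage_of[i]}"
    cluster[is_hvg] = "highly_variable"

    # -- latent log2 expression -------------------------------------------
    # truncated normal (support >= 0) for the baseline log2 level
    from scipy import stats as _stats

    a = (0.0 - cfg.baseline_mean_log2) / cfg.baseline_sd_log2
    base = _stats.truncnorm.rvs(
        a, np.inf, loc=cfg.baseline_mean_log2, scale=cfg.baseline_sd_log2,
        size=n, random_state=rng,
    )
    drift_scale = np.where(is_hvg, cfg.hvg_variance_inflation, 1.0)
    drift = _brownian_species_effects(tree, n, drift_scale, rng)  # transcripts x species

    sample_ids, meta_rows = [], []
    for sp in species:
        for ti in TISSUES:
            for r in range(1, cfg.n_replicates + 1):
                sid = f"{sp}_{ti}_{r}"
                sample_ids.append(sid)
                meta_rows.append((sid, sp, ti, r))
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "species", "tissue", "replicate"])
    meta = meta.set_index("sample_id")

    log2x = np.empty((n, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        sp, ti = meta.loc[sid, "species"], meta.loc[sid, "tissue"]
        col = base + drift[sp].to_numpy()
        col = col + np.where(tissue_of == ti, cfg.tissue_effect_log2, 0.0)
        in_clade = np.array(
            [bool(lg) and sp in lg.split("+") for lg in lineage_of], dtype=bool
        )
        col = col + np.where(in_clade, cfg.lineage_effect_log2, 0.0)
        log2x[:, j] = col
    if cfg.replicate_noise_sd_log2 > 0:
        log2x = log2x + rng.normal(0.0, cfg.replicate_noise_sd_log2, size=log2x.shape)

    # -- scale distortions on the linear scale ----------------------------
    if isinstance(cfg.sample_scale_factors, str) and cfg.sample_scale_factors == "random":
        factors = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(sample_ids)))
    elif isinstance(cfg.sample_scale_factors, str) and cfg.sample_scale_factors == "none":
        factors = np.ones(len(sample_ids))
    else:
        factors = np.array([float(cfg.sample_scale_factors[s]) for s in sample_ids])
    if (factors <= 0).any():
        raise ValueError("scale factors must be positive")
    fpkm = np.clip(np.exp2(log2x) - 1.0, 0.0, None) * factors[None, :]

    values = pd.DataFrame(fpkm, index=ids, columns=sample_ids)
    matrix = ExpressionMatrix(values, meta, is_log=False)

    # -- omega with planted expression correlation ------------------------
    omega_raw = rng.gamma(shape=cfg.omega_shape, scale=1.0 / cfg.omega_rate, size=n)
    mean_log2 = np.log2(fpkm.mean(axis=1) + 1.0)
    tilt = cfg.omega_expression_slope * (mean_log2 - mean_log2.mean())
    omegas = pd.Series(np.clip(omega_raw + tilt, 0.0, None), index=ids)

    # -- planted-partition interaction graph ------------------------------
    order = np.argsort(cluster, kind="stable")
    sizes, block_ids = [], []
    start = 0
    while start < n:
        lbl = cluster[order[start]]
        end = start
        while end < n and cluster[order[end]] == lbl:
            end += 1
        sizes.append(end - start)
        block_ids.extend(order[start:end])
        start = end
    k = len(sizes)
    p = np.full((k, k), cfg.ppi_between_p)
    np.fill_diagonal(p, cfg.ppi_within_p)
    g_sbm = nx.stochastic_block_model(
        sizes, p.tolist(), seed=int(rng.integers(0, 2**31 - 1))
    )
    mapping = {i: ids[block_ids[i]] for i in range(n)}
    g_named = nx.relabel_nodes(g_sbm, mapping)
    graph = InteractionGraph(nodes=g_named.nodes, edges=g_named.edges)

    labels = pd.DataFrame(
        {
            "tissue_enriched_in": tissue_of,
            "lineage_group": lineage_of,
            "is_hvg": is_hvg,
            "cluster": cluster,
        },
        index=ids,
    )
    truth = SimulationTruth(
        labels=labels,
        scale_factors=pd.Series(factors, index=sample_ids),
        species_tree=tree,
        omegas=omegas,
        config=cfg,
    )
    return matrix, truth, graph, OmegaTable(omegas)


def worked_toy_dataset():
    """Load the fixed 50-transcript toy dataset shipped with the package.

    Returns (ExpressionMatrix, SimulationTruth). The fixture was generated
    by :func:`simulate_dataset` at a fixed seed and checked in as TSV so
    that documentation examples and regression tests are bit-stable.
    """
    from .io import read_expression_matrix

    data = resources.files("xspecies_expr") / "data"
    m = read_expression_matrix(data / "toy_expression.tsv", data / "toy_meta.tsv")
    labels = pd.read_csv(data / "toy_truth.tsv", sep="\t", index_col=0, keep_default_na=False)
    labels["is_hvg"] = labels["is_hvg"].astype(str).str.lower().isin(("true", "1"))
    factors = pd.read_csv(data / "toy_scale_factors.tsv", sep="\t", index_col=0).iloc[:, 0]
    omegas = pd.read_csv(data / "toy_omega.tsv", sep="\t", index_col=0).iloc[:, 0]
    tree = read_newick(data / "toy_species_tree.nwk")
    truth = SimulationTruth(
        labels=labels,
        scale_factors=factors,
        species_tree=tree,
        omegas=omegas,
        config=None,
    )
    return m, truth
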