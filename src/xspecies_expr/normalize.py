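"""Cross-species expression normalisation via rank-stability weighting factors.

The procedure makes expression comparable across species and tissues by
finding orthologs whose expression *rank* is most stable across samples and
using them as an internal reference:

1. replicates are collapsed to log2(mean(replicates) + 1) per
   (species, tissue) condition ("preprocessing");
2. within each condition, orthologs are ranked ascending by preprocessed
   expression (average ranks on ties);
3. per ortholog, the median and the variance of its ranks across conditions
   are computed; orthologs outside the inter-quartile range of median rank
   (the globally lowest- and highest-expressed quarters) are removed;
4. of the survivors, the tertile with the lowest rank variance — the most
   rank-stable orthologs — becomes the reference set;
5. each condition's weighting factor is the median preprocessed expression
   of the reference orthologs divided by the global mean of those medians.

Dividing every log-scale value by its condition's factor equalises the
reference medians across conditions exactly, which is the testable contract
of the whole procedure. (Multiplying instead — the ``literal_multiply``
mode — pushes medians apart; it is kept only as an explicitly named
alternative.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix

__all__ = [
    "WeightingFactors",
    "preprocess_replicates",
    "select_reference_orthologs",
    "compute_weighting_factors",
    "apply_weighting",
    "normalize_expression",
]

_COND_SEP = "."


def _condition_id(species: str, tissue: str) -> str:
    return f"{species}{_COND_SEP}{tissue}"


@dataclass
class WeightingFactors:
    """Per-condition scale factors plus the reference set that produced them.

    ``factors`` is indexed by condition id (one per species x tissue);
    every factor equals that condition's reference median divided by the
    global mean, and the factors average to 1 by construction.
    """

    factors: pd.Series
    reference_orthologs: list
    global_mean: float
    sample_medians: pd.Series
    condition_of_sample: dict = field(default_factory=dict, repr=False)

    def factor_for(self, species: str, tissue: str) -> float:
        return float(self.factors[_condition_id(species, tissue)])


def preprocess_replicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse replicates: one column per (species, tissue), log2(mean + 1)."""
    if m.is_log:
        raise ValueError("preprocessing expects linear FPKM input")
    means = m.replicate_means()  # MultiIndex (species, tissue) columns
    cols = [_condition_id(sp, ti) for sp, ti in means.columns]
    values = pd.DataFrame(np.log2(means.to_numpy() + 1.0), index=means.index, columns=cols)
    meta = pd.DataFrame(
        {
            "species": [sp for sp, _ in means.columns],
            "tissue": [ti for _, ti in means.columns],
            "replicate": 1,
        },
        index=pd.Index(cols, name="sample_id"),
    )
    return ExpressionMatrix(values, meta, is_log=True)


def select_reference_orthologs(p: ExpressionMatrix) -> list:
    """Pick the rank-stable reference orthologs from a preprocessed matrix.

    Returns transcript ids sorted by ascending rank variance (ties broken by
    id). Requires at least 4 transcripts; the IQR cut removes floor(n/4)
    transcripts at each end of the median-rank ordering and the final cut
    keeps the first tertile (at least one transcript) by rank variance.
    """
    n = len(p.transcript_ids)
    if n < 4:
        raise ValueError("too few orthologs: need at least 4 with complete expression")
    ranks = p.values.rank(axis=0, method="average")
    med = ranks.median(axis=1)
    var = ranks.var(axis=1, ddof=1) if ranks.shape[1] > 1 else pd.Series(0.0, index=ranks.index)
    by_median = sorted(p.transcript_ids, key=lambda t: (med[t], t))
    cut = n // 4
    survivors = by_median[cut : n - cut]
    by_var = sorted(survivors, key=lambda t: (var[t], t))
    keep = max(1, len(survivors) // 3)
    return by_var[:keep]


def compute_weighting_factors(p: ExpressionMatrix, refs) -> WeightingFactors:
    """Per-condition reference medians, their global mean, and the factors."""
    refs = list(refs)
    missing = [r for r in refs if r not in p.values.index]
    if missing:
        raise ValueError(f"reference orthologs absent from matrix: {missing[:5]}")
    conds = [_condition_id(sp, ti) for sp, ti in zip(p.meta["species"], p.meta["tissue"])]
    if len(set(conds)) != len(conds):
        raise ValueError(
            "weighting factors are per (species, tissue): collapse replicates first "
            "(preprocess_replicates)"
        )
    medians = p.values.loc[refs].median(axis=0)
    medians.index = conds
    global_mean = float(medians.mean())
    if global_mean == 0:
        raise ValueError("global mean of reference medians is zero; cannot form factors")
    factors = medians / global_mean
    return WeightingFactors(
        factors=factors,
        reference_orthologs=refs,
        global_mean=global_mean,
        sample_medians=medians,
    )


def apply_weighting(
    m: ExpressionMatrix, w: WeightingFactors, literal_multiply: bool = False
) -> ExpressionMatrix:
    """Scale each sample's log-scale values by its condition's factor.

    ``m`` must be on the log2(FPKM + 1) scale — either the preprocessed
    per-condition matrix or a per-replicate log matrix; replicate columns
    inherit the factor of their (species, tissue) condition. The default
    divides by the factor, after which the reference-ortholog median of
    every condition equals the global mean (to 1e-9) on preprocessed input.
    """
    if not m.is_log:
        raise ValueError("apply_weighting expects log2(FPKM+1) values")
    if (w.factors <= 0).any():
        bad = w.factors.index[w.factors <= 0][0]
        raise ValueError(f"non-positive weighting factor for {bad!r}")
    scaled = m.values.copy()
    for sid in m.sample_ids:
        sp, ti = m.meta.loc[sid, "species"], m.meta.loc[sid, "tissue"]
        cond = _condition_id(sp, ti)
        if cond not in w.factors.index:
            raise ValueError(f"no weighting factor for condition {cond!r}")
        f = float(w.factors[cond])
        scaled[sid] = scaled[sid] * f if literal_multiply else scaled[sid] / f
    return ExpressionMatrix(scaled, m.meta, is_log=True)


def normalize_expression(m: ExpressionMatrix, ortholog_ids=None):
    """End-to-end normalisation of a linear FPKM matrix.

    Preprocesses replicates, selects reference orthologs (within
    ``ortholog_ids`` if given, else all transcripts), computes weighting
    factors, and applies them to the per-replicate log2(FPKM + 1) matrix.

    Returns (normalized_replicate_matrix, normalized_condition_matrix,
    WeightingFactors).
    """
    from .datamodel import log_transform

    pre = preprocess_replicates(m)
    pool = pre if ortholog_ids is None else pre.subset_transcripts(ortholog_ids)
    refs = select_reference_orthologs(pool)
    w = compute_weighting_factors(pre, refs)
    norm_rep = apply_weighting(log_transform(m), w)
    norm_cond = apply_weighting(pre, w)
    return norm_rep, norm_cond, w
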