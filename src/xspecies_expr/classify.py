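"""Tissue-enrichment classification of transcripts from relative expression.

Per species, each transcript's relative expression in a focal tissue versus
the other tissue is summarised as log2FC = log2(fold change + 1), with a
pseudocount of 1 on both sides of the fold change to tame zeros:

    FC = (expr_focal + 1) / (expr_other + 1),   log2FC = log2(FC + 1)

and classified as highly enriched (log2FC >= 3.5), enriched
(2 <= log2FC < 3.5), ubiquitous (-2 <= log2FC < 2) or depleted
(log2FC < -2). Note the "+1 inside the log" convention keeps log2FC
strictly positive; the conventional log2FC = log2(FC) is available via
``plain_log2fc=True``, under which the depleted band becomes reachable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix

__all__ = [
    "EnrichmentCall",
    "CATEGORIES",
    "categorize_log2fc",
    "classify",
    "category_proportions",
]

HIGHLY_ENRICHED = "HIGHLY_ENRICHED"
ENRICHED = "ENRICHED"
UBIQUITOUS = "UBIQUITOUS"
DEPLETED = "DEPLETED"
CATEGORIES = (HIGHLY_ENRICHED, ENRICHED, UBIQUITOUS, DEPLETED)


@dataclass(frozen=True)
class EnrichmentCall:
    transcript_id: str
    species: str
    tissue: str
    log2fc: float
    category: str


def categorize_log2fc(
    log2fc: float, t_high: float = 3.5, t_enr: float = 2.0, t_ubi_low: float = -2.0
) -> str:
    """Map a log2FC value to its category; boundaries exactly as printed."""
    if not np.isfinite(log2fc):
        raise ValueError(f"non-finite log2fc {log2fc}")
    if log2fc >= t_high:
        return HIGHLY_ENRICHED
    if log2fc >= t_enr:
        return ENRICHED
    if log2fc >= t_ubi_low:
        return UBIQUITOUS
    return DEPLETED


def classify(
    m_norm: ExpressionMatrix,
    pseudo: float = 1.0,
    t_high: float = 3.5,
    t_enr: float = 2.0,
    t_ubi_low: float = -2.0,
    plain_log2fc: bool = False,
) -> pd.DataFrame:
    """Classify every transcript per species and focal tissue.

    ``m_norm`` must be on the linear (normalised FPKM) scale; replicates are
    averaged per condition. Requires exactly two tissues. Returns a tidy
    DataFrame with columns transcript_id, species, tissue, log2fc, category
    (one row per transcript x species x focal tissue).
    """
    if m_norm.is_log:
        raise ValueError("classify expects linear-scale expression (back-transform first)")
    tissues = m_norm.tissues
    if len(tissues) != 2:
        raise ValueError(f"classification needs exactly two tissues, got {tissues}")
    if pseudo <= 0:
        raise ValueError("pseudocount must be positive")
    means = m_norm.replicate_means()
    rows = []
    for sp in m_norm.species:
        for focal in tissues:
            other = tissues[1] if focal == tissues[0] else tissues[0]
            if (sp, focal) not in means.columns or (sp, other) not in means.columns:
                raise ValueError(f"species {sp!r} lacks a tissue condition")
            fc = (means[(sp, focal)] + pseudo) / (means[(sp, other)] + pseudo)
            log2fc = np.log2(fc) if plain_log2fc else np.log2(fc + 1.0)
            rows.append(
                pd.DataFrame(
                    {
                        "transcript_id": means.index,
                        "species": sp,
                        "tissue": focal,
                        "log2fc": log2fc.to_numpy(),
                    }
                )
            )
    out = pd.concat(rows, ignore_index=True)
    out["category"] = [
        categorize_log2fc(v, t_high, t_enr, t_ubi_low) for v in out["log2fc"]
    ]
    return out


def category_proportions(calls: pd.DataFrame) -> pd.DataFrame:
    """Percentage of each category per (species, tissue); rows sum to 100."""
    if len(calls) == 0:
        raise ValueError("no enrichment calls")
    counts = (
        calls.groupby(["species", "tissue"])["category"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(CATEGORIES), fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0) * 100.0
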