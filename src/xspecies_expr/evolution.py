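"""Evolutionary rate (dN/dS) versus expression.

Relates per-transcript omega = dN/dS values (estimated upstream; inputs
here) to expression: empirical cumulative distributions of omega per gene
group with a Kolmogorov-Smirnov contrast against the all-orthologs
background, OLS regression of summarised expression on omega per group,
and strict-threshold flagging of transcripts under positive selection
(omega > 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix, OmegaTable

__all__ = [
    "OmegaAnalysis",
    "ecdf_by_group",
    "expression_omega_regression",
    "flag_positive_selection",
    "summarise_expression",
]


@dataclass
class OmegaAnalysis:
    """ECDFs, KS statistics and expression-omega regressions per group."""

    ecdf: dict = field(default_factory=dict)  # group -> (omega grid, cumulative fraction)
    ks_statistic: dict = field(default_factory=dict)  # group -> KS vs background
    regression: dict = field(default_factory=dict)  # group -> dict(slope, intercept, r_squared, n)
    positive_selection_set: set = field(default_factory=set)


def ecdf_by_group(omegas: OmegaTable, groups: dict) -> OmegaAnalysis:
    """Empirical CDF of omega per group on the shared grid, plus KS vs all.

    ``groups`` maps group label -> iterable of transcript ids; every id
    must have an omega. The background is the full omega table.
    """
    background = omegas.omegas.to_numpy()
    grid = np.unique(background)
    out = OmegaAnalysis()
    for label in sorted(groups):
        ids = list(groups[label])
        if not ids:
            raise ValueError(f"group {label!r} is empty")
        missing = [i for i in ids if i not in omegas.omegas.index]
        if missing:
            raise ValueError(f"group {label!r} has ids without omega: {missing[:5]}")
        vals = omegas.omegas.loc[ids].to_numpy()
        frac = np.searchsorted(np.sort(vals), grid, side="right") / len(vals)
        out.ecdf[label] = (grid, frac)
        out.ks_statistic[label] = float(stats.ks_2samp(vals, background).statistic)
    return out


def summarise_expression(
    m: ExpressionMatrix, tissue: str = None, per_species_mean: bool = True
) -> pd.Series:
    """Per-transcript log2(mean FPKM + 1) over the relevant samples."""
    if m.is_log:
        raise ValueError("expression summary expects linear FPKM")
    sub = m.subset_tissue(tissue) if tissue is not None else m
    if per_species_mean:
        prof = sub.replicate_means().mean(axis=1)
    else:
        prof = sub.values.mean(axis=1)
    return np.log2(prof + 1.0)


def expression_omega_regression(
    omegas: OmegaTable, expression: pd.Series, groups: dict = None
) -> OmegaAnalysis:
    """OLS of summarised expression on omega, per group and for the full set.

    ``expression`` is a per-transcript summary (e.g. log2 mean FPKM + 1).
    Returns slope, intercept, R^2 and n under each group label plus "all".
    """
    common = omegas.omegas.index.intersection(expression.index)
    groups = dict(groups or {})
    groups["all"] = list(common)
    out = OmegaAnalysis()
    for label in sorted(groups):
        ids = [i for i in groups[label] if i in common]
        if len(ids) < 3:
            raise ValueError(f"group {label!r} has fewer than 3 transcripts with data")
        x = omegas.omegas.loc[ids].to_numpy()
        y = expression.loc[ids].to_numpy()
        if np.ptp(x) == 0:  # e.g. a small group with every omega clipped at 0
            warnings.warn(f"group {label!r} has constant omega; regression skipped")
            continue
        res = stats.linregress(x, y)
        out.regression[label] = {
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "r_squared": float(res.rvalue**2),
            "n": len(ids),
        }
    return out


def flag_positive_selection(omegas: OmegaTable, threshold: float = 1.0) -> set:
    """Transcripts with omega strictly greater than the threshold."""
    om = omegas.omegas
    return set(om.index[om > threshold])
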