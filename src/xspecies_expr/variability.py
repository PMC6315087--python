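"""Highly variable transcripts from CV-vs-mean regression in log-log space.

For one tissue, each transcript's mean and coefficient of variation
(sd/mean) are computed from the expression values of all the species:
by default the per-species replicate means (one value per species), with
an option to use every replicate sample instead. log10(CV) is regressed
on log10(mean) by ordinary least squares;
transcripts are ranked by their leverage-adjusted standardized residual,
and a transcript is highly variable when it lies above the upper bound of
the two-sided prediction interval at the requested confidence level
(i.e. above the (1+confidence)/2 prediction quantile).

Because CV and mean both scale linearly under a uniform rescaling of the
expression values, the fitted line shifts but residuals — and hence flags
and ranks — are invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix

__all__ = ["VariabilityTable", "detect_highly_variable", "variability_summary"]


@dataclass
class VariabilityTable:
    """Per-transcript variability statistics and the highly-variable flags."""

    table: pd.DataFrame  # mean_expr, cv, log10_mean, log10_cv, residual,
    #                      standardized_residual, above_upper_ci, rank,
    #                      is_highly_variable
    slope: float
    intercept: float
    residual_se: float
    confidence: float

    @property
    def highly_variable_ids(self) -> list:
        t = self.table
        return list(t.index[t["is_highly_variable"]])


def detect_highly_variable(
    m: ExpressionMatrix,
    confidence: float = 0.95,
    mode: str = "ci",
    fraction: float = 0.05,
    per_species: bool = True,
) -> VariabilityTable:
    """Flag transcripts whose cross-species CV exceeds the mean-CV trend.

    ``m`` should hold one tissue on the linear scale. The CV uses the
    replicate means (one value per species) by default; with
    ``per_species=False`` it uses every sample column of the tissue.
    Transcripts with zero mean or zero
    variance are excluded from the regression with a warning. ``mode`` is
    "ci" (all points above the upper prediction bound) or "top_fraction"
    (the top ceil(fraction * n) ranked transcripts that are also above
    the bound).
    """
    if m.is_log:
        raise ValueError("CV requires linear-scale expression")
    if mode not in ("ci", "top_fraction"):
        raise ValueError(f"unknown selection mode {mode!r}")
    prof = m.replicate_means() if per_species else m.values
    if prof.shape[1] < 3:
        raise ValueError("need at least 3 expression profiles for a CV")
    mean = prof.mean(axis=1)
    sd = prof.std(axis=1, ddof=1)
    cv = sd / mean.where(mean > 0)
    usable = (mean > 0) & (cv > 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        warnings.warn(f"excluding {n_dropped} transcripts with zero mean or zero CV")
    if usable.sum() < 3:
        raise ValueError("fewer than 3 transcripts with positive mean and CV")

    lx = np.log10(mean[usable].to_numpy())
    ly = np.log10(cv[usable].to_numpy())
    n = len(lx)
    X = np.column_stack([np.ones(n), lx])
    beta, *_ = np.linalg.lstsq(X, ly, rcond=None)
    fitted = X @ beta
    resid = ly - fitted
    dof = n - 2
    s = float(np.sqrt((resid**2).sum() / dof))
    if s <= 1e-12 * max(1.0, float(np.abs(ly).max())):
        s = 0.0  # numerically exact fit: no deviation, nothing to flag
    # leverage of each point under the simple regression
    hat = 1.0 / n + (lx - lx.mean()) ** 2 / ((lx - lx.mean()) ** 2).sum()
    if s > 0:
        std_resid = resid / (s * np.sqrt(np.clip(1.0 - hat, 1e-12, None)))
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, dof)
        upper = fitted + tcrit * s * np.sqrt(1.0 + hat)
        above = ly > upper
    else:
        std_resid = np.zeros(n)
        above = np.zeros(n, dtype=bool)

    out = pd.DataFrame(
        {
            "mean_expr": mean[usable],
            "cv": cv[usable],
            "log10_mean": lx,
            "log10_cv": ly,
            "residual": resid,
            "standardized_residual": std_resid,
            "above_upper_ci": above,
        },
        index=mean[usable].index,
    )
    # rank by standardized residual descending, ties broken by transcript id
    order = out.iloc[
        np.lexsort((out.index.to_numpy(), -out["standardized_residual"].to_numpy()))
    ]
    rank = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    out["rank"] = rank
    if mode == "ci":
        out["is_highly_variable"] = out["above_upper_ci"]
    else:
        top = int(np.ceil(fraction * len(out)))
        out["is_highly_variable"] = (out["rank"] <= top) & out["above_upper_ci"]
    return VariabilityTable(
        table=out,
        slope=float(beta[1]),
        intercept=float(beta[0]),
        residual_se=s,
        confidence=confidence,
    )


def variability_summary(t: VariabilityTable) -> tuple:
    """(number flagged, fraction of the analysed transcripts)."""
    n = len(t.table)
    flagged = int(t.table["is_highly_variable"].sum())
    return flagged, flagged / n if n else 0.0
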