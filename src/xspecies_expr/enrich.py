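"""Hypergeometric over-representation tests with FDR control.

For a selection of transcripts drawn from a universe, each annotation term
is scored with the upper-tail hypergeometric probability P(X >= k) of
seeing at least the observed overlap k between the selection (size n) and
the term's members within the universe (term size K, universe size N).
P values are corrected across terms with the Benjamini-Hochberg step-up
procedure; a term is significant when its q-value falls below alpha.
Bonferroni correction is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "hypergeometric_enrichment", "bh_adjust"]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    universe_size: int
    term_size: int
    selection_size: int
    overlap: int
    p_value: float
    q_value: float
    significant: bool


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for overlap k of a size-n draw with K successes."""
    if k < 0 or k > min(K, n):
        raise ValueError(f"impossible overlap k={k} for K={K}, n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> list:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min over j >= i of (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def hypergeometric_enrichment(
    selection,
    universe,
    terms,
    alpha: float = 0.05,
    min_term_size: int = 2,
    correction: str = "bh",
) -> list:
    """Test every annotation term for over-representation in the selection.

    Term member sets are intersected with the universe before testing;
    terms smaller than ``min_term_size`` (after intersection) are skipped.
    Returns EnrichmentResults sorted by p-value (ties by term id).
    """
    selection = set(selection)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not selection:
        raise ValueError("empty selection")
    stray = selection - universe
    if stray:
        raise ValueError(f"selection ids outside universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(selection)
    tested = []
    for t in terms:
        members = set(t.member_transcripts) & universe
        if len(members) < min_term_size:
            continue
        K = len(members)
        k = len(members & selection)
        tested.append((t, N, K, n, k, hypergeom_pvalue(N, K, n, k)))
    if not tested:
        return []
    pvals = [x[5] for x in tested]
    if correction == "bh":
        qvals = bh_adjust(pvals)
    elif correction == "bonferroni":
        qvals = list(np.minimum(np.asarray(pvals) * len(pvals), 1.0))
    else:
        raise ValueError(f"unknown correction {correction!r}")
    results = [
        EnrichmentResult(
            term_id=t.term_id,
            term_name=t.term_name,
            universe_size=N,
            term_size=K,
            selection_size=n,
            overlap=k,
            p_value=p,
            q_value=q,
            significant=bool(q < alpha),
        )
        for (t, N, K, n, k, p), q in zip(tested, qvals)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.term_id))


def enrichment_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
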