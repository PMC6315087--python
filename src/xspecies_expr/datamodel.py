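"""Core in-memory containers shared by every stage of the pipeline.

The central object is :class:`ExpressionMatrix`, a transcripts x samples
table of FPKM values with per-sample metadata (species, tissue, replicate).
Expression is stored either on the linear FPKM scale or as log2(FPKM + 1);
the ``is_log`` flag records which, and :func:`log_transform` moves from the
former to the latter exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "ExpressionMatrix",
    "AnnotationSet",
    "InteractionGraph",
    "OmegaTable",
    "log_transform",
    "inverse_log_transform",
]

META_COLUMNS = ("species", "tissue", "replicate")


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one RNA-seq sample: which species, tissue and replicate."""

    sample_id: str
    species: str
    tissue: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(
                f"replicate must be a positive integer, got {self.replicate} "
                f"for sample {self.sample_id!r}"
            )


class ExpressionMatrix:
    """Dense transcripts x samples expression table with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by transcript id with one column per sample id.
        Non-negative FPKM when ``is_log`` is False, log2(FPKM + 1) otherwise.
    meta
        DataFrame indexed by sample_id with columns species, tissue,
        replicate; row order must match the columns of ``values``.
    is_log
        Whether values are on the log2(FPKM + 1) scale.
    """

    def __init__(self, values: pd.DataFrame, meta: pd.DataFrame, is_log: bool = False):
        values = values.copy()
        meta = meta.copy()
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript_ids: {dups[:5]}")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        missing = [c for c in values.columns if c not in meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        for col in META_COLUMNS:
            if col not in meta.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        meta = meta.loc[values.columns, list(META_COLUMNS)]
        meta["replicate"] = meta["replicate"].astype(int)
        if (meta["replicate"] < 1).any():
            raise ValueError("replicate numbers must be positive integers")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if not is_log and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression value at transcript {values.index[i]!r}, "
                f"sample {values.columns[j]!r}"
            )
        self.values = values.astype(float)
        self.meta = meta
        self.is_log = bool(is_log)

    # -- conveniences -----------------------------------------------------
    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def samples(self) -> list[SampleMeta]:
        return [
            SampleMeta(sid, row["species"], row["tissue"], int(row["replicate"]))
            for sid, row in self.meta.iterrows()
        ]

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.meta["species"]))

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.meta["tissue"]))

    def subset_transcripts(self, ids) -> "ExpressionMatrix":
        ids = [t for t in ids if t in self.values.index]
        return ExpressionMatrix(self.values.loc[ids], self.meta, self.is_log)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.meta, self.is_log)

    def subset_tissue(self, tissue: str) -> "ExpressionMatrix":
        keep = self.meta.index[self.meta["tissue"] == tissue]
        if len(keep) == 0:
            raise ValueError(f"no samples with tissue {tissue!r}")
        return self.subset_samples(keep)

    def replicate_means(self) -> pd.DataFrame:
        """Mean over replicates: one column per (species, tissue) condition.

        Columns are a MultiIndex (species, tissue) ordered by first
        appearance in the sample metadata. Operates on the current scale.
        """
        key = list(zip(self.meta["species"], self.meta["tissue"]))
        order = list(dict.fromkeys(key))
        out = {}
        for cond in order:
            cols = [s for s, k in zip(self.values.columns, key) if k == cond]
            out[cond] = self.values[cols].mean(axis=1)
        df = pd.DataFrame(out)
        df.columns = pd.MultiIndex.from_tuples(order, names=["species", "tissue"])
        return df

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        scale = "log2(FPKM+1)" if self.is_log else "FPKM"
        return (
            f"<ExpressionMatrix {len(self.transcript_ids)} transcripts x "
            f"{len(self.sample_ids)} samples [{scale}]>"
        )


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Return a copy of ``m`` with every value v replaced by log2(v + 1).

    Refuses to transform a matrix that is already on the log scale (double
    transforms silently corrupt downstream fold changes).
    """
    if m.is_log:
        raise ValueError("matrix is already log2(FPKM+1); refusing double transform")
    return ExpressionMatrix(np.log2(m.values + 1.0), m.meta, is_log=True)


def inverse_log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Undo log2(FPKM + 1): v -> 2**v - 1, clipped at 0 against round-off."""
    if not m.is_log:
        raise ValueError("matrix is already on the linear scale")
    linear = np.clip(np.exp2(m.values) - 1.0, 0.0, None)
    return ExpressionMatrix(linear, m.meta, is_log=False)


@dataclass(frozen=True)
class AnnotationSet:
    """One gene-set annotation term (GO/KEGG-like): id, name, members."""

    term_id: str
    term_name: str
    member_transcripts: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_transcripts", frozenset(self.member_transcripts))
        if not self.member_transcripts:
            raise ValueError(f"annotation term {self.term_id!r} has no members")


class InteractionGraph:
    """Simple undirected protein-protein interaction graph.

    Thin wrapper over a :class:`networkx.Graph` enforcing the invariants the
    pipeline relies on: no self-loops, no duplicate edges, endpoints present.
    """

    def __init__(self, nodes=(), edges=()):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r} not allowed")
            if u not in g or v not in g:
                g.add_node(u)
                g.add_node(v)
            g.add_edge(u, v)
        self._g = g

    @property
    def nx(self):
        return self._g

    @property
    def nodes(self) -> set:
        return set(self._g.nodes)

    @property
    def edges(self) -> set:
        return {frozenset(e) for e in self._g.edges}

    def __len__(self) -> int:
        return self._g.number_of_nodes()


class OmegaTable:
    """Per-transcript dN/dS (omega) values.

    omega > 1 indicates positive selection, omega < 1 purifying selection.
    """

    def __init__(self, omegas: pd.Series):
        omegas = pd.Series(omegas, dtype=float)
        if omegas.index.has_duplicates:
            raise ValueError("duplicate transcript ids in omega table")
        if (omegas < 0).any():
            bad = omegas.index[omegas < 0][0]
            raise ValueError(f"negative omega for transcript {bad!r}")
        if omegas.isna().any():
            raise ValueError("missing omega values")
        self.omegas = omegas

    def __getitem__(self, transcript_id: str) -> float:
        return float(self.omegas[transcript_id])

    def __len__(self) -> int:
        return len(self.omegas)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.omegas.index)
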