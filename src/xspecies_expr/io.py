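"""Readers and writers for every plain-text format the pipeline touches.

All tables are tab-separated UTF-8 with '.' decimals and no quoting. The
expression table has a header row of sample ids and a first column named
``transcript_id``; sample metadata is a four-column TSV (sample_id, species,
tissue, replicate). Gene sets use the GMT convention
(term_id<TAB>term_name<TAB>member...), interactomes a two-column edge list,
and dN/dS a two-column (transcript_id, omega) table. Expression round-trips
at full float precision.
"""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd

from .datamodel import AnnotationSet, ExpressionMatrix, InteractionGraph, OmegaTable

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_omega_table",
    "write_omega_table",
]


def read_sample_metadata(meta_path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    required = {"sample_id", "species", "tissue", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata file lacks columns: {sorted(missing)}")
    meta = meta.set_index("sample_id")
    meta["replicate"] = meta["replicate"].astype(int)
    return meta


def write_sample_metadata(meta: pd.DataFrame, meta_path) -> None:
    out = meta.reset_index()
    out = out.rename(columns={out.columns[0]: "sample_id"})
    out.to_csv(meta_path, sep="\t", index=False)


def read_expression_matrix(path, meta_path) -> ExpressionMatrix:
    """Read an expression TSV plus its sample-metadata TSV.

    Fails hard (naming the offender) on samples absent from the metadata,
    non-numeric cells, negative values, or an empty table.
    """
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"no transcripts in {path}") from None
    if raw.shape[0] == 0:
        raise ValueError(f"no transcripts in {path}")
    if raw.shape[1] == 0:
        raise ValueError(f"no samples in {path}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric expression value {raw.iat[i, j]!r} at transcript "
            f"{raw.index[i]!r} (row {i + 2}), sample {raw.columns[j]!r} "
            f"(column {j + 2})"
        )
    if values.isna().to_numpy().any():
        i, j = np.argwhere(values.isna().to_numpy())[0]
        raise ValueError(
            f"missing expression value at transcript {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r}"
        )
    meta = read_sample_metadata(meta_path)
    absent = [s for s in values.columns if s not in meta.index]
    if absent:
        raise ValueError(f"sample {absent[0]!r} not present in metadata")
    # exact float parsing (pd.to_numeric above is fast but not round-trip safe)
    exact = pd.DataFrame(
        {c: [float(x) for x in raw[c]] for c in raw.columns}, index=raw.index
    )
    return ExpressionMatrix(exact, meta, is_log=False)


def write_expression_matrix(m: ExpressionMatrix, path, meta_path=None) -> None:
    out = m.values.copy()
    out.index.name = "transcript_id"
    # repr-precision floats so that write -> read is the identity
    out.to_csv(path, sep="\t", float_format="%.17g")
    if meta_path is not None:
        write_sample_metadata(m.meta, meta_path)


def read_gmt(path) -> list[AnnotationSet]:
    terms = []
    with open(path, newline="") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            terms.append(AnnotationSet(parts[0], parts[1], frozenset(parts[2:])))
    return terms


def write_gmt(terms, path) -> None:
    with open(path, "w", newline="") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.term_name, *sorted(t.member_transcripts)]) + "\n")


def read_edge_list(path) -> InteractionGraph:
    """Two-column TSV edge list -> simple undirected graph.

    Duplicate edges (either orientation) collapse; self-loops are an error.
    """
    edges = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"edge line with fewer than two columns: {row}")
            edges.append((row[0], row[1]))
    return InteractionGraph(edges=edges)


def write_edge_list(g: InteractionGraph, path) -> None:
    with open(path, "w", newline="") as fh:
        for e in sorted(tuple(sorted(edge)) for edge in g.edges):
            fh.write(f"{e[0]}\t{e[1]}\n")
    # isolated nodes are not representable in a pure edge list; they are
    # dropped on round-trip, which the pipeline never relies on.


def read_omega_table(path) -> OmegaTable:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("omega table needs two columns: transcript_id, omega")
    ser = pd.Series(df.iloc[:, 1].astype(float).values, index=df.iloc[:, 0].values)
    return OmegaTable(ser)


def write_omega_table(t: OmegaTable, path) -> None:
    df = pd.DataFrame({"transcript_id": t.omegas.index, "omega": t.omegas.values})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
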