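"""One-to-one ortholog inference from tabular pairwise hit files.

Implements the reciprocal-best-hit (RBH) criterion plus the threshold
filters used to build a 1:1 ortholog table across species: E-value <=
1e-10, percent identity >= 40, and transcript length difference <= 10% of
the longer transcript. Running the aligner itself is out of scope; inputs
are BLAST outfmt-6-like tables plus a two-column transcript-length TSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "HitRecord",
    "read_blast_tab",
    "read_length_table",
    "reciprocal_best_hits",
    "filter_orthologs",
    "intersect_across_species",
]


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    query_length: int
    subject_length: int
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if self.query_length <= 0 or self.subject_length <= 0:
            raise ValueError("transcript lengths must be positive")


def read_length_table(path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    return {str(r[0]): int(r[1]) for r in df.itertuples(index=False)}


def read_blast_tab(path, lengths: dict) -> list:
    """Parse BLAST tabular output (outfmt 6 column order).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. Transcript lengths come from the separate
    length table, not from the alignment-length column.
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            q, s = f[0], f[1]
            if q not in lengths:
                raise ValueError(f"no length for query transcript {q!r}")
            if s not in lengths:
                raise ValueError(f"no length for subject transcript {s!r}")
            hits.append(
                HitRecord(
                    query_id=q,
                    subject_id=s,
                    percent_identity=float(f[2]),
                    evalue=float(f[10]),
                    query_length=lengths[q],
                    subject_length=lengths[s],
                    bitscore=float(f[11]),
                )
            )
    return hits


def _best_hits(hits) -> dict:
    """query -> subject of its best hit.

    Best = highest bitscore, ties broken by lowest E-value, then by
    lexicographically smallest subject id (fully deterministic).
    """
    best: dict = {}
    for h in hits:
        cur = best.get(h.query_id)
        key = (-h.bitscore, h.evalue, h.subject_id)
        if cur is None or key < cur[0]:
            best[h.query_id] = (key, h.subject_id)
    return {q: s for q, (_, s) in best.items()}


def reciprocal_best_hits(fwd, rev) -> set:
    """Pairs (a, b) where b is a's best A->B hit and a is b's best B->A hit."""
    fbest = _best_hits(fwd)
    rbest = _best_hits(rev)
    return {(a, b) for a, b in fbest.items() if rbest.get(b) == a}


def filter_orthologs(
    pairs,
    hits,
    evalue_max: float = 1e-10,
    identity_min: float = 40.0,
    max_len_diff_frac: float = 0.10,
    strict_below: bool = False,
) -> set:
    """Keep pairs passing the E-value, identity and length-difference filters.

    ``strict_below`` switches the E-value comparison from <= to < (the
    boundary value 1e-10 is then dropped). Each pair must be supported by a
    hit record; the best-scoring record for the pair is used.
    """
    by_pair: dict = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        cur = by_pair.get(key)
        if cur is None or (-h.bitscore, h.evalue) < (-cur.bitscore, cur.evalue):
            by_pair[key] = h
    kept = set()
    for a, b in pairs:
        h = by_pair.get((a, b))
        if h is None:
            raise ValueError(f"pair ({a!r}, {b!r}) has no supporting hit record")
        ok_e = h.evalue < evalue_max if strict_below else h.evalue <= evalue_max
        len_diff = abs(h.query_length - h.subject_length)
        ok_len = len_diff <= max_len_diff_frac * max(h.query_length, h.subject_length)
        if ok_e and h.percent_identity >= identity_min and ok_len:
            kept.add((a, b))
    return kept


def intersect_across_species(per_species_pairs: dict, manual_additions: dict = None) -> pd.DataFrame:
    """Build the 1:1 ortholog table over all species.

    ``per_species_pairs`` maps each non-reference species to a set of
    (reference_id, species_id) pairs. A reference transcript enters the
    table only if it has exactly one partner in every species. Manual
    additions (same shape) bypass the filters but must not contradict an
    existing mapping.
    """
    manual_additions = manual_additions or {}
    species = sorted(set(per_species_pairs) | set(manual_additions))
    maps: dict = {sp: {} for sp in species}
    for sp in species:
        for a, b in sorted(per_species_pairs.get(sp, ())):
            maps[sp].setdefault(a, set()).add(b)
    for sp, additions in manual_additions.items():
        for a, b in sorted(additions):
            existing = maps[sp].get(a)
            if existing and b not in existing:
                raise ValueError(
                    f"manual addition ({a!r}, {b!r}) conflicts with existing "
                    f"1:1 mapping {a!r} -> {sorted(existing)[0]!r} in {sp}"
                )
            used_by = {ra for ra, bs in maps[sp].items() if b in bs and ra != a}
            if used_by:
                raise ValueError(
                    f"manual addition ({a!r}, {b!r}) conflicts: {b!r} already "
                    f"mapped to {sorted(used_by)[0]!r} in {sp}"
                )
            maps[sp].setdefault(a, set()).add(b)
    rows = []
    refs = set.intersection(*(set(maps[sp]) for sp in species)) if species else set()
    for ref in sorted(refs):
        partners = {sp: maps[sp][ref] for sp in species}
        if any(len(p) != 1 for p in partners.values()):
            continue
        rows.append({"reference": ref, **{sp: next(iter(p)) for sp, p in partners.items()}})
    df = pd.DataFrame(rows, columns=["reference", *species])
    for sp in species:
        if not df.empty and df[sp].duplicated().any():
            dup = df[sp][df[sp].duplicated()].iloc[0]
            raise ValueError(f"transcript {dup!r} mapped to multiple references in {sp}")
    return df.set_index("reference") if not df.empty else df
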