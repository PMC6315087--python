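"""Regenerate the shipped 50-transcript toy dataset under src/xspecies_expr/data/.

Run from the repository root. The fixture is deterministic (fixed seed) and
checked in so examples and regression tests are bit-stable.
"""

from pathlib import Path

from xspecies_expr.datamodel import AnnotationSet
from xspecies_expr.io import (
    write_edge_list,
    write_expression_matrix,
    write_gmt,
    write_omega_table,
)
from xspecies_expr.simulate import SimulationConfig, simulate_dataset

OUT = Path(__file__).resolve().parents[1] / "src" / "xspecies_expr" / "data"

cfg = SimulationConfig(
    seed=42,
    n_transcripts=50,
    frac_tissue_enriched=0.2,
    frac_lineage_dependent=0.2,
    frac_highly_variable=0.1,
    ppi_within_p=0.5,
    ppi_between_p=0.05,
)

m, truth, graph, omega = simulate_dataset(cfg)
OUT.mkdir(parents=True, exist_ok=True)
write_expression_matrix(m, OUT / "toy_expression.tsv", OUT / "toy_meta.tsv")
truth.labels.to_csv(OUT / "toy_truth.tsv", sep="\t", index_label="transcript_id")
truth.scale_factors.to_csv(
    OUT / "toy_scale_factors.tsv", sep="\t", index_label="sample_id",
    header=["factor"], float_format="%.17g",
)
write_omega_table(omega, OUT / "toy_omega.tsv")
write_edge_list(graph, OUT / "toy_ppi_edges.tsv")
with open(OUT / "toy_species_tree.nwk", "w") as fh:
    fh.write(truth.species_tree.as_newick() + "\n")

# annotation terms: the planted groups (signal) plus arbitrary slices (null)
ids = sorted(m.transcript_ids)
terms = [
    AnnotationSet(f"SYN:{name}", f"planted {name} group", members)
    for name, members in sorted(truth.cluster_members.items())
    if name != "background" and len(members) >= 2
]
terms += [
    AnnotationSet("SYN:oddset", "synthetic null term (odd ids)", frozenset(ids[1::2])),
    AnnotationSet("SYN:firsthalf", "synthetic null term (first half)", frozenset(ids[:25])),
]
write_gmt(terms, OUT / "toy_annotations.gmt")

with open(OUT / "toy_run.yaml", "w") as fh:
    fh.write(
        "expression: toy_expression.tsv\n"
        "meta: toy_meta.tsv\n"
        "annotations: toy_annotations.gmt\n"
        "ppi_edges: toy_ppi_edges.tsv\n"
        "omega: toy_omega.tsv\n"
        "seed: 1\n"
        "n_boot: 100\n"
        "k: 6\n"
        "n_init: 10\n"
    )
print("fixture written to", OUT)
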