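"""Neighbor-joining trees for the largest expanded lineages.

Each lineage's sequences are reduced to the fixed-length subsequence
(10-nt V tail + CDR3 + J region), duplicates collapsed, p-distances computed,
and an NJ tree written as Newick with a per-taxon annotation sidecar
(multiplicity, mutation rate, isotype, samples).
"""

from bcrdyn import phylo, pipeline
from common import RESULTS, load_cohort, run_pipeline

records, _ = load_cohort()
res, fc, calls = run_pipeline(records)
annotated = pipeline.assign_lineages_to_records(records, res.clonotypes)

outdir = RESULTS / "07_trees"
outdir.mkdir(parents=True, exist_ok=True)

expanded = calls[calls["expanded"]].copy()
sizes = res.summary.set_index("lineage_id")["n_cdr3"]
expanded["n_cdr3"] = expanded["lineage_id"].map(sizes)
top = expanded.sort_values("n_cdr3", ascending=False).head(5)

for _, call in top.iterrows():
    sub = annotated[annotated["lineage_id"] == call["lineage_id"]]
    aln = phylo.build_alignment(sub, call["lineage_id"])
    tree = phylo.neighbor_joining(phylo.distance_matrix(aln), aln.taxa)
    path = phylo.write_newick(tree, outdir / f"{call['lineage_id']}.nwk",
                              aln.annotations)
    span = aln.annotations["mutation_rate"]
    print(f"{call['lineage_id']}: {len(aln.taxa)} unique subsequences of "
          f"{aln.length} nt, mutation rates {span.min():.1f}-{span.max():.1f}%, "
          f"tree -> {path.name}")
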