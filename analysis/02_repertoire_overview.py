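"""Global repertoire overview: diversity, gene usage, kappa/lambda, mutation classes.

Per sample and chain group: clonotype- and lineage-level Shannon/Gini/Top-100,
V/J/V-J gene-usage Gini, the kappa/lambda sequence ratio, and the mutation-
class composition.  On this synthetic cohort the planted expansions concentrate
the repertoire at 48-72 h, so Top-100 rises and Shannon falls at the trigger
timepoints while the null timepoints stay flat.
"""

import pandas as pd

from bcrdyn.diversity import gini_index
from bcrdyn.mutation import class_proportions
from bcrdyn.repertoire import gene_usage, kappa_lambda_ratio, prepare_records
from bcrdyn import pipeline
from common import load_cohort, run_pipeline, write

records, _ = load_cohort()
prepared = prepare_records(records)
res, fc, calls = run_pipeline(prepared)

write(pipeline.sample_diversity_table(prepared), "02_diversity_clonotypes.tsv")
write(pipeline.lineage_diversity_table(res.metrics), "02_diversity_lineages.tsv")

rows = []
for (animal, tp, cg), grp in prepared.groupby(
    ["animal_id", "timepoint_hr", "chain_group"]
):
    row = dict(animal_id=animal, timepoint_hr=tp, chain_group=cg)
    for level in ("V", "J", "VJ"):
        row[f"gini_{level}"] = gini_index(gene_usage(grp, level))
    if cg == "IgKL":
        row["kappa_lambda_ratio"] = kappa_lambda_ratio(grp)
    rows.append(row)
usage = pd.DataFrame(rows)
write(usage, "02_gene_usage_gini.tsv")

props = []
for (animal, tp), grp in prepared.groupby(["animal_id", "timepoint_hr"]):
    cp = class_proportions(grp)
    cp.insert(0, "animal_id", animal)
    cp.insert(1, "timepoint_hr", tp)
    props.append(cp)
write(pd.concat(props, ignore_index=True), "02_mutation_class_proportions.tsv")

kl = usage.dropna(subset=["kappa_lambda_ratio"]) if "kappa_lambda_ratio" in usage else usage
base = kl[kl["timepoint_hr"] == 0]["kappa_lambda_ratio"].mean()
trig = kl[kl["timepoint_hr"].isin([48, 72])]["kappa_lambda_ratio"].mean()
print(f"mean kappa/lambda ratio: {base:.2f} at 0 h -> {trig:.2f} at 48-72 h "
      f"(lambda-biased planted expansions pull the ratio down)")
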