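"""Characterise the expanded-lineage set: lambda bias, persistence, sharing.

Compares expanded lineages against frequency-matched controls on the
kappa/lambda lineage ratio, computes the timepoint-overlap index for expanded
vs all lineages, and measures inter-individual similarity (Spearman V-gene
usage correlation and Morisita-Horn clonotype similarity) within the expanded
vs control sets.
"""

import itertools

import pandas as pd

from bcrdyn import pipeline
from bcrdyn.dynamics import kappa_lambda_lineage_ratio, sample_control_lineages
from bcrdyn.similarity import gene_usage_correlation, morisita_horn
from common import SEED, load_cohort, run_pipeline, write

LINEAGE_KEY = ["animal_id", "chain_group", "lineage_id"]

records, truth = load_cohort()
res, fc, calls = run_pipeline(records)
expanded = calls[calls["expanded"]]
expanded_ids = set(expanded["lineage_id"])

baseline = res.metrics[res.metrics["timepoint_hr"] == 0][
    LINEAGE_KEY + ["cum_frequency"]
].rename(columns={"cum_frequency": "baseline_frequency"})
summary = res.summary.merge(baseline, on=LINEAGE_KEY, how="left")

light = summary[summary["chain_group"] == "IgKL"]
light_exp = light[light["lineage_id"].isin(
    set(expanded.loc[expanded["chain_group"] == "IgKL", "lineage_id"]))]
pool = light[~light["lineage_id"].isin(expanded_ids)
             & (light["baseline_frequency"] > 0)]
control = sample_control_lineages(
    pool, light_exp, "match_frequency_distribution",
    seed=SEED + 1, frequency_col="baseline_frequency")

kl = pd.DataFrame(
    [
        dict(group="expanded", kappa_lambda=kappa_lambda_lineage_ratio(light_exp),
             n=len(light_exp)),
        dict(group="control", kappa_lambda=kappa_lambda_lineage_ratio(control),
             n=len(control)),
    ]
)
write(kl, "05_kappa_lambda_expanded_vs_control.tsv")

overlap = pd.DataFrame(
    [
        dict(lineage_set="expanded",
             mean_overlap=pipeline.mean_timepoint_overlap(res.metrics,
                                                          subset=expanded_ids)),
        dict(lineage_set="all",
             mean_overlap=pipeline.mean_timepoint_overlap(res.metrics)),
    ]
)
write(overlap, "05_timepoint_overlap.tsv")

# Inter-individual similarity of the expanded sets (are induced antibodies
# shared across animals?)
rows = []
ct = res.clonotypes
for group, ids in (("expanded", expanded_ids),
                   ("control", set(control["lineage_id"]))):
    sub = ct[ct["lineage_id"].isin(ids) & (ct["chain_group"] == "IgKL")]
    for a1, a2 in itertools.combinations(sorted(sub["animal_id"].unique()), 2):
        g1 = sub[sub["animal_id"] == a1]
        g2 = sub[sub["animal_id"] == a2]
        u1 = g1.groupby("v_gene")["count"].sum()
        u2 = g2.groupby("v_gene")["count"].sum()
        c1 = g1.groupby(["v_gene", "j_gene", "cdr3_aa"])["count"].sum()
        c2 = g2.groupby(["v_gene", "j_gene", "cdr3_aa"])["count"].sum()
        c1.index = ["|".join(t) for t in c1.index]
        c2.index = ["|".join(t) for t in c2.index]
        rows.append(
            dict(group=group, pair=f"{a1}-{a2}",
                 v_usage_spearman=gene_usage_correlation(u1 / u1.sum(), u2 / u2.sum()),
                 morisita_horn=morisita_horn(c1, c2))
        )
sim = pd.DataFrame(rows)
write(sim, "05_interindividual_similarity.tsv")

print(kl.to_string(index=False))
print(overlap.to_string(index=False))
print("mean inter-individual Morisita-Horn by group:")
print(sim.groupby("group")["morisita_horn"].mean().to_string())
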