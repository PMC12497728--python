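"""Trace expanded lineages back to their pre-stimulation (0 h) members.

The 0 h sequences of expanded lineages ("original-expanded" lineages) are
summarised by isotype and mutation class and compared with an equal number of
randomly sampled non-expanded control lineages: a dominant IgA/G/E-mutated
fraction marks a memory/effector-like B-cell origin, matching the planted
origin class of the cohort.
"""

import numpy as np
import pandas as pd

from bcrdyn import pipeline
from bcrdyn.dynamics import original_expanded
from bcrdyn.mutation import shm_rate
from common import SEED, load_cohort, run_pipeline, write

records, truth = load_cohort()
res, fc, calls = run_pipeline(records)
annotated = pipeline.assign_lineages_to_records(records, res.clonotypes)

expanded = calls[calls["expanded"]]
heavy_ids = set(expanded.loc[expanded["chain_group"] == "IGH", "lineage_id"])
present0 = set(
    res.metrics[(res.metrics["timepoint_hr"] == 0)
                & (res.metrics["chain_group"] == "IGH")]["lineage_id"]
)
pool = sorted((present0 - set(expanded["lineage_id"])))
rng = np.random.default_rng(SEED + 2)
control_ids = set(rng.choice(pool, size=len(heavy_ids), replace=False))

rows = []
for group, ids in (("original_expanded", heavy_ids), ("control", control_ids)):
    origin, n_excluded = original_expanded(annotated, ids)
    frac = pipeline.origin_class_fractions(annotated, ids)
    frac.insert(0, "group", group)
    rows.append(frac)
    iso = origin.groupby("isotype")["duplicate_count"].sum()
    iso = iso / iso.sum()
    mean_rate = shm_rate(origin)
    print(f"{group}: n={len(ids)} lineages ({n_excluded} absent at 0 h), "
          f"pooled 0 h mutation rate {mean_rate:.2f}%, "
          f"IgA fraction {iso.get('IgA', 0):.2f}, IgM fraction {iso.get('IgM', 0):.2f}")
origin_classes = pd.concat(rows, ignore_index=True)
write(origin_classes, "06_origin_class_fractions.tsv")
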