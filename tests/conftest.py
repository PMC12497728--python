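import numpy as np
import pandas as pd
import pytest

from bcrdyn import pipeline, synthetic


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Build a record table from partial row dicts, filling valid defaults."""
    defaults = dict(
        sequence_id="s", animal_id="M1", species="IRM", timepoint_hr=0,
        locus="IGK", v_call="IGKV1", j_call="IGKJ1", cdr3_aa="CQQYNSYPT",
        isotype="NA", v_mismatches=0, j_mismatches=0,
        v_aligned_len=140, j_aligned_len=36, duplicate_count=1,
        v_tail_nt="ACGTACGTAC", j_region_nt="ACG" * 12,
    )
    out = []
    for i, row in enumerate(rows):
        r = {**defaults, **row}
        r.setdefault("cdr3", synthetic.aa_to_nt(r["cdr3_aa"]))
        if r["sequence_id"] == "s":
            r["sequence_id"] = f"s{i}"
        out.append(r)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def tiny_cohort():
    """One planted tiny cohort shared across tests (generation is the cost)."""
    records, truth = synthetic.generate_cohort(synthetic.tiny_config(7))
    return records, truth


@pytest.fixture(scope="session")
def tiny_pipeline(tiny_cohort):
    records, truth = tiny_cohort
    res = pipeline.run_lineage_pipeline(records)
    fc, calls = pipeline.call_expansions(res.metrics)
    return dict(records=records, truth=truth, result=res, fold_changes=fc, calls=calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
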