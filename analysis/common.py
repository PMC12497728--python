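"""Shared plumbing for the analysis drivers.

The drivers operate on one simulated mid-scale cohort (3 animals, 20k
sequences per chain group per sample, 36 planted expanded lineages) cached
under scratch/cohort so the sequence of scripts 01..07 reuses the same data.
"""

from pathlib import Path

import pandas as pd

from bcrdyn import io_airr, pipeline, synthetic
from bcrdyn.synthetic import CohortConfig, PlantedConfig

ROOT = Path(__file__).resolve().parent.parent
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
SEED = 20260928


def cohort_config(seed: int = SEED) -> CohortConfig:
    return CohortConfig(
        seed=seed,
        n_animals=3,
        depth={"IGH": 20000, "IgKL": 20000},
        n_lineages={"IGH": 240, "IgKL": 300},
        n_transient={"IGH": 240, "IgKL": 300},
        planted=PlantedConfig(n_light=24, n_heavy=12, baseline_frequency=5e-4),
    )


def load_cohort():
    """Read the cached cohort, simulating it on first use."""
    if not (COHORT_DIR / "truth.tsv").exists():
        print(f"simulating cohort (seed={SEED}) under {COHORT_DIR} ...")
        synthetic.write_fixture(cohort_config(), COHORT_DIR)
    records = io_airr.read_cohort(COHORT_DIR)
    truth = pd.read_csv(COHORT_DIR / "truth.tsv", sep="\t")
    return records, truth


def run_pipeline(records):
    res = pipeline.run_lineage_pipeline(records)
    fc, calls = pipeline.call_expansions(res.metrics)
    return res, fc, calls


def write(df: pd.DataFrame, name: str) -> Path:
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, sep="\t", index=False)
    print(f"  wrote {path.relative_to(ROOT)} ({len(df)} rows)")
    return path
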