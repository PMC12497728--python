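"""Reading and writing annotated rearrangement tables.

The on-disk dialect is an AIRR-Rearrangement-style TSV (tab separated, UTF-8,
header row) using the community column names where they exist (``v_call``,
``j_call``, ``duplicate_count``, ``locus``) plus extension columns carrying the
alignment mismatch counts and the fixed-length V tail used for lineage
phylogenies.  A column map can rename foreign headers onto this dialect at read
time.

One file holds one sample: all records share ``animal_id`` and
``timepoint_hr``.  Rows violating the record invariants are rejected (never
silently kept) and counted in the returned sample's rejection report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: Columns every rearrangement table must provide (after column-map renaming).
REQUIRED_COLUMNS = (
    "sequence_id",
    "animal_id",
    "species",
    "timepoint_hr",
    "locus",
    "v_call",
    "j_call",
    "cdr3_aa",
    "cdr3",
    "isotype",
    "v_mismatches",
    "j_mismatches",
    "v_aligned_len",
    "j_aligned_len",
    "duplicate_count",
)

#: Optional columns (needed only for phylogeny construction).
OPTIONAL_COLUMNS = ("v_tail_nt", "j_region_nt")

LOCI = ("IGH", "IGK", "IGL")
HEAVY_ISOTYPES = ("IgM", "IgD", "IgG", "IgA", "IgE")
TIMEPOINTS_HR = (0, 8, 24, 48, 72, 168)

_INT_COLUMNS = (
    "timepoint_hr",
    "v_mismatches",
    "j_mismatches",
    "v_aligned_len",
    "j_aligned_len",
    "duplicate_count",
)


class MissingColumnError(ValueError):
    """A required column is absent from the input table."""


class EmptySampleError(ValueError):
    """The input table holds no data rows."""


def chain_group(locus: pd.Series | str):
    """Map a locus to its analysis chain group: IGH alone, IGK+IGL pooled as IgKL.

    Heavy- and light-chain repertoires are sequenced and normalised separately;
    the two light-chain loci share one denominator because the kappa/lambda
    ratio and light-chain diversity are joint quantities.
    """
    if isinstance(locus, str):
        return "IGH" if locus == "IGH" else "IgKL"
    return locus.map(lambda x: "IGH" if x == "IGH" else "IgKL")


@dataclass
class RepertoireSample:
    """All rearrangement records of one animal at one timepoint."""

    animal_id: str
    species: str
    timepoint_hr: int
    records: pd.DataFrame
    n_rejected: int = 0
    rejection_reasons: dict = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return int(self.records["duplicate_count"].sum())

    def __len__(self) -> int:
        return len(self.records)


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Split rows into (valid, per-reason rejection counts).

    Enforced invariants:

    * ``len(cdr3) == 3 * len(cdr3_aa)``
    * ``v_mismatches <= v_aligned_len`` and ``j_mismatches <= j_aligned_len``
    * mismatch counts >= 0, aligned lengths >= 1, duplicate_count >= 1
    * light-chain isotype is ``NA``; heavy-chain isotype is a real class
    * ``v_tail_nt`` has length 10 when present
    * locus is one of IGH/IGK/IGL
    """
    reasons: dict[str, int] = {}
    ok = pd.Series(True, index=df.index)

    def _flag(mask: pd.Series, reason: str) -> None:
        bad = mask & ok
        n = int(bad.sum())
        if n:
            reasons[reason] = n
        ok[bad] = False

    _flag(~df["locus"].isin(LOCI), "unknown_locus")
    _flag(
        df["cdr3"].str.len() != 3 * df["cdr3_aa"].str.len(),
        "cdr3_nt_aa_length_mismatch",
    )
    _flag(df["v_mismatches"] > df["v_aligned_len"], "v_mismatches_exceed_length")
    _flag(df["j_mismatches"] > df["j_aligned_len"], "j_mismatches_exceed_length")
    _flag((df["v_mismatches"] < 0) | (df["j_mismatches"] < 0), "negative_mismatches")
    _flag((df["v_aligned_len"] < 1) | (df["j_aligned_len"] < 1), "nonpositive_aligned_length")
    _flag(df["duplicate_count"] < 1, "nonpositive_duplicate_count")

    is_heavy = df["locus"] == "IGH"
    _flag(is_heavy & ~df["isotype"].isin(HEAVY_ISOTYPES), "heavy_chain_without_isotype")
    _flag(~is_heavy & (df["isotype"] != "NA"), "light_chain_with_isotype")

    if "v_tail_nt" in df.columns:
        has_tail = df["v_tail_nt"].notna() & (df["v_tail_nt"] != "")
        _flag(has_tail & (df["v_tail_nt"].str.len() != 10), "v_tail_not_10nt")

    return df[ok].copy(), reasons


def read_rearrangements(
    path: str | Path, column_map: dict[str, str] | None = None
) -> RepertoireSample:
    """Read one sample's rearrangement TSV and validate it.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    column_map
        Optional ``{file_column: dialect_column}`` renaming applied before
        validation, for tables produced with foreign headers.

    Raises
    ------
    MissingColumnError
        If a required column is absent after renaming.
    EmptySampleError
        If the file holds a header but no rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing required column(s): {missing}")
    if df.empty:
        raise EmptySampleError(f"{path}: no data rows")

    for col in _INT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    coerce_bad = df[list(_INT_COLUMNS)].isna().any(axis=1)
    reasons = {}
    if coerce_bad.any():
        reasons["non_integer_numeric_field"] = int(coerce_bad.sum())
        df = df[~coerce_bad]
    df = df.astype({c: "int64" for c in _INT_COLUMNS})

    valid, more_reasons = validate_records(df)
    for k, v in more_reasons.items():
        reasons[k] = reasons.get(k, 0) + v
    n_rejected = sum(reasons.values())
    if n_rejected:
        logger.warning("%s: rejected %d row(s): %s", path, n_rejected, reasons)

    if valid.empty:
        raise EmptySampleError(f"{path}: all {n_rejected} rows failed validation")

    animals = valid["animal_id"].unique()
    tps = valid["timepoint_hr"].unique()
    if len(animals) != 1 or len(tps) != 1:
        raise ValueError(
            f"{path}: a sample file must hold one animal/timepoint, "
            f"got animals={list(animals)}, timepoints={list(tps)}"
        )

    return RepertoireSample(
        animal_id=animals[0],
        species=valid["species"].iloc[0],
        timepoint_hr=int(tps[0]),
        records=valid.reset_index(drop=True),
        n_rejected=n_rejected,
        rejection_reasons=reasons,
    )


def write_rearrangements(sample: RepertoireSample, path: str | Path) -> Path:
    """Write a sample as TSV with a stable column order; round-trips losslessly."""
    path = Path(path)
    cols = [c for c in (*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS) if c in sample.records.columns]
    extra = [c for c in sample.records.columns if c not in cols]
    sample.records[cols + extra].to_csv(path, sep="\t", index=False)
    return path


def write_cohort(records: pd.DataFrame, outdir: str | Path) -> list[Path]:
    """Split a cohort record table into per-(animal, timepoint) sample files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (animal, tp), grp in records.groupby(["animal_id", "timepoint_hr"], sort=True):
        sample = RepertoireSample(
            animal_id=animal,
            species=grp["species"].iloc[0],
            timepoint_hr=int(tp),
            records=grp.reset_index(drop=True),
        )
        paths.append(write_rearrangements(sample, outdir / f"{animal}_{tp:03d}hr.tsv"))
    return paths


def read_cohort(directory: str | Path, pattern: str = "*hr.tsv") -> pd.DataFrame:
    """Read every sample TSV in a directory into one cohort record table."""
    directory = Path(directory)
    files = sorted(directory.glob(pattern))
    if not files:
        raise FileNotFoundError(f"no sample files matching {pattern!r} in {directory}")
    frames = [read_rearrangements(f).records for f in files]
    return pd.concat(frames, ignore_index=True)
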