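"""Synthetic longitudinal antibody-repertoire cohorts with planted expansions.

The generator emulates the statistical structure the downstream analysis
assumes: per animal, a fixed baseline repertoire of clonal lineages with
power-law abundances, a three-peak mutation-rate mixture (naive-like,
intermediate, memory/effector-like) with isotype assignment conditional on the
mutation class, and a kappa/lambda split of the light-chain loci.  The
baseline pool models the *reliably sampled* portion of a repertoire: the
default lineage counts are chosen so that every lineage's expected
per-timepoint count stays above the Poisson noise floor at the configured
depth, where a spurious 8-fold frequency jump between two resamples is
vanishingly rare; the large singleton tail of a real repertoire, which a
fold-change analysis cannot classify either way, is deliberately not
represented.  Each
timepoint is an independent multinomial resample of the baseline at the
configured sequencing depth, so a cohort without planted effects is an exact
null for the fold-change machinery.

Planted expanded lineages perturb the resampling weights at 48 h and 72 h by
three mechanisms that mirror the expansion criteria: a frequency boost
(2^target log2 FC), a burst of new one-mismatch CDR3 variants (unique-CDR3
boost), and an elevated per-sequence mutation rate.  Planted light-chain
lineages are biased toward the lambda locus; a configurable fraction persists
to 1 week, the rest contract below detection.  Every random draw flows from a
single seeded generator, so identical config + seed gives identical output
bytes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_airr

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: One fixed codon per amino acid, so cdr3 (nt) is a deterministic function of
#: cdr3_aa and single-aa variants differ in exactly one codon.
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
NUCLEOTIDES = "ACGT"

MUTATION_CLASSES = ("naive", "intermediate", "memory")

#: Heavy-chain isotype probabilities conditional on the mutation class.
ISOTYPE_GIVEN_CLASS = {
    "naive": {"IgM": 0.8, "IgD": 0.2},
    "intermediate": {"IgM": 0.5, "IgG": 0.3, "IgA": 0.2},
    "memory": {"IgG": 0.5, "IgA": 0.42, "IgE": 0.08},
}


@dataclass
class PlantedConfig:
    """Specification of the planted expanded lineages and their mechanisms.

    Fold-change targets default to one log2 unit above each chain-specific
    expansion threshold (frequency 3 -> 4, unique CDR3 2 -> 3, mutation rate
    1.3 -> 2.3 light / 1.5 -> 2.5 heavy).
    """

    n_light: int = 30
    n_heavy: int = 20
    mechanisms: tuple = ("frequency", "unique_cdr3", "mutation_rate")
    log2_fc_frequency: float = 4.0
    log2_fc_unique_cdr3: float = 3.0
    log2_fc_mutation_light: float = 2.3
    log2_fc_mutation_heavy: float = 2.5
    baseline_frequency: float = 4e-4
    burst_variants: int = 21
    lambda_bias: float = 0.8
    persistence_prob: float = 0.6
    origin_class: str = "memory"  # mutation class of the founding B cells


@dataclass
class CohortConfig:
    """Study-design and distributional parameters of a synthetic cohort."""

    seed: int
    n_animals: int = 6
    timepoints: tuple = io_airr.TIMEPOINTS_HR
    depth: dict = field(default_factory=lambda: {"IGH": 100_000, "IgKL": 100_000})
    n_lineages: dict = field(default_factory=lambda: {"IGH": 800, "IgKL": 1000})
    #: Transient lineages model clones transiting the blood: each is present at
    #: exactly one (random) timepoint with an expected count near the detection
    #: floor.  They shape presence/overlap and diversity but, lacking a
    #: measurable baseline-vs-post ratio, never enter fold-change calls.
    n_transient: dict = field(default_factory=lambda: {"IGH": 800, "IgKL": 1000})
    transient_count_range: tuple = (3.0, 12.0)  # expected reads at their timepoint
    powerlaw_alpha: float = 0.9
    mutation_weights: tuple = (0.4, 0.3, 0.3)
    mutation_peaks: tuple = (0.05, 1.5, 6.5)  # percent, per class
    rate_spread_log2: float = 0.35
    kappa_fraction: float = 0.6
    n_v_genes: dict = field(default_factory=lambda: {"IGH": 60, "IGK": 40, "IGL": 40})
    n_j_genes: dict = field(default_factory=lambda: {"IGH": 6, "IGK": 5, "IGL": 5})
    cdr3_len_range: dict = field(
        default_factory=lambda: {"IGH": (8, 30), "IgKL": (8, 24)}
    )
    v_aligned_len_range: tuple = (120, 160)
    j_region_len_range: tuple = (30, 48)
    max_variants: int = 5
    mean_extra_variants: float = 1.2
    seed_cdr3_min_distance: int = 4
    planted: PlantedConfig | None = field(default_factory=PlantedConfig)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if abs(sum(self.mutation_weights) - 1.0) > 1e-9:
            raise ValueError("mutation mixture weights must sum to 1")
        if self.planted:
            per_cg = {"IgKL": self.planted.n_light, "IGH": self.planted.n_heavy}
            for cg, n in per_cg.items():
                if n > self.n_lineages[cg]:
                    raise ValueError(f"more planted than baseline lineages for {cg}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def tiny_config(seed: int, planted: bool = True) -> CohortConfig:
    """Small cohort for fast tests: 2 animals, 5k sequences per chain group."""
    return CohortConfig(
        seed=seed,
        n_animals=2,
        depth={"IGH": 5000, "IgKL": 5000},
        n_lineages={"IGH": 120, "IgKL": 160},
        n_transient={"IGH": 120, "IgKL": 160},
        planted=PlantedConfig(n_light=8, n_heavy=6, baseline_frequency=2e-3)
        if planted
        else None,
    )


def _random_aa(rng, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _random_nt(rng, length: int) -> str:
    return "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, size=length))


def _mutate_one(rng, seq: str, existing: set) -> str:
    """A single-aa substitution variant of ``seq`` not already in ``existing``."""
    for _ in range(200):
        pos = int(rng.integers(0, len(seq)))
        new = AMINO_ACIDS[int(rng.integers(0, 20))]
        if new != seq[pos]:
            cand = seq[:pos] + new + seq[pos + 1:]
            if cand not in existing:
                return cand
    raise RuntimeError("could not generate a fresh CDR3 variant")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def aa_to_nt(seq: str) -> str:
    return "".join(CODON[a] for a in seq)


class _GenePools:
    """Cohort-level gene label sets, usage probabilities, and segment sequences."""

    def __init__(self, config: CohortConfig, rng):
        self.v_genes, self.v_probs, self.v_tail = {}, {}, {}
        self.j_genes, self.j_probs, self.j_region, self.j_len = {}, {}, {}, {}
        for locus in ("IGH", "IGK", "IGL"):
            nv, nj = config.n_v_genes[locus], config.n_j_genes[locus]
            self.v_genes[locus] = [f"{locus}V{i + 1}" for i in range(nv)]
            self.j_genes[locus] = [f"{locus}J{i + 1}" for i in range(nj)]
            self.v_probs[locus] = rng.dirichlet(np.ones(nv))
            self.j_probs[locus] = rng.dirichlet(np.ones(nj))
            for g in self.v_genes[locus]:
                self.v_tail[g] = _random_nt(rng, 10)
            lo, hi = config.j_region_len_range
            for g in self.j_genes[locus]:
                n = int(rng.integers(lo, hi + 1))
                self.j_region[g] = _random_nt(rng, n)
                self.j_len[g] = n


def _build_universe(config, rng, pools, animal_id, chain_group, planted_specs):
    """Clonotype universe of one animal's chain group.

    Returns (clonotype table, lineage table).  ``planted_specs`` is the list of
    planted-lineage dicts assigned to this animal/chain group.
    """
    n_base = config.n_lineages[chain_group]
    alpha = config.powerlaw_alpha
    lo_len, hi_len = config.cdr3_len_range[chain_group]
    vlo, vhi = config.v_aligned_len_range

    # Zipf weights over shuffled ranks, normalised to 1 for the baseline pool.
    ranks = np.arange(1, n_base + 1, dtype=float)
    w = ranks ** (-alpha)
    w /= w.sum()
    w = w[rng.permutation(n_base)]

    if chain_group == "IGH":
        loci = np.full(n_base, "IGH")
    else:
        loci = np.where(rng.random(n_base) < config.kappa_fraction, "IGK", "IGL")
    classes = rng.choice(len(MUTATION_CLASSES), size=n_base, p=config.mutation_weights)
    peaks = np.asarray(config.mutation_peaks)
    rates = peaks[classes] * 2.0 ** rng.normal(0.0, config.rate_spread_log2, n_base)
    rates = np.clip(rates, 0.02, 30.0)
    lens = rng.integers(lo_len, hi_len + 1, size=n_base)
    v_lens = rng.integers(vlo, vhi + 1, size=n_base)
    n_extra = np.minimum(
        rng.poisson(config.mean_extra_variants, size=n_base), config.max_variants - 1
    )

    lineages = []
    seeds_by_bucket: dict[tuple, list[str]] = {}

    def _draw_seed(locus, v, j, length):
        bucket = seeds_by_bucket.setdefault((locus, v, j, length), [])
        for _ in range(50):
            cand = _random_aa(rng, length)
            if all(
                _hamming(cand, s) >= config.seed_cdr3_min_distance for s in bucket
            ):
                bucket.append(cand)
                return cand
        raise RuntimeError("CDR3 space exhausted; reduce lineage count or widen lengths")

    for i in range(n_base):
        locus = str(loci[i])
        v = pools.v_genes[locus][
            int(rng.choice(len(pools.v_genes[locus]), p=pools.v_probs[locus]))
        ]
        j = pools.j_genes[locus][
            int(rng.choice(len(pools.j_genes[locus]), p=pools.j_probs[locus]))
        ]
        seed_cdr3 = _draw_seed(locus, v, j, int(lens[i]))
        klass = MUTATION_CLASSES[classes[i]]
        iso = "NA"
        if chain_group == "IGH":
            probs = ISOTYPE_GIVEN_CLASS[klass]
            iso = list(probs)[int(rng.choice(len(probs), p=list(probs.values())))]
        lineages.append(
            dict(
                uid=f"{animal_id}:{chain_group}:L{i}",
                planted=False,
                locus=locus,
                v=v,
                j=j,
                seed_cdr3=seed_cdr3,
                weight=w[i],
                rate=rates[i],
                isotype=iso,
                v_len=int(v_lens[i]),
                n_extra=int(n_extra[i]),
                n_burst=0,
                persistent=True,
                present_tp=-1,
                mechanisms=(),
                fc_freq=0.0,
                fc_mut=0.0,
            )
        )

    # Transient lineages: single-clonotype clones transiting the blood at one
    # random timepoint, with abundance near the detection floor.
    n_trans = config.n_transient.get(chain_group, 0)
    depth = config.depth[chain_group]
    clo, chi = config.transient_count_range
    for i in range(n_trans):
        if chain_group == "IGH":
            locus = "IGH"
        else:
            locus = "IGK" if rng.random() < config.kappa_fraction else "IGL"
        v = pools.v_genes[locus][
            int(rng.choice(len(pools.v_genes[locus]), p=pools.v_probs[locus]))
        ]
        j = pools.j_genes[locus][
            int(rng.choice(len(pools.j_genes[locus]), p=pools.j_probs[locus]))
        ]
        length = int(rng.integers(lo_len, hi_len + 1))
        seed_cdr3 = _draw_seed(locus, v, j, length)
        klass = MUTATION_CLASSES[
            int(rng.choice(3, p=config.mutation_weights))
        ]
        peak = config.mutation_peaks[MUTATION_CLASSES.index(klass)]
        rate = float(
            np.clip(peak * 2.0 ** rng.normal(0.0, config.rate_spread_log2), 0.02, 30.0)
        )
        iso = "NA"
        if chain_group == "IGH":
            probs = ISOTYPE_GIVEN_CLASS[klass]
            iso = list(probs)[int(rng.choice(len(probs), p=list(probs.values())))]
        lineages.append(
            dict(
                uid=f"{animal_id}:{chain_group}:T{i}",
                planted=False,
                locus=locus,
                v=v,
                j=j,
                seed_cdr3=seed_cdr3,
                weight=float(rng.uniform(clo, chi)) / depth,
                rate=rate,
                isotype=iso,
                v_len=int(rng.integers(vlo, vhi + 1)),
                n_extra=0,
                n_burst=0,
                persistent=False,
                present_tp=int(
                    config.timepoints[int(rng.integers(0, len(config.timepoints)))]
                ),
                mechanisms=(),
                fc_freq=0.0,
                fc_mut=0.0,
            )
        )

    for k, spec in enumerate(planted_specs):
        if chain_group == "IGH":
            locus = "IGH"
        else:
            locus = "IGL" if rng.random() < spec["lambda_bias"] else "IGK"
        v = pools.v_genes[locus][
            int(rng.choice(len(pools.v_genes[locus]), p=pools.v_probs[locus]))
        ]
        j = pools.j_genes[locus][
            int(rng.choice(len(pools.j_genes[locus]), p=pools.j_probs[locus]))
        ]
        length = int(rng.integers(lo_len, hi_len + 1))
        seed_cdr3 = _draw_seed(locus, v, j, length)
        klass = spec["origin_class"]
        peak = config.mutation_peaks[MUTATION_CLASSES.index(klass)]
        rate = float(
            np.clip(peak * 2.0 ** rng.normal(0.0, config.rate_spread_log2), 0.02, 30.0)
        )
        iso = "NA"
        if chain_group == "IGH":
            probs = ISOTYPE_GIVEN_CLASS[klass]
            iso = list(probs)[int(rng.choice(len(probs), p=list(probs.values())))]
        lineages.append(
            dict(
                uid=f"{animal_id}:{chain_group}:P{k}",
                planted=True,
                locus=locus,
                v=v,
                j=j,
                seed_cdr3=seed_cdr3,
                weight=spec["baseline_frequency"],
                rate=rate,
                isotype=iso,
                v_len=int(rng.integers(vlo, vhi + 1)),
                n_extra=2,  # two minor baseline variants besides the seed
                n_burst=int(spec["n_burst"]),
                present_tp=-1,
                persistent=bool(rng.random() < spec["persistence_prob"]),
                mechanisms=tuple(spec["mechanisms"]),
                fc_freq=spec["fc_freq"],
                fc_mut=spec["fc_mut"],
            )
        )

    # Expand lineages into clonotypes (baseline variants + planted bursts).
    # Mismatch counts are drawn once per clonotype — mutations are a property
    # of the clone's sequences, so resampling a clonotype at another timepoint
    # observes the same mismatches.  Planted mutation-mechanism lineages carry
    # a second, elevated mismatch draw used at trigger timepoints.
    rows = []
    for lin_idx, lin in enumerate(lineages):
        variants = {lin["seed_cdr3"]}
        ordered = [lin["seed_cdr3"]]
        for _ in range(lin["n_extra"]):
            var = _mutate_one(rng, lin["seed_cdr3"], variants)
            variants.add(var)
            ordered.append(var)
        n_var = len(ordered)
        base_shares = (
            [1.0] if n_var == 1 else [0.6] + [0.4 / (n_var - 1)] * (n_var - 1)
        )
        bursts = []
        if lin["planted"] and "unique_cdr3" in lin["mechanisms"]:
            for _ in range(lin["n_burst"]):
                var = _mutate_one(rng, lin["seed_cdr3"], variants)
                variants.add(var)
                bursts.append(var)
        if lin["planted"]:
            # Trigger-time allocation: seed keeps 30%, minors 10% each, the
            # burst pool shares 50% (or renormalised without bursts).
            trig = [0.3] + [0.1] * (n_var - 1)
            if bursts:
                trig += [0.5 / len(bursts)] * len(bursts)
            trig = list(np.asarray(trig) / np.sum(trig))
        else:
            trig = base_shares

        all_vars = ordered + bursts
        all_base = base_shares + [0.0] * len(bursts)
        n_all = len(all_vars)
        v_len = lin["v_len"]
        j_len = pools.j_len[lin["j"]]
        hot = lin["planted"] and "mutation_rate" in lin["mechanisms"]
        hot_rate = min(35.0, lin["rate"] * 2.0 ** lin["fc_mut"]) if hot else lin["rate"]
        # The founding clone's V/J mismatches are drawn once; CDR3 variants
        # inherit them (the CDR3 lies outside the V/J aligned regions) plus a
        # small number of additional substitutions of their own.
        v_seed_mm = rng.binomial(v_len, lin["rate"] / 100.0)
        j_seed_mm = rng.binomial(j_len, lin["rate"] / 100.0)
        v_mm_base = np.minimum(v_len, v_seed_mm + rng.poisson(0.15, size=n_all))
        j_mm_base = np.minimum(j_len, j_seed_mm + rng.poisson(0.05, size=n_all))
        if hot:
            v_mm_hot = np.maximum(
                rng.binomial(v_len, hot_rate / 100.0, size=n_all), v_mm_base
            )
            j_mm_hot = np.maximum(
                rng.binomial(j_len, hot_rate / 100.0, size=n_all), j_mm_base
            )
        else:
            v_mm_hot, j_mm_hot = v_mm_base, j_mm_base
        for k, (cdr3, sb, st) in enumerate(zip(all_vars, all_base, trig)):
            rows.append(
                (lin_idx, cdr3, sb, st,
                 int(v_mm_base[k]), int(j_mm_base[k]),
                 int(v_mm_hot[k]), int(j_mm_hot[k]))
            )

    clono = pd.DataFrame(
        rows,
        columns=["lin_idx", "cdr3_aa", "share_base", "share_trig",
                 "v_mm_base", "j_mm_base", "v_mm_hot", "j_mm_hot"],
    )
    lin_table = pd.DataFrame(lineages)
    lin_table["lin_idx"] = np.arange(len(lin_table))
    return clono, lin_table


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full cohort.

    Returns ``(records, truth)``: the cohort record table in the io dialect and
    the planted-lineage ground-truth table (empty for a null cohort).
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pools = _GenePools(config, rng)

    animals = [f"M{i + 1}" for i in range(config.n_animals)]
    species = {
        a: ("IRM" if i < (config.n_animals + 1) // 2 else "AGM")
        for i, a in enumerate(animals)
    }

    # Distribute planted lineages round-robin over animals.
    planted_by = {(a, cg): [] for a in animals for cg in ("IGH", "IgKL")}
    p = config.planted
    if p is not None:
        for cg, n, fc_mut in (
            ("IgKL", p.n_light, p.log2_fc_mutation_light),
            ("IGH", p.n_heavy, p.log2_fc_mutation_heavy),
        ):
            for k in range(n):
                planted_by[(animals[k % len(animals)], cg)].append(
                    dict(
                        mechanisms=p.mechanisms,
                        fc_freq=p.log2_fc_frequency,
                        fc_mut=fc_mut,
                        baseline_frequency=p.baseline_frequency,
                        lambda_bias=p.lambda_bias,
                        persistence_prob=p.persistence_prob,
                        origin_class=p.origin_class,
                        n_burst=p.burst_variants,
                    )
                )

    universes = {}
    for a in animals:
        for cg in ("IGH", "IgKL"):
            specs = planted_by[(a, cg)]
            for s in specs:
                s.setdefault("n_burst", p.burst_variants if p else 0)
            universes[(a, cg)] = _build_universe(config, rng, pools, a, cg, specs)

    trigger = {48, 72}
    frames = []
    realized = {}  # (uid, tp) -> drawn count
    for a in animals:
        for tp in config.timepoints:
            for cg in ("IGH", "IgKL"):
                clono, lins = universes[(a, cg)]
                lw = lins["weight"].to_numpy()
                planted_mask = lins["planted"].to_numpy()
                persistent = lins["persistent"].to_numpy()
                freq_mech = np.array(
                    ["frequency" in m for m in lins["mechanisms"]]
                )
                mut_mech = np.array(
                    ["mutation_rate" in m for m in lins["mechanisms"]]
                )
                boosted = tp in trigger or (tp == 168)
                lin_w = lw.copy()
                present_tp = lins["present_tp"].to_numpy()
                lin_w[(present_tp >= 0) & (present_tp != tp)] = 0.0
                use_trig_shares = np.zeros(len(lins), dtype=bool)
                elevated = np.zeros(len(lins), dtype=bool)
                if boosted and planted_mask.any():
                    if tp in trigger:
                        active = planted_mask
                    else:  # 1 week: persistent lineages stay up, the rest vanish
                        active = planted_mask & persistent
                        lin_w[planted_mask & ~persistent] = 0.0
                    lin_w[active & freq_mech] = (
                        lw[active & freq_mech]
                        * 2.0 ** lins.loc[active & freq_mech, "fc_freq"].to_numpy()
                    )
                    use_trig_shares[active] = True
                    elevated[active & mut_mech] = True

                li = clono["lin_idx"].to_numpy()
                shares = np.where(
                    use_trig_shares[li],
                    clono["share_trig"].to_numpy(),
                    clono["share_base"].to_numpy(),
                )
                wts = lin_w[li] * shares
                total = wts.sum()
                counts = rng.multinomial(config.depth[cg], wts / total)
                nz = np.flatnonzero(counts)

                bump = elevated[li[nz]]
                v_len = lins["v_len"].to_numpy()[li[nz]]
                j_gene = lins["j"].to_numpy()[li[nz]]
                j_len = np.array([pools.j_len[g] for g in j_gene])
                v_mm = np.where(
                    bump, clono["v_mm_hot"].to_numpy()[nz], clono["v_mm_base"].to_numpy()[nz]
                )
                j_mm = np.where(
                    bump, clono["j_mm_hot"].to_numpy()[nz], clono["j_mm_base"].to_numpy()[nz]
                )

                cdr3_aa = clono["cdr3_aa"].to_numpy()[nz]
                v_gene = lins["v"].to_numpy()[li[nz]]
                df = pd.DataFrame(
                    {
                        "sequence_id": [
                            f"{a}-{cg}-{tp}-{k}" for k in range(len(nz))
                        ],
                        "animal_id": a,
                        "species": species[a],
                        "timepoint_hr": tp,
                        "locus": lins["locus"].to_numpy()[li[nz]],
                        "v_call": v_gene,
                        "j_call": j_gene,
                        "cdr3_aa": cdr3_aa,
                        "cdr3": [aa_to_nt(s) for s in cdr3_aa],
                        "isotype": lins["isotype"].to_numpy()[li[nz]],
                        "v_mismatches": v_mm,
                        "j_mismatches": j_mm,
                        "v_aligned_len": v_len,
                        "j_aligned_len": j_len,
                        "duplicate_count": counts[nz],
                        "v_tail_nt": [pools.v_tail[g] for g in v_gene],
                        "j_region_nt": [pools.j_region[g] for g in j_gene],
                    }
                )
                frames.append(df)

                if planted_mask.any():
                    planted_counts = pd.Series(counts, index=li).groupby(level=0).sum()
                    for idx in np.flatnonzero(planted_mask):
                        realized[(lins["uid"].iloc[idx], tp)] = int(
                            planted_counts.get(idx, 0)
                        )

    records = pd.concat(frames, ignore_index=True)

    truth_rows = []
    for (a, cg), (clono, lins) in universes.items():
        for _, lin in lins[lins["planted"]].iterrows():
            row = dict(
                lineage_uid=lin["uid"],
                animal_id=a,
                chain_group=cg,
                locus=lin["locus"],
                v_call=lin["v"],
                j_call=lin["j"],
                cdr3_len=len(lin["seed_cdr3"]),
                seed_cdr3=lin["seed_cdr3"],
                mechanisms=",".join(lin["mechanisms"]),
                log2_fc_frequency=lin["fc_freq"],
                log2_fc_mutation=lin["fc_mut"],
                baseline_frequency=lin["weight"],
                persistent=lin["persistent"],
                origin_class=config.planted.origin_class,
            )
            for tp in config.timepoints:
                row[f"count_{tp}"] = realized.get((lin["uid"], tp), 0)
            truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)
    return records, truth


def emit_fixture(scale: str, outdir: str | Path, seed: int) -> dict:
    """Generate and write a packaged cohort fixture.

    ``tiny``: 2 animals x 6 timepoints x 5,000 sequences per chain group, for
    fast tests.  ``default``: 6 animals x 6 timepoints x 200,000 sequences per
    sample (100k per chain group).  Writes per-sample TSVs, the truth table,
    and a JSON echo of the config.
    """
    if scale == "tiny":
        config = tiny_config(seed)
    elif scale == "default":
        config = CohortConfig(seed=seed)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return write_fixture(config, outdir)


def write_fixture(config: CohortConfig, outdir: str | Path) -> dict:
    """Generate a cohort from ``config`` and write it under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = generate_cohort(config)
    paths = io_airr.write_cohort(records, outdir)
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    config_path = outdir / "config.json"
    config_path.write_text(json.dumps(config.to_dict(), indent=2, default=str) + "\n")
    return {
        "sample_paths": paths,
        "truth_path": truth_path,
        "config_path": config_path,
        "n_records": len(records),
    }


def match_truth_to_lineages(truth: pd.DataFrame, summary: pd.DataFrame) -> pd.DataFrame:
    """Attach the detected ``lineage_id`` to each planted ground-truth row.

    A planted lineage matches the detected lineage of the same animal, chain
    group, V and J gene whose member CDR3 set contains the planted seed CDR3.
    """
    merged = truth.merge(
        summary,
        left_on=["animal_id", "chain_group", "v_call", "j_call"],
        right_on=["animal_id", "chain_group", "v_gene", "j_gene"],
        how="left",
    )
    hit = [
        isinstance(s, tuple) and row_seed in s
        for s, row_seed in zip(merged["cdr3_set"], merged["seed_cdr3"])
    ]
    matched = merged[hit].drop_duplicates(subset=["lineage_uid"])
    return truth.merge(
        matched[["lineage_uid", "lineage_id"]], on="lineage_uid", how="left"
    )
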