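# Methods

## Scope and data model

The package analyses longitudinal AIRR-seq rearrangement tables. A record is
one annotated antibody sequence: animal, species, timepoint (hours; 1 week =
168), locus (IGH/IGK/IGL), V and J gene calls, CDR3 in nucleotides and amino
acids, heavy-chain isotype, V/J mismatch counts with the corresponding aligned
lengths, a duplicate count, and (for phylogenies) a 10-nt non-CDR3 V-region
tail plus the J-region nucleotides. Upstream read processing (merging, V/J
alignment, CDR3 calling, error correction) is out of scope: the input is
assumed error-corrected and annotated. Light-chain loci are pooled into one
"IgKL" chain group for all frequency denominators, because the κ/λ ratio and
light-chain diversity are joint quantities; IGH is normalised separately.

## Lineage clustering

Clonotypes (chain group, V gene, J gene, CDR3-aa; allele suffixes stripped by
default) from all timepoints of one animal are partitioned into lineages:
same V, J and CDR3 length, CDR3s connected under single linkage at Hamming
distance ≤ 1. Single linkage is deliberate — two CDR3s two mismatches apart
co-cluster when an intermediate links them. The implementation hashes the L
one-position-masked variants of each CDR3 (two equal-length strings are at
distance ≤ 1 iff they share a masked variant) and unions buckets, which is
O(n·L) and exact; the test suite checks it against an independent all-pairs
connected-components oracle. Lineage IDs are SHA-1 hashes of the sorted member
set, so they are stable across runs and row orders. Indel-tolerant clustering
is not supported: CDR3s of unequal length never co-cluster.

## Indices and statistics

Diversity uses the natural-log Shannon index with 0·ln 0 ≡ 0, the
mean-absolute-difference Gini form ΣΣ|xᵢ−xⱼ|/(2nΣx) (computed via the sorted
identity, O(n log n)), and the Top-N cumulative frequency with deterministic
ties (frequency desc, label asc). Lineage-level diversity substitutes lineage
cumulative frequencies for clonotype frequencies. Morisita–Horn is computed on
counts aligned over the label union. The SHM rate of any record set is the
pooled ratio 100·(Σv+Σj)/(ΣV+ΣJ) weighted by duplicate counts — not the mean
of per-sequence rates — so it is additive under pooling; per-lineage mutation
rates use the same pooled form. Mutation classes use strict inequalities
(light: < 0.5 % non-mutated, > 4 % mutated; heavy: IgM/D < 0.5 %, IgA/G/E
> 3 %, IgM > 3 %); boundary values fall into the intermediate/other classes.

Paired comparisons use the two-sided Wilcoxon signed-rank test (exact null for
n ≤ 25 without ties after dropping zero differences, normal approximation with
continuity correction otherwise), Benjamini–Hochberg FDR for families of
tests, and Spearman rank correlation with average-rank ties. Degenerate inputs
return an explicit undefined flag.

## Fold changes and expansion calls

Per lineage, per timepoint: cumulative frequency, unique CDR3 count, pooled
mutation rate; log₂ fold changes are taken against the 0 h baseline. A fold
change is defined only when **both** endpoints are positive. This is stricter
than excluding only baseline-absent lineages: log₂ of a zero ratio is
undefined in either direction, and the symmetric rule keeps increased and
decreased classifications exactly exchangeable under swapping the two
timepoints, which the homeostasis null argument (and the null-cohort
calibration test) relies on. Lineages absent at baseline are therefore never
classified, and disappearances are not counted as decreases.

Increased: log₂FC > 1. Decreased: FC < 0.5, i.e. log₂FC < −1 — the symmetric
reading; the literal alternative (log₂FC < 0.5), which would label mild
increases as decreases, is available via `literal_decreased=True`. Expanded: at
48 h or 72 h, at least one chain-specific criterion pair (log₂FC threshold AND
absolute threshold on the post value, both at the same timepoint) holds; the
criteria are OR-combined and the absolute thresholds are evaluated on the
trigger-timepoint value. Expanded thresholds all exceed 1, so every expanded
lineage is also increased on at least one index.

Control lineage sets are drawn either frequency-matched (10 log₁₀-spaced bins
over the pool's nonzero range, per-bin counts equal to the reference's, with
nearest-bin fallback) or matched on count and κ:λ lineage composition.

## Phylogenies

Within a lineage all CDR3s share one length, so the concatenation 10-nt V tail
+ CDR3 + J region yields equal-length strings and no alignment step is needed.
Distances are uncorrected p-distances (Jukes–Cantor behind a flag); duplicate
subsequences collapse to one taxon with a multiplicity annotation because NJ
degenerates on zero distances. Neighbor joining follows Saitou–Nei with the
Q-criterion; ties break at the lowest (row, column) pair and negative branch
lengths are clamped to zero with a flag. On additive matrices the
implementation recovers the generating topology and branch lengths exactly
(verified against random additive trees and dendropy's tree comparison).

## Synthetic cohorts

The generator emulates the cohort design the analysis expects: `n_animals`
(default 6: 3 IRM + 3 AGM — the two species share one generative process), six
timepoints, and per sample 100k heavy + 100k light sequences — scaled down
from the 400–500k-read depths typical of deep antibody-repertoire sequencing
so a full cohort stays analysable in minutes on one CPU.
Per animal and chain group the baseline repertoire has `n_lineages` lineages
(default 1000 light / 800 heavy) with Zipf(α = 0.9) abundances, 1–5 CDR3
variants each (seed variant holds 60 % of lineage mass), Dirichlet-drawn V/J
usage shared across animals, CDR3 lengths 8–24 aa (light) / 8–30 aa (heavy),
and a three-component mutation mixture with weights (0.4, 0.3, 0.3) and peaks
(0.05 %, 1.5 %, 6.5 %). The peaks are placed inside the naive (< 0.5 %),
intermediate, and mutated (> 4 %) bands with margin: over ~200 nt of aligned
V+J a single mismatch is already ~0.55 %, so a naive-like sequence must carry
essentially zero mutations — biologically expected for naive B cells — or the
classes would smear across the thresholds. Heavy-chain isotypes are drawn
conditional on the class (naive → IgM/IgD; memory → IgG/IgA/IgE). Mismatch
counts are drawn **once per clonotype** — the founder's V/J mismatches plus a
small Poisson increment per variant, since CDR3 variants inherit the V/J
mutations of their ancestor — and are re-observed, not re-drawn, at each
timepoint.

Each timepoint is an independent multinomial resample of the clonotype weights
at the configured depth, so a cohort without planted effects is an exact null
for the fold-change machinery. Two deliberate design choices shape the
baseline:

* **Noise floor.** Default lineage counts keep every baseline lineage's
  expected per-timepoint count ≳ 15, where a spurious 8-fold observed jump
  between two Poisson resamples has probability < 10⁻⁶. The singleton tail of
  a real repertoire (expected counts near 1, where a one-read baseline
  followed by a nine-read draw crosses the frequency criterion by chance) is
  intentionally not part of the persistent baseline — a fold-change analysis
  cannot classify such lineages either way, and planting truth in that regime
  would make recovery ill-defined.
* **Transient lineages.** An equal-sized pool of single-clonotype lineages,
  each present at exactly one random timepoint with an expected count of 3–12
  reads, models clones transiting the blood. They contribute realistic
  sporadic presence (lowering the all-lineage timepoint overlap) and diversity
  but never enter fold-change classification, having no measurable ratio.

Planted expanded lineages (default 50: 30 light, 20 heavy, distributed
round-robin over animals at baseline frequency 4 × 10⁻⁴) act through three
mechanisms at 48 h and 72 h: the frequency mechanism multiplies the lineage
weight by 2^4.0; the unique-CDR3 mechanism releases 21 burst variants (one
mismatch from the seed) carrying half the lineage mass, moving the observed
unique-CDR3 count from ~3 to ~24 (log₂FC ≈ 3); the mutation mechanism switches
members to an elevated mismatch draw at 2^2.3 (light) / 2^2.5 (heavy) times
the founding rate. Targets sit exactly one log₂ unit above each expansion
threshold. Light planted lineages are λ with probability 0.8; origin class
defaults to memory-like (high baseline mutation, IgA/IgG isotypes). With
probability 0.6 a planted lineage persists to 1 week (keeping its boost);
otherwise it contracts below detection, so the constant-lineage fraction
tracks the persistence probability. Within every (V, J, CDR3-length) stratum,
lineage seed CDR3s are kept ≥ 4 mismatches apart so generated lineages map
one-to-one onto detected lineages and ground-truth matching is exact.

All draws flow from one `numpy` generator seeded by the mandatory config seed:
identical config + seed reproduces output files byte for byte.

## What passing tests do and do not show

The synthetic cohort reproduces the statistical skeleton the method assumes —
power-law clonal abundances, three mutation modes, isotype–mutation coupling,
multinomial sampling noise, planted effect sizes on the right scales. It does
not emulate real biology in ways that matter for external validity: no shared
(public) clonotypes across animals, no germline-gene database (gene labels are
synthetic), no selection or drift between timepoints beyond resampling, no
sequencing error, no paired heavy/light chains, and a truncated abundance tail
(see noise floor above). Recovery metrics on this cohort certify the pipeline
logic, not performance on real repertoires with their singleton-dominated
tails.

## Problem sizes and numerics

Defaults are sized so the full default cohort (6 animals × 6 timepoints ×
200k sequences/sample) generates and analyses in roughly a minute, and the
complete test suite — including 20-replicate null-calibration and directional
batches at reduced scale (2–6 animals, 5k–20k sequences per chain group) —
runs in a few minutes on one CPU. Frequencies are exact fractions of the
per-sample chain-group total; percent thresholds are converted internally
(0.001 % = 10⁻⁵). Clonotype tables sort deterministically; all tie-breaks
(Top-N, NJ joins, control-lineage draws) are deterministic or seeded, and every
entry point that uses randomness takes an explicit seed.
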