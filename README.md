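# bcrdyn

Longitudinal B-cell receptor (BCR) repertoire dynamics: clonal-lineage
clustering, repertoire diversity and similarity indices, somatic-hypermutation
classification, and multi-criteria detection of stimulation-induced expanded
antibody lineages — with a synthetic cohort generator that plants ground-truth
expansions so every stage of the pipeline is testable end to end.

## The problem

Innate-immune stimulants such as TLR7/8 agonists activate B cells broadly
rather than selecting antigen-specific clones, so the responding antibodies
cannot be isolated by antigen baiting. The alternative is longitudinal
repertoire sequencing: sample the antibody repertoire of each animal before
stimulation and at a series of timepoints afterwards (0, 8, 24, 48, 72 h,
1 wk), and identify the clonal lineages whose behaviour over time departs from
repertoire homeostasis. This package implements that analysis for AIRR-seq
rearrangement tables carrying heavy (IGH) and light (IGK/IGL, analysed jointly
as "IgKL") chains.

## The method

**Units.** A *clonotype* is a unique (V gene, J gene, CDR3 amino-acid
sequence). A *lineage* groups clonotypes of one animal (all timepoints pooled)
that share V and J genes and CDR3 length and whose CDR3s are connected under
single linkage at Hamming distance ≤ 1 — a proxy for descent from one
ancestral B cell.

**Indices.** Per sample: Shannon index −Σᵢ pᵢ ln pᵢ, Gini index
ΣᵢΣⱼ|xᵢ−xⱼ| / (2 n Σxⱼ), Top-100 cumulative frequency, Morisita–Horn
similarity CH = 2Σxᵢyᵢ / ((Σxᵢ²/X² + Σyᵢ²/Y²)·X·Y), and the pooled
somatic-hypermutation rate SHM% = 100·(Σvᵢ + Σjᵢ)/(ΣVᵢ + ΣJᵢ) from V/J
mismatch counts over aligned lengths.

**Expansion calls.** Per lineage and timepoint, three indices are computed —
cumulative frequency, unique CDR3 count, mean mutation rate — and converted to
log₂ fold changes against the 0 h baseline. A lineage is *increased* on an
index when log₂FC > 1, *decreased* when FC < 0.5, and *expanded* when at 48 h
or 72 h at least one chain-specific criterion pair holds:

| chain | index | log₂FC | absolute |
|-------|-------|--------|----------|
| IgKL  | frequency | > 3 | > 0.001 % |
| IgKL  | unique CDR3 | > 2 | > 5 |
| IgKL  | mutation rate | > 1.3 | > 6 % |
| IGH   | frequency | > 3 | > 0.001 % |
| IGH   | mutation rate | > 1.5 | > 5 % |

Expanded lineages are then characterised: κ/λ lineage ratio against
frequency-matched controls, timepoint-overlap index |A∩B|/min(|A|,|B|),
constant-lineage fraction, origin tracing of their 0 h members by isotype and
mutation class (IgM/D non-mutated < 0.5 % vs IgA/G/E mutated > 3 %), and
neighbor-joining trees built from fixed-length subsequences (10-nt V tail +
CDR3 + J region, p-distances, Saitou–Nei NJ).

## Worked example

```python
from bcrdyn import pipeline, synthetic

records, truth = synthetic.generate_cohort(synthetic.tiny_config(seed=7))
res = pipeline.run_lineage_pipeline(records)
fc, calls = pipeline.call_expansions(res.metrics)
ev = pipeline.evaluate_calls(calls, res.summary, truth)
```

This simulates 2 animals × 6 timepoints × 5,000 sequences per chain group with
14 planted expanded lineages, clusters lineages, and applies the expansion
criteria. It prints:

```
8,446 records -> 1,128 lineages in 2 animals
expanded lineages called: 14 (planted: 14, recall 1.00, precision 1.00)
animal_id chain_group                        criteria_met  trigger_timepoint
       M1         IGH             frequency,mutation_rate               48.0
       M1         IGH             frequency,mutation_rate               48.0
       M1         IGH             frequency,mutation_rate               48.0
       M1        IgKL frequency,mutation_rate,unique_cdr3               48.0
```

Every planted lineage is recovered (recall 1.00) with no spurious calls
(precision 1.00); heavy-chain lineages trigger on frequency + mutation rate
(IGH has no unique-CDR3 criterion), light-chain ones on all three.

The same pipeline is scriptable from the shell (`bcrdyn simulate / lineages /
dynamics / expanded / phylo / report`), and the numbered drivers under
`analysis/` walk through the full study: cohort simulation, repertoire
overview, increased/decreased dynamics, expansion calls, expanded-lineage
characterisation, origin tracing, and lineage phylogenies, writing tables
under `results/`.

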