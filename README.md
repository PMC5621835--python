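# indeltrace

CRISPR amplicon indel lineage tracing: allele calling, reads-per-million
quantification and regeneration-fidelity statistics.

## What this is for

In highly regenerative animals such as the axolotl, zygotic CRISPR/Cas
mutagenesis writes a different indel into each edited embryonic cell, so
every indel allele marks a cell lineage. Deep sequencing of the target
amplicon from a limb before amputation and from the regenerated limb that
replaces it yields two clonal composition vectors, and comparing them
measures how faithfully regeneration reconstitutes the original lineages.
`indeltrace` is for researchers running such experiments: it turns pooled
amplicon FASTQ (with inline sample tags) into per-sample allele count
tables, applies control-based exclusion filters, normalizes to reads per
million (RPM), and computes the fidelity and tissue-enrichment statistics.

The central statistic is the **percent change in allelic identity** between
two samples *a*, *b* with RPM compositions over the union of allele classes
(intact sequence included):

```
identity change = ( Σ_k | RPM_k(a) − RPM_k(b) | ) / 2 / 10⁶ × 100 %
```

i.e. the total-variation distance between the two clonal compositions on a
0–100 scale. Supporting statistics: pooled OLS regressions of
log₁₀(RPM+1) between limb stages, frequency bins (low < 1.6 %, high >
6.5 % of reads), per-allele fold-change categories, lost/recovered allele
accounting, cross-animal allele sharing, 16-fold tissue-enrichment calls
with two-tailed Fisher exact tests, and a tissue–tissue r² matrix.

A first-class synthetic-data module simulates the whole experiment —
mosaic embryos, Dirichlet limb compositions, near-faithful regeneration
resampling, sparse tissue splits, tagged error-bearing reads — with full
ground truth, so every pipeline stage is validated end to end without any
external data.

## Worked example

Simulate a small cohort and run the full pipeline:

```
indeltrace run-all --seed 23 --out out/ \
  --config <(echo '{"n_animals": 4, "n_targets": 2, "n_tertiary": 2,
                    "n_tissue": 1, "read_depth": 10000}')
```

or equivalently in Python:

```python
from indeltrace import SimulationConfig, simulate_cohort, analyze_cohort

cfg = SimulationConfig(seed=7, n_animals=6, n_targets=2, n_tertiary=4,
                       n_tissue=2, read_depth=10_000)
cohort = simulate_cohort(cfg)
analyses, report = analyze_cohort(cohort)
for a in report.animals:
    true = cohort.truths[a.animal_id].identity_change_true["primary_secondary"]
    print(a.animal_id, round(a.identity_change_primary_secondary, 2), round(true, 2))
```

which prints (estimated vs. generator-true identity change, in percent):

```
animal_01 46.22 46.94
animal_03 27.71 27.12
animal_05 25.44 25.16
animal_02 26.62 26.15
animal_04 30.68 29.82
animal_06 26.41 26.35
```

Each line is one animal's primary→secondary limb comparison: an identity
change of ~26 % means about a quarter of the regenerated limb's reads would
have to be reassigned to reproduce the original limb's clonal composition;
the pipeline estimate tracks the simulator's true total-variation distance
to well under one percentage point at this depth. `report` further carries
the pooled log-RPM regressions, frequency-bin and fold-change summaries,
allele sharing across animals, lost/recovered accounting, and (for animals
with dissected tissue panels) enrichment calls, Fisher tests and the
tissue r² heatmap; `run-all` writes the same content as `report.json` plus
per-target count/RPM/audit TSVs.

The stages are also exposed individually (`indeltrace simulate / demux /
call / quantify / fidelity / tissue`) and exchange plain TSV/FASTQ files,
so real sequencing data can enter at the demultiplexing step with a sample
sheet, a target registry (reference amplicon, protospacer, PAM, position)
and pooled FASTQ.

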