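# ratebuffer

Joint estimation of transcription rate and mRNA half-life from 4sU metabolic
labeling time courses, and downstream analysis of how decay buffers
transcriptional change.

Steady-state RNA-seq cannot tell whether a gene's abundance changed because
its transcription changed or because its mRNA stability changed — and it is
blind to genes where the two changes cancel. Metabolic labeling resolves
this: pulse-labeled RNA approaches equilibrium along a saturation curve whose
initial slope is the transcription rate and whose timescale is the half-life.
`ratebuffer` implements that analysis end to end for a two-genotype design
(e.g. a transcriptional-regulator mutant versus isogenic control), plus the
sequence-level follow-ups: predicting the direction of kinetic changes from
gene-body dinucleotide composition, and testing miRNA-seed / RBP motif
enrichment in 3ʹUTRs of decay-regulated genes. It is aimed at computational
biologists analysing labeling time courses (or nuclear/whole-cell fraction
designs used as a labeling-free proxy) and ships a synthetic-data generator
with known ground truth so every estimator can be validated.

## Model

Labeled abundance of a gene follows first-order turnover,

    dY/dt = α − βY  ⇒  Y(t) = Y_ss (1 − e^{−βt}),   Y_ss = α/β,   HL = ln2/β,

so

* **transcription rate** α is the early-time slope: labeled signal at 0.5 h
  divided by 0.5 h (fly spike-in normalized; the 1 h sample halved serves as
  an extra, flagged pseudo-replicate);
* **absolute half-life** comes from a two-pass weighted least-squares fit of
  the saturation curve (pass-2 weights 1/Ŷ), with t-based sandwich CIs;
* **relative half-life change** needs no fit: log2FC_HL = log2FC_SS −
  log2FC_TR, with negative-binomial Wald fold-changes and SEs propagated in
  quadrature, and Z_FC = |log2FC_HL|/√(SE_A² + SE_B²) grading confidence.

Genes are then categorized: `TR_only` (steady state tracks transcription
within 25%), `full_buffered` / `partial_buffered` (opposite half-life change
cancels all / part of the transcription change), `HL_only` (stability change
with no transcription change), `concordant`, `unchanged`.

## Worked example

Simulate a 1,000-gene experiment with planted buffering categories
(4 replicates, |Δlog2| = 2 effects) and run the human workflow:

```python
from ratebuffer import simdata, pipeline

cfg = simdata.SimConfig(n_genes=1000, seed=7, n_replicates=4)
truth = simdata.sample_gene_kinetics(cfg)
exp = simdata.simulate_labeling_counts(truth, cfg)
res = pipeline.run_human_analysis(exp, config=pipeline.PipelineConfig(seed=7))
print(res["category_counts"])
print(res["half_life_shift"][["genotype", "n_genes", "median_h", "mean_h"]])
```

prints

```
category
HL_only              45
TR_only              94
concordant           53
full_buffered       156
partial_buffered     77
unchanged           575

genotype  n_genes  median_h  mean_h
     MUT      866     2.553   3.632
      WT      866     2.524   2.837
```

The planted proportions were 15% fully buffered (150 genes), 6% partially
buffered, 10% half-life-only, 9% transcription-only, 60% unchanged; the
recovered counts track them, with the expected leakage of half-life-only
genes into `concordant` — strong stability changes alias into small apparent
transcription-rate changes through decay during the 0.5 h pulse (the
generator's `linear_labeling` flag removes that bias for exact-recovery
experiments). Both genotype medians sit near the planted 2.5 h; the MUT mean
is raised by its planted stabilized genes. A per-gene record looks like:

```
gene g00000 truth category: full_buffered | estimated log2FC_HL = 1.683 +/- 0.252
```

The same objects expose the saturation fits (`res["saturation_fits"]`),
direction labels, and — when sequences and a motif table are supplied —
classifier reports and motif-enrichment tables. A `ratebuffer` CLI wraps the
stages (`simulate`, `normalize`, `kinetics`, `diffexp`, `categorize`,
`classify`, `motifs`, `run`) around TSV/FASTA/YAML files; see
`ratebuffer --help`.

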