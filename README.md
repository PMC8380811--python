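# qpcrkinetics

Analysis pipeline for **high-throughput microfluidic RT-qPCR time courses**
of induced chondrogenesis. It covers the full path from raw cycle-threshold
(Ct) exports to biological summaries: dual-reference comparative-Ct
quantification, per-gene time-course significance testing, first-onset
trajectory classification, annotation-group timing tables, and four-pattern
cell-type divergence categorization — together with a synthetic-data
generator that makes every stage testable against known ground truth.

## Who it is for

Labs running 96.96 microfluidic qPCR chips (or any plate-based RT-qPCR
panel) over a differentiation time course across multiple cell types — the
motivating design is TGF-β1-induced chondrogenesis in fetal interzone,
anlagen and dermal-fibroblast cultures sampled at monolayer plus ten pellet
time points (0–336 h) with seven biological replicates.

## The model

Quantification is the comparative-Ct method with two endogenous controls
and a pooled positive-control calibrator:

    ΔCt   = Ct(gene) − mean[Ct(control₁), Ct(control₂)]     (within sample)
    ΔΔCt  = ΔCt(sample) − ΔCt(calibrator)                   (per gene)
    RQ    = 2^(−ΔΔCt)

Controls are chosen by raw Ct stability (smallest SD across all
experimental samples). Genes whose maximal group-mean RQ never reaches 0.02
are excluded as minimally expressed. Statistics run on log₂RQ = −ΔΔCt:

* **within cell type** — one-way ANOVA over the 11 culture conditions
  (monolayer + 10 pellet time points), Tukey HSD over all pairs; the
  reported contrasts are each time point vs the 0 h baseline, significance
  at *P* < 0.05;
* **between cell types** — one-way ANOVA over the three cell types at each
  time point, Tukey HSD over the 3 pairs.

A gene × cell type trajectory is **UP / DOWN / MIXED / STABLE** according to
the directions of its significant baseline contrasts, and its *first onset*
is the earliest significant pellet time point. For each cell-type pair a
gene is **RETAINED / LOST / BECAME / SIMILAR** according to whether it
differed at 0 h and whether it differed at any post-induction time point.
Amplification efficiency E = 10^(−1/slope) − 1 is estimated per assay from a
7-point 3-fold dilution standard curve (reported, not used to correct RQ).

## Worked example

Run the bundled synthetic study — 96 assays (3 control candidates + 93
targets), 231 experimental samples, with engineered kinetics — through the
whole pipeline:

```bash
qpcrkinetics demo --seed 1 --out-dir out/
# analyzed 87 genes, 261 gene x cell-type combinations
```

`out/` then contains the simulated inputs (`ct_long.csv`, `samples.csv`,
`panel.csv`, `truth.csv`), every analysis table (`rq_long.csv`,
`contrasts_timecourse.csv`, `contrasts_celltype.csv`, `onsets.csv`,
`trajectory_counts.csv`, `onset_summary.csv`, `divergence_patterns.csv`,
`divergence_summary.csv`, `gene_sets.txt`, `efficiency.csv`) and a
`manifest.json` recording the seed, parameters and per-stage counts. With
seed 1 the run selects GUSB and RPLP0 as the two stable controls, excludes
the 5 minimally expressed targets and the low-fluorescence assay, and
classifies the 261 analyzed gene × cell type combinations as 117
upregulated, 78 downregulated, 15 mixed and 51 stable, with the earliest
onset at 1.5 h — all of which can be compared against the generator's
ground truth in `truth.csv`.

The same stages are available as library functions
(`qpcrkinetics.normalize`, `.stats`, `.kinetics`, `.divergence`) and as the
`simulate` / `run` subcommands for analyzing an existing CSV directory.

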