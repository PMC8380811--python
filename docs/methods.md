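# Methods

## Quantification model

All expression values are relative quantities from the comparative-Ct
(2^−ΔΔCt) method with a dual endogenous reference. Within each sample,
ΔCt = Ct(gene) − mean Ct of the two selected control genes; ΔΔCt subtracts
the same gene's ΔCt in the calibrator sample (a pooled multi-tissue positive
control); RQ = 2^−ΔΔCt. Two consequences are exploited throughout:

* log₂RQ = −ΔΔCt exactly, so all statistics are run on −ΔΔCt;
* because both references are measured in the same chamber set as the gene,
  any additive per-chip Ct offset cancels already in ΔCt. The pipeline
  therefore applies no inter-plate correction; the on-chip dilution series
  is used only to estimate amplification efficiency and to report the
  maximal cross-chip Ct deviation at matched concentration.

Control selection ranks candidates by the standard deviation of raw Ct
across all experimental samples (ascending, ties alphabetical) and keeps
the best two. This deliberately simple stability metric matches how control
stability is usually visualized (mean ± error over the time course);
pairwise-ratio schemes (geNorm/NormFinder style) are out of scope but the
selection step is pluggable via an explicit control list.

Efficiency is estimated per assay by OLS of Ct on log₁₀(concentration) over
a 7-point 3-fold dilution series; E = 10^(−1/slope) − 1 with R² reported.
Slopes ≥ 0 or shallower than 1 cycle/decade are flagged as having no valid
standard curve. Efficiency is reported, never used to rescale RQ: the
quantification deliberately assumes perfect doubling, and an
efficiency-corrected fold change would silently change every downstream
count.

### Non-detects and filters

A reaction with no threshold crossing is a non-detect. The default policy
(`drop`) treats it as missing; the alternative (`censor`) assigns the
detection-limit Ct, which biases fold changes toward the limit but keeps
heavily censored genes computable (needed e.g. when a gene is undetected in
the calibrator but measurable after pre-amplification). If a selected
*control* is undetected, the whole sample is dropped — ΔCt is undefined
there.

A gene is excluded as minimally expressed when its maximum
(cell type × time point) group-mean RQ stays below 0.02, i.e. it never
reaches 2 % of its calibrator level in any condition; a gene with no
computable RQ at all is excluded the same way. "Group-mean" is the most
conservative reading that still excludes globally silent genes while
tolerating single noisy replicates. Assays can additionally be excluded by
an instrument-side low-fluorescence quality flag, which is pass-through
metadata: it cannot be derived from Ct values. Assays that fail to amplify
in the positive-control assessment are flagged but retained — absence from
the calibrator RNA pool does not preclude expression in the experimental
samples.

## Significance machinery

Each gene is tested separately (per-gene univariate one-way ANOVA; no
across-gene multiplicity correction, and no multivariate statistic — the
reported results are per-gene significance calls and nothing else).
Within a cell type the factor is the culture condition with all 11 levels
(monolayer + 10 pellet time points) in a single Tukey family of 55 pairs;
the reported contrasts are the nine time-vs-baseline pairs and the
monolayer-vs-0 h pair. Keeping the monolayer inside the family means one
familywise adjustment per gene × cell type. Across cell types the factor is
cell type at a fixed time point (3 pairs). Tukey p-values come from the
studentized range distribution with the Tukey–Kramer standard error for
unequal group sizes; computing the p-value only for reported pairs is exact
because the adjustment depends on the family's k and residual df, not on
which pairs are read out. Significance is strict (p < α, default α = 0.05);
a p equal to α is not significant. Degenerate fits (zero residual variance)
warn and report p = 0 when means differ, p = 1 when all values coincide.

Replicates are treated as independent draws; no donor blocking is modeled
(no pairing structure is assumed by the tests).

## Classification layers

Trajectory class per gene × cell type: UP if at least one significant
baseline contrast exists and all are upward; DOWN symmetrically; MIXED if
both directions occur; STABLE if none. The first onset is the earliest
significant pellet time point and its direction travels with it; the
monolayer contrast is reported separately and never counts as an onset, so
an onset can never fall at the 0 h baseline. Timing summaries report, per
annotation group (transcription regulation / signal transduction / ECM) and
cell type, the percentage of the group's genes with first onset at each
time point, with the group size as denominator and half-up rounding to one
decimal; multi-annotated genes count once in each group, unannotated genes
are omitted. Percentages therefore sum to 100 (within rounding slack) only
when every gene in the group responded.

Divergence per gene × cell-type pair uses two flags — significantly
different at 0 h, and significantly different at ≥ 1 post-baseline time
point — mapped to RETAINED / LOST / BECAME / SIMILAR. "Post different at
one or more points" (rather than all points) is the operative definition,
so LOST means different at baseline and at *no* later point. Direction is
ignored: a pair that flips sign while staying significant is still
RETAINED. Cross-pair summaries intersect category membership across all
pairs ("common") and subtract it pairwise ("specific").

## Synthetic data generator

The generator works on the post-pre-amplification Ct scale:

    Ct = chip_offset + control_level + baseline_dct − effect(t) + ε

with ε ~ N(0, noise_sd), a per-chip offset ~ N(0, chip_offset_sd), and
step-shaped effects (0 before the onset, ±magnitude from the onset on;
MIXED flips sign at a second onset; an optional ramp reaches the magnitude
linearly). Step kinetics are the default truth model because the analysis
only resolves onsets on the sampling grid — a step makes "exact onset
recovery" unambiguous. Control candidates have their own means and
stability SDs; the calibrator is generated noise-free at its own per-gene
level, distinct from the cell-type baselines as a pooled multi-tissue RNA
sample would be. Ct values above the non-detect limit (default 28 cycles)
are emitted as non-detects.

Key defaults and why: replicate noise 0.3 cycles (typical inter-replicate
scatter for biological replicates on microfluidic chips), chip offset 0.2
cycles, 7 replicates, response magnitudes 2–3.2 cycles (4–9-fold changes),
detection limit 28 cycles. Biological replicates are independent draws — no
per-donor random effect is modeled, so the generator underestimates the
replicate correlation a paired design would show.

The bundled default study (`qpcrkinetics.demo`) freezes a full-size ground
truth: 96 assays (3 controls, of which one drifts; 93 targets of which 5
are minimally expressed, 1 carries a low-fluorescence flag and 1 amplifies
only after pre-amplification), 3 cell types × 11 conditions × 7 replicates.
The layout is frozen under an internal construction seed so every run
simulates the *same* study; the run seed drives only noise. Engineered
structure: the interzone–anlagen divergence roles are exact by construction
(11 retained / 3 lost / 47 became / 26 similar); transcription-annotated
genes always respond in both chondrogenic cell types, with onsets no later
than 24 h; signaling and ECM genes spread over the full course with ECM
never before 3 h; fibroblast responses are delayed; exactly one gene
responds nowhere; four signaling genes sit two cycles lower in monolayers.
Class proportions across the 261 combinations (~117 up / 79 down / 14
mixed / 51 stable in truth) were chosen once to resemble a realistic
induction experiment. Note the *measured* divergence counts deviate
slightly from the constructed ones: with ten 3-group Tukey families per
gene-pair, ~4 % of truly identical pairs pick up a false baseline or
post-baseline difference, which is the expected behavior of the
significance machinery, not a defect.

What the generator does not emulate: amplification chemistry and
pre-amplification bias, probe cross-hybridization, donor pairing,
non-additive chip effects, and heteroscedastic Ct noise near the detection
limit. Passing tests therefore validate the analysis logic and its
statistical calibration, not instrument physics.

## Calibration experiments and problem sizes

* **Type-I error** — 1,000 null genes (flat profiles, noise 0.3, n = 7,
  one cell type): fraction of gene families with any significant
  time-vs-baseline contrast. Tukey adjustment over the 55-pair family makes
  this markedly conservative for the 9 reported baseline contrasts
  (measured ≈ 0.006, bound 0.06).
* **Onset recovery** — 200 step genes (magnitude 2 cycles, onsets cycling
  over the full post-baseline grid), at noise 0.3 and 0.05: fraction with
  exactly the true class and onset. ≥ 90 % is expected at 0.3; near-perfect
  at 0.05, where the residual failure mode is a familywise false positive
  at a pre-onset time point (marginal per-pair probability ≈ 0.1 %).
* **Efficiency recovery** — three assays with true E ∈ {0.85, 0.95, 1.0},
  7-point series on 3 chips, 0.15 cycles noise: estimates within ±0.05.

These sizes keep the whole validation suite at roughly two minutes on a
single CPU while leaving the Monte-Carlo error of each rate well below the
margin it is compared against.

## Known limitations

* The stability ranking uses raw Ct SD and will prefer a control that is
  uniformly low-variance over one that is stable *across conditions* but
  noisy within them.
* The RQ < 0.02 exclusion depends on the calibrator's composition: a gene
  absent from the calibrator pool has inflated RQs and can escape the
  filter.
* With ~10 Tukey families per gene × cell-type pair, divergence categories
  inherit a per-gene false-positive probability of a few percent; counts of
  rare categories (LOST) are accordingly fragile.
* Monolayer effects share the within-cell-type family; a gene with strong
  pellet kinetics has a slightly conservative monolayer contrast (larger
  within-family spread raises the critical range).
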