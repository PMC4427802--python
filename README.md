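# serodiff

Cross-validated differential-abundance analysis of label-free serum
proteomes, built for the problem of telling **cholangiocarcinoma (CCA)**
apart from **benign biliary tract diseases (BBTD)**. Both conditions present
with biliary obstruction and similar imaging, and the routine serum markers
CA19-9 and CEA are neither sensitive nor specific enough, so candidate
protein biomarkers are sought in the serum proteome itself. `serodiff` is
aimed at analysts working with protein × sample quantitation matrices from
LC-MS/MS label-free experiments who want a stringent, reproducible selection
of differentially expressed (DE) proteins from a small case–control cohort.

## The method

Starting from a matrix of relative quantitation ratios (rows = proteins,
columns = sera), the pipeline:

1. **Normalizes**: values are log2-transformed (when not already on the log
   scale), each sample is median-centered, and a cross-sample quantile
   ("rank") normalization makes the sample distributions identical.
2. **Builds a stratified fold plan**: the cohort is split *k* = 6 times into
   a training set of 30 (13–15 BBTD, 15–17 CCA) and a held-out validation
   set of 6 (2–4 of each group); by default the six validation sets
   partition the 36 samples.
3. **Selects DE proteins by a Welch-test intersection rule**: per fold, each
   quantifiable protein is tested with the unequal-variance two-sample
   t-test,

   t = (x̄_CCA − x̄_BBTD) / √(s²_CCA/n_CCA + s²_BBTD/n_BBTD),

   with Welch–Satterthwaite degrees of freedom. A protein is called DE only
   when *P* < 0.01 in **every** fold — an intersection criterion whose
   per-protein false-positive probability is bounded by the single-fold
   level α = 0.01.
4. **Validates without labels**: hierarchical clustering (Euclidean,
   average linkage, per-protein z-scores clipped to ±3) and PCA of the
   DE-restricted matrix, volcano coordinates (log2 fold change vs
   −log10 p), and five-number box summaries of the top proteins by fold
   change.
5. **Compares the cohorts clinically**: sex by Pearson chi-squared, age by
   Student's t, the skewed assay-censored markers CEA and CA19-9 by
   Mann-Whitney U.

Because the underlying patient-level study data are not publicly deposited,
the package ships a **synthetic-data generator** that emulates the discovery
setting (19 CCA vs 17 BBTD sera, 951 proteins, log2 effects of 0.25–1.7,
within-group SDs of 0.1–0.9, per-sample loading shifts, missing
quantifications) together with a ground-truth record, so every stage is
testable end to end. A packaged reference table of 93 reported serum DE
proteins (group mean ± SD, n = 19/17, reported p) supports auditing
published summary statistics via the Welch test computed directly from
summary statistics.

## Worked example

```sh
cat > example.yaml <<'YAML'
out_dir: example_run
seed: 7
simulate:
  seed: 7
  n_proteins: 951
  frac_de: 0.1
  missing_rate: 0.05
YAML
serodiff run --config example.yaml
```

The run manifest records the stage funnel:

```
simulate       951 proteins, 36 samples, 95 true DE
normalize      stages log2, median, rank
select_de      951 quantifiable, 72 selected (37 up, 35 down)
multivariate   cluster misassignments 0, PCA separation 5.84
```

72 of the 95 spiked proteins are recovered (those with small effects fall
below the power of the intersection rule at n = 19/17); the two-cluster cut
of the sample dendrogram reproduces the CCA/BBTD split with zero
misassignments. The head of `de_table.tsv`, sorted by worst-case fold p:

```
protein  mean_cca  mean_bbtd  max_fold_p  direction
P0443      -0.445      1.02     3.55e-19  down
P0942       1.13     -0.00605   1.95e-17  up
P0254       0.991    -0.469     2.35e-16  up
```

`mean_cca − mean_bbtd` is the log2 fold change; `max_fold_p` is the largest
of the six per-fold Welch p-values (the quantity the selection rule
constrains). `cohort_comparison.tsv` shows the clinical picture the
simulator emulates — no significant group difference in sex, age, or CEA,
but strongly elevated CA19-9 in CCA (Mann-Whitney *P* < 0.001).

Every subcommand is also available standalone
(`serodiff simulate | normalize | select-de | multivariate |
compare-cohorts | audit-table`); see `serodiff <cmd> --help`.

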