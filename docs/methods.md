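# Methods

## Scope and model of the data

`serodiff` operates on a protein × sample matrix of relative quantitation
values from label-free LC-MS/MS of serum, with a two-group case–control
design (CCA vs BBTD). Everything upstream of the quantitation matrix —
spectra, peptide identification, protein inference — is out of scope. The
working model of an observed value is, on the log2 scale,

    x_ij = b_i + d_i·[group_j = CCA] + s_j + e_ij,    e_ij ~ N(0, σ_i²)

with protein baseline `b_i`, true group effect `d_i` (zero for non-DE
proteins), a per-sample additive distortion `s_j` (loading/instrument
drift), and protein-specific within-group noise. Gaussian noise on the log2
scale (equivalently lognormal raw intensities) is the standard assumption
for such data; heavy-tailed noise is not modeled.

## Normalization

* **log2 transform** — refused on non-positive values and on matrices
  already flagged as log-scaled. Upstream software sometimes exports ratios
  already on the log scale; the pipeline accepts those via a flag
  (`log2: false`, the default for the simulator's output, which is
  generated directly in log2 units).
* **Median centering** — per sample, subtract the median over non-missing
  values; removes `s_j` exactly in the model above. Even-count medians are
  the mean of the two middle values. Idempotent.
* **Rank (quantile) normalization** — within each sample, non-missing
  values are ranked with tie-averaging; rank r of m observations maps to
  probability p = (r−1)/(m−1); the value is replaced by the mean over all
  samples of their linearly interpolated empirical quantile at p. For
  complete matrices this is classic quantile normalization (exactly
  idempotent, and any two samples share the same sorted multiset
  afterwards); with missing values the reference quantile curve is an
  interpolated mean over unequal sample sizes and idempotence is only
  approximate. Ranking "across the data set" admits a second reading —
  replacing each protein row by centered cross-sample ranks — which is
  implemented behind `rank_method: within_protein` but is off the default
  path, since making sample distributions comparable is the conventional
  purpose of the step.

Every stage preserves shape, missingness pattern, and within-sample
ordering.

### A known artifact worth stating

Quantile normalization transfers information between proteins that occupy
the same ranks. When a sizable set of proteins carries strong one-group
shifts, null proteins sitting in the distribution tails inherit small
group-correlated shifts; with 19/17 samples this can push a handful of true
nulls below α in every fold. In simulations with ten spiked effects of
1.5–2 log2 units among 951 proteins, the intersection rule returns all ten
spikes plus typically 1–5 tail false positives that are absent when the
quantile stage is skipped. Interpreting small-|fold-change| hits near the
distribution tails therefore warrants caution.

## Fold plan

`build_folds` stratifies by group: members of each group are shuffled and
cut into k chunks whose sizes differ by at most one, with the remainder
chunks of the two groups placed at opposite ends of the fold list so
validation-set sizes stay even; plans violating the per-group count bounds
are re-drawn. In the default **partition** mode the six validation sets are
disjoint and cover the cohort — the conventional meaning of 6-fold
cross-validation. A **resample** mode draws each fold's split
independently, since small-cohort studies sometimes describe repeated
random splits as folds. For the 36-sample reference design the plans
reproduce the canonical bounds (training 30 with 13–15 BBTD / 15–17 CCA;
validation 6 with 2–4 of each); for other cohorts the validator scales the
per-group bounds proportionally (floor(n_g/k)−1 to ceil(n_g/k)+1, never
below 1).

## DE selection

Per fold, each protein is tested with the Welch unequal-variance t-test on
the fold's **training set** (default). The defining rule — p < α in *all*
folds — is ambiguous about which per-fold sample set is tested: the
training sets (n = 30 comfortably supports a t-test), the validation sets
(n = 6 with 2–4 per group barely does), or both. The training-set reading
is the default because it is the only one under which the stated stringency
is realistically achievable at these sizes; `test_scope: validation` and
`test_scope: all` expose the alternatives.

* **Quantifiable** is defined as ≥ `min_obs_per_group` (default 2)
  non-missing observations per group in every tested set; unquantifiable
  proteins are flagged, not errored.
* **Degenerate variances**: both groups constant with equal means → p = 1;
  with distinct means → perfect separation, p = 0 (limiting convention).
* **Direction** (up = higher in CCA) comes from the all-sample group-mean
  difference, as do the reported overall mean ± SD per group.
* **No multiple-testing correction** is part of the rule itself — the
  intersection event is contained in each single-fold rejection event, so
  the per-protein false-positive probability is ≤ α. A Benjamini–Hochberg
  q-value over the per-protein max fold p is emitted for information only.
  Note the intersection's effective stringency is much less than α^k
  because the six training sets share ~80% of their samples and the
  per-fold p-values are strongly correlated: in null simulations
  (951 proteins, α = 0.01) the mean selected count is ≈ 1–1.5 per cohort,
  roughly an eightfold reduction against a single test rather than the
  10⁻¹² an independence assumption would suggest.

The reported per-protein p is the **maximum across folds** — the quantity
the rule constrains. Published single p-values per protein aggregated from
a fold procedure in an unstated way are not reproducible from this; the
packaged reference table is therefore audited against bounds, not matched.

## Cohort statistics

`compare_cohorts` fixes the variable→test mapping (overridable): sex →
Pearson chi-squared on the 2×2 table without Yates correction (the named
test; the correction is available by flag), age → Student's t, CEA and
CA19-9 → Mann-Whitney U (right-skewed, censored at the assay limits), exact
null distribution when the combined n ≤ 20 and the tie-corrected normal
approximation otherwise. Significance is declared at 0.05. Variables
constant across both groups are reported with undefined statistics rather
than raising. `audit_summary_table` re-derives Welch p-values from printed
group mean/SD/n and flags rows failing the recomputed threshold, rows whose
printed p violates the stated cutoff, and direction labels contradicting
the sign of the mean difference.

## Unsupervised views

Clustering and PCA are label-blind; group labels enter only in the post-hoc
summaries. Distance and linkage are not dictated by the procedure being
emulated, so the defaults are Euclidean distance with average linkage —
the common choice of expression-heatmap tools — both configurable.
Per-protein z-standardization uses the sample SD (ddof = 1) and the display
matrix is clipped to ±3. Missing entries are imputed at the protein mean
(z = 0) for distance/PCA computation only. PCA centers but does not scale
features by default (inputs are already quantile-normalized); the
separation summary is the between-centroid distance divided by the mean
sample-to-own-centroid distance in component space. Quartiles in the box
summaries use linear interpolation, fixed for reproducibility. The volcano
y-axis uses the max per-fold p, with the DE flag a strict `p < cutoff`.

## Synthetic data

The generator's defaults describe the discovery setting the pipeline
targets: 19 CCA / 17 BBTD samples, 951 proteins, a DE fraction of 0.1
(≈ 95 proteins, close to the ~10% reported in comparable serum screens),
effects uniform on 0.25–1.7 log2 units split evenly between directions,
within-group SDs uniform on 0.1–0.9, baselines N(0, 1) (spanning roughly
−2.6 to 2.4 log2 units over 951 proteins, the value range reported for
serum DE panels), per-sample shifts N(0, 0.3) — present precisely so median
normalization has something to remove — and 5% missingness, completely at
random by default. A left-censored missingness mode (dropout probability
decreasing linearly in the value's overall rank, expected rate preserved)
is provided but off by default, as low-abundance dropout is plausible but
uncharacterized for these data. Clinical covariates are drawn from the
reference demographics (age N(60.9, 13) / N(52.6, 13); CEA and CA19-9
lognormal around the reported medians with log-SDs of 1.2 and 2.2, clipped
to the assay ranges — CA19-9 visibly saturates at 10000 ng/mL in the CCA
group, as in practice).

What the simulator does **not** emulate: correlated proteins (co-regulation,
shared peptides), intensity-dependent variance, batch structure beyond a
scalar per-sample shift, heavy-tailed noise, and informative missingness by
default. Passing tests therefore demonstrate correctness of the procedure
under its own model assumptions, not robustness to every pathology of real
serum data.

## Problem sizes used in tests

Deterministic checks run on the packaged 93-row reference table and small
closed-form matrices. Stochastic checks use: 20 null cohorts of 951
proteins for false-positive control; 200 replicates of 60-protein matrices
for spiked-effect sensitivity (effects 1.1–1.7, SDs 0.3–0.7 — the range of
the top reported serum effects); 100 seeds for fold-plan invariants; and
40–100 seeds for calibration properties (KS uniformity of null p-values,
chance-level null clustering, truth-effect coverage). These sizes give
stable Monte-Carlo estimates for the asserted bounds while keeping the
whole suite fast.

## Known limitations

* The quantile-normalization leakage described above.
* The intersection rule's selection probability depends on the fold plan's
  seed; two analysts with different seeds can disagree on borderline
  proteins (the fold plan is exported as JSON to make any run exactly
  reproducible).
* `welch_from_summary` audits printed tables only up to the precision of
  the printed means/SDs; a row printed at one decimal can flip across
  α = 0.01 within its rounding interval.
* With 2–4 samples per group, `test_scope: validation` p-values are
  unstable; the option exists for completeness, not recommendation.
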