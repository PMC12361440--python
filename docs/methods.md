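# Methods

This note documents the statistical model behind each pipeline stage, the
generative model of the synthetic study, the default parameters and why they
were chosen, numerical conventions, and known limitations.

## Synthetic study model

The generator emulates a five-group placental cohort at delivery. Every
analyte has a link-scale signal

    s = baseline
        + slope · (GA − 37)        [GA-regulated analytes, matching sex]
        + λ · f                    [community members, matching condition]
        + log2FC · ln 2            [signature analytes, matching condition]
        + ε,   ε ~ Normal(0, noise_sd)

Abundance layers (metabolites, proteins, histopathology scores) report `s`
directly — these emulate normalized assay outputs, which are roughly
log-scale and may be negative. Counts layers (miRNA, mRNA) report
`round(exp(s))`, i.e. rounded log-normal read counts. Spearman statistics
are rank-based, so the marginal family of the counts is immaterial to the
network stage; the log-normal form was chosen for simplicity and because the
exponential preserves the latent-factor correlation structure in the ranks.

**Cohort.** Group sizes default to 113/36/30/71/71
(Control/FGR/FGR+HDP/PE/PTD) for 321 samples, fetal sex Bernoulli(1/2).
Gestational age at delivery is normal per condition (means 39.3/36.5/33.0/
35.5/33.5 weeks, clipped to each condition's clinical window inside the
23–42-week inclusion range), pregravid BMI is log-normal around 26 kg/m²,
spontaneous-labor probability is condition-specific (1.0 for PTD, which is
spontaneous by definition; 0.25 for the hypertensive groups), and smoking
and illicit-drug-use rates are 14%. These are qualitative matches to a
delivery cohort's summary statistics, not fitted distributions.

**GA regulation.** Default: 20 female-only, 20 male-only and 20 shared
analytes in the abundance layers with slope 0.05 per week. The slope is
deliberately small relative to `noise_sd = 0.5`: GA effect sizes on
placental analytes are small, and a large slope would make every pair of
GA-regulated analytes strongly correlated within conditions, swamping the
correlation networks with GA-driven edges — a regime the covariate-adjusted
analysis is designed to avoid. Per-sex detection power at these defaults is
moderate (roughly half the planted analytes are called per realization),
which also gives the overlap-null stage a non-degenerate observed overlap.
Effects are centered at 37 weeks so that a sex-specific slope does not plant
a sex main effect at the cohort's typical gestational age; the regression
slope of a planted analyte on GA is still exactly the planted value.

**Communities.** Each planted community has one latent factor
`f ~ Normal(0, 1)` per sample, applied only to samples of the community's
condition. Members load with |λ| = 1.2 and alternating signs (so the
recovered network has both positive and negative edges); the hub loads with
+2.5. Two members with loadings λᵢ, λⱼ correlate at
λᵢλⱼ / √((λᵢ²+σ²)(λⱼ²+σ²)), so member–member Pearson correlation is ~0.85
and hub–member ~0.91 at the defaults — large effect sizes, as interomics
networks surviving a Bonferroni threshold near 1e-7 require. The default
ground truth plants (i) a 100-analyte control community spanning all four
molecular layers whose hub is its first miRNA member, and (ii) a disrupted
FGR+HDP remnant — a different miRNA hub (itself an ordinary member of the
control community) plus six abundance-layer members shared with the control
community. Each hub is its community's *sole* correlated miRNA partner set:
because within-layer pairs are never tested, the hub has strictly the
largest cross-layer partner count, making argmax closeness a structural
property rather than a tie. The disease community's non-hub members live in
abundance layers only: a latent factor on a counts layer's log scale would
inflate that analyte's mean multiplicatively and contaminate the planted
fold-change signature.

**Signature.** Twelve mRNA members of the control community receive
log2FC = 1.5 in FGR+HDP. On the count scale this multiplies the mean by
2^1.5 exactly, so the ratio-of-means estimator is unbiased for the planted
value. **Composition.** Cell fractions are Dirichlet (10 cell types,
placenta-like concentrations); the planted shift moves the target cell
type's clr coordinate by exactly the requested amount (the sampled rows are
clr-transformed, translated along a zero-sum direction scaled so the target
coordinate moves by δ, and mapped back through softmax).

What the generator does **not** emulate: batch effects, assay detection
limits and censoring, count overdispersion beyond log-normality,
inter-condition covariate confounding beyond GA, correlated missingness, or
real single-cell reference profiles. Passing tests therefore demonstrate
correctness of the statistical machinery and recoverability of planted
structure under a clean generative model — not performance on real placental
data.

## Stage-by-stage notes

**Preprocessing.** Order is fixed: missingness filter → imputation →
uniqueness filter → count floor, with strict inequalities (kept iff missing
fraction < 0.20; kept iff distinct-value fraction > 0.50). Missing entries
are imputed as half the analyte's observed minimum in abundance layers and
as zero in counts layers (sequencing absence is a zero measurement). Count
floors (mRNA 500, miRNA 10) are totals across samples — a per-sample floor
would remove nearly all miRNAs — and the `FilterReport` records this scope.

**Composition.** clr uses additive zero imputation (+1e-6 to zero entries,
then renormalization). The two-sample KS test keeps scipy's automatic
exact/asymptotic switch at small n. BH families are per
condition-vs-control comparison (the conservative reading; pooling across
conditions is a caller choice since the function is per-comparison).

**Covariate adjustment.** The family rule is a pure function of the analyte
vector: gamma iff Anderson–Darling p < 0.05 or more than 2.5% of values have
|z| > 3 (z from the analyte's own mean and sample sd, ddof = 1). Gaussian
identity-link fits are closed-form least squares batched across analytes
(t-based two-sided GA p on n − p df); gamma fits use a log link — the log
guarantees positive fitted means and a multiplicative adjustment — through
IRLS, with a recorded shift of |min| + 1e-6 when the response is not
strictly positive. A zero-deviance (perfect) fit is treated as converged.
The BH family is all analytes within one sex, pooled over layers. BMI
enters as its square only, GA in weeks, maternal age is excluded
(collinear with GA).

Adjustment removes all nuisance terms (GA, BMI², labor, smoking, drug) by
default, restrictable to GA alone. The default location convention
(`preserve="mean"`) subtracts the *mean-centered* nuisance predictor so each
sex keeps its observed mean level. The alternative (`preserve="intercept"`)
subtracts the raw nuisance predictor, parking values at the fitted
intercept — the level extrapolated to GA = 0 weeks and BMI² = 0. Because
fits are sex-stratified, the intercept convention gives an analyte adjusted
in only one sex an artificial between-sex offset (each sex's intercept
absorbs its own covariate means), and any two such analytes then correlate
through fetal sex in the pooled-sample networks; the mean convention
eliminates this artifact and is what the pipeline uses.

**Overlap null.** Unrestricted random relabeling of all samples into two
pseudo-groups sized as the real sexes, full re-run of family selection, GLM
fitting and BH per group, 100 iterations by default. The empirical FDR
counts iterations with *strictly fewer* shared analytes than observed (ties
add nothing). A sex-stratified shuffling variant is available behind a flag.

**Networks.** Spearman's ρ is the Pearson correlation of average ranks
(tie-corrected), evaluated per layer pair as one matrix product; p-values
use the t approximation on n − 2 df, with |ρ| ≥ 1 − 1e-12 mapped to p = 0
and sub-underflow p clamped to 0 (always passing any positive threshold).
The Bonferroni denominator m counts tests actually performed: constant
analytes (undefined ρ) are skipped and logged, and only cross-layer pairs
are ever tested. Nodes are layer-qualified (`mrna:FLT1`) because gene
symbols recur across layers, and only endpoints of retained edges become
nodes. Downsampling draws a seeded uniform subsample without replacement.
A caveat measured during development and reflected in the test suite: at
n = 30 the t approximation is about 2× anti-conservative at the ~5e-6 tail
(per-test tail probability ≈ 1.03e-5 against a nominal 5e-6 over 10M null
draws), so the realized family-wise error of a 10,000-test Bonferroni
screen at α = 0.05 is near 10%, not ≤ 5%. The t approximation is
nevertheless retained as the standard (and the reference analysis's) method;
exact or permutation nulls are out of scope.

**Communities.** Louvain proper (greedy multi-level node aggregation) from
networkx, unweighted, seeded; resolution (default 0.45) enters the
optimization objective while reported modularity is the standard γ = 1
quantity. Coverage is the intra-community edge fraction and performance the
fraction of correctly classified node pairs — the standard definitions
computed by `networkx.community.partition_quality`. Closeness uses the
reachable-count scaling for disconnected graphs (isolates score 0).
Community connectivity reports per-community size, average shortest path
(largest connected component when disconnected, flagged; singletons
excluded from means, logged) and average local clustering.

**Signature mining.** Fold-change records cover all unordered condition
pairs, with pooled-variance two-tailed t-tests BH-corrected across analytes
within each comparison and the analyte-level filter flag
(q < 0.05 and |log2FC| ≥ log2 1.5 in ≥ 1 comparison). The default
fold-change estimator is the difference of group means of per-sample log2
values ("log-mean"); the ratio-of-means estimator is available via
`fc_method` but is sensitive to the heavy upper tail of log-normal
abundances. Selection clusters *all* candidate analytes' fold-change
profiles (average linkage, Euclidean) — the non-differential background
anchors the tree — and cuts it at the largest gap between consecutive merge
heights, with the cluster-count parameter (default 6) as an upper bound on
the number of clusters; a fixed cut count would shatter a coherent
fold-change block whenever few analytes pass the filter. Clusters are
ranked by mean |log2FC| over comparisons involving the target condition,
and the top-ranked cluster retaining at least `min_cluster_size` (default 2)
filter-passing members is the signature; this skips a lone extreme analyte
in favor of the coherent block, and degenerate inputs (nothing passing, all
profiles identical, no cluster large enough) raise with the ranking
attached. Projections divide each analyte by its mean level (analytes with
a mean at floating-point zero relative to their scale are dropped with a
warning), center, and use two-component PCA (variance explained from the
eigenvalue ratios) or PLS-DA (X-variance captured per score); separation is
the silhouette of the two-component scores under the condition labels.

## Numerical conventions and determinism

All randomness flows through `numpy.random.default_rng` seeds; the pipeline
derives stage seeds as fixed offsets from the config seed, and identical
configs produce byte-identical stage outputs. Partitions store communities
sorted (largest first, ties by smallest node id) so they serialize
reproducibly. Matrices are TSV with sample ids in the first column and
empty cells for missing values; networks are archived as GraphML plus an
edge-list TSV and a JSON sidecar carrying the Bonferroni bookkeeping.

## Problem sizes used in the checks

The recovery analyses run the full 321-sample cohort with layers scaled to
about 12% of the study's post-filter feature counts (roughly
104/41/54/1150 analytes plus 13 histopathology features, ~232k cross-layer
tests per condition), ten seeds for the pipeline chain, 200 replicates for
error-rate and estimator checks, and 50 outer replicates of the
100-iteration overlap null at 30 analytes. These sizes were chosen so the
whole suite completes in a few minutes while every planted effect remains
comfortably detectable at the study's group sizes.

## Known limitations

* The t-approximation miscalibration quantified above means Bonferroni
  control of the network stage is approximate at n = 30; at n = 113 the
  effect is much smaller.
* Gamma-family adjustment of values near zero is sensitive to the recorded
  positive shift; adjusted "counts" are continuous and are treated as
  abundance-kind downstream.
* The overlap null refits families per pseudo-group, which is faithful to
  the procedure but means its runtime scales with analyte count times
  iterations; reduced analyte panels are advisable for exploratory runs.
* Partition-quality values on synthetic networks depend on the planted
  community design and are not expected to match any particular cohort's
  numbers.
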