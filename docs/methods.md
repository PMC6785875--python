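# Methods

This note documents the statistical models, the synthetic-cohort generator,
the numerical choices, and the known limits of what the test suite can and
cannot show.

## Survival models

**Unpenalized Cox.** `survstats.CoxPH` maximizes the partial likelihood by
Newton-Raphson with step-halving. Tied event times use Efron's correction by
default (`ties="breslow"` available); standard errors come from the inverse
observed information. Monotone likelihood (a covariate that separates the
risk sets, so β̂ → ±∞) is detected when any |β| exceeds 20 during iteration
and is reported via `monotone=True` / `converged=False` rather than
returning a divergent estimate. Constant columns are dropped with an `NA`
coefficient. An optional ridge term ((ridge/2)·‖β‖²) stabilizes fits where a
factor level has no events — the kernel test's covariates-only null model
falls back to `ridge=0.1` with a warning when this occurs, which is routine
at n ≈ 27 with a three-level metastatic-site factor.

**Elastic-net Cox.** `survstats.CoxnetPath` minimizes
−(1/n)·log PL(β) + λ·Σⱼ wⱼ[α|βⱼ| + (1−α)βⱼ²/2] with Breslow ties, penalty
factors wⱼ = 1 for microbiome features and 0 for the six clinical
covariates, and α = 0.5 by default. The solver is the glmnet strategy:
an outer IRLS loop builds a diagonal-Hessian quadratic approximation around
the current linear predictor η, an inner cyclic coordinate-descent loop with
active-set iteration solves the penalized weighted least squares, and
solutions are warm-started down a log-spaced λ ladder (default 50 values for
single fits, 30 inside cross-validation; λ_min_ratio 0.01 when p ≥ n, 1e-4
otherwise). All columns are standardized internally to 1/n-variance;
coefficients are returned on the input (clr) scale. η is clamped to ±30:
beyond that the fit is heading into monotone likelihood and the quadratic
approximation is meaningless, so the IRLS loop stops for that λ. Convergence
is measured as max_j xv_j·Δβ_j² < tol (default 1e-13 for single path fits,
giving KKT residuals below 1e-6 along the path; 1e-7 inside
cross-validation, where only the nonzero pattern matters).

**Cross-validation.** `cv_coxnet` uses event-stratified folds (events and
censored observations dealt separately, so folds differ by at most one
event) and the Verweij-van Houwelingen partial deviance: fold k contributes
D_all(β_k) − D_train(β_k). The deviance-minimizing λ_min is the default
extraction rule; λ_1se is available. Fold assignments that leave a training
set with zero events are redrawn (up to 10 times).

**Stability selection.** `StabilitySelector` repeats cv_coxnet R times
(500 in the reference configuration) with independent refoldings, counting
how often each feature is nonzero at the repetition's chosen λ. The
full-data path is repetition-invariant and fitted once. Each repetition
draws from its own spawned RNG substream, so counts do not depend on feature
order. A companion covariate-adjusted single-feature Cox fit supplies
p-values, BH-adjusted within each feature table. The selection rule is
count ≥ 25% of repetitions AND q < 0.20; functional features additionally
require positively correlated metatranscriptomic expression (Spearman
p < 0.05, ρ > 0; the positive-only reading is configurable).

## Diversity and clustering

Richness and Shannon index (log base 2) are averaged over rarefactions
(default 100 iterations; depth = minimum sample depth) drawn as exact
multivariate hypergeometric subsamples. Shotgun relative-abundance tables
are summarized without rarefaction. JSD uses the natural log (bounded by
ln 2); weighted UniFrac is non-normalized by default (normalized behind a
flag); both are delegated to scipy/scikit-bio behind the module surface and
verified against brute-force oracles in the tests. PCoA reports the full
eigenspectrum including negative eigenvalues. Ward clustering defaults to
Ward.D2 (Lance-Williams update on squared dissimilarities; scipy `ward`);
the Ward.D variant is provided through the identity
ward.D(D) = ward.D2(√D) on merge order. Risk tagging: within each platform
the cluster with the longer Kaplan-Meier median PFS is "low-risk" (ties:
lower event fraction); the combined grouping is low/high when concordant,
intermediate when discordant. Because the tags are derived from the same
survival data subsequently tested by log-rank, the combined-group test is
partially circular; this mirrors the original design and is deliberate.

**Kernel survival test.** K = −½·J·D²·J (Gower centering), negative
eigenvalues truncated to zero by eigendecomposition. The score statistic
Q = r'Kr uses martingale residuals r of the covariates-only Cox null model;
significance comes from a permutation null on r,
p = (1 + #{Q_perm ≥ Q_obs})/(1 + n_perm), which at cohort sample sizes is
preferable to re-deriving a small-sample tail approximation. Note an
algebraic point: Q is invariant to adding a constant to every entry of K
(because Σr = 0), but *not* to adding a constant to the distances before
squaring — the cross term survives double centering. The property suite
asserts the kernel-level invariance.

## Compositional handling

Counts are closed to proportions; the clr transform adds a pseudocount
(default: half the smallest nonzero relative abundance of the table) and
centers each row's log-abundance on its geometric mean. "0.01%"/"0.03%"
abundance screens are proportions 1e-4/3e-4. The variance screen for
functional features is computed on clr-transformed values (raw-proportion
variance is dominated by abundant features) among features already passing
the prevalence and abundance screens; since the quantile is relative to the
surviving set, the variance screen is a one-shot rule — idempotence holds
for the prevalence/abundance screens only. Taxonomic agglomeration sums
features sharing a rank-prefixed name down to the target rank and removes
features unclassified at that rank.

Baseline cohort tables use Fisher's exact test with the probability-mass
two-sided convention (sum of tables no more probable than observed;
Freeman-Halton full enumeration for 2×k), and the Wilcoxon rank-sum test
(exact enumeration when combined n ≤ 20 without ties, otherwise the normal
approximation with tie and continuity corrections). Spearman correlations
use average ranks; p-values are exact (permutation enumeration) for n ≤ 9
and t-approximate otherwise.

## Synthetic cohorts

The generator emulates the study design it stands in for: 27 patients, a
17-sample metatranscriptome subset, 16S s-OTU counts at per-sample depths
drawn uniformly in 18,368-60,000 reads with a random coalescent-style
phylogeny (exponential branch lengths), species-level shotgun relative
abundances, HUMAnN-style stratified pathway tables, and clinical covariates
with cohort-matched marginals (age ~ N(70, 12); BMI ~ N(27.5, 5); 78% male;
56% recent antibiotics; 2/3 stage IV; metastatic sites 0/1-2/≥3 with
probabilities 0.41/0.33/0.26).

Latent species log-abundances are heavy-tailed (between-species SD 2.0,
within-sample SD 1.0), giving a realistic rank-abundance curve. Two
community types shift a random half of the taxa by ±2.0 latent log units
(signed, so dominance is reshuffled rather than uniformly enriched — this is
what makes the types separable by composition, as the emulated study's
clusters are). Taxa present on both platforms share the same latent value
before independent platform noise (SD 0.3); 16S counts are multinomial
draws; shotgun profiles apply a 1e-5 detection limit so prevalence filtering
is meaningful. Survival follows a proportional-hazards model: hazard =
h₀·exp(Σⱼ βⱼ·clrᵢⱼ + γ'Zᵢ + cluster term), with exponential event times by
inverse transform, administrative censoring at 25 months plus 10% uniform
early dropout. h₀ = 0.01/month is calibrated so the default cohort yields
roughly 12 events among 27 patients; per-feature contributions are centered
across patients so h₀ refers to the average patient; planted species'
baseline abundances are clamped at or above the population median, since the
emulated analysis only tests taxa passing the abundance screens. Default
planted effects: log HR +1.0, −1.0, +0.8 on three shared species; default
cluster hazard multiplier 5 (log 5) for community type 2; small covariate
effects (age +0.03/yr, BMI −0.04/unit) matching the cohort's direction of
imbalance.

Two derived configurations isolate a single planted structure:
`recovery_config` (n = 200, 3 planted taxa among 60 noise taxa, cluster
hazard off) for selection-pipeline validation, and `cluster_config`
(n = 150, cluster hazard only) for the clustering stages.

What the generator does **not** emulate: batch effects, sequencing error
profiles, chimeras, taxon-taxon ecological interactions beyond compositional
closure, non-proportional hazards, and informative censoring. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not robustness to those real-data phenomena.

## Calibration findings the tests encode

* **Per-fit null band.** On pure-noise data (n = 100, p = 30), one 10-fold
  cross-validated fit at λ_min selects a median of 1 feature; the 95th
  percentile over 200 null replicates is 9 (maximum 12). This is the
  calibration the null tests assert.
* **Repetition counts are not a null calibration.** Across repeated
  refoldings of one fixed null dataset, the per-feature selection-count
  distribution is bimodal: in roughly 45% of null datasets some
  dataset-lucky feature is selected in every repetition, because stability
  selection resamples folds, not data. Calibration must therefore happen at
  the per-fit level (above), and selection counts must be paired with the
  per-feature FDR screen, as the pipeline's dual criterion does.
* **Exact-set recovery is not a property of the dual criterion.** With
  3 planted taxa (|log HR| ≥ 0.8) among 60 survival-neutral taxa at n = 200
  and 100×10-fold repetitions, the pipeline recovers *all* planted taxa with
  maximal counts in every tested seed (sensitivity 1.0), but the selected
  set equals the planted set exactly in only about 2 of 10 seeds: BH at
  q < 0.20 admits ≥ 1 null feature in roughly half of seeds by construction,
  and compositional closure gives "noise" taxa genuinely nonzero hazard
  associations through their correlation with planted abundant taxa —
  associations the α = 0.5 elastic net is designed to co-select. The
  recovery acceptance test asserts exact-set recovery in ≥ 9/10 seeds and
  therefore fails by design under these conditions; the measured exact
  fraction and sensitivity are reported by `scripts/acceptance.py`.

## Problem sizes and defaults used in validation

The validation suites run the pipeline at the following scales, chosen as
representative of the workflow while keeping the suites practical: oracle
comparisons at n ≤ 60; recovery at n = 200 with 100×10-fold repetitions over
10 seeds; null calibration from 200 precomputed replicates plus 20 fresh
instances and 200 null kernel tests (199 permutations each); the end-to-end
run at the study's exact cohort shape (27 patients, 17-sample subset) with
repetitions scaled to 50 and the count threshold scaled proportionally
to 13. All randomness flows from one root seed through named, per-stage
substreams, so every stage is individually reproducible.
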