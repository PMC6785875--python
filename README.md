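# microsurv

Pre-treatment gut microbiome composition and function versus
progression-free survival (PFS) in small immunotherapy cohorts.

`microsurv` re-implements, as a tested and reusable Python pipeline, the
statistical workflow of a paired 16S amplicon / shotgun metagenome /
metatranscriptome cohort study of melanoma patients on checkpoint-inhibitor
immunotherapy: within- and between-sample diversity and their survival
association, concordance risk clustering, stability-selected penalized Cox
identification of survival-associated taxa and functional pathways, and
metagenome-metatranscriptome integration. It ships a synthetic-cohort
generator with planted ground truth, so every stage is testable without
access to patient-level sequencing data.

It is aimed at microbiome statisticians and computational biologists who
want a transparent, fully scripted version of this analysis to validate,
adapt, or power-check against their own cohorts.

## What it computes

* **Alpha diversity.** Richness and the Shannon index (log base 2),
  averaged over 100 rarefactions of 16S s-OTU counts to the minimum sample
  depth; shotgun subspecies tables are summarized without rarefaction. Each
  index is related to PFS with a Cox proportional hazards model adjusting
  for age, sex, BMI, stage, number of metastatic sites, and recent
  antibiotic use.
* **Beta diversity and risk clustering.** Jensen-Shannon divergence
  (JSD(P,Q) = ½KL(P‖M) + ½KL(Q‖M), M = (P+Q)/2, natural log) and weighted
  UniFrac (Σᵢ bᵢ·|p_A(i) − p_B(i)| over branches i); PCoA; Ward.D2
  clustering into two groups per platform; a combined low / intermediate /
  high risk grouping from 16S-shotgun cluster concordance, compared by
  Kaplan-Meier curves and log-rank tests; and a kernel machine score test
  (Q = r'Kr on covariate-adjusted martingale residuals, permutation null)
  for the community-level association with PFS.
* **Taxon and pathway selection.** Features are agglomerated (Greengenes
  rank strings), screened (prevalence ≥ 25%, mean relative abundance
  > 0.01% for taxa / > 0.03% for pathways, clr-variance above the 25th
  percentile for functions), clr-transformed, and passed through repeated
  cross-validated elastic-net penalized Cox regression

      -(1/n)·log PL(β) + λ·Σⱼ wⱼ[α|βⱼ| + (1−α)βⱼ²/2],   α = 0.5,

  with the clinical covariates unpenalized (wⱼ = 0). Over 500 repetitions
  of 10-fold cross-validation a feature's selection count is tallied; a
  feature is called when it is selected in ≥ 25% of repetitions *and* its
  covariate-adjusted per-feature Cox q-value (Benjamini-Hochberg within
  table) is < 0.20. Functional features additionally require positively
  correlated metatranscriptomic expression (Spearman p < 0.05).
* **Functional integration.** RNA/DNA relative expression, per-species
  pathway contribution summaries (shares normalized to 100% per patient,
  averaged), and covariate-adjusted Cox fits per (species, pathway) stratum.

The elastic-net Cox solver (cyclic coordinate descent on an IRLS quadratic
approximation, warm-started down a log-spaced λ ladder, Breslow ties) and
the Newton-Raphson Cox fitter (Efron ties, monotone-likelihood detection)
are implemented in-package and are cross-checked in the test suite against
independent oracles (grid-search partial-likelihood maximization, KKT
conditions, scikit-survival, lifelines).

## Worked example

```python
from microsurv import SyntheticConfig, generate_cohort, StabilitySelector
from microsurv.compositional import clr_transform, filter_features, to_relative_abundance
from microsurv.diversity import jsd_matrix
from microsurv.riskcluster import ward_cluster, assign_risk_groups, logrank_test
from microsurv._rng import substream

cohort = generate_cohort(SyntheticConfig(seed=7))
sv = cohort.survival
print(f"{sv.n} patients, {sv.n_events} progression events")

lab16 = ward_cluster(jsd_matrix(to_relative_abundance(cohort.table_16s)), k=2)
labsg = ward_cluster(jsd_matrix(to_relative_abundance(cohort.table_shotgun)), k=2)
groups = assign_risk_groups(lab16, labsg, sv)
chi, df, p = logrank_test(sv, groups["combined_group"])
print(groups["combined_group"].value_counts().to_dict())
print(f"log-rank chi2 = {chi:.2f} (df={df}), p = {p:.4f}")

filtered, _ = filter_features(cohort.table_shotgun, prevalence_min=0.25,
                              mean_relabund_min=1e-4)
clr = clr_transform(filtered)
sel = StabilitySelector(clr.values, survival=sv, repeats=100, folds=10)
res = sel.fit(rng=substream(7, "stability"))
top = res.summary().sort_values("selection_count", ascending=False)
print(top[["selection_count", "HR", "q"]].head(5).round(3))
```

prints

```
27 patients, 17 progression events
{'high': 15, 'low': 11, 'intermediate': 1}
log-rank chi2 = 7.07 (df=2), p = 0.0291
       selection_count     HR      q
sp159              100  0.284  0.048
sp003               68  2.730  0.015
sp002               68  0.208  0.015
sp021               68  0.292  0.022
sp012               62  2.376  0.048
```

The 27-patient cohort carries two community types with a five-fold hazard
difference and three planted taxa (`sp001`-`sp003`, log hazard ratios +1.0,
−1.0, +0.8). The concordance grouping separates survival (log-rank
p = 0.03), and planted taxa appear among the top selections with hazard
ratios in the planted directions (`sp003`: HR 2.7 > 1; `sp002`: HR 0.2 < 1);
at n = 27 the counts of correlated neighbours (e.g. `sp159`) illustrate why
the published design repeats the cross-validation 500 times and applies the
dual count/FDR criterion.

The same pipeline is exposed as a CLI:

```bash
microsurv simulate --seed 7 --outdir sim/
microsurv run-all --config cfg.json --outdir results/
```

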