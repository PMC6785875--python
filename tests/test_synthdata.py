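import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microsurv.compositional import clr_transform
from microsurv.containers import ClrTable
from microsurv.survstats import cox_fit
from microsurv.synthdata import (
    SyntheticConfig,
    generate_cohort,
    generate_function_tables,
    generate_survival,
    generate_taxa_tables,
    recovery_config,
)

# 5th percentile of Spearman rho between observed shotgun abundance and the
# latent log-abundance of a planted shared taxon (noise sd 0.3, n=100),
# precomputed from 1000 generator replicates (mean 0.84, min 0.42).
RHO_THRESHOLD_Q05 = 0.66


class TestTaxaTables:
    def test_identical_seed_bitwise_identical(self):
        a = generate_cohort(SyntheticConfig(seed=1))
        b = generate_cohort(SyntheticConfig(seed=1))
        assert (a.table_16s.values.to_numpy() == b.table_16s.values.to_numpy()).all()
        assert (a.table_shotgun.values.to_numpy() == b.table_shotgun.values.to_numpy()).all()
        assert (a.survival.frame.to_numpy() == b.survival.frame.to_numpy()).all()
        assert str(a.tree) == str(b.tree)
        assert (a.mgx.stratified.to_numpy() == b.mgx.stratified.to_numpy()).all()

    def test_depths_within_stated_range(self):
        cfg = SyntheticConfig(seed=2)
        t16, *_ = generate_taxa_tables(cfg)
        depths = t16.values.sum(axis=1)
        assert depths.min() >= cfg.depth_range[0]
        assert depths.max() <= cfg.depth_range[1]
        assert t16.is_counts

    def test_shotgun_rows_close_to_one(self):
        _, tsg, *_ = generate_taxa_tables(SyntheticConfig(seed=3))
        assert np.allclose(tsg.values.sum(axis=1), 1.0, atol=1e-9)

    def test_tree_covers_16s_features(self):
        t16, _, tree, _ = generate_taxa_tables(SyntheticConfig(seed=4))
        tips = {t.name for t in tree.tips()}
        assert set(t16.feature_ids) <= tips
        assert all((n.length or 0) >= 0 for n in tree.traverse(include_self=False))

    def test_noise_free_limit_gives_perfect_pairing(self):
        cfg = SyntheticConfig(platform_noise_sd=0.0, shared_fraction=1.0,
                              n_taxa_16s=40, n_taxa_shotgun=40, n_patients=30,
                              seed=5, detection_limit=0.0)
        t16, tsg, _, truth = generate_taxa_tables(cfg)
        sotu_by_sp = {v: k for k, v in truth.sotu_to_species.items()}
        for sp in truth.shared_species:
            rho = stats.spearmanr(truth.prob_16s[sotu_by_sp[sp]],
                                  tsg.values[sp]).statistic
            assert rho == pytest.approx(1.0)

    def test_noisy_taxon_tracks_latent_truth(self):
        cfg = SyntheticConfig(n_patients=100, n_taxa_16s=40, n_taxa_shotgun=40,
                              seed=20000, platform_noise_sd=0.3)
        _, tsg, _, truth = generate_taxa_tables(cfg)
        rho = stats.spearmanr(tsg.values["sp001"],
                              truth.latent_log_abundance["sp001"]).statistic
        assert rho > RHO_THRESHOLD_Q05

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SyntheticConfig(n_patients=0)
        with pytest.raises(ValueError, match="positive"):
            SyntheticConfig(n_taxa_16s=-5)

    def test_unknown_planted_feature_rejected(self):
        cfg = SyntheticConfig(planted_effects={"nothere": 1.0})
        with pytest.raises(ValueError, match="nothere"):
            generate_taxa_tables(cfg)


class TestSurvival:
    def test_null_model_times_are_exponential(self):
        # no planted effects, no covariate effects, no cluster effect, no
        # censoring: observed times are iid Exp(baseline rate)
        cfg = SyntheticConfig(n_patients=2000, n_taxa_16s=10, n_taxa_shotgun=10,
                              planted_effects={}, covariate_log_hrs={},
                              cluster_log_hr=0.0, cluster_separation=0.0,
                              dropout_fraction=0.0, censoring_horizon=1e9,
                              baseline_hazard_rate=0.05, seed=6)
        _, tsg, _, truth = generate_taxa_tables(cfg)
        sv = generate_survival(cfg, clr_transform(tsg), truth)
        assert sv.n_events == 2000
        _, p = stats.kstest(sv.time, "expon", args=(0, 1 / 0.05))
        assert p > 0.01

    def test_positive_effect_shortens_high_tertile_pfs(self):
        cfg = recovery_config(seed=8, n_patients=500,
                              planted_effects={"sp001": 1.0})
        _, tsg, _, truth = generate_taxa_tables(cfg)
        clr = clr_transform(tsg)
        sv = generate_survival(cfg, clr, truth)
        x = clr.values["sp001"]
        lo = sv.frame.loc[x[x <= x.quantile(1 / 3)].index, "time"]
        hi = sv.frame.loc[x[x >= x.quantile(2 / 3)].index, "time"]
        assert hi.median() < lo.median()

    def test_planted_beta_recovered_by_adjusted_cox(self):
        # independent Newton-Raphson maximizer recovers the planted log HR;
        # band +/-0.15 derived from repeated generator runs at this size
        cfg = SyntheticConfig(n_patients=400, seed=7,
                              planted_effects={"sp001": 0.8},
                              cluster_log_hr=0.0, cluster_separation=0.0)
        _, tsg, _, truth = generate_taxa_tables(cfg)
        clr = clr_transform(tsg)
        sv = generate_survival(cfg, clr, truth)
        res = cox_fit(clr.values[["sp001"]], survival=sv)
        assert abs(res.params.iloc[0] - 0.8) < 0.15

    def test_event_indicator_consistent_with_horizon(self):
        b = generate_cohort(SyntheticConfig(seed=9))
        sv = b.survival
        assert (sv.time <= b.config.censoring_horizon + 1e-9).all()
        # events strictly before the horizon (censored exactly at it)
        assert (sv.time[sv.event == 1] <= b.config.censoring_horizon).all()

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SyntheticConfig(baseline_hazard_rate=0.0)

    def test_uncentered_clr_rejected(self):
        cfg = SyntheticConfig(seed=10)
        _, tsg, _, truth = generate_taxa_tables(cfg)
        bad = ClrTable.__new__(ClrTable)  # bypass validation to feed bad rows
        bad.values = tsg.values * 1.0
        bad.pseudocount = 1e-6
        with pytest.raises(ValueError, match="centered"):
            generate_survival(cfg, bad, truth)


class TestFunctionTables:
    def test_expression_factor_one_noise_zero_recovers_mgx(self):
        cfg = SyntheticConfig(seed=11, expression_factor_sd=0.0, mtx_noise_sd=0.0)
        _, tsg, _, truth = generate_taxa_tables(cfg)
        mgx, mtx = generate_function_tables(cfg, tsg, truth)
        sub = mtx.total.index
        assert np.allclose(mtx.total.to_numpy(),
                           mgx.total.loc[sub].to_numpy(), atol=1e-9)

    def test_single_species_pathway_contributes_everything(self):
        cfg = SyntheticConfig(seed=12)
        _, tsg, _, truth = generate_taxa_tables(cfg)
        w = truth.contribution_weights
        single = [pw for pw in w.index if (w.loc[pw] > 0).sum() == 1]
        assert single, "generator should produce some single-species pathways"
        mgx, _ = generate_function_tables(cfg, tsg, truth)
        pw = single[0]
        strat = mgx.stratified[pw]
        assert np.allclose(strat.sum(axis=1), mgx.total[pw], atol=1e-12)
        assert strat.shape[1] == 1

    def test_weights_rows_sum_to_one(self):
        *_, truth = generate_taxa_tables(SyntheticConfig(seed=13))
        assert np.allclose(truth.contribution_weights.sum(axis=1), 1.0)

    def test_three_to_one_weights_give_75_25_shares(self):
        # closed form: equal species abundance with weights (0.75, 0.25)
        from microsurv.containers import FeatureTable, StratifiedFunctionTable
        from microsurv.funcintegration import species_contribution

        A = pd.DataFrame({"spA": [0.5] * 4, "spB": [0.5] * 4},
                         index=[f"P{i}" for i in range(4)])
        strat = pd.DataFrame({("PWY1", "spA"): 0.75 * A["spA"],
                              ("PWY1", "spB"): 0.25 * A["spB"]})
        strat.columns = pd.MultiIndex.from_tuples(strat.columns,
                                                  names=["pathway", "species"])
        table = StratifiedFunctionTable(total=strat.T.groupby(level=0).sum().T,
                                        stratified=strat)
        out = species_contribution(table).set_index("species")
        assert out.loc["spA", "mean_percent"] == pytest.approx(75.0)
        assert out.loc["spB", "mean_percent"] == pytest.approx(25.0)

    def test_unknown_species_in_weights_rejected(self):
        cfg = SyntheticConfig(seed=14)
        _, tsg, _, truth = generate_taxa_tables(cfg)
        truth.contribution_weights = truth.contribution_weights.rename(
            columns={truth.contribution_weights.columns[0]: "ghost_species"})
        with pytest.raises(ValueError, match="unknown species"):
            generate_function_tables(cfg, tsg, truth)

    def test_mtx_restricted_to_subset(self):
        cfg = SyntheticConfig(seed=15)
        b = generate_cohort(cfg)
        n_expected = int(round(cfg.mtx_subset_fraction * cfg.n_patients))
        assert len(b.mtx.sample_ids) == n_expected
        assert set(b.mtx.sample_ids) <= set(b.mgx.sample_ids)

    def test_mtx_subset_too_small_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            SyntheticConfig(n_patients=4, mtx_subset_fraction=0.25)
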