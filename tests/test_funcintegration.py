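import numpy as np
import pandas as pd
import pytest

from microsurv.containers import StratifiedFunctionTable
from microsurv.funcintegration import (
    mgx_mtx_correlations,
    mgx_mtx_gate,
    per_species_pathway_cox,
    relative_expression,
    spearman,
    species_contribution,
)
from microsurv.survstats.stability import StabilityResults


class TestSpearman:
    def test_monotone_increasing_pair(self):
        assert spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50]).rho == pytest.approx(1.0)

    def test_reversed_pair(self):
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]).rho == pytest.approx(-1.0)

    def test_rank_difference_formula_by_hand(self):
        # d^2 = (1,1,1,1,0): rho = 1 - 6*4/(5*(25-1)) = 1 - 24/120 = 0.8
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rho == pytest.approx(0.8)
        assert res.method == "exact-permutation"

    def test_exact_permutation_p_matches_enumeration(self):
        from itertools import permutations

        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 4, 3, 6, 5]
        mine = spearman(x, y)
        # independent route: enumerate pairings, rho from the sum-of-squared
        # rank differences formula (valid without ties)
        n = 6

        def rho_d2(yperm):
            d2 = sum((i + 1 - yperm[i]) ** 2 for i in range(n))
            return 1 - 6 * d2 / (n * (n * n - 1))

        obs = abs(rho_d2(y))
        hits = sum(abs(rho_d2(p)) >= obs - 1e-12 for p in permutations(range(1, n + 1)))
        assert mine.p_value == pytest.approx(hits / 720, abs=1e-12)

    def test_constant_vector_flagged_undefined(self):
        res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert not res.defined
        assert np.isnan(res.rho)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(0)
        res = spearman(rng.normal(size=20), rng.normal(size=20))
        assert res.method == "t-approximation"
        assert 0 <= res.p_value <= 1


def make_stability(counts, qs, repeats=500):
    table = pd.DataFrame({
        "selection_count": counts,
        "selection_frequency": np.asarray(counts) / repeats,
        "q": qs,
    }, index=[f"pw{i}" for i in range(len(counts))])
    return StabilityResults(table=table, repeats=repeats, folds=10,
                            alpha=0.5, lambda_rule="min")


def make_corr(rhos, ps):
    return pd.DataFrame({"rho": rhos, "p": ps, "n": 17, "defined": True},
                        index=[f"pw{i}" for i in range(len(rhos))])


class TestGate:
    def test_all_three_criteria_required(self):
        stab = make_stability([300, 300, 300, 100], [0.01, 0.01, 0.01, 0.01])
        corr = make_corr([0.6, 0.6, -0.6, 0.6], [0.01, 0.20, 0.01, 0.01])
        audit = mgx_mtx_gate(stab, corr, 125, 0.20, 0.05)
        assert audit.loc["pw0", "gated"]          # passes (a), (b), (c)
        assert not audit.loc["pw1", "gated"]      # correlation p too large
        assert not audit.loc["pw2", "gated"]      # negative rho
        assert not audit.loc["pw3", "gated"]      # count below threshold

    def test_negative_rho_allowed_when_relaxed(self):
        stab = make_stability([300], [0.01])
        corr = make_corr([-0.7], [0.001])
        audit = mgx_mtx_gate(stab, corr, 125, 0.20, 0.05, require_positive=False)
        assert audit.loc["pw0", "gated"]

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 501, 12)
        qs = rng.uniform(0, 0.5, 12)
        rhos = rng.uniform(-1, 1, 12)
        ps = rng.uniform(0, 0.2, 12)
        audit = mgx_mtx_gate(make_stability(counts, qs), make_corr(rhos, ps),
                             125, 0.20, 0.05)
        brute = {f"pw{i}" for i in range(12)
                 if counts[i] >= 125 and qs[i] < 0.20 and ps[i] < 0.05 and rhos[i] > 0}
        assert set(audit.index[audit["gated"]]) == brute

    def test_gated_subset_of_stability_selected(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 501, 15)
        qs = rng.uniform(0, 0.4, 15)
        stab = make_stability(counts, qs)
        audit = mgx_mtx_gate(stab, make_corr(rng.uniform(-1, 1, 15),
                                             rng.uniform(0, 0.2, 15)), 125, 0.2)
        gated = set(audit.index[audit["gated"]])
        selected = set(stab.selected(125, 0.2))
        assert gated <= selected


def stratified(total_rows, strata, samples=None):
    samples = samples or [f"P{i}" for i in range(len(next(iter(strata.values()))))]
    strat = pd.DataFrame(strata, index=samples)
    strat.columns = pd.MultiIndex.from_tuples(strat.columns,
                                              names=["pathway", "species"])
    total = strat.T.groupby(level=0).sum().T
    return StratifiedFunctionTable(total=total, stratified=strat)


class TestRelativeExpression:
    def test_identical_tables_ratio_one(self):
        t = stratified(None, {("PWY1", "spA"): [0.4, 0.6], ("PWY2", "spB"): [0.6, 0.4]})
        out = relative_expression(t, t, smoothing=1e-12)
        assert np.allclose(out.values.to_numpy(), 1.0, atol=1e-6)

    def test_zero_dna_smoothing_contract(self):
        mgx = stratified(None, {("PWY1", "spA"): [0.0, 1.0], ("PWY2", "spB"): [1.0, 0.0]})
        mtx = stratified(None, {("PWY1", "spA"): [0.5, 0.5], ("PWY2", "spB"): [0.5, 0.5]})
        s = 0.1
        out = relative_expression(mtx, mgx, smoothing=s)
        assert out.values.loc["P0", "PWY1"] == pytest.approx((0.5 + s) / s)
        more = relative_expression(
            stratified(None, {("PWY1", "spA"): [0.8, 0.2], ("PWY2", "spB"): [0.2, 0.8]}),
            mgx, smoothing=s)
        assert more.values.loc["P0", "PWY1"] > out.values.loc["P0", "PWY1"]

    def test_toy_ratios_match_hand_division(self):
        mgx = stratified(None, {("PWY1", "spA"): [0.2, 0.8], ("PWY2", "spB"): [0.8, 0.2]})
        mtx = stratified(None, {("PWY1", "spA"): [0.4, 0.4], ("PWY2", "spB"): [0.6, 0.6]})
        out = relative_expression(mtx, mgx, smoothing=1e-12)
        assert out.values.loc["P0", "PWY1"] == pytest.approx(2.0, rel=1e-6)
        assert out.values.loc["P1", "PWY2"] == pytest.approx(3.0, rel=1e-6)


class TestSpeciesContribution:
    def test_single_species_pathway_full_share(self):
        t = stratified(None, {("PWY1", "spA"): [0.3, 0.7]})
        out = species_contribution(t)
        assert (out["mean_percent"] == 100.0).all()

    def test_shares_sum_to_hundred_per_pathway(self):
        rng = np.random.default_rng(3)
        t = stratified(None, {("PWY1", "spA"): rng.uniform(0.1, 1, 5),
                              ("PWY1", "spB"): rng.uniform(0.1, 1, 5),
                              ("PWY1", "spC"): rng.uniform(0.1, 1, 5)},
                       samples=[f"P{i}" for i in range(5)])
        out = species_contribution(t)
        assert out[out.pathway == "PWY1"]["mean_percent"].sum() == pytest.approx(100.0)

    def test_invariant_to_scaling_a_patient(self):
        strata = {("PWY1", "spA"): [0.2, 0.5], ("PWY1", "spB"): [0.6, 0.1]}
        t1 = stratified(None, strata)
        scaled = {k: np.array(v) * np.array([3.0, 1.0]) for k, v in strata.items()}
        t2 = stratified(None, scaled)
        a = species_contribution(t1).set_index("species")["mean_percent"]
        b = species_contribution(t2).set_index("species")["mean_percent"]
        assert np.allclose(a, b)

    def test_absent_pathway_skipped(self):
        t = stratified(None, {("PWY1", "spA"): [0.5, 0.5], ("PWY2", "spB"): [0.0, 0.0]})
        out = species_contribution(t)
        assert "PWY2" not in set(out["pathway"])


class TestPerSpeciesPathwayCox:
    def test_combination_count_equals_nonzero_strata(self, default_bundle):
        b = default_bundle
        out = per_species_pathway_cox(b.mgx, b.survival)
        nonzero = sum(1 for c in b.mgx.stratified.columns
                      if b.mgx.stratified[c].to_numpy().sum() > 0)
        assert len(out) == nonzero
        assert {"pathway", "species", "HR", "p"} <= set(out.columns)

    def test_planted_risk_stratum_direction_recovered(self):
        from microsurv.synthdata import generate_cohort, recovery_config

        b = generate_cohort(recovery_config(seed=30, n_patients=200))
        out = per_species_pathway_cox(b.mgx, b.survival).set_index(["species"])
        risk = out.loc[["sp001"]]  # planted log HR +1.0
        converged = risk[risk["converged"]]
        assert (converged["HR"] > 1).mean() > 0.5


class TestCorrelationsTable:
    def test_mgx_mtx_correlations_shapes(self, default_bundle):
        b = default_bundle
        corr = mgx_mtx_correlations(b.mgx.total, b.mtx.total)
        assert len(corr) == len(b.mgx.total.columns)
        assert corr["rho"].abs().max() <= 1.0 + 1e-12
        assert (corr["n"] == len(b.mtx.sample_ids)).all()
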