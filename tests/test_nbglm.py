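import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dystromon import simulate
from dystromon.core_io import CountMatrix
from dystromon.nbglm import (
    NBFit,
    _irls,
    block_pc_summary,
    build_cohort_design,
    cohort_tests,
    fit_nb_glm,
    nb_deviance,
    pc_association,
    qlf_test,
    treatment_analysis,
    treatment_concordance,
)
from dystromon.simulate import _nb_counts


def _counts(rng, G=60, n=12, phi=0.1, mu_log=5.0):
    mu = rng.normal(mu_log, 1.0, G)
    libs = rng.lognormal(np.log(1e6), 0.2, n)
    y = _nb_counts(rng, np.tile(mu[:, None], (1, n)), libs, np.full(G, phi))
    return y, libs


class TestFitNbGlm:
    def test_intercept_only_fitted_mean_is_pooled_ratio(self, rng):
        # in the Poisson limit the ML intercept with offsets is exactly
        # log(sum of counts / sum of effective libraries)
        y, libs = _counts(rng)
        X = np.ones((12, 1))
        beta, mu, _, conv, _ = _irls(y, X, np.log(libs), 1e-12)
        expect = y.sum(axis=1) / libs.sum()
        assert np.allclose(np.exp(beta[:, 0]), expect, rtol=1e-8)

    def test_rank_deficient_design_rejected(self, rng):
        y, libs = _counts(rng)
        X = np.column_stack([np.ones(12), np.ones(12)])
        with pytest.raises(ValueError, match="aliased"):
            fit_nb_glm(y, X, np.log(libs))

    def test_offset_rescaling_leaves_pvalues_unchanged(self, rng):
        y, libs = _counts(rng, G=40)
        grp = (np.arange(12) % 2).astype(float)
        X = np.column_stack([np.ones(12), grp])
        f1 = fit_nb_glm(y, X, np.log(libs))
        f2 = fit_nb_glm(y, X, np.log(libs * 7.3))
        t1 = qlf_test(f1, [1])
        t2 = qlf_test(f2, [1])
        assert np.allclose(t1["p"], t2["p"], atol=1e-8)
        assert np.allclose(t1["logFC"], t2["logFC"], atol=1e-8)

    def test_quasi_one_df_f_is_square_of_quasi_t(self, rng):
        y, libs = _counts(rng, G=40)
        grp = (np.arange(12) % 2).astype(float)
        X = np.column_stack([np.ones(12), grp])
        fit = fit_nb_glm(y, X, np.log(libs))
        tab = qlf_test(fit, [1])
        t = np.sign(tab["logFC"]) * np.sqrt(tab["F"])
        assert np.allclose(t ** 2, tab["F"], atol=1e-8)

    def test_zero_dispersion_matches_poisson_deviance_test(self, rng):
        # dispersion forced to ~0 and squeeze disabled: QLF deviance drop
        # equals the Poisson GLM likelihood-ratio statistic (statsmodels)
        import statsmodels.api as sm
        y, libs = _counts(rng, G=8, phi=1e-12)
        grp = (np.arange(12) % 2).astype(float)
        X = np.column_stack([np.ones(12), grp])
        off = np.log(libs)
        beta, mu, dev, conv, _ = _irls(y, X, off, 1e-12)
        _, _, dev0, _, _ = _irls(y, X[:, :1], off, 1e-12)
        drop = dev0 - dev
        for g in range(8):
            full = sm.GLM(y[g], X, family=sm.families.Poisson(), offset=off).fit()
            null = sm.GLM(y[g], X[:, :1], family=sm.families.Poisson(), offset=off).fit()
            lr = 2 * (full.llf - null.llf)
            assert drop[g] == pytest.approx(lr, abs=1e-5)

    def test_dispersion_recovery_window(self, rng):
        y, libs = _counts(rng, G=400, n=20, phi=0.1)
        X = np.column_stack([np.ones(20), (np.arange(20) % 2).astype(float)])
        fit = fit_nb_glm(y, X, np.log(libs))
        assert 0.05 <= np.median(fit.dispersion) <= 0.2


class TestTreatmentConcordance:
    def _run(self, kappa, seed, n_de=100, **kw):
        d_long = simulate.molong_design(n_genes=400, n_de=n_de, modules=None, seed=seed)
        _, _, truth_l = simulate.simulate_longitudinal(d_long)
        dt = simulate.motreat_design(
            n_genes=400, n_de=n_de, modules=None, seed=seed + 1,
            treatment=simulate.TreatmentSpec(kappa=kappa, n_side_effect=0), **kw)
        cm, st_meta, truth_t = simulate.simulate_treatment(dt, truth_l)
        rep = treatment_analysis(cm, st_meta, truth_l.de_genes,
                                 truth_l.logfc["week12"])
        return rep, truth_t

    def test_full_restoration_noiseless_recovers_planted_set(self):
        rep, truth = self._run({"PMO": 1.0, "PS49": 1.0}, seed=50,
                               phi_meanlog=np.log(1e-12), phi_sdlog=0.0,
                               lib_meanlog=np.log(5e7), lib_sdlog=0.01)
        found = set(rep.concordant[rep.concordant].index)
        planted = set(truth.concordant_genes) & set(rep.analyzed_genes)
        assert found == planted

    def test_no_restoration_matches_orthant_probability(self):
        # with kappa = 0 both arms the concordance is pure chance; the two
        # logFC estimates share the saline arm, so the chance level is the
        # bivariate-normal orthant probability 1/4 + arcsin(rho)/(2 pi)
        rep, _ = self._run({"PMO": 0.0, "PS49": 0.0}, seed=52, n_de=200)
        rho = np.corrcoef(rep.arm_logfc["PMO"], rep.arm_logfc["PS49"])[0, 1]
        expect = 0.25 + np.arcsin(rho) / (2 * np.pi)
        n = len(rep.analyzed_genes)
        frac = rep.n_concordant / n
        ci = 3 * np.sqrt(expect * (1 - expect) / n)
        assert abs(frac - expect) <= ci

    def test_filter_bookkeeping_reports_both_counts(self, rng):
        # genes below the count filter are dropped and counted, echoing a
        # 416 -> 395 style report
        d_long = simulate.molong_design(n_genes=300, n_de=80, modules=None, seed=60)
        _, _, truth_l = simulate.simulate_longitudinal(d_long)
        dt = simulate.motreat_design(n_genes=300, n_de=80, modules=None, seed=61,
                                     treatment=simulate.TreatmentSpec(n_side_effect=0))
        cm, st_meta, _ = simulate.simulate_treatment(dt, truth_l)
        ghost = [f"missing{i}" for i in range(21)]
        gene_list = truth_l.de_genes + ghost
        rep = treatment_analysis(cm, st_meta, gene_list, truth_l.logfc["week12"])
        assert rep.n_requested == len(gene_list)
        assert rep.n_dropped_by_filter >= len(ghost)
        assert len(rep.analyzed_genes) == rep.n_requested - rep.n_dropped_by_filter

    def test_side_effect_genes_detected_in_ps49_arm(self):
        d_long = simulate.molong_design(n_genes=400, n_de=50, modules=None, seed=70)
        _, _, truth_l = simulate.simulate_longitudinal(d_long)
        dt = simulate.motreat_design(n_genes=400, n_de=50, modules=None, seed=71)
        cm, st_meta, truth_t = simulate.simulate_treatment(dt, truth_l)
        # test all filtered genes so side-effect genes are in the analysis
        from dystromon.normalize import filter_by_cpm, tmm_factors
        filt = filter_by_cpm(cm)
        off = np.log(filt.lib_sizes * tmm_factors(filt))
        arm = st_meta["treatment"].to_numpy()
        X = np.column_stack([np.ones(len(arm)), (arm == "PMO").astype(float),
                             (arm == "PS49").astype(float)])
        fit = fit_nb_glm(filt.counts, X, off, gene_ids=filt.gene_ids)
        tab = qlf_test(fit, [2]).set_index("gene_id")
        side = [g for g in truth_t.side_effect_genes if g in tab.index]
        assert (tab.loc[side, "adj_p"] < 0.05).mean() >= 0.8

    def test_concordance_invariant_to_gene_order_and_magnitude(self, rng):
        genes = [f"g{i}" for i in range(50)]
        lfc = pd.DataFrame({"PMO": rng.normal(size=50), "PS49": rng.normal(size=50)},
                           index=genes)
        disease = pd.Series(rng.normal(size=50), index=genes)
        conc1, _ = treatment_concordance(lfc, disease)
        perm = rng.permutation(50)
        conc2, _ = treatment_concordance(lfc.iloc[perm], disease)
        assert conc1.sort_index().equals(conc2.sort_index())
        conc3, _ = treatment_concordance(lfc * 100.0, disease)
        assert conc1.equals(conc3)


class TestCohort:
    def test_confounded_design_names_aliased_terms(self):
        meta = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(8)],
            "group": ["healthy"] * 4 + ["DMD"] * 4,
            "age": [10.0] * 8,
            "treatment": [0, 0, 0, 0, 1, 1, 1, 1],
        })
        X, names = build_cohort_design(meta)
        rng = np.random.default_rng(0)
        y = rng.poisson(50, (20, 8))
        with pytest.raises(ValueError, match="aliased"):
            fit_nb_glm(y, X, np.zeros(8))

    def test_group_and_steroid_and_interaction_recovered(self):
        d = simulate.dmdmex_design(n_genes=800, modules=None, seed=32)
        cm, st_meta, blocks, truth = simulate.simulate_cohort(d)
        res = cohort_tests(cm, st_meta)
        g = res["group"].set_index("gene_id")
        ster = [x for x in truth.steroid_genes if x in g.index]
        sign_agree = (np.sign(g.loc[ster, "steroid_log2fc"])
                      == -np.sign(g.loc[ster, "baseline_log2fc"])).mean()
        assert sign_agree >= 0.8
        up = [x for x in truth.de_genes if x in g.index
              and truth.logfc.loc[x, "DMD_vs_healthy"] > 0]
        assert (g.loc[up, "interaction"] < 0).mean() > 0.8
        # the per-week style nesting: group/treatment tables only contain
        # omnibus-significant genes
        omni_sig = set(res["omnibus"].loc[res["omnibus"]["adj_p"] < 0.05, "gene_id"])
        assert set(res["group"]["gene_id"]) <= omni_sig
        assert set(res["treatment"]["gene_id"]) <= omni_sig


class TestBlockPc:
    def test_noiseless_block_explains_everything(self, rng):
        f = rng.normal(size=30)
        block = pd.DataFrame(np.outer(f, rng.uniform(0.5, 2, 8)),
                             index=[f"p{i}" for i in range(30)])
        scores, ve, loadings = block_pc_summary(block)
        assert ve == pytest.approx(1.0, abs=1e-10)

    def test_target_share_realized_at_cohort_size(self, rng):
        shares = []
        for seed in range(10):
            d = simulate.dmdmex_design(n_genes=60, modules=None,
                                       treatment=simulate.TreatmentSpec(n_side_effect=0),
                                       n_de=10, seed=200 + seed)
            _, _, blocks, _ = simulate.simulate_cohort(d)
            _, ve, _ = block_pc_summary(blocks["body"])
            shares.append(ve)
        assert np.mean(shares) * 100 == pytest.approx(70.0, abs=5.0)

    def test_anchor_negation_flips_scores_and_loadings(self, rng):
        vals = rng.normal(size=(25, 6)) + rng.normal(size=(25, 1))
        block = pd.DataFrame(vals, columns=[f"v{i}" for i in range(6)])
        s1, _, l1 = block_pc_summary(block, anchor="v0")
        flipped = block.copy()
        flipped["v0"] = -flipped["v0"]
        s2, _, l2 = block_pc_summary(flipped, anchor="v0")
        assert np.allclose(s1, -s2, atol=1e-8)
        assert l1["v0"] > 0 and l2["v0"] > 0

    def test_missing_subjects_excluded(self, rng):
        block = pd.DataFrame(rng.normal(size=(10, 4)))
        block.iloc[3, 2] = np.nan
        scores, _, _ = block_pc_summary(block)
        assert 3 not in scores.index


class TestPcAssociation:
    def test_constant_scores_rejected(self, rng):
        d = simulate.dmdmex_design(n_genes=60, n_de=0, modules=None, seed=1,
                                   treatment=simulate.TreatmentSpec(n_side_effect=0))
        cm, st_meta, blocks, truth = simulate.simulate_cohort(d)
        scores = pd.Series(1.0, index=blocks["body"].index)
        with pytest.raises(ValueError, match="constant"):
            pc_association(cm, scores)

    def test_anchor_gene_ranks_near_top(self):
        # the planted physical-factor gene should be among the strongest
        # associations even when it misses formal FDR significance
        ranks = []
        for seed in range(5):
            d = simulate.dmdmex_design(n_genes=400, modules=None, seed=300 + seed)
            cm, st_meta, blocks, truth = simulate.simulate_cohort(d)
            scores, _, _ = block_pc_summary(blocks["physical"])
            tab = pc_association(cm, scores).set_index("gene_id")
            p_anchor = tab.loc[truth.anchor_gene, "p"]
            ranks.append(int((tab["p"] < p_anchor).sum()))
        assert np.median(ranks) <= 0.02 * 400
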