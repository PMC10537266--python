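"""Design resolution, the REML mixed model, moderation, BH and classification."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

import drosvir as dv
from drosvir import de as dd
from drosvir.simulate import COEF_SEX, interaction_coef, virus_coef


def _meta(projects, genotypes, tissues, sexes):
    n = len(projects)
    return pd.DataFrame(
        {"project": projects, "genotype": genotypes, "tissue": tissues, "sex": sexes},
        index=[f"l{i}" for i in range(n)],
    )


class TestBuildDesign:
    def test_full_model_with_both_sexes_and_two_datasets(self):
        meta = _meta(["P1"] * 4 + ["P2"] * 4, ["g1"] * 8, ["whole"] * 8,
                     ["male", "female"] * 4)
        calls = pd.DataFrame({"v": [True, True, False, False] * 2}, index=meta.index)
        spec = dv.build_design(meta, calls, "v")
        assert spec.fixed_terms == ["sex", "virus", "sex:virus"]
        assert list(spec.design.columns) == [
            "Intercept", COEF_SEX, virus_coef("v"), interaction_coef("v")
        ]
        assert spec.random_group == "project"
        assert spec.groups.nunique() == 2

    def test_single_sex_infections_drop_sex_terms(self):
        meta = _meta(["P1"] * 8, ["g1"] * 8, ["whole"] * 8, ["male", "female"] * 4)
        calls = pd.DataFrame({"v": [True, False] * 4}, index=meta.index)  # males only
        spec = dv.build_design(meta, calls, "v")
        assert spec.fixed_terms == ["virus"]
        assert list(spec.design.columns) == ["Intercept", virus_coef("v")]

    def test_single_stratum_drops_random_effect(self):
        meta = _meta(["P1"] * 6, ["g1"] * 6, ["whole"] * 6, ["female"] * 6)
        calls = pd.DataFrame({"v": [True] * 3 + [False] * 3}, index=meta.index)
        spec = dv.build_design(meta, calls, "v")
        assert spec.random_group is None and spec.groups is None

    def test_libraries_restricted_to_projects_with_the_virus(self):
        meta = _meta(["P1"] * 4 + ["P2"] * 4, ["g1"] * 4 + ["g2"] * 4,
                     ["whole"] * 8, ["female"] * 8)
        calls = pd.DataFrame({"v": [True, True, False, False] + [False] * 4},
                             index=meta.index)
        spec = dv.build_design(meta, calls, "v")
        assert spec.libraries == [f"l{i}" for i in range(4)]

    def test_never_called_virus_raises(self):
        meta = _meta(["P1"] * 2, ["g"] * 2, ["t"] * 2, ["female"] * 2)
        calls = pd.DataFrame({"v": [False, False]}, index=meta.index)
        with pytest.raises(ValueError):
            dv.build_design(meta, calls, "v")


class TestNormalizeAndFilter:
    def test_zero_count_value(self):
        counts = pd.DataFrame({"lib": [0, 10 ** 6 - 0]}, index=["g0", "g1"])
        counts.loc["g1"] = 10 ** 6
        out = dv.normalize_logcpm(counts)
        expected = np.log2(0.5 / (10 ** 6 + 1) * 1e6)
        assert out.at["g0", "lib"] == pytest.approx(expected, abs=1e-9)
        assert out.at["g0", "lib"] == pytest.approx(-1.0, abs=2e-5)

    def test_proportional_libraries_have_identical_logcpm(self):
        counts = pd.DataFrame({"a": [10, 20, 70], "b": [100, 200, 700]})
        out = dv.normalize_logcpm(counts, prior_count=0.0)
        assert np.allclose(out["a"], out["b"])

    def test_round_trip_recovers_scaled_counts(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, (50, 8)))
        out = dv.normalize_logcpm(counts, prior_count=0.5)
        sizes = counts.sum(axis=0)
        back = np.exp2(out)
        want = (counts + 0.5).div(sizes + 1.0, axis=1) * 1e6
        assert np.allclose(back, want)

    def test_zero_size_library_dropped_with_warning(self):
        counts = pd.DataFrame({"ok": [5, 5], "empty": [0, 0]})
        with pytest.warns(UserWarning, match="empty"):
            out = dv.normalize_logcpm(counts)
        assert list(out.columns) == ["ok"]

    def test_filter_matches_brute_force(self, rng):
        counts = pd.DataFrame(rng.integers(0, 50, (100, 20)))
        kept = dv.filter_genes(counts, min_cpm=1.0, min_fraction=0.05)
        sizes = counts.sum(axis=0)
        brute = []
        for g in counts.index:
            cpm = counts.loc[g] / sizes * 1e6
            if (cpm > 1.0).mean() >= 0.05:
                brute.append(g)
        assert list(kept) == brute

    def test_all_zero_gene_removed_and_ubiquitous_gene_kept(self):
        counts = pd.DataFrame({"a": [0, 50, 1000], "b": [0, 60, 1000]},
                              index=["zero", "mid", "high"])
        kept = dv.filter_genes(counts)
        assert "zero" not in kept and "mid" in kept and "high" in kept


class TestFitGeneModel:
    def test_constant_expression_gives_zero_effects(self):
        X = pd.DataFrame({"Intercept": 1.0, "x": [0, 0, 1, 1, 0, 1]})
        res = dv.fit_gene_model(np.full(6, 3.7), X)
        assert res.loc[1, "logFC"] == pytest.approx(0.0, abs=1e-10)

    def test_ols_equals_classical_two_sample_t(self, rng):
        y = rng.normal(size=40)
        y[20:] += 0.6
        X = pd.DataFrame({"Intercept": 1.0, "g": np.r_[np.zeros(20), np.ones(20)]})
        res = dv.fit_gene_model(y, X)
        t, p = stats.ttest_ind(y[20:], y[:20], equal_var=True)
        assert res.loc[1, "logFC"] == pytest.approx(y[20:].mean() - y[:20].mean())
        assert res.loc[1, "stat"] == pytest.approx(t)
        assert res.loc[1, "p"] == pytest.approx(p)
        assert res.loc[1, "df"] == 38.0

    def test_reml_matches_statsmodels_mixedlm(self, rng):
        for _ in range(5):
            groups = np.repeat(np.arange(8), 6)
            X = pd.DataFrame({"Intercept": 1.0,
                              "x": (rng.random(48) > 0.5).astype(float)})
            y = (0.4 * X["x"].to_numpy() + rng.normal(0, 0.6, 8)[groups]
                 + rng.normal(0, 0.5, 48))
            mine = dv.fit_gene_model(y, X, pd.Series(groups))
            ref = MixedLM(y, X.to_numpy(), groups).fit(reml=True)
            assert np.allclose(mine["logFC"], ref.fe_params, atol=1e-4)
            assert np.allclose(mine["se"], np.asarray(ref.bse_fe), rtol=2e-2)

    def test_satterthwaite_matches_lmertest(self, tmp_path):
        """Estimates, SEs, dfs and p-values agree with the R reference."""
        rng = np.random.default_rng(42)
        groups = np.repeat(np.arange(10), 6)
        X = pd.DataFrame({"Intercept": 1.0,
                          "x": (rng.random(60) > 0.5).astype(float)})
        y = (1.0 + 0.5 * X["x"].to_numpy() + rng.normal(0, 0.7, 10)[groups]
             + rng.normal(0, 0.5, 60))
        mine = dv.fit_gene_model(y, X, pd.Series(groups))
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        csv = tmp_path / "mm.csv"
        pd.DataFrame({"y": y, "x": X["x"], "g": groups}).to_csv(csv, index=False)
        script = (
            "suppressMessages(library(lmerTest));"
            f"d<-read.csv('{csv}');"
            "m<-lmer(y~x+(1|g),data=d);s<-coef(summary(m));"
            "cat(s[,'Estimate'],s[,'Std. Error'],s[,'df'],s[,'Pr(>|t|)'],sep='\\n')"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        vals = [float(v) for v in out.stdout.strip().splitlines()]
        est, se, df, p = vals[0:2], vals[2:4], vals[4:6], vals[6:8]
        assert np.allclose(mine["logFC"], est, atol=1e-5)
        assert np.allclose(mine["se"], se, rtol=1e-3)
        assert np.allclose(mine["df"], df, rtol=2e-2)
        assert np.allclose(mine["p"], p, rtol=2e-2)

    def test_rank_deficient_design_raises(self):
        X = pd.DataFrame({"Intercept": 1.0, "a": [0, 1, 0, 1], "b": [0, 1, 0, 1]})
        with pytest.raises(ValueError, match="rank"):
            dv.fit_gene_model(np.arange(4.0), X)

    def test_planted_effect_recovered_with_grouping(self, rng):
        groups = np.repeat(np.arange(20), 6)
        n = 120
        X = pd.DataFrame({"Intercept": 1.0,
                          "x": (rng.random(n) > 0.5).astype(float)})
        ests = []
        for _ in range(60):
            y = (1.0 * X["x"].to_numpy() + rng.normal(0, 0.5, 20)[groups]
                 + rng.normal(0, 0.6, n))
            ests.append(dv.fit_gene_model(y, X, pd.Series(groups)).loc[1, "logFC"])
        assert abs(np.mean(ests) - 1.0) < 0.1


class TestModerateVariances:
    def test_equal_variances_collapse_to_common_value(self):
        s2 = np.full(50, 0.8)
        post, d0, s0 = dv.moderate_variances(s2, 10.0)
        assert np.allclose(post, 0.8)

    def test_posterior_lies_between_raw_and_prior(self, rng):
        s2 = np.exp(rng.normal(0, 1, 500))
        post, d0, s0 = dv.moderate_variances(s2, 15.0)
        assert d0 > 0
        lo, hi = np.minimum(s2, s0), np.maximum(s2, s0)
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)

    def test_hyperparameters_recovered_from_simulated_variances(self, rng):
        d0_true, s0_true, d = 8.0, 0.25, 20.0
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, 5000)
        s2 = sigma2 * rng.chisquare(d, 5000) / d
        post, d0, s0 = dv.moderate_variances(s2, d)
        assert d0 == pytest.approx(d0_true, rel=0.2)
        assert s0 == pytest.approx(s0_true, rel=0.2)

    def test_too_few_genes_raise(self):
        with pytest.raises(ValueError):
            dv.moderate_variances(np.ones(5), 10.0)


class TestAdjustBH:
    def test_step_up_hand_example(self):
        assert np.allclose(dv.adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_identical_and_singleton_inputs(self):
        assert np.allclose(dv.adjust_bh([0.2, 0.2, 0.2, 0.2]), 0.2)
        assert dv.adjust_bh([0.007])[0] == pytest.approx(0.007)

    def test_matches_statsmodels_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 200))
            want = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(dv.adjust_bh(p), want)

    def test_permutation_equivariance(self, rng):
        p = rng.random(100)
        perm = rng.permutation(100)
        assert np.allclose(dv.adjust_bh(p)[perm], dv.adjust_bh(p[perm]))

    def test_invalid_pvalues_raise(self):
        with pytest.raises(ValueError):
            dv.adjust_bh([0.5, 1.2])


class TestClassifyDE:
    @pytest.mark.parametrize(
        "logfc,p_adj,expected",
        [
            (0.6, 0.0005, "up"),
            (0.6, 0.01, "ns"),
            (-2.0, 1e-6, "down"),
            (0.4, 1e-6, "ns"),
            (0.5, 1e-6, "ns"),  # strict inequality at the cutoff
        ],
    )
    def test_cutoff_rules(self, logfc, p_adj, expected):
        df = pd.DataFrame({"logFC": [logfc], "p_adj": [p_adj]})
        assert dv.classify_de(df).iloc[0] == expected


class TestVirusDEModel:
    def test_null_calibration_without_planted_effects(self):
        cfg = dv.SimConfig(
            n_projects=1, libraries_per_project=100, n_genes=1000,
            viruses={"v": 0.4}, virus_affected_fraction=0.0,
            sex_affected_fraction=0.0, interaction_affected_fraction=0.0,
            sexes=("male",), genotypes_per_project=5, seed=31,
        )
        meta, vc, gc, _ = dv.simulate_experiment(cfg)
        calls = dv.call_infections(vc, projects=meta["project"]).present
        res = dv.VirusDEModel(gc, meta, calls, "v").fit(moderate=False)
        pv = res.coef_table(virus_coef("v"))["p"]
        frac = (pv < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(pv))
        assert abs(frac - 0.05) < 3 * se

    def test_mixed_sex_coefficients_are_unbiased(self):
        cfg = dv.SimConfig(
            n_projects=2, libraries_per_project=100, n_genes=600,
            viruses={"v": 0.4}, virus_lfc=1.0, interaction_lfc=1.0,
            sex_lfc=1.0, group_sd=0.5, genotypes_per_project=5, seed=13,
        )
        meta, vc, gc, truth = dv.simulate_experiment(cfg)
        calls = dv.call_infections(vc, projects=meta["project"]).present
        res = dv.VirusDEModel(gc, meta, calls, "v").fit(moderate=False)
        for coef in (COEF_SEX, virus_coef("v"), interaction_coef("v")):
            est = res.coef_table(coef)["logFC"]
            true = truth.true_logfc[coef].reindex(est.index).fillna(0.0)
            aff = true != 0
            assert aff.sum() > 10
            bias = (est[aff] - true[aff]).mean()
            assert abs(bias) < 0.1, coef

    def test_moderation_shrinks_se_spread_and_summary_prints(self, small_de_results):
        res = small_de_results["nora_virus"]
        assert res.moderation is not None and res.moderation["d0"] > 0
        text = res.summary()
        assert "nora_virus" in text and "random intercept" in text
        cc = res.class_counts()
        non_intercept = [c for c in res.coefficients() if c != "Intercept"]
        assert set(cc["coefficient"]) == set(non_intercept)
        total = res.table["gene"].nunique() * len(non_intercept)
        assert int(cc[["up", "down", "ns"]].to_numpy().sum()) == total

    def test_classification_consistent_with_rules(self, small_de_results):
        table = small_de_results["DAV"].table
        want = dv.classify_de(table)
        assert (table["de_class"] == want).all()
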