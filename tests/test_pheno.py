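"""Genetic-value estimation: closed-form oracles, Cullis H2, subsetting."""

import numpy as np
import pandas as pd
import pytest

from gsfoundry import pheno, simulate
from conftest import anova_oneway, make_oneway_trial


class TestOneWayClosedForms:
    """Balanced one-way designs have textbook ANOVA/BLUP solutions."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reml_matches_anova_estimators(self, seed):
        trial = make_oneway_trial(n_lines=8, n_reps=4, seed=seed)
        fit = pheno.fit_random_genotype(trial, "YLD")
        vg, ve = anova_oneway(trial)
        assert fit.varcomp.var_G == pytest.approx(vg, abs=1e-6)
        assert fit.varcomp.var_eps == pytest.approx(ve, abs=1e-6)

    def test_blup_is_shrunken_line_mean_deviation(self):
        trial = make_oneway_trial(n_lines=10, n_reps=5, seed=3)
        fit = pheno.fit_random_genotype(trial, "YLD")
        vg, ve = fit.varcomp.var_G, fit.varcomp.var_eps
        n = 5
        shrink = n * vg / (n * vg + ve)
        means = trial.groupby("line_id")["value"].mean()
        expected = shrink * (means - means.mean())
        np.testing.assert_allclose(
            fit.blups.reindex(expected.index), expected, atol=1e-6)

    def test_emm_equals_line_mean_on_balanced_data(self):
        trial = make_oneway_trial(n_lines=6, n_reps=3, seed=4)
        ffit = pheno.fit_fixed_genotype(trial, "YLD")
        means = trial.groupby("line_id")["value"].mean()
        np.testing.assert_allclose(
            ffit.emms.reindex(means.index), means, atol=1e-8)

    def test_emm_blup_perfectly_correlated_when_balanced(self):
        trial = make_oneway_trial(n_lines=8, n_reps=4, seed=5)
        emm = pheno.fit_fixed_genotype(trial, "YLD").emms
        blup = pheno.fit_random_genotype(trial, "YLD").blups
        r = np.corrcoef(emm.sort_index(), blup.sort_index())[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)


class TestMultiEnvironment:
    def test_emm_matches_direct_gls_on_unbalanced_toy(self):
        # 3 lines x 2 envs, unbalanced: EMMs must equal a hand-built GLS
        # solve at the same variance components.
        rows = []
        data = [("A", "E1", 5.0), ("A", "E1", 5.6), ("A", "E2", 7.1),
                ("B", "E1", 4.1), ("B", "E2", 6.4), ("B", "E2", 6.0),
                ("C", "E1", 5.5), ("C", "E2", 8.0)]
        for i, (l, e, v) in enumerate(data):
            rows.append({"line_id": l, "location": e, "year": "Y",
                         "rep": i, "trait": "YLD", "value": v})
        trial = pd.DataFrame(rows)
        ffit = pheno.fit_fixed_genotype(trial, "YLD")

        d = trial.copy()
        lines = sorted(d["line_id"].unique())
        X = np.array([[l == li for li in lines] for l in d["line_id"]],
                     dtype=float)
        factors = {
            "E": d["location"],
            "R": d["location"] + ":" + d["rep"].astype(str),
            "GE": d["line_id"] + ":" + d["location"],
        }
        vc = ffit.varcomp
        V = vc["residual"] * np.eye(len(d))
        for name, lab in factors.items():
            if name in vc:
                Z = pd.get_dummies(lab).to_numpy(dtype=float)
                V += vc[name] * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ d["value"].to_numpy())
        np.testing.assert_allclose(
            ffit.emms.reindex(lines), beta, atol=1e-8)

    def test_emm_shift_equivariance(self, small_trial):
        base = pheno.fit_fixed_genotype(small_trial, "YLD").emms
        shifted = small_trial.copy()
        shifted["value"] += 250.0
        new = pheno.fit_fixed_genotype(shifted, "YLD").emms
        np.testing.assert_allclose(new - base, 250.0, atol=1e-6)

    def test_null_genetic_variance_detected(self):
        # all lines share one genetic value: var_G collapses toward zero
        # (averaged over seeds; a single REML fit has half-normal noise at
        # the boundary) and BLUPs shrink toward 0
        ratios, blup_max = [], []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            rows = [{"line_id": f"L{i}", "location": f"X{e}", "year": "Y",
                     "rep": 1, "trait": "YLD",
                     "value": 10 + rng.normal(0, 1)}
                    for i in range(80) for e in range(30)]
            fit = pheno.fit_random_genotype(pd.DataFrame(rows), "YLD")
            ratios.append(fit.varcomp.var_G / fit.varcomp.var_eps)
            blup_max.append(np.abs(fit.blups).max())
        assert np.mean(ratios) < 0.01
        assert np.mean(blup_max) < 0.15

    def test_single_observation_line_flagged(self):
        trial = make_oneway_trial(n_lines=5, n_reps=3, seed=9)
        extra = pd.DataFrame([{"line_id": "LONE", "location": "X",
                               "year": "2020", "rep": 9, "trait": "YLD",
                               "value": 11.0}])
        ffit = pheno.fit_fixed_genotype(
            pd.concat([trial, extra], ignore_index=True), "YLD")
        flags = ffit.values.set_index("line_id")["large_se_flag"]
        assert flags["LONE"]
        assert not flags.drop("LONE").any()

    def test_unbalanced_emm_blup_strongly_correlated(self, small_trial):
        emm = pheno.fit_fixed_genotype(small_trial, "YLD").emms
        blup = pheno.fit_random_genotype(small_trial, "YLD").blups
        common = emm.index.intersection(blup.index)
        r = np.corrcoef(emm.reindex(common), blup.reindex(common))[0, 1]
        assert r > 0.9


class TestCullisH2:
    def test_noiseless_limit_gives_h2_near_one(self):
        trial = make_oneway_trial(n_lines=12, n_reps=4, var_G=4.0,
                                  var_e=1e-6, seed=11)
        fit = pheno.fit_random_genotype(trial, "YLD")
        assert pheno.cullis_h2(fit) > 0.999

    def test_balanced_oneway_matches_line_mean_formula(self):
        trial = make_oneway_trial(n_lines=40, n_reps=4, var_G=4.0,
                                  var_e=2.0, seed=12)
        fit = pheno.fit_random_genotype(trial, "YLD")
        vg, ve = fit.varcomp.var_G, fit.varcomp.var_eps
        expected = vg / (vg + ve / 4)
        assert pheno.cullis_h2(fit) == pytest.approx(expected, abs=0.01)

    def test_degenerate_var_g_returns_zero(self):
        rng = np.random.default_rng(1)
        rows = [{"line_id": f"L{i}", "location": "X", "year": "Y",
                 "rep": k, "trait": "YLD", "value": rng.normal()}
                for i in range(10) for k in range(3)]
        trial = pd.DataFrame(rows)
        for r in trial.index:     # identical line values -> var_G ~ 0
            trial.loc[r, "value"] = rng.normal()
        fit = pheno.fit_random_genotype(trial, "YLD")
        if fit.varcomp.var_G <= 1e-8:
            with pytest.warns(UserWarning):
                assert pheno.cullis_h2(fit) == 0.0


class TestSubsetTrials:
    def test_full_group_is_identity(self, small_trial):
        envs = (small_trial["location"].astype(str) + "_"
                + small_trial["year"].astype(str)).unique()
        out = pheno.subset_trials(small_trial, list(envs))
        assert len(out) == len(small_trial)

    def test_small_group_rejected(self, small_trial):
        env = (small_trial["location"].astype(str) + "_"
               + small_trial["year"].astype(str)).iloc[0]
        with pytest.raises(ValueError, match="minimum"):
            pheno.subset_trials(small_trial, [env], min_obs=10**9)

    def test_disjoint_groups_partition_records(self, small_trial):
        locs = sorted(small_trial["location"].unique())
        total = sum(
            len(pheno.subset_trials(small_trial, [l], min_obs=1))
            for l in locs
        )
        assert total == len(small_trial)

    def test_unknown_group_errors(self, small_trial):
        with pytest.raises(ValueError, match="no records"):
            pheno.subset_trials(small_trial, ["NOWHERE_1999"])


class TestAgainstLme4:
    def test_variance_components_match_lme4(self, tmp_path):
        """Independent oracle: R lme4 REML fit on an unbalanced crossed design."""
        import shutil
        import subprocess

        rscript = shutil.which("Rscript")
        if rscript is None:
            pytest.skip("Rscript not available")

        cfg = simulate.SimulationConfig(
            n_lines=25, n_markers=20, n_qtl=10, n_locations=3, n_years=1,
            reps_range=(2, 2), presence_fraction=0.8,
            var_G=4.0, var_E=2.0, var_R=0.5, var_GE=1.0, var_eps=1.5,
            mu=20.0, seed=2,
        )
        _, truth = simulate.simulate_genotypes(cfg)
        trial = simulate.simulate_trial(cfg, truth)
        fit = pheno.fit_random_genotype(trial, "YLD")

        csv = tmp_path / "trial.csv"
        trial.to_csv(csv, index=False)
        r_code = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        d$ge <- factor(paste(d$line_id, d$env))
        d$repf <- factor(paste(d$env, d$rep))
        m <- lmer(value ~ (1|line_id) + (1|env) + (1|repf) + (1|ge),
                  data=d, REML=TRUE,
                  control=lmerControl(check.conv.singular="ignore"))
        vc <- as.data.frame(VarCorr(m))
        out <- vc[, c("grp", "vcov")]
        write.csv(out, "{tmp_path / 'vc.csv'}", row.names=FALSE)
        cat(logLik(m), "\\n")
        """
        res = subprocess.run([rscript, "-e", r_code], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        vc = pd.read_csv(tmp_path / "vc.csv").set_index("grp")["vcov"]
        ours = {"line_id": fit.varcomp.var_G, "env": fit.varcomp.var_E,
                "repf": fit.varcomp.var_R, "ge": fit.varcomp.var_GE,
                "Residual": fit.varcomp.var_eps}
        scale = trial["value"].var()
        for grp, val in ours.items():
            assert vc[grp] == pytest.approx(val, rel=2e-3, abs=2e-3 * scale)
        lme4_ll = float(res.stdout.strip().split()[-1])
        assert fit.varcomp.loglik_restricted == pytest.approx(lme4_ll,
                                                              abs=1e-3)
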