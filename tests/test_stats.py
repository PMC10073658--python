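import subprocess
import textwrap
from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import oracles
from cageclimb.stats import (
    LMMSpec,
    benjamini_hochberg,
    boxcox,
    compare_models,
    emmeans_contrasts,
    fit_lmm,
    significance_stars,
    transition_analysis,
)
from cageclimb.synthetic import ActivityScenario, generate_activity
from cageclimb.ethogram import window_means


class TestBoxCox:
    def test_lambda_one_is_shift(self, rng):
        x = rng.uniform(1, 10, 50)
        y, lam, shift = boxcox(x, 1.0)
        np.testing.assert_allclose(y, x - 1)
        assert shift == 0.0

    def test_lambda_zero_is_log(self, rng):
        x = rng.uniform(1, 10, 50)
        y, _, _ = boxcox(x, 0.0)
        np.testing.assert_allclose(y, np.log(x))

    def test_mle_recovers_log_for_lognormal(self):
        rng = np.random.default_rng(42)
        x = np.exp(rng.normal(0, 1, 500))
        _, lam, _ = boxcox(x, "mle")
        assert abs(lam) < 0.15

    def test_mle_matches_scipy_profile(self, rng):
        from scipy import stats as sps

        x = rng.gamma(2.0, 3.0, 300)
        _, lam, _ = boxcox(x, "mle")
        _, lam_scipy = sps.boxcox(x)
        assert lam == pytest.approx(lam_scipy, abs=1e-3)

    def test_nonpositive_requires_shift(self):
        with pytest.raises(ValueError, match="positive"):
            boxcox(np.array([-1.0, 2.0]), 1.0)
        with pytest.warns(UserWarning, match="shifting"):
            y, lam, shift = boxcox(np.array([-1.0, 2.0]), 1.0, allow_shift=True)
        assert shift > 1.0


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.03]), [0.03])

    def test_hand_stepup_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_stepup_oracle(self, pvals):
        got = benjamini_hochberg(pvals)
        np.testing.assert_allclose(got, oracles.bh_oracle(pvals), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_monotone_bounded_and_dominates_raw(self, pvals):
        p = np.asarray(pvals)
        adj = benjamini_hochberg(p)
        assert (adj <= 1).all() and (adj >= p - 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 40)
        np.testing.assert_allclose(
            benjamini_hochberg(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


def _factorial_data(seed, noise_sd=1.0, n_per_group=3, effects=True):
    """Balanced Age x Genotype x Sex cages, 3 days, no random-effect variance."""
    rng = np.random.default_rng(seed)
    rows, cage = [], 0
    for age, geno, sex in product(["young", "old"], ["WT", "Hemi"], ["F", "M"]):
        for _ in range(n_per_group):
            cid = f"c{cage:02d}"
            cage += 1
            mu = 100.0
            if effects:
                mu += (age == "old") * 20 - (geno == "Hemi") * 30 + (sex == "F") * 15
            for day in (1, 2, 3):
                rows.append((cid, age, geno, sex, day, mu + rng.normal(0, noise_sd)))
    return pd.DataFrame(
        rows,
        columns=["cage_id", "Age", "Genotype", "Sex", "day_of_recording", "mean_activity"],
    )


class TestFitLMM:
    def test_zero_random_variance_matches_ols(self):
        """With no cage-level variance the GLS estimator collapses to OLS."""
        data = _factorial_data(seed=0, noise_sd=1e-6)
        fit = fit_lmm(data, LMMSpec(transform="none"))
        X = np.asarray(fit.result.model.exog)
        y = np.asarray(fit.result.model.endog)
        ols = oracles.ols_fit(X, y)
        np.testing.assert_allclose(fit.params.to_numpy(), ols, atol=1e-6)

    def test_constant_response_degenerate(self):
        data = _factorial_data(seed=0, noise_sd=0.0, effects=False)
        with pytest.raises(ValueError, match="constant"):
            fit_lmm(data, LMMSpec(transform="none"))

    def test_fewer_than_two_cages_rejected(self):
        data = _factorial_data(seed=0)
        with pytest.raises(ValueError, match="2 cages"):
            fit_lmm(data[data["cage_id"] == "c00"], LMMSpec(transform="none"))

    def test_missing_column_rejected(self):
        data = _factorial_data(seed=0).drop(columns=["Sex"])
        with pytest.raises(ValueError, match="missing"):
            fit_lmm(data, LMMSpec(transform="none"))

    def test_singular_fit_reported_and_simplified(self):
        data = _factorial_data(seed=3, noise_sd=1e-6)
        fit = fit_lmm(data, LMMSpec(transform="none"), simplify_on_singular=True)
        assert fit.simplified or not fit.spec.day_slope or fit.singular is not None
        fit2 = fit_lmm(data, LMMSpec(transform="none"), simplify_on_singular=False)
        assert fit2.spec.day_slope  # untouched model structure


class TestCompareModels:
    def test_identical_models_stat_zero(self):
        data = _factorial_data(seed=1)
        spec = LMMSpec(transform="none", interaction="full")
        f1 = fit_lmm(data, spec, reml=False)
        f2 = fit_lmm(data, spec, reml=False)
        tab = compare_models([f1, f2])
        assert tab["chi2"].iloc[0] == pytest.approx(0.0, abs=1e-5)
        assert tab["p_value"].iloc[0] == pytest.approx(1.0)

    def test_reml_fits_rejected(self):
        data = _factorial_data(seed=1)
        f = fit_lmm(data, LMMSpec(transform="none"))
        with pytest.raises(ValueError, match="ML"):
            compare_models([f, f])

    def test_chi2_formula(self):
        """The statistic must equal 2 * delta loglik with df = delta params."""
        data = _factorial_data(seed=2)
        small = fit_lmm(
            data, LMMSpec(transform="none", factors=("Genotype",)), reml=False,
            simplify_on_singular=False,
        )
        big = fit_lmm(
            data, LMMSpec(transform="none", factors=("Genotype", "Sex")), reml=False,
            simplify_on_singular=False,
        )
        tab = compare_models([small, big])
        assert tab["chi2"].iloc[0] == pytest.approx(
            2 * (big.loglike - small.loglike), abs=1e-8
        )
        assert tab["df"].iloc[0] == 2  # Sex main effect + interaction

    def test_null_factor_p_roughly_uniform(self):
        """Adding a pure-noise factor yields approximately uniform LRT p-values."""
        ps = []
        for seed in range(20):
            data = _factorial_data(seed=100 + seed, noise_sd=5.0, effects=False)
            small = fit_lmm(
                data, LMMSpec(transform="none", factors=("Genotype",)), reml=False,
                simplify_on_singular=False,
            )
            big = fit_lmm(
                data, LMMSpec(transform="none", factors=("Genotype", "Sex")),
                reml=False, simplify_on_singular=False,
            )
            ps.append(compare_models([small, big])["p_value"].iloc[0])
        ps = np.array(ps)
        assert np.isfinite(ps).all()
        assert np.mean(ps < 0.05) <= 0.25  # ~1 expected under the null
        assert 0.2 < ps.mean() < 0.8


class TestEmmeans:
    def test_balanced_one_factor_equals_group_means(self):
        data = _factorial_data(seed=4, noise_sd=1e-6)
        fit = fit_lmm(data, LMMSpec(transform="none"))
        (c,) = emmeans_contrasts(fit, ["Genotype"], adjust="none", df_method="residual")
        raw_diff = (
            data[data["Genotype"] == "Hemi"]["mean_activity"].mean()
            - data[data["Genotype"] == "WT"]["mean_activity"].mean()
        )
        assert c.estimate == pytest.approx(raw_diff, abs=1e-6)

    def test_identical_groups_zero_contrast(self):
        data = _factorial_data(seed=5, noise_sd=1e-6, effects=False)
        data["mean_activity"] += np.tile([1.0, 2.0, 3.0], len(data) // 3)  # day effect only
        fit = fit_lmm(data, LMMSpec(transform="none"))
        (c,) = emmeans_contrasts(fit, ["Genotype"], adjust="none", df_method="residual")
        assert c.estimate == pytest.approx(0.0, abs=1e-6)

    def test_adjusted_p_dominates_raw(self):
        data = _factorial_data(seed=6, noise_sd=3.0)
        fit = fit_lmm(data, LMMSpec(transform="none"))
        contrasts = emmeans_contrasts(fit, ["Genotype", "Sex"], adjust="bh")
        for c in contrasts:
            if c.estimable:
                assert c.p_adjusted >= c.p_value - 1e-15

    def test_unknown_factor_rejected(self):
        data = _factorial_data(seed=6)
        fit = fit_lmm(data, LMMSpec(transform="none"))
        with pytest.raises(ValueError, match="not in the model"):
            emmeans_contrasts(fit, ["Diet"])

    def test_matches_r_lmertest_emmeans(self, tmp_path):
        """Independent cross-check of estimate, SE, Satterthwaite df and p
        against R's lmer/emmeans on a non-singular dataset."""
        binned = generate_activity(
            ActivityScenario(seed=11, cage_intercept_sd=120, day_slope_sd=60,
                             noise_sd=40)
        )
        wm = window_means(binned, "end_of_dark", value="distance_mm")
        data = wm.merge(
            binned[["cage_id", "Age", "Genotype", "Sex"]].drop_duplicates("cage_id"),
            on="cage_id",
        )
        fit = fit_lmm(data, LMMSpec(transform="none"), simplify_on_singular=False)
        if fit.singular:
            pytest.skip("random-effects fit singular for this draw; oracle undefined")
        (c,) = emmeans_contrasts(fit, ["Genotype"], adjust="none")
        csv = tmp_path / "wm.csv"
        data.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages({{library(lmerTest); library(emmeans)}})
            d <- read.csv("{csv}")
            m <- lmer(mean_activity ~ Age*Genotype*Sex + (1 + day_of_recording | cage_id), data=d)
            s <- summary(pairs(emmeans(m, ~ Genotype, lmer.df="satterthwaite")), adjust="none")
            cat(s$estimate, s$SE, s$df, as.numeric(logLik(m)), sep="\\n")
            """
        )
        rfile = tmp_path / "oracle.R"
        rfile.write_text(script)
        try:
            out = subprocess.run(
                ["Rscript", str(rfile)], capture_output=True, text=True, timeout=300
            )
        except FileNotFoundError:
            pytest.skip("Rscript not available")
        assert out.returncode == 0, out.stderr
        est, se, df, llf = map(float, out.stdout.strip().splitlines()[-4:])
        assert fit.loglike == pytest.approx(llf, abs=1e-2)
        assert c.estimate == pytest.approx(est, rel=1e-3)
        assert c.se == pytest.approx(se, rel=0.02)
        assert c.df == pytest.approx(df, rel=0.05)


class TestSignificanceStars:
    @pytest.mark.parametrize(
        "p,stars",
        [(0.5, "ns"), (0.049, "*"), (0.009, "**"), (0.0009, "***"), (0.00009, "****")],
    )
    def test_convention(self, p, stars):
        assert significance_stars(p) == stars


class TestTransitionAnalysis:
    def test_deficit_detected_in_dark_window_only(self):
        binned = generate_activity(ActivityScenario(seed=2))
        tab = transition_analysis(binned, value="distance_mm")
        dark = tab[tab["window"] == "end_of_dark"].iloc[0]
        light = tab[tab["window"] == "end_of_light"].iloc[0]
        assert dark["p_adjusted"] < 0.05
        assert light["p_adjusted"] > 0.05
        assert dark["estimate"] < 0  # Hemi below WT

    def test_null_fdr_control(self):
        """Under no genotype effect the BH-adjusted genotype contrasts are
        significant at most at about the FDR level."""
        n_rep = 200
        hits = total = 0
        for rep in range(n_rep):
            scenario = ActivityScenario(
                seed=50_000 + rep,
                genotype_deficit=1.0,
                ages=("young",),
                sexes=("F",),
                n_cages_per_group=4,
            )
            binned = generate_activity(scenario)
            tab = transition_analysis(
                binned, value="distance_mm", factors=("Genotype",), transform="none",
                df_method="residual",
            )
            hits += int((tab["p_adjusted"] < 0.05).sum())
            total += len(tab)
        rate = hits / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + 2 * se
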