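"""AICc machinery, GLMM fitting, candidate suites, bootstrap and VIF."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import phenosync as ps
from phenosync.model_comparison import MixedGLM, comparison_table

pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")


class TestAicc:
    def test_closed_form(self):
        assert ps.aicc(-50.0, 2, 100) == pytest.approx(104 + 12 / 97)

    def test_large_n_limit_is_plain_aic(self):
        assert ps.aicc(-50.0, 3, 10**9) == pytest.approx(106.0, abs=1e-6)

    def test_zero_parameters(self):
        assert ps.aicc(-50.0, 0, 100) == pytest.approx(100.0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            ps.aicc(-50.0, 5, 6)


class TestVif:
    def test_orthogonal_columns_are_one(self):
        rng = np.random.default_rng(0)
        # columns orthogonal to each other and to the constant
        Q = np.linalg.qr(np.column_stack([np.ones(200), rng.standard_normal((200, 3))]))[0]
        assert np.allclose(ps.vif(pd.DataFrame(Q[:, 1:])), 1.0, atol=1e-10)

    def test_known_correlation_closed_form(self):
        # two columns with exact sample correlation 0.9 -> VIF = 1/(1-0.81)
        n = 500
        rng = np.random.default_rng(1)
        x = rng.standard_normal(n)
        e = rng.standard_normal(n)
        e -= e.mean() + (x - x.mean()) @ (e - e.mean()) / ((x - x.mean()) @ (x - x.mean())) * (x - x.mean())
        y = 0.9 * (x - x.mean()) / x.std() + np.sqrt(1 - 0.81) * (e - e.mean()) / e.std()
        v = ps.vif(pd.DataFrame({"x": (x - x.mean()) / x.std(), "y": y}))
        assert v["x"] == pytest.approx(1 / (1 - 0.81), rel=1e-9)

    def test_duplicated_column_infinite(self):
        x = np.arange(50.0)
        v = ps.vif(pd.DataFrame({"a": x, "b": x, "c": np.sin(x)}))
        assert np.isinf(v["a"]) and np.isinf(v["b"])


class TestMixedGLM:
    def _sim(self, family, n=600, seed=3, sd_g=0.0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        g = rng.integers(0, 15, n)
        eta = -0.3 + 0.5 * x + (rng.normal(0, sd_g, 15)[g] if sd_g else 0.0)
        if family == "binomial":
            y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        else:
            y = rng.poisson(np.exp(eta)).astype(float)
        X = np.column_stack([np.ones(n), x])
        return y, X, g

    @pytest.mark.parametrize("family", ["binomial", "poisson"])
    def test_glm_matches_statsmodels(self, family):
        import statsmodels.api as sm

        y, X, _ = self._sim(family)
        mine = MixedGLM(y, X, family).fit()
        ref = sm.GLM(y, X, family=sm.families.Binomial() if family == "binomial"
                     else sm.families.Poisson()).fit()
        np.testing.assert_allclose(mine.params, ref.params, atol=1e-6)
        assert mine.loglik == pytest.approx(ref.llf, abs=1e-6)

    @pytest.mark.parametrize("family", ["binomial", "poisson"])
    def test_laplace_exact_at_zero_variance(self, family):
        # with every component at zero the Laplace objective IS the GLM:
        # identical log-likelihood and fixed coefficients
        y, X, g = self._sim(family, sd_g=0.0)
        plain = MixedGLM(y, X, family).fit()
        mixed = MixedGLM(y, X, family, groups=[("g", g)])
        ll, beta = mixed._laplace_loglik(np.zeros(1))
        assert ll == pytest.approx(plain.loglik, abs=1e-8)
        np.testing.assert_allclose(beta, plain.params, atol=1e-6)

    @pytest.mark.parametrize("family", ["binomial", "poisson"])
    def test_zero_variance_truth_estimated_fit_near_glm(self, family):
        # data generated with no group effect: the estimated mixed fit may
        # keep a small spurious variance (a legitimate finite-sample ML
        # estimate) but the fixed coefficients stay close to the plain GLM
        y, X, g = self._sim(family, sd_g=0.0)
        plain = MixedGLM(y, X, family).fit()
        mixed = MixedGLM(y, X, family, groups=[("g", g)]).fit()
        np.testing.assert_allclose(mixed.params, plain.params, atol=0.02)

    def test_recovers_generating_variance(self):
        y, X, g = self._sim("poisson", n=4000, sd_g=0.6, seed=8)
        res = MixedGLM(y, X, "poisson", groups=[("g", g)]).fit()
        assert 0.3 < res.vc_sd[0] < 0.9
        assert res.k == 3

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_laplace_matches_lme4(self, tmp_path):
        y, X, g = self._sim("poisson", n=400, sd_g=0.5, seed=5)
        mine = MixedGLM(y, X, "poisson", groups=[("g", g)]).fit()
        df = pd.DataFrame({"y": y, "x": X[:, 1], "g": g})
        df.to_csv(tmp_path / "d.csv", index=False)
        script = textwrap.dedent("""
            suppressMessages(library(lme4))
            d <- read.csv(commandArgs(TRUE)[1])
            m <- glmer(y ~ x + (1|g), data=d, family=poisson)
            cat(fixef(m), sqrt(unlist(VarCorr(m))), as.numeric(logLik(m)), sep="\\n")
        """)
        (tmp_path / "fit.R").write_text(script)
        out = subprocess.run(
            ["Rscript", str(tmp_path / "fit.R"), str(tmp_path / "d.csv")],
            capture_output=True, text=True, check=True,
        )
        b0, b1, sd_g_hat, ll = map(float, out.stdout.split())
        assert mine.params[0] == pytest.approx(b0, abs=0.05)
        assert mine.params[1] == pytest.approx(b1, abs=0.02)
        assert mine.vc_sd[0] == pytest.approx(sd_g_hat, abs=0.05)
        assert mine.loglik == pytest.approx(ll, abs=0.1)


class TestComparisonTable:
    def _fits(self, shift=0.0):
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 1] * 12, dtype=float)
        X = np.column_stack([np.ones(len(y))])
        res = MixedGLM(y, X, "binomial", name="a").fit()
        other = MixedGLM(y, np.column_stack([X, np.arange(len(y)) % 2]),
                         "binomial", name="b").fit()
        for r in (res, other):
            r.loglik += shift
        return {"a": res, "b": other}

    def test_delta_invariant_to_loglik_constant(self):
        t0 = comparison_table(self._fits(0.0)).table
        t1 = comparison_table(self._fits(17.3)).table
        pd.testing.assert_series_equal(t0["dAICc"], t1["dAICc"])

    def test_best_row_first_with_zero_delta(self):
        t = comparison_table(self._fits()).table
        assert t["dAICc"].iloc[0] == 0.0
        assert t["dAICc"].is_monotonic_increasing


class TestSuites:
    def test_recruitment_suite_has_four_named_candidates(self, small_study, small_sync):
        _, study = small_study
        comp = ps.fit_recruitment_suite(study.breeding, small_sync.brood_metrics)
        assert set(comp.table["model"]) == {
            "Dens + BCI", "Dens + BCI + MD_b", "Dens + BCI + MD_b + MD_b^2",
            "Dens + BCI + MO_b",
        }
        assert (comp.table["n"] == comp.table["n"].iloc[0]).all()

    def test_quadratic_truth_ranks_quadratic_model_first(self, small_study, small_sync):
        # the session study is generated with beta_md2 < 0 and no MO effect
        _, study = small_study
        comp = ps.fit_recruitment_suite(study.breeding, small_sync.brood_metrics)
        assert comp.table.iloc[0]["model"] == "Dens + BCI + MD_b + MD_b^2"

    def test_selection_suite_has_nine_candidates(self, small_study, small_sync):
        _, study = small_study
        comp = ps.fit_selection_suite(study.breeding, small_sync.year_metrics)
        assert len(comp.table) == 9
        assert "Base + MO_p + MO_p:ELD + MO_p^2" in set(comp.table["model"])

    def test_eld_centred_within_years(self, small_study, small_sync):
        from phenosync.model_comparison import selection_frame

        _, study = small_study
        df = selection_frame(study.breeding, small_sync.year_metrics)
        means = df.groupby("year")["eld"].mean()
        assert np.allclose(means, 0.0, atol=1e-12)

    def test_shape_variants_add_four_rows(self, small_study, small_sync):
        _, study = small_study
        comp = ps.fit_selection_shape_variants(study.breeding, small_sync.year_metrics)
        assert len(comp.table) == 13
        names = set(comp.table["model"])
        assert "Base + MO_p + MO_p:ELD + Skewness" in names
        assert "Base + MD_p + MD_p:ELD + Kurtosis" in names


class TestBootstrap:
    def test_null_effect_ci_covers_zero_and_is_ordered(self):
        rng = np.random.default_rng(21)
        n = 300
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(0.2 + 0.0 * x)).astype(float)
        fit = MixedGLM(y, np.column_stack([np.ones(n), x]), "poisson",
                       param_names=["int", "x"]).fit()
        ci = ps.bootstrap_ci(fit, B=200, seed=4)
        assert (ci["lo95"] < ci["hi95"]).all()
        row = ci.set_index("term").loc["x"]
        assert row["lo95"] < 0 < row["hi95"]

    def test_same_seed_identical(self):
        rng = np.random.default_rng(22)
        n = 200
        y = rng.poisson(1.0, n).astype(float)
        fit = MixedGLM(y, np.ones((n, 1)), "poisson").fit()
        a = ps.bootstrap_ci(fit, B=100, seed=9)
        b = ps.bootstrap_ci(fit, B=100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_tiny_b_rejected(self):
        rng = np.random.default_rng(23)
        y = rng.poisson(1.0, 50).astype(float)
        fit = MixedGLM(y, np.ones((50, 1)), "poisson").fit()
        with pytest.raises(ValueError):
            ps.bootstrap_ci(fit, B=50)
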