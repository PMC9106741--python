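import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from hashladder._glm import fit_nb_glm
from hashladder.de import (
    DEModel,
    DeModelSpec,
    bh_adjust,
    build_design,
    classify_unresponsive_gene,
    dex_responsive_genes,
    fit_gene_glm,
    lrt,
    percent_expressing_bootstrap,
)


@pytest.fixture
def binary_meta(rng):
    n = 200
    return pd.DataFrame(
        {
            "d": np.repeat([0.0, 1.0], n // 2),
            "plate": np.tile(["P1", "P2"], n // 2),
            "pseudotime": rng.uniform(0, 1, n),
        }
    )


class TestBuildDesign:
    def test_binary_only_two_columns(self, binary_meta):
        X, names, red = build_design(binary_meta, DeModelSpec(treatment="d"))
        assert names == ["intercept", "d"]
        assert X.shape[1] == 2
        assert red.tolist() == [True, False]

    def test_spline_rank_four_with_intercept(self, binary_meta):
        X, names, _ = build_design(binary_meta, DeModelSpec(pseudotime="pseudotime"))
        assert X.shape[1] == 4  # intercept + 3 spline columns
        assert np.linalg.matrix_rank(X) == 4

    def test_two_plates_plus_treatment(self, binary_meta):
        X, names, red = build_design(
            binary_meta, DeModelSpec(treatment="d", covariates=["plate"])
        )
        assert len(names) == 3  # intercept, d, plate[P2]
        # reduced design keeps covariates, drops the treatment term
        assert [n for n, m in zip(names, red) if m] == ["intercept", "plate[P2]"]

    def test_constant_treatment_rejected(self, binary_meta):
        meta = binary_meta.assign(d=0.0)
        with pytest.raises(ValueError):
            build_design(meta, DeModelSpec(treatment="d"))

    def test_nonfinite_pseudotime_rejected(self, binary_meta):
        meta = binary_meta.copy()
        meta.loc[0, "pseudotime"] = np.nan
        with pytest.raises(ValueError):
            build_design(meta, DeModelSpec(pseudotime="pseudotime"))


class TestLrt:
    def test_identical_models_statistic_zero(self, rng):
        y = rng.poisson(5, 100).astype(float)
        X = np.ones((100, 1))
        fit = fit_nb_glm(y, X)
        stat, p = lrt(fit, fit, df=1)
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_chi_square_quantile(self):
        class F:
            llf = 1.92

        class R:
            llf = 0.0

        stat, p = lrt(F, R, df=1)
        assert stat == pytest.approx(3.84)
        assert p == pytest.approx(stats.chi2.sf(3.84, 1), abs=1e-12)
        assert p == pytest.approx(0.05, abs=0.001)

    def test_statistic_monotone_in_p(self):
        class R:
            llf = 0.0

        ps = []
        for s in (1.0, 2.0, 4.0):
            class F:
                llf = s / 2

            ps.append(lrt(F, R, 1)[1])
        assert ps[0] > ps[1] > ps[2]


class TestBhAdjust:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_stepup_by_hand(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])


class TestFitGeneGlm:
    def test_offset_rescaling_leaves_slope_coefficients(self, rng):
        n = 150
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2)])
        y = rng.poisson(np.exp(1.0 + 0.5 * X[:, 1]))
        off = np.log(rng.uniform(0.5, 2.0, n))
        a = fit_gene_glm(y, X, offset=off)
        b = fit_gene_glm(y, X, offset=off + np.log(2.0))
        assert b.beta[1] == pytest.approx(a.beta[1], abs=1e-6)
        assert b.beta[0] == pytest.approx(a.beta[0] - np.log(2.0), abs=1e-6)

    def test_agrees_with_statsmodels_on_twenty_genes(self, rng):
        n = 120
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2)])
        off = np.log(rng.uniform(0.5, 2.0, n))
        for _ in range(20):
            mu = np.exp(0.8 + rng.normal(0, 0.5) * X[:, 1] + off)
            y = rng.poisson(rng.gamma(1 / 0.3, 0.3 * mu)).astype(float)
            fit = fit_gene_glm(y, X, offset=off)
            oracle = sm.GLM(
                y, X, offset=off,
                family=sm.families.NegativeBinomial(alpha=max(fit.alpha, 1e-8)),
            ).fit()
            assert np.allclose(fit.beta, oracle.params, atol=1e-4)

    def test_log2fc_recovery(self, rng):
        n = 500
        meta = pd.DataFrame({"d": np.repeat([0.0, 1.0], n // 2)})
        mu = np.exp(np.log(20) + np.log(2) * meta.d.to_numpy())
        counts = rng.poisson(rng.gamma(1 / 0.2, 0.2 * mu)).reshape(-1, 1)
        res = DEModel(counts, meta, DeModelSpec(treatment="d"), np.ones(n)).fit()
        assert res.table.log2fc[0] == pytest.approx(1.0, abs=0.2)

    def test_all_zero_gene_fails_cleanly(self):
        meta = pd.DataFrame({"d": np.repeat([0.0, 1.0], 20)})
        res = DEModel(
            np.zeros((40, 1)), meta, DeModelSpec(treatment="d"), np.ones(40)
        ).fit()
        assert res.table.status[0] == "failed"
        assert np.isnan(res.table.q_value[0])


class TestDexWorkflow:
    def test_null_simulation_few_false_positives(self, rng):
        n, g = 300, 200
        meta = pd.DataFrame({"dex": np.repeat([0.0, 1.0], n // 2)})
        counts = rng.poisson(10, size=(n, g))
        hits = dex_responsive_genes(counts, meta, np.ones(n), treatment="dex")
        assert len(hits) <= 5

    def test_planted_genes_recovered(self, rng):
        n, g = 400, 100
        meta = pd.DataFrame({"dex": np.repeat([0.0, 1.0], n // 2)})
        lfc = np.zeros(g)
        lfc[:20] = 2.0
        mu = 15 * 2.0 ** (lfc[None, :] * meta.dex.to_numpy()[:, None])
        counts = rng.poisson(mu)
        hits = dex_responsive_genes(counts, meta, np.ones(n), treatment="dex")
        planted = {f"g{i}" for i in range(20)}
        assert len(planted & set(hits.gene)) >= 18

    def test_constant_treatment_rejected(self):
        meta = pd.DataFrame({"dex": np.zeros(50)})
        with pytest.raises(ValueError):
            dex_responsive_genes(np.ones((50, 3)), meta, np.ones(50), treatment="dex")


class TestClassifyUnresponsive:
    @pytest.mark.parametrize(
        "responds,hdaci_sig,hdaci_lfc,dex_lfc,expected",
        [
            (True, True, 1.0, 1.0, "responsive"),
            (False, True, 1.0, 1.0, "saturated"),
            (False, True, -1.0, 1.0, "dominated"),
            (False, False, 0.0, 1.0, "attenuated"),
            (False, True, 0.0, 1.0, "attenuated"),  # zero-lfc tie
        ],
    )
    def test_classification_table(self, responds, hdaci_sig, hdaci_lfc, dex_lfc, expected):
        got = classify_unresponsive_gene(
            dex_significant_alone=True,
            responds_under_hdaci=responds,
            hdaci_alone_lfc=hdaci_lfc,
            hdaci_alone_significant=hdaci_sig,
            dex_alone_lfc=dex_lfc,
        )
        assert got == expected

    def test_requires_dex_responsive_gene(self):
        with pytest.raises(ValueError):
            classify_unresponsive_gene(False, False, 0.0, False, 0.0)


class TestPercentExpressing:
    def test_all_above_threshold(self):
        pct, (lo, hi) = percent_expressing_bootstrap(np.full(50, 2.0), seed=1)
        assert (pct, lo, hi) == (100.0, 100.0, 100.0)

    def test_all_zero(self):
        pct, (lo, hi) = percent_expressing_bootstrap(np.zeros(50), seed=1)
        assert (pct, lo, hi) == (0.0, 0.0, 0.0)

    def test_ci_width_matches_binomial_theory(self, rng):
        v = np.concatenate([np.full(500, 2.0), np.zeros(500)])
        pct, (lo, hi) = percent_expressing_bootstrap(v, n_boot=500, seed=2)
        assert pct == pytest.approx(50.0)
        width = hi - lo
        theory = 2 * 1.96 * np.sqrt(0.25 / 1000) * 100  # ~6.2
        assert width == pytest.approx(theory, rel=0.25)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            percent_expressing_bootstrap([])
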