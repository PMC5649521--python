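import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fibrostrat.diffexpr import (
    EBPrior,
    bh_adjust,
    call_degs,
    de_table,
    estimate_eb_prior,
    fit_gene_models,
    moderated_t,
    pearson_chi2_2x2,
    pooled_t_from_summary,
)
from fibrostrat.io_formats import ExpressionMatrix


def _matrix(values, samples=None):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix.from_arrays(
        [f"g{i}" for i in range(values.shape[0])],
        samples or [f"s{j}" for j in range(values.shape[1])],
        values,
    )


def _groups(labels, samples=None):
    samples = samples or [f"s{j}" for j in range(len(labels))]
    return pd.Series(labels, index=samples)


class TestGeneModels:
    def test_constant_groups(self):
        m = _matrix([[1.0, 1.0, 0.0, 0.0]])
        fit = fit_gene_models(m, _groups(["A", "A", "B", "B"]), ("A", "B"))
        assert fit.diff[0] == pytest.approx(1.0)
        assert fit.s2[0] == pytest.approx(0.0)
        assert fit.df == 2

    def test_identical_groups_have_zero_difference(self, rng):
        col = rng.normal(size=5)
        m = _matrix(np.column_stack([col, col, col, col]))
        fit = fit_gene_models(m, _groups(["A", "B", "A", "B"]), ("A", "B"))
        np.testing.assert_allclose(fit.diff, 0.0, atol=1e-12)

    def test_matches_brute_force_summaries(self, rng):
        values = rng.normal(size=(20, 9))
        labels = ["A"] * 4 + ["B"] * 5
        fit = fit_gene_models(_matrix(values), _groups(labels), ("A", "B"))
        for i in range(20):
            a, b = values[i, :4], values[i, 4:]
            assert fit.diff[i] == pytest.approx(a.mean() - b.mean())
            pooled = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / 7
            assert fit.s2[i] == pytest.approx(pooled)
        assert fit.v == pytest.approx(1 / 4 + 1 / 5)

    def test_single_sample_group_raises(self):
        m = _matrix([[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError):
            fit_gene_models(m, _groups(["A", "B", "B"]), ("A", "B"))


class TestEBPrior:
    def test_equal_variances_give_infinite_prior_df(self):
        prior = estimate_eb_prior(np.full(50, 2.0), 4.0)
        assert math.isinf(prior.df_prior)
        # geometric-mean-consistent constant: corrects the log-scale
        # bias E[log s^2] - log sigma^2 = digamma(d/2) - log(d/2)
        from scipy.special import digamma

        expected = 2.0 * math.exp(math.log(2.0) - digamma(2.0))
        assert prior.var_prior == pytest.approx(expected, rel=1e-9)

    def test_recovers_simulated_hyperparameters(self):
        rng = np.random.default_rng(11)
        d0, s0_sq, d = 4.0, 1.0, 4.0
        sigma2 = d0 * s0_sq / rng.chisquare(d0, size=5000)
        s2 = sigma2 * rng.chisquare(d, size=5000) / d
        prior = estimate_eb_prior(s2, d)
        assert prior.df_prior == pytest.approx(d0, rel=0.15)
        assert prior.var_prior == pytest.approx(s0_sq, rel=0.15)

    def test_scale_equivariance(self, rng):
        s2 = rng.chisquare(4, size=2000) / 4
        p1 = estimate_eb_prior(s2, 4.0)
        p2 = estimate_eb_prior(2 * s2, 4.0)
        assert p2.var_prior == pytest.approx(2 * p1.var_prior, rel=1e-8)
        assert p2.df_prior == pytest.approx(p1.df_prior, rel=1e-8)

    def test_all_zero_variances_raise(self):
        with pytest.raises(ValueError):
            estimate_eb_prior(np.zeros(100), 4.0)


class TestModeratedT:
    def test_posterior_variance_arithmetic(self):
        t, p, df = moderated_t(
            np.array([1.0]), np.array([2.0]), 4.0, 2 / 3, EBPrior(4.0, 1.0)
        )
        # s2_post = (4*1 + 4*2)/8 = 1.5; t = 1/sqrt(1.5 * 2/3) = 1; df = 8
        assert t[0] == pytest.approx(1.0)
        assert df[0] == pytest.approx(8.0)
        assert p[0] == pytest.approx(2 * stats.t.sf(1.0, 8))

    def test_zero_prior_df_recovers_ordinary_t(self, rng):
        diff = rng.normal(size=200)
        s2 = rng.chisquare(4, size=200) / 4 + 0.05
        t_mod, p_mod, _ = moderated_t(diff, s2, 4.0, 0.5, EBPrior(0.0, 1.0))
        t_ord = diff / np.sqrt(s2 * 0.5)
        np.testing.assert_allclose(t_mod, t_ord, atol=1e-10)
        np.testing.assert_allclose(p_mod, 2 * stats.t.sf(np.abs(t_ord), 4), atol=1e-10)

    def test_zero_difference_gives_p_one(self):
        t, p, _ = moderated_t(np.array([0.0]), np.array([1.0]), 4.0, 0.5, EBPrior(4.0, 1.0))
        assert t[0] == 0.0 and p[0] == pytest.approx(1.0)

    def test_infinite_prior_uses_normal_limit(self):
        t, p, _ = moderated_t(
            np.array([2.0]), np.array([5.0]), 4.0, 1.0, EBPrior(math.inf, 1.0)
        )
        assert t[0] == pytest.approx(2.0)
        assert p[0] == pytest.approx(2 * stats.norm.sf(2.0), rel=1e-6)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(5)
        n = 5000
        sigma2 = 4 * 1.0 / rng.chisquare(4, size=n)
        a = rng.normal(0, np.sqrt(sigma2)[:, None], size=(n, 4))
        b = rng.normal(0, np.sqrt(sigma2)[:, None], size=(n, 4))
        diff = a.mean(1) - b.mean(1)
        s2 = (
            ((a - a.mean(1, keepdims=True)) ** 2).sum(1)
            + ((b - b.mean(1, keepdims=True)) ** 2).sum(1)
        ) / 6
        prior = estimate_eb_prior(s2, 6.0)
        _, p, _ = moderated_t(diff, s2, 6.0, 0.5, prior)
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestBH:
    def test_textbook_example(self):
        got = bh_adjust(np.array([0.005, 0.011, 0.02, 0.04]))
        np.testing.assert_allclose(got, [0.02, 0.022, 0.02667, 0.04], atol=1e-4)

    def test_single_and_tied_inputs(self):
        assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_adjust(np.full(7, 0.02)), 0.02)

    def test_matches_statsmodels_and_is_monotone_idempotent(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        got = bh_adjust(p)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(got, expected, atol=1e-12)
        # order-preserving: adjusted values are monotone in the raw p order
        order = np.argsort(p)
        assert (np.diff(got[order]) >= -1e-12).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.1, 1.5]))


class TestDegCalls:
    def _de(self, rows):
        return pd.DataFrame(rows)

    def test_thresholds_are_inclusive(self):
        de = self._de(
            [
                {"gene": "a", "contrast": "c", "lfc": 1.0, "q": 0.05},
                {"gene": "b", "contrast": "c", "lfc": 0.9, "q": 0.04},
                {"gene": "c", "contrast": "c", "lfc": -1.2, "q": 0.01},
            ]
        )
        got = call_degs(de)
        assert got["c"] == {"a": "up", "c": "down"}

    def test_matches_brute_force_filter(self, rng):
        de = self._de(
            [
                {
                    "gene": f"g{i}",
                    "contrast": "k",
                    "lfc": rng.normal(scale=1.5),
                    "q": rng.uniform(),
                }
                for i in range(300)
            ]
        )
        got = set(call_degs(de)["k"])
        expected = {
            r.gene for r in de.itertuples() if r.q <= 0.05 and abs(r.lfc) >= 1.0
        }
        assert got == expected


class TestClinicalComparisons:
    def test_fev1_row_reproduces_reported_p(self):
        _, _, p = pooled_t_from_summary(71.37, 19.00, 131, 94.33, 9.86, 12)
        assert p == pytest.approx(6.3e-5, rel=0.15)

    def test_equal_means_give_p_one(self):
        t, _, p = pooled_t_from_summary(5, 1, 10, 5, 1, 10)
        assert t == 0 and p == pytest.approx(1.0)

    def test_closed_form_small_case(self):
        t, df, p = pooled_t_from_summary(0, 1, 2, 1, 1, 2)
        assert t == pytest.approx(-1.0)
        assert df == 2
        assert p == pytest.approx(0.4226, abs=1e-3)

    def test_chi2_identical_proportions(self):
        chi2, p = pearson_chi2_2x2(10, 10, 5, 5)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_chi2_perfect_association(self):
        chi2, p = pearson_chi2_2x2(10, 0, 0, 10)
        assert chi2 == pytest.approx(20.0)
        assert p == pytest.approx(7.7e-6, rel=1e-2)

    def test_chi2_matches_scipy_without_correction(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 40, size=4)
            chi2, p = pearson_chi2_2x2(a, b, c, d)
            expected = stats.chi2_contingency([[a, b], [c, d]], correction=False)
            assert chi2 == pytest.approx(expected.statistic)
            assert p == pytest.approx(expected.pvalue)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            pearson_chi2_2x2(0, 0, 3, 4)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="no Rscript available")
def test_moderated_t_matches_limma_on_small_fixture(tmp_path, rng):
    """Cross-check the eBayes engine against the reference implementation."""
    n, na, nb = 60, 5, 5
    sigma2 = 4 * 0.25 / rng.chisquare(4, size=n)
    effects = np.where(np.arange(n) < 10, 1.0, 0.0)
    a = rng.normal(effects[:, None], np.sqrt(sigma2)[:, None], size=(n, na))
    b = rng.normal(0, np.sqrt(sigma2)[:, None], size=(n, nb))
    values = np.hstack([a, b])
    samples = [f"A{i}" for i in range(na)] + [f"B{i}" for i in range(nb)]
    m = _matrix(values, samples=samples)
    de = de_table(m, _groups(["A"] * na + ["B"] * nb, samples), [("A", "B")])

    csv = tmp_path / "expr.csv"
    pd.DataFrame(values, index=[f"g{i}" for i in range(n)], columns=samples).to_csv(csv)
    out = tmp_path / "limma.csv"
    script = tmp_path / "run.R"
    script.write_text(
        f"""
suppressMessages(library(limma))
x <- as.matrix(read.csv("{csv}", row.names=1))
design <- cbind(Intercept=1, AvsB=c(rep(1,{na}), rep(0,{nb})))
fit <- eBayes(lmFit(x, design))
tab <- topTable(fit, coef="AvsB", number=Inf, sort.by="none", adjust.method="BH")
write.csv(tab[, c("logFC","t","P.Value","adj.P.Val")], "{out}")
"""
    )
    subprocess.run(["Rscript", "--vanilla", str(script)], check=True, capture_output=True)
    ref = pd.read_csv(out, index_col=0)
    np.testing.assert_allclose(de["lfc"].to_numpy(), ref["logFC"].to_numpy(), atol=1e-8)
    np.testing.assert_allclose(de["t"].to_numpy(), ref["t"].to_numpy(), rtol=1e-4)
    np.testing.assert_allclose(de["p"].to_numpy(), ref["P.Value"].to_numpy(), rtol=1e-3)
    np.testing.assert_allclose(de["q"].to_numpy(), ref["adj.P.Val"].to_numpy(), rtol=1e-3)
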