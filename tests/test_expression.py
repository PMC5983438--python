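"""Differential-expression stage: normalization, moderated t, BH, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from promotif.expression import (
    ModeratedTParams,
    bh_adjust,
    delta_ct,
    fit_prior,
    moderated_t,
    normalize_quantile,
    select_de_genes,
)

DESIGN = (
    {f"c{i}": "control" for i in range(1, 5)}
    | {f"m{i}": "MCAO" for i in range(1, 4)}
    | {f"n{i}": "MCAO_NRG1" for i in range(1, 4)}
)
SAMPLES = list(DESIGN)


def _matrix(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=genes, columns=SAMPLES[: values.shape[1]])


class TestQuantileNormalization:
    def test_identical_columns_unchanged(self):
        m = pd.DataFrame(
            np.tile([[1.0], [3.0], [2.0]], (1, 3)), columns=["a", "b", "c"]
        )
        out = normalize_quantile(m)
        pd.testing.assert_frame_equal(out, m)

    def test_permuted_columns_get_identical_multisets(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=50)
        m = pd.DataFrame({"a": col, "b": rng.permutation(col)})
        out = normalize_quantile(m)
        assert np.allclose(np.sort(out["a"]), np.sort(out["b"]))

    def test_three_by_three_against_hand_computation(self):
        # mean order statistics assigned back by within-column rank
        m = pd.DataFrame(
            [[2.0, 4.0, 9.0], [5.0, 1.0, 6.0], [3.0, 8.0, 7.0]],
            index=list("xyz"),
            columns=["a", "b", "c"],
        )
        # sorted columns: a=(2,3,5), b=(1,4,8), c=(6,7,9); row means (3, 14/3, 22/3)
        expected = pd.DataFrame(
            [[3.0, 14 / 3, 22 / 3], [22 / 3, 3.0, 3.0], [14 / 3, 22 / 3, 14 / 3]],
            index=list("xyz"),
            columns=["a", "b", "c"],
        )
        pd.testing.assert_frame_equal(normalize_quantile(m), expected)

    def test_preserves_within_column_rank_order(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        out = normalize_quantile(m)
        for c in m.columns:
            assert (np.argsort(m[c].to_numpy()) == np.argsort(out[c].to_numpy())).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            normalize_quantile(pd.DataFrame({"a": [1.0, 2.0]}))


class TestPriorEstimation:
    def test_equal_variances_give_infinite_prior_df(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=10)
        m = _matrix(np.tile(base, (30, 1)) + np.arange(30)[:, None])
        params = fit_prior(m, DESIGN)
        assert np.isinf(params.d0)

    def test_two_genes_unequal_variances_finite_d0(self):
        rng = np.random.default_rng(3)
        x = np.vstack([rng.normal(0, 0.1, 10), rng.normal(0, 10.0, 10)])
        params = fit_prior(_matrix(x), DESIGN)
        assert 0 < params.d0 < np.inf

    def test_recovers_inverse_chisquare_hyperparameters(self):
        # s_g^2 ~ s0^2 * d0 / chi2_d0 with d0=4, s0^2=0.09, 2000 genes
        rng = np.random.default_rng(4)
        d0_true, s0_true = 4.0, 0.09
        sigma = np.sqrt(s0_true * d0_true / rng.chisquare(d0_true, 2000))
        x = rng.normal(size=(2000, 10)) * sigma[:, None]
        params = fit_prior(_matrix(x), DESIGN)
        assert 2.0 <= params.d0 <= 8.0
        assert abs(params.s0_sq - s0_true) <= 0.25 * s0_true

    def test_all_zero_variance_is_an_error(self):
        m = _matrix(np.ones((5, 10)))
        with pytest.raises(ValueError):
            fit_prior(m, DESIGN)


class TestModeratedT:
    def test_d0_zero_equals_ordinary_pooled_t(self):
        rng = np.random.default_rng(5)
        m = _matrix(rng.normal(size=(30, 10)))
        params = ModeratedTParams(d0=0.0, s0_sq=1.0)
        res = moderated_t(m, DESIGN, ("MCAO", "control"), params)
        # ordinary two-sample t with the pooled *residual* variance (7 df)
        x = m.to_numpy()
        a, b = x[:, 4:7], x[:, :4]
        rss = sum(
            ((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            for g in (x[:, :4], x[:, 4:7], x[:, 7:])
        )
        s2 = rss / 7
        t_expected = (a.mean(1) - b.mean(1)) / np.sqrt(s2 * (1 / 3 + 1 / 4))
        assert np.allclose(res["t"], t_expected)

    def test_equal_group_means_give_t_zero_p_one(self):
        x = np.zeros((3, 10))
        x[:, :] = [1, 2, 3, 4, 2, 3, 2.5, 9, 9, 9]  # control mean 2.5 == MCAO mean
        res = moderated_t(
            _matrix(x), DESIGN, ("MCAO", "control"), ModeratedTParams(2.0, 0.5)
        )
        assert np.allclose(res["t"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_infinite_d0_uses_prior_variance_for_every_gene(self):
        rng = np.random.default_rng(6)
        m = _matrix(rng.normal(size=(20, 10)))
        s0 = 0.25
        res = moderated_t(
            m, DESIGN, ("MCAO", "control"), ModeratedTParams(np.inf, s0)
        )
        x = m.to_numpy()
        diff = x[:, 4:7].mean(1) - x[:, :4].mean(1)
        assert np.allclose(res["t"], diff / np.sqrt(s0 * (1 / 3 + 1 / 4)))

    def test_null_pvalues_are_uniform(self):
        # 500 null genes, common variance: KS distance to U(0,1) below 0.10
        rng = np.random.default_rng(7)
        m = _matrix(rng.normal(0, 0.3, size=(500, 10)))
        params = fit_prior(m, DESIGN)
        res = moderated_t(m, DESIGN, ("MCAO", "control"), params)
        d = stats.kstest(res["p"], "uniform").statistic
        assert d < 0.10

    def test_matches_limma_on_shared_data(self, tmp_path):
        """The full chain (prior + t + p) agrees with the Bioconductor
        reference implementation on identical input."""
        pytest.importorskip("shutil")
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(42)
        sigma = np.sqrt(0.04 * 4 / rng.chisquare(4, 80))
        x = rng.normal(size=(80, 10)) * sigma[:, None]
        x[:20, 4:7] += 1.5
        m = _matrix(x)
        expr = tmp_path / "expr.tsv"
        m.to_csv(expr, sep="\t")
        params = fit_prior(m, DESIGN)
        res = moderated_t(m, DESIGN, ("MCAO", "control"), params)
        rscript = tmp_path / "limma.R"
        rscript.write_text(
            f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{expr}", row.names=1))
            g <- factor(c(rep("control",4), rep("MCAO",3), rep("NRG",3)),
                        levels=c("control","MCAO","NRG"))
            d <- model.matrix(~0+g); colnames(d) <- levels(g)
            f <- eBayes(contrasts.fit(lmFit(x, d),
                        makeContrasts(MCAO-control, levels=d)))
            out <- data.frame(d0=f$df.prior, s0=f$s2.prior, t=f$t[,1], p=f$p.value[,1])
            write.table(out, "{tmp_path / 'limma_out.tsv'}", sep="\\t", quote=FALSE)
            """
        )
        proc = subprocess.run(
            ["Rscript", str(rscript)], capture_output=True, text=True
        )
        if proc.returncode != 0:
            pytest.skip(f"limma unavailable: {proc.stderr[-200:]}")
        ref = pd.read_csv(tmp_path / "limma_out.tsv", sep="\t")
        assert params.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert params.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-6)
        assert np.allclose(res["t"], ref["t"], atol=1e-8)
        assert np.allclose(res["p"], ref["p"], atol=1e-10)


class TestBHAdjustment:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_value_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40)
    )
    def test_bounds_and_monotone_dominance(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)

    def test_matches_independent_step_up_oracle(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=25)
        n = len(p)
        order = np.argsort(p)
        q_sorted = np.minimum.accumulate(
            (p[order] * n / np.arange(1, n + 1))[::-1]
        )[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(bh_adjust(p), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDESelection:
    def _frame(self, genes, q):
        return pd.DataFrame({"q": q, "p": q}, index=genes)

    def test_union_rule(self):
        res = {
            ("MCAO", "control"): self._frame(["a", "b"], [0.01, 0.9]),
            ("MCAO_NRG1", "control"): self._frame(["a", "b"], [0.9, 0.9]),
            ("MCAO_NRG1", "MCAO"): self._frame(["a", "b"], [0.9, 0.03]),
        }
        assert select_de_genes(res, 0.05) == ["a", "b"]

    def test_no_significant_genes_empty(self):
        res = {("MCAO", "control"): self._frame(["a"], [0.5])}
        assert select_de_genes(res, 0.05) == []

    def test_planted_de_recovery(self):
        """100 genes shifted by 2 log2 units among 900 nulls: recall >= 0.9
        with false positives within twice the nominal level."""
        from promotif.expression import CONTRASTS
        rng = np.random.default_rng(9)
        x = rng.normal(0, 0.25, size=(1000, 10))
        x[:100, 4:7] += 2.0
        m = _matrix(x)
        params = fit_prior(m, DESIGN)
        res = {c: moderated_t(m, DESIGN, c, params) for c in CONTRASTS}
        selected = set(select_de_genes(res, 0.05))
        truth = {f"g{i}" for i in range(100)}
        recall = len(selected & truth) / 100
        fpr = len(selected - truth) / 900
        assert recall >= 0.9
        assert fpr <= 0.10


class TestDeltaCt:
    def test_arithmetic(self):
        assert delta_ct(25, 20) == 5
        assert delta_ct(20, 20) == 0

    def test_linearity_over_replicates(self):
        target, ref = [24.0, 25.0, 26.0], [20.0, 21.0, 19.0]
        assert delta_ct(target, ref) == pytest.approx(
            np.mean(target) - np.mean(ref)
        )
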