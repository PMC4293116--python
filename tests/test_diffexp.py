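"""Moderated paired differential expression and BH adjustment."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from prognosig.containers import ExpressionMatrix, PairedDesign
from prognosig.diffexp import (
    ModerationPrior,
    bh_adjust,
    estimate_moderation_prior,
    filter_de_genes,
    moderated_t_test,
    paired_log_fold_changes,
)


def bh_brute_force(p):
    """Direct step-up definition: padj_(i) = min_{j>=i} m p_(j)/j, capped."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    running = np.inf
    for rank_from_top in range(m, 0, -1):
        j = order[rank_from_top - 1]
        running = min(running, m * p[j] / rank_from_top)
        out[j] = min(running, 1.0)
    return out


def make_paired(diffs, base=5.0):
    """Expression matrix where tumour - normal equals the given diffs."""
    diffs = np.atleast_2d(np.asarray(diffs, float))
    G, n = diffs.shape
    normal = np.full((G, n), base)
    tum = normal + diffs
    tid = [f"t{i}" for i in range(n)]
    nid = [f"n{i}" for i in range(n)]
    vals = pd.DataFrame(
        np.hstack([tum, normal]),
        index=[f"g{i}" for i in range(G)],
        columns=tid + nid,
    )
    return ExpressionMatrix(vals), PairedDesign(list(zip(tid, nid)))


class TestPairedFoldChanges:
    def test_identical_pairs_zero(self):
        expr, design = make_paired(np.zeros((3, 4)))
        fc = paired_log_fold_changes(expr, design)
        assert np.allclose(fc["lfc"], 0) and np.allclose(fc["s2"], 0)

    @pytest.mark.parametrize(
        "diffs,lfc,s2",
        [((1.0, 1.0, 1.0), 1.0, 0.0), ((0.0, 1.0, 2.0), 1.0, 1.0)],
    )
    def test_hand_computed_mean_and_variance(self, diffs, lfc, s2):
        expr, design = make_paired([diffs])
        fc = paired_log_fold_changes(expr, design)
        assert fc["lfc"].iloc[0] == pytest.approx(lfc)
        assert fc["s2"].iloc[0] == pytest.approx(s2)
        assert fc["df"].iloc[0] == 2

    def test_missing_sample_named(self):
        expr, _ = make_paired(np.zeros((2, 3)))
        design = PairedDesign([("t0", "n0"), ("t9", "n1")])
        with pytest.raises(ValueError, match="t9"):
            paired_log_fold_changes(expr, design)

    def test_single_pair_rejected(self):
        expr, _ = make_paired(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="2 pairs"):
            paired_log_fold_changes(expr, PairedDesign([("t0", "n0")]))


class TestModerationPrior:
    def test_one_gene_errors(self):
        with pytest.raises(ValueError):
            estimate_moderation_prior([1.0], df=3)

    def test_all_zero_variances_error(self):
        with pytest.raises(ValueError):
            estimate_moderation_prior([0.0, 0.0, 0.0], df=3)

    def test_equal_true_variances_reported_infinite(self):
        """Scaled chi2 draws with no variance heterogeneity: d0 = inf (or
        astronomically large) in >=90% of seeds."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            s2 = rng.chisquare(10, 5000) / 10
            d0 = estimate_moderation_prior(s2, df=10).d0
            hits += np.isinf(d0) or d0 > 1e6
        assert hits / 50 >= 0.9

    def test_parameter_recovery_within_25pct(self):
        rng = np.random.default_rng(11)
        true_var = 4.0 / rng.chisquare(4, 5000)  # d0=4, s0_sq=1
        s2 = true_var * rng.chisquare(10, 5000) / 10
        prior = estimate_moderation_prior(s2, df=10)
        assert abs(prior.d0 - 4.0) / 4.0 < 0.25
        assert abs(prior.s0_sq - 1.0) < 0.25


class TestModeratedT:
    def test_no_moderation_limit_is_ordinary_t(self, rng):
        lfc = rng.normal(size=200)
        s2 = rng.chisquare(5, 200) / 5
        df, n = 5, 6
        de = moderated_t_test(lfc, s2, df, ModerationPrior(0.0, 1.0), n)
        t_ref = lfc / np.sqrt(s2 / n)
        assert np.allclose(de["t_mod"], t_ref, atol=1e-12)
        assert np.allclose(de["p"], 2 * stats.t.sf(np.abs(t_ref), df), atol=1e-12)

    def test_full_shrinkage_limit_uses_prior_variance(self, rng):
        s2 = rng.chisquare(5, 50) / 5
        de = moderated_t_test(
            np.ones(50), s2, 5, ModerationPrior(np.inf, 2.0), n_pairs=4
        )
        assert np.allclose(de["t_mod"], 1.0 / np.sqrt(2.0 / 4))

    def test_posterior_variance_formula(self):
        de = moderated_t_test([1.0], [4.0], 2, ModerationPrior(4.0, 1.0), n_pairs=3)
        s2_tilde = (4.0 * 1.0 + 2 * 4.0) / 6.0
        assert s2_tilde == 2.0
        assert de["t_mod"].iloc[0] == pytest.approx(1.0 / np.sqrt(2.0 / 3))

    def test_agrees_with_limma_ebayes(self, tmp_path):
        """Independent oracle: Bioconductor limma on the same differences."""
        rng = np.random.default_rng(77)
        G, n = 120, 8
        tv = 4.0 / rng.chisquare(4, G)
        d = rng.normal(0, np.sqrt(tv)[:, None], (G, n))
        d[:10] += 1.0
        dpath = tmp_path / "diffs.tsv"
        pd.DataFrame(d, index=[f"g{i}" for i in range(G)]).to_csv(dpath, sep="\t")
        rpath = tmp_path / "ebayes.R"
        rpath.write_text(
            'suppressMessages(library(limma))\n'
            'args <- commandArgs(trailingOnly=TRUE)\n'
            'd <- as.matrix(read.delim(args[1], row.names=1))\n'
            'fit <- eBayes(lmFit(d, design=matrix(1, ncol(d), 1)))\n'
            'out <- data.frame(t=fit$t[,1], p=fit$p.value[,1],\n'
            '                  d0=fit$df.prior, s0sq=fit$s2.prior)\n'
            'write.table(out, args[2], sep="\\t", quote=FALSE, row.names=FALSE)\n'
        )
        opath = tmp_path / "out.tsv"
        subprocess.run(
            ["Rscript", str(rpath), str(dpath), str(opath)], check=True,
            capture_output=True,
        )
        ref = pd.read_csv(opath, sep="\t")
        lfc, s2, df = d.mean(axis=1), d.var(axis=1, ddof=1), n - 1
        prior = estimate_moderation_prior(s2, df)
        de = moderated_t_test(lfc, s2, df, prior, n_pairs=n)
        assert prior.d0 == pytest.approx(ref["d0"][0], rel=1e-6)
        assert prior.s0_sq == pytest.approx(ref["s0sq"][0], rel=1e-6)
        assert np.allclose(de["t_mod"], ref["t"], atol=1e-8)
        assert np.allclose(de["p"], ref["p"], atol=1e-10)


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust([1.0]).tolist() == [1.0]

    def test_hand_stepped_example(self):
        out = bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(out, [0.02, 0.02, 0.04, 0.04])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_matches_brute_force_and_dominates(self, p):
        out = bh_adjust(p)
        assert np.allclose(out, bh_brute_force(p), atol=1e-12)
        assert (out >= np.asarray(p) - 1e-12).all()


class TestFilter:
    def make_de(self, padj, lfc):
        return pd.DataFrame(
            {"padj": padj, "lfc": lfc, "p": padj},
            index=[f"g{i}" for i in range(len(padj))],
        )

    def test_threshold_application_and_strictness(self):
        de = self.make_de([0.005, 0.005, 0.01, 0.5], [0.5, 0.0, 1.0, 2.0])
        assert filter_de_genes(de, 0.01, 0.0) == ["g0"]

    def test_order_preserved(self):
        de = self.make_de([0.001, 0.002, 0.0005], [1.0, -1.0, 2.0])
        assert filter_de_genes(de) == ["g0", "g1", "g2"]


def test_null_pvalue_calibration():
    """With no planted fold change the p-value histogram is uniform:
    pooled rejection at 0.05 inside the 99% binomial interval."""
    hits, total = 0, 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        d = rng.normal(0, 1.0, (500, 10))
        lfc, s2 = d.mean(axis=1), d.var(axis=1, ddof=1)
        prior = estimate_moderation_prior(s2, 9)
        de = moderated_t_test(lfc, s2, 9, prior, n_pairs=10)
        hits += (de["p"] < 0.05).sum()
        total += len(de)
    lo, hi = stats.binom.ppf([0.005, 0.995], total, 0.05) / total
    assert lo <= hits / total <= hi
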