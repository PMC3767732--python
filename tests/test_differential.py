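import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lobeconcord import differential as de
from lobeconcord import preprocess as pp
from lobeconcord.io_formats import DetectionMatrix
from lobeconcord.synthetic import SyntheticConfig, generate_cohort

from conftest import make_expr, make_ann, paired_ann


def diffs_to_matrix(diffs):
    """Build a log2 matrix + annotation whose paired differences are
    exactly ``diffs`` (probes x subjects): lower = 0, upper = diff."""
    diffs = np.asarray(diffs, dtype=float)
    m, n = diffs.shape
    ann = paired_ann(n)
    cols = {}
    for j in range(n):
        cols[f"S{j}_u"] = diffs[:, j]
        cols[f"S{j}_l"] = np.zeros(m)
    x = make_expr(
        np.column_stack([cols[s] for s in ann.sample_ids]),
        samples=ann.sample_ids,
        scale="log2",
    )
    return x, ann


class TestPairedT:
    def test_constant_differences_degenerate(self):
        x, ann = diffs_to_matrix([[1.0, 1.0, 1.0, 1.0]])
        out = de.paired_t(x, ann)
        assert bool(out["degenerate"].iloc[0])
        assert out["p"].iloc[0] == 1.0

    def test_antisymmetric_differences(self):
        x, ann = diffs_to_matrix([[1.0, -1.0, 1.0, -1.0]])
        out = de.paired_t(x, ann)
        assert out["t_stat"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_scipy_ttest_rel(self):
        rng = np.random.default_rng(0)
        diffs = rng.normal(0.2, 1.0, (50, 8))
        x, ann = diffs_to_matrix(diffs)
        out = de.paired_t(x, ann)
        t_ref, p_ref = stats.ttest_rel(diffs, np.zeros_like(diffs), axis=1)
        assert np.allclose(out["t_stat"], t_ref, atol=1e-12)
        assert np.allclose(out["p"], p_ref, atol=1e-12)

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(42)
        diffs = rng.normal(0.0, 1.0, (2000, 8))
        x, ann = diffs_to_matrix(diffs)
        out = de.paired_t(x, ann)
        frac = float((out["p"] < 0.05).mean())
        ci = 1.96 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) < ci

    def test_too_few_pairs(self):
        x, ann = diffs_to_matrix([[1.0]])
        with pytest.raises(ValueError):
            de.paired_t(x, ann)


class TestModeratedT:
    def test_identical_variances_collapse_shrinkage(self):
        """All probes with the same sample variance v: the prior absorbs
        everything (d0 -> inf), every posterior variance equals the common
        prior, and that prior equals v times the analytic log-chi-square
        bias factor exp(log(d/2) - digamma(d/2)) (-> 1 as d grows)."""
        from scipy import special

        rng = np.random.default_rng(1)
        n = 6
        base = rng.normal(0, 1, n)
        base = (base - base.mean()) / base.std(ddof=1)  # variance exactly 1
        offsets = rng.uniform(-2.0, 2.0, 30)
        diffs = offsets[:, None] + base[None, :]
        x, ann = diffs_to_matrix(diffs)
        mod, fit = de.moderated_t(x, ann, design="paired")
        d = n - 1
        bias = np.exp(np.log(d / 2) - special.digamma(d / 2))
        assert np.isinf(fit.d0)
        assert fit.s0_sq == pytest.approx(bias, rel=1e-9)
        assert np.allclose(fit.posterior_var, fit.s0_sq)
        classical = de.paired_t(x, ann)
        ratio = mod["t_stat"] / classical["t_stat"]
        assert np.allclose(ratio, 1.0 / np.sqrt(bias), rtol=1e-9)

    def test_infinite_prior_pools_variance(self):
        rng = np.random.default_rng(2)
        x, ann = diffs_to_matrix(rng.normal(0, 1, (40, 6)))
        _, fit = de.moderated_t(x, ann, design="paired", d0_override=np.inf)
        assert np.allclose(fit.posterior_var, fit.s0_sq)

    def test_zero_prior_recovers_classical(self):
        rng = np.random.default_rng(3)
        diffs = rng.normal(0, 1, (40, 6))
        x, ann = diffs_to_matrix(diffs)
        mod, _ = de.moderated_t(x, ann, design="paired", d0_override=0.0)
        classical = de.paired_t(x, ann)
        assert np.allclose(mod["t_stat"], classical["t_stat"], atol=1e-12)
        assert np.allclose(mod["p"], classical["p"], atol=1e-12)

    def test_hyperparameter_recovery(self):
        # scaled inverse chi-square variances: d0=4, s0^2=0.05
        rng = np.random.default_rng(7)
        m, n, d0_true, s0_true = 1000, 7, 4.0, 0.05
        var = d0_true * s0_true / rng.chisquare(d0_true, m)
        diffs = rng.normal(0.0, np.sqrt(var)[:, None], (m, n))
        x, ann = diffs_to_matrix(diffs)
        _, fit = de.moderated_t(x, ann, design="paired")
        assert abs(fit.d0 - d0_true) / d0_true < 0.25
        assert abs(fit.s0_sq - s0_true) / s0_true < 0.25

    def test_posterior_is_convex_combination(self):
        rng = np.random.default_rng(8)
        diffs = rng.normal(0, rng.uniform(0.5, 2.0, (60, 1)), (60, 6))
        x, ann = diffs_to_matrix(diffs)
        _, fit = de.moderated_t(x, ann, design="paired")
        s2 = np.var(diffs, axis=1, ddof=1)
        lo = np.minimum(s2, fit.s0_sq) - 1e-12
        hi = np.maximum(s2, fit.s0_sq) + 1e-12
        post = fit.posterior_var.to_numpy()
        assert np.all((post >= lo) & (post <= hi))

    def test_too_few_probes(self):
        x, ann = diffs_to_matrix(np.ones((2, 4)) + np.arange(4))
        with pytest.raises(ValueError):
            de.moderated_t(x, ann, design="paired")

    def test_agrees_with_limma_ebayes(self, tmp_path):
        """Independent oracle: Bioconductor limma's eBayes on the same
        two-group data gives the same prior, posterior variances and t."""
        rng = np.random.default_rng(5)
        m, na, nb = 200, 5, 6
        var = 4.0 * 0.05 / rng.chisquare(4.0, m)
        X = np.concatenate(
            [
                rng.normal(0.0, np.sqrt(var)[:, None], (m, na)),
                rng.normal(0.3, np.sqrt(var)[:, None], (m, nb)),
            ],
            axis=1,
        )
        cols = [f"A{i}" for i in range(na)] + [f"B{i}" for i in range(nb)]
        df = pd.DataFrame(X, index=[f"P{i}" for i in range(m)], columns=cols)
        df.to_csv(tmp_path / "in.tsv", sep="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            x <- as.matrix(read.delim(args[1], row.names=1))
            grp <- factor(c(rep("A",5), rep("B",6)), levels=c("A","B"))
            fit <- eBayes(lmFit(x, model.matrix(~grp)))
            out <- data.frame(t=fit$t[,2], s2post=fit$s2.post,
                              d0=fit$df.prior, s20=fit$s2.prior)
            write.table(out, args[2], sep="\\t", quote=FALSE)
            """
        )
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "oracle.R"), str(tmp_path / "in.tsv"),
             str(tmp_path / "out.tsv")],
            check=True,
            capture_output=True,
        )
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")

        x = make_expr(X, probes=list(df.index), samples=cols, scale="log2")
        ann = make_ann(
            [(c, c, "lower", "smoker" if c.startswith("A") else "nonsmoker") for c in cols]
        )
        tab, fit = de.moderated_t(x, ann, design="two_group")
        assert fit.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert fit.s0_sq == pytest.approx(ref["s20"].iloc[0], rel=1e-6)
        # limma's contrast is B - A; ours is smoker(A) - nonsmoker(B)
        assert np.allclose(-tab["t_stat"], ref["t"], atol=1e-9)
        assert np.allclose(fit.posterior_var, ref["s2post"], rtol=1e-9)


def bh_bruteforce(p):
    """Literal step-up definition: adj_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj[order[rank - 1]] = min(running, 1.0)
    return adj


class TestBH:
    def test_step_up_example(self):
        out = de.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.all(de.bh_adjust(np.ones(5)) == 1.0)

    def test_single_p_unchanged(self):
        assert de.bh_adjust([0.3])[0] == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 13))
        assert np.allclose(de.bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])


class TestStoreyQ:
    def test_uniform_null_pi0(self):
        rng = np.random.default_rng(9)
        p = rng.random(1000)
        assert 0.85 <= de.storey_pi0(p) <= 1.0
        q = de.storey_q(p)
        assert np.all((q >= 0.0) & (q <= 1.0))

    def test_reduces_to_bh_when_pi0_one(self):
        # every p > lambda -> pi0 estimate clips to 1 -> q == BH
        p = np.linspace(0.6, 0.99, 12)
        assert np.allclose(de.storey_q(p), de.bh_adjust(p), atol=1e-12)

    def test_all_ones(self):
        assert np.all(de.storey_q(np.ones(10)) == 1.0)

    def test_q_below_bh(self):
        rng = np.random.default_rng(10)
        p = np.concatenate([rng.random(500) * 0.01, rng.random(500)])
        assert np.all(de.storey_q(p) <= de.bh_adjust(p) + 1e-12)

    def test_needs_ten(self):
        with pytest.raises(ValueError):
            de.storey_q(np.linspace(0.1, 0.9, 5))


class TestFoldChange:
    @pytest.mark.parametrize("a,b,expected", [(3.0, 2.0, 1.5), (2.0, 3.0, 1.5), (2.0, 2.0, 1.0)])
    def test_symmetric(self, a, b, expected):
        x = make_expr([[a, a, b, b]], samples=["a1", "a2", "b1", "b2"])
        fc = de.symmetric_fold_change(x, ["a1", "a2"], ["b1", "b2"])
        assert fc.iloc[0] == pytest.approx(expected)

    def test_zero_mean_flagged_nan(self):
        x = make_expr([[0.0, 0.0, 1.0, 1.0]], samples=["a1", "a2", "b1", "b2"])
        fc = de.symmetric_fold_change(x, ["a1", "a2"], ["b1", "b2"])
        assert np.isnan(fc.iloc[0])


class TestDeriveSignature:
    def test_identical_groups_empty(self):
        rng = np.random.default_rng(11)
        vals = rng.gamma(2.0, 10.0, (60, 16))
        samples = [f"s{i}" for i in range(16)]
        x = make_expr(vals, samples=samples)
        ann = make_ann(
            [(s, s, "lower", "smoker" if i < 8 else "nonsmoker") for i, s in enumerate(samples)]
        )
        det = DetectionMatrix(x.data.astype(bool) | True)
        sig, _ = de.derive_signature(x, det, ann)
        assert len(sig) == 0

    def test_thresholds_disabled_returns_all_present(self, small_cohort):
        expr, det, ann, _ = small_cohort
        norm = pp.normalize_per_gene(pp.normalize_per_chip(expr))
        det = DetectionMatrix(det.data.loc[norm.probe_ids, norm.sample_ids])
        sig, table = de.derive_signature(norm, det, ann, fc_min=1.0, p_bh_max=1.000001)
        assert len(sig) == len(table)

    def test_sample_order_invariance(self, small_cohort):
        expr, det, ann, _ = small_cohort
        norm = pp.normalize_per_gene(pp.normalize_per_chip(expr))
        det = DetectionMatrix(det.data.loc[norm.probe_ids, norm.sample_ids])
        sig1, _ = de.derive_signature(norm, det, ann)
        rng = np.random.default_rng(12)
        perm = list(rng.permutation(norm.sample_ids))
        norm2 = make_expr(norm.data[perm].to_numpy(), probes=norm.probe_ids, samples=perm)
        det2 = DetectionMatrix(det.data[perm])
        sig2, _ = de.derive_signature(norm2, det2, ann)
        assert set(sig1.probe_ids) == set(sig2.probe_ids)

    def test_planted_recovery_small(self, small_cohort):
        expr, det, ann, planted = small_cohort
        norm = pp.normalize_per_gene(pp.normalize_per_chip(expr))
        det = DetectionMatrix(det.data.loc[norm.probe_ids, norm.sample_ids])
        sig, _ = de.derive_signature(norm, det, ann)
        tp = len(set(sig.probe_ids) & set(planted.probe_ids))
        assert tp / len(planted) >= 0.7  # small cohort: 5 vs 12 subjects
        assert (len(sig) - tp) <= 0.1 * max(len(sig), 1)

    def test_direction_concordance_classical_vs_moderated(self, small_cohort):
        """The two tests must agree on effect direction for every
        signature probe (the role of a second moderated test)."""
        expr, det, ann, _ = small_cohort
        norm = pp.normalize_per_gene(pp.normalize_per_chip(expr))
        det = DetectionMatrix(det.data.loc[norm.probe_ids, norm.sample_ids])
        sig_m, tab_m = de.derive_signature(norm, det, ann, method="moderated")
        _, tab_c = de.derive_signature(norm, det, ann, method="classical")
        ids = sig_m.probe_ids
        assert np.all(
            np.sign(tab_m.loc[ids, "effect"]) == np.sign(tab_c.loc[ids, "effect"])
        )
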