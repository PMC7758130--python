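"""Moderated differential-expression machinery: fold changes, empirical-Bayes
shrinkage, moderated t/P/B, BH adjustment, and the DE calling rule."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mircrosstalk import diffexpr
from mircrosstalk.diffexpr import (
    ExpressionStudy,
    ModerationParams,
    bh_adjust,
    call_differential,
    fit_contrast,
    log2_fold_change,
    moderate_variances,
    moderated_t_test,
    pooled_residual_variance,
)
from mircrosstalk.errors import DegenerateInputError, InputError


def _two_group_study(ctl, exp):
    mat = pd.DataFrame(
        np.column_stack([np.atleast_2d(ctl), np.atleast_2d(exp)]),
        index=[f"g{i}" for i in range(np.atleast_2d(ctl).shape[0])],
        columns=["A1", "A2", "A3", "B1", "B2", "B3"][: len(ctl[0]) + len(exp[0])],
    )
    design = {c: c[0] for c in mat.columns}
    return ExpressionStudy(mat, design, contrasts=[("B", "A")])


def test_logfc_and_aveexpr_arithmetic():
    study = _two_group_study([[4.0, 4.2, 4.4]], [[5.1, 5.3, 5.5]])
    out = log2_fold_change(study, ("B", "A"))
    assert out["logFC"].iloc[0] == pytest.approx(1.1)
    assert out["AveExpr"].iloc[0] == pytest.approx(4.75)


def test_logfc_zero_for_identical_group_means():
    study = _two_group_study([[5.0, 6.0, 7.0]], [[7.0, 5.0, 6.0]])
    assert log2_fold_change(study, ("B", "A"))["logFC"].iloc[0] == 0.0


def test_equal_variances_give_infinite_prior_df_and_no_dispersion():
    params = moderate_variances(np.full(50, 0.3), d=4)
    assert np.isinf(params.d0)
    assert params.s0_sq == pytest.approx(0.3)
    assert np.allclose(params.s_post_sq, 0.3)


def test_zero_prior_df_means_no_shrinkage():
    s2 = np.array([0.1, 0.5, 2.0])
    params = ModerationParams(d0=0.0, s0_sq=1.0, d=4.0,
                              s_post_sq=(0.0 * 1.0 + 4 * s2) / (0.0 + 4))
    assert np.allclose(params.s_post_sq, s2)


def test_all_zero_variances_rejected():
    with pytest.raises(DegenerateInputError):
        moderate_variances(np.zeros(10), d=4)


def test_hyperparameter_recovery_from_hierarchical_variances():
    """s^2 ~ s0^2*F(d, d0) with d0=4, s0^2=0.04 is recovered within bounds."""
    for seed in range(1, 21):
        rng = np.random.default_rng(seed)
        sigma2 = 4 * 0.04 / rng.chisquare(4, 2000)
        s2 = sigma2 * rng.chisquare(4, 2000) / 4
        params = moderate_variances(s2, d=4)
        assert 2.0 <= params.d0 <= 8.0
        assert 0.03 <= params.s0_sq <= 0.05


def test_shrinkage_lies_between_observed_and_prior():
    rng = np.random.default_rng(3)
    s2 = rng.chisquare(4, 500) / 4 * 0.2
    params = moderate_variances(s2, d=4)
    lo = np.minimum(s2, params.s0_sq) - 1e-12
    hi = np.maximum(s2, params.s0_sq) + 1e-12
    assert np.all((params.s_post_sq >= lo) & (params.s_post_sq <= hi))


def test_moderated_t_arithmetic():
    params = ModerationParams(d0=4.0, s0_sq=1.0, d=4.0, s_post_sq=np.array([1.0]))
    out = moderated_t_test(np.array([2.0]), params, n1=3, n2=3)
    assert out["t"].iloc[0] == pytest.approx(2.0 / np.sqrt(2 / 3))


def test_zero_logfc_gives_t_zero_p_one():
    params = ModerationParams(d0=4.0, s0_sq=1.0, d=4.0, s_post_sq=np.ones(3))
    out = moderated_t_test(np.array([0.0, 1.0, 0.0]), params, 3, 3)
    assert out.loc[0, "t"] == 0.0 and out.loc[0, "P"] == pytest.approx(1.0)


def test_infinite_prior_df_matches_z_test():
    logfc = np.array([0.5, -1.2, 2.0, 0.1])
    params = ModerationParams(d0=np.inf, s0_sq=0.25, d=4.0,
                              s_post_sq=np.full(4, 0.25))
    out = moderated_t_test(logfc, params, 3, 3)
    z = logfc / np.sqrt(0.25 * (2 / 3))
    assert np.allclose(out["P"], 2 * stats.norm.sf(np.abs(z)))


def test_zero_prior_df_equals_ordinary_pooled_t():
    """With no moderation the statistic is the classical two-sample t."""
    rng = np.random.default_rng(8)
    ctl = rng.normal(5, 0.5, (40, 3))
    exp = rng.normal(5.3, 0.5, (40, 3))
    study = _two_group_study(ctl, exp)
    fc = log2_fold_change(study, ("B", "A"))
    s2, d = pooled_residual_variance(study, ("B", "A"))
    params = ModerationParams(d0=0.0, s0_sq=1.0, d=float(d), s_post_sq=s2)
    out = moderated_t_test(fc["logFC"].to_numpy(), params, 3, 3)
    t_ref, p_ref = stats.ttest_ind(exp, ctl, axis=1)
    assert np.allclose(out["t"], t_ref)


def test_bh_adjust_hand_example_and_edge_cases():
    assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])
    assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)
    assert np.allclose(bh_adjust(np.full(5, 0.07)), 0.07)
    with pytest.raises(InputError):
        bh_adjust(np.array([0.5, 1.5]))


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
def test_bh_matches_hand_stepup(ps):
    """BH output equals an independently coded step-up procedure."""
    p = np.asarray(ps)
    order = np.argsort(p, kind="mergesort")
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    got = bh_adjust(p)
    assert np.allclose(got, adj)
    assert np.all(got >= p - 1e-12)


@pytest.mark.parametrize(
    "p,lfc,expected",
    [(0.04, 0.6, "up"), (0.04, -0.6, "down"), (0.04, 0.3, "none"),
     (0.06, 2.0, "none"), (0.05, 0.6, "none"), (0.04, 0.5, "up")],
)
def test_de_calling_thresholds(p, lfc, expected):
    rec = pd.DataFrame({"P": [p], "logFC": [lfc]})
    assert call_differential(rec)["direction"].iloc[0] == expected


def test_null_type_one_error_calibrated():
    from mircrosstalk import synthdata

    cfg = synthdata.SynthConfig(effect_size_log2=0.0, seed=5)
    bundle, _ = synthdata.generate_study(cfg)
    tab = fit_contrast(bundle.mrna, ("B", "A"))
    rate = (tab["P"] < 0.05).mean()
    tol = 2 * np.sqrt(0.05 * 0.95 / len(tab))
    assert abs(rate - 0.05) < tol


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_matches_limma_reference(tmp_path):
    """Full pipeline (logFC/t/P/adjP/B) agrees with Bioconductor limma."""
    rng = np.random.default_rng(7)
    n = 200
    sig2 = 4 * 0.04 / rng.chisquare(4, n)
    mat = (rng.uniform(4, 12, n)[:, None]
           + rng.standard_normal((n, 6)) * np.sqrt(sig2)[:, None])
    mat[:20, 3:] += 1.0
    df = pd.DataFrame(mat, index=[f"g{i:03d}" for i in range(n)],
                      columns=["A1", "A2", "A3", "B1", "B2", "B3"])
    df.to_csv(tmp_path / "mat.tsv", sep="\t")
    study = ExpressionStudy(df, {c: c[0] for c in df.columns},
                            contrasts=[("B", "A")])
    mine = fit_contrast(study, ("B", "A")).set_index("feature_id").sort_index()
    script = f"""
    suppressMessages(library(limma))
    x <- as.matrix(read.delim("{tmp_path}/mat.tsv", row.names=1))
    design <- cbind(A=rep(c(1,0),each=3), B=rep(c(0,1),each=3))
    fit <- lmFit(x, design)
    fit <- contrasts.fit(fit, makeContrasts(B-A, levels=design))
    fit <- eBayes(fit, proportion=0.01)
    tt <- topTable(fit, number=Inf, sort.by="none")
    write.table(data.frame(feature_id=rownames(tt), tt),
                "{tmp_path}/r.tsv", sep="\\t", row.names=FALSE, quote=FALSE)
    """
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "r.tsv", sep="\t", index_col=0).sort_index()
    for mine_col, ref_col in [("logFC", "logFC"), ("AveExpr", "AveExpr"),
                              ("t", "t"), ("P", "P.Value"),
                              ("adjP", "adj.P.Val"), ("B", "B")]:
        assert np.abs(mine[mine_col] - ref[ref_col]).max() < 1e-8
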