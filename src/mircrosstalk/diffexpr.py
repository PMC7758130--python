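"""Empirical-Bayes moderated differential expression for two-group contrasts.

Implements the standard moderated t workflow on log2 intensity matrices:
per-feature pooled residual variances are shrunk toward a prior variance
``s0_sq`` with prior degrees of freedom ``d0`` estimated by method of moments
on log variances (matching the moments of a log F distribution), the moderated
t is referred to a t distribution on ``d0 + d`` degrees of freedom, and a
log-posterior-odds B statistic is reported with prior differential-expression
proportion 0.01.  Differential features are called at raw P < 0.05 and
|log2FC| >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from mircrosstalk.errors import DegenerateInputError, InputError

P_CUT = 0.05
LFC_CUT = 0.5
DE_PRIOR_PROPORTION = 0.01

#: Output column order of the differential-expression report tables.
REPORT_COLUMNS = [
    "Gene",
    "logFC",
    "AveExpr",
    "t value",
    "P value",
    "Adj. P value",
    "B value",
    "Regulation pattern",
]


@dataclass
class ExpressionStudy:
    """A log2 expression matrix plus its sample-to-group design.

    matrix: features x samples DataFrame of log2 intensities (no NaNs).
    design: mapping sample id -> group label (e.g. "A".."D").
    contrasts: ordered (experimental, control) group pairs.
    """

    matrix: pd.DataFrame
    design: Mapping[str, str]
    contrasts: Sequence[tuple[str, str]] = (("B", "A"), ("D", "C"))

    def __post_init__(self) -> None:
        missing = [s for s in self.design if s not in self.matrix.columns]
        if missing:
            raise InputError(f"design samples absent from matrix: {missing}")
        if self.matrix.isna().any().any():
            raise InputError("expression matrix contains missing values")
        for exp, ctl in self.contrasts:
            for grp in (exp, ctl):
                if len(self.group_samples(grp)) < 2:
                    raise InputError(
                        f"contrast group {grp!r} has fewer than 2 samples"
                    )

    def group_samples(self, group: str) -> list[str]:
        return [s for s, g in self.design.items() if g == group]


@dataclass
class ModerationParams:
    """Empirical-Bayes variance moderation hyperparameters and posteriors.

    s_post_sq = (d0*s0_sq + d*s2) / (d0 + d) per feature; s_post_sq = s0_sq
    when d0 is infinite.
    """

    d0: float
    s0_sq: float
    d: float
    s_post_sq: np.ndarray = field(repr=False)


def log2_fold_change(
    study: ExpressionStudy, contrast: tuple[str, str]
) -> pd.DataFrame:
    """Per-feature logFC (experimental - control group mean) and AveExpr."""
    exp_group, ctl_group = contrast
    exp_cols = study.group_samples(exp_group)
    ctl_cols = study.group_samples(ctl_group)
    if not exp_cols or not ctl_cols:
        raise InputError(f"empty group in contrast {contrast}")
    exp_mean = study.matrix[exp_cols].mean(axis=1)
    ctl_mean = study.matrix[ctl_cols].mean(axis=1)
    ave = study.matrix[exp_cols + ctl_cols].mean(axis=1)
    return pd.DataFrame({"logFC": exp_mean - ctl_mean, "AveExpr": ave})


def pooled_residual_variance(
    study: ExpressionStudy, contrast: tuple[str, str]
) -> tuple[np.ndarray, int]:
    """Pooled within-group variance s^2 and residual df d = n1 + n2 - 2."""
    exp_cols = study.group_samples(contrast[0])
    ctl_cols = study.group_samples(contrast[1])
    n1, n2 = len(exp_cols), len(ctl_cols)
    x1 = study.matrix[exp_cols].to_numpy()
    x2 = study.matrix[ctl_cols].to_numpy()
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    d = n1 + n2 - 2
    return ss / d, d


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration on 1/trigamma (monotone)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(s2: np.ndarray, d: float) -> ModerationParams:
    """Estimate (d0, s0_sq) by method of moments on log s^2 and shrink.

    Under the hierarchical model s^2 ~ s0^2 * F(d, d0), log s^2 has mean
    log s0^2 + digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2) and excess
    variance trigamma(d0/2) beyond the sampling term trigamma(d/2); matching
    those moments yields the estimates.  Zero excess variance gives d0 = inf
    with s0_sq the mean of s^2 (complete shrinkage to a common variance).
    """
    s2 = np.asarray(s2, dtype=float)
    if d < 1:
        raise InputError(f"residual df must be >= 1 (got {d})")
    if np.any(s2 < 0):
        raise InputError("variances must be nonnegative")
    if np.all(s2 == 0):
        raise DegenerateInputError("all residual variances are zero")
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if len(e) > 1 else 0.0
    excess = evar - float(special.polygamma(1, d / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(
            np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
        s_post = (d0 * s0_sq + d * s2) / (d0 + d)
    else:
        # no excess dispersion beyond sampling noise: point-mass prior; the
        # arithmetic mean is the unbiased estimate of the common variance
        d0 = np.inf
        s0_sq = float(s2.mean())
        s_post = np.full_like(s2, s0_sq)
    return ModerationParams(d0=d0, s0_sq=s0_sq, d=float(d), s_post_sq=s_post)


def _tmixture(
    tstat: np.ndarray,
    stdev_unscaled: float,
    df_total: float,
    proportion: float,
    v0_lim: tuple[float, float],
) -> float:
    """Estimate the prior variance of true log fold changes among DE features.

    Moment-matching on the top |t| quantiles under a two-component mixture
    (the standard companion estimator to the moderated t's B statistic).
    """
    ngenes = len(tstat)
    ntarget = int(np.ceil(proportion / 2.0 * ngenes))
    if ntarget < 1:
        return v0_lim[0]
    p = max(ntarget / ngenes, proportion)
    tabs = np.sort(np.abs(tstat))[::-1][:ntarget]
    v1 = stdev_unscaled**2
    r = np.arange(1, ntarget + 1)
    p0 = 2.0 * stats.t.sf(tabs, df=df_total)
    ptarget = ((r - 0.5) / ngenes - (1.0 - p) * p0) / p
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if np.any(pos):
        qtarget = stats.t.isf(ptarget[pos] / 2.0, df=df_total)
        v0[pos] = v1 * ((tabs[pos] / qtarget) ** 2 - 1.0)
    v0 = np.clip(v0, v0_lim[0], v0_lim[1])
    return float(v0.mean())


def moderated_t_test(
    logfc: np.ndarray,
    params: ModerationParams,
    n1: int,
    n2: int,
    proportion: float = DE_PRIOR_PROPORTION,
) -> pd.DataFrame:
    """Moderated t, two-sided P on d0 + d df, and log-odds B per feature.

    t = logFC / sqrt(s_post_sq * (1/n1 + 1/n2)); P is referred to a t
    distribution on d0 + d df (normal limit when d0 is infinite, where the
    total df is capped at the pooled residual df as is conventional).
    """
    logfc = np.asarray(logfc, dtype=float)
    u = np.sqrt(1.0 / n1 + 1.0 / n2)
    # limits on the standardized coefficient prior sd, rescaled by the
    # residual-variance prior (coefficient sds between 0.1 and 4)
    v0_lim = (0.1**2 / params.s0_sq, 4.0**2 / params.s0_sq)
    se = u * np.sqrt(params.s_post_sq)
    t = np.where(logfc == 0.0, 0.0, logfc / se)
    t2 = t**2
    r = None
    if np.isfinite(params.d0):
        df_total = min(params.d0 + params.d, params.d * len(logfc))
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
        v0 = _tmixture(t, u, df_total, proportion, v0_lim)
        r = (u**2 + v0) / u**2
        kernel = (1.0 + df_total) / 2.0 * np.log(
            (t2 + df_total) / (t2 / r + df_total)
        )
    else:
        # Infinite prior df: the moderated t is a z statistic and the
        # posterior-odds kernel takes its Gaussian limit.
        p = 2.0 * stats.norm.sf(np.abs(t))
        v0 = _tmixture(t, u, params.d * max(len(logfc), 2), proportion, v0_lim)
        r = (u**2 + v0) / u**2
        kernel = t2 * (1.0 - 1.0 / r) / 2.0
    b = np.log(proportion / (1.0 - proportion)) - np.log(r) / 2.0 + kernel
    return pd.DataFrame({"t": t, "P": np.minimum(p, 1.0), "B": b})


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    records: pd.DataFrame, p_cut: float = P_CUT, lfc_cut: float = LFC_CUT
) -> pd.DataFrame:
    """Assign up/down/none direction calls: raw P < p_cut and |logFC| >= lfc_cut."""
    rec = records.copy()
    sig = rec["P"] < p_cut
    rec["direction"] = "none"
    rec.loc[sig & (rec["logFC"] >= lfc_cut), "direction"] = "up"
    rec.loc[sig & (rec["logFC"] <= -lfc_cut), "direction"] = "down"
    return rec


def fit_contrast(
    study: ExpressionStudy,
    contrast: tuple[str, str],
    p_cut: float = P_CUT,
    lfc_cut: float = LFC_CUT,
) -> pd.DataFrame:
    """Full moderated-DE table for one contrast, sorted by ascending P.

    Columns: feature_id (index), logFC, AveExpr, t, P, adjP, B, direction.
    Ties in P are broken by feature id for deterministic reports.
    """
    fc = log2_fold_change(study, contrast)
    s2, d = pooled_residual_variance(study, contrast)
    params = moderate_variances(s2, d)
    n1 = len(study.group_samples(contrast[0]))
    n2 = len(study.group_samples(contrast[1]))
    tpb = moderated_t_test(fc["logFC"].to_numpy(), params, n1, n2)
    tab = fc.copy()
    tab[["t", "P", "B"]] = tpb[["t", "P", "B"]].to_numpy()
    tab["adjP"] = bh_adjust(tab["P"].to_numpy())
    tab = call_differential(tab, p_cut=p_cut, lfc_cut=lfc_cut)
    tab = tab.rename_axis("feature_id").reset_index()
    tab = tab.sort_values(["P", "feature_id"], kind="mergesort").reset_index(drop=True)
    return tab[["feature_id", "logFC", "AveExpr", "t", "P", "adjP", "B", "direction"]]


def de_features(table: pd.DataFrame) -> dict[str, str]:
    """Mapping feature_id -> direction for called features only."""
    de = table[table["direction"] != "none"]
    return dict(zip(de["feature_id"], de["direction"]))


def report_table(table: pd.DataFrame) -> pd.DataFrame:
    """Rename a fit_contrast table to the published report column layout."""
    out = table.rename(
        columns={
            "feature_id": "Gene",
            "t": "t value",
            "P": "P value",
            "adjP": "Adj. P value",
            "B": "B value",
            "direction": "Regulation pattern",
        }
    )
    out["Regulation pattern"] = out["Regulation pattern"].map(
        {"up": "Up", "down": "Down", "none": "None"}
    )
    return out[REPORT_COLUMNS]
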