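"""Probe-level differential methylation with moderated statistics.

M-values are modelled probe-by-probe with a common fixed-effect design
(group or time, sex, plate, cell composition) and a shared within-subject
("consensus") correlation that turns repeated measures into a generalised
least squares fit under block equicorrelation. Per-probe residual
variances are shrunk towards a pooled prior by empirical Bayes
(moment-matching a scaled F to the variance distribution), yielding
moderated t-statistics with augmented degrees of freedom; p-values are
Benjamini-Hochberg adjusted within each contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "DesignSpec",
    "ModerationParams",
    "build_design",
    "estimate_consensus_correlation",
    "fit_moderated",
    "bh_adjust",
    "delta_beta",
]

CROSS_SECTIONAL_CONTRASTS = ("Ob.C", "ObDia.C", "ObDia.Ob")
LONGITUDINAL_CONTRASTS = ("0>6", "6>12")


@dataclass
class DesignSpec:
    """Fixed-effect design, subject blocking and contrast vectors."""

    X: pd.DataFrame  # samples x columns
    blocks: pd.Series  # subject id per sample
    contrasts: dict[str, np.ndarray]
    mode: str


@dataclass
class ModerationParams:
    """Empirical-Bayes prior for the residual variances."""

    d0: float  # prior degrees of freedom, may be inf
    s0_sq: float
    d_residual: float  # per-probe residual df (common design => common d_g)


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(arr)
        diag = np.abs(np.diag(R))
        aliased = list(X.columns[diag < 1e-8 * max(diag.max(), 1.0)])
        raise ValueError(f"design not full rank; aliased columns: {aliased}")


def build_design(
    samplesheet: pd.DataFrame,
    proportions: pd.DataFrame,
    mode: str,
) -> DesignSpec:
    """Treatment-coded design matrix with subject blocks and contrasts.

    ``mode='cross_sectional'`` uses group (C reference) as the independent
    variable; ``'longitudinal'`` uses timepoint (t0 reference). Covariates:
    sex, plate (first level reference) and cell proportions with one cell
    type dropped to break the sum-to-one collinearity.
    """
    if mode not in ("cross_sectional", "longitudinal"):
        raise ValueError(f"unknown mode {mode!r}")
    var = "group" if mode == "cross_sectional" else "timepoint"
    levels = sorted(samplesheet[var].unique())
    if len(levels) < 2:
        raise ValueError(f"{var} has fewer than 2 levels; nothing to contrast")

    X = pd.DataFrame(index=samplesheet.index)
    X["intercept"] = 1.0
    ref = {"group": "C", "timepoint": "t0"}[var]
    for lv in levels:
        if lv == ref:
            continue
        X[f"{var}_{lv}"] = (samplesheet[var] == lv).astype(float)
    X["sex_F"] = (samplesheet["sex"] == "F").astype(float)
    plates = sorted(samplesheet["plate"].unique())
    for pl in plates[1:]:
        X[f"plate_{pl}"] = (samplesheet["plate"] == pl).astype(float)
    # drop the most abundant cell type as reference
    props = proportions.loc[samplesheet.index]
    drop_ct = props.mean().idxmax()
    for ct in props.columns:
        if ct == drop_ct:
            continue
        X[f"cell_{ct}"] = props[ct].astype(float)

    _check_full_rank(X)

    cols = list(X.columns)
    contrasts: dict[str, np.ndarray] = {}

    def unit(col: str) -> np.ndarray:
        v = np.zeros(len(cols))
        v[cols.index(col)] = 1.0
        return v

    if mode == "cross_sectional":
        if "group_Ob" in cols:
            contrasts["Ob.C"] = unit("group_Ob")
        if "group_ObDia" in cols:
            contrasts["ObDia.C"] = unit("group_ObDia")
        if "group_Ob" in cols and "group_ObDia" in cols:
            contrasts["ObDia.Ob"] = unit("group_ObDia") - unit("group_Ob")
    else:
        if "timepoint_t6" in cols:
            contrasts["0>6"] = unit("timepoint_t6")
        if "timepoint_t6" in cols and "timepoint_t12" in cols:
            contrasts["6>12"] = unit("timepoint_t12") - unit("timepoint_t6")

    return DesignSpec(X=X, blocks=samplesheet["subject_id"].copy(), contrasts=contrasts, mode=mode)


# ---------------------------------------------------------------------------
# Block-equicorrelation machinery
# ---------------------------------------------------------------------------


def _block_transform(blocks: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal block-Helmert transform Q and per-row component codes.

    Under an equicorrelated residual covariance (1-rho) I + rho J within
    each subject block, Q diagonalises the covariance: the block-mean
    component has variance 1 + (m-1) rho and each within-block contrast
    has variance 1 - rho. Returns Q (n x n) and a matrix ``meta`` with
    rows (is_mean_component, block_size).
    """
    n = len(blocks)
    Q = np.zeros((n, n))
    meta = np.zeros((n, 2))
    row = 0
    for _, idx in blocks.groupby(blocks, sort=False).groups.items():
        pos = np.array([blocks.index.get_loc(i) for i in idx])
        m = len(pos)
        # block mean direction
        Q[row, pos] = 1.0 / np.sqrt(m)
        meta[row] = (1, m)
        row += 1
        # Helmert contrasts
        for j in range(1, m):
            v = np.zeros(m)
            v[:j] = 1.0
            v[j] = -j
            v /= np.linalg.norm(v)
            Q[row, pos] = v
            meta[row] = (0, m)
            row += 1
    return Q, meta


def _component_variances(meta: np.ndarray, rho: float) -> np.ndarray:
    is_mean = meta[:, 0] == 1
    m = meta[:, 1]
    v = np.where(is_mean, 1 + (m - 1) * rho, 1 - rho)
    return np.clip(v, 1e-8, None)


def estimate_consensus_correlation(
    M: pd.DataFrame,
    design: DesignSpec,
    n_probes_sub: int = 5000,
    seed: int = 0,
    grid: np.ndarray | None = None,
    trim: float = 0.15,
) -> float:
    """Consensus within-subject correlation by profile REML on a grid.

    For a seeded random subsample of probes, the restricted likelihood of
    the equicorrelated GLS model is evaluated on a rho grid (exactly, via
    the block-Helmert eigenbasis); each probe's REML maximiser is pooled
    by a trimmed mean on the atanh scale and mapped back with tanh,
    capped at 0.99.
    """
    blocks = design.blocks
    if blocks.value_counts().max() < 2:
        raise ValueError("no subject has repeated samples; correlation inestimable")
    rng = np.random.default_rng(seed)
    if len(M) > n_probes_sub:
        take = np.sort(rng.choice(len(M), size=n_probes_sub, replace=False))
        Y = M.iloc[take].to_numpy(dtype=float)
    else:
        Y = M.to_numpy(dtype=float)

    Q, meta = _block_transform(blocks)
    Xt = Q @ design.X.to_numpy(dtype=float)
    Yt = Y @ Q.T
    n, p = Xt.shape
    if grid is None:
        grid = np.arange(-0.20, 0.99, 0.01)

    best_ll = np.full(Y.shape[0], -np.inf)
    best_rho = np.zeros(Y.shape[0])
    for rho in grid:
        v = _component_variances(meta, rho)
        sw = 1.0 / np.sqrt(v)
        Xw = Xt * sw[:, None]
        Yw = Yt * sw[None, :]
        XtX = Xw.T @ Xw
        sign, logdet = np.linalg.slogdet(XtX)
        if sign <= 0:
            continue
        coefs = np.linalg.solve(XtX, Xw.T @ Yw.T)  # p x G
        resid = Yw - (Xw @ coefs).T
        rss = np.einsum("ij,ij->i", resid, resid)
        rss = np.clip(rss, 1e-300, None)
        ll = -0.5 * (np.log(v).sum() + logdet + (n - p) * np.log(rss))
        better = ll > best_ll
        best_ll[better] = ll[better]
        best_rho[better] = rho

    z = np.arctanh(np.clip(best_rho, -0.999, 0.999))
    pooled = float(np.tanh(stats.trim_mean(z, trim)))
    return float(min(pooled, 0.99))


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y (Newton on the log scale)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_f_dist(s_sq: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior (d0, s0^2) to residual variances."""
    s_sq = np.clip(s_sq, 1e-12, None)
    z = np.log(s_sq)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0_sq


def fit_moderated(
    M: pd.DataFrame,
    design: DesignSpec,
    rho: float,
    contrasts: dict[str, np.ndarray] | None = None,
    prior_df_override: float | None = None,
) -> tuple[dict[str, pd.DataFrame], ModerationParams]:
    """GLS fits under block equicorrelation + empirical-Bayes moderation.

    Returns one table per contrast (columns: coef_M, t, p, fdr) and the
    fitted moderation prior. ``prior_df_override=0`` recovers ordinary
    (unmoderated) GLS t-statistics.
    """
    contrasts = contrasts if contrasts is not None else design.contrasts
    Q, meta = _block_transform(design.blocks)
    v = _component_variances(meta, rho)
    sw = 1.0 / np.sqrt(v)
    Xw = (Q @ design.X.to_numpy(dtype=float)) * sw[:, None]
    Yw = (M.to_numpy(dtype=float) @ Q.T) * sw[None, :]
    n, p = Xw.shape
    d_resid = n - p
    if d_resid <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")

    XtX = Xw.T @ Xw
    XtX_inv = np.linalg.inv(XtX)
    coefs = XtX_inv @ Xw.T @ Yw.T  # p x G
    resid = Yw - (Xw @ coefs).T
    s_sq = np.einsum("ij,ij->i", resid, resid) / d_resid

    if prior_df_override is not None:
        d0 = prior_df_override
        s0_sq = float(np.median(s_sq)) if np.isfinite(d0) and d0 > 0 else 1.0
    else:
        d0, s0_sq = _fit_f_dist(s_sq, d_resid)
    if np.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s_tilde_sq = s_sq
        df_total = d_resid
    else:
        s_tilde_sq = (d0 * s0_sq + d_resid * s_sq) / (d0 + d_resid)
        df_total = d0 + d_resid

    out: dict[str, pd.DataFrame] = {}
    for name, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        b = c @ coefs  # G
        u = float(np.sqrt(c @ XtX_inv @ c))
        t = b / (u * np.sqrt(s_tilde_sq))
        if np.isinf(df_total):
            pvals = 2 * stats.norm.sf(np.abs(t))
        else:
            pvals = 2 * stats.t.sf(np.abs(t), df_total)
        tab = pd.DataFrame(
            {"coef_M": b, "t": t, "p": pvals, "fdr": bh_adjust(pvals)},
            index=M.index,
        )
        out[name] = tab
    return out, ModerationParams(d0=d0, s0_sq=s0_sq, d_residual=float(d_resid))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def delta_beta(
    beta: pd.DataFrame, samplesheet: pd.DataFrame, contrast: str
) -> pd.Series:
    """Mean beta difference for one contrast.

    Cross-sectional contrasts (``Ob.C`` etc.) pool all timepoints per
    group; longitudinal contrasts (``0>6``, ``6>12``) compare timepoint
    means (later minus earlier).
    """
    ss = samplesheet.loc[beta.columns]
    if contrast in CROSS_SECTIONAL_CONTRASTS:
        a, b = contrast.split(".")
        sel_a = ss.index[ss["group"] == {"Ob": "Ob", "ObDia": "ObDia"}[a]]
        sel_b = ss.index[ss["group"] == ("C" if b == "C" else b)]
    elif contrast in LONGITUDINAL_CONTRASTS:
        t_from, t_to = {"0>6": ("t0", "t6"), "6>12": ("t6", "t12")}[contrast]
        sel_a = ss.index[ss["timepoint"] == t_to]
        sel_b = ss.index[ss["timepoint"] == t_from]
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError(f"contrast {contrast!r} has an empty level")
    return beta[sel_a].mean(axis=1) - beta[sel_b].mean(axis=1)


def dmp_table(
    fit: pd.DataFrame, delta: pd.Series, fdr_cutoff: float = 0.05
) -> pd.DataFrame:
    """Merge a contrast fit with its delta-beta into the reported DMP table."""
    tab = fit.copy()
    tab["delta_beta"] = delta.loc[tab.index]
    tab["direction"] = np.where(tab["delta_beta"] > 0, "hyper", "hypo")
    tab["significant"] = tab["fdr"] < fdr_cutoff
    return tab
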