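"""Reference-based cell-type deconvolution (Houseman-style projection).

Each sample's methylome at cell-type-discriminating CpGs is projected onto
purified reference profiles under non-negativity with a soft sum-to-one
constraint, then the weights are renormalised to proportions. Cord-blood
samples (birth) use the cord reference panel; 6- and 12-month peripheral
samples use the peripheral panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

__all__ = [
    "CellReference",
    "CellProportions",
    "select_discriminating_cpgs",
    "estimate_proportions",
    "deconvolve_cohort",
]


@dataclass
class CellReference:
    """Purified cell-type beta profiles for one tissue."""

    tissue: str  # "cord" or "peripheral"
    betas: pd.DataFrame  # probes x cell types, values in (0, 1)

    @property
    def cell_types(self) -> list[str]:
        return list(self.betas.columns)


@dataclass
class CellProportions:
    """Estimated per-sample cell-type weights (non-negative, sum to 1)."""

    proportions: pd.DataFrame  # samples x cell types
    residual_norm: pd.Series
    tissue: str


def select_discriminating_cpgs(
    reference: CellReference, n_per_type: int = 100
) -> set[str]:
    """Top one-vs-rest probes per cell type, both directions.

    For each cell type the probes are ranked by the one-vs-rest
    t-statistic of reference betas; the top ``n_per_type / 2`` in each
    direction are taken and the union over cell types returned.
    """
    R = reference.betas
    k = R.shape[1]
    if k < 2:
        raise ValueError("need at least 2 cell types to discriminate")
    half = max(n_per_type // 2, 1)
    chosen: set[str] = set()
    for ct in R.columns:
        target = R[ct].to_numpy()
        rest = R.drop(columns=ct).to_numpy()
        rest_mean = rest.mean(axis=1)
        rest_sd = rest.std(axis=1, ddof=1) if k > 2 else np.full(len(target), 0.0)
        tstat = (target - rest_mean) / np.sqrt(rest_sd**2 / max(k - 1, 1) + 1e-4)
        order = np.argsort(tstat, kind="stable")
        n_take = min(half, len(order))
        if half > len(order):
            warnings.warn("n_per_type exceeds available probes; capped")
        chosen.update(R.index[order[:n_take]])
        chosen.update(R.index[order[-n_take:]])
    # drop probes that do not discriminate at all
    spread = R.loc[sorted(chosen)].max(axis=1) - R.loc[sorted(chosen)].min(axis=1)
    informative = set(spread.index[spread > 1e-8])
    if not informative:
        raise ValueError("no discriminating probes: reference columns are identical")
    return informative


def estimate_proportions(
    beta: pd.DataFrame,
    reference: CellReference,
    probe_set: set[str] | None = None,
    sum_tol: float = 0.15,
) -> CellProportions:
    """Constrained projection of each sample onto the reference panel.

    Solves min ||b - R w||^2 subject to w >= 0 with a soft sum-to-one row
    (augmented-system NNLS), then renormalises w to sum exactly to 1. A
    pre-normalisation sum outside [1 - sum_tol, 1 + sum_tol] triggers a
    warning.
    """
    probes = sorted(probe_set) if probe_set is not None else list(reference.betas.index)
    missing = [p for p in probes if p not in beta.index or p not in reference.betas.index]
    if missing:
        raise ValueError(f"{len(missing)} probes of probe_set absent from inputs")
    R = reference.betas.loc[probes].to_numpy()
    if np.linalg.matrix_rank(R) < R.shape[1]:
        corr = np.corrcoef(R.T)
        pairs = [
            (reference.cell_types[i], reference.cell_types[j])
            for i in range(len(corr))
            for j in range(i + 1, len(corr))
            if abs(corr[i, j]) > 0.9999
        ]
        raise ValueError(f"rank-deficient reference; collinear cell types: {pairs}")

    lam = np.sqrt(R.shape[0])  # sum-constraint weight on the scale of the data
    A = np.vstack([R, lam * np.ones((1, R.shape[1]))])
    W = np.zeros((beta.shape[1], R.shape[1]))
    resid = np.zeros(beta.shape[1])
    B = beta.loc[probes].to_numpy()
    for s in range(beta.shape[1]):
        y = np.concatenate([B[:, s], [lam]])
        w, _ = nnls(A, y)
        total = w.sum()
        if not (1 - sum_tol <= total <= 1 + sum_tol):
            warnings.warn(
                f"sample {beta.columns[s]}: raw weight sum {total:.3f} outside "
                f"[{1 - sum_tol:.2f}, {1 + sum_tol:.2f}]"
            )
        W[s] = w / total if total > 0 else np.full_like(w, 1 / len(w))
        resid[s] = float(np.linalg.norm(B[:, s] - R @ W[s]))
    props = pd.DataFrame(W, index=beta.columns, columns=reference.cell_types)
    return CellProportions(props, pd.Series(resid, index=beta.columns), reference.tissue)


def deconvolve_cohort(
    beta: pd.DataFrame,
    samplesheet: pd.DataFrame,
    cord_reference: CellReference,
    peripheral_reference: CellReference,
    n_per_type: int = 100,
) -> dict[str, CellProportions]:
    """Tissue-routed deconvolution: t0 -> cord panel, t6/t12 -> peripheral."""
    out: dict[str, CellProportions] = {}
    for tissue, ref in (("cord", cord_reference), ("peripheral", peripheral_reference)):
        samples = samplesheet.index[samplesheet["tissue"] == tissue]
        if len(samples) == 0:
            continue
        probes = select_discriminating_cpgs(ref, n_per_type)
        probes &= set(beta.index)
        out[tissue] = estimate_proportions(beta[samples], ref, probes)
    return out
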