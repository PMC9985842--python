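"""Spatially-combined DMR calling in the comb-p style.

Per-probe p-values are converted to z-scores, their spatial
autocorrelation is estimated in base-pair lag bins, each probe's p is
smoothed by a correlation-aware Stouffer-Liptak combination over its
neighbourhood, significant "seed" probes are grown into candidate regions,
each region is re-scored by combining its raw p-values, and the combined p
is Sidak-corrected for the number of region-sized windows the tested
probes span. Final DMRs must have a Sidak p < 0.05, at least 3 CpGs, at
least 66% of member CpGs changing in the same direction, and an absolute
mean beta change above 1%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AcfProfile",
    "DMRRecord",
    "DmrParams",
    "estimate_acf",
    "stouffer_liptak",
    "smooth_and_seed",
    "grow_regions",
    "score_region",
    "filter_regions",
    "call_dmrs",
    "dmrs_to_bed",
]

_PMIN = 1e-15  # guards Phi^{-1} against infinities


@dataclass
class AcfProfile:
    """Spatial autocorrelation of p-value z-scores by base-pair lag bin."""

    bin_edges: np.ndarray  # len nbins+1, starting at 0... first bin is (0, bin_bp]
    corr: np.ndarray  # len nbins, clipped to [0, 1]

    def lookup(self, dist_bp: np.ndarray) -> np.ndarray:
        """Correlation for pairwise distances; 1 at lag 0, 0 beyond range."""
        dist_bp = np.asarray(dist_bp, dtype=float)
        out = np.zeros_like(dist_bp)
        out[dist_bp == 0] = 1.0
        idx = np.searchsorted(self.bin_edges[1:], dist_bp, side="left")
        inside = (dist_bp > 0) & (dist_bp <= self.bin_edges[-1])
        out[inside] = self.corr[idx[inside]]
        return out


@dataclass
class DmrParams:
    """Pinned comb-p style defaults; every value is surfaced in output headers."""

    seed_p: float = 0.01
    window_bp: int = 1000
    max_gap_bp: int = 1000
    acf_bin_bp: int = 50
    acf_max_lag_bp: int = 1000
    sidak_cutoff: float = 0.05
    min_probes: int = 3
    consistency: float = 0.66
    min_abs_delta: float = 0.01
    fdr_select: bool = True
    fdr_cutoff: float = 0.05


@dataclass
class DMRRecord:
    chrom: str
    start: int  # 0-based half-open
    end: int
    probe_ids: list[str]
    n_probes: int
    slk_p: float
    sidak_p: float
    mean_delta_beta: float
    consistency: float
    direction: str
    cgi_status: str = ""
    gene_region: str = ""


def _z_from_p(p: np.ndarray) -> np.ndarray:
    return stats.norm.isf(np.clip(p, _PMIN, 1 - _PMIN))


def estimate_acf(
    p: np.ndarray,
    chroms: np.ndarray,
    positions: np.ndarray,
    max_lag_bp: int = 1000,
    bin_bp: int = 50,
) -> AcfProfile:
    """Autocorrelation of z = Phi^{-1}(1-p) by pairwise-distance bin.

    Pairs are formed within chromosomes among probes at most ``max_lag_bp``
    apart; bins with fewer than 10 pairs inherit the previous bin's value.
    """
    z = _z_from_p(np.asarray(p, dtype=float))
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    edges = np.arange(0, max_lag_bp + bin_bp, bin_bp)
    nbins = len(edges) - 1
    pairs_a: list[np.ndarray] = [[] for _ in range(nbins)]
    pairs_b: list[np.ndarray] = [[] for _ in range(nbins)]

    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        pos = positions[mask]
        idx = np.flatnonzero(mask)
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        idx = idx[order]
        # two-pointer pair enumeration within max_lag_bp
        j_hi = np.searchsorted(pos, pos + max_lag_bp, side="right")
        for i in range(len(pos)):
            for j in range(i + 1, j_hi[i]):
                d = pos[j] - pos[i]
                if d == 0:
                    continue
                b = min(int((d - 1) // bin_bp), nbins - 1)
                pairs_a[b].append(idx[i])
                pairs_b[b].append(idx[j])

    if sum(len(a) for a in pairs_a) == 0:
        warnings.warn("no probe pairs within the ACF lag range; flat zero profile")
        return AcfProfile(bin_edges=edges.astype(float), corr=np.zeros(nbins))

    corr = np.zeros(nbins)
    prev = 0.0
    for b in range(nbins):
        if len(pairs_a[b]) < 10:
            if len(pairs_a[b]) > 0:
                warnings.warn(
                    f"ACF bin {b}: only {len(pairs_a[b])} pairs; carrying previous value"
                )
            corr[b] = prev
            continue
        za = z[np.asarray(pairs_a[b])]
        zb = z[np.asarray(pairs_b[b])]
        if np.std(za) == 0 or np.std(zb) == 0:
            corr[b] = prev
            continue
        r = np.corrcoef(za, zb)[0, 1]
        corr[b] = max(float(r), 0.0)  # negative estimates floored at 0
        prev = corr[b]
    return AcfProfile(bin_edges=edges.astype(float), corr=corr)


def _nearest_psd(corr: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= -1e-10:
        return corr
    warnings.warn("correlation matrix not PSD; repairing by eigenvalue clipping")
    vals = np.clip(vals, 1e-10, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def stouffer_liptak(p: np.ndarray, corr: np.ndarray) -> float:
    """Combine correlated p-values: z_comb = sum(z) / sqrt(1' Sigma 1)."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if p.size == 1:
        return float(p[0])
    corr = np.asarray(corr, dtype=float)
    corr = _nearest_psd(corr)
    z = _z_from_p(p)
    denom = corr.sum()
    if denom <= 0:
        denom = p.size
    z_comb = z.sum() / np.sqrt(denom)
    return float(stats.norm.sf(z_comb))


def smooth_and_seed(
    p: np.ndarray,
    chroms: np.ndarray,
    positions: np.ndarray,
    acf: AcfProfile,
    window_bp: int = 1000,
    seed_p: float = 0.01,
    fdr_select: bool = True,
    fdr_cutoff: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlation-aware smoothing of each probe's p over +/- window_bp.

    Returns (smoothed p, seed flags). Seeds require smoothed p < seed_p
    and, when ``fdr_select``, a BH-adjusted smoothed p below ``fdr_cutoff``
    — this is the "selected under an FDR threshold" step preceding the
    Sidak correction.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    smoothed = np.empty_like(p)

    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        idx = np.flatnonzero(mask)
        pos = positions[idx]
        order = np.argsort(pos, kind="stable")
        idx = idx[order]
        pos = pos[order]
        lo = np.searchsorted(pos, pos - window_bp, side="left")
        hi = np.searchsorted(pos, pos + window_bp, side="right")
        for k in range(len(idx)):
            nb = idx[lo[k] : hi[k]]
            if len(nb) == 1:
                smoothed[idx[k]] = p[idx[k]]
                continue
            dists = np.abs(pos[lo[k] : hi[k], None] - pos[None, lo[k] : hi[k]])
            corr = acf.lookup(dists)
            np.fill_diagonal(corr, 1.0)
            smoothed[idx[k]] = stouffer_liptak(p[nb], corr)

    seeds = smoothed < seed_p
    if fdr_select:
        fdr = multipletests(smoothed, method="fdr_bh")[1]
        seeds &= fdr < fdr_cutoff
    return smoothed, seeds


def grow_regions(
    seeds: np.ndarray,
    chroms: np.ndarray,
    positions: np.ndarray,
    max_gap_bp: int = 1000,
) -> list[tuple[str, np.ndarray]]:
    """Maximal runs of seed probes with inter-probe gaps <= max_gap_bp.

    Returns (chrom, member index array) pairs; member indices refer to the
    input arrays.
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    seeds = np.asarray(seeds, dtype=bool)
    regions: list[tuple[str, np.ndarray]] = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero((chroms == chrom) & seeds)
        if len(idx) == 0:
            continue
        pos = positions[idx]
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        breaks = np.flatnonzero(np.diff(pos) > max_gap_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(idx)]])
        for s, e in zip(starts, ends):
            regions.append((str(chrom), idx[s:e]))
    return regions


def score_region(
    member_p: np.ndarray,
    member_positions: np.ndarray,
    acf: AcfProfile,
    total_covered_bp: float,
) -> tuple[float, float]:
    """(Stouffer-Liptak p, Sidak p) for one candidate region.

    The Sidak correction exponent is the total base pairs spanned by the
    tested probes divided by the region width, i.e. the number of
    region-sized windows that could have been tested.
    """
    member_positions = np.asarray(member_positions)
    width = max(int(member_positions.max() - member_positions.min() + 1), 1)
    dists = np.abs(member_positions[:, None] - member_positions[None, :])
    corr = acf.lookup(dists)
    np.fill_diagonal(corr, 1.0)
    slk_p = stouffer_liptak(np.asarray(member_p, dtype=float), corr)
    exponent = max(total_covered_bp / width, 1.0)
    sidak_p = 1.0 - (1.0 - slk_p) ** exponent if slk_p < 1 else 1.0
    return slk_p, float(min(max(sidak_p, 0.0), 1.0))


def filter_regions(
    candidates: list[DMRRecord],
    params: DmrParams | None = None,
) -> list[DMRRecord]:
    """Apply the final DMR filters.

    Keep a region iff Sidak p < 0.05, it contains >= 3 CpGs, at least 66%
    of member CpGs change in the modal direction, and |mean delta beta|
    exceeds 1% — mixed and negligible-change regions are dropped.
    """
    params = params or DmrParams()
    kept = []
    for r in candidates:
        if r.sidak_p >= params.sidak_cutoff:
            continue
        if r.n_probes < params.min_probes:
            continue
        if r.consistency < params.consistency:
            continue
        if abs(r.mean_delta_beta) <= params.min_abs_delta:
            continue
        kept.append(r)
    return kept


def _region_record(
    chrom: str,
    member_idx: np.ndarray,
    probe_ids: np.ndarray,
    positions: np.ndarray,
    p: np.ndarray,
    delta_beta: np.ndarray,
    acf: AcfProfile,
    total_covered_bp: float,
) -> DMRRecord:
    pos = positions[member_idx]
    slk_p, sidak_p = score_region(p[member_idx], pos, acf, total_covered_bp)
    db = delta_beta[member_idx]
    signs = np.sign(db)
    n_pos = int((signs > 0).sum())
    n_neg = int((signs < 0).sum())
    modal = 1.0 if n_pos >= n_neg else -1.0
    consistency = max(n_pos, n_neg) / len(db) if len(db) else 0.0
    return DMRRecord(
        chrom=chrom,
        start=int(pos.min() - 1),  # manifest positions are 1-based
        end=int(pos.max()),
        probe_ids=list(probe_ids[member_idx]),
        n_probes=len(member_idx),
        slk_p=slk_p,
        sidak_p=sidak_p,
        mean_delta_beta=float(db.mean()),
        consistency=float(consistency),
        direction="hyper" if modal > 0 else "hypo",
    )


def call_dmrs(
    dmp: pd.DataFrame,
    manifest: pd.DataFrame,
    params: DmrParams | None = None,
) -> tuple[list[DMRRecord], list[DMRRecord]]:
    """Full region-calling pass for one contrast.

    ``dmp`` is a probe-indexed table with columns ``p`` and ``delta_beta``.
    Returns (final DMRs after filters, all scored candidates).
    """
    params = params or DmrParams()
    man = manifest.loc[dmp.index]
    order = np.lexsort((man["pos"].to_numpy(), man["chrom"].to_numpy()))
    probe_ids = dmp.index.to_numpy()[order]
    chroms = man["chrom"].to_numpy()[order]
    positions = man["pos"].to_numpy()[order]
    p = dmp["p"].to_numpy()[order]
    db = dmp["delta_beta"].to_numpy()[order]

    acf = estimate_acf(p, chroms, positions, params.acf_max_lag_bp, params.acf_bin_bp)
    _, seeds = smooth_and_seed(
        p, chroms, positions, acf, params.window_bp, params.seed_p,
        params.fdr_select, params.fdr_cutoff,
    )
    regions = grow_regions(seeds, chroms, positions, params.max_gap_bp)

    # correction exponent numerator: bp spanned by tested probes per chromosome
    total_bp = 0.0
    for chrom in pd.unique(chroms):
        pos = positions[chroms == chrom]
        if len(pos) > 1:
            total_bp += float(pos.max() - pos.min() + 1)

    candidates = [
        _region_record(chrom, idx, probe_ids, positions, p, db, acf, total_bp)
        for chrom, idx in regions
    ]
    return filter_regions(candidates, params), candidates


def dmrs_to_bed(dmrs: list[DMRRecord], name_prefix: str = "dmr") -> pd.DataFrame:
    """BED6+ table: coordinates are 0-based half-open."""
    rows = []
    for i, r in enumerate(dmrs, 1):
        score = -np.log10(max(r.sidak_p, _PMIN))
        rows.append(
            (
                r.chrom,
                r.start,
                r.end,
                f"{name_prefix}_{i}",
                round(float(score), 4),
                ".",
                r.n_probes,
                r.mean_delta_beta,
                r.consistency,
                r.direction,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "n_probes", "mean_delta_beta", "consistency", "direction",
        ],
    )
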