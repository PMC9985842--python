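"""Probe-level preprocessing: filtering, gap-signal detection, BMIQ-style
normalisation and the beta <-> M transform.

Beta values are methylation fractions in (0, 1); M-values are
``log2(beta / (1 - beta))``, the variance-stabilised scale used for linear
modelling. Filtering removes probes that fail detection in any sample, sit
on sex chromosomes, are cross-reactive, or overlap common SNPs — in that
order, so per-criterion counts are reproducible. Gap-signal probes
(multi-modal beta distributions, typically SNP-driven) are flagged with the
gaphunter rule. Type-II probe betas are rescaled onto the type-I scale with
a three-state (unmethylated / hemimethylated / methylated) beta-mixture
quantile map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "FilterReport",
    "GapHunterParams",
    "filter_probes",
    "gaphunter",
    "bmiq_normalize",
    "beta_to_m",
    "m_to_beta",
]


@dataclass
class FilterReport:
    """Per-criterion probe removal counts, attributed disjointly in order."""

    initial: int
    removed_detection_p: int = 0
    removed_sex_chrom: int = 0
    removed_cross_reactive: int = 0
    removed_snp: int = 0
    removed_gap_signal: int = 0
    final: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("initial", self.initial),
            ("detection_p", self.removed_detection_p),
            ("sex_chrom", self.removed_sex_chrom),
            ("cross_reactive", self.removed_cross_reactive),
            ("snp", self.removed_snp),
            ("gap_signal", self.removed_gap_signal),
            ("final", self.final),
        ]
        return pd.DataFrame(rows, columns=["criterion", "n_probes"])


@dataclass
class GapHunterParams:
    """Parameters of the gap-signal rule.

    A probe is a *gap signal* when its sorted betas contain a jump larger
    than ``threshold``; it is *outlier-driven* when all sample groups but
    one are small (each at most ``out_cutoff`` of the samples).
    """

    threshold: float = 0.25
    out_cutoff: float = 5 / 90
    discard_mode: str = "all_gap_signals"  # or "outlier_driven_only"

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("gap threshold must be in (0, 1)")
        if not 0 < self.out_cutoff < 0.5:
            raise ValueError("out_cutoff must be in (0, 0.5)")
        if self.discard_mode not in ("all_gap_signals", "outlier_driven_only"):
            raise ValueError(f"unknown discard_mode {self.discard_mode!r}")


def filter_probes(
    beta: pd.DataFrame,
    detp: pd.DataFrame,
    manifest: pd.DataFrame,
    detp_cutoff: float = 0.01,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove failing probes in a fixed order and account for each removal.

    Order: (1) detection p > ``detp_cutoff`` in *any* sample; (2) sex
    chromosome; (3) cross-reactive; (4) SNP-overlapping. Each probe is
    attributed to the first criterion that removes it.

    Returns the filtered beta matrix (detection-p columns aligned) and a
    :class:`FilterReport`.
    """
    if not beta.index.equals(detp.index) or not beta.columns.equals(detp.columns):
        raise ValueError("beta and detection-p matrices are misaligned")
    missing = beta.index.difference(manifest.index)
    if len(missing):
        raise ValueError(f"{len(missing)} probes absent from manifest (e.g. {missing[0]})")

    man = manifest.loc[beta.index]
    report = FilterReport(initial=len(beta))

    alive = pd.Series(True, index=beta.index)

    fail_detp = (detp > detp_cutoff).any(axis=1)
    report.removed_detection_p = int((alive & fail_detp).sum())
    alive &= ~fail_detp

    for flag, attr in (
        ("flag_sex_chrom", "removed_sex_chrom"),
        ("flag_cross_reactive", "removed_cross_reactive"),
        ("flag_snp", "removed_snp"),
    ):
        hit = man[flag].astype(bool) & alive
        setattr(report, attr, int(hit.sum()))
        alive &= ~hit

    report.final = int(alive.sum())
    return beta.loc[alive], report


def _gap_groups(sorted_beta: np.ndarray, threshold: float) -> list[int]:
    """Sizes of the sample groups delimited by gaps larger than threshold."""
    diffs = np.diff(sorted_beta)
    cuts = np.flatnonzero(diffs > threshold)
    bounds = np.concatenate([[0], cuts + 1, [len(sorted_beta)]])
    return list(np.diff(bounds))


def gaphunter(
    beta: pd.DataFrame, params: GapHunterParams | None = None
) -> tuple[set[str], pd.DataFrame]:
    """Flag probes whose beta distribution splits into clusters.

    Returns the set of probe ids to discard (per ``params.discard_mode``)
    and a table with ``is_gap`` / ``outlier_driven`` columns for every gap
    probe.
    """
    params = params or GapHunterParams()
    n = beta.shape[1]
    if n < 2:
        raise ValueError("gaphunter needs at least 2 samples")

    values = np.sort(beta.to_numpy(), axis=1)
    records = []
    for pid, row in zip(beta.index, values):
        groups = _gap_groups(row, params.threshold)
        if len(groups) < 2:
            continue
        cutoff = params.out_cutoff * n
        small = [g <= cutoff for g in groups]
        outlier_driven = sum(not s for s in small) <= 1
        records.append((pid, True, outlier_driven))

    table = pd.DataFrame(records, columns=["probe_id", "is_gap", "outlier_driven"])
    table = table.set_index("probe_id") if len(table) else table
    if params.discard_mode == "all_gap_signals":
        flagged = set(table.index) if len(table) else set()
    else:
        flagged = set(table.index[table["outlier_driven"]]) if len(table) else set()
    return flagged, table


# ---------------------------------------------------------------------------
# BMIQ-style normalisation
# ---------------------------------------------------------------------------


@dataclass
class BmiqParams:
    max_iter: int = 100
    tol: float = 1e-4
    init_cuts: tuple[float, float] = (0.2, 0.8)
    eps: float = 1e-6


@dataclass
class _BetaMixture:
    """Three-state beta mixture ordered U (low) < H < M (high)."""

    a: np.ndarray  # shape (3,)
    b: np.ndarray
    w: np.ndarray
    converged: bool = True

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        dens = np.stack(
            [self.w[k] * stats.beta.pdf(x, self.a[k], self.b[k]) for k in range(3)]
        )
        dens = np.clip(dens, 1e-300, None)
        return dens / dens.sum(axis=0)


def _fit_beta_mixture(x: np.ndarray, params: BmiqParams) -> _BetaMixture:
    """EM fit of a 3-state beta mixture with moment-matching M-step."""
    lo, hi = params.init_cuts
    resp = np.zeros((3, len(x)))
    resp[0] = x < lo
    resp[1] = (x >= lo) & (x <= hi)
    resp[2] = x > hi
    # guard: every state needs some mass to start
    resp += 1e-3
    resp /= resp.sum(axis=0)

    a = np.array([2.0, 5.0, 20.0])
    b = np.array([20.0, 5.0, 2.0])
    w = resp.mean(axis=1)
    ll_old = -np.inf
    converged = False
    for _ in range(params.max_iter):
        # M-step: weighted moment matching per component
        for k in range(3):
            wk = resp[k]
            sw = wk.sum()
            m = (wk * x).sum() / sw
            v = (wk * (x - m) ** 2).sum() / sw
            v = max(v, 1e-6)
            common = m * (1 - m) / v - 1
            if common <= 0:
                common = 1e-2
            a[k] = max(m * common, 1e-2)
            b[k] = max((1 - m) * common, 1e-2)
        w = resp.mean(axis=1)
        # E-step
        dens = np.stack([w[k] * stats.beta.pdf(x, a[k], b[k]) for k in range(3)])
        dens = np.clip(dens, 1e-300, None)
        tot = dens.sum(axis=0)
        resp = dens / tot
        ll = np.log(tot).sum()
        if abs(ll - ll_old) < params.tol * (abs(ll_old) + 1):
            converged = True
            break
        ll_old = ll
    order = np.argsort(a / (a + b))
    return _BetaMixture(a[order], b[order], w[order], converged)


def _state_cutpoints(mix: _BetaMixture, x: np.ndarray) -> tuple[float, float]:
    """Beta-value cutpoints separating U/H and H/M states.

    Assignment by value interval (rather than pointwise max responsibility)
    keeps the normalisation map monotone.
    """
    grid = np.linspace(1e-4, 1 - 1e-4, 2001)
    resp = mix.responsibilities(grid)
    state = resp.argmax(axis=0)
    u_idx = np.flatnonzero(state == 0)
    m_idx = np.flatnonzero(state == 2)
    u_cut = grid[u_idx].max() if len(u_idx) else 0.0
    m_cut = grid[m_idx].min() if len(m_idx) else 1.0
    if m_cut <= u_cut:  # degenerate overlap; split at midpoint
        mid = 0.5 * (u_cut + m_cut)
        u_cut, m_cut = mid, mid
    return float(u_cut), float(m_cut)


def bmiq_normalize(
    beta: pd.DataFrame,
    design_types: pd.Series,
    params: BmiqParams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Map type-II probe betas onto the type-I distribution, per sample.

    Per sample, a 3-state beta mixture is fitted separately to type-I and
    type-II betas; type-II unmethylated- and methylated-state betas are
    mapped by inverse-CDF quantile matching onto the corresponding type-I
    state, and the hemimethylated stretch in between is rescaled linearly
    (dilation) between the mapped boundaries. Type-I betas pass through
    unchanged. The fitted map is enforced to be monotone.

    ``seed`` is accepted for interface symmetry; the EM is deterministic.
    """
    params = params or BmiqParams()
    dt = design_types.loc[beta.index]
    is_one = (dt == "I").to_numpy()
    is_two = (dt == "II").to_numpy()
    if is_one.sum() < 100 or is_two.sum() < 100:
        raise ValueError("both design types need at least 100 probes")

    out = beta.copy()
    for col in beta.columns:
        x = beta[col].to_numpy()
        x1 = np.clip(x[is_one], params.eps, 1 - params.eps)
        x2 = np.clip(x[is_two], params.eps, 1 - params.eps)
        mix1 = _fit_beta_mixture(x1, params)
        mix2 = _fit_beta_mixture(x2, params)
        if not (mix1.converged and mix2.converged):
            logger.warning("BMIQ EM did not converge for sample %s; identity map", col)
            warnings.warn(f"BMIQ EM non-convergence for sample {col}; identity map")
            continue
        u_cut, m_cut = _state_cutpoints(mix2, x2)

        mapped = x2.copy()
        u_mask = x2 <= u_cut
        m_mask = x2 >= m_cut
        h_mask = ~(u_mask | m_mask)
        # inverse-CDF quantile matching for the outer states
        if u_mask.any():
            q = stats.beta.cdf(x2[u_mask], mix2.a[0], mix2.b[0])
            mapped[u_mask] = stats.beta.ppf(np.clip(q, 1e-12, 1 - 1e-12), mix1.a[0], mix1.b[0])
        if m_mask.any():
            q = stats.beta.cdf(x2[m_mask], mix2.a[2], mix2.b[2])
            mapped[m_mask] = stats.beta.ppf(np.clip(q, 1e-12, 1 - 1e-12), mix1.a[2], mix1.b[2])
        if h_mask.any():
            # dilation: linear rescale between the mapped state boundaries
            src_lo = u_cut
            src_hi = m_cut
            dst_lo = mapped[u_mask].max() if u_mask.any() else stats.beta.ppf(
                stats.beta.cdf(u_cut, mix2.a[0], mix2.b[0]), mix1.a[0], mix1.b[0]
            )
            dst_hi = mapped[m_mask].min() if m_mask.any() else stats.beta.ppf(
                stats.beta.cdf(m_cut, mix2.a[2], mix2.b[2]), mix1.a[2], mix1.b[2]
            )
            if dst_hi <= dst_lo:
                dst_lo, dst_hi = src_lo, src_hi  # fall back to identity span
            scale = (dst_hi - dst_lo) / max(src_hi - src_lo, 1e-12)
            mapped[h_mask] = dst_lo + (x2[h_mask] - src_lo) * scale

        # enforce monotonicity of the overall map in sorted-beta order
        order = np.argsort(x2, kind="stable")
        mapped[order] = np.maximum.accumulate(mapped[order])
        mapped = np.clip(mapped, params.eps, 1 - params.eps)

        new_col = x.copy()
        new_col[is_two] = mapped
        out[col] = new_col
    return out


def beta_to_m(beta, eps: float = 1e-6):
    """M = log2(beta / (1 - beta)) with betas clipped to [eps, 1 - eps]."""
    arr = np.clip(np.asarray(beta, dtype=float), eps, 1 - eps)
    m = np.log2(arr / (1 - arr))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (exact on unclipped values)."""
    arr = np.asarray(m, dtype=float)
    b = 1.0 / (1.0 + 2.0 ** (-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(b, index=m.index)
    return b
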