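"""Developmental vs maternal methylation interplay.

Developmental CpGs ("Dev CpGs") are probes differentially methylated in at
least one longitudinal window (birth->6 months or 6->12 months) whose
direction of change is preserved across the first year. They are crossed
with the maternal-condition contrasts by classifying mean beta differences
into Hyper (> +1%), Hypo (< -1%) and Equal (within +/-1%), testing the
direction association by Fisher's exact test, and tabulating Sankey-style
flow counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DevCpGSet",
    "define_dev_cpgs",
    "classify_by_delta",
    "direction_association",
    "sankey_counts",
]


@dataclass
class DevCpGSet:
    """Developmental probes with their preserved direction and provenance."""

    table: pd.DataFrame  # index probe_id; columns: direction, provenance

    @property
    def probes(self) -> pd.Index:
        return self.table.index

    def directions(self) -> pd.Series:
        return self.table["direction"]


def define_dev_cpgs(
    dmp_06: pd.DataFrame,
    dmp_612: pd.DataFrame,
    fdr_cutoff: float = 0.05,
) -> DevCpGSet:
    """Select probes changing in at least one longitudinal window with a
    preserved direction of change.

    ``dmp_06`` / ``dmp_612`` are probe-indexed tables with ``fdr`` and
    ``delta_beta`` columns for the 0>6 and 6>12 comparisons. A probe
    significant in only one window is kept unless the other window's
    delta-beta has the strictly opposite sign (zero does not contradict).
    Probes significant in both windows must agree in sign.
    """
    common = dmp_06.index.intersection(dmp_612.index)
    if not (len(common) == len(dmp_06) == len(dmp_612)):
        raise ValueError("probe universes of the two longitudinal tables differ")
    d06 = dmp_06.loc[common]
    d612 = dmp_612.loc[common]

    sig06 = d06["fdr"] < fdr_cutoff
    sig612 = d612["fdr"] < fdr_cutoff
    s06 = np.sign(d06["delta_beta"])
    s612 = np.sign(d612["delta_beta"])
    contradicts = (s06 * s612) < 0

    keep = (sig06 | sig612) & ~contradicts
    # direction = sign of the significant window(s); fall back to whichever is nonzero
    direction_sign = np.where(sig06, s06, s612)
    direction_sign = np.where(direction_sign == 0, np.where(s612 != 0, s612, s06), direction_sign)
    keep &= direction_sign != 0

    provenance = np.select(
        [sig06 & sig612, sig06, sig612], ["both", "0>6", "6>12"], default=""
    )
    tab = pd.DataFrame(
        {
            "direction": np.where(direction_sign > 0, "hyper", "hypo"),
            "provenance": provenance,
        },
        index=common,
    ).loc[keep]
    return DevCpGSet(tab)


def classify_by_delta(delta_beta: pd.Series, threshold: float = 0.01) -> pd.Series:
    """Three-way classification of mean methylation change.

    Hyper: delta > +threshold; Hypo: delta < -threshold; Equal otherwise
    (the boundary +/-threshold itself is Equal).
    """
    db = pd.Series(delta_beta, dtype=float)
    if not np.isfinite(db).all():
        raise ValueError("delta_beta contains non-finite values")
    out = pd.Series("Equal", index=db.index, dtype=object)
    out[db > threshold] = "Hyper"
    out[db < -threshold] = "Hypo"
    return out


def direction_association(
    dev_directions: pd.Series,
    maternal_labels: pd.Series,
    or_estimator: str = "haldane",
) -> tuple[pd.DataFrame, float, float]:
    """Fisher test of developmental vs maternal direction concordance.

    ``dev_directions`` holds 'hyper'/'hypo'; ``maternal_labels`` holds
    'Hyper'/'Hypo' (probes classified Equal must be excluded beforehand).
    Returns (2x2 count table, odds ratio, exact p).
    """
    from .annotate import _fisher

    common = dev_directions.index.intersection(maternal_labels.index)
    dev = dev_directions.loc[common].str.lower()
    mat = maternal_labels.loc[common].str.lower()
    if (mat == "equal").any():
        raise ValueError("maternal labels must exclude the Equal class")
    table = pd.crosstab(dev, mat).reindex(
        index=["hyper", "hypo"], columns=["hyper", "hypo"], fill_value=0
    )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("empty margin in the direction cross-table")
    a, b = int(table.iloc[0, 0]), int(table.iloc[0, 1])
    c, d = int(table.iloc[1, 0]), int(table.iloc[1, 1])
    odds, p = _fisher(a, b, c, d, or_estimator)
    return table, odds, p


def sankey_counts(labels: pd.Series, source: str = "all") -> pd.DataFrame:
    """Flow counts and largest-remainder integer percentages per class.

    Percentages are rounded so that they sum to 100 (largest-remainder
    rule); an empty input yields an empty table.
    """
    if len(labels) == 0:
        return pd.DataFrame(columns=["source", "destination", "n", "percent"])
    counts = labels.value_counts()
    total = int(counts.sum())
    raw = counts / total * 100.0
    floors = np.floor(raw).astype(int)
    shortfall = 100 - int(floors.sum())
    remainders = raw - floors
    order = np.argsort(-remainders.to_numpy(), kind="stable")
    pct = floors.copy()
    for i in order[:shortfall]:
        pct.iloc[i] += 1
    return pd.DataFrame(
        {
            "source": source,
            "destination": counts.index,
            "n": counts.to_numpy(),
            "percent": pct.to_numpy(),
        }
    ).reset_index(drop=True)
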