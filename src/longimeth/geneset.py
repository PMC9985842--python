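"""Probe-count-bias-aware gene-set over-representation testing.

Genes carrying more array probes are more likely to harbour at least one
significant CpG by chance; an over-representation test that ignores this is
anti-conservative. Here the per-gene selection probability is modelled as a
monotone function of probe count (isotonic regression of the selection
indicator on probe count); a gene set's bias odds ``w`` is the ratio of
mean fitted probability inside vs outside the set, and the p-value is the
upper tail of the Wallenius noncentral hypergeometric distribution with
those odds. With equal probe counts everywhere w = 1 and the test reduces
to the one-sided Fisher / central hypergeometric tail.
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
    "GeneSetResult",
    "map_probes_to_genes",
    "bias_weighted_test",
    "read_gmt",
    "write_gmt",
    "jaccard_table",
]


@dataclass
class GeneSetResult:
    set_id: str
    set_size: int
    n_selected_in_set: int
    bias_odds: float
    p_value: float
    fdr: float = np.nan


def map_probes_to_genes(
    manifest: pd.DataFrame,
) -> tuple[pd.Series, dict[str, list[str]]]:
    """Per-gene probe counts and a probe -> genes map.

    ``gene_symbol`` may hold several semicolon-separated genes; a
    multi-gene probe contributes to each. Intergenic probes (empty symbol)
    map to no gene.
    """
    probe_genes: dict[str, list[str]] = {}
    counts: dict[str, int] = {}
    for pid, sym in manifest["gene_symbol"].items():
        if not isinstance(sym, str) or not sym:
            probe_genes[pid] = []
            continue
        genes = sorted(set(g for g in sym.split(";") if g))
        probe_genes[pid] = genes
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return pd.Series(counts, dtype=int).sort_index(), probe_genes


def _selected_genes(
    probes: set[str], probe_genes: dict[str, list[str]]
) -> set[str]:
    out: set[str] = set()
    for p in probes:
        out.update(probe_genes.get(p, []))
    return out


def bias_weighted_test(
    selected: set[str],
    background: set[str],
    gene_sets: dict[str, set[str]],
    gene_counts: pd.Series,
    probe_genes: dict[str, list[str]],
) -> pd.DataFrame:
    """Wallenius-weighted over-representation test per gene set.

    ``selected``/``background`` are CpG probe ids (selected must be a
    subset of background). The gene universe is every gene with at least
    one background probe; selected genes are those with at least one
    selected probe.
    """
    from sklearn.isotonic import IsotonicRegression
    from statsmodels.stats.multitest import multipletests

    if not selected <= background:
        raise ValueError("selected probes must be a subset of the background")
    universe = sorted(_selected_genes(background, probe_genes))
    sel_genes = _selected_genes(selected, probe_genes)
    n_genes = len(universe)
    n_sel = len(sel_genes)
    if n_genes == 0 or n_sel == 0:
        raise ValueError("empty gene universe or empty selection")

    counts = gene_counts.reindex(universe).fillna(1).to_numpy(dtype=float)
    indicator = np.array([g in sel_genes for g in universe], dtype=float)
    iso = IsotonicRegression(y_min=1e-9, y_max=1 - 1e-9, increasing=True)
    fitted = iso.fit_transform(counts, indicator)
    fitted = pd.Series(fitted, index=universe)

    rows: list[GeneSetResult] = []
    for set_id, members in gene_sets.items():
        in_set = [g for g in universe if g in members]
        m = len(in_set)
        if m == 0:
            warnings.warn(f"gene set {set_id!r} has no genes in the universe; skipped")
            continue
        k = sum(g in sel_genes for g in in_set)
        mean_in = float(fitted.loc[in_set].mean())
        outside = fitted.drop(in_set)
        mean_out = float(outside.mean()) if len(outside) else mean_in
        # odds ratio of the mean fitted probabilities: Wallenius' noncentral
        # parameter is an odds, so a probability ratio would under-correct
        # when selection probabilities are large
        if 0 < mean_in < 1 and 0 < mean_out < 1:
            w = (mean_in / (1 - mean_in)) / (mean_out / (1 - mean_out))
        else:
            w = 1.0
        p = _wallenius_upper_tail(n_genes, m, n_sel, w, k)
        rows.append(GeneSetResult(set_id, m, k, w, p))

    df = pd.DataFrame(
        {
            "set_id": [r.set_id for r in rows],
            "set_size": [r.set_size for r in rows],
            "n_selected_in_set": [r.n_selected_in_set for r in rows],
            "bias_odds": [r.bias_odds for r in rows],
            "p": [r.p_value for r in rows],
        }
    )
    if len(df):
        df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["fdr"] = pd.Series(dtype=float)
    return df


def _wallenius_upper_tail(n_genes: int, set_size: int, n_drawn: int, w: float, k: int) -> float:
    """P(X >= k) for Wallenius' noncentral hypergeometric.

    X counts selected genes inside the set when ``n_drawn`` genes are drawn
    without replacement from ``n_genes`` with item odds ``w`` for set
    members. At w == 1 this is the central hypergeometric tail.
    """
    if k <= 0:
        return 1.0
    if abs(w - 1.0) < 1e-12:
        return float(stats.hypergeom.sf(k - 1, n_genes, set_size, n_drawn))
    dist = stats.nchypergeom_wallenius(n_genes, set_size, n_drawn, w)
    return float(dist.sf(k - 1))


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: fewer than 3 fields")
            name = parts[0]
            members = {g for g in parts[2:] if g}
            if not members:
                raise ValueError(f"malformed GMT line {lineno}: empty gene set {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, set[str]], path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def jaccard_table(gene_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Pairwise Jaccard similarity between gene sets (long format)."""
    names = sorted(gene_sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = len(gene_sets[a] & gene_sets[b])
            union = len(gene_sets[a] | gene_sets[b])
            rows.append((a, b, inter / union if union else 0.0))
    return pd.DataFrame(rows, columns=["set_a", "set_b", "jaccard"])
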