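"""Probe/region annotation and Fisher-exact feature enrichment.

Regions inherit the highest-precedence category among their member probes,
separately for CpG-island status and for gene location. Enrichment of a
selected probe set in an annotation feature is tested against the
post-filter array background with Fisher's exact test; the odds ratio is
the cross-product estimate with a Haldane (+0.5) correction when a cell is
zero.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = [
    "CGI_PRECEDENCE",
    "GENE_REGION_PRECEDENCE",
    "EnrichmentResult",
    "annotate_region",
    "enrichment_or",
    "enrichment_table",
]

CGI_PRECEDENCE = ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"]
GENE_REGION_PRECEDENCE = [
    "TSS1500",
    "TSS200",
    "5'UTR",
    "1stExon",
    "Body",
    "ExonBnd",
    "3'UTR",
    "Intergenic",
]

_CGI_RANK = {c: i for i, c in enumerate(CGI_PRECEDENCE)}
_GENE_RANK = {c: i for i, c in enumerate(GENE_REGION_PRECEDENCE)}


@dataclass
class EnrichmentResult:
    feature: str
    a: int  # selected & feature
    b: int  # selected & not feature
    c: int  # background-only & feature
    d: int  # background-only & not feature
    odds_ratio: float
    p_value: float


def annotate_region(
    cgi_statuses: Iterable[str], gene_regions: Iterable[str]
) -> tuple[str, str]:
    """Collapse member-probe annotations to one (CGI, gene-region) pair.

    The region takes the highest-precedence category present:
    Island > N_Shore > S_Shore > N_Shelf > S_Shelf > OpenSea, and
    TSS1500 > TSS200 > 5'UTR > 1stExon > Body > ExonBnd > 3'UTR > Intergenic.
    """
    cgi = list(cgi_statuses)
    gene = list(gene_regions)
    if not cgi or not gene:
        raise ValueError("annotate_region needs at least one probe")
    unknown = [c for c in cgi if c not in _CGI_RANK]
    unknown += [g for g in gene if g not in _GENE_RANK]
    if unknown:
        raise ValueError(f"unknown annotation categories: {sorted(set(unknown))}")
    return (
        min(cgi, key=_CGI_RANK.__getitem__),
        min(gene, key=_GENE_RANK.__getitem__),
    )


def _fisher(a: int, b: int, c: int, d: int, or_estimator: str) -> tuple[float, float]:
    p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    if or_estimator == "cmle":
        from scipy.stats.contingency import odds_ratio as _cmle_or

        res = _cmle_or([[a, b], [c, d]])
        return float(res.statistic), float(p)
    if min(a, b, c, d) == 0:
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a_, b_, c_, d_ = a, b, c, d
    return (a_ * d_) / (b_ * c_), float(p)


def enrichment_or(
    selected: set[str],
    background: set[str],
    feature_labels: pd.Series,
    feature: str,
    or_estimator: str = "haldane",
) -> EnrichmentResult:
    """Test enrichment of ``feature`` among ``selected`` vs the background.

    ``feature_labels`` maps every background probe to its category. The 2x2
    table crosses selected-vs-rest with feature-vs-not; p is the two-sided
    exact hypergeometric probability.
    """
    if not selected:
        raise ValueError("selected probe set is empty")
    if not selected <= background:
        raise ValueError("selected set must be a subset of the background")
    rest = background - selected
    if not rest:
        raise ValueError("selected set equals background; odds ratio undefined")
    labels = feature_labels.loc[list(background)]
    in_feat = set(labels.index[labels == feature])
    a = len(selected & in_feat)
    b = len(selected) - a
    c = len(rest & in_feat)
    d = len(rest) - c
    odds, p = _fisher(a, b, c, d, or_estimator)
    return EnrichmentResult(feature, a, b, c, d, odds, p)


def enrichment_table(
    selected: set[str],
    background: set[str],
    feature_labels: pd.Series,
    or_estimator: str = "haldane",
) -> pd.DataFrame:
    """Enrichment of every category of ``feature_labels``, BH-adjusted."""
    from statsmodels.stats.multitest import multipletests

    feats = sorted(feature_labels.loc[list(background)].unique())
    rows = [enrichment_or(selected, background, feature_labels, f, or_estimator) for f in feats]
    df = pd.DataFrame(
        {
            "feature": [r.feature for r in rows],
            "a": [r.a for r in rows],
            "b": [r.b for r in rows],
            "c": [r.c for r in rows],
            "d": [r.d for r in rows],
            "odds_ratio": [r.odds_ratio for r in rows],
            "p": [r.p_value for r in rows],
        }
    )
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
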