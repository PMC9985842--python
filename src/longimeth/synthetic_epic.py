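"""Synthetic EPIC-like methylation cohort with planted ground truth.

Generates a probe manifest with island/promoter-enriched annotation and
clustered genomic spacing, purified cell-type reference panels (cord blood
with nucleated red blood cells; peripheral blood), and a longitudinal
three-group cohort (control C, maternal obesity Ob, maternal obesity with
gestational diabetes ObDia) sampled at birth (t0, cord blood), 6 months
(t6) and 12 months (t12, sparse follow-up). Betas follow a bimodal
baseline; effects are planted on the logit scale and mixed through
timepoint-dependent cell composition, with subject random effects, plate
batch effects and probe-level noise. Every planted effect is recorded in a
``SimTruth`` ledger so downstream recovery is testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_deconv import CellReference

logger = logging.getLogger(__name__)

__all__ = [
    "CohortDesign",
    "TruthParams",
    "SimTruth",
    "generate_manifest",
    "build_cell_references",
    "simulate_cohort",
    "plant_probe_effects",
    "plant_dmrs",
    "classify_ogtt",
]

CGI_CATEGORIES = ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"]
GENE_CATEGORIES = [
    "TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "ExonBnd", "3'UTR", "Intergenic",
]

# EPIC-like background annotation proportions (island/promoter enriched
# relative to the genome; open sea still the largest class).
DEFAULT_CGI_PROPS = {
    "Island": 0.20, "N_Shore": 0.07, "S_Shore": 0.06,
    "N_Shelf": 0.03, "S_Shelf": 0.03, "OpenSea": 0.61,
}
DEFAULT_GENE_PROPS = {
    "TSS1500": 0.10, "TSS200": 0.08, "5'UTR": 0.09, "1stExon": 0.04,
    "Body": 0.35, "ExonBnd": 0.01, "3'UTR": 0.03, "Intergenic": 0.30,
}

CORD_CELL_TYPES = ["CD4T", "CD8T", "Bcell", "NK", "Gran", "Mono", "nRBC"]
PERIPHERAL_CELL_TYPES = ["CD4T", "CD8T", "Bcell", "NK", "Gran", "Mono"]


def _logit(x: np.ndarray) -> np.ndarray:
    return np.log(x / (1 - x))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_manifest(
    n_probes: int,
    n_chroms: int,
    seed: int,
    cgi_props: dict[str, float] | None = None,
    gene_props: dict[str, float] | None = None,
    flag_rate: float = 0.02,
    type_two_fraction: float = 0.84,
) -> pd.DataFrame:
    """Probe manifest with clustered spacing and EPIC-like annotation.

    Probes are laid out in clusters (median within-cluster gap ~150 bp) so
    that 1 kb windows routinely contain 3+ probes, as on the real array at
    CpG islands. Gene symbols are assigned in positional runs so genes
    carry several probes each.
    """
    if n_probes < 100 or n_chroms < 1:
        raise ValueError("need n_probes >= 100 and n_chroms >= 1")
    cgi_props = cgi_props or DEFAULT_CGI_PROPS
    gene_props = gene_props or DEFAULT_GENE_PROPS
    rng = np.random.default_rng(seed)

    per_chrom = np.full(n_chroms, n_probes // n_chroms)
    per_chrom[: n_probes % n_chroms] += 1

    rows = []
    gene_counter = 0
    probe_counter = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        pos = 10_000
        gene = None
        for _ in range(per_chrom[ci]):
            if rng.random() < 0.3:  # new cluster
                pos += int(rng.integers(2_000, 20_000))
                gene = None
            else:
                pos += int(rng.integers(30, 300))
            if gene is None or rng.random() < 0.15:
                gene_counter += 1
                gene = f"GENE{gene_counter:05d}"
            probe_counter += 1
            rows.append((f"cg{probe_counter:08d}", chrom, pos, gene))

    man = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "_gene"])
    n = len(man)
    man["design_type"] = np.where(rng.random(n) < type_two_fraction, "II", "I")
    man["cgi_status"] = rng.choice(
        list(cgi_props), size=n, p=np.array(list(cgi_props.values()))
    )
    man["gene_region"] = rng.choice(
        list(gene_props), size=n, p=np.array(list(gene_props.values()))
    )
    man["gene_symbol"] = np.where(man["gene_region"] == "Intergenic", "", man["_gene"])
    man = man.drop(columns="_gene")
    man["flag_sex_chrom"] = rng.random(n) < flag_rate
    man["flag_cross_reactive"] = rng.random(n) < flag_rate
    man["flag_snp"] = rng.random(n) < flag_rate
    # baseline beta: bimodal mixture with a hemimethylated minority
    comp = rng.choice(3, size=n, p=[0.45, 0.45, 0.10])
    mu = np.empty(n)
    mu[comp == 0] = rng.beta(2, 20, (comp == 0).sum())  # hypomethylated
    mu[comp == 1] = rng.beta(20, 2, (comp == 1).sum())  # hypermethylated
    mu[comp == 2] = rng.beta(10, 10, (comp == 2).sum())  # hemimethylated
    man["baseline_beta"] = np.clip(mu, 0.03, 0.97)
    return man.set_index("probe_id")


def build_cell_references(
    manifest: pd.DataFrame,
    seed: int,
    n_specific_per_type: int = 60,
) -> tuple[CellReference, CellReference]:
    """Synthetic purified-cell panels (cord, peripheral).

    Stand-ins for flow-sorted reference datasets: every cell type shares
    the manifest baseline except at its own discriminating probes, where
    its beta is displaced by more than 0.5 from the other types.
    """
    rng = np.random.default_rng(seed)
    base = manifest["baseline_beta"].to_numpy()
    total_types = len(CORD_CELL_TYPES) + len(PERIPHERAL_CELL_TYPES)
    n_specific_per_type = min(
        n_specific_per_type, max(len(base) // (2 * total_types), 1)
    )
    refs = []
    used: set[int] = set()
    for tissue, types in (("cord", CORD_CELL_TYPES), ("peripheral", PERIPHERAL_CELL_TYPES)):
        R = np.tile(base[:, None], (1, len(types)))
        for k in range(len(types)):
            avail = np.setdiff1d(np.arange(len(base)), np.fromiter(used, int, len(used)))
            pick = rng.choice(avail, size=n_specific_per_type, replace=False)
            used.update(pick.tolist())
            lo = base[pick] < 0.5
            R[pick, k] = np.where(lo, np.clip(base[pick] + 0.7, 0.05, 0.95),
                                  np.clip(base[pick] - 0.7, 0.05, 0.95))
        refs.append(
            CellReference(tissue, pd.DataFrame(R, index=manifest.index, columns=types))
        )
    return refs[0], refs[1]


@dataclass
class CohortDesign:
    """Cohort layout mirroring the study: 13/15/11 subjects, sparse t12."""

    n_subjects: dict[str, int] = field(
        default_factory=lambda: {"C": 13, "Ob": 15, "ObDia": 11}
    )
    n_t12: dict[str, int] = field(default_factory=lambda: {"C": 4, "Ob": 4, "ObDia": 4})
    n_male: dict[str, int] = field(default_factory=lambda: {"C": 8, "Ob": 11, "ObDia": 6})
    n_plates: int = 2

    def samplesheet(self) -> pd.DataFrame:
        rows = []
        sid = 0
        for group, n_sub in self.n_subjects.items():
            for j in range(n_sub):
                sid += 1
                subject = f"S{sid:03d}"
                sex = "M" if j < self.n_male.get(group, n_sub // 2) else "F"
                plate = f"P{sid % self.n_plates + 1}"
                tps = ["t0", "t6"] + (["t12"] if j < self.n_t12.get(group, 0) else [])
                for tp in tps:
                    tissue = "cord" if tp == "t0" else "peripheral"
                    rows.append(
                        (f"{subject}_{tp}", subject, group, tp, sex, plate, tissue)
                    )
        ss = pd.DataFrame(
            rows,
            columns=["sample_id", "subject_id", "group", "timepoint", "sex", "plate", "tissue"],
        ).set_index("sample_id")
        assert not ss.duplicated(subset=["subject_id", "timepoint"]).any()
        return ss


# timepoint-dependent composition: cord blood granulocyte/nRBC rich;
# lymphocyte fractions rise over the first year
DEFAULT_DIRICHLET = {
    "t0": {"CD4T": 8, "CD8T": 4, "Bcell": 4, "NK": 3, "Gran": 35, "Mono": 5, "nRBC": 6},
    "t6": {"CD4T": 18, "CD8T": 8, "Bcell": 8, "NK": 4, "Gran": 25, "Mono": 5},
    "t12": {"CD4T": 16, "CD8T": 8, "Bcell": 7, "NK": 5, "Gran": 28, "Mono": 5},
}


@dataclass
class TruthParams:
    """Simulation parameters and the planted-effect ledger."""

    subject_sd: float = 0.2  # logit scale; with noise_sd 0.2 gives ICC 0.5
    plate_sd: float = 0.1
    noise_sd: float = 0.2  # ~0.02-0.05 beta-scale SD, array-realistic
    dirichlet: dict[str, dict[str, float]] = field(
        default_factory=lambda: {t: dict(a) for t, a in DEFAULT_DIRICHLET.items()}
    )
    detp_fail_rate: float = 0.001
    # planted effects: rows probe_id, contrast, delta_beta, region_id
    effects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["probe_id", "contrast", "delta_beta", "region_id"]
        )
    )

    def add_effects(self, effects: pd.DataFrame) -> None:
        for _, row in effects.iterrows():
            if not -0.5 < row["delta_beta"] < 0.5:
                raise ValueError("planted effect sizes must lie in (-0.5, 0.5)")
        if self.effects.empty:
            self.effects = effects.reset_index(drop=True)
        else:
            self.effects = pd.concat([self.effects, effects], ignore_index=True)


@dataclass
class SimTruth:
    """Everything planted: effects, cell proportions, random effects."""

    effects: pd.DataFrame  # probe_id, contrast, delta_beta, realized aliases
    cell_proportions: pd.DataFrame  # samples x union cell types
    subject_effects: pd.Series
    params: TruthParams
    seed: int

    def region_members(self, region_id: str) -> list[str]:
        sel = self.effects[self.effects["region_id"] == region_id]
        return list(sel["probe_id"])


def plant_probe_effects(
    manifest: pd.DataFrame,
    contrast: str,
    n_probes: int,
    delta_beta: float,
    seed: int,
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Pick random unflagged probes and assign a constant planted effect."""
    rng = np.random.default_rng(seed)
    ok = manifest.index[
        ~(manifest["flag_sex_chrom"] | manifest["flag_cross_reactive"] | manifest["flag_snp"])
    ]
    if exclude:
        ok = ok.difference(exclude)
    # keep planted means inside (0.01, 0.99)
    mu = manifest.loc[ok, "baseline_beta"]
    ok = ok[(mu + delta_beta > 0.01) & (mu + delta_beta < 0.99)]
    pick = rng.choice(ok, size=n_probes, replace=False)
    return pd.DataFrame(
        {"probe_id": pick, "contrast": contrast, "delta_beta": delta_beta, "region_id": ""}
    )


def plant_dmrs(
    manifest: pd.DataFrame,
    contrast: str,
    n_regions: int,
    probes_per_region: int,
    delta_beta: float,
    seed: int,
    window_bp: int = 1000,
) -> pd.DataFrame:
    """Plant effects on isolated probe clusters forming tight regions.

    A plantable region is a complete spatial cluster of exactly
    ``probes_per_region`` probes: consecutive gaps within the cluster are
    at most ``window_bp`` and the cluster is separated from its neighbours
    by more than ``window_bp``, so the planted region and the spatial unit
    a region caller sees coincide (as a real DMR spans a whole CpG
    cluster).
    """
    rng = np.random.default_rng(seed)
    flagged = manifest["flag_sex_chrom"] | manifest["flag_cross_reactive"] | manifest["flag_snp"]
    man_sorted = manifest.sort_values(["chrom", "pos"])
    ids = man_sorted.index.to_numpy()
    chroms = man_sorted["chrom"].to_numpy()
    pos = man_sorted["pos"].to_numpy()
    mu = man_sorted["baseline_beta"].to_numpy()
    fl = flagged.loc[man_sorted.index].to_numpy()

    # cluster boundaries: chromosome change or gap beyond the window
    new_cluster = np.ones(len(ids), dtype=bool)
    same_chrom = chroms[1:] == chroms[:-1]
    new_cluster[1:] = ~same_chrom | (np.diff(pos) > window_bp)
    starts = np.flatnonzero(new_cluster)
    ends = np.append(starts[1:], len(ids))

    candidates = []
    for i, j in zip(starts, ends):
        if j - i != probes_per_region:
            continue
        if fl[i:j].any():
            continue
        if np.any(mu[i:j] + delta_beta <= 0.01) or np.any(mu[i:j] + delta_beta >= 0.99):
            continue
        candidates.append(i)
    rng.shuffle(candidates)
    if len(candidates) < n_regions:
        raise ValueError(
            f"only {len(candidates)}/{n_regions} plantable clusters found"
        )
    rows = []
    for taken, i in enumerate(candidates[:n_regions], start=1):
        rid = f"{contrast}_dmr{taken:03d}"
        for pid in ids[i : i + probes_per_region]:
            rows.append((pid, contrast, delta_beta, rid))
    return pd.DataFrame(rows, columns=["probe_id", "contrast", "delta_beta", "region_id"])


def _effect_applies(contrast: str, group: str, timepoint: str) -> bool:
    """Which samples carry a planted contrast effect.

    Cross-sectional effects shift the first-named group at every
    timepoint; longitudinal effects are persistent changes acquired at the
    later timepoint (0>6 shifts t6 and t12; 6>12 shifts t12).
    """
    if contrast == "Ob.C":
        return group == "Ob"
    if contrast == "ObDia.C":
        return group == "ObDia"
    if contrast == "ObDia.Ob":
        return group == "ObDia"
    if contrast == "0>6":
        return timepoint in ("t6", "t12")
    if contrast == "6>12":
        return timepoint == "t12"
    raise ValueError(f"unknown contrast {contrast!r}")


def simulate_cohort(
    manifest: pd.DataFrame,
    references: tuple[CellReference, CellReference],
    design: CohortDesign,
    truth_params: TruthParams,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate betas, detection p-values and the sample sheet.

    beta(probe, sample) = sum_k w_k * expit(logit(ref_k) + planted shift +
    subject effect + plate effect + noise), with per-sample cell weights w
    from the timepoint's Dirichlet. Planted shifts are computed on the
    logit scale so that the noise-free mean beta moves by exactly the
    requested delta at the probe's baseline.
    """
    rng = np.random.default_rng(seed)
    ss = design.samplesheet()
    cord_ref, peri_ref = references
    probes = manifest.index

    # planted shift per probe per contrast, on the logit scale
    mu = manifest["baseline_beta"]
    shift_logit: dict[str, pd.Series] = {}
    for contrast, sub in truth_params.effects.groupby("contrast"):
        target = mu.loc[sub["probe_id"]].to_numpy() + sub["delta_beta"].to_numpy()
        if np.any(target <= 0.01) or np.any(target >= 0.99):
            raise ValueError("planted effect pushes mean beta outside (0.01, 0.99)")
        d = _logit(target) - _logit(mu.loc[sub["probe_id"]].to_numpy())
        s = pd.Series(0.0, index=probes)
        s.loc[sub["probe_id"].to_numpy()] = d
        shift_logit[contrast] = s

    subjects = ss["subject_id"].unique()
    subj_eff = pd.Series(
        rng.normal(0, truth_params.subject_sd, len(subjects)), index=subjects
    )
    plates = sorted(ss["plate"].unique())
    plate_eff = pd.Series(rng.normal(0, truth_params.plate_sd, len(plates)), index=plates)

    all_types = list(cord_ref.cell_types) + [
        t for t in peri_ref.cell_types if t not in cord_ref.cell_types
    ]
    props = pd.DataFrame(0.0, index=ss.index, columns=all_types)

    logit_ref = {
        "cord": _logit(np.clip(cord_ref.betas.to_numpy(), 1e-4, 1 - 1e-4)),
        "peripheral": _logit(np.clip(peri_ref.betas.to_numpy(), 1e-4, 1 - 1e-4)),
    }
    panel_types = {"cord": cord_ref.cell_types, "peripheral": peri_ref.cell_types}

    n_probes = len(probes)
    beta = np.empty((n_probes, len(ss)))
    for s_idx, (sample, row) in enumerate(ss.iterrows()):
        tissue = row["tissue"]
        alpha_map = truth_params.dirichlet[row["timepoint"]]
        types = panel_types[tissue]
        alpha = np.array([alpha_map[t] for t in types], dtype=float)
        w = rng.dirichlet(alpha)
        props.loc[sample, types] = w

        shift = np.zeros(n_probes)
        for contrast, s in shift_logit.items():
            if _effect_applies(contrast, row["group"], row["timepoint"]):
                shift += s.to_numpy()
        offset = subj_eff[row["subject_id"]] + plate_eff[row["plate"]]
        noise = rng.normal(0, truth_params.noise_sd, n_probes) if truth_params.noise_sd > 0 else 0.0
        L = logit_ref[tissue] + (shift + offset + noise)[:, None]
        beta[:, s_idx] = _expit(L) @ w

    beta = np.clip(beta, 1e-6, 1 - 1e-6)
    beta_df = pd.DataFrame(beta, index=probes, columns=ss.index)

    detp = rng.uniform(0, 1e-3, size=beta.shape)
    fails = rng.random(beta.shape) < truth_params.detp_fail_rate
    detp[fails] = rng.uniform(0.011, 0.5, size=int(fails.sum()))
    detp_df = pd.DataFrame(detp, index=probes, columns=ss.index)

    truth = SimTruth(
        effects=truth_params.effects.copy(),
        cell_proportions=props,
        subject_effects=subj_eff,
        params=truth_params,
        seed=seed,
    )
    return beta_df, detp_df, ss, truth


# ---------------------------------------------------------------------------
# GDM screening (labels for simulated mothers)
# ---------------------------------------------------------------------------

OGTT_THRESHOLDS_MG_DL = (105.0, 190.0, 165.0, 145.0)  # fasting, 1h, 2h, 3h
GCT_CUTOFF_MG_DL = 140.0


def classify_ogtt(gct_mg_dl: float, ogtt_values_mg_dl) -> str:
    """Two-step gestational diabetes screen.

    A 50 g glucose challenge above 140 mg/dL triggers the full 100 g OGTT;
    GDM requires at least two of the four plasma values (fasting, 1 h,
    2 h, 3 h) to be equal to or above 105 / 190 / 165 / 145 mg/dL.
    """
    vals = list(ogtt_values_mg_dl)
    if len(vals) != 4:
        raise ValueError("OGTT requires exactly 4 plasma glucose values")
    if gct_mg_dl <= 0 or any(v <= 0 for v in vals):
        raise ValueError("glucose values must be positive")
    if gct_mg_dl <= GCT_CUTOFF_MG_DL:
        return "gct_negative"
    n_meet = sum(v >= t for v, t in zip(vals, OGTT_THRESHOLDS_MG_DL))
    return "gdm" if n_meet >= 2 else "no_gdm"
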