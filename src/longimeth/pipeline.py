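"""End-to-end orchestration of the longitudinal methylome analysis.

Runs simulate -> preprocess -> deconvolve -> DMP -> DMR -> annotate ->
trajectories -> interplay -> gene-set enrichment on a synthetic cohort,
writing each stage's artifacts as TSV plus a run log that records every
parameter actually used. All randomness derives from one root seed,
expanded deterministically per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import cell_deconv, dmp_model, dmr_caller, geneset, interplay, preprocess
from . import synthetic_epic as sim
from . import trajectory
from .io import ensure_dir, write_matrix, write_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_KNOWN_KEYS = {
    "seed", "n_probes", "n_chroms", "detp_cutoff", "gap_threshold", "gap_out_cutoff",
    "fdr_cutoff", "sidak_cutoff", "dmr_min_probes", "dmr_consistency",
    "dmr_min_abs_delta", "dmr_seed_p", "dmr_window_bp", "class_threshold",
    "n_planted_dmp", "planted_delta", "n_planted_dmr", "dmr_probes_per_region",
    "run_bmiq", "subject_sd", "noise_sd", "plate_sd", "k_range",
}


@dataclass
class RunConfig:
    """Pipeline parameters; thresholds default to the study's values."""

    seed: int = 1
    n_probes: int = 6000
    n_chroms: int = 4
    detp_cutoff: float = 0.01
    gap_threshold: float = 0.25
    gap_out_cutoff: float = 5 / 90
    fdr_cutoff: float = 0.05
    sidak_cutoff: float = 0.05
    dmr_min_probes: int = 3
    dmr_consistency: float = 0.66
    dmr_min_abs_delta: float = 0.01
    dmr_seed_p: float = 0.01
    dmr_window_bp: int = 1000
    class_threshold: float = 0.01
    n_planted_dmp: int = 200
    planted_delta: float = 0.10
    n_planted_dmr: int = 10
    dmr_probes_per_region: int = 5
    run_bmiq: bool = False
    subject_sd: float = 0.2
    noise_sd: float = 0.2
    plate_sd: float = 0.1
    k_range: tuple[int, int] = (2, 8)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.k_range, list):
            cfg.k_range = tuple(cfg.k_range)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages; returns a dict of key in-memory results."""
    out = ensure_dir(out_dir)
    log_lines = [f"config_hash={config.config_hash()}"]
    for k, v in asdict(config).items():
        log_lines.append(f"param {k}={v}")
    t_start = time.time()
    results: dict = {"config": config}

    def stage(name):
        log_lines.append(f"stage {name} t={time.time() - t_start:.1f}s")
        logger.info("stage %s", name)

    try:
        # ---- simulate ----------------------------------------------------
        stage("simulate")
        seed = _stage_seed(config.seed, "simulate")
        manifest = sim.generate_manifest(config.n_probes, config.n_chroms, seed)
        cord_ref, peri_ref = sim.build_cell_references(manifest, seed + 1)
        design = sim.CohortDesign()
        tp = sim.TruthParams(
            subject_sd=config.subject_sd,
            noise_sd=config.noise_sd,
            plate_sd=config.plate_sd,
        )
        planted_probes = sim.plant_probe_effects(
            manifest, "Ob.C", config.n_planted_dmp, config.planted_delta, seed + 2
        )
        tp.add_effects(planted_probes)
        long_probes = sim.plant_probe_effects(
            manifest, "0>6", config.n_planted_dmp, config.planted_delta, seed + 3,
            exclude=set(planted_probes["probe_id"]),
        )
        tp.add_effects(long_probes)
        exclude = set(planted_probes["probe_id"]) | set(long_probes["probe_id"])
        dmr_truth = sim.plant_dmrs(
            manifest, "ObDia.C", config.n_planted_dmr,
            config.dmr_probes_per_region, config.planted_delta, seed + 4,
        )
        dmr_truth = dmr_truth[~dmr_truth["probe_id"].isin(exclude)]
        tp.add_effects(dmr_truth)
        beta, detp, ss, truth = sim.simulate_cohort(
            manifest, (cord_ref, peri_ref), design, tp, seed + 5
        )
        write_table(manifest, out / "manifest.tsv")
        write_table(ss, out / "samplesheet.tsv")
        write_matrix(beta, out / "beta_raw.tsv.gz")
        write_table(truth.effects, out / "truth_effects.tsv", index=False)
        results.update(manifest=manifest, samplesheet=ss, truth=truth)

        # ---- preprocess --------------------------------------------------
        stage("preprocess")
        beta_f, report = preprocess.filter_probes(beta, detp, manifest, config.detp_cutoff)
        gaps, _ = preprocess.gaphunter(
            beta_f,
            preprocess.GapHunterParams(config.gap_threshold, config.gap_out_cutoff),
        )
        report.removed_gap_signal = len(gaps & set(beta_f.index))
        beta_f = beta_f.drop(index=sorted(gaps & set(beta_f.index)))
        report.final = len(beta_f)
        if config.run_bmiq:
            beta_f = preprocess.bmiq_normalize(beta_f, manifest["design_type"])
        M = preprocess.beta_to_m(beta_f)
        write_table(report.as_frame(), out / "filter_report.tsv", index=False)
        write_matrix(beta_f, out / "beta_filtered.tsv.gz")
        results.update(beta=beta_f, M=M, filter_report=report)

        # ---- deconvolve --------------------------------------------------
        stage("deconv")
        deconv = cell_deconv.deconvolve_cohort(beta_f, ss, cord_ref, peri_ref)
        all_types = sorted({ct for d in deconv.values() for ct in d.proportions.columns})
        props = pd.DataFrame(0.0, index=ss.index, columns=all_types)
        for d in deconv.values():
            props.loc[d.proportions.index, d.proportions.columns] = d.proportions
        write_table(props, out / "cell_proportions.tsv")
        results["proportions"] = props

        # ---- DMP ---------------------------------------------------------
        stage("dmp")
        seed_dmp = _stage_seed(config.seed, "dmp")
        dmp_tables: dict[str, pd.DataFrame] = {}
        for mode in ("cross_sectional", "longitudinal"):
            dspec = dmp_model.build_design(ss, props, mode)
            rho = dmp_model.estimate_consensus_correlation(M, dspec, seed=seed_dmp)
            log_lines.append(f"consensus_rho {mode}={rho:.4f}")
            fits, mod = dmp_model.fit_moderated(M, dspec, rho)
            log_lines.append(f"moderation {mode} d0={mod.d0:.3g} s0_sq={mod.s0_sq:.3g}")
            for name, fit in fits.items():
                db = dmp_model.delta_beta(beta_f, ss, name)
                tab = dmp_model.dmp_table(fit, db, config.fdr_cutoff)
                dmp_tables[name] = tab
                safe = name.replace(">", "gt").replace(".", "_")
                write_table(tab, out / f"dmp_{safe}.tsv")
        results["dmp"] = dmp_tables

        # ---- DMR ---------------------------------------------------------
        stage("dmr")
        dmr_params = dmr_caller.DmrParams(
            seed_p=config.dmr_seed_p,
            window_bp=config.dmr_window_bp,
            max_gap_bp=config.dmr_window_bp,
            sidak_cutoff=config.sidak_cutoff,
            min_probes=config.dmr_min_probes,
            consistency=config.dmr_consistency,
            min_abs_delta=config.dmr_min_abs_delta,
        )
        dmrs: dict[str, list] = {}
        for name, tab in dmp_tables.items():
            final, _ = dmr_caller.call_dmrs(
                tab[["p", "delta_beta"]], manifest, dmr_params
            )
            for r in final:  # annotate regions
                sub = manifest.loc[r.probe_ids]
                r.cgi_status, r.gene_region = ann.annotate_region(
                    sub["cgi_status"], sub["gene_region"]
                )
            dmrs[name] = final
            safe = name.replace(">", "gt").replace(".", "_")
            write_table(dmr_caller.dmrs_to_bed(final, safe), out / f"dmr_{safe}.bed", index=False)
        results["dmrs"] = dmrs

        # ---- annotate (probe-level enrichment) ---------------------------
        stage("annotate")
        background = set(beta_f.index)
        sig_long = set(dmp_tables["0>6"].index[dmp_tables["0>6"]["significant"]])
        if sig_long:
            enr = ann.enrichment_table(
                sig_long, background, manifest["cgi_status"]
            )
            write_table(enr, out / "enrichment_cgi_0gt6.tsv", index=False)
            results["enrichment_cgi"] = enr

        # ---- trajectories ------------------------------------------------
        stage("cluster")
        dev_sig = sorted(
            set(dmp_tables["0>6"].index[dmp_tables["0>6"]["significant"]])
            | set(dmp_tables["6>12"].index[dmp_tables["6>12"]["significant"]])
        )
        if len(dev_sig) >= 20:
            means = pd.DataFrame(
                {
                    t: beta_f.loc[dev_sig, ss.index[ss["timepoint"] == t]].mean(axis=1)
                    for t in ("t0", "t6", "t12")
                }
            )
            scaled = trajectory.scale_trajectories(means)
            k_star, curve = trajectory.select_k(
                scaled, range(config.k_range[0], config.k_range[1] + 1),
                seed=_stage_seed(config.seed, "cluster"),
            )
            labels = trajectory.cluster_trajectories(
                scaled, k_star, seed=_stage_seed(config.seed, "cluster")
            )
            write_table(labels.to_frame(), out / "trajectory_clusters.tsv")
            write_table(curve.to_frame("wss"), out / "trajectory_wss.tsv")
            results.update(k_star=k_star, trajectory_labels=labels)
            log_lines.append(f"trajectory k_star={k_star}")

        # ---- interplay ---------------------------------------------------
        stage("interplay")
        dev = interplay.define_dev_cpgs(
            dmp_tables["0>6"], dmp_tables["6>12"], config.fdr_cutoff
        )
        if len(dev.table):
            mat_delta = dmp_tables["Ob.C"]["delta_beta"].loc[dev.probes]
            labels = interplay.classify_by_delta(mat_delta, config.class_threshold)
            sankey = interplay.sankey_counts(labels, source="DevCpG")
            write_table(sankey, out / "interplay_sankey.tsv", index=False)
            results.update(dev_cpgs=dev, maternal_labels=labels, sankey=sankey)
            keep = labels[labels != "Equal"]
            if len(keep) and keep.nunique() == 2 and dev.directions().loc[keep.index].nunique() == 2:
                table, odds, p = interplay.direction_association(
                    dev.directions().loc[keep.index], keep
                )
                results["direction_or"] = odds
                log_lines.append(f"interplay direction OR={odds:.3g} p={p:.3g}")

        # ---- geneset -----------------------------------------------------
        stage("enrich")
        gene_counts, probe_genes = geneset.map_probes_to_genes(manifest)
        rng = np.random.default_rng(_stage_seed(config.seed, "enrich"))
        genes = list(gene_counts.index)
        sets = {
            f"SYNSET_{i:02d}": set(rng.choice(genes, size=min(50, len(genes)), replace=False))
            for i in range(10)
        }
        sel = set(dmp_tables["0>6"].index[dmp_tables["0>6"]["significant"]]) & background
        if sel:
            gs = geneset.bias_weighted_test(sel, background, sets, gene_counts, probe_genes)
            write_table(gs, out / "geneset_0gt6.tsv", index=False)
            results["geneset"] = gs
    except Exception as exc:
        log_lines.append(f"FAILED stage={exc.__class__.__name__}: {exc}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline halted: {exc}") from exc

    log_lines.append(f"done t={time.time() - t_start:.1f}s")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return results
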