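"""Shared fixtures: small synthetic cohorts built once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import longimeth.cell_deconv as cd
import longimeth.synthetic_epic as sim


@pytest.fixture(scope="session")
def manifest():
    return sim.generate_manifest(3000, 3, seed=11)


@pytest.fixture(scope="session")
def references(manifest):
    return sim.build_cell_references(manifest, seed=12)


@pytest.fixture(scope="session")
def cohort(manifest, references):
    """Default-design cohort with planted cross-sectional and longitudinal
    probe effects (delta beta = 0.10)."""
    tp = sim.TruthParams()
    tp.add_effects(sim.plant_probe_effects(manifest, "Ob.C", 120, 0.10, seed=13))
    tp.add_effects(
        sim.plant_probe_effects(
            manifest, "0>6", 120, 0.10, seed=14, exclude=set(tp.effects["probe_id"])
        )
    )
    beta, detp, ss, truth = sim.simulate_cohort(
        manifest, references, sim.CohortDesign(), tp, seed=15
    )
    return beta, detp, ss, truth


def single_cell_reference(manifest):
    """Degenerate one-cell-type panel pair: removes composition effects."""
    betas = manifest[["baseline_beta"]].rename(columns={"baseline_beta": "WBC"})
    return (
        cd.CellReference("cord", betas.copy()),
        cd.CellReference("peripheral", betas.copy()),
    )


def null_truth_params(**overrides) -> sim.TruthParams:
    """No planted effects, no subject/plate variance: a clean null."""
    kw = dict(
        subject_sd=0.0,
        plate_sd=0.0,
        noise_sd=0.2,
        dirichlet={t: {"WBC": 1.0} for t in ("t0", "t6", "t12")},
        detp_fail_rate=0.0,
    )
    kw.update(overrides)
    return sim.TruthParams(**kw)
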