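"""Design construction, consensus-correlation recovery, empirical-Bayes
moderation and multiple-testing behaviour."""

import numpy as np
import pandas as pd
import pytest

import longimeth.dmp_model as dm
import longimeth.preprocess as pp
import longimeth.synthetic_epic as sim
from .conftest import null_truth_params, single_cell_reference


@pytest.fixture(scope="module")
def design_inputs(cohort):
    beta, _, ss, truth = cohort
    return ss, truth.cell_proportions


class TestBuildDesign:
    def test_expected_column_count(self, design_inputs):
        ss, props = design_inputs
        # 3 groups, 2 plates, 7 union cell types:
        # intercept + 2 group + 1 sex + 1 plate + 6 cell columns = 11
        spec = dm.build_design(ss, props, "cross_sectional")
        assert spec.X.shape[1] == 11
        assert set(spec.contrasts) == {"Ob.C", "ObDia.C", "ObDia.Ob"}

    def test_longitudinal_contrasts(self, design_inputs):
        ss, props = design_inputs
        spec = dm.build_design(ss, props, "longitudinal")
        assert set(spec.contrasts) == {"0>6", "6>12"}
        cols = list(spec.X.columns)
        c = spec.contrasts["6>12"]
        assert c[cols.index("timepoint_t12")] == 1
        assert c[cols.index("timepoint_t6")] == -1

    def test_single_level_rejected(self, design_inputs):
        ss, props = design_inputs
        only_c = ss[ss["group"] == "C"]
        with pytest.raises(ValueError, match="fewer than 2"):
            dm.build_design(only_c, props.loc[only_c.index], "cross_sectional")

    def test_confounded_plate_rejected(self, design_inputs):
        ss, props = design_inputs
        confounded = ss.copy()
        confounded["plate"] = confounded["group"].map(
            {"C": "P1", "Ob": "P2", "ObDia": "P3"}
        )
        with pytest.raises(ValueError, match="aliased"):
            dm.build_design(confounded, props, "cross_sectional")


def _null_m_values(manifest, subject_sd, seed, noise_sd=0.2):
    refs = single_cell_reference(manifest)
    tp = null_truth_params(subject_sd=subject_sd, noise_sd=noise_sd)
    beta, _, ss, truth = sim.simulate_cohort(
        manifest, refs, sim.CohortDesign(), tp, seed=seed
    )
    return pp.beta_to_m(beta), ss, truth


class TestConsensusCorrelation:
    def test_zero_subject_variance_gives_near_zero_rho(self, manifest):
        M, ss, truth = _null_m_values(manifest, subject_sd=0.0, seed=31)
        spec = dm.build_design(ss, truth.cell_proportions, "cross_sectional")
        rho = dm.estimate_consensus_correlation(M, spec, seed=1)
        assert abs(rho) < 0.05

    def test_icc_half_recovered(self, manifest):
        M, ss, truth = _null_m_values(manifest, subject_sd=0.2, seed=32)
        spec = dm.build_design(ss, truth.cell_proportions, "cross_sectional")
        rho = dm.estimate_consensus_correlation(M, spec, seed=1)
        assert 0.4 <= rho <= 0.6

    def test_duplicated_samples_cap_at_high_rho(self, manifest):
        M, ss, truth = _null_m_values(manifest, subject_sd=0.0, seed=33)
        # overwrite each subject's later samples with its first sample
        M2 = M.copy()
        for _, grp in ss.groupby("subject_id"):
            first = grp.index[0]
            for other in grp.index[1:]:
                M2[other] = M[first]
        spec = dm.build_design(ss, truth.cell_proportions, "cross_sectional")
        rho = dm.estimate_consensus_correlation(M2, spec, seed=1)
        assert rho >= 0.95
        assert rho <= 0.99

    def test_no_repeats_rejected(self, manifest):
        M, ss, truth = _null_m_values(manifest, subject_sd=0.0, seed=34)
        t0_only = ss[ss["timepoint"] == "t0"]
        spec = dm.build_design(t0_only, truth.cell_proportions, "cross_sectional")
        with pytest.raises(ValueError, match="repeated"):
            dm.estimate_consensus_correlation(M[t0_only.index], spec, seed=1)


class TestModeratedFit:
    def test_zero_prior_df_equals_ordinary_gls(self, manifest):
        M, ss, truth = _null_m_values(manifest, subject_sd=0.2, seed=35)
        spec = dm.build_design(ss, truth.cell_proportions, "cross_sectional")
        fits0, params0 = dm.fit_moderated(M.iloc[:300], spec, 0.5, prior_df_override=0)
        # recompute ordinary GLS t by hand via the same whitening path
        fits_eb, _ = dm.fit_moderated(M.iloc[:300], spec, 0.5)
        t0 = fits0["Ob.C"]["t"]
        t_eb = fits_eb["Ob.C"]["t"]
        assert params0.d0 == 0
        assert not np.allclose(t0, t_eb)  # moderation changes something
        # unmoderated t must reproduce scale: same coef, variance unshrunk
        pd.testing.assert_series_equal(
            fits0["Ob.C"]["coef_M"], fits_eb["Ob.C"]["coef_M"]
        )

    def test_equal_variances_drive_prior_df_to_infinity(self):
        rng = np.random.default_rng(5)
        n_sub, n_probes = 30, 200
        ss = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n_sub)],
                "group": ["C", "Ob"] * (n_sub // 2),
                "timepoint": "t0",
                "sex": ["M", "M", "F", "F"] * (n_sub // 4) + ["M", "F"] * ((n_sub % 4) // 2),
                "plate": "P1",
                "tissue": "cord",
            },
            index=[f"smp{i}" for i in range(n_sub)],
        )
        props = pd.DataFrame({"WBC": 1.0}, index=ss.index)
        Y = rng.standard_normal((n_probes, n_sub))
        # force all residual variances identical by scaling rows
        spec = dm.build_design(ss, props, "cross_sectional")
        M = pd.DataFrame(Y, index=[f"p{i}" for i in range(n_probes)], columns=ss.index)
        Mn = M.div(M.std(axis=1), axis=0)
        _, params = dm.fit_moderated(Mn, spec, 0.0)
        assert params.d0 > 50  # near-equal variances => very strong prior

    def test_moderation_shrinks_toward_prior(self, manifest):
        M, ss, truth = _null_m_values(manifest, subject_sd=0.2, seed=36)
        spec = dm.build_design(ss, truth.cell_proportions, "cross_sectional")
        fits, params = dm.fit_moderated(M.iloc[:500], spec, 0.5)
        assert params.d0 > 0 and params.s0_sq > 0

    def test_null_type_one_error_calibrated(self, manifest):
        M, ss, truth = _null_m_values(manifest, subject_sd=0.0, seed=37)
        spec = dm.build_design(ss, truth.cell_proportions, "cross_sectional")
        fits, _ = dm.fit_moderated(M, spec, 0.0)
        frac = (fits["Ob.C"]["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(M))
        assert abs(frac - 0.05) < 4 * se


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            dm.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_equal_and_single_inputs_unchanged(self):
        np.testing.assert_allclose(dm.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        np.testing.assert_allclose(dm.bh_adjust([0.42]), [0.42])

    def test_order_invariant_and_never_below_raw(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=50)
        adj = dm.bh_adjust(p)
        perm = rng.permutation(50)
        adj_perm = dm.bh_adjust(p[perm])
        np.testing.assert_allclose(adj[perm], adj_perm)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            dm.bh_adjust([0.5, 1.2])


class TestDeltaBeta:
    def test_identical_groups_give_zero(self, cohort):
        beta, _, ss, _ = cohort
        c_samples = ss.index[ss["group"] == "C"]
        # clone every control sample into a fake Ob group with identical betas
        clones = [f"clone_{s}" for s in c_samples]
        beta2 = pd.concat(
            [beta[c_samples], beta[c_samples].set_axis(clones, axis=1)], axis=1
        )
        ss2 = pd.concat(
            [ss.loc[c_samples], ss.loc[c_samples].set_axis(clones).assign(group="Ob")]
        )
        db = dm.delta_beta(beta2, ss2, "Ob.C")
        np.testing.assert_allclose(db, 0.0, atol=1e-12)

    def test_planted_delta_recovered(self, cohort):
        beta, _, ss, truth = cohort
        planted = truth.effects.query("contrast == 'Ob.C'")["probe_id"]
        db = dm.delta_beta(beta, ss, "Ob.C")
        assert abs(db.loc[planted].mean() - 0.10) < 0.02

    def test_direction_consistent_with_sign(self, cohort):
        beta, _, ss, _ = cohort
        db = dm.delta_beta(beta, ss, "0>6")
        tab = dm.dmp_table(
            pd.DataFrame(
                {"coef_M": 0.0, "t": 0.0, "p": 1.0, "fdr": 1.0}, index=beta.index
            ),
            db,
        )
        assert (tab.loc[tab["delta_beta"] > 0, "direction"] == "hyper").all()
        assert (tab.loc[tab["delta_beta"] <= 0, "direction"] == "hypo").all()

    def test_empty_level_rejected(self, cohort):
        beta, _, ss, _ = cohort
        no_t12 = ss[ss["timepoint"] != "t12"]
        with pytest.raises(ValueError, match="empty"):
            dm.delta_beta(beta[no_t12.index], no_t12, "6>12")
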