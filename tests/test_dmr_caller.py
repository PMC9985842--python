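"""Region calling: correlation-aware p combination, Sidak correction, seed
growth and the three region filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import longimeth.dmr_caller as dc


class TestStoufferLiptak:
    def test_single_p_unchanged(self):
        assert dc.stouffer_liptak([0.07], np.array([[1.0]])) == pytest.approx(0.07)

    def test_perfect_duplication_adds_nothing(self):
        p = dc.stouffer_liptak([0.025, 0.025], np.ones((2, 2)))
        assert p == pytest.approx(0.025, rel=1e-9)

    def test_independent_pair_closed_form(self):
        # z = Phi^-1(0.975); combined = 1 - Phi(2 z / sqrt(2))
        p = dc.stouffer_liptak([0.025, 0.025], np.eye(2))
        z = stats.norm.isf(0.025)
        expected = stats.norm.sf(2 * z / np.sqrt(2))
        assert p == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(0.00279, abs=5e-5)

    def test_non_psd_corr_repaired(self):
        corr = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.warns(UserWarning, match="PSD"):
            p = dc.stouffer_liptak([0.01, 0.5, 0.9], corr)
        assert 0 < p < 1

    def test_monte_carlo_oracle_agreement(self):
        """Analytic combined p vs 10^6-draw multivariate-normal simulation."""
        rng = np.random.default_rng(123)
        k, rho = 4, 0.4
        corr = np.full((k, k), rho)
        np.fill_diagonal(corr, 1.0)
        L = np.linalg.cholesky(corr)
        draws = rng.standard_normal((1_000_000, k)) @ L.T
        stat = draws.sum(axis=1) / np.sqrt(corr.sum())
        for pvals in ([0.05, 0.02, 0.10, 0.30], [0.5, 0.5, 0.5, 0.5],
                      [0.01, 0.01, 0.2, 0.8]):
            target = stats.norm.isf(pvals).sum() / np.sqrt(corr.sum())
            mc = (stat >= target).mean()
            analytic = dc.stouffer_liptak(pvals, corr)
            assert analytic >= 1e-4
            assert abs(analytic - mc) / mc < 0.10


class TestSidak:
    def test_zero_slk_stays_zero(self):
        slk, sidak = dc.score_region([1e-300], [100], _flat_acf(), 5000)
        assert sidak == 0.0 or sidak < 1e-250

    def test_exponent_one_is_identity(self):
        acf = _flat_acf()
        # one probe, width floored to 1, covered bp == 1
        slk, sidak = dc.score_region([0.03], [100], acf, 1)
        assert sidak == pytest.approx(slk)

    def test_closed_form_value(self):
        # slk = 0.01, exponent 50 -> 1 - 0.99^50
        assert 1 - (1 - 0.01) ** 50 == pytest.approx(0.39499, abs=1e-5)
        acf = _flat_acf()
        slk, sidak = dc.score_region([0.01], [100], acf, 50)
        assert sidak == pytest.approx(1 - (1 - slk) ** 50, rel=1e-12)

    def test_monotone_in_exponent(self):
        acf = _flat_acf()
        sidaks = [dc.score_region([0.02], [100], acf, m)[1] for m in (1, 10, 100, 1000)]
        assert all(np.diff(sidaks) > 0)


def _flat_acf(corr=0.0):
    return dc.AcfProfile(
        bin_edges=np.arange(0, 1050, 50, dtype=float), corr=np.full(20, corr)
    )


class TestEstimateAcf:
    def _positions(self, n, rng, spacing=100):
        return np.arange(n) * spacing + rng.integers(0, 10, n)

    def test_iid_uniform_p_gives_near_zero_profile(self):
        rng = np.random.default_rng(2)
        n = 4000
        pos = self._positions(n, rng)
        p = rng.uniform(size=n)
        acf = dc.estimate_acf(p, np.repeat("chr1", n), pos, 1000, 100)
        assert np.abs(acf.corr).max() < 0.08  # ~3 SE at thousands of pairs

    def test_ar1_process_gives_decreasing_profile(self):
        rng = np.random.default_rng(3)
        n = 6000
        pos = np.arange(n) * 100
        z = np.empty(n)
        z[0] = rng.standard_normal()
        phi = 0.8  # per-100bp decay
        for i in range(1, n):
            z[i] = phi * z[i - 1] + np.sqrt(1 - phi**2) * rng.standard_normal()
        p = stats.norm.sf(z)
        acf = dc.estimate_acf(p, np.repeat("chr1", n), pos, 500, 100)
        assert acf.corr[0] > 0.6
        assert all(np.diff(acf.corr) < 0.05)  # essentially monotone decreasing

    def test_single_probe_chromosomes_warn_and_zero(self):
        with pytest.warns(UserWarning, match="no probe pairs"):
            acf = dc.estimate_acf(
                np.array([0.5, 0.5]),
                np.array(["chr1", "chr2"]),
                np.array([100, 100]),
                1000,
                50,
            )
        assert (acf.corr == 0).all()


class TestSmoothAndSeed:
    def test_isolated_probe_keeps_raw_p(self):
        p = np.array([0.004, 0.8])
        chroms = np.array(["chr1", "chr1"])
        pos = np.array([100, 50_000])
        smoothed, seeds = dc.smooth_and_seed(
            p, chroms, pos, _flat_acf(), window_bp=1000, seed_p=0.01, fdr_select=False
        )
        assert smoothed[0] == pytest.approx(0.004)
        assert seeds[0] and not seeds[1]

    def test_concordant_run_strengthens_centre(self):
        p = np.full(5, 0.001)
        chroms = np.repeat("chr1", 5)
        pos = np.arange(5) * 200 + 100
        smoothed, _ = dc.smooth_and_seed(
            p, chroms, pos, _flat_acf(0.3), window_bp=1000, seed_p=0.01,
            fdr_select=False,
        )
        assert smoothed[2] <= 0.001

    def test_discordant_neighbours_dilute_centre(self):
        p = np.array([0.9, 0.001, 0.9])
        chroms = np.repeat("chr1", 3)
        pos = np.array([100, 300, 500])
        smoothed, _ = dc.smooth_and_seed(
            p, chroms, pos, _flat_acf(0.0), window_bp=1000, seed_p=0.01,
            fdr_select=False,
        )
        assert smoothed[1] > 0.001


class TestGrowRegions:
    def test_no_seeds_empty(self):
        out = dc.grow_regions(np.zeros(5, bool), np.repeat("chr1", 5),
                              np.arange(5) * 100)
        assert out == []

    def test_run_within_gap_is_one_region(self):
        seeds = np.array([True, True, True])
        out = dc.grow_regions(seeds, np.repeat("chr1", 3),
                              np.array([100, 200, 300]), max_gap_bp=500)
        assert len(out) == 1
        chrom, idx = out[0]
        assert chrom == "chr1" and list(idx) == [0, 1, 2]

    def test_large_gap_splits_regions(self):
        seeds = np.array([True, True])
        out = dc.grow_regions(seeds, np.repeat("chr1", 2),
                              np.array([100, 5000]), max_gap_bp=500)
        assert len(out) == 2


def _record(n_probes, sidak_p, deltas):
    signs = np.sign(deltas)
    n_pos, n_neg = int((signs > 0).sum()), int((signs < 0).sum())
    return dc.DMRRecord(
        chrom="chr1", start=0, end=100, probe_ids=[f"p{i}" for i in range(n_probes)],
        n_probes=n_probes, slk_p=sidak_p, sidak_p=sidak_p,
        mean_delta_beta=float(np.mean(deltas)),
        consistency=max(n_pos, n_neg) / n_probes,
        direction="hyper" if n_pos >= n_neg else "hypo",
    )


class TestFilterRegions:
    def test_two_probe_region_dropped_despite_tiny_p(self):
        r = _record(2, 1e-6, [0.05, 0.05])
        assert dc.filter_regions([r]) == []

    def test_mixed_direction_region_dropped(self):
        # 3 of 5 in the same direction = 60% < 66%
        r = _record(5, 1e-6, [0.05, 0.05, 0.05, -0.05, -0.05])
        assert dc.filter_regions([r]) == []

    def test_mean_delta_boundary(self):
        dropped = _record(4, 1e-6, [0.010] * 4)  # exactly 1%: dropped
        kept = _record(4, 1e-6, [0.011] * 4)
        assert dc.filter_regions([dropped]) == []
        assert dc.filter_regions([kept]) == [kept]

    def test_sidak_threshold(self):
        r = _record(4, 0.06, [0.05] * 4)
        assert dc.filter_regions([r]) == []


class TestEndToEnd:
    def test_planted_regions_recovered(self, manifest):
        """Planted 5-probe regions with strong p-values are found; isolated
        null probes are not."""
        rng = np.random.default_rng(6)
        import longimeth.synthetic_epic as sim

        truth = sim.plant_dmrs(manifest, "Ob.C", 8, 5, 0.10, seed=7)
        p = rng.uniform(size=len(manifest))
        dmp = pd.DataFrame(
            {"p": p, "delta_beta": rng.normal(0, 0.002, len(manifest))},
            index=manifest.index,
        )
        planted_probes = truth["probe_id"]
        dmp.loc[planted_probes, "p"] = rng.uniform(0, 1e-5, len(planted_probes))
        dmp.loc[planted_probes, "delta_beta"] = 0.10
        final, _ = dc.call_dmrs(dmp, manifest)
        # every planted region overlaps a reported DMR
        found = 0
        for rid, grp in truth.groupby("region_id"):
            probes = set(grp["probe_id"])
            if any(probes & set(r.probe_ids) for r in final):
                found += 1
        assert found >= 7  # at least 7 of 8
        # no reported region consists solely of null probes
        for r in final:
            assert set(r.probe_ids) & set(planted_probes)

    def test_output_regions_do_not_overlap(self, manifest):
        rng = np.random.default_rng(8)
        import longimeth.synthetic_epic as sim

        truth = sim.plant_dmrs(manifest, "Ob.C", 5, 5, 0.10, seed=9)
        dmp = pd.DataFrame(
            {"p": rng.uniform(size=len(manifest)),
             "delta_beta": rng.normal(0, 0.002, len(manifest))},
            index=manifest.index,
        )
        dmp.loc[truth["probe_id"], "p"] = 1e-6
        dmp.loc[truth["probe_id"], "delta_beta"] = 0.10
        final, _ = dc.call_dmrs(dmp, manifest)
        by_chrom: dict[str, list] = {}
        for r in final:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        for intervals in by_chrom.values():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert e1 <= s2
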