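"""Synthetic-data generator: determinism, distributional laws, construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from steeproot import rootgeom, simulate
from steeproot.simulate import (
    ForceCurveParams,
    RootSimParams,
    SimConfig,
    make_bulks,
    mutate_cds,
    simulate_bulk_theta,
    simulate_f2,
    simulate_force_curve,
    simulate_mutant_panel,
    simulate_root_polyline,
)

SMALL = dict(
    n_chromosomes=2,
    chrom_length_bp=1_000_000,
    marker_spacing_bp=100_000,
    causal_gene=("chr1", 500_000, 502_999),
)


class TestConfig:
    def test_rejects_bulks_larger_than_half_the_f2(self):
        with pytest.raises(ValueError, match="2 \\* bulk_size"):
            SimConfig(f2_size=20, bulk_size=15)

    def test_rejects_causal_gene_outside_genome(self):
        with pytest.raises(ValueError, match="causal gene"):
            SimConfig(causal_gene=("chr99", 1, 100))
        with pytest.raises(ValueError, match="bounds"):
            SimConfig(causal_gene=("chr1", 1, 10**12))

    def test_rejects_non_probability_error_rate(self):
        with pytest.raises(ValueError, match="probability"):
            SimConfig(base_error_rate=1.5)


class TestMutantPanel:
    def test_same_seed_gives_identical_tables(self):
        cfg = SimConfig(seed=7, **SMALL)
        panel1, _ = simulate_mutant_panel(cfg)
        panel2, _ = simulate_mutant_panel(cfg)
        assert panel1.to_csv() == panel2.to_csv()

    def test_zero_background_rate_leaves_only_causal_snvs(self):
        cfg = SimConfig(seed=3, background_mutation_rate=0.0, **SMALL)
        panel, truth = simulate_mutant_panel(cfg)
        assert len(panel) == cfg.n_focal_lines
        assert set(zip(panel["chrom"], panel["pos"])) == set(truth.causal_positions.values())

    def test_background_counts_follow_poisson_law(self):
        """~100 SNVs/line at 1/Mb on 100 Mb; chi-square GOF over 200 replicates."""
        lam = 100.0
        counts = []
        for seed in range(200):
            cfg = SimConfig(
                seed=seed, n_chromosomes=2, chrom_length_bp=50_000_000,
                background_mutation_rate=1.0, n_mutant_lines=10,
                causal_gene=("chr1", 500_000, 502_999), mean_depth=5.0,
            )
            _, truth = simulate_mutant_panel(cfg)
            counts.extend(len(v) for v in truth.background_positions.values())
        counts = np.asarray(counts)
        assert abs(counts.mean() - lam) < 2.0
        # bin the Poisson support on half-integer cuts so every expected count is >= 5
        cuts = np.unique(stats.poisson.ppf(np.linspace(0.01, 0.99, 12), lam)) - 0.5
        edges = np.concatenate([[-np.inf], cuts, [np.inf]])
        observed, _ = np.histogram(counts, bins=edges)
        probs = np.diff(stats.poisson.cdf(edges, lam))
        probs = probs / probs.sum()
        chi2, p = stats.chisquare(observed, probs * len(counts))
        assert p > 0.01

    def test_dv_given_dp_is_binomial_at_the_error_rate(self):
        cfg = SimConfig(seed=11, mean_depth=30.0, base_error_rate=0.02, **SMALL)
        panel, _ = simulate_mutant_panel(cfg)
        non_owner_dv = non_owner_dp = 0
        owner_ratios = []
        for line in cfg.line_names:
            owner = panel["owner"] == line
            non_owner_dv += panel.loc[~owner, f"DV_{line}"].sum()
            non_owner_dp += panel.loc[~owner, f"DP_{line}"].sum()
            dp = panel.loc[owner, f"DP_{line}"]
            owner_ratios.extend(panel.loc[owner, f"DV_{line}"][dp > 0] / dp[dp > 0])
        assert stats.binomtest(int(non_owner_dv), int(non_owner_dp), 0.02).pvalue > 0.01
        assert np.mean(owner_ratios) > 0.9

    def test_dv_never_exceeds_dp(self):
        cfg = SimConfig(seed=5, **SMALL)
        panel, _ = simulate_mutant_panel(cfg)
        for line in cfg.line_names:
            assert (panel[f"DV_{line}"] <= panel[f"DP_{line}"]).all()


class TestF2:
    def test_causal_genotypes_segregate_1_2_1(self):
        cfg = SimConfig(seed=2, f2_size=10_000, bulk_size=100, **SMALL)
        _, _, truth = simulate_f2(cfg)
        counts = np.bincount(truth.f2_causal_genotypes, minlength=3)
        _, p = stats.chisquare(counts, np.array([0.25, 0.5, 0.25]) * counts.sum())
        assert p > 0.01

    def test_phenotypes_segregate_3_to_1(self):
        cfg = SimConfig(seed=2, f2_size=10_000, bulk_size=100, **SMALL)
        _, _, truth = simulate_f2(cfg)
        n_wt = (truth.phenotypes == "wild-type").sum()
        n_steep = (truth.phenotypes == "steep").sum()
        _, p = stats.chisquare([n_wt, n_steep], np.array([0.75, 0.25]) * (n_wt + n_steep))
        assert p > 0.01
        # recessive: steep iff causal genotype 2
        assert ((truth.f2_causal_genotypes == 2) == (truth.phenotypes == "steep")).all()

    def test_zero_map_distance_coinherits_markers_perfectly(self):
        cfg = SimConfig(seed=4, cm_per_mb=0.0, **SMALL)
        markers, genotypes, _ = simulate_f2(cfg)
        for chrom in cfg.chromosomes:
            cols = markers.loc[markers["chrom"] == chrom, "marker"]
            geno = genotypes[cols].to_numpy()
            assert (geno == geno[:, [0]]).all()

    def test_every_plant_has_exactly_one_phenotype_class(self):
        cfg = SimConfig(seed=6, **SMALL)
        _, _, truth = simulate_f2(cfg)
        assert set(truth.phenotypes) <= {"wild-type", "steep"}
        assert len(truth.phenotypes) == cfg.f2_size


class TestBulkTheta:
    @staticmethod
    def _hand_built():
        """30 plants: 10 steep (aa, dosage 2); 20 wild-type as 1 AA : 2 Aa."""
        linked = np.array([2] * 10 + [0] * 7 + [1] * 13)  # 7 AA ~ 1/3, 13 Aa
        markers = pd.DataFrame({"marker": ["m1"], "chrom": ["chr1"], "pos": [100]})
        genotypes = pd.DataFrame({"m1": linked})
        return markers, genotypes

    def test_fully_linked_marker_gives_mendelian_thetas(self, rng):
        """Steep bulk theta -> 1; wild-type (1 AA : 2 Aa) -> ~1/3; delta ~ 4/9."""
        linked = np.array([2] * 15 + [0] * 5 + [1] * 10)
        markers = pd.DataFrame({"marker": ["m1"], "chrom": ["chr1"], "pos": [100]})
        genotypes = pd.DataFrame({"m1": linked})
        thetas = simulate_bulk_theta(
            markers, genotypes, np.arange(15, 30), np.arange(15), 0.0, rng
        )
        assert thetas["theta_bulk_mut"].iloc[0] == 1.0
        assert thetas["theta_bulk_wt"].iloc[0] == pytest.approx(1 / 3, abs=1e-12)
        delta = (thetas["theta_bulk_wt"] - thetas["theta_bulk_mut"]) ** 2
        assert delta.iloc[0] == pytest.approx(4 / 9, abs=1e-12)

    def test_unlinked_marker_sits_near_half_in_both_bulks(self):
        cfg = SimConfig(seed=8, f2_size=2000, bulk_size=500, **SMALL)
        markers, genotypes, truth = simulate_f2(cfg)
        rng = cfg.rng("bulks")
        wt, mut = make_bulks(truth.phenotypes, 500, rng)
        thetas = simulate_bulk_theta(markers, genotypes, wt, mut, 0.0, rng)
        unlinked = thetas[thetas["chrom"] == "chr2"]
        assert np.allclose(unlinked["theta_bulk_wt"], 0.5, atol=0.05)
        assert np.allclose(unlinked["theta_bulk_mut"], 0.5, atol=0.05)

    def test_monomorphic_marker_theta_exactly_zero(self, rng):
        markers = pd.DataFrame({"marker": ["m1"], "chrom": ["chr1"], "pos": [1]})
        genotypes = pd.DataFrame({"m1": np.zeros(30, dtype=int)})
        thetas = simulate_bulk_theta(markers, genotypes, np.arange(15), np.arange(15, 30), 0.0, rng)
        assert thetas["theta_bulk_wt"].iloc[0] == 0.0
        assert thetas["theta_bulk_mut"].iloc[0] == 0.0

    def test_overlapping_or_empty_bulks_rejected(self, rng):
        markers, genotypes = self._hand_built()
        with pytest.raises(ValueError, match="disjoint"):
            simulate_bulk_theta(markers, genotypes, np.array([0, 1]), np.array([1, 2]), 0.0, rng)
        with pytest.raises(ValueError, match="non-empty"):
            simulate_bulk_theta(markers, genotypes, np.array([], dtype=int), np.array([1]), 0.0, rng)

    def test_theta_always_within_unit_interval(self, rng):
        markers, genotypes = self._hand_built()
        thetas = simulate_bulk_theta(
            markers, genotypes, np.arange(10), np.arange(10, 30), 0.5, rng, n_replicates=3
        )
        for col in ("theta_bulk_wt", "theta_bulk_mut"):
            assert ((thetas[col] >= 0) & (thetas[col] <= 1)).all()


class TestInstruments:
    def test_noiseless_polyline_recovers_angle_exactly(self):
        params = RootSimParams(true_vertical_angle=30.0, waviness_sd=0.0, n_points=40)
        pts = simulate_root_polyline(params, 1)
        rec = rootgeom.vertical_angle(pts)
        assert rec.vertical_angle == pytest.approx(30.0, abs=1e-9)

    def test_zero_angle_gives_plumb_line(self):
        pts = simulate_root_polyline(RootSimParams(true_vertical_angle=0.0, waviness_sd=0.0), 1)
        assert np.allclose(pts[["x", "y"]], 0.0)
        assert (np.diff(pts["z"]) < 0).all()

    def test_mean_measured_angle_unbiased_at_45_degrees(self):
        params = RootSimParams(true_vertical_angle=45.0, waviness_sd=5.0, n_points=50)
        angles = [
            rootgeom.vertical_angle(simulate_root_polyline(params, seed)).vertical_angle
            for seed in range(100)
        ]
        assert abs(np.mean(angles) - 45.0) < 1.0

    def test_z_descends_monotonically(self):
        params = RootSimParams(true_vertical_angle=60.0, waviness_sd=10.0, n_points=80)
        pts = simulate_root_polyline(params, 12)
        assert (np.diff(pts["z"]) < 0).all()

    def test_noiseless_force_curve_is_exact_piecewise_linear(self):
        p = ForceCurveParams(true_slope=7.6, contact_z=500.0, baseline_noise_sd=0.0, n_points=500)
        curve = simulate_force_curve(p, 1)
        z, f = curve["z_nm"].to_numpy(), curve["force_pN"].to_numpy()
        pre = z < 500.0
        assert np.all(f[pre] == 0.0)
        assert np.allclose(f[~pre], 7.6 * (z[~pre] - 500.0))

    def test_zero_slope_force_curve_is_flat(self):
        p = ForceCurveParams(true_slope=0.0, baseline_noise_sd=0.0)
        assert np.all(simulate_force_curve(p, 1)["force_pN"] == 0.0)

    def test_contact_outside_range_rejected(self):
        with pytest.raises(ValueError, match="contact_z"):
            simulate_force_curve(ForceCurveParams(contact_z=2000.0, z_max=1000.0), 1)


class TestMutateCds:
    def test_empty_substitution_list_returns_reference(self):
        assert mutate_cds("ATGGCTTAA", []) == "ATGGCTTAA"

    def test_single_substitution_gives_hamming_distance_one(self):
        out = mutate_cds("ATGGCTTAA", [(5, "G")])
        assert sum(a != b for a, b in zip(out, "ATGGCTTAA")) == 1
        assert out[4] == "G"

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError, match="outside CDS"):
            mutate_cds("ATGGCTTAA", [(10, "A")])


class TestDeterminism:
    def test_full_bsa_inputs_are_bytewise_reproducible(self):
        cfg = SimConfig(seed=13, **SMALL)
        t1, _ = simulate.simulate_bsa_inputs(cfg)
        t2, _ = simulate.simulate_bsa_inputs(cfg)
        assert t1.to_csv() == t2.to_csv()

    def test_different_seeds_differ(self):
        a, _ = simulate.simulate_bsa_inputs(SimConfig(seed=1, **SMALL))
        b, _ = simulate.simulate_bsa_inputs(SimConfig(seed=2, **SMALL))
        assert a.to_csv() != b.to_csv()
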