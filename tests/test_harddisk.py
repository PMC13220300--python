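"""Hard-disk Monte Carlo: packing, g(r), structure factor, proximity."""

import numpy as np
import pytest

from secwall import harddisk as hd
from secwall.harddisk import (
    DiskConfiguration,
    MCSettings,
    RadialDistribution,
    build_structure_factor_table,
    direct_structure_factor,
    effective_area_fraction,
    effective_radius,
    generate_configuration,
    proximity_fractions,
    radial_distribution,
    structure_factor_from_rdf,
)

FAST = MCSettings(equil_sweeps=200)


class TestEffectiveGeometry:
    def test_sheath_halved(self):
        assert effective_radius(13.5, 4.7) == pytest.approx(15.85)
        assert effective_radius(10.0, 4.0) == pytest.approx(12.0)
        assert effective_radius(7.0, 0.0) == pytest.approx(7.0)

    def test_negative_separation_rejected(self):
        with pytest.raises(ValueError):
            effective_radius(13.5, -1.0)

    def test_area_fraction_scales_with_radius_ratio(self):
        assert effective_area_fraction(0.29, 13.5, 15.85) == pytest.approx(
            0.3998, abs=2e-4
        )
        assert effective_area_fraction(0.2, 5.0, 5.0) == pytest.approx(0.2)
        assert effective_area_fraction(0.1, 5.0, 10.0) == pytest.approx(0.4)

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="close-packing"):
            effective_area_fraction(0.4, 5.0, 10.0)


class TestGenerateConfiguration:
    def test_single_disk(self):
        cfg = generate_configuration(1, 0.3, 2.0, 1.5, seed=0, settings=FAST)
        assert cfg.n_disks == 1
        cfg.assert_valid()

    def test_no_overlaps_brute_force(self):
        cfg = generate_configuration(500, 0.05, 3.0, 3.0, seed=2, settings=FAST)
        assert cfg.min_pair_distance() >= 2 * cfg.radius_eff - 1e-9

    def test_dense_packing_no_overlaps(self):
        cfg = generate_configuration(400, 0.40, 1.0, seed=3, settings=FAST)
        assert cfg.min_pair_distance() >= 2 * cfg.radius_eff - 1e-9

    def test_determinism(self):
        a = generate_configuration(300, 0.3, 1.0, seed=42, settings=FAST)
        b = generate_configuration(300, 0.3, 1.0, seed=42, settings=FAST)
        assert np.array_equal(a.centers, b.centers)

    def test_area_fraction_honoured(self):
        cfg = generate_configuration(800, 0.35, 1.0, seed=4, settings=FAST)
        one_disk = np.pi / cfg.box_side**2
        assert abs(cfg.phi_eff - 0.35) <= one_disk

    def test_compression_path_reaches_high_density(self):
        cfg = generate_configuration(
            150, 0.54, 1.0, seed=5, settings=MCSettings(equil_sweeps=100)
        )
        assert cfg.phi_eff == pytest.approx(0.54, abs=1e-6)
        assert cfg.min_pair_distance() >= 2 * cfg.radius_eff - 1e-9
        assert "compression" in cfg.metadata["protocol"]

    def test_infeasible_phi_rejected(self):
        with pytest.raises(ValueError):
            generate_configuration(100, 0.95, 1.0, seed=0)


class TestRadialDistribution:
    def test_ideal_gas_control_is_flat(self):
        # nearly point-like disks behave as a Poisson process: g ~ 1
        # enough tuned sweeps for the step size to reach the dilute-limit
        # cap (L/4), so snapshots decorrelate fully between samples
        cfg = generate_configuration(700, 1e-4, 1.0, seed=6,
                                     settings=MCSettings(equil_sweeps=400))
        rdf = radial_distribution(cfg, bin_width=10.0, r_max=200.0, n_samples=25)
        sel = rdf.r_centers > 15.0
        z = np.abs(rdf.g[sel] - 1.0) / rdf.g_stderr[sel]
        assert np.median(z) < 2.0
        assert np.max(z) < 5.0
        assert np.mean(rdf.g[sel]) == pytest.approx(1.0, abs=0.05)

    def test_zero_below_contact_and_structured_at_contact(self):
        cfg = generate_configuration(500, 0.40, 1.0, seed=7, settings=FAST)
        rdf = radial_distribution(cfg, bin_width=0.1, n_samples=15)
        below = rdf.r_centers < 2.0 * cfg.radius_eff - 0.1
        assert np.all(rdf.g[below] == 0.0)
        contact = (rdf.r_centers > 2.0) & (rdf.r_centers < 2.4)
        assert rdf.g[contact].max() > 1.0
        tail = rdf.r_centers > 0.9 * rdf.r_centers[-1]
        assert np.all(np.abs(rdf.g[tail] - 1.0) < 5 * rdf.g_stderr[tail] + 0.05)

    def test_rmax_beyond_half_box_rejected(self):
        cfg = generate_configuration(100, 0.3, 1.0, seed=8, settings=FAST)
        with pytest.raises(ValueError, match="minimum-image"):
            radial_distribution(cfg, bin_width=0.1, r_max=cfg.box_side)


class TestStructureFactor:
    def test_uniform_g_gives_unit_s(self):
        r = np.arange(0.05, 20.0, 0.1)
        rdf = RadialDistribution(r, np.ones_like(r), np.zeros_like(r),
                                 density=0.1, box_side=100.0, n_snapshots=1)
        s, err = structure_factor_from_rdf(rdf, [0.5, 1.0, 2.0])
        assert np.allclose(s, 1.0)
        assert np.allclose(err, 0.0)

    def test_dilute_limit_bound(self):
        phi = 0.01
        cfg = generate_configuration(600, phi, 1.0, seed=9, settings=FAST)
        rdf = radial_distribution(cfg, bin_width=0.25, n_samples=25)
        q = np.linspace(0.5, 5.0, 10)
        s, err = structure_factor_from_rdf(rdf, q)
        # excluded-area virial: |S - 1| <= 8 phi at leading order
        assert np.max(np.abs(s - 1.0) - 3 * err) < 8 * phi

    def test_low_q_flagged_unreliable(self):
        cfg = generate_configuration(100, 0.3, 1.0, seed=10, settings=FAST)
        rdf = radial_distribution(cfg, bin_width=0.2, n_samples=5)
        with pytest.raises(ValueError, match="unreliable"):
            structure_factor_from_rdf(rdf, [0.5 * 2 * np.pi / cfg.box_side])

    def test_direct_summation_oracle_agrees(self):
        cfg = generate_configuration(500, 0.35, 1.0, seed=12, settings=FAST)
        rdf = radial_distribution(cfg, bin_width=0.05, n_samples=25)
        targets = np.linspace(1.0, 8.0, 8)
        q_act, s_dir, e_dir = direct_structure_factor(cfg, targets, n_samples=25)
        s_rdf, e_rdf = structure_factor_from_rdf(rdf, q_act)
        combined = np.sqrt(e_dir**2 + e_rdf**2)
        assert np.all(np.abs(s_rdf - s_dir) < 3.0 * combined + 0.02)


class TestStructureFactorTable:
    def test_phi_zero_row_is_unity(self):
        x = np.linspace(0.5, 10, 30)
        table = build_structure_factor_table(
            [0.0, 0.2], x, n_disks=300, n_samples=10, settings=FAST, seed=1
        )
        assert np.allclose(table.s_values[0], 1.0)
        assert np.allclose(table(0.0, x), 1.0, atol=1e-9)

    def test_node_roundtrip(self):
        x = np.linspace(0.5, 10, 25)
        phis = [0.1, 0.2, 0.3, 0.4]
        table = build_structure_factor_table(
            phis, x, n_disks=300, n_samples=10, settings=FAST, seed=2
        )
        for i, phi in enumerate(phis):
            assert np.allclose(table(phi, x), table.s_values[i], atol=1e-8)

    def test_out_of_range_queries_raise(self):
        x = np.linspace(0.5, 10, 25)
        table = build_structure_factor_table(
            [0.1, 0.3], x, n_disks=200, n_samples=5, settings=FAST, seed=3
        )
        with pytest.raises(ValueError):
            table(0.5, 5.0)
        with pytest.raises(ValueError):
            table(0.2, 15.0)

    def test_midcell_query_matches_fresh_simulation(self):
        x = np.linspace(1.0, 8.0, 25)
        table = build_structure_factor_table(
            [0.20, 0.25, 0.30, 0.35], x, n_disks=500, n_samples=25,
            settings=FAST, seed=4,
        )
        phi_mid = 0.275
        cfg = generate_configuration(500, phi_mid, 1.0, seed=99, settings=FAST)
        rdf = radial_distribution(cfg, bin_width=0.05, n_samples=25)
        s_fresh, e_fresh = structure_factor_from_rdf(rdf, x)
        # allow a small interpolation-bias floor on top of the MC error
        assert np.all(np.abs(table(phi_mid, x) - s_fresh) < 3 * e_fresh + 0.03)

    def test_json_roundtrip(self, tmp_path):
        x = np.linspace(0.5, 5, 10)
        table = build_structure_factor_table(
            [0.1], x, n_disks=150, n_samples=5, settings=FAST, seed=5
        )
        path = tmp_path / "table.json"
        table.save(path)
        back = hd.StructureFactorTable.load(path)
        assert np.allclose(back(0.1, x), table(0.1, x))


class TestProximity:
    def test_monotone_in_distance(self):
        cfg = generate_configuration(400, 0.4, 15.85, 13.5, seed=13, settings=FAST)
        res = proximity_fractions(cfg, distances=np.arange(1.0, 13.0))
        assert np.all(np.diff(res.matrix_fraction_within) >= 0.0)
        assert res.matrix_fraction_within[-1] <= 1.0

    def test_single_disk_matches_shell_formula(self):
        # one disk in a huge box: fraction = rho pi ((R+d)^2 - R^2) / (1 - phi)
        cfg = generate_configuration(1, 0.001, 15.85, 13.5, seed=0, settings=FAST)
        res = proximity_fractions(cfg, distances=[6.0], grid_spacing=1.0)
        rho = cfg.density
        expected = rho * np.pi * ((13.5 + 6.0) ** 2 - 13.5**2) / (1 - cfg.phi_phys)
        assert res.matrix_fraction_within[0] == pytest.approx(expected, rel=0.05)

    def test_dilute_consistency(self):
        cfg = generate_configuration(150, 0.02, 15.85, 13.5, seed=14, settings=FAST)
        res = proximity_fractions(cfg, distances=[6.0], grid_spacing=1.0)
        rho = cfg.density
        expected = rho * np.pi * ((13.5 + 6.0) ** 2 - 13.5**2) / (1 - cfg.phi_phys)
        assert res.matrix_fraction_within[0] == pytest.approx(expected, rel=0.05)

    def test_insensitive_to_system_size(self, paper_geometry):
        fr = []
        for n, seed in ((400, 15), (800, 16)):
            cfg = generate_configuration(
                n, paper_geometry["phi_eff"], paper_geometry["radius_eff"],
                paper_geometry["radius"], seed=seed, settings=FAST,
            )
            fr.append(proximity_fractions(cfg, distances=[6.0]).matrix_fraction_within[0])
        assert abs(fr[0] - fr[1]) < 0.02

    def test_grid_spacing_convergence(self, paper_geometry):
        cfg = generate_configuration(
            300, paper_geometry["phi_eff"], paper_geometry["radius_eff"],
            paper_geometry["radius"], seed=17, settings=FAST,
        )
        f1 = proximity_fractions(cfg, distances=[6.0], grid_spacing=1.0)
        f05 = proximity_fractions(cfg, distances=[6.0], grid_spacing=0.5)
        assert f1.matrix_fraction_within[0] == pytest.approx(
            f05.matrix_fraction_within[0], abs=0.005
        )

    def test_degenerate_all_covered(self):
        cfg = generate_configuration(50, 0.3, 1.0, seed=18, settings=FAST)
        with pytest.raises(ValueError, match="matrix"):
            proximity_fractions(cfg, radius=cfg.box_side, distances=[1.0])

    def test_coarse_grid_rejected(self):
        cfg = generate_configuration(50, 0.3, 1.0, seed=19, settings=FAST)
        with pytest.raises(ValueError, match="spacing"):
            proximity_fractions(cfg, distances=[0.5], grid_spacing=2.0)
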