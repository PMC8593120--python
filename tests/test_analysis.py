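"""Density maps, enrichment, slope fits, hydration, composition summaries."""

import numpy as np
import pytest

import memstalk as ms
from memstalk.analysis import (CompositionScan, LipidSpec, RegionBox,
                               _linfit, composition_summary, density_map,
                               enrichment, fit_dg_slope,
                               hydration_from_counts, hydration_metrics)


def slab_config(n=4000, box=(6.0, 6.0, 10.0), z_lo=4.0, z_hi=6.0, seed=0,
                mass=72.0):
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    pos = np.c_[rng.uniform(0, box[0], n), rng.uniform(0, box[1], n),
                rng.uniform(z_lo, z_hi, n)]
    return ms.Configuration(pos, box, np.zeros(n, dtype=int),
                            np.array(["A"] * n),
                            masses=np.full(n, mass))


class TestDensityMap:
    def test_uniform_slab_density(self):
        cfg = slab_config()
        r_edges = np.linspace(0, 2.5, 11)
        z_edges = np.linspace(-2.0, 2.0, 17)
        dmap = density_map([cfg], r_edges, z_edges)
        # inside the slab: rho = N m / (A h)
        expected = 4000 * 72.0 / (36.0 * 2.0)
        inside = dmap.total[:, (np.abs(
            0.5 * (z_edges[:-1] + z_edges[1:])) < 0.8)]
        assert np.median(inside) == pytest.approx(expected, rel=0.15)
        outside = dmap.total[:, 0.5 * (z_edges[:-1] + z_edges[1:]) < -1.2]
        assert np.all(outside == 0)

    def test_species_maps_sum_to_total(self):
        rng = np.random.default_rng(1)
        cfg = slab_config(seed=1)
        cfg.species = rng.choice(["A", "B", "C"], cfg.n_beads)
        dmap = density_map([cfg], np.linspace(0, 2, 9),
                           np.linspace(-2, 2, 9))
        total = sum(dmap.densities.values())
        np.testing.assert_allclose(total, dmap.total, atol=1e-12)

    def test_on_axis_bin_finite(self):
        cfg = ms.Configuration(np.array([[3.0, 3.0, 5.0]]),
                               np.array([6.0, 6.0, 10.0]), [0],
                               np.array(["A"]), masses=np.array([72.0]))
        dmap = density_map([cfg], np.linspace(0, 1, 5),
                           np.linspace(-1, 1, 5))
        assert np.all(np.isfinite(dmap.total))
        assert dmap.total[0].sum() > 0

    def test_mass_conservation(self):
        cfg = slab_config(n=500, z_lo=3.5, z_hi=6.5, seed=2)
        r_edges = np.linspace(0, 6.0, 40)   # covers min(Lx, Ly)/2? generous
        z_edges = np.linspace(-5.0, 5.0, 101)
        dmap = density_map([cfg], r_edges, z_edges)
        captured = (dmap.total * dmap.bin_volumes).sum()
        # the circular footprint r < 3 inside the 6x6 box captures only
        # part of the mass; restrict to beads within the radial range
        center = cfg.box[:2] / 2
        d = cfg.positions[:, :2] - center
        r = np.hypot(d[:, 0], d[:, 1])
        expected = 72.0 * np.count_nonzero(r < 6.0)
        assert captured == pytest.approx(expected, rel=1e-6)


class TestEnrichment:
    def regions(self):
        return RegionBox(stalk_r=(0.0, 1.0), stalk_z=(-1.5, 1.5),
                         ref_r=(2.0, 2.8), ref_z=(-1.5, 1.5))

    def uniform_map(self, value=5.0):
        r_edges = np.linspace(0, 3.0, 31)
        z_edges = np.linspace(-2, 2, 41)
        d = np.full((30, 40), value)
        return ms.DensityMap2D(r_edges, z_edges, {"A": d}, 1)

    def test_uniform_density_gives_zero(self):
        assert enrichment(self.uniform_map(), self.regions()) == \
            pytest.approx(0.0, abs=1e-12)

    def test_doubled_stalk_density_gives_plus_one(self):
        dmap = self.uniform_map(5.0)
        rc = 0.5 * (dmap.r_edges[:-1] + dmap.r_edges[1:])
        zc = 0.5 * (dmap.z_edges[:-1] + dmap.z_edges[1:])
        sel = np.ix_(rc <= 1.0, np.abs(zc) <= 1.5)
        dmap.densities["A"][sel] = 10.0
        assert enrichment(dmap, self.regions()) == pytest.approx(1.0,
                                                                 abs=1e-9)

    def test_scale_invariance(self):
        dmap = self.uniform_map(5.0)
        rng = np.random.default_rng(3)
        dmap.densities["A"] *= rng.uniform(0.5, 2.0)  # uniform rescale
        e1 = enrichment(dmap, self.regions())
        dmap.densities["A"] *= 7.3
        assert enrichment(dmap, self.regions()) == pytest.approx(e1,
                                                                 abs=1e-12)

    def test_gaussian_blob_matches_quadrature(self):
        # Gaussian blob on a uniform background, enrichment verified by
        # direct numerical integration over both region boxes
        from scipy.integrate import dblquad
        r_edges = np.linspace(0, 3.0, 241)
        z_edges = np.linspace(-2, 2, 321)
        rc = 0.5 * (r_edges[:-1] + r_edges[1:])
        zc = 0.5 * (z_edges[:-1] + z_edges[1:])
        bg, amp, sr, sz = 2.0, 6.0, 0.5, 0.8
        dens = bg + amp * np.exp(-(rc[:, None] ** 2) / (2 * sr ** 2)
                                 - (zc[None, :] ** 2) / (2 * sz ** 2))
        dmap = ms.DensityMap2D(r_edges, z_edges, {"A": dens}, 1)
        reg = self.regions()

        def mean_density(r0, r1, z0, z1):
            num = dblquad(
                lambda z, r: 2 * np.pi * r * (
                    bg + amp * np.exp(-r**2 / (2 * sr**2)
                                      - z**2 / (2 * sz**2))),
                r0, r1, z0, z1, epsabs=1e-10)[0]
            vol = np.pi * (r1**2 - r0**2) * (z1 - z0)
            return num / vol

        expected = mean_density(*reg.stalk_r, *reg.stalk_z) \
            / mean_density(*reg.ref_r, *reg.ref_z) - 1
        assert enrichment(dmap, reg) == pytest.approx(expected, rel=1e-3)

    def test_zero_reference_density_rejected(self):
        dmap = self.uniform_map(0.0)
        rc = 0.5 * (dmap.r_edges[:-1] + dmap.r_edges[1:])
        dmap.densities["A"][rc <= 1.0, :] = 1.0
        with pytest.raises(ValueError):
            enrichment(dmap, self.regions())

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError):
            RegionBox(stalk_r=(0, 2.5), stalk_z=(-1, 1),
                      ref_r=(2.0, 3.0), ref_z=(-1, 1))


class TestSlopeFit:
    def test_exact_line_recovered(self):
        x = np.array([0.0, 0.1, 0.2, 0.3, 0.4])
        scan = CompositionScan(x, 10.0 - 120.0 * x)
        slope, se = fit_dg_slope(scan)
        assert slope == pytest.approx(-120.0, abs=1e-10)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_weighted_equals_unweighted_for_equal_ses(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0, 0.5, 6)
        y = 5 - 40 * x + rng.normal(0, 1.0, 6)
        s_w, _ = fit_dg_slope(CompositionScan(x, y, np.full(6, 2.0)), "se")
        s_u, _ = fit_dg_slope(CompositionScan(x, y))
        assert s_w == pytest.approx(s_u, rel=1e-12)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        x = np.linspace(0, 0.5, 8)
        y = 3 - 55 * x + rng.normal(0, 2.0, 8)
        slope, se = fit_dg_slope(CompositionScan(x, y))
        res = sm.OLS(y, sm.add_constant(x)).fit()
        assert slope == pytest.approx(res.params[1], rel=1e-10)
        assert se == pytest.approx(res.bse[1], rel=1e-10)

    def test_two_point_guard(self):
        slope, _, se = _linfit(np.array([0.0, 1.0]), np.array([2.0, 5.0]))
        assert slope == pytest.approx(3.0)
        assert se == 0.0
        with pytest.raises(ValueError):
            fit_dg_slope(CompositionScan(np.array([0.0, 0.1]),
                                         np.array([1.0, 2.0])))

    def test_monte_carlo_coverage(self):
        # scans with known Gaussian noise (sigma = 2 kJ/mol at 5 mole
        # fractions): the SE-weighted slope must fall within 2 SE of truth
        # in >= 93 % of replicates (Gaussian coverage ~95 %)
        rng = np.random.default_rng(6)
        x = np.linspace(0.0, 0.4, 5)
        sigma = 2.0
        true_slope = -80.0
        hits = 0
        n_rep = 500
        for rep in range(n_rep):
            y = 12 + true_slope * x + rng.normal(0, sigma, len(x))
            scan = CompositionScan(x, y, np.full(len(x), sigma))
            slope, se = fit_dg_slope(scan, weighting="se")
            if abs(slope - true_slope) <= 2 * se:
                hits += 1
        assert hits / n_rep >= 0.93


class TestHydration:
    def test_zero_waters(self):
        assert hydration_from_counts(0, 100, 32.1) == (0.0, 0.0)

    def test_printed_pairing(self):
        per_lipid, per_area = hydration_from_counts(180, 100, 32.1)
        assert per_lipid == pytest.approx(1.8)
        assert per_area == pytest.approx(5.61, abs=0.01)

    def test_intensivity(self):
        a = hydration_from_counts(180, 100, 32.1)
        b = hydration_from_counts(360, 200, 64.2)
        assert a == pytest.approx(b)

    def test_no_lipids_rejected(self):
        with pytest.raises(ValueError):
            hydration_from_counts(10, 0, 32.1)

    def test_counts_solvent_in_gap_of_built_system(self):
        spec = ms.SystemBuildSpec(lipids_per_leaflet=16, separation=1.6,
                                  n_solvent=48)
        system = ms.build_double_bilayer(spec, seed=2)
        per_lipid, per_area = hydration_metrics(system.config)
        # all 48 solvent beads sit between the proximal leaflets of the
        # freshly built system; 32 proximal lipids
        assert per_lipid == pytest.approx(48 / 32)
        area = system.config.box[0] * system.config.box[1]
        assert per_area == pytest.approx(48 / area)


class TestComposition:
    def test_single_fully_saturated_species(self):
        spec = LipidSpec("DPPC", "PC", [[True] * 4, [True] * 4])
        out = composition_summary([(spec, 1.0)])
        assert out["saturated_bead_fraction"] == 1.0
        assert out["mean_tail_length_beads"] == 4.0

    def test_fifty_fifty_mix_enumeration(self):
        sat = LipidSpec("A", "PC", [[True] * 4])
        half = LipidSpec("B", "PE", [[True, True, False, False]])
        out = composition_summary([(sat, 0.5), (half, 0.5)])
        assert out["saturated_bead_fraction"] == pytest.approx(0.75)
        assert out["mean_tail_length_beads"] == pytest.approx(4.0)
        assert out["headgroup_fractions"] == {"PC": 0.5, "PE": 0.5}

    def test_sterol_only_rejected(self):
        chol = LipidSpec("CHOL", "sterol", [], is_sterol=True)
        with pytest.raises(ValueError, match="tail"):
            composition_summary([(chol, 1.0)])

    def test_sterols_excluded_from_tail_stats(self):
        chol = LipidSpec("CHOL", "sterol", [], is_sterol=True)
        popc = LipidSpec("POPC", "PC", [[True] * 4, [True, False, True,
                                                     True]])
        out = composition_summary([(chol, 0.43), (popc, 0.57)])
        assert out["saturated_bead_fraction"] == pytest.approx(7 / 8)
        assert out["headgroup_fractions"]["sterol"] == pytest.approx(0.43)

    def test_fractions_must_sum_to_one(self):
        spec = LipidSpec("A", "PC", [[True]])
        with pytest.raises(ValueError, match="sum"):
            composition_summary([(spec, 0.7)])
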