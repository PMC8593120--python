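"""Chain-coordinate correctness: values, gradients, smoothness, invariants."""

import numpy as np
import pytest
from dataclasses import replace

import memstalk as ms
from memstalk.chain_coordinate import (occupancy_cap, radial_switch,
                                       converge_center)

from helpers import xi_brute_force


def make_config(pos, box=(8.0, 8.0, 8.0), classes=None, species=None):
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    n = len(pos)
    return ms.Configuration(
        pos, np.asarray(box, dtype=float),
        np.zeros(n, dtype=int) if classes is None else classes,
        np.array(["LIP"] * n) if species is None else species)


class TestSelection:
    def test_all_solvent_is_empty(self):
        cfg = make_config([[1, 1, 1]], classes=[int(ms.BeadClass.SOLVENT)])
        with pytest.warns(UserWarning):
            idx = ms.select_apolar_beads(cfg)
        assert idx.size == 0

    def test_label_round_trip(self):
        classes = np.array([0, 1, 0, 2, 3, 0])
        cfg = make_config(np.zeros((6, 3)), classes=classes)
        idx = ms.select_apolar_beads(cfg)
        assert list(idx) == [0, 2, 5]

    def test_class_and_species_rule_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        classes = rng.integers(0, 4, 50)
        species = rng.choice(["POPC", "DOPE", "CHOL"], 50)
        cfg = make_config(np.zeros((50, 3)), classes=classes, species=species)
        rule = ms.SelectionRule(classes=(ms.BeadClass.APOLAR_TAIL,),
                                species=("POPC",))
        idx = ms.select_apolar_beads(cfg, rule)
        expected = [i for i in range(50)
                    if classes[i] == 0 and species[i] == "POPC"]
        assert list(idx) == expected


class TestOccupancies:
    def test_partition_of_unity_at_slice_boundary(self, std_cylinder,
                                                  std_params):
        # bead exactly on the boundary between slices, on-axis
        z_edge = std_cylinder.z_bottom + 3 * std_cylinder.slice_thickness
        cfg = make_config([[4.0, 4.0, z_edge]])
        n_s, _ = ms.slice_occupancies(cfg, std_cylinder, std_params)
        assert n_s.sum() == pytest.approx(1.0, abs=1e-12)
        assert n_s[2] == pytest.approx(0.5, abs=1e-12)
        assert n_s[3] == pytest.approx(0.5, abs=1e-12)

    def test_radial_cutoff_zeroes_contribution(self, std_cylinder, std_params):
        rho = std_cylinder.radius + std_params.eps_r
        cfg = make_config([[4.0 + rho, 4.0, 4.0]])
        n_s, _ = ms.slice_occupancies(cfg, std_cylinder, std_params)
        assert np.all(n_s == 0)

    def test_uniform_gas_mean_count_matches_quadrature(self, std_cylinder,
                                                       std_params):
        # ideal gas at density rho0: <n_s> = rho0 * integral(w_ax * w_rad)
        # = rho0 * pi R^2 d for interior slices (the switch integrals cancel
        # by symmetry); checked by Monte-Carlo integration
        rng = np.random.default_rng(42)
        rho0 = 60.0
        box = np.array([8.0, 8.0, 8.0])
        n = int(rho0 * box.prod())
        n_acc = np.zeros(std_cylinder.n_slices)
        reps = 12
        for r in range(reps):
            pos = rng.uniform(0, 8, (n, 3))
            cfg = make_config(pos)
            n_s, _ = ms.slice_occupancies(cfg, std_cylinder, std_params)
            n_acc += n_s
        n_acc /= reps
        d = std_cylinder.slice_thickness
        expected = rho0 * np.pi * std_cylinder.radius ** 2 * d
        interior = n_acc[1:-1]
        assert interior.mean() == pytest.approx(expected, rel=0.02)

    def test_overlapping_ramps_rejected(self, std_cylinder):
        params = ms.ChainCoordParams(zeta=0.06)  # slice thickness is 0.1
        cfg = make_config([[4.0, 4.0, 4.0]])
        with pytest.raises(ValueError, match="partition of unity"):
            ms.slice_occupancies(cfg, std_cylinder, params)


class TestComputeXi:
    def test_empty_cylinder_gives_zero(self, std_cylinder, std_params):
        cfg = make_config([[0.5, 0.5, 0.5]])
        res = ms.compute_xi(cfg, std_cylinder, std_params)
        assert res.xi == 0.0
        assert np.all(res.gradient == 0)

    def test_saturation_gives_one(self, std_cylinder, std_params):
        # pile many beads in each slice center
        zs = std_cylinder.z_bottom + (np.arange(20) + 0.5) * 0.1
        pos = [[4.0, 4.0, z] for z in zs for _ in range(5)]
        res = ms.compute_xi(make_config(pos), std_cylinder, std_params)
        assert res.xi == 1.0

    def test_single_bead_half_occupancy(self):
        # N_s = 10, N_0 = 2, one on-axis bead centered in a slice:
        # xi = Psi(0.5) / 10 = 0.05, away from every switch region
        cyl = ms.CylinderSpec(np.array([4.0, 4.0]), 3.0, 4.0, 1.2, 10)
        cfg = make_config([[4.0, 4.0, 3.55]])
        res = ms.compute_xi(cfg, cyl, ms.ChainCoordParams())
        assert res.xi == pytest.approx(0.05, abs=1e-12)

    def test_matches_brute_force_evaluation(self, random_config, std_cylinder,
                                            std_params):
        res = ms.compute_xi(random_config, std_cylinder, std_params)
        xi_bf, n_bf, _ = xi_brute_force(
            random_config.positions, random_config.box,
            np.ones(random_config.n_beads, dtype=bool),
            std_cylinder.center_xy, std_cylinder.z_bottom, std_cylinder.z_top,
            std_cylinder.radius, std_cylinder.n_slices, std_params.n0,
            std_params.zeta, std_params.eps_r, std_params.cap_h)
        assert res.xi == pytest.approx(xi_bf, abs=1e-12)
        np.testing.assert_allclose(res.raw_counts, n_bf, atol=1e-12)

    def test_xi_equals_mean_occupancy(self, random_config, std_cylinder,
                                      std_params):
        res = ms.compute_xi(random_config, std_cylinder, std_params)
        assert res.xi == pytest.approx(res.occupancies.mean(), abs=1e-15)

    def test_wrap_invariance(self, random_config, std_cylinder, std_params):
        res0 = ms.compute_xi(random_config, std_cylinder, std_params)
        shifted = random_config.copy()
        shifted.positions = np.mod(shifted.positions
                                   + np.array([5.0, -3.0, 7.0]),
                                   shifted.box) - np.array([8.0, 0.0, 0.0])
        # unwrapped coordinates (some now negative / beyond the box)
        shifted.positions += np.array([8.0, 0.0, 0.0])
        cyl = replace(std_cylinder,
                      center_xy=std_cylinder.center_xy + np.array([5.0, -3.0]))
        cyl = replace(cyl, z_bottom=cyl.z_bottom + 7.0, z_top=cyl.z_top + 7.0)
        res1 = ms.compute_xi(shifted, cyl, std_params)
        assert res1.xi == pytest.approx(res0.xi, abs=1e-12)


class TestGradient:
    def test_gradient_matches_finite_differences(self, std_cylinder,
                                                 std_params):
        rng = np.random.default_rng(7)
        h = 1e-5
        worst = 0.0
        for rep in range(10):
            n = 25
            pos = rng.uniform(2.5, 5.5, (n, 3))
            cfg = make_config(pos)
            res = ms.compute_xi(cfg, std_cylinder, std_params)
            for i in range(n):
                for d in range(3):
                    pp = pos.copy(); pp[i, d] += h
                    pm = pos.copy(); pm[i, d] -= h
                    fd = (ms.compute_xi(make_config(pp), std_cylinder,
                                        std_params).xi
                          - ms.compute_xi(make_config(pm), std_cylinder,
                                          std_params).xi) / (2 * h)
                    g = res.gradient[i, d]
                    if abs(g) > 1e-10:
                        worst = max(worst, abs(fd - g) / abs(g))
                    else:
                        assert abs(fd - g) < 1e-10
        assert worst < 1e-5

    def test_c1_continuity_across_switches(self, std_params):
        # scan a bead across a slice boundary, the radial switch and the
        # occupancy cap; value and gradient must be continuous
        cyl = ms.CylinderSpec(np.array([4.0, 4.0]), 3.0, 5.0, 1.2, 20)
        zb = cyl.z_bottom + 5 * cyl.slice_thickness
        for path in ("axial", "radial"):
            vals, grads = [], []
            ts = np.linspace(-0.06, 0.06, 241)
            for t in ts:
                if path == "axial":
                    p = [4.0, 4.0, zb + t]
                else:
                    p = [4.0 + cyl.radius + t, 4.0, zb + 0.05]
                res = ms.compute_xi(make_config(p), cyl, std_params)
                vals.append(res.xi)
                grads.append(res.gradient[0].copy())
            vals = np.array(vals); grads = np.array(grads)
            dt = ts[1] - ts[0]
            assert np.max(np.abs(np.diff(vals))) < 5 * dt  # no value jump
            assert np.max(np.abs(np.diff(grads, axis=0))) < 0.5  # no kink

    def test_cap_bridge_is_c1_and_monotone(self):
        x = np.linspace(0.0, 2.0, 4001)
        v, dv = occupancy_cap(x, 0.25)
        num = np.gradient(v, x)
        assert np.all(np.diff(v) >= -1e-15)
        assert np.max(np.abs(num[2:-2] - dv[2:-2])) < 2e-3
        assert v.max() <= 1.0 and v.min() >= 0.0


class TestInvariants:
    def test_xi_in_unit_interval_random(self, std_cylinder, std_params):
        rng = np.random.default_rng(11)
        for rep in range(20):
            n = rng.integers(1, 120)
            pos = rng.uniform(0, 8, (n, 3))
            res = ms.compute_xi(make_config(pos), std_cylinder, std_params)
            assert 0.0 <= res.xi <= 1.0

    def test_adding_a_bead_never_decreases_xi(self, std_cylinder, std_params):
        rng = np.random.default_rng(13)
        pos = rng.uniform(2.5, 5.5, (40, 3))
        base = ms.compute_xi(make_config(pos), std_cylinder, std_params).xi
        for rep in range(25):
            extra = rng.uniform(0, 8, 3)
            xi = ms.compute_xi(make_config(np.vstack([pos, extra])),
                               std_cylinder, std_params).xi
            assert xi >= base - 1e-12

    def test_permutation_invariance(self, random_config, std_cylinder,
                                    std_params):
        res0 = ms.compute_xi(random_config, std_cylinder, std_params)
        perm = np.random.default_rng(3).permutation(random_config.n_beads)
        shuffled = random_config.copy()
        shuffled.positions = shuffled.positions[perm]
        res1 = ms.compute_xi(shuffled, std_cylinder, std_params)
        assert res1.xi == pytest.approx(res0.xi, abs=1e-14)

    def test_xy_translation_invariance_with_dynamic_center(self, std_params):
        rng = np.random.default_rng(17)
        box = np.array([8.0, 8.0, 8.0])
        pos = np.c_[rng.normal(4.0, 0.4, 50), rng.normal(4.0, 0.4, 50),
                    rng.uniform(3.2, 4.8, 50)]
        params = ms.ChainCoordParams(center_mode="dynamic")
        cyl = ms.CylinderSpec(np.array([4.0, 4.0]), 3.0, 5.0, 1.2, 20)
        cfg = make_config(pos, box)
        cyl0 = converge_center(cfg, cyl, params)
        xi0 = ms.compute_xi(cfg, cyl0, params).xi
        shift = np.array([1.7, -2.3, 0.0])
        cfg2 = make_config(np.mod(pos + shift, box), box)
        cyl_s = replace(cyl, center_xy=np.mod(cyl.center_xy + shift[:2], 8.0))
        cyl2 = converge_center(cfg2, cyl_s, params)
        xi1 = ms.compute_xi(cfg2, cyl2, params).xi
        assert abs(xi1 - xi0) < 1e-8


class TestMembraneRelativeAnchor:
    def test_offsets_follow_tail_slabs(self, std_params):
        # two tail slabs; membrane-relative offsets resolve against their
        # instantaneous mean heights, so shifting both membranes in z
        # leaves xi unchanged
        rng = np.random.default_rng(31)
        box = np.array([6.0, 6.0, 12.0])
        n = 300
        slab1 = np.c_[rng.uniform(0, 6, n), rng.uniform(0, 6, n),
                      rng.normal(3.0, 0.3, n)]
        slab2 = np.c_[rng.uniform(0, 6, n), rng.uniform(0, 6, n),
                      rng.normal(7.0, 0.3, n)]
        pos = np.vstack([slab1, slab2])
        membrane = np.repeat([0, 1], n)
        cfg = ms.Configuration(pos, box, np.zeros(2 * n, dtype=int),
                               np.array(["LIP"] * 2 * n), membrane=membrane)
        cyl = ms.CylinderSpec(np.array([3.0, 3.0]), -0.5, 0.5, 1.2, 40,
                              z_anchor="membrane_relative")
        xi0 = ms.compute_xi(cfg, cyl, std_params).xi
        shifted = cfg.copy()
        shifted.positions[:, 2] = np.mod(shifted.positions[:, 2] + 1.7,
                                         box[2])
        xi1 = ms.compute_xi(shifted, cyl, std_params).xi
        assert xi1 == pytest.approx(xi0, abs=0.02)
        assert xi0 > 0.1   # the offsets reach into both slabs

    def test_requires_membrane_labels(self, std_params):
        cfg = ms.Configuration(np.zeros((4, 3)) + 2.0,
                               np.array([6.0, 6.0, 12.0]),
                               np.zeros(4, dtype=int),
                               np.array(["LIP"] * 4))
        cyl = ms.CylinderSpec(np.array([3.0, 3.0]), -0.5, 0.5, 1.2, 10,
                              z_anchor="membrane_relative")
        with pytest.raises(ValueError, match="membrane"):
            ms.compute_xi(cfg, cyl, std_params)


class TestUpdateCenter:
    def test_symmetric_beads_leave_center(self, std_params):
        cyl = ms.CylinderSpec(np.array([4.0, 4.0]), 3.0, 5.0, 1.2, 20)
        pos = [[4.5, 4.0, 4.0], [3.5, 4.0, 4.0],
               [4.0, 4.5, 4.0], [4.0, 3.5, 4.0]]
        new = ms.update_center(make_config(pos), cyl, std_params)
        np.testing.assert_allclose(new, [4.0, 4.0], atol=1e-12)

    def test_displaced_beads_move_center_to_weighted_mean(self, std_params):
        cyl = ms.CylinderSpec(np.array([4.0, 4.0]), 3.0, 5.0, 1.2, 20)
        base = np.array([[4.1, 4.0, 4.0], [3.9, 4.0, 4.05],
                         [4.0, 4.1, 3.95]])
        moved = base + np.array([0.3, 0.0, 0.0])
        new = ms.update_center(make_config(moved), cyl, std_params)
        # all beads well inside every switch: weights equal, mean exact
        np.testing.assert_allclose(new, moved[:, :2].mean(axis=0), atol=1e-12)

    def test_empty_cylinder_is_noop(self, std_params):
        cyl = ms.CylinderSpec(np.array([4.0, 4.0]), 3.0, 5.0, 1.2, 20)
        new = ms.update_center(make_config([[0.3, 0.2, 0.1]]), cyl,
                               std_params)
        np.testing.assert_allclose(new, [4.0, 4.0])


class TestCalibration:
    def test_target_zero_in_solvent_gap_returns_unextended(self, std_params):
        cyl = ms.CylinderSpec(np.array([4.0, 4.0]), 3.5, 4.5, 1.2, 10)
        cfg = make_config([[4.0, 4.0, 7.5]])  # bead far away
        cal = ms.calibrate_cylinder(cfg, 0.0, cyl, std_params)
        assert cal.z_bottom == cyl.z_bottom and cal.z_top == cyl.z_top

    def test_synthetic_slab_reaches_20_percent(self, std_params):
        # two dense tail slabs flanking an empty gap: extending the cylinder
        # into the slabs fills exactly the outer slices
        rng = np.random.default_rng(23)
        box = np.array([6.0, 6.0, 10.0])
        slab1 = np.c_[rng.uniform(0, 6, 600), rng.uniform(0, 6, 600),
                      rng.uniform(2.0, 3.5, 600)]
        slab2 = np.c_[rng.uniform(0, 6, 600), rng.uniform(0, 6, 600),
                      rng.uniform(6.5, 8.0, 600)]
        cfg = make_config(np.vstack([slab1, slab2]), box)
        template = ms.CylinderSpec(np.array([3.0, 3.0]), 3.5, 6.5, 1.2, 30)
        cal = ms.calibrate_cylinder(cfg, 0.20, template, std_params)
        res = ms.compute_xi(cfg, cal, std_params)
        assert abs(res.xi - 0.20) <= 0.02

    def test_unreachable_target_reports_range(self, std_params):
        cfg = make_config([[4.0, 4.0, 7.9]], box=(8.0, 8.0, 8.0))
        cyl = ms.CylinderSpec(np.array([4.0, 4.0]), 3.5, 4.5, 1.2, 10)
        with pytest.raises(ValueError, match="achievable"):
            ms.calibrate_cylinder(cfg, 0.9, cyl, std_params)
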