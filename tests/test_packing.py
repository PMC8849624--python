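"""Trimer packing: closed forms vs independent oracles, limits, monotonicity."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from astrodensity.packing import (TrimerGeometry, cell_max_density,
                                  circle_capacity, cylinder_capacity,
                                  cylinder_patch_area, disc_capacity,
                                  flat_triangle_area, lunar_triangle_area,
                                  planar_monomer_density, soma_capacity,
                                  sphere_capacity, sphere_patch_area,
                                  tip_capacity, tree_capacity)

OMEGA = 8.0


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def greedy_circle_oracle(r_in: float, omega: float) -> int:
    """Place chords of length omega around a circle one by one."""
    if 2.0 * r_in <= omega:
        return 0
    width = 2.0 * math.asin(omega / (2.0 * r_in))
    n, used = 0, 0.0
    while used + width <= 2.0 * math.pi + 1e-12:
        n += 1
        used += width
    return n


def girard_lunar_oracle(r: float, omega: float) -> float:
    """Spherical-excess area of the equilateral spherical triangle of chord omega."""
    f = lambda t: 2 * r * r * (1 - math.cos(t) ** 2
                               - math.sin(t) ** 2 * math.cos(2 * math.pi / 3)) - omega ** 2
    t = brentq(f, 1e-9, math.pi / 2)
    verts = [np.array([math.sin(t) * math.cos(a), math.sin(t) * math.sin(a),
                       math.cos(t)]) for a in (0, 2 * math.pi / 3, 4 * math.pi / 3)]
    angle_sum = 0.0
    for i in range(3):
        A, B, C = verts[i], verts[(i + 1) % 3], verts[(i + 2) % 3]
        u = B - A * (A @ B)
        v = C - A * (A @ C)
        cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
        angle_sum += math.acos(np.clip(cosang, -1.0, 1.0))
    return (angle_sum - math.pi) * r * r


def mc_patch_oracle(kind: str, r: float, omega: float, n: int = 400_000,
                    seed: int = 0) -> float:
    """Monte Carlo surface integral over the centred equilateral triangle."""
    verts = [np.array([math.cos(a), math.sin(a)]) * omega / math.sqrt(3)
             for a in (-math.pi / 6, math.pi / 2, 7 * math.pi / 6)]
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=(n, 2))
    flip = u.sum(axis=1) > 1
    u[flip] = 1 - u[flip]
    p = verts[0] + np.outer(u[:, 0], verts[1] - verts[0]) \
        + np.outer(u[:, 1], verts[2] - verts[0])
    x, y = p[:, 0], p[:, 1]
    area = flat_triangle_area(omega)
    if kind == "sphere":
        return float(area * np.mean(r / np.sqrt(r * r - x * x - y * y)))
    return float(area * np.mean(r / np.sqrt(r * r - x * x)))


def row_enumeration_oracle(r_in: float, L: float, omega: float) -> int:
    """Count triangular-tiling cells row by row along a cylinder axis."""
    row_height = omega * math.sqrt(3.0) / 2.0
    per_row = 2 * greedy_circle_oracle(r_in, omega)
    n, z = 0, 0.0
    while z + row_height <= L + 1e-12:
        n += per_row
        z += row_height
    return n


# ---------------------------------------------------------------------------
# closed form vs oracle on random small instances
# ---------------------------------------------------------------------------

class TestOracles:
    def test_circle_capacity_vs_greedy_placement(self, rng):
        for _ in range(25):
            r1 = float(rng.uniform(5.0, 400.0))
            h = float(rng.uniform(0.0, 3.5))
            geom = TrimerGeometry(insertion_depth=h)
            assert circle_capacity(r1, geom) == greedy_circle_oracle(r1 - h, OMEGA)

    def test_lunar_area_vs_girard_excess(self, rng):
        for _ in range(25):
            r = float(rng.uniform(5.0, 500.0))
            assert lunar_triangle_area(r, OMEGA) == pytest.approx(
                girard_lunar_oracle(r, OMEGA), rel=1e-9)

    def test_sphere_patch_closed_vs_integral(self, rng):
        for _ in range(25):
            r = float(rng.uniform(5.0, 500.0))
            assert sphere_patch_area(r, OMEGA, "closed") == pytest.approx(
                sphere_patch_area(r, OMEGA, "integral"), rel=1e-3)

    def test_cylinder_patch_closed_vs_integral(self, rng):
        for _ in range(25):
            r = float(rng.uniform(4.1, 500.0))
            assert cylinder_patch_area(r, OMEGA, "closed") == pytest.approx(
                cylinder_patch_area(r, OMEGA, "integral"), rel=1e-3)

    @pytest.mark.parametrize("kind,r", [("sphere", 10.0), ("cylinder", 15.0)])
    def test_patch_vs_monte_carlo(self, kind, r):
        fn = sphere_patch_area if kind == "sphere" else cylinder_patch_area
        assert fn(r, OMEGA, "integral") == pytest.approx(
            mc_patch_oracle(kind, r, OMEGA), rel=1e-3)

    def test_cylinder_capacity_vs_row_enumeration(self, rng):
        for _ in range(20):
            r = float(rng.uniform(10.0, 300.0))
            L = float(rng.uniform(10.0, 2000.0))
            h = float(rng.uniform(0.0, 3.5))
            geom = TrimerGeometry(insertion_depth=h)
            assert cylinder_capacity(r, L, geom) == row_enumeration_oracle(
                r - h, L, OMEGA)

    def test_soma_capacity_vs_direct_evaluation(self):
        # r = 5 um, K = 5, delta1 = 5 um in nm
        geom = TrimerGeometry()
        r, K, d = 5000.0, 5, 5000.0
        cap = 2 * math.pi * r * (r - math.sqrt(r * r - (d / 2) ** 2))
        expect = int((4 * math.pi * r * r - K * cap) / (4 * math.pi * r * r)
                     * sphere_capacity(r, geom))
        assert soma_capacity(r, K, d, geom) == expect


class TestLimits:
    def test_flat_limits_of_patch_areas(self):
        flat = flat_triangle_area(OMEGA)
        assert sphere_patch_area(1e7, OMEGA, "integral") == pytest.approx(flat, rel=1e-6)
        assert cylinder_patch_area(1e7, OMEGA, "integral") == pytest.approx(flat, rel=1e-6)
        assert lunar_triangle_area(1e7, OMEGA) == pytest.approx(flat, rel=1e-4)

    def test_omega_to_zero(self):
        assert sphere_patch_area(10.0, 0.0) == 0.0
        assert cylinder_patch_area(10.0, 0.0) == 0.0

    def test_perimeter_fully_tiled_at_large_radius(self):
        geom = TrimerGeometry()  # h_in = 0
        r = 1e6
        n = circle_capacity(r, geom)
        assert n * OMEGA / (2 * math.pi * r) == pytest.approx(1.0, abs=1e-4)

    def test_planar_density_limit_on_large_shapes(self):
        geom = TrimerGeometry()
        r = 2e5
        n = sphere_capacity(r, geom)
        density = 3.0 * n / (4 * math.pi * r * r)
        assert density == pytest.approx(planar_monomer_density(OMEGA), rel=1e-3)
        n_cyl = cylinder_capacity(r, 1e4, geom)
        rows = int(1e4 / (OMEGA * math.sqrt(3) / 2))
        dens_cyl = 3.0 * n_cyl / (2 * math.pi * r * rows * OMEGA * math.sqrt(3) / 2)
        assert dens_cyl == pytest.approx(planar_monomer_density(OMEGA), rel=1e-3)

    def test_cylinder_occupied_fraction_plateau_below_one(self):
        geom = TrimerGeometry(insertion_depth=1.75)
        for r in (1e3, 1e4, 1e5):
            L = 1e4
            n = cylinder_capacity(r, L, geom)
            phi = n * cylinder_patch_area(r, OMEGA, "closed") / (2 * math.pi * r * L)
            assert 0.8 < phi < 1.0


class TestDegenerateGeometry:
    def test_too_small_shapes_hold_nothing(self):
        geom = TrimerGeometry(insertion_depth=3.5)
        assert circle_capacity(5.0, geom) == 0        # omega > 2 r_-1
        assert sphere_capacity(7.0, geom) == 0        # below circumradius
        assert cylinder_capacity(40.0, 5.0, geom) == 0  # L < row height
        assert disc_capacity(3.0, OMEGA) == 0
        assert tip_capacity(5.0, geom) == 0

    def test_lunar_area_raises_below_chord_limit(self):
        with pytest.raises(ValueError):
            lunar_triangle_area(3.9, OMEGA)

    def test_full_cap_exclusion_empties_the_soma(self):
        geom = TrimerGeometry()
        assert soma_capacity(100.0, 2, 200.0, geom) == 0   # two hemispheric caps

    def test_k_zero_is_plain_sphere(self):
        geom = TrimerGeometry(insertion_depth=1.75)
        assert soma_capacity(5000.0, 0, 5000.0, geom) == sphere_capacity(5000.0, geom)

    def test_hemisphere_is_half_sphere(self):
        geom = TrimerGeometry()
        assert tip_capacity(40.0, geom) == sphere_capacity(40.0, geom) // 2


class TestMonotonicity:
    @pytest.mark.parametrize("r", [20.0, 40.0, 100.0, 1000.0])
    def test_capacities_non_increasing_in_insertion_depth(self, r):
        depths = np.linspace(0.0, 3.5, 8)
        for fn in (lambda g: circle_capacity(r, g),
                   lambda g: sphere_capacity(r, g),
                   lambda g: cylinder_capacity(r, 500.0, g)):
            vals = [fn(TrimerGeometry(insertion_depth=h)) for h in depths]
            assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_capacities_non_decreasing_in_radius(self):
        geom = TrimerGeometry(insertion_depth=3.5)
        radii = np.linspace(10.0, 400.0, 25)
        vals = [sphere_capacity(r, geom) for r in radii]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_tip_occupied_fraction_drops_with_insertion(self):
        r = 40.0
        phis = []
        for h in (0.0, 3.5):
            geom = TrimerGeometry(insertion_depth=h)
            n = tip_capacity(r, geom)
            phi = n * sphere_patch_area(r, OMEGA, "closed") / (2 * math.pi * r * r)
            phis.append(min(phi, 1.0))
        assert phis[1] < phis[0]


class TestWholeCell:
    def test_single_segment_tree_equals_cylinder(self):
        from astrodensity.morphology import MorphologyParams, generate_astrocyte
        params = MorphologyParams(n_primary_range=(1, 1),
                                  max_primary_branchpoints=1, max_levels=1)
        model = generate_astrocyte(params, seed=2, with_leaves=False)
        geom = TrimerGeometry(insertion_depth=1.75)
        seg = model.segments[0]
        a, n, s = tree_capacity(model, geom)
        assert n == cylinder_capacity(seg.diameter / 2 * 1000,
                                      seg.length * 1000, geom)
        assert a == pytest.approx(math.pi * seg.diameter * seg.length)

    def test_branch_point_crowding_reduces_capacity(self, small_cell):
        geom = TrimerGeometry(insertion_depth=1.75)
        parents = [s for s in small_cell.segments if s.daughter_diameters]
        assert parents
        seg = parents[0]
        from astrodensity.packing import _segment_packing
        _, n_crowded, _ = _segment_packing(seg, geom)
        bare = cylinder_capacity(seg.diameter / 2 * 1000, seg.length * 1000, geom)
        assert n_crowded < bare

    def test_cell_assembly_conservation_and_ordering(self, small_cell):
        geom = TrimerGeometry(insertion_depth=1.75)
        res = cell_max_density(small_cell, geom)
        assert res.n_total == sum(s.n_trimers for s in res.compartments.values())
        assert res.sigma_monomer == pytest.approx(3 * res.n_total / res.area_total)
        for s in res.compartments.values():
            assert 0.0 <= s.occupied_fraction <= 1.0
        assert 0.0 < res.phi <= 1.0
        # fine structure packs less densely than the soma sphere
        assert res.compartments["tips_leaves"].trimer_density \
            < res.compartments["soma"].trimer_density

    def test_sigma_decreases_with_insertion_depth_everywhere(self, small_cell):
        results = [cell_max_density(small_cell, TrimerGeometry(insertion_depth=h))
                   for h in (0.0, 1.75, 3.5)]
        for comp in results[0].compartments:
            dens = [r.compartments[comp].trimer_density for r in results]
            assert dens[0] >= dens[1] >= dens[2]
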