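"""Stochastic astrocyte generator: structure rules, determinism, morphometrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from astrodensity.morphology import (COMPARTMENTS, MorphologyParams,
                                     classify_compartments, cube_cover,
                                     generate_astrocyte, load_swc,
                                     morphometrics, save_swc, sholl_profile,
                                     soma_cap_area, split_diameter)


class TestSplitDiameter:
    def test_symmetric_split_matches_reference(self):
        d1, d2 = split_diameter(1.3, 1.0)
        assert d1 == d2
        assert d2 == pytest.approx(0.819, abs=1e-3)   # ~0.8 um secondary

    def test_large_bias_limit(self):
        d1, d2 = split_diameter(1.0, 50.0)
        assert d2 < 0.05
        assert d1 == pytest.approx(1.0, rel=1e-2)

    @given(st.floats(min_value=0.01, max_value=10.0),
           st.floats(min_value=1.0, max_value=100.0))
    @settings(max_examples=100, deadline=None)
    def test_three_halves_identity(self, D, f):
        d1, d2 = split_diameter(D, f)
        assert d1 ** 1.5 + d2 ** 1.5 == pytest.approx(D ** 1.5, rel=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            split_diameter(-1.0, 1.2)
        with pytest.raises(ValueError):
            split_diameter(1.0, 0.5)


class TestGeneration:
    def test_same_seed_is_bit_identical(self):
        a = generate_astrocyte(seed=123)
        b = generate_astrocyte(seed=123)
        assert len(a.segments) == len(b.segments)
        assert len(a.leaves) == len(b.leaves)
        for sa, sb in zip(a.segments, b.segments):
            assert np.array_equal(sa.start, sb.start)
            assert np.array_equal(sa.end, sb.end)
            assert sa.diameter == sb.diameter

    def test_different_seeds_differ(self):
        a = generate_astrocyte(seed=1)
        b = generate_astrocyte(seed=2)
        assert len(a.segments) != len(b.segments) or not np.array_equal(
            a.segments[0].end, b.segments[0].end)

    def test_no_primaries_gives_bare_sphere(self):
        model = generate_astrocyte(MorphologyParams(n_primary_range=(0, 0)), seed=0)
        assert not model.segments and not model.leaves
        areas = classify_compartments(model)
        assert areas["soma"] == pytest.approx(4 * math.pi * 25.0)
        assert sum(v for k, v in areas.items() if k != "soma") == 0.0

    def test_structure_rules_hold_across_ensemble(self, ensemble):
        for model in ensemble:
            assert 3 <= model.n_primary <= 7
            levels = [s.level for s in model.segments]
            assert max(levels) <= 11
            by_id = {s.id: s for s in model.segments}
            continuation = {}   # parent segment id -> same-branch child
            for s in model.segments:
                if s.parent >= 0 and by_id[s.parent].branch == s.branch:
                    continuation[s.parent] = s
            # every branch point satisfies the biased 3/2 identity
            for seg in model.segments:
                for d2 in seg.daughter_diameters:
                    d1 = continuation[seg.id].diameter
                    assert d1 ** 1.5 + d2 ** 1.5 == pytest.approx(
                        seg.diameter ** 1.5, rel=1e-9)
            # daughters: level = parent level + 1; continuations: equal
            for seg in model.segments:
                if seg.parent >= 0:
                    parent = by_id[seg.parent]
                    expected = parent.level if seg.branch == parent.branch \
                        else parent.level + 1
                    assert seg.level == expected

    def test_branchpoint_budgets(self, ensemble):
        for model in ensemble:
            per_branch: dict[int, int] = {}
            level_of: dict[int, int] = {}
            for seg in model.segments:
                per_branch[seg.branch] = per_branch.get(seg.branch, 0) \
                    + len(seg.daughter_diameters)
                level_of[seg.branch] = seg.level
            for branch, n_bp in per_branch.items():
                cap = 15 if level_of[branch] == 1 else 11
                assert n_bp <= cap

    def test_terminal_tips_at_least_termination_floor(self, ensemble):
        # tips can only undershoot d_max via leaf-emission updates
        for model in ensemble:
            for seg in model.terminal_segments():
                assert seg.diameter > 0.0
                assert seg.tip_diameter is not None


class TestLeaves:
    def test_leaf_geometry(self, ensemble):
        model = ensemble[0]
        assert model.leaves, "default cells must carry leaves"
        for leaf in model.leaves[:200]:
            assert leaf.length == pytest.approx(0.7)
            seg = model.segments[leaf.segment_id]
            # perpendicular to the parent axis
            assert abs(float(leaf.direction @ seg.direction)) < 1e-9
            assert leaf.diameter < seg.diameter

    def test_mean_tip_leaf_diameter_in_range(self, ensemble_stats):
        means = [m.mean_tip_leaf_diameter for m, _ in ensemble_stats]
        assert 0.02 < np.mean(means) < 0.19

    def test_short_branch_bears_no_leaves(self):
        params = MorphologyParams(n_primary_range=(1, 1),
                                  max_primary_branchpoints=1, max_levels=1,
                                  segment_baseline_max=1e-6,
                                  segment_extra_max=2.0)
        model = generate_astrocyte(params, seed=3)
        total_len = sum(s.length for s in model.segments)
        assert total_len < 3.0 and len(model.leaves) == 0


class TestSholl:
    def test_sphere_only_has_no_intersections(self):
        model = generate_astrocyte(MorphologyParams(n_primary_range=(0, 0)), seed=0)
        assert sholl_profile(model).size == 0

    def test_single_straight_primary(self):
        params = MorphologyParams(n_primary_range=(1, 1),
                                  max_primary_branchpoints=1, max_levels=1,
                                  segment_baseline_max=20.0)
        model = generate_astrocyte(params, seed=5, with_leaves=False)
        seg = model.segments[0]
        counts = sholl_profile(model, spacing=0.5)
        r0, r1 = 5.0, 5.0 + seg.length
        radii = np.arange(0.5, r1 + 0.5, 0.5)[:counts.size]
        inside = (radii > r0) & (radii <= r1)
        assert np.array_equal(counts[inside], np.ones(inside.sum(), dtype=int))
        assert counts[~inside].sum() == 0

    def test_profile_counts_nonnegative_and_finite(self, ensemble):
        counts = sholl_profile(ensemble[0])
        assert counts.min() >= 0
        assert counts.sum() > 0


class TestCompartments:
    def test_fractions_sum_to_one(self, ensemble):
        for model in ensemble:
            areas = classify_compartments(model)
            m = morphometrics(model)
            assert sum(m.compartment_fractions.values()) == pytest.approx(1.0, abs=1e-9)
            assert sum(areas.values()) == pytest.approx(m.surface_area, rel=1e-12)

    def test_soma_cap_subtraction(self):
        # hemispheric cap: delta = 2r removes half the sphere
        assert soma_cap_area(5.0, 10.0) == pytest.approx(2 * math.pi * 25.0)
        with pytest.raises(ValueError):
            soma_cap_area(5.0, 11.0)


class TestCubeCover:
    def test_empty_model_is_an_error(self):
        model = generate_astrocyte(MorphologyParams(n_primary_range=(0, 0)), seed=0)
        with pytest.raises(ValueError, match="non-core"):
            cube_cover(model)

    def test_cover_statistics_positive(self, ensemble_stats):
        for _, cc in ensemble_stats:
            assert 0 < cc["neuropil_fraction"] < 1
            assert cc["process_density"] > 0
            assert cc["kept_cubes"] > 0


class TestMorphometrics:
    def test_single_cylinder_sv_ratio(self):
        params = MorphologyParams(n_primary_range=(1, 1),
                                  max_primary_branchpoints=1, max_levels=1,
                                  segment_baseline_max=24.99)
        model = generate_astrocyte(params, seed=11, with_leaves=False)
        seg = model.segments[0]
        r = seg.diameter / 2.0
        # lateral S/V of a long cylinder = 2/r
        assert seg.lateral_area / seg.volume == pytest.approx(2.0 / r, rel=1e-12)

    def test_whole_cell_quantities_positive(self, ensemble_stats):
        for m, _ in ensemble_stats:
            assert m.volume > m.volume_no_leaves > 0
            assert m.surface_area > m.surface_area_no_leaves > 0
            assert m.sv_ratio > m.sv_ratio_no_leaves > 0
            assert m.radius > 5.0
            assert 0 < m.non_core_volume_fraction < 1


class TestSwcRoundTrip:
    def test_save_load_preserves_packing_inputs(self, small_cell, tmp_path):
        path = tmp_path / "cell.swc"
        save_swc(small_cell, path)
        loaded = load_swc(path)
        assert len(loaded.segments) == len(small_cell.segments)
        assert len(loaded.leaves) == len(small_cell.leaves)
        for a, b in zip(small_cell.segments, loaded.segments):
            assert a.level == b.level and a.is_terminal == b.is_terminal
            assert a.diameter == pytest.approx(b.diameter)
            assert np.allclose(a.end, b.end)
        m0, m1 = morphometrics(small_cell), morphometrics(loaded)
        assert m0.surface_area == pytest.approx(m1.surface_area, rel=1e-9)
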