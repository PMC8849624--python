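"""Stochastic 3D model astrocytes: recursive branching, leaves, morphometrics.

A model astrocyte is a spherical soma (radius 5 um) with 3-7 straight primary
branches (diameter 5 um) emerging radially at random points.  Branches grow as
chains of cylindrical segments; at each branching point the parent spawns one
daughter at an opening angle that widens with branching level, and the two
emerging diameters follow the Rall 3/2 rule ``D^{3/2} = d1^{3/2} + d2^{3/2}``
with a random bias ``d1 = f d2`` (f ~ U(1, 1.5)).  A branch terminates when
either emerging diameter falls below a per-primary termination diameter
d_max ~ U(0.02, 0.15) um, or when branching-point/level budgets are exhausted.
Terminal tips are hemispheres.  Leaves — thin 0.7-um lateral cylinders whose
diameter also follows the 3/2 rule with a thickness-adaptive bias — decorate
every branch every 3-8 um.

All lengths are micrometres.  Morphometric readouts (Sholl profile,
compartment surface fractions, 2-um walking-cube neuropil cover, S/V ratios)
are computed analytically from the cylinder/sphere/hemisphere primitives.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MorphologyParams",
    "BranchSegment",
    "Leaf",
    "AstrocyteModel",
    "Morphometrics",
    "split_diameter",
    "generate_astrocyte",
    "add_leaves",
    "sholl_profile",
    "classify_compartments",
    "cube_cover",
    "morphometrics",
    "soma_cap_area",
    "save_swc",
    "load_swc",
]

COMPARTMENTS = ("tips_leaves", "shafts", "stems", "soma")


@dataclass(frozen=True)
class MorphologyParams:
    """Generator parameters; defaults reproduce the reference hippocampal model."""

    soma_radius: float = 5.0            # um
    n_primary_range: tuple[int, int] = (3, 7)     # inclusive
    primary_diameter: float = 5.0       # um
    max_primary_branchpoints: int = 15  # M: branching points per primary branch
    max_levels: int = 11                # N: levels, and branching points per higher-order branch
    base_opening_angle: float = math.pi / 6.0
    opening_increment: float = math.pi / 80.0   # added per branching level
    segment_baseline_max: float = 25.0  # c0 ~ U(0, 25) per cell
    segment_extra_max: float = 10.0     # per-segment extra ~ U(0, 10)
    diameter_bias_range: tuple[float, float] = (1.0, 1.5)   # f ~ U(1, 1.5)
    termination_diameter_range: tuple[float, float] = (0.02, 0.15)  # d_max per primary
    leaf_length: float = 0.7            # um
    leaf_spacing_range: tuple[float, float] = (3.0, 8.0)    # um between leaves
    leaf_end_margin: float = 0.35       # no leaves this close to segment endpoints
    core_diameter_threshold: float = 1.0  # branches thicker than this are "core"

    def __post_init__(self) -> None:
        if self.soma_radius <= 0 or self.primary_diameter <= 0:
            raise ValueError("soma radius and primary diameter must be positive")
        if self.n_primary_range[0] < 0 or self.n_primary_range[0] > self.n_primary_range[1]:
            raise ValueError("invalid primary-branch count range")
        lo, hi = self.termination_diameter_range
        if not (0 < lo <= hi):
            raise ValueError("invalid termination diameter range")
        if self.diameter_bias_range[0] < 1.0:
            raise ValueError("diameter bias f must be >= 1")


@dataclass
class BranchSegment:
    """Cylinder between two branching points (or a point and a terminus)."""

    id: int
    parent: int                 # id of upstream segment, -1 for primaries
    branch: int                 # id of the branch (chain of continuations)
    level: int                  # 1 = primary
    start: np.ndarray
    end: np.ndarray
    diameter: float
    is_terminal: bool = False
    tip_diameter: float | None = None   # terminal hemisphere diameter (after leaf update)
    daughter_diameters: list[float] = field(default_factory=list)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def direction(self) -> np.ndarray:
        v = self.end - self.start
        return v / np.linalg.norm(v)

    @property
    def lateral_area(self) -> float:
        return math.pi * self.diameter * self.length

    @property
    def volume(self) -> float:
        return math.pi * (self.diameter / 2.0) ** 2 * self.length


@dataclass
class Leaf:
    """Thin lateral protrusion: 0.7-um cylinder with a hemispheric cap."""

    segment_id: int
    base: np.ndarray
    direction: np.ndarray
    length: float
    diameter: float

    @property
    def area(self) -> float:      # lateral + hemispheric cap
        r = self.diameter / 2.0
        return math.pi * self.diameter * self.length + 2.0 * math.pi * r * r

    @property
    def volume(self) -> float:
        r = self.diameter / 2.0
        return math.pi * r * r * self.length + (2.0 / 3.0) * math.pi * r ** 3


@dataclass
class AstrocyteModel:
    """Soma sphere + branch segments + leaves."""

    params: MorphologyParams
    segments: list[BranchSegment]
    leaves: list[Leaf] = field(default_factory=list)
    n_primary: int = 0
    branch_points: int = 0
    seed: int | None = None

    @property
    def soma_radius(self) -> float:
        return self.params.soma_radius

    @property
    def levels(self) -> int:
        return max((s.level for s in self.segments), default=0)

    def terminal_segments(self) -> list[BranchSegment]:
        return [s for s in self.segments if s.is_terminal]

    def primary_diameters(self) -> list[float]:
        return [s.diameter for s in self.segments if s.level == 1 and s.parent == -1]


@dataclass
class Morphometrics:
    """Whole-cell analytic morphometry."""

    volume: float               # um^3, with leaves
    volume_no_leaves: float
    surface_area: float         # um^2, with leaves
    surface_area_no_leaves: float
    total_branch_length: float  # um
    branch_points: int
    levels: int
    n_leaves: int
    n_tips: int
    radius: float               # R_astro: farthest structure point from soma centre
    sv_ratio: float             # surface / volume, with leaves (um^-1)
    sv_ratio_no_leaves: float
    compartment_areas: dict[str, float]
    compartment_fractions: dict[str, float]
    mean_tip_leaf_diameter: float
    non_core_volume_fraction: float   # fine-structure share of total volume


# ---------------------------------------------------------------------------
# 3/2 rule
# ---------------------------------------------------------------------------

def split_diameter(D: float, f: float) -> tuple[float, float]:
    """Daughter/continuation diameters from the biased Rall 3/2 rule.

    ``D^{3/2} = d1^{3/2} + d2^{3/2}`` with ``d1 = f d2``; d1 is the parent
    continuation, d2 the daughter.  For f = 1 the split is symmetric.
    """
    if D <= 0:
        raise ValueError("parent diameter must be positive")
    if f < 1.0:
        raise ValueError("bias f must be >= 1")
    d2 = D / (1.0 + f ** 1.5) ** (2.0 / 3.0)
    return f * d2, d2


def _leaf_continuation_factor(f: float) -> float:
    """Parent-diameter multiplier after emitting one leaf with bias f."""
    return f / (1.0 + f ** 1.5) ** (2.0 / 3.0)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _perpendicular_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``axis`` (deterministic reference frame)."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    return u, np.cross(axis, u)


def _rotated_direction(axis: np.ndarray, opening: float, azimuth: float) -> np.ndarray:
    """Unit vector at angle ``opening`` from axis, rotated by ``azimuth`` about it."""
    u, w = _perpendicular_frame(axis)
    d = (math.cos(opening) * axis
         + math.sin(opening) * (math.cos(azimuth) * u + math.sin(azimuth) * w))
    return d / np.linalg.norm(d)


class _Builder:
    def __init__(self, params: MorphologyParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.segments: list[BranchSegment] = []
        self.branch_points = 0
        self._next_branch = 0

    def grow_branch(self, start: np.ndarray, direction: np.ndarray, diameter: float,
                    level: int, parent_seg: int, c: float, d_max: float) -> None:
        p = self.params
        rng = self.rng
        branch_id = self._next_branch
        self._next_branch += 1
        max_bp = p.max_primary_branchpoints if level == 1 else p.max_levels

        pos, D, prev = np.asarray(start, dtype=float), diameter, parent_seg
        last: BranchSegment | None = None
        # a branch is segment, bp, segment, ..., bp, final segment: every
        # branching point is followed by a thinner continuation
        for n_bp in range(max_bp + 1):
            length = c + rng.uniform(0.0, p.segment_extra_max)
            end = pos + length * direction
            seg = BranchSegment(id=len(self.segments), parent=prev, branch=branch_id,
                                level=level, start=pos, end=end, diameter=D)
            self.segments.append(seg)
            prev, last = seg.id, seg

            if n_bp == max_bp or level >= p.max_levels:
                break
            f = rng.uniform(*p.diameter_bias_range)
            d1, d2 = split_diameter(D, f)
            if d1 < d_max or d2 < d_max:
                break
            opening = p.base_opening_angle + (level - 1) * p.opening_increment
            azimuth = rng.uniform(0.0, 2.0 * math.pi)
            daughter_dir = _rotated_direction(direction, opening, azimuth)
            self.branch_points += 1
            seg.daughter_diameters.append(d2)
            self.grow_branch(end, daughter_dir, d2, level + 1, seg.id, c, d_max)
            pos, D = end, d1
        if last is not None:
            last.is_terminal = True
            last.tip_diameter = last.diameter


def generate_astrocyte(params: MorphologyParams = MorphologyParams(),
                       seed: int | np.random.Generator | None = None,
                       with_leaves: bool = True) -> AstrocyteModel:
    """Generate one model astrocyte; the seed fixes the whole cell."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = _Builder(params, rng)
    lo, hi = params.n_primary_range
    n_primary = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
    c0 = rng.uniform(0.0, params.segment_baseline_max)

    for _ in range(n_primary):
        direction = _random_unit_vector(rng)
        start = params.soma_radius * direction   # radial emergence from the soma
        c = rng.uniform(0.0, c0)
        d_max = rng.uniform(*params.termination_diameter_range)
        b.grow_branch(start, direction, params.primary_diameter, 1, -1, c, d_max)

    model = AstrocyteModel(params=params, segments=b.segments,
                           n_primary=n_primary, branch_points=b.branch_points,
                           seed=seed if isinstance(seed, int) else None)
    if with_leaves and n_primary > 0:
        add_leaves(model, rng)
    return model


def add_leaves(model: AstrocyteModel, rng: np.random.Generator | int | None = None
               ) -> AstrocyteModel:
    """Attach leaves every 3-8 um along each branch, perpendicular to its axis.

    Leaf diameters follow the 3/2 rule with bias ``f = 0.5 + 3 (1 + rho) D``
    (rho ~ U(0, 1), D the parent diameter), so thick branches do not bear
    thick leaves.  The branch diameter is treated as constant along each
    segment; only the terminal tip hemisphere is updated for leaves emitted
    by the terminal segment.  Positions closer than 0.35 um to a segment
    endpoint are skipped to avoid overlapping the branch-point geometry.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p = model.params
    by_branch: dict[int, list[BranchSegment]] = {}
    for seg in model.segments:
        by_branch.setdefault(seg.branch, []).append(seg)

    for segs in by_branch.values():
        lengths = np.array([s.length for s in segs])
        cum = np.concatenate([[0.0], np.cumsum(lengths)])
        total = float(cum[-1])
        pos = rng.uniform(*p.leaf_spacing_range)
        while pos < total:
            i = int(np.searchsorted(cum, pos, side="right")) - 1
            i = min(i, len(segs) - 1)
            seg = segs[i]
            offset = pos - cum[i]
            if p.leaf_end_margin <= offset <= seg.length - p.leaf_end_margin:
                rho = rng.uniform(0.0, 1.0)
                f = 0.5 + 3.0 * (1.0 + rho) * seg.diameter
                d_leaf = seg.diameter / (1.0 + f ** 1.5) ** (2.0 / 3.0)
                azimuth = rng.uniform(0.0, 2.0 * math.pi)
                u, w = _perpendicular_frame(seg.direction)
                direction = math.cos(azimuth) * u + math.sin(azimuth) * w
                model.leaves.append(Leaf(seg.id, seg.start + offset * seg.direction,
                                         direction, p.leaf_length, d_leaf))
                if seg.is_terminal:
                    seg.tip_diameter = (seg.tip_diameter or seg.diameter) \
                        * _leaf_continuation_factor(f)
            pos += rng.uniform(*p.leaf_spacing_range)
    return model


# ---------------------------------------------------------------------------
# morphometrics
# ---------------------------------------------------------------------------

def soma_cap_area(r: float, delta: float) -> float:
    """Spherical-cap area covered on a soma of radius r by a branch of diameter delta."""
    if delta > 2.0 * r:
        raise ValueError("branch diameter cannot exceed the soma diameter")
    return 2.0 * math.pi * r * (r - math.sqrt(r * r - (delta / 2.0) ** 2))


def classify_compartments(model: AstrocyteModel) -> dict[str, float]:
    """Surface area (um^2) of the four membrane compartments.

    soma: sphere area minus the caps under the primary branches; stems:
    lateral area of levels 1-2; tips/leaves: terminal hemispheres plus leaf
    surfaces; shafts: lateral area of levels >= 3.  The four areas sum to the
    total model surface area exactly.
    """
    r = model.soma_radius
    soma = 4.0 * math.pi * r * r
    for delta in model.primary_diameters():
        soma -= soma_cap_area(r, delta)
    stems = sum(s.lateral_area for s in model.segments if s.level <= 2)
    shafts = sum(s.lateral_area for s in model.segments if s.level >= 3)
    tips = sum(2.0 * math.pi * ((s.tip_diameter or s.diameter) / 2.0) ** 2
               for s in model.terminal_segments())
    leaves = sum(leaf.area for leaf in model.leaves)
    return {"tips_leaves": tips + leaves, "shafts": shafts,
            "stems": stems, "soma": max(soma, 0.0)}


def sholl_profile(model: AstrocyteModel, spacing: float = 0.5) -> np.ndarray:
    """Branch-centreline intersections with concentric spheres (0.5 um apart).

    Shells are centred on the soma; leaves are excluded.  Returns counts for
    shells at radii ``spacing, 2*spacing, ...`` out past the farthest branch
    point.
    """
    if not model.segments:
        return np.zeros(0, dtype=int)
    rmax = max(float(np.linalg.norm(s.end)) for s in model.segments)
    radii = np.arange(spacing, rmax + spacing, spacing)
    counts = np.zeros(radii.size, dtype=int)
    for seg in model.segments:
        a, b = seg.start, seg.end
        d0, d1 = float(np.linalg.norm(a)), float(np.linalg.norm(b))
        v = b - a
        L2 = float(v @ v)
        t_star = -float(a @ v) / L2 if L2 > 0 else 0.0
        lo_d, hi_d = min(d0, d1), max(d0, d1)
        if 0.0 < t_star < 1.0:
            dmin = float(np.linalg.norm(a + t_star * v))
            counts += 2 * ((radii > dmin) & (radii < lo_d))
            counts += (radii >= lo_d) & (radii <= hi_d)
        else:
            counts += (radii > lo_d) & (radii <= hi_d)
    return counts


def cube_cover(model: AstrocyteModel, cube_side: float = 2.0) -> dict[str, float]:
    """Walking-cube neuropil cover of the fine (non-core) structure.

    Space is partitioned into axis-aligned cubes of ``cube_side``; cubes
    intersected by non-core branches (diameter below 1 um) or leaves are
    retained as the simulated neuropil.  Returns the neuropil volume fraction
    (non-core structure volume / retained-cube volume) and the density of
    processes per um^3 of retained volume (non-core segments + leaves).
    """
    thr = model.params.core_diameter_threshold
    fine_segments = [s for s in model.segments if s.diameter < thr]
    if not fine_segments and not model.leaves:
        raise ValueError("model has no non-core structure to cover")

    occupied: set[tuple[int, int, int]] = set()

    def mark_line(p0: np.ndarray, p1: np.ndarray) -> None:
        L = float(np.linalg.norm(p1 - p0))
        n = max(2, int(math.ceil(L / (cube_side / 4.0))) + 1)
        pts = p0[None, :] + np.linspace(0.0, 1.0, n)[:, None] * (p1 - p0)[None, :]
        for idx in np.unique(np.floor(pts / cube_side).astype(int), axis=0):
            occupied.add(tuple(idx))

    for seg in fine_segments:
        mark_line(seg.start, seg.end)
    for leaf in model.leaves:
        mark_line(leaf.base, leaf.base + leaf.length * leaf.direction)

    kept_volume = len(occupied) * cube_side ** 3
    non_core_volume = (sum(s.volume for s in fine_segments)
                       + sum(leaf.volume for leaf in model.leaves)
                       + sum((2.0 / 3.0) * math.pi * ((s.tip_diameter or s.diameter) / 2.0) ** 3
                             for s in model.terminal_segments() if s.diameter < thr))
    n_processes = len(fine_segments) + len(model.leaves)
    return {
        "neuropil_fraction": non_core_volume / kept_volume,
        "process_density": n_processes / kept_volume,
        "kept_cubes": len(occupied),
        "kept_volume": kept_volume,
        "non_core_volume": non_core_volume,
        "n_processes": n_processes,
    }


def morphometrics(model: AstrocyteModel) -> Morphometrics:
    """Analytic whole-cell morphometry from cylinder/sphere/hemisphere sums."""
    r = model.soma_radius
    soma_volume = (4.0 / 3.0) * math.pi * r ** 3
    seg_volume = sum(s.volume for s in model.segments)
    tip_volume = sum((2.0 / 3.0) * math.pi * ((s.tip_diameter or s.diameter) / 2.0) ** 3
                     for s in model.terminal_segments())
    leaf_volume = sum(leaf.volume for leaf in model.leaves)
    leaf_area = sum(leaf.area for leaf in model.leaves)

    areas = classify_compartments(model)
    area_with = sum(areas.values())
    area_without = area_with - leaf_area
    vol_without = soma_volume + seg_volume + tip_volume
    vol_with = vol_without + leaf_volume

    thr = model.params.core_diameter_threshold
    non_core = (sum(s.volume for s in model.segments if s.diameter < thr)
                + leaf_volume
                + sum((2.0 / 3.0) * math.pi * ((s.tip_diameter or s.diameter) / 2.0) ** 3
                      for s in model.terminal_segments() if s.diameter < thr))

    endpoints = [float(np.linalg.norm(s.end)) for s in model.segments] or [r]
    tips_and_leaves = ([(s.tip_diameter or s.diameter) for s in model.terminal_segments()]
                       + [leaf.diameter for leaf in model.leaves])

    return Morphometrics(
        volume=vol_with,
        volume_no_leaves=vol_without,
        surface_area=area_with,
        surface_area_no_leaves=area_without,
        total_branch_length=sum(s.length for s in model.segments),
        branch_points=model.branch_points,
        levels=model.levels,
        n_leaves=len(model.leaves),
        n_tips=len(model.terminal_segments()),
        radius=max(endpoints),
        sv_ratio=area_with / vol_with,
        sv_ratio_no_leaves=area_without / vol_without,
        compartment_areas=areas,
        compartment_fractions={k: v / area_with for k, v in areas.items()},
        mean_tip_leaf_diameter=float(np.mean(tips_and_leaves)) if tips_and_leaves else 0.0,
        non_core_volume_fraction=non_core / vol_with,
    )


# ---------------------------------------------------------------------------
# SWC-like I/O
# ---------------------------------------------------------------------------

def save_swc(model: AstrocyteModel, path: str | Path) -> None:
    """Write an SWC-like morphology file plus a JSON sidecar for the leaves.

    Columns: id, type, x, y, z, radius, parent.  The type column stores the
    branching level (0 for the soma node); terminal nodes carry the updated
    tip radius.  Leaves (base point, direction, length, diameter) and
    generator metadata go to ``<path>.leaves.json``.
    """
    path = Path(path)
    lines = ["# id type x y z radius parent",
             f"1 0 0 0 0 {model.soma_radius} -1"]
    node_of_segment: dict[int, int] = {}
    next_id = 2
    for seg in model.segments:
        parent_node = node_of_segment.get(seg.parent, 1)
        x, y, z = seg.end
        radius = (seg.tip_diameter or seg.diameter) / 2.0 if seg.is_terminal \
            else seg.diameter / 2.0
        lines.append(f"{next_id} {seg.level} {x:.6f} {y:.6f} {z:.6f} "
                     f"{radius:.6f} {parent_node}")
        node_of_segment[seg.id] = next_id
        next_id += 1
    path.write_text("\n".join(lines) + "\n")

    sidecar = {
        "soma_radius": model.soma_radius,
        "n_primary": model.n_primary,
        "branch_points": model.branch_points,
        "seed": model.seed,
        "segments": [
            {"id": s.id, "parent": s.parent, "branch": s.branch, "level": s.level,
             "start": s.start.tolist(), "end": s.end.tolist(),
             "diameter": s.diameter, "is_terminal": s.is_terminal,
             "tip_diameter": s.tip_diameter,
             "daughter_diameters": s.daughter_diameters}
            for s in model.segments],
        "leaves": [
            {"segment_id": leaf.segment_id, "base": leaf.base.tolist(),
             "direction": leaf.direction.tolist(), "length": leaf.length,
             "diameter": leaf.diameter}
            for leaf in model.leaves],
    }
    Path(str(path) + ".leaves.json").write_text(json.dumps(sidecar))


def load_swc(path: str | Path, params: MorphologyParams = MorphologyParams()
             ) -> AstrocyteModel:
    """Reload a model written by :func:`save_swc` (sidecar required)."""
    sidecar = json.loads(Path(str(Path(path)) + ".leaves.json").read_text())
    segments = [BranchSegment(id=d["id"], parent=d["parent"], branch=d["branch"],
                              level=d["level"], start=np.array(d["start"]),
                              end=np.array(d["end"]), diameter=d["diameter"],
                              is_terminal=d["is_terminal"],
                              tip_diameter=d["tip_diameter"],
                              daughter_diameters=list(d["daughter_diameters"]))
                for d in sidecar["segments"]]
    leaves = [Leaf(segment_id=d["segment_id"], base=np.array(d["base"]),
                   direction=np.array(d["direction"]), length=d["length"],
                   diameter=d["diameter"])
              for d in sidecar["leaves"]]
    if sidecar["soma_radius"] != params.soma_radius:
        params = MorphologyParams(soma_radius=sidecar["soma_radius"])
    return AstrocyteModel(params=params, segments=segments, leaves=leaves,
                          n_primary=sidecar["n_primary"],
                          branch_points=sidecar["branch_points"],
                          seed=sidecar["seed"])
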