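"""Maximum packing of transporter trimers on curved astrocyte membranes.

Glial glutamate transporters assemble as trimers whose cross-section is
approximated by a triangular prism: an equilateral base of side omega = 8 nm
and height 6.5 nm.  On a curved membrane the trimers cannot tile the surface
as densely as on a plane, because the parts protruding toward the cytoplasm
(insertion depth ``h_in``, 0-3.5 nm depending on conformational state)
collide on the concave side.  The capacity of each elementary shape is
obtained by tiling the *inner* collision surface of radius ``r - h_in``:

* circle: chords of length omega around the inner circumference;
* sphere: the inner sphere partitioned into equilateral "lunar" spherical
  triangles of chord side omega (area from Girard's theorem);
* cylinder: planar triangular rows of height omega*sqrt(3)/2 wrapped around
  the inner circumference.

The membrane area each trimer occupies is the area of the outer surface above
a flat centred equilateral triangle of side omega, computed by numerical
integration (closed forms are kept as cross-checks).  Shape capacities are
assembled over a whole model astrocyte (soma sphere minus primary-branch
caps, cylindrical branch segments with branch-point crowding, hemispheric
tips, cylindrical leaves) into a maximal trimer/monomer surface density sigma
and occupied surface fraction Phi per sub-cellular compartment.

Shape-level functions use nanometres; whole-cell results are per um^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .morphology import COMPARTMENTS, AstrocyteModel, soma_cap_area

__all__ = [
    "TrimerGeometry",
    "ShapePacking",
    "PackingResult",
    "circle_capacity",
    "lunar_triangle_area",
    "sphere_capacity",
    "sphere_patch_area",
    "cylinder_patch_area",
    "cylinder_capacity",
    "disc_capacity",
    "soma_capacity",
    "tip_capacity",
    "tree_capacity",
    "cell_max_density",
    "flat_triangle_area",
    "planar_monomer_density",
]

NM2_PER_UM2 = 1e6


@dataclass(frozen=True)
class TrimerGeometry:
    """Triangular-prism approximation of a transporter trimer (nm)."""

    side: float = 8.0              # omega, nm
    height: float = 6.5            # prism height, nm
    insertion_depth: float = 0.0   # h_in, nm; cytoplasmic protrusion

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("trimer side must be positive")
        if not (0.0 <= self.insertion_depth <= self.height):
            raise ValueError("insertion depth must lie in [0, height]")

    def inner_radius(self, r: float) -> float:
        """Collision radius on the concave side of a shape of radius r (nm)."""
        return r - self.insertion_depth


def flat_triangle_area(omega: float) -> float:
    """Planar equilateral-triangle area, the flat limit of every patch."""
    return math.sqrt(3.0) / 4.0 * omega * omega


def planar_monomer_density(omega: float) -> float:
    """Flat-membrane monomer packing bound: 2 trimers per omega x omega*sqrt(3)/2 cell (nm^-2)."""
    return 3.0 * 2.0 / (omega * omega * math.sqrt(3.0) / 2.0)


# ---------------------------------------------------------------------------
# elementary shapes
# ---------------------------------------------------------------------------

def circle_capacity(r1: float, geom: TrimerGeometry = TrimerGeometry()) -> int:
    """Trimers that fit around the perimeter of a circle of radius r1 (nm).

    Bases are chords of length omega on the inner collision circle; each
    subtends 2*arcsin(omega / 2 r_-1).  Zero when the chord does not fit.
    """
    r_in = geom.inner_radius(r1)
    if r_in <= 0 or geom.side > 2.0 * r_in:
        return 0
    return int(math.pi / math.asin(geom.side / (2.0 * r_in)))


def lunar_triangle_area(r_minus1: float, omega: float) -> float:
    """Area of the equilateral spherical (lunar) triangle of chord side omega.

    From Girard's theorem, ``A = r^2 (3 alpha - pi)`` with
    ``cos(alpha) = (2 r^2 - omega^2) / (4 r^2 - omega^2)``; this is the
    surface budget one trimer base consumes on a sphere of radius r.
    """
    if 2.0 * r_minus1 <= omega:
        raise ValueError("sphere too small for the trimer chord")
    if r_minus1 <= omega / math.sqrt(3.0):
        # three pairwise chords of length omega need circumradius <= r
        raise ValueError("sphere smaller than the triangle circumradius")
    alpha = math.acos((2.0 * r_minus1 ** 2 - omega ** 2)
                      / (4.0 * r_minus1 ** 2 - omega ** 2))
    return r_minus1 ** 2 * (3.0 * alpha - math.pi)


def sphere_capacity(r1: float, geom: TrimerGeometry = TrimerGeometry()) -> int:
    """Trimers that fit on a sphere of radius r1 (nm): inner-sphere area / lunar triangle."""
    r_in = geom.inner_radius(r1)
    if r_in <= geom.side / math.sqrt(3.0):
        return 0
    return int(4.0 * math.pi * r_in ** 2 / lunar_triangle_area(r_in, geom.side))


def sphere_patch_area(r1: float, omega: float, method: str = "integral") -> float:
    """Membrane area on a sphere of radius r1 above a centred flat triangle of side omega.

    ``method='integral'`` (authoritative) integrates the surface-area element
    in polar coordinates; ``method='closed'`` evaluates the closed form
    ``2 pi r^2 - 3 r^2 [2 atan(sqrt(3)/sqrt(1-4 a^2)) - 2 a asin(sqrt(3) a /
    sqrt(1-a^2))]`` with ``a = omega / (2 sqrt(3) r1)``.
    """
    if omega <= 0:
        return 0.0
    circumradius = omega / math.sqrt(3.0)
    if circumradius >= r1:
        raise ValueError("triangle does not fit under the sphere")
    a = omega / (2.0 * math.sqrt(3.0) * r1)
    if method == "closed":
        return 2.0 * math.pi * r1 ** 2 - 3.0 * r1 ** 2 * (
            2.0 * math.atan(math.sqrt(3.0) / math.sqrt(1.0 - 4.0 * a * a))
            - 2.0 * a * math.asin(math.sqrt(3.0) * a / math.sqrt(1.0 - a * a)))
    if method != "integral":
        raise ValueError(f"unknown method {method!r}")

    def integrand(tau: float) -> float:
        # 1 - sqrt(1-u) written as u / (1 + sqrt(1-u)): stable for u -> 0
        u = (a / math.sin(tau)) ** 2
        return u / (1.0 + math.sqrt(max(0.0, 1.0 - u)))

    val, _ = quad(integrand, math.pi / 6.0, 5.0 * math.pi / 6.0,
                  limit=200, epsabs=0.0, epsrel=1e-11)
    return 3.0 * r1 ** 2 * val


def cylinder_patch_area(r_cyl: float, omega: float, method: str = "integral") -> float:
    """Membrane area on a cylinder of radius r_cyl above a centred flat triangle.

    The triangle has one median along the cylinder axis.  Closed form:
    ``sqrt(3) omega r asin(omega/2r) + sqrt(3) r sqrt(4 r^2 - omega^2)
    - 2 sqrt(3) r^2``.
    """
    if omega <= 0:
        return 0.0
    if omega / 2.0 >= r_cyl:
        raise ValueError("triangle does not fit under the cylinder")
    if method == "closed":
        return (math.sqrt(3.0) * omega * r_cyl * math.asin(omega / (2.0 * r_cyl))
                + math.sqrt(3.0) * r_cyl * math.sqrt(4.0 * r_cyl ** 2 - omega ** 2)
                - 2.0 * math.sqrt(3.0) * r_cyl ** 2)
    if method != "integral":
        raise ValueError(f"unknown method {method!r}")

    def integrand(x: float) -> float:
        # cross-triangle width at |x| times the cylindrical arc stretch
        return 2.0 * math.sqrt(3.0) * (omega / 2.0 - x) * r_cyl \
            / math.sqrt(r_cyl ** 2 - x * x)

    val, _ = quad(integrand, 0.0, omega / 2.0, limit=200)
    return val


def cylinder_capacity(r_cyl: float, L: float,
                      geom: TrimerGeometry = TrimerGeometry()) -> int:
    """Trimers on the lateral surface of a cylinder (nm), planar triangular tiling.

    Rows of height omega*sqrt(3)/2 stacked along the axis; within a row,
    alternating up/down triangles give two trimers per circumferential chord
    cell of the inner collision circle.
    """
    n_row = circle_capacity(r_cyl, geom)
    if n_row == 0 or L <= 0:
        return 0
    rows = int(L / (geom.side * math.sqrt(3.0) / 2.0))
    return rows * 2 * n_row


def disc_capacity(r: float, omega: float) -> int:
    """Trimers on a flat disc of radius r (area budget of the planar tiling)."""
    if 2.0 * r <= omega:
        return 0
    return int(math.pi * r * r / flat_triangle_area(omega))


def soma_capacity(r_soma: float, K: int, delta1: float,
                  geom: TrimerGeometry = TrimerGeometry()) -> int:
    """Trimers on the soma sphere after excluding K primary-branch caps.

    ``n = (4 pi r^2 - K A_cap) / (4 pi r^2) * n_sphere`` with the cap area
    under a branch of diameter delta1.  All lengths in nm.
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    a_total = 4.0 * math.pi * r_soma ** 2
    a_free = a_total - K * soma_cap_area(r_soma, delta1)
    if a_free <= 0:
        return 0
    return int(a_free / a_total * sphere_capacity(r_soma, geom))


def tip_capacity(r_tip: float, geom: TrimerGeometry = TrimerGeometry(),
                 mode: str = "hemisphere") -> int:
    """Trimers on a terminal process ending (nm).

    ``mode='hemisphere'``: half the sphere capacity.  ``mode='cylinder'``:
    a cylindrical ending of length r_tip plus its flat end disc.
    """
    if mode == "hemisphere":
        return sphere_capacity(r_tip, geom) // 2
    if mode == "cylinder":
        return (cylinder_capacity(r_tip, r_tip, geom)
                + disc_capacity(geom.inner_radius(r_tip), geom.side))
    raise ValueError(f"unknown tip mode {mode!r}")


# ---------------------------------------------------------------------------
# whole-cell assembly
# ---------------------------------------------------------------------------

@dataclass
class ShapePacking:
    """Capacity of one membrane compartment (areas in um^2)."""

    area: float = 0.0
    n_trimers: int = 0
    occupied_area: float = 0.0

    @property
    def n_monomers(self) -> int:
        return 3 * self.n_trimers

    @property
    def trimer_density(self) -> float:     # trimers / um^2
        return self.n_trimers / self.area if self.area > 0 else 0.0

    @property
    def monomer_density(self) -> float:    # molecules / um^2
        return 3.0 * self.trimer_density

    @property
    def occupied_fraction(self) -> float:
        if self.area <= 0:
            return 0.0
        return min(self.occupied_area / self.area, 1.0)

    def add(self, area_um2: float, n: int, occupied_um2: float) -> None:
        self.area += area_um2
        self.n_trimers += n
        # a trimer cannot occupy more membrane than exists on its shape
        self.occupied_area += min(occupied_um2, area_um2)


@dataclass
class PackingResult:
    """Per-compartment and whole-cell maximal packing of transporter trimers."""

    geom: TrimerGeometry
    compartments: dict[str, ShapePacking] = field(default_factory=dict)

    @property
    def area_total(self) -> float:
        return sum(s.area for s in self.compartments.values())

    @property
    def n_total(self) -> int:
        return sum(s.n_trimers for s in self.compartments.values())

    @property
    def occupied_total(self) -> float:
        return sum(s.occupied_area for s in self.compartments.values())

    @property
    def sigma_trimer(self) -> float:       # trimers / um^2, whole cell
        return self.n_total / self.area_total if self.area_total > 0 else 0.0

    @property
    def sigma_monomer(self) -> float:      # molecules / um^2, whole cell
        return 3.0 * self.sigma_trimer

    @property
    def phi(self) -> float:                # occupied surface fraction
        if self.area_total <= 0:
            return 0.0
        return min(self.occupied_total / self.area_total, 1.0)


def _um2(nm2: float) -> float:
    return nm2 / NM2_PER_UM2


def tree_capacity(model: AstrocyteModel, geom: TrimerGeometry = TrimerGeometry()
                  ) -> tuple[float, int, float]:
    """Total lateral area (um^2), trimer capacity and occupied area of the branch tree.

    Each segment is a cylinder; at every branch point a disc of the daughter's
    diameter is excluded from the parent's available area (crowding), scaling
    the segment's capacity by the remaining area fraction.
    """
    a_tree = 0.0
    n_tree = 0
    s_tree = 0.0
    for seg in model.segments:
        a, n, s = _segment_packing(seg, geom)
        a_tree += a
        n_tree += n
        s_tree += s
    return a_tree, n_tree, s_tree


def _segment_packing(seg, geom: TrimerGeometry) -> tuple[float, int, float]:
    r_nm = seg.diameter / 2.0 * 1000.0
    L_nm = seg.length * 1000.0
    area_nm2 = math.pi * seg.diameter * 1000.0 * L_nm
    n = cylinder_capacity(r_nm, L_nm, geom)
    if n > 0 and seg.daughter_diameters:
        excluded = sum(math.pi * (d / 2.0 * 1000.0) ** 2
                       for d in seg.daughter_diameters)
        n = int(n * max(0.0, 1.0 - excluded / area_nm2))
    occupied = 0.0
    if n > 0:
        occupied = n * cylinder_patch_area(r_nm, geom.side, method="closed")
    return _um2(area_nm2), n, _um2(occupied)


def cell_max_density(model: AstrocyteModel,
                     geom: TrimerGeometry = TrimerGeometry()) -> PackingResult:
    """Maximal trimer packing of a whole model astrocyte, by compartment.

    Compartments follow the morphology classification: soma (sphere minus
    primary caps, Eq-10-style area scaling), stems (level 1-2 segments),
    shafts (level >= 3 segments), tips/leaves (terminal hemispheres plus leaf
    cylinders with hemispheric caps).
    """
    res = PackingResult(geom=geom, compartments={c: ShapePacking()
                                                 for c in COMPARTMENTS})
    omega = geom.side
    r_soma_nm = model.soma_radius * 1000.0

    # soma
    prim = model.primary_diameters()
    a_soma_nm2 = 4.0 * math.pi * r_soma_nm ** 2
    for d in prim:
        a_soma_nm2 -= soma_cap_area(r_soma_nm, d * 1000.0)
    n_soma = 0
    occ_soma = 0.0
    if a_soma_nm2 > 0:
        frac = a_soma_nm2 / (4.0 * math.pi * r_soma_nm ** 2)
        n_soma = int(frac * sphere_capacity(r_soma_nm, geom))
        occ_soma = n_soma * sphere_patch_area(r_soma_nm, omega, method="closed")
    res.compartments["soma"].add(_um2(max(a_soma_nm2, 0.0)), n_soma, _um2(occ_soma))

    # branch segments -> stems / shafts
    for seg in model.segments:
        a, n, s = _segment_packing(seg, geom)
        key = "stems" if seg.level <= 2 else "shafts"
        res.compartments[key].add(a, n, s)

    # terminal hemispheres
    tl = res.compartments["tips_leaves"]
    for seg in model.terminal_segments():
        d = seg.tip_diameter or seg.diameter
        r_nm = d / 2.0 * 1000.0
        area = 2.0 * math.pi * r_nm ** 2
        n = tip_capacity(r_nm, geom, mode="hemisphere")
        occ = 0.0
        if n > 0:
            occ = n * sphere_patch_area(r_nm, omega, method="closed")
        tl.add(_um2(area), n, _um2(occ))

    # leaves: lateral cylinder + hemispheric cap
    for leaf in model.leaves:
        r_nm = leaf.diameter / 2.0 * 1000.0
        L_nm = leaf.length * 1000.0
        a_lat = 2.0 * math.pi * r_nm * L_nm
        a_cap = 2.0 * math.pi * r_nm ** 2
        n_lat = cylinder_capacity(r_nm, L_nm, geom)
        n_cap = tip_capacity(r_nm, geom, mode="hemisphere")
        occ = 0.0
        if n_lat > 0:
            occ += n_lat * cylinder_patch_area(r_nm, omega, method="closed")
        if n_cap > 0:
            occ += n_cap * sphere_patch_area(r_nm, omega, method="closed")
        tl.add(_um2(a_lat + a_cap), n_lat + n_cap, _um2(occ))

    return res
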