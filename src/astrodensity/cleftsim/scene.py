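"""Geometry and parameters of the 7-synapse glutamate-uptake simulation.

The world is a 3 x 3 x 3 um cube containing a central synapse and six
inactive neighbours at the vertices of a hexagon, 1 um centre-to-centre
(500 nm edge-to-edge).  Each synapse is a pair of 250-nm-radius hemispheres
(pre- and post-synaptic terminal) separated by a 20-nm cleft.  Four of the
seven synapses (the central one and three alternating neighbours) are
flanked by a glial sheet: a 50-nm-thick, 250-nm-tall section of a
cylindrical shell covering 43% of the synaptic perimeter, 20 nm away from
the synapse edge.  Transporters populate both faces of the sheets at a
chosen surface density and diffuse laterally on them.

Internal units: nm, us; diffusion coefficients nm^2/us
(1 cm^2/s = 1e8 nm^2/us).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.constants import Avogadro

__all__ = [
    "TransporterKinetics",
    "SimParams",
    "SimScene",
    "build_scene",
    "binding_probability",
    "CM2_PER_S",
]

CM2_PER_S = 1e8        # nm^2/us per cm^2/s
RELEASE_SITES = ("center", "near_sheet", "far_sheet")


@dataclass(frozen=True)
class TransporterKinetics:
    """Simplified 3-state glial transporter scheme (rates at 35 C, Q10-adjusted).

    To --k_on [glu]--> ToG --k_transloc--> TiG --k_reset--> To, with
    ToG --k_unbind--> To returning glutamate to the extracellular space and
    the translocation step moving it to the absorbed (cytoplasmic) pool.
    """

    k_on: float = 18e6          # M^-1 s^-1, To + glu -> ToG
    k_unbind: float = 3594.0    # s^-1, ToG -> To (glu released)
    k_transloc: float = 6e3     # s^-1, ToG -> TiG (glu translocated)
    k_reset: float = 150.0      # s^-1, TiG -> To
    surface_diffusion: float = 0.23e-8  # cm^2/s, lateral diffusion on the sheet

    def __post_init__(self) -> None:
        if min(self.k_on, self.k_unbind, self.k_transloc, self.k_reset) < 0:
            raise ValueError("rates must be non-negative")

    def step_probabilities(self, dt_us: float) -> tuple[float, float, float]:
        """(p_unbind, p_transloc, p_reset) for one time step, 1 - exp(-k dt)."""
        dt_s = dt_us * 1e-6
        probs = tuple(1.0 - math.exp(-k * dt_s)
                      for k in (self.k_unbind, self.k_transloc, self.k_reset))
        if any(p >= 0.1 for p in probs):
            raise ValueError("k*dt too large: per-step probability >= 0.1")
        return probs


def binding_probability(k_on: float, dt_us: float, rho_nm: float,
                        halfspace: bool = True) -> float:
    """Per-step binding probability inside the interaction shell.

    Chosen so that, in a homogeneous volume, the expected binding flux equals
    mass action at ``k_on``: ``p = k_on dt / (N_A V_shell)``.  For a
    transporter sitting on a wall only a half-sphere of the shell is
    accessible (``halfspace=True``).
    """
    v_shell = (4.0 / 3.0) * math.pi * rho_nm ** 3   # nm^3
    if halfspace:
        v_shell /= 2.0
    k_per_molecule = k_on / Avogadro * 1e24          # nm^3 / s
    p = k_per_molecule * dt_us * 1e-6 / v_shell
    if p >= 1.0:
        raise ValueError("binding probability >= 1; reduce dt or enlarge shell")
    return p


@dataclass(frozen=True)
class SimParams:
    """Run-scale parameters for the reaction-diffusion simulation."""

    n_glutamate: int = 2000
    D_cleft: float = 3.30e-6        # cm^2/s, inside the synaptic cleft
    D_out: float = 1.29e-6          # cm^2/s, tortuosity lambda = 1.6
    dt: float = 1.0                 # us
    n_steps: int = 100_000          # 100 ms
    sample_every: int = 10          # record every 10 us
    n_reps: int = 20
    sigma_astro: float = 10_000.0   # transporters / um^2 of sheet membrane
    release_site: str = "center"
    binding_shell: float = 5.0      # nm
    world_boundary: str = "reflective"   # or "open"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_astro < 0:
            raise ValueError("sigma_astro must be >= 0")
        if self.release_site not in RELEASE_SITES:
            raise ValueError(f"release_site must be one of {RELEASE_SITES}")
        if self.world_boundary not in ("reflective", "open"):
            raise ValueError("world_boundary must be 'reflective' or 'open'")
        if self.n_glutamate <= 0 or self.n_steps <= 0 or self.dt <= 0:
            raise ValueError("n_glutamate, n_steps and dt must be positive")


@dataclass
class SimScene:
    """Concrete geometry plus initial transporter placement."""

    world_half: float = 1500.0          # nm
    synapse_radius: float = 250.0       # nm, terminal hemisphere radius
    half_cleft: float = 10.0            # nm (20-nm cleft)
    synapse_centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    sheet_synapses: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    sheet_phi0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sheet_half_angle: float = 0.43 * math.pi    # 43% of the perimeter
    sheet_r_in: float = 270.0           # nm: synapse edge + 20 nm gap
    sheet_r_out: float = 320.0          # nm: + 50 nm thickness
    sheet_half_height: float = 125.0    # nm: 250 nm tall, centred on the cleft
    sigma_astro: float = 0.0            # transporters / um^2
    release_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    # transporter state arrays (parallel)
    tr_sheet: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    tr_face: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    tr_theta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    tr_z: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_transporters(self) -> int:
        return self.tr_sheet.size

    @property
    def sheet_area_um2(self) -> float:
        """Reactive membrane area of one sheet (inner + outer face), um^2."""
        arc = 2.0 * self.sheet_half_angle
        h = 2.0 * self.sheet_half_height
        return arc * (self.sheet_r_in + self.sheet_r_out) * h / 1e6

    def region_volumes_um3(self) -> dict[str, float]:
        """Volumes of the PSD cylinder, perisynaptic annulus and free ECS (um^3)."""
        r_psd = self.synapse_radius / 2.0
        h = 2.0 * self.half_cleft
        v_psd = math.pi * r_psd ** 2 * h
        v_peri = math.pi * (self.synapse_radius ** 2 - r_psd ** 2) * h
        v_world = (2.0 * self.world_half) ** 3
        v_hemis = len(self.synapse_centers) * 2 * (2.0 / 3.0) * math.pi \
            * self.synapse_radius ** 3
        v_sheets = len(self.sheet_synapses) * self.sheet_half_angle \
            * (self.sheet_r_out ** 2 - self.sheet_r_in ** 2) \
            * 2.0 * self.sheet_half_height
        v_ecs = v_world - v_hemis - v_sheets - v_psd - v_peri
        return {"psd": v_psd / 1e9, "perisynaptic": v_peri / 1e9,
                "extracellular": v_ecs / 1e9}


def build_scene(params: SimParams, rng: np.random.Generator | None = None,
                n_neighbours: int = 6) -> SimScene:
    """Deterministic 7-synapse geometry with randomly placed sheet transporters.

    The central synapse and neighbours 1, 3, 5 carry glial sheets (4/7 = 57%
    of synapses).  All sheet arcs face the +x direction of their synapse.
    Transporter count per sheet = round(sheet area x sigma_astro), placed
    uniformly on the two faces (area-weighted).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    centers = [(0.0, 0.0)]
    for k in range(n_neighbours):
        ang = k * math.pi / 3.0
        centers.append((1000.0 * math.cos(ang), 1000.0 * math.sin(ang)))
    sheet_ids = [i for i in (0, 1, 3, 5) if i < len(centers)]

    scene = SimScene(
        synapse_centers=np.array(centers),
        sheet_synapses=np.array(sheet_ids, dtype=np.int64),
        sheet_phi0=np.zeros(len(sheet_ids)),
        sigma_astro=params.sigma_astro,
    )

    edge = scene.synapse_radius - 5.0   # 5-nm margin inside the cleft
    sites = {"center": np.zeros(3),
             "near_sheet": np.array([edge, 0.0, 0.0]),
             "far_sheet": np.array([-edge, 0.0, 0.0])}
    scene.release_point = sites[params.release_site]

    n_per_sheet = int(round(scene.sheet_area_um2 * params.sigma_astro))
    n_total = n_per_sheet * len(sheet_ids)
    scene.tr_sheet = np.repeat(np.arange(len(sheet_ids), dtype=np.int64), n_per_sheet)
    p_outer = scene.sheet_r_out / (scene.sheet_r_in + scene.sheet_r_out)
    scene.tr_face = (rng.random(n_total) < p_outer).astype(np.int64)
    half = scene.sheet_half_angle
    scene.tr_theta = scene.sheet_phi0[scene.tr_sheet] + rng.uniform(-half, half, n_total)
    scene.tr_z = rng.uniform(-scene.sheet_half_height, scene.sheet_half_height, n_total)
    return scene
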