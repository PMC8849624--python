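"""Drivers for the synaptic glutamate uptake simulation.

``run_simulation`` advances one scene realisation and returns region-resolved
glutamate concentration waveforms plus transporter state occupancies;
``sweep`` repeats it over transporter surface densities and release-site
locations; ``well_mixed_occupancies`` runs the closed-box validation
geometry whose occupancies must follow the 3-state mass-action ODE
(:func:`three_state_ode`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.constants import Avogadro
from scipy.integrate import solve_ivp

from ._kernels import simulate, well_mixed
from .scene import (CM2_PER_S, SimParams, SimScene, TransporterKinetics,
                    binding_probability, build_scene)

__all__ = [
    "ConcentrationWaveform",
    "run_simulation",
    "run_ensemble",
    "sweep",
    "well_mixed_occupancies",
    "three_state_ode",
    "free_diffusion_positions",
]

REGIONS = ("psd", "perisynaptic", "extracellular")


def _counts_to_uM(counts: np.ndarray, volume_um3: float) -> np.ndarray:
    # molecules / um^3 -> mol/L -> uM; 1 um^3 = 1e-15 L
    return counts / volume_um3 / (Avogadro * 1e-15) * 1e6


@dataclass
class ConcentrationWaveform:
    """Region-resolved [glu](t) and particle/transporter bookkeeping for one run."""

    times: np.ndarray               # us
    counts: np.ndarray              # (n_samples, 6): psd, peri, ecs, bound, transloc, escaped
    transporter_counts: np.ndarray  # (n_samples, 3): To, ToG, TiG
    volumes_um3: dict[str, float]
    n_glutamate: int

    def concentration(self, region: str) -> np.ndarray:
        """Waveform in uM for 'psd', 'perisynaptic' or 'extracellular'."""
        idx = REGIONS.index(region)
        return _counts_to_uM(self.counts[:, idx].astype(float),
                             self.volumes_um3[region])

    def peak(self, region: str) -> float:
        return float(self.concentration(region).max())

    @property
    def total_accounted(self) -> np.ndarray:
        """Free + bound + translocated (+ escaped) at each sample; conserved."""
        return self.counts.sum(axis=1)

    def state_fractions(self) -> np.ndarray:
        m = self.transporter_counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(m > 0, self.transporter_counts / m, 0.0)


def run_simulation(params: SimParams,
                   kinetics: TransporterKinetics = TransporterKinetics(),
                   scene: SimScene | None = None,
                   seed: int | None = None,
                   record_positions: bool = False,
                   ) -> ConcentrationWaveform | tuple[ConcentrationWaveform, np.ndarray]:
    """Run one realisation of the 7-synapse scene.

    2,000 glutamate molecules are released instantaneously from the chosen
    release point at t = 0; concentrations are sampled every
    ``params.sample_every`` steps in the PSD cylinder, the perisynaptic
    annulus and the remaining extracellular space.
    """
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if scene is None:
        scene = build_scene(params, rng)

    n = params.n_glutamate
    glu_pos = np.tile(scene.release_point.astype(float), (n, 1))
    glu_state = np.zeros(n, dtype=np.int8)
    tr_state = np.zeros(scene.n_transporters, dtype=np.int8)
    tr_glu = np.full(scene.n_transporters, -1, dtype=np.int64)
    tr_theta = scene.tr_theta.copy()
    tr_z = scene.tr_z.copy()

    p_unbind, p_transloc, p_reset = kinetics.step_probabilities(params.dt)
    p_bind = binding_probability(kinetics.k_on, params.dt, params.binding_shell,
                                 halfspace=True)

    n_samples = params.n_steps // params.sample_every + 1
    out_counts = np.zeros((n_samples, 6), dtype=np.int64)
    out_tr = np.zeros((n_samples, 3), dtype=np.int64)
    out_pos = np.zeros((n_samples if record_positions else 1, n, 3))

    simulate(int(rng.integers(2 ** 31 - 1)), params.n_steps, params.sample_every,
             params.dt,
             glu_pos, glu_state,
             scene.synapse_centers, scene.synapse_radius, scene.half_cleft,
             scene.sheet_synapses, scene.sheet_phi0, scene.sheet_half_angle,
             scene.sheet_r_in, scene.sheet_r_out, scene.sheet_half_height,
             scene.tr_sheet, scene.tr_face, tr_theta, tr_z, tr_state, tr_glu,
             params.D_cleft * CM2_PER_S, params.D_out * CM2_PER_S,
             kinetics.surface_diffusion * CM2_PER_S,
             p_bind, params.binding_shell, p_unbind, p_transloc, p_reset,
             scene.world_half, params.world_boundary == "reflective",
             out_counts, out_tr, record_positions, out_pos)

    times = np.arange(n_samples) * params.sample_every * params.dt
    wf = ConcentrationWaveform(times=times, counts=out_counts,
                               transporter_counts=out_tr,
                               volumes_um3=scene.region_volumes_um3(),
                               n_glutamate=n)
    if record_positions:
        return wf, out_pos
    return wf


def run_ensemble(params: SimParams,
                 kinetics: TransporterKinetics = TransporterKinetics(),
                 ) -> list[ConcentrationWaveform]:
    """Independent repetitions with per-rep derived seeds."""
    root = np.random.SeedSequence(params.seed)
    return [run_simulation(params, kinetics,
                           seed=int(child.generate_state(1)[0] % (2 ** 31 - 1)))
            for child in root.spawn(params.n_reps)]


def sweep(params: SimParams, sigmas, release_sites=("center",),
          kinetics: TransporterKinetics = TransporterKinetics()) -> pd.DataFrame:
    """Peak concentrations and transporter occupancies vs density and release site.

    Returns one row per (sigma, release site) with rep-averaged peak [glu]
    per region, peak bound-state (ToG + TiG) occupancy fractions, and the
    fraction of released glutamate translocated by the end of the run.
    """
    rows = []
    for site in release_sites:
        for sig in sigmas:
            p = SimParams(**{**params.__dict__, "sigma_astro": float(sig),
                             "release_site": site})
            reps = run_ensemble(p, kinetics)
            peaks = {r: np.mean([w.peak(r) for w in reps]) for r in REGIONS}
            frac = np.stack([w.state_fractions() for w in reps]).mean(axis=0)
            transloc = np.mean([w.counts[-1, 4] for w in reps]) / p.n_glutamate
            rows.append({"sigma_astro": sig, "release_site": site,
                         "peak_psd_uM": peaks["psd"],
                         "peak_peri_uM": peaks["perisynaptic"],
                         "peak_ecs_uM": peaks["extracellular"],
                         "peak_tog_fraction": float(frac[:, 1].max()),
                         "peak_tig_fraction": float(frac[:, 2].max()),
                         "peak_bound_fraction": float((frac[:, 1] + frac[:, 2]).max()),
                         "translocated_fraction": float(transloc),
                         "n_reps": p.n_reps})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# validation geometries
# ---------------------------------------------------------------------------

def free_diffusion_positions(n: int, n_steps: int, sample_every: int,
                             D_cm2s: float, dt: float = 1.0, seed: int = 0,
                             world_half: float = 1e7) -> tuple[np.ndarray, np.ndarray]:
    """Obstacle-free run of the scene kernel, returning sampled positions.

    Used to verify the Einstein relation MSD = 6 D t of the stepping rule.
    """
    n_samples = n_steps // sample_every + 1
    glu_pos = np.zeros((n, 3))
    glu_state = np.zeros(n, dtype=np.int8)
    empty_i = np.zeros(0, dtype=np.int64)
    empty_f = np.zeros(0)
    out_counts = np.zeros((n_samples, 6), dtype=np.int64)
    out_tr = np.zeros((n_samples, 3), dtype=np.int64)
    out_pos = np.zeros((n_samples, n, 3))
    D = D_cm2s * CM2_PER_S
    simulate(seed, n_steps, sample_every, dt,
             glu_pos, glu_state,
             np.zeros((0, 2)), 250.0, 10.0,
             empty_i, empty_f, 0.43 * math.pi, 270.0, 320.0, 125.0,
             empty_i, empty_i, empty_f, empty_f,
             np.zeros(0, dtype=np.int8), empty_i,
             D, D, 0.0,
             0.0, 5.0, 0.0, 0.0, 0.0,
             world_half, True,
             out_counts, out_tr, True, out_pos)
    times = np.arange(n_samples) * sample_every * dt
    return times, out_pos


def three_state_ode(t_us: np.ndarray, glu0_uM: float, trans0_uM: float,
                    kinetics: TransporterKinetics = TransporterKinetics()
                    ) -> np.ndarray:
    """Mass-action solution of the closed To/ToG/TiG system.

    State vector fractions (To, ToG, TiG) of the transporter pool, with free
    glutamate depleted by binding and removed by translocation.  Reference
    oracle for :func:`well_mixed_occupancies`.
    """
    k_on = kinetics.k_on * 1e-6          # uM^-1 s^-1

    # transporter pool as state fractions; glutamate in uM
    def rhs(t, y):
        to, tog, tig, glu = y
        bind = k_on * glu * to           # per-second fraction of transporters binding
        return [-bind + kinetics.k_unbind * tog + kinetics.k_reset * tig,
                bind - (kinetics.k_unbind + kinetics.k_transloc) * tog,
                kinetics.k_transloc * tog - kinetics.k_reset * tig,
                (-bind + kinetics.k_unbind * tog) * trans0_uM]

    t_s = np.asarray(t_us) * 1e-6
    sol = solve_ivp(rhs, (t_s[0], t_s[-1]), [1.0, 0.0, 0.0, glu0_uM],
                    t_eval=t_s, method="LSODA", rtol=1e-8, atol=1e-10)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y


def well_mixed_occupancies(n_glu: int, n_trans: int, box_half_nm: float,
                           n_steps: int, sample_every: int = 10,
                           dt: float = 1.0, seed: int = 0,
                           D_cm2s: float = 1.29e-6,
                           kinetics: TransporterKinetics = TransporterKinetics(),
                           binding_shell: float = 5.0,
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-box run with volume-distributed static transporters.

    Returns (times_us, glu_counts[free, bound, transloc], transporter state
    fractions).  Initial positions are uniform, so the box starts well mixed
    and occupancies are comparable to :func:`three_state_ode`.
    """
    rng = np.random.default_rng(seed)
    glu_pos = rng.uniform(-box_half_nm, box_half_nm, size=(n_glu, 3))
    tr_pos = rng.uniform(-box_half_nm, box_half_nm, size=(n_trans, 3))
    glu_state = np.zeros(n_glu, dtype=np.int8)
    tr_state = np.zeros(n_trans, dtype=np.int8)
    tr_glu = np.full(n_trans, -1, dtype=np.int64)

    p_unbind, p_transloc, p_reset = kinetics.step_probabilities(dt)
    p_bind = binding_probability(kinetics.k_on, dt, binding_shell, halfspace=False)

    n_samples = n_steps // sample_every + 1
    out_counts = np.zeros((n_samples, 3), dtype=np.int64)
    out_tr = np.zeros((n_samples, 3), dtype=np.int64)
    well_mixed(int(rng.integers(2 ** 31 - 1)), n_steps, sample_every, dt,
               box_half_nm, glu_pos, glu_state, tr_pos, tr_state, tr_glu,
               D_cm2s * CM2_PER_S, p_bind, binding_shell,
               p_unbind, p_transloc, p_reset, out_counts, out_tr)
    times = np.arange(n_samples) * sample_every * dt
    fractions = out_tr / max(n_trans, 1)
    return times, out_counts, fractions
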