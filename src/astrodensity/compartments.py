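"""Distributing mean transporter surface densities across astrocyte compartments.

Immunostaining studies give per-transporter expression ratios between the
astrocyte sub-cellular compartments (tips/leaves : shafts : stems : soma,
soma-normalised): GLAST 0.6 : 0.5 : 0.8 : 1 and GLT-1 2.3 : 1.4 : 0.7 : 1.
Given a whole-cell mean surface density (from the dot-blot pipeline) and the
compartment surface-area fractions (from the morphology model), the
compartment densities are the unique scaling of the ratio vector whose
area-weighted mean returns the measured whole-cell value:

    d_i = mean * r_i / sum_j a_j r_j

Relative density and effective occupied fraction compare these against the
packing model's per-compartment maxima: phi_exp = sigma_exp / sigma_model *
phi_model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphology import COMPARTMENTS

__all__ = [
    "RatioVector",
    "CompartmentProfile",
    "GLAST_RATIOS",
    "GLT1_RATIOS",
    "distribute_density",
    "combine_ratios",
    "relative_density_and_effective_fraction",
    "synapse_contact_stats",
]


@dataclass(frozen=True)
class RatioVector:
    """Soma-normalised expression weights (tips/leaves, shafts, stems, soma)."""

    tips_leaves: float
    shafts: float
    stems: float
    soma: float = 1.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.as_array()):
            raise ValueError("ratio weights must be positive")
        if abs(self.soma - 1.0) > 1e-9:
            raise ValueError("ratio vectors are soma-normalised (soma entry = 1)")

    def as_array(self) -> np.ndarray:
        return np.array([self.tips_leaves, self.shafts, self.stems, self.soma])

    def sum_normalised(self) -> np.ndarray:
        """Scaled so the four weights sum to 1 (plotting convention)."""
        a = self.as_array()
        return a / a.sum()


GLAST_RATIOS = RatioVector(0.6, 0.5, 0.8, 1.0)
GLT1_RATIOS = RatioVector(2.3, 1.4, 0.7, 1.0)


@dataclass(frozen=True)
class CompartmentProfile:
    """Per-compartment surface densities consistent with a whole-cell mean."""

    area_fractions: dict[str, float]
    densities: dict[str, float]        # molecules / um^2
    mean_density: float

    def __post_init__(self) -> None:
        weighted = sum(self.area_fractions[c] * self.densities[c] for c in COMPARTMENTS)
        if abs(weighted - self.mean_density) > 1e-6 * max(self.mean_density, 1.0):
            raise ValueError("area-weighted mean does not reproduce the input mean")


def _as_vector(x, name: str) -> np.ndarray:
    if isinstance(x, RatioVector):
        return x.as_array()
    if isinstance(x, dict):
        return np.array([x[c] for c in COMPARTMENTS], dtype=float)
    a = np.asarray(x, dtype=float)
    if a.shape != (4,):
        raise ValueError(f"{name} must have 4 entries (tips/leaves, shafts, stems, soma)")
    return a


def distribute_density(mean_density: float, ratios, area_fractions) -> CompartmentProfile:
    """Split a whole-cell mean density across compartments along a ratio vector.

    ``d_i = mean * r_i / sum_j a_j r_j`` — the only scaling for which the
    area-weighted average over compartments equals the measured mean.
    """
    r = _as_vector(ratios, "ratios")
    a = _as_vector(area_fractions, "area_fractions")
    if mean_density < 0:
        raise ValueError("mean density must be non-negative")
    if abs(a.sum() - 1.0) > 1e-6:
        raise ValueError("area fractions must sum to 1")
    denom = float(a @ r)
    if denom <= 0:
        raise ValueError("area-weighted ratio sum is zero; cannot distribute")
    d = mean_density * r / denom
    return CompartmentProfile(
        area_fractions=dict(zip(COMPARTMENTS, a)),
        densities=dict(zip(COMPARTMENTS, d)),
        mean_density=float(mean_density))


def combine_ratios(glast_density: float, glt1_density: float,
                   glast_ratios: RatioVector = GLAST_RATIOS,
                   glt1_ratios: RatioVector = GLT1_RATIOS) -> RatioVector:
    """Abundance-weighted combined expression ratio for GLAST + GLT-1.

    Per compartment, the combined level is the density-weighted sum of the
    per-transporter weights, renormalised to soma = 1.  Homogeneous of degree
    zero in the absolute densities.
    """
    if glast_density < 0 or glt1_density < 0 or glast_density + glt1_density == 0:
        raise ValueError("densities must be non-negative and not both zero")
    combined = (glast_density * glast_ratios.as_array()
                + glt1_density * glt1_ratios.as_array())
    combined = combined / combined[3]
    return RatioVector(*combined)


def relative_density_and_effective_fraction(d, sigma_model, phi_model
                                            ) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise ``d / sigma_model`` and ``phi_exp = d/sigma_model * phi_model``.

    ``sigma_model``/``phi_model`` are the packing model's maximal density and
    occupied fraction for the same compartments.  Values above 1 mean the
    measured density exceeds the geometric packing limit.
    """
    d = np.asarray(d, dtype=float)
    sigma_model = np.asarray(sigma_model, dtype=float)
    phi_model = np.asarray(phi_model, dtype=float)
    if np.any(sigma_model <= 0):
        raise ValueError("model maximal densities must be positive")
    rel = d / sigma_model
    return rel, rel * phi_model


def synapse_contact_stats(domain_volume: float,
                          synapse_density_range: tuple[float, float],
                          coverage_fraction: float,
                          n_tips: float) -> dict:
    """Synapses contacted by one astrocyte and the share reachable by tips/leaves.

    ``contacted = volume x density x coverage`` for each end of the synapse
    density range; ``tip % = n_tips / contacted x 100``.
    """
    if domain_volume <= 0:
        raise ValueError("domain volume must be positive")
    lo, hi = synapse_density_range
    contacted = (domain_volume * lo * coverage_fraction,
                 domain_volume * hi * coverage_fraction)
    if min(contacted) <= 0:
        raise ValueError("no synapses contacted (zero coverage or density); "
                         "tip-contact percentage undefined")
    tip_pct = (n_tips / contacted[1] * 100.0, n_tips / contacted[0] * 100.0)
    return {"contacted_range": contacted, "tip_contact_percent_range": tip_pct}
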