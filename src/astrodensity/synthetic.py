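"""Synthetic inputs with the statistical structure the pipeline assumes.

No raw blot images or dot tables are distributed with this package, so end-
to-end tests run on synthetic dot-blot tables generated through the same
forward model the quantification inverts: a sigmoidal RID response over
mass-corrected standard amounts, 2-3 technical dots per condition, 3
biological replicates, blank (PBS) dots, and multiplicative log-normal
noise on the RID (imaging/exposure variability).  The generating truth is
stored alongside so recovery can be asserted.

Also provides miniature deterministic fixtures (single-branch astrocytes,
transporter-free scenes) for fast tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dotblot
from .dotblot import (StandardCurve, TissueAssumptions, TransporterMeta,
                      sigmoid)
from .morphology import AstrocyteModel, MorphologyParams, generate_astrocyte

__all__ = [
    "SynthDotBlotSpec",
    "synth_dotblot",
    "recover_mg_per_g",
    "minimal_astrocyte",
    "soma_only_astrocyte",
]


@dataclass(frozen=True)
class SynthDotBlotSpec:
    """Generating truth and noise structure for one synthetic dot-blot assay."""

    meta: TransporterMeta = dotblot.GLT1_MOUSE
    true_mg_per_g: float = 4.40          # truth to recover (mg transporter / g tissue)
    curve_max: float = 40_000.0          # RID units at saturation
    curve_xhalf_ng: float = 150.0        # native-equivalent ng at half-max
    curve_rate_ng: float = 60.0
    standard_masses_ng: tuple = (10.0, 25.0, 50.0, 100.0, 200.0, 400.0, 800.0)
    membrane_protein_ug: float = 5.0     # spotted per sample dot; keeps abundant
                                         # targets inside the curve's dynamic range
    noise_cv: float = 0.05               # multiplicative log-normal SD on RID
    n_biological: int = 3
    n_technical: int = 3
    blank_rid: float = 500.0             # background level
    assumptions: TissueAssumptions = field(default_factory=TissueAssumptions)

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.standard_masses_ng):
            raise ValueError("standard masses must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise SD must be >= 0")

    def true_curve(self) -> StandardCurve:
        """Generating sigmoid on the mole axis used by the fitting code."""
        to_mol = self.meta.native_molar_mass * 1e9   # ng native-equivalent -> mol
        return StandardCurve(self.curve_max,
                             self.curve_xhalf_ng / to_mol,
                             self.curve_rate_ng / to_mol,
                             self.meta)


def _noisy(rng: np.random.Generator, value: float, cv: float) -> float:
    if cv == 0:
        return value
    return float(value * rng.lognormal(mean=-0.5 * np.log(1 + cv ** 2),
                                       sigma=np.sqrt(np.log(1 + cv ** 2))))


def synth_dotblot(spec: SynthDotBlotSpec, seed: int | np.random.Generator = 0
                  ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (standards table, samples table, truth record).

    Standards: the spec's masses of recombinant protein, each spotted
    ``n_technical`` times; RID from the generating sigmoid evaluated at the
    purity/molar-mass-corrected mole amount, plus background and noise.
    Samples: ``n_biological`` membrane-protein dots whose native transporter
    content follows from the true mg-per-g and the tissue assumptions.  Both
    tables carry blank dots at the background level.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    meta, a = spec.meta, spec.assumptions
    curve = spec.true_curve()

    rows = []
    dot = 0
    for _ in range(spec.n_technical):
        rows.append({"dot_id": dot, "condition": "blank", "mass_ng": np.nan,
                     "rid": _noisy(rng, spec.blank_rid, spec.noise_cv)})
        dot += 1
    for mass in spec.standard_masses_ng:
        mol = dotblot.mass_correct_standard(mass, meta)
        signal = float(curve.predict(mol))
        for _ in range(spec.n_technical):
            rows.append({"dot_id": dot, "condition": "standard", "mass_ng": mass,
                         "rid": _noisy(rng, signal, spec.noise_cv) + spec.blank_rid})
            dot += 1
    standards = pd.DataFrame(rows)

    # forward model for samples: mg/g -> native ng in the spotted dot
    native_ng = (spec.true_mg_per_g / a.protein_per_tissue
                 * spec.membrane_protein_ug * 1e3)
    mol = native_ng * 1e-9 / meta.native_molar_mass
    signal = float(curve.predict(mol))

    rows = []
    dot = 0
    for _ in range(spec.n_technical):
        rows.append({"dot_id": dot, "condition": "blank", "sample_id": None,
                     "membrane_protein_ug": np.nan,
                     "rid": _noisy(rng, spec.blank_rid, spec.noise_cv)})
        dot += 1
    for b in range(spec.n_biological):
        for _ in range(spec.n_technical):
            rows.append({"dot_id": dot, "condition": "sample", "sample_id": f"s{b}",
                         "membrane_protein_ug": spec.membrane_protein_ug,
                         "rid": _noisy(rng, signal, spec.noise_cv) + spec.blank_rid})
            dot += 1
    samples = pd.DataFrame(rows)

    conc = dotblot.tissue_concentration(spec.true_mg_per_g,
                                        meta.native_molar_mass, a)
    truth = {"mg_per_g": spec.true_mg_per_g, "native_ng_per_dot": native_ng,
             "uM": conc["uM"], "per_volume": conc["per_volume"],
             "per_area": dotblot.surface_density(conc["per_volume"], a)}
    return standards, samples, truth


def recover_mg_per_g(standards: pd.DataFrame, samples: pd.DataFrame,
                     meta: TransporterMeta,
                     assumptions: TissueAssumptions = TissueAssumptions()
                     ) -> dotblot.DensityEstimate:
    """Full pipeline on synthetic tables: fit, invert, aggregate replicates."""
    per_sample, _curve = dotblot.mg_per_g_from_tables(standards, samples,
                                                      meta, assumptions)
    return dotblot.quantify_samples(per_sample["mg_per_g_tissue"].to_numpy(),
                                    meta, assumptions)


# ---------------------------------------------------------------------------
# morphology / scene fixtures
# ---------------------------------------------------------------------------

def soma_only_astrocyte(params: MorphologyParams | None = None) -> AstrocyteModel:
    """Sphere-only degenerate cell: no branches, no leaves."""
    if params is None:
        params = MorphologyParams(n_primary_range=(0, 0))
    return generate_astrocyte(params, seed=0, with_leaves=False)


def minimal_astrocyte(seed: int = 0) -> AstrocyteModel:
    """Tiny deterministic cell: few short primaries, sparse tree, with leaves."""
    params = MorphologyParams(n_primary_range=(1, 1),
                              max_primary_branchpoints=3,
                              max_levels=3,
                              segment_baseline_max=5.0)
    return generate_astrocyte(params, seed=seed)
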