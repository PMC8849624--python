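"""Quantitative dot-blot calibration and transporter tissue/surface density.

Converts raw integrated densities (RID) of immunoblot dots into astrocytic
glutamate transporter surface densities.  The chain is:

1. background-correct and replicate-average dot RIDs;
2. fit a sigmoidal standard curve ``F(x) = max / (1 + exp((xhalf - x)/rate))``
   to recombinant-protein standards, after converting spotted recombinant mass
   to moles of native-equivalent protein (purity and molar-mass correction);
3. invert the curve for sample dots, yielding native transporter mass per dot;
4. express the transporter as a fraction of spotted membrane protein, scale by
   the tissue protein content (97.8 mg protein per g tissue) to mg transporter
   per g tissue;
5. convert to molar tissue concentration (tissue density 1.05 g/cm^3), to
   molecules per um^3 of tissue (Avogadro), and to molecules per um^2 of
   astrocyte membrane (astrocyte membrane density 3.15 um^2/um^3).

Standard curves are fitted on a mole axis so that the same calibration serves
recombinant human standards and native mouse/rat proteins of different size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.constants import Avogadro
from scipy.optimize import curve_fit

__all__ = [
    "StandardCurve",
    "TissueAssumptions",
    "DensityEstimate",
    "GLAST_MOUSE",
    "GLT1_MOUSE",
    "GLAST_RAT",
    "GLT1_RAT",
    "correct_background",
    "fit_standard_curve",
    "mass_correct_standard",
    "invert_standard_curve",
    "protein_fractions",
    "tissue_concentration",
    "surface_density",
    "ecs_effective_concentration",
    "astro_apposed_ecs_fraction",
    "quantify_samples",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransporterMeta:
    """Recombinant standard and native protein identity for one transporter."""

    name: str
    recombinant_molar_mass: float  # Da, GST-tagged human recombinant
    purity: float                  # fraction of the recombinant prep that is protein of interest
    native_molar_mass: float       # Da, endogenous protein in the species assayed

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.recombinant_molar_mass <= 0 or self.native_molar_mass <= 0:
            raise ValueError("molar masses must be positive")


# Recombinant GST-tagged human homologs and endogenous molecular weights.
GLAST_MOUSE = TransporterMeta("GLAST", 87_387.0, 0.9282, 59_619.0)
GLT1_MOUSE = TransporterMeta("GLT-1", 89_988.0, 0.8693, 62_027.0)
GLAST_RAT = TransporterMeta("GLAST", 87_387.0, 0.9282, 54_374.0)
GLT1_RAT = TransporterMeta("GLT-1", 89_988.0, 0.8693, 60_914.0)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted sigmoid ``F(x) = max / (1 + exp((xhalf - x)/rate))``.

    The abscissa is moles of native-equivalent transporter per dot (fitting on
    a mole axis makes the calibration independent of the recombinant tag).
    """

    max: float     # RID units
    xhalf: float   # mol
    rate: float    # mol
    meta: TransporterMeta
    residual_norm: float = float("nan")

    def __post_init__(self) -> None:
        if self.max <= 0:
            raise ValueError("max must be > 0")
        if self.rate == 0:
            raise ValueError("rate must be nonzero")

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return sigmoid(x, self.max, self.xhalf, self.rate)


def sigmoid(x, fmax, xhalf, rate):
    """The dot-blot calibration sigmoid."""
    return fmax / (1.0 + np.exp((xhalf - x) / rate))


@dataclass(frozen=True)
class TissueAssumptions:
    """Literature constants converting tissue content to surface density."""

    protein_per_tissue: float = 97.8      # mg protein per g tissue
    tissue_density: float = 1.05          # g / cm^3
    astro_membrane_density: float = 3.15  # um^2 astrocyte membrane / um^3 tissue
    total_membrane_density: float = 14.0  # um^2 all membranes / um^3 tissue
    ecs_fraction: float = 0.15            # extracellular volume fraction

    def __post_init__(self) -> None:
        vals = (self.protein_per_tissue, self.tissue_density,
                self.astro_membrane_density, self.total_membrane_density)
        if any(v <= 0 for v in vals):
            raise ValueError("all tissue assumptions must be strictly positive")
        if not (0.0 < self.ecs_fraction < 1.0):
            raise ValueError("ecs_fraction must lie in (0, 1)")
        if self.astro_membrane_density >= self.total_membrane_density:
            raise ValueError("astrocyte membrane density must be below the total")


@dataclass(frozen=True)
class DensityEstimate:
    """Per-transporter tissue content and surface density (mean +/- SD over samples)."""

    target: str
    mg_per_g_tissue: float
    concentration_uM: float
    per_volume: float          # molecules / um^3 tissue
    per_area: float            # molecules / um^2 astrocyte membrane
    mg_per_g_sd: float = 0.0
    concentration_uM_sd: float = 0.0
    per_volume_sd: float = 0.0
    per_area_sd: float = 0.0
    n: int = 1


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

_REQUIRED_COLS = {"dot_id", "condition", "rid"}


def _check_table(dots: pd.DataFrame) -> None:
    missing = _REQUIRED_COLS - set(dots.columns)
    if missing:
        raise ValueError(f"dot table is missing columns: {sorted(missing)}")


def correct_background(dots: pd.DataFrame) -> pd.DataFrame:
    """Subtract the mean blank RID from every dot and clip negatives to zero.

    Blank dots (``condition == 'blank'``, PBS only) define the background.
    Returns a copy with corrected ``rid``; blank rows are dropped.

    Raises
    ------
    ValueError
        If the table contains no blank dots.
    """
    _check_table(dots)
    blanks = dots.loc[dots["condition"] == "blank", "rid"]
    if blanks.empty:
        raise ValueError("background correction requires at least one blank dot")
    out = dots.loc[dots["condition"] != "blank"].copy()
    out["rid"] = np.clip(out["rid"].to_numpy(dtype=float) - blanks.mean(), 0.0, None)
    return out


def average_replicates(dots: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Average technical replicate dots (2-3 per spotted condition)."""
    _check_table(dots)
    if by is None:
        by = [c for c in ("condition", "target", "sample_id", "mass_ng",
                          "membrane_protein_ug") if c in dots.columns]
    return dots.groupby(by, dropna=False, as_index=False)["rid"].mean()


def mass_correct_standard(spotted_mass_ng: np.ndarray | float,
                          meta: TransporterMeta) -> np.ndarray | float:
    """Moles of native-equivalent protein in a recombinant standard dot.

    moles = spotted mass x purity / recombinant molar mass.  Multiplying by
    the native molar mass yields the native-equivalent mass.
    """
    spotted_mass_ng = np.asarray(spotted_mass_ng, dtype=float)
    if np.any(spotted_mass_ng < 0):
        raise ValueError("spotted mass must be >= 0")
    mol = spotted_mass_ng * 1e-9 * meta.purity / meta.recombinant_molar_mass
    return mol if mol.ndim else float(mol)


def fit_standard_curve(standards: pd.DataFrame, meta: TransporterMeta) -> StandardCurve:
    """Least-squares fit of the calibration sigmoid to standard dots.

    ``standards`` needs columns ``mass_ng`` (spotted recombinant mass) and
    ``rid`` (background-corrected, replicate-averaged).  The fit is performed
    against moles of native-equivalent protein.

    Initialisation: max = 1.1 x max(RID), xhalf = median mole amount,
    rate = (max - min mole amount) / 4; unweighted least squares.
    """
    if "mass_ng" not in standards.columns:
        raise ValueError("standards table needs a 'mass_ng' column")
    tbl = standards.dropna(subset=["mass_ng", "rid"])
    masses = tbl["mass_ng"].to_numpy(dtype=float)
    rids = tbl["rid"].to_numpy(dtype=float)
    if np.unique(masses).size < 4:
        raise ValueError("need at least 4 distinct standard masses to fit the sigmoid")

    x = np.asarray(mass_correct_standard(masses, meta))
    p0 = (1.1 * rids.max(), float(np.median(x)), (x.max() - x.min()) / 4.0)
    try:
        popt, _ = curve_fit(sigmoid, x, rids, p0=p0, maxfev=20_000)
    except RuntimeError as err:  # pragma: no cover - depends on optimizer path
        raise RuntimeError(f"standard-curve fit did not converge (init {p0})") from err
    resid = rids - sigmoid(x, *popt)
    return StandardCurve(float(popt[0]), float(popt[1]), float(abs(popt[2])),
                         meta, float(np.linalg.norm(resid)))


def invert_standard_curve(curve: StandardCurve, rid: float) -> float:
    """Native transporter mass (ng) in a sample dot from its corrected RID.

    Inverts the sigmoid, ``x = xhalf - rate * ln(max/rid - 1)`` (moles), then
    converts to native mass via the native molar mass.
    """
    if rid <= 0:
        raise ValueError("RID must be positive to invert the standard curve")
    if rid >= curve.max:
        raise ValueError(
            f"RID {rid} at or above curve saturation ({curve.max}); dot unusable")
    mol = curve.xhalf - curve.rate * np.log(curve.max / rid - 1.0)
    return float(mol * curve.meta.native_molar_mass * 1e9)


def protein_fractions(native_mass_ng: float, spotted_membrane_protein_ug: float,
                      assumptions: TissueAssumptions = TissueAssumptions()) -> dict:
    """Transporter as a fraction of spotted protein and per gram of tissue.

    The transporter mass detected in a dot, divided by the total membrane
    protein spotted, gives the membrane-protein fraction; scaling by the
    tissue protein content (97.8 mg/g) gives mg transporter per g tissue.
    """
    if spotted_membrane_protein_ug <= 0:
        raise ValueError("spotted membrane protein must be > 0")
    frac = native_mass_ng * 1e-3 / spotted_membrane_protein_ug
    mg_per_g = frac * assumptions.protein_per_tissue
    return {
        "fraction_of_membrane_protein": frac,
        "mg_per_g_tissue": mg_per_g,
        "percent_of_total_protein": mg_per_g / assumptions.protein_per_tissue * 100.0,
    }


def tissue_concentration(mg_per_g: float, molar_mass: float,
                         assumptions: TissueAssumptions = TissueAssumptions()) -> dict:
    """Molar tissue concentration (uM) and molecules per um^3 of tissue.

    uM = mg/g x tissue density [g/cm^3] / molar mass [g/mol] x 1e6; molecules
    per um^3 follows from Avogadro's number (1 uM = 602.214 um^-3).
    """
    if mg_per_g < 0 or molar_mass <= 0:
        raise ValueError("inputs must be non-negative (molar mass positive)")
    # mg/g * g/cm^3 = mg/cm^3 = g/L; / (g/mol) = mol/L
    molar = mg_per_g * assumptions.tissue_density / molar_mass
    per_volume = molar * Avogadro * 1e-15  # molecules per um^3 (1 L = 1e15 um^3)
    return {"uM": molar * 1e6, "per_volume": per_volume}


def surface_density(per_volume: float,
                    assumptions: TissueAssumptions = TissueAssumptions()) -> float:
    """Molecules per um^2 of astrocyte membrane from molecules per um^3 tissue."""
    if per_volume < 0:
        raise ValueError("per_volume must be >= 0")
    return per_volume / assumptions.astro_membrane_density


def ecs_effective_concentration(uM: float,
                                assumptions: TissueAssumptions = TissueAssumptions()) -> float:
    """Effective concentration if all transporters faced the extracellular space.

    Divides the tissue concentration by the extracellular volume fraction
    (~15% in mouse hippocampus).
    """
    return uM / assumptions.ecs_fraction


def astro_apposed_ecs_fraction(assumptions: TissueAssumptions = TissueAssumptions()) -> float:
    """Fraction of ECS enclosed between an astrocyte membrane and any other membrane.

    With astrocyte membrane density a and total membrane density T, a randomly
    placed sheet of ECS is astrocyte-apposed on exactly one side with
    probability 2 (a/T) ((T-a)/T).
    """
    a = assumptions.astro_membrane_density
    t = assumptions.total_membrane_density
    return 2.0 * (a / t) * ((t - a) / t)


# ---------------------------------------------------------------------------
# pipeline: dot table -> Table-4-style output
# ---------------------------------------------------------------------------

def mg_per_g_from_tables(standards: pd.DataFrame, samples: pd.DataFrame,
                         meta: TransporterMeta,
                         assumptions: TissueAssumptions = TissueAssumptions(),
                         ) -> tuple[pd.DataFrame, StandardCurve]:
    """Per-sample mg transporter per g tissue from raw standard + sample dots.

    Both tables are background-corrected against their blank dots and
    replicate-averaged before fitting/inversion.  ``samples`` needs columns
    ``sample_id``, ``membrane_protein_ug`` and ``rid``.
    """
    std = average_replicates(correct_background(standards))
    smp = average_replicates(correct_background(samples))
    curve = fit_standard_curve(std.loc[std["condition"] == "standard"], meta)

    rows = []
    for _, row in smp.loc[smp["condition"] == "sample"].iterrows():
        native_ng = invert_standard_curve(curve, float(row["rid"]))
        fr = protein_fractions(native_ng, float(row["membrane_protein_ug"]), assumptions)
        rows.append({"sample_id": row.get("sample_id"),
                     "native_mass_ng": native_ng, **fr})
    return pd.DataFrame(rows), curve


def quantify_samples(mg_per_g_values: np.ndarray, meta: TransporterMeta,
                     assumptions: TissueAssumptions = TissueAssumptions(),
                     target: str | None = None) -> DensityEstimate:
    """Aggregate biological replicates into a Table-4-style density estimate."""
    vals = np.asarray(mg_per_g_values, dtype=float)
    per_sample = []
    for mg in vals:
        conc = tissue_concentration(mg, meta.native_molar_mass, assumptions)
        per_sample.append((mg, conc["uM"], conc["per_volume"],
                           surface_density(conc["per_volume"], assumptions)))
    arr = np.array(per_sample)
    mean, sd = arr.mean(axis=0), arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(4)
    return DensityEstimate(
        target=target or meta.name,
        mg_per_g_tissue=mean[0], concentration_uM=mean[1],
        per_volume=mean[2], per_area=mean[3],
        mg_per_g_sd=sd[0], concentration_uM_sd=sd[1],
        per_volume_sd=sd[2], per_area_sd=sd[3], n=len(arr))
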