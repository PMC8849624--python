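"""Dot-blot calibration and the tissue/surface density conversion chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from astrodensity import dotblot
from astrodensity.dotblot import (GLAST_MOUSE, GLAST_RAT, GLT1_MOUSE, GLT1_RAT,
                                  StandardCurve, TissueAssumptions,
                                  correct_background, fit_standard_curve,
                                  invert_standard_curve, mass_correct_standard,
                                  protein_fractions, sigmoid,
                                  surface_density, tissue_concentration)


def make_table(rids, condition="standard", masses=None):
    rows = [{"dot_id": i, "condition": condition, "rid": r,
             "mass_ng": (masses[i] if masses else np.nan)}
            for i, r in enumerate(rids)]
    return pd.DataFrame(rows)


class TestBackgroundCorrection:
    def test_mean_blank_subtracted_and_negatives_clipped(self):
        df = pd.DataFrame({
            "dot_id": range(5),
            "condition": ["blank"] * 3 + ["sample"] * 2,
            "rid": [10.0, 10.0, 10.0, 110.0, 5.0],
        })
        out = correct_background(df)
        assert list(out["rid"]) == [100.0, 0.0]

    def test_replicates_averaged(self):
        df = pd.DataFrame({
            "dot_id": range(3),
            "condition": ["blank", "sample", "sample"],
            "sample_id": [None, "a", "a"],
            "rid": [0.0, 100.0, 120.0],
        })
        avg = dotblot.average_replicates(correct_background(df))
        assert avg.loc[avg["condition"] == "sample", "rid"].item() == pytest.approx(110.0)

    def test_no_blanks_is_an_error(self):
        df = make_table([100.0, 200.0])
        with pytest.raises(ValueError, match="blank"):
            correct_background(df)


class TestMassCorrection:
    def test_recombinant_glast_dot(self):
        # 100 ng GST-GLAST, purity 0.9282, MW 87,387 Da -> 1.062e-12 mol
        mol = mass_correct_standard(100.0, GLAST_MOUSE)
        assert mol == pytest.approx(1.0622e-12, rel=1e-3)

    def test_zero_mass_and_identity(self):
        assert mass_correct_standard(0.0, GLT1_MOUSE) == 0.0
        meta = dotblot.TransporterMeta("x", 5e4, 1.0, 5e4)
        mol = mass_correct_standard(123.0, meta)
        assert mol * meta.native_molar_mass * 1e9 == pytest.approx(123.0)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            mass_correct_standard(-1.0, GLAST_MOUSE)


class TestStandardCurve:
    def _noiseless_table(self, curve, masses):
        mols = np.array([mass_correct_standard(m, curve.meta) for m in masses])
        rids = sigmoid(mols, curve.max, curve.xhalf, curve.rate)
        return make_table(list(rids), masses=list(masses))

    def test_noiseless_parameters_recovered(self):
        truth = StandardCurve(5e4, 2e-12, 8e-13, GLT1_MOUSE)
        masses = [10, 50, 100, 200, 400, 800, 1600]
        fit = fit_standard_curve(self._noiseless_table(truth, masses), GLT1_MOUSE)
        assert fit.max == pytest.approx(truth.max, rel=1e-3)
        assert fit.xhalf == pytest.approx(truth.xhalf, rel=1e-3)
        assert fit.rate == pytest.approx(truth.rate, rel=1e-3)

    def test_noisy_parameters_within_ten_percent(self, rng):
        truth = StandardCurve(5e4, 2e-12, 8e-13, GLT1_MOUSE)
        masses = [10, 50, 100, 200, 400, 800, 1600]
        tbl = self._noiseless_table(truth, masses)
        tbl["rid"] *= rng.lognormal(sigma=0.05, size=len(tbl))
        fit = fit_standard_curve(tbl, GLT1_MOUSE)
        assert fit.max == pytest.approx(truth.max, rel=0.1)
        assert fit.xhalf == pytest.approx(truth.xhalf, rel=0.1)

    def test_three_points_rejected(self):
        tbl = make_table([10.0, 20.0, 30.0], masses=[1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="4 distinct"):
            fit_standard_curve(tbl, GLAST_MOUSE)

    def test_midpoint_inversion(self):
        curve = StandardCurve(1000.0, 3e-12, 1e-12, GLAST_MOUSE)
        ng = invert_standard_curve(curve, 500.0)
        assert ng == pytest.approx(3e-12 * GLAST_MOUSE.native_molar_mass * 1e9)

    @given(st.floats(min_value=0.01, max_value=0.99))
    @settings(max_examples=50, deadline=None)
    def test_forward_invert_round_trip(self, frac):
        curve = StandardCurve(2e4, 5e-12, 2e-12, GLT1_MOUSE)
        rid = frac * curve.max
        mol = curve.xhalf - curve.rate * np.log(curve.max / rid - 1.0)
        assert float(curve.predict(mol)) == pytest.approx(rid, rel=1e-9)

    def test_saturated_or_nonpositive_rid_rejected(self):
        curve = StandardCurve(1000.0, 3e-12, 1e-12, GLAST_MOUSE)
        with pytest.raises(ValueError):
            invert_standard_curve(curve, 1000.0)
        with pytest.raises(ValueError):
            invert_standard_curve(curve, 0.0)

    def test_mg_per_g_monotone_in_rid(self):
        curve = StandardCurve(1000.0, 3e-12, 1e-12, GLT1_MOUSE)
        masses = [invert_standard_curve(curve, r) for r in (100, 300, 600, 900)]
        mg = [protein_fractions(m, 10.0)["mg_per_g_tissue"] for m in masses]
        assert np.all(np.diff(mg) > 0)


class TestConversions:
    def test_percent_of_total_protein(self):
        # combined 6-month mouse content ~6% and rat ~3.5% of all proteins
        assert protein_fractions(5.72 / 97.8 * 10 * 1e3, 10.0)[
            "percent_of_total_protein"] == pytest.approx(5.85, abs=0.01)
        assert protein_fractions(3.42 / 97.8 * 10 * 1e3, 10.0)[
            "percent_of_total_protein"] == pytest.approx(3.50, abs=0.01)
        assert protein_fractions(0.0, 10.0)["percent_of_total_protein"] == 0.0

    @pytest.mark.parametrize("mg, mw, uM, per_vol, per_area", [
        (0.51, 59_619, 9, 5_399, 1_714),     # GLAST, 2-week mouse
        (4.40, 62_027, 75, 44_880, 14_248),  # GLT-1, 6-month mouse
    ])
    def test_tissue_rows(self, mg, mw, uM, per_vol, per_area):
        conc = tissue_concentration(mg, mw)
        assert conc["uM"] == pytest.approx(uM, rel=0.01, abs=0.5)
        assert conc["per_volume"] == pytest.approx(per_vol, rel=0.01)
        assert surface_density(conc["per_volume"]) == pytest.approx(per_area, rel=0.01)

    def test_zero_content(self):
        conc = tissue_concentration(0.0, 59_619)
        assert conc["uM"] == 0.0
        assert surface_density(0.0) == 0.0

    def test_unit_chain_round_trip(self):
        # per_area * membrane density * MW / (N_A * tissue density) -> mg/g
        from scipy.constants import Avogadro
        a = TissueAssumptions()
        for mg, mw in [(0.51, 59_619), (1.15, 59_619), (4.40, 62_027),
                       (2.44, 60_914)]:
            per_area = surface_density(
                tissue_concentration(mg, mw, a)["per_volume"], a)
            back = per_area * a.astro_membrane_density * mw \
                / (Avogadro * a.tissue_density) * 1e15
            assert back == pytest.approx(mg, rel=1e-6)

    def test_ecs_effective_concentration(self):
        assert dotblot.ecs_effective_concentration(98.0) == pytest.approx(653.3, abs=0.1)
        assert dotblot.ecs_effective_concentration(17.0) == pytest.approx(113.3, abs=0.1)
        assert dotblot.ecs_effective_concentration(0.0) == 0.0

    def test_apposed_ecs_fraction(self):
        assert dotblot.astro_apposed_ecs_fraction() == pytest.approx(0.349, abs=5e-3)
        half = TissueAssumptions(astro_membrane_density=7.0 - 1e-9)
        assert dotblot.astro_apposed_ecs_fraction(half) == pytest.approx(0.5, abs=1e-6)
        # a -> 0 limit
        tiny = TissueAssumptions(astro_membrane_density=1e-12)
        assert dotblot.astro_apposed_ecs_fraction(tiny) == pytest.approx(0.0, abs=1e-9)


class TestAssumptionValidation:
    def test_invalid_assumptions_rejected(self):
        with pytest.raises(ValueError):
            TissueAssumptions(ecs_fraction=1.5)
        with pytest.raises(ValueError):
            TissueAssumptions(astro_membrane_density=20.0)
        with pytest.raises(ValueError):
            dotblot.TransporterMeta("x", 5e4, 1.2, 5e4)
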