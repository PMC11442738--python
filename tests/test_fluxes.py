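import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cropwater as cw
from cropwater import fluxes

finite_reflectance = st.floats(0.0, 1.0, allow_nan=False)


class TestNdvi:
    @pytest.mark.parametrize(
        "red,nir,expected",
        [(0.1, 0.5, 0.666667), (0.3, 0.3, 0.0), (0.0, 0.4, 1.0), (0.4, 0.0, -1.0)],
    )
    def test_closed_form(self, red, nir, expected):
        assert cw.compute_ndvi(red, nir) == pytest.approx(expected, abs=1e-6)

    def test_zero_total_reflectance_dropped(self):
        out = cw.compute_ndvi(np.array([0.0, 0.1]), np.array([0.0, 0.3]))
        assert np.isnan(out[0]) and out[1] == pytest.approx(0.5)

    def test_negative_reflectance_rejected(self):
        with pytest.raises(ValueError):
            cw.compute_ndvi(-0.1, 0.5)

    @given(red=finite_reflectance, nir=finite_reflectance)
    def test_antisymmetric_and_bounded(self, red, nir):
        if red + nir == 0:
            return
        v = cw.compute_ndvi(red, nir)
        assert -1.0 <= v <= 1.0
        assert cw.compute_ndvi(nir, red) == pytest.approx(-v, abs=1e-12)


class TestDeriveWue:
    def test_two_sources_averaged(self):
        assert cw.derive_wue([4.0, 6.0], 2.0) == pytest.approx(2.5)

    def test_single_source(self):
        assert cw.derive_wue([5.0], 2.0) == pytest.approx(2.5)

    def test_random_pairs_match_formula_oracle(self):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(1, 10, 50), rng.uniform(1, 10, 50)
        et = rng.uniform(0.5, 8, 50)
        np.testing.assert_allclose(cw.derive_wue([a, b], et), (a + b) / (2 * et), rtol=1e-12)

    def test_zero_et_dropped(self):
        out = cw.derive_wue([4.0], np.array([0.0, 2.0]))
        assert np.isnan(out[0]) and out[1] == pytest.approx(2.0)

    def test_no_sources_rejected(self):
        with pytest.raises(ValueError):
            cw.derive_wue([], 1.0)


class TestUnitConversion:
    @pytest.mark.parametrize("mm,expected", [(1.0, 10_000.0), (5.0, 50_000.0)])
    def test_mm_per_day(self, mm, expected):
        assert cw.to_liters_per_ha(mm, "mm_per_day") == pytest.approx(expected)

    def test_latent_heat_flux(self):
        # independently recomputed: 28.4 W/m2 x 86,400 s/d / 2.45 MJ/kg -> mm, x 10^4
        expected = 28.4 * 86_400.0 / 2.45e6 * 1e4
        got = cw.to_liters_per_ha(28.4, "W_per_m2")
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(10_015.0, rel=1e-4)

    def test_identity_unit(self):
        assert cw.to_liters_per_ha(123.0, "L_per_ha_day") == 123.0

    def test_unknown_unit(self):
        with pytest.raises(ValueError, match="unknown water unit"):
            cw.to_liters_per_ha(1.0, "acre_feet")

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cw.to_liters_per_ha(-1.0, "mm_per_day")


class TestPartitionCanopy:
    def _frame(self, et, fc, wue=2.0):
        return pd.DataFrame({"et": [et], "canopy_fraction": [fc], "wue": [wue]})

    @pytest.mark.parametrize(
        "et,fc,expected_t", [(50_000.0, 0.6, 30_000.0), (50_000.0, 0.0, 0.0), (50_000.0, 1.0, 50_000.0)]
    )
    def test_product(self, et, fc, expected_t):
        out = cw.partition_canopy(self._frame(et, fc))
        assert out.loc[0, "transpiration"] == pytest.approx(expected_t)
        assert out.loc[0, "wue_t"] == pytest.approx(2.0 * fc)

    def test_out_of_range_canopy_rejected(self):
        out = cw.partition_canopy(self._frame(100.0, 1.3))
        assert out.empty

    @given(
        et=st.floats(0.0, 1e5, allow_nan=False, allow_subnormal=False),
        fc=st.floats(0.0, 1.0, allow_nan=False),
        wue=st.floats(0.1, 10.0, allow_nan=False),
    )
    def test_bounds_and_cross_consistency(self, et, fc, wue):
        """0 <= T <= ET, and T/ET = wue_t/wue = canopy fraction."""
        out = cw.partition_canopy(self._frame(et, fc, wue)).iloc[0]
        assert 0.0 <= out["transpiration"] <= et * (1 + 1e-12) + 1e-12
        if et > 0:
            assert out["transpiration"] / et == pytest.approx(fc, rel=1e-9, abs=1e-12)
        assert out["wue_t"] / wue == pytest.approx(fc, rel=1e-9, abs=1e-12)

    def test_commutes_with_unit_conversion(self):
        df_mm = self._frame(5.0, 0.6)
        converted_first = df_mm.assign(et=cw.to_liters_per_ha(df_mm["et"], "mm_per_day"))
        a = cw.partition_canopy(converted_first).loc[0, "transpiration"]
        b = cw.to_liters_per_ha(
            cw.partition_canopy(df_mm).loc[0, "transpiration"], "mm_per_day"
        )
        assert a == pytest.approx(b, rel=1e-12)


class TestNdviToCanopy:
    def test_direct_clips(self):
        assert fluxes.ndvi_to_canopy(-0.2) == 0.0
        assert fluxes.ndvi_to_canopy(0.7) == pytest.approx(0.7)

    def test_rescale(self):
        assert fluxes.ndvi_to_canopy(0.5, "rescale", 0.2, 0.8) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            fluxes.ndvi_to_canopy(0.5, "rescale", 0.8, 0.2)


class TestAssembleFluxSeries:
    def _stats(self, rows):
        return pd.DataFrame(rows, columns=["field_id", "crop", "date", "variable", "mean", "n_pixels"])

    def test_et_only(self):
        stats = self._stats([("f", "c", "2022-06-01", "et", 5.0, 4)])
        stats["date"] = pd.to_datetime(stats["date"])
        out = cw.assemble_flux_series(stats)
        assert out.loc[0, "et"] == pytest.approx(50_000.0)
        assert np.isnan(out.loc[0, "transpiration"])

    def test_canopy_pairing_window(self):
        """An ET day without same-day canopy borrows the nearest canopy
        observation within +/-8 days; beyond the window it stays unpaired."""
        rows = [
            ("f", "c", "2022-06-01", "et", 5.0, 4),
            ("f", "c", "2022-06-06", "canopy", 0.5, 4),
            ("f", "c", "2022-07-15", "et", 4.0, 4),
        ]
        stats = self._stats(rows)
        stats["date"] = pd.to_datetime(stats["date"])
        out = cw.assemble_flux_series(stats).set_index("date")
        assert out.loc["2022-06-01", "canopy_fraction"] == pytest.approx(0.5)
        assert out.loc["2022-06-01", "transpiration"] == pytest.approx(25_000.0)
        assert np.isnan(out.loc["2022-07-15", "canopy_fraction"])

    def test_canopy_percent_product_rescaled(self):
        rows = [
            ("f", "c", "2022-06-01", "et", 5.0, 4),
            ("f", "c", "2022-06-01", "canopy", 60.0, 4),  # percent, not fraction
        ]
        stats = self._stats(rows)
        stats["date"] = pd.to_datetime(stats["date"])
        out = cw.assemble_flux_series(stats)
        assert out.loc[0, "canopy_fraction"] == pytest.approx(0.6)

    def test_product_wue_preferred_over_quotient(self):
        rows = [
            ("f", "c", "2022-06-01", "et", 5.0, 4),
            ("f", "c", "2022-06-01", "wue", 3.0, 4),
            ("f", "c", "2022-06-01", "gpp", 5.0, 4),  # quotient would be 1.0
            ("f", "c", "2022-06-02", "et", 5.0, 4),
            ("f", "c", "2022-06-02", "gpp", 10.0, 4),  # no product WUE -> quotient
        ]
        stats = self._stats(rows)
        stats["date"] = pd.to_datetime(stats["date"])
        out = cw.assemble_flux_series(stats).set_index("date")
        assert out.loc["2022-06-01", "wue"] == pytest.approx(3.0)
        assert out.loc["2022-06-02", "wue"] == pytest.approx(2.0)

    def test_ndvi_as_canopy_source(self):
        rows = [
            ("f", "c", "2022-06-01", "et", 5.0, 4),
            ("f", "c", "2022-06-01", "red", 0.1, 4),
            ("f", "c", "2022-06-01", "nir", 0.5, 4),
        ]
        stats = self._stats(rows)
        stats["date"] = pd.to_datetime(stats["date"])
        out = cw.assemble_flux_series(stats, canopy_source="ndvi")
        assert out.loc[0, "ndvi"] == pytest.approx(2.0 / 3.0)
        assert out.loc[0, "canopy_fraction"] == pytest.approx(2.0 / 3.0)
        assert out.loc[0, "transpiration"] == pytest.approx(50_000.0 * 2.0 / 3.0)

    def test_scene_flux_recovers_truth(self, clean_scene):
        """Noise-free scene: flux table reproduces curve values, NDVI encodes
        canopy, and WUE equals the profile constant."""
        flux = cw.scene_to_flux(clean_scene)
        for prof in clean_scene.truth["profiles"]:
            sub = flux[flux["crop"] == prof.name]
            dates = [d.date() for d in sub["date"]]
            np.testing.assert_allclose(
                sub["et"].to_numpy(), prof.et_curve(dates) * 1e4, rtol=1e-10
            )
            np.testing.assert_allclose(
                sub["canopy_fraction"].to_numpy(), prof.canopy_curve(dates), rtol=1e-9, atol=1e-12
            )
            np.testing.assert_allclose(sub["wue"].to_numpy(), prof.wue_base, rtol=1e-10)
            np.testing.assert_allclose(
                sub["ndvi"].to_numpy(), prof.canopy_curve(dates), rtol=1e-9, atol=1e-9
            )
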