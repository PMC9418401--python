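"""Dose engine: legacy conventions, interpolation, S values, dose assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phantombridge import (
    EmissionSpectrum,
    LegacySAF,
    SAFMatrix,
    TIAVector,
    compute_dose,
    interpolate_saf,
    legacy_saf,
    s_value,
)
from phantombridge.errors import DoseError, PhantomMismatchError, ValidationError
from phantombridge.regions import PhantomCatalog, Region
from phantombridge.units import S_VALUE_MGY_PER_MBQ_S


@pytest.fixture(scope="module")
def toy_catalog():
    """Three-region phantom: an organ, a wall and its contents."""
    regions = [
        Region("ICRP", "Organ", "Organ", "both", 1.0, "other"),
        Region("ICRP", "W-wall", "Wall", "both", 4.0, "other", frozenset({"wall"})),
        Region("ICRP", "W-cont", "Contents", "source", 2.0, "other", frozenset({"contents"})),
    ]
    return PhantomCatalog("ICRP", regions)


class TestLegacySAF:
    def test_self_irradiation_is_reciprocal_mass(self, toy_catalog):
        organ = toy_catalog.lookup("Organ")
        assert legacy_saf(organ, organ, "electron", toy_catalog) == 1.0

    def test_wall_from_own_contents_is_half_contents_self(self, toy_catalog):
        wall = toy_catalog.lookup("W-wall")
        cont = toy_catalog.lookup("W-cont")
        # contents self-SAF is 1/2 g^-1; the wall receives half of that
        assert legacy_saf(cont, wall, "electron", toy_catalog) == 0.25
        ratio = legacy_saf(cont, wall, "electron", toy_catalog) / legacy_saf(
            cont, cont, "electron", toy_catalog
        )
        assert ratio == 0.5

    def test_cross_organ_dose_is_zero(self, toy_catalog):
        organ = toy_catalog.lookup("Organ")
        cont = toy_catalog.lookup("W-cont")
        assert legacy_saf(cont, organ, "electron", toy_catalog) == 0.0
        # contents are not irradiated by their wall under the legacy rule
        wall = toy_catalog.lookup("W-wall")
        assert legacy_saf(wall, cont, "electron", toy_catalog) == 0.0

    def test_alpha_reuses_non_penetrating_rules(self, toy_catalog):
        organ = toy_catalog.lookup("Organ")
        assert legacy_saf(organ, organ, "alpha", toy_catalog) == 1.0

    def test_photon_requires_a_matrix(self, toy_catalog):
        organ = toy_catalog.lookup("Organ")
        with pytest.raises(DoseError, match="matrix"):
            legacy_saf(organ, organ, "photon", toy_catalog)

    def test_legacy_invariants_over_real_catalogs(self, ce_catalog, icrp_catalog):
        """self-SAF x m = 1 and wall/contents ratio = 0.5 wherever masses exist."""
        for cat in (ce_catalog, icrp_catalog):
            saf = LegacySAF(cat)
            for region in cat.targets():
                if region.mass_g is None:
                    continue
                phi = saf.phi("electron", region.acronym, region.acronym)
                assert phi * region.mass_g == pytest.approx(1.0, rel=1e-12)
        icrp_saf = LegacySAF(icrp_catalog)
        for stem in ("RC", "LC", "RS"):
            wall_phi = icrp_saf.phi("electron", f"{stem}-wall", f"{stem}-cont")
            cont_phi = icrp_saf.phi("electron", f"{stem}-cont", f"{stem}-cont")
            assert wall_phi / cont_phi == 0.5


class TestInterpolation:
    @pytest.fixture()
    def saf(self):
        m = SAFMatrix()
        m.add("photon", "Organ", "Organ", [0.01, 0.1, 1.0], [0.01, 0.04, 0.002])
        return m

    def test_exact_at_grid_nodes(self, saf):
        for e, phi in [(0.01, 0.01), (0.1, 0.04), (1.0, 0.002)]:
            assert saf.phi("photon", "Organ", "Organ", e) == phi

    def test_constant_segment_stays_constant(self):
        m = SAFMatrix()
        m.add("photon", "Organ", "Organ", [0.1, 1.0], [0.1, 0.1])
        for e in (0.1, 0.2, 0.5, 0.99, 1.0):
            assert m.phi("photon", "Organ", "Organ", e) == pytest.approx(0.1)

    def test_geometric_midpoint_gives_geometric_mean(self, saf):
        e_mid = math.sqrt(0.01 * 0.1)
        assert saf.phi("photon", "Organ", "Organ", e_mid) == pytest.approx(
            math.sqrt(0.01 * 0.04), rel=1e-12
        )

    def test_no_extrapolation(self, saf):
        for e in (0.005, 1.5):
            with pytest.raises(DoseError, match="grid"):
                saf.phi("photon", "Organ", "Organ", e)

    def test_zero_node_falls_back_to_linear(self):
        m = SAFMatrix()
        m.add("photon", "Organ", "Organ", [0.1, 0.3], [0.0, 0.1])
        assert m.phi("photon", "Organ", "Organ", 0.2) == pytest.approx(0.05)

    def test_functional_alias(self, saf):
        assert interpolate_saf(saf, "photon", "Organ", "Organ", 0.1) == 0.04

    def test_grid_validation(self):
        m = SAFMatrix()
        with pytest.raises(ValidationError):
            m.add("photon", "A", "A", [0.1, 0.1], [1.0, 1.0])
        with pytest.raises(ValidationError):
            m.add("photon", "A", "A", [0.1, 0.2], [1.0, -1.0])


class TestSValue:
    def test_single_electron_line_closed_form(self, toy_catalog):
        """1 MeV, yield 1, legacy self-dose in a 1 g organ.

        Energy deposition is 1 MeV/g per decay, i.e. 1.602e-10 Gy per
        decay, which the declared unit chain reports as mGy per MBq*s.
        """
        spectrum = EmissionSpectrum.from_rows([("electron", 1.0, 1.0)])
        s = s_value(spectrum, LegacySAF(toy_catalog), "Organ", "Organ")
        assert s == pytest.approx(1.602176634e-10 * 1e6 * 1e3, rel=1e-12)
        assert s == pytest.approx(S_VALUE_MGY_PER_MBQ_S, rel=1e-12)

    def test_empty_spectrum_gives_zero(self, toy_catalog):
        assert s_value(EmissionSpectrum(), LegacySAF(toy_catalog), "Organ", "Organ") == 0.0

    @settings(derandomize=True, max_examples=25)
    @given(alpha=st.floats(min_value=0.0, max_value=10.0))
    def test_linear_in_yields(self, toy_catalog, alpha):
        spectrum = EmissionSpectrum.from_rows(
            [("electron", 0.5, 0.9), ("alpha", 5.0, 0.01)]
        )
        saf = LegacySAF(toy_catalog)
        s1 = s_value(spectrum, saf, "Organ", "Organ")
        s2 = s_value(spectrum.scaled_yields(alpha), saf, "Organ", "Organ")
        assert s2 == pytest.approx(alpha * s1, rel=1e-12, abs=1e-300)


class TestComputeDose:
    def test_single_source_dose_is_product(self, toy_catalog):
        spectrum = EmissionSpectrum.from_rows([("electron", 1.0, 1.0)])
        saf = LegacySAF(toy_catalog)
        report = compute_dose(TIAVector("ICRP", {"Organ": 1.0}), spectrum, saf)
        s = s_value(spectrum, saf, "Organ", "Organ")
        assert report.doses["Organ"] == pytest.approx(1.0 * s, rel=1e-12)

    def test_additive_over_sources(self, toy_catalog):
        spectrum = EmissionSpectrum.from_rows([("electron", 1.0, 1.0)])
        saf = LegacySAF(toy_catalog)
        d_both = compute_dose(
            TIAVector("ICRP", {"W-cont": 3.0, "W-wall": 2.0}), spectrum, saf
        ).doses["W-wall"]
        d_cont = compute_dose(TIAVector("ICRP", {"W-cont": 3.0}), spectrum, saf).doses["W-wall"]
        d_wall = compute_dose(TIAVector("ICRP", {"W-wall": 2.0}), spectrum, saf).doses["W-wall"]
        assert d_both == pytest.approx(d_cont + d_wall, rel=1e-12)

    def test_zero_tia_gives_zero_report(self, toy_catalog):
        spectrum = EmissionSpectrum.from_rows([("electron", 1.0, 1.0)])
        report = compute_dose(
            TIAVector("ICRP", {"Organ": 0.0}), spectrum, LegacySAF(toy_catalog)
        )
        assert all(d == 0.0 for d in report.doses.values())

    def test_matches_hand_computed_matrix_vector_product(self, toy_catalog):
        """Independent oracle: D = S @ A~ assembled by hand with numpy."""
        spectrum = EmissionSpectrum.from_rows(
            [("electron", 0.7, 0.95), ("alpha", 5.3, 0.02)]
        )
        saf = LegacySAF(toy_catalog)
        names = ["Organ", "W-wall", "W-cont"]
        masses = {"Organ": 1.0, "W-wall": 4.0, "W-cont": 2.0}
        k = S_VALUE_MGY_PER_MBQ_S
        e_sum = 0.7 * 0.95 + 5.3 * 0.02
        S = np.zeros((3, 3))
        for i, t in enumerate(names):
            S[i, i] = k * e_sum / masses[t]
        S[names.index("W-wall"), names.index("W-cont")] = (
            k * e_sum * 0.5 / masses["W-cont"]
        )
        activity = np.array([3.0, 0.5, 11.0])
        expected = S @ activity
        report = compute_dose(
            TIAVector("ICRP", dict(zip(names, activity))), spectrum, saf, targets=names
        )
        for i, t in enumerate(names):
            assert report.doses[t] == pytest.approx(expected[i], rel=1e-12)

    def test_phantom_mismatch_rejected(self, toy_catalog):
        spectrum = EmissionSpectrum.from_rows([("electron", 1.0, 1.0)])
        with pytest.raises(PhantomMismatchError):
            compute_dose(TIAVector("CE", {"Organ": 1.0}), spectrum, LegacySAF(toy_catalog))

    def test_strict_mode_errors_on_missing_saf_entries(self):
        m = SAFMatrix(phantom="ICRP")
        m.add("electron", "Organ", "Organ", [0.01, 1.0], [1.0, 1.0])
        spectrum = EmissionSpectrum.from_rows([("electron", 0.5, 1.0)])
        tia = TIAVector("ICRP", {"Organ": 1.0, "Elsewhere": 1.0})
        with pytest.raises(DoseError):
            compute_dose(tia, spectrum, m, targets=["Organ"])
        report = compute_dose(tia, spectrum, m, targets=["Organ"], strict=False)
        assert report.doses["Organ"] > 0

    def test_report_totals_equal_contribution_sums(self, toy_catalog):
        spectrum = EmissionSpectrum.from_rows([("electron", 1.0, 0.3)])
        report = compute_dose(
            TIAVector("ICRP", {"Organ": 2.0, "W-cont": 1.0}),
            spectrum,
            LegacySAF(toy_catalog),
        )
        for target, dose in report.doses.items():
            assert dose == pytest.approx(sum(report.contributions[target].values()))
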