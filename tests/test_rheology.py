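"""Rheology: relative viscosity, hard-sphere models, geometry, thickening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesiscope.rheology import (
    VesicleGeometry,
    ViscosityCurve,
    bound_chain_gap,
    compare_models,
    einstein_model,
    face_to_face_distance,
    krieger_dougherty,
    relative_viscosity,
    thickening_metrics,
    vesicle_volume_fraction,
)
from vesiscope.synthetic import gen_viscosity_curve
from vesiscope.units import AVOGADRO


class TestRelativeViscosity:
    def test_identity(self):
        c = gen_viscosity_curve(noise_sd=0.0, seed=0)
        er = relative_viscosity(c, c)
        assert np.allclose(er.eta, 1.0)

    def test_scaling(self):
        c = gen_viscosity_curve(noise_sd=0.0, seed=0)
        double = ViscosityCurve(c.temperature, 2 * c.eta)
        assert np.allclose(relative_viscosity(double, c).eta, 2.0)

    def test_step_preserved(self):
        sample = gen_viscosity_curve(eta_r_base=1.0, jump_fraction=0.10,
                                     T_m=23.5, width=2.0, noise_sd=0.0, seed=0)
        water = gen_viscosity_curve(eta_r_base=1.0, jump_fraction=0.0,
                                    noise_sd=0.0, seed=0)
        er = relative_viscosity(sample, water)
        assert er.eta[0] == pytest.approx(1.0, rel=1e-6)
        assert er.eta[-1] == pytest.approx(1.10, rel=1e-4)

    def test_no_overlap_raises(self):
        a = ViscosityCurve(np.array([10.0, 20.0]), np.array([1.0, 1.0]))
        b = ViscosityCurve(np.array([30.0, 40.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            relative_viscosity(a, b)


class TestHardSphereModels:
    @pytest.mark.parametrize("phi,er", [(0.0, 1.0), (0.092, 1.23), (0.2, 1.5)])
    def test_einstein(self, phi, er):
        assert einstein_model(phi) == pytest.approx(er, abs=0.005)

    @pytest.mark.parametrize("phi,er", [(0.0, 1.0), (0.092, 1.305)])
    def test_krieger_dougherty(self, phi, er):
        assert krieger_dougherty(phi) == pytest.approx(er, abs=0.005)

    def test_kd_taylor_limit(self):
        phi = 1e-6
        assert krieger_dougherty(phi) == pytest.approx(1 + 2.7 * phi, rel=1e-5)

    def test_kd_divergence(self):
        with pytest.raises(ValueError):
            krieger_dougherty(0.71)

    def test_kd_dominates_einstein(self):
        phi = np.linspace(0.001, 0.70, 500)
        assert np.all(krieger_dougherty(phi) >= einstein_model(phi))


class TestVolumeFraction:
    GEOM = dict(outer_diameter=119.9, bilayer_thickness=4.4, area_per_lipid=0.60,
                lipid_molar_mass=678.0, lipid_mass_concentration=17.0)

    @staticmethod
    def _brute_force(g: VesicleGeometry) -> float:
        """Independent step-by-step recomputation of the geometry chain."""
        R_out = g.outer_diameter / 2
        R_in = R_out - g.bilayer_thickness
        area_out = 4 * np.pi * R_out**2
        area_in = 4 * np.pi * R_in**2
        lipids = (area_out + area_in) / g.area_per_lipid
        grams_per_vesicle = lipids * g.lipid_molar_mass / AVOGADRO
        vesicles_per_L = g.lipid_mass_concentration / grams_per_vesicle
        volume_nm3 = 4 / 3 * np.pi * R_out**3
        litres_per_vesicle = volume_nm3 * 1e-24
        return vesicles_per_L * litres_per_vesicle

    def test_study_geometry(self):
        phi, n_lipid, dens = vesicle_volume_fraction(VesicleGeometry(**self.GEOM))
        assert phi == pytest.approx(0.097, abs=0.002)
        assert phi == pytest.approx(self._brute_force(VesicleGeometry(**self.GEOM)), rel=1e-12)

    def test_linear_in_concentration(self):
        g2 = dict(self.GEOM, lipid_mass_concentration=34.0)
        phi1, _, _ = vesicle_volume_fraction(VesicleGeometry(**self.GEOM))
        phi2, _, _ = vesicle_volume_fraction(VesicleGeometry(**g2))
        assert phi2 == pytest.approx(2 * phi1, rel=1e-12)

    def test_area_per_lipid_doubles_phi(self):
        """Half the lipids per vesicle means twice the vesicles."""
        g2 = dict(self.GEOM, area_per_lipid=1.20)
        phi1, _, _ = vesicle_volume_fraction(VesicleGeometry(**self.GEOM))
        phi2, _, _ = vesicle_volume_fraction(VesicleGeometry(**g2))
        assert phi2 == pytest.approx(2 * phi1, rel=1e-12)
        assert phi2 == pytest.approx(self._brute_force(VesicleGeometry(**g2)), rel=1e-12)

    def test_phi_increases_with_diameter(self):
        """Bigger vesicles at fixed lipid mass enclose more water."""
        phis = []
        for d in np.linspace(60.0, 400.0, 12):
            g = VesicleGeometry(**dict(self.GEOM, outer_diameter=d))
            phi, _, _ = vesicle_volume_fraction(g)
            assert phi == pytest.approx(self._brute_force(g), rel=1e-12)
            phis.append(phi)
        assert np.all(np.diff(phis) > 0)

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            VesicleGeometry(**dict(self.GEOM, outer_diameter=8.0))


class TestDistances:
    @pytest.mark.parametrize(
        "phi,d,L", [(0.092, 100.0, 90.6), (0.092, 119.9, 108.6)]
    )
    def test_face_to_face_examples(self, phi, d, L):
        val, contact = face_to_face_distance(phi, d)
        assert val == pytest.approx(L, abs=0.1)
        assert not contact

    def test_contact_limit(self):
        val, contact = face_to_face_distance(2 / np.pi, 123.0)
        assert val == 0.0 and contact

    @given(st.floats(min_value=0.01, max_value=0.6),
           st.floats(min_value=1.0, max_value=1e3))
    @settings(deadline=None)
    def test_homogeneous_in_diameter(self, phi, d):
        L1, _ = face_to_face_distance(phi, d)
        L2, _ = face_to_face_distance(phi, 2 * d)
        assert L2 == pytest.approx(2 * L1, rel=1e-12)

    @pytest.mark.parametrize(
        "L,ext,gap,overlap",
        [(90.0, 23.0, 44.0, False), (90.0, 45.0, 0.0, False), (90.0, 46.0, -2.0, True)],
    )
    def test_bound_chain_gap(self, L, ext, gap, overlap):
        g, o = bound_chain_gap(L, ext)
        assert g == pytest.approx(gap)
        assert o is overlap


class TestThickening:
    def _metrics(self, jump, width, pw, seed=5):
        sample = gen_viscosity_curve(eta_r_base=1.2, jump_fraction=jump, T_m=23.5,
                                     width=width, noise_sd=0.003, seed=seed,
                                     T_range=(5.0, 42.0), n_points=371)
        water = gen_viscosity_curve(eta_r_base=1.0, jump_fraction=0.0,
                                    noise_sd=0.0, seed=0,
                                    T_range=(5.0, 42.0), n_points=371)
        er = relative_viscosity(sample, water)
        return thickening_metrics(er, 23.5, plateau_window=pw)

    def test_large_broad_step(self):
        """An 80% rise spread over ~7 degC, as for large multilamellar vesicles."""
        m = self._metrics(0.80, 7.0, (4.0, 10.0))
        assert m["jump_percent"] == pytest.approx(80.0, abs=2.0)
        assert m["transition_width_C"] == pytest.approx(7.0, abs=0.5)

    def test_small_sharp_step(self):
        """A <10% rise over ~2 degC, as for small unilamellar vesicles."""
        m = self._metrics(0.10, 2.0, (2.0, 6.0))
        assert m["jump_percent"] == pytest.approx(10.0, abs=1.0)
        assert m["transition_width_C"] == pytest.approx(2.0, abs=0.5)

    def test_flat_curve(self):
        sample = gen_viscosity_curve(eta_r_base=1.2, jump_fraction=0.0,
                                     noise_sd=0.0, seed=0)
        water = gen_viscosity_curve(eta_r_base=1.0, jump_fraction=0.0,
                                    noise_sd=0.0, seed=0)
        m = thickening_metrics(relative_viscosity(sample, water), 23.5)
        assert m["jump_percent"] == pytest.approx(0.0, abs=1e-9)
        assert m["transition_width_C"] is None

    def test_insufficient_span(self):
        c = ViscosityCurve(np.linspace(22, 25, 31), np.ones(31))
        with pytest.raises(ValueError):
            thickening_metrics(c, 23.5)


class TestCompareModels:
    PHI = np.array([0.03, 0.06, 0.09, 0.12])

    def test_kd_self_consistency(self):
        obs = krieger_dougherty(self.PHI)
        res = compare_models(self.PHI, obs)
        assert res["kd_rms"] == pytest.approx(0.0, abs=1e-12)
        assert res["einstein_rms"] > 0

    def test_einstein_self_consistency(self):
        obs = einstein_model(self.PHI)
        res = compare_models(self.PHI, obs)
        assert res["einstein_rms"] == pytest.approx(0.0, abs=1e-12)

    def test_scaled_observations(self):
        obs = krieger_dougherty(self.PHI) * 1.1
        res = compare_models(self.PHI, obs)
        assert 0 < res["kd_rms"] < res["einstein_rms"]

    def test_supercritical_phi_excluded(self):
        phi = np.array([0.05, 0.75])
        res = compare_models(phi, np.array([1.2, 9.0]))
        assert res["excluded"] == [0.75]
        assert np.isfinite(res["kd_rms"])
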