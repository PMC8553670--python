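"""Kinetics, boundary fluxes, initialization, and conservation structure."""

import numpy as np
import pytest

from yaptaz3d import model_core as mc
from yaptaz3d.geometry import MOLECULES_PER_UM3_PER_UM as CONV


def _uniform_state(geom, case_id, rng=None, protocol=None):
    case = mc.case_config(case_id)
    protocol = protocol or mc.ActivationProtocol()
    state = mc.initialize_state(geom, case, protocol, mc.ParameterSet())
    if rng is not None:
        # perturb to generic positive uniform values, keeping FAK's footprint
        for name in state.vol:
            state.vol[name][:] = rng.uniform(0.05, 1.5)
        for name in state.surf:
            mask = geom.activation_faces if name.startswith("FAK") else slice(None)
            state.surf[name][:] = 0.0
            state.surf[name][mask] = rng.uniform(0.05, 1.5)
        state.ytn = float(rng.uniform(0.0, 1e5))
    return case, state


class TestThreshold:
    @pytest.mark.parametrize("value,base,expected", [
        (0.26, 0.26, 0.0),
        (0.36, 0.26, 0.10),
        (0.10, 0.13, 0.0),
        (-0.5, 0.0, 0.0),
    ])
    def test_values(self, value, base, expected):
        assert mc.threshold(value, base) == pytest.approx(expected)

    def test_negative_base_raises(self):
        with pytest.raises(mc.ModelError):
            mc.threshold(1.0, -0.1)


class TestVolumetricRates:
    def test_resting_state_only_cofilin_turns_over(self, geom_coarse, params):
        case, state = _uniform_state(geom_coarse, 1)
        for name in state.vol:
            state.vol[name][:] = 0.0
        state.vol["Cofi"][:] = 1.0
        rates = mc.volumetric_rates(state, params, case)
        assert np.allclose(rates["Cof"], params.K_turnover)
        assert np.allclose(rates["Cofi"], -params.K_turnover)
        for name, r in rates.items():
            if name not in ("Cof", "Cofi"):
                assert np.all(r == 0.0)

    def test_factin_decays_without_mdia(self, geom_coarse, params):
        case, state = _uniform_state(geom_coarse, 1)
        for name in state.vol:
            state.vol[name][:] = 0.0
        state.vol["Fcyto"][:] = 1.0
        rates = mc.volumetric_rates(state, params, case)
        assert np.allclose(rates["Fcyto"], -params.K_dep)
        assert np.allclose(rates["Gactin"], params.K_dep)

    def test_yaptaz_activation_gated_by_product(self, geom_coarse, params):
        case, state = _uniform_state(geom_coarse, 1)
        state.vol["Myo"][:] = 0.0
        state.vol["YTci"][:] = 1.0
        state.vol["YTc"][:] = 0.0
        rates = mc.volumetric_rates(state, params, case)
        assert np.all(rates["YTc"] == 0.0)

    def test_case1_rhoa_activation_value(self, geom_coarse, params):
        case, state = _uniform_state(geom_coarse, 1)
        state.vol["FAK"][:] = 0.035
        state.vol["RhoAci"][:] = 1.0
        state.vol["RhoA"][:] = 0.0
        rates = mc.volumetric_rates(state, params, case)
        assert np.allclose(rates["RhoA"], 9.0 * 0.035**2 * 1.0)

    def test_nan_input_rejected(self, geom_coarse, params):
        case, state = _uniform_state(geom_coarse, 1)
        state.vol["ROCK"][0] = np.nan
        with pytest.raises(mc.ModelError):
            mc.volumetric_rates(state, params, case)


class TestBoundaryFluxes:
    def test_no_fak_no_exchange_flux(self, geom_coarse, params):
        case, state = _uniform_state(geom_coarse, 5)
        state.vol["FAKci"][:] = 0.0
        for name in ("FAK", "FAKmi"):
            state.surf[name][:] = 0.0
        vol_rates, surf_rates = mc.boundary_fluxes(state, params, case, geom_coarse)
        assert np.all(surf_rates["FAKmi"] == 0.0)
        assert "FAKci" not in vol_rates or np.all(vol_rates["FAKci"] == 0.0)

    def test_exchange_equilibrium_is_stationary(self, geom_coarse, params):
        case, state = _uniform_state(geom_coarse, 2)
        c = 0.7
        state.vol["RhoAci"][:] = c
        state.vol["FAK"][:] = 0.0  # no activation, isolate the exchange
        state.surf["RhoA"][:] = 0.0
        m_star = params.K_on * c / (geom_coarse.N * params.K_off)
        state.surf["RhoAmi"][:] = m_star
        vol_rates, surf_rates = mc.boundary_fluxes(state, params, case, geom_coarse)
        assert np.allclose(surf_rates["RhoAmi"], 0.0, atol=1e-12)
        assert np.allclose(vol_rates.get("RhoAci", 0.0), 0.0, atol=1e-12)

    def test_case4_activation_confined_to_footprint(self, geom_coarse, params):
        case, state = _uniform_state(geom_coarse, 4)
        state.surf["RhoAmi"][:] = 1.0
        state.surf["RhoA"][:] = 0.0
        _, surf_rates = mc.boundary_fluxes(state, params, case, geom_coarse)
        act = geom_coarse.activation_faces
        assert np.all(surf_rates["RhoA"][act] > 0.0)
        assert np.all(surf_rates["RhoA"][~act] == 0.0)
        # brute-force face sum: production = K_frho * FAK^2 * RhoAmi per face
        fak = state.surf["FAK"]
        expected = params.K_frho * fak[act] ** 2 * 1.0
        assert np.allclose(surf_rates["RhoA"][act], expected)

    def test_sustained_mode_forbidden_for_cytosolic_fak(self, geom_coarse, params):
        case, state = _uniform_state(geom_coarse, 1)
        protocol = mc.ActivationProtocol(mode="sustained_rate")
        with pytest.raises(mc.ModelError):
            mc.boundary_fluxes(state, params, case, geom_coarse, 0.0, protocol)


class TestConservationStructure:
    @pytest.mark.parametrize("case_id", [1, 2, 3, 4, 5])
    def test_total_molecule_rates_vanish_per_family(self, geom_coarse, params,
                                                    rng, case_id):
        """Activation/deactivation/exchange only move molecules, never create."""
        case, state = _uniform_state(geom_coarse, case_id, rng)
        rates = mc.volumetric_rates(state, params, case, validate=False)
        vol_flux, surf_rates = mc.boundary_fluxes(state, params, case, geom_coarse)
        nuc_rate, ytn_rate = mc.nuclear_import(state, params, geom_coarse)
        vv = geom_coarse.voxel_volume
        for fam, (vol_names, surf_names, with_nuc) in mc.FAMILIES.items():
            total = 0.0
            scale = 1e-30
            for name in vol_names:
                if name in state.vol:
                    arr = rates[name] + vol_flux.get(name, 0.0)
                    if with_nuc and name == "YTc":
                        arr = arr + nuc_rate
                    total += float(arr.sum()) * vv * CONV
                    scale += float(np.abs(arr).sum()) * vv * CONV
            for name in surf_names:
                if name in state.surf:
                    total += float((surf_rates[name] * geom_coarse.mem_area).sum()) \
                        * mc.SURFACE_UNIT
                    scale += float((np.abs(surf_rates[name]) * geom_coarse.mem_area).sum()) \
                        * mc.SURFACE_UNIT
            if with_nuc:
                total += ytn_rate
                scale += abs(ytn_rate)
            assert abs(total) < 1e-10 * scale


class TestNuclearImport:
    def test_zero_field_gives_zero_import(self, geom_coarse, params):
        case, state = _uniform_state(geom_coarse, 1)
        state.vol["YTc"][:] = 0.0
        _, ytn_rate = mc.nuclear_import(state, params, geom_coarse)
        assert ytn_rate == 0.0

    def test_linearity_in_import_rate(self, geom_coarse, params, rng):
        case, state = _uniform_state(geom_coarse, 1, rng)
        _, rate1 = mc.nuclear_import(state, params, geom_coarse)
        doubled = params.with_overrides(K_CN=2 * params.K_CN)
        _, rate2 = mc.nuclear_import(state, doubled, geom_coarse)
        assert rate2 == pytest.approx(2 * rate1, rel=1e-12)

    def test_uniform_field_flux_over_nuclear_area(self, geom_coarse, params):
        """A uniform field imports K_CN * c over the smooth nuclear area:
        the bare surface flux, with no volume-to-surface amplification,
        makes the small nuclear membrane the translocation bottleneck."""
        case, state = _uniform_state(geom_coarse, 1)
        c0 = 0.8
        state.vol["YTc"][:] = c0
        vol_rate, ytn_rate = mc.nuclear_import(state, params, geom_coarse)
        expected = params.K_CN * c0 * CONV * geom_coarse.nuclear_area
        assert ytn_rate == pytest.approx(expected, rel=1e-12)
        vv = geom_coarse.voxel_volume
        assert float(vol_rate.sum()) * vv * CONV == pytest.approx(-expected, rel=1e-12)


class TestInitializeState:
    def test_case1_active_fak_concentration(self, geom_coarse, params, protocol):
        state = mc.initialize_state(geom_coarse, mc.case_config(1), protocol, params)
        conc = state.vol["FAK"][0]
        assert conc == pytest.approx(58104.35 / (CONV * geom_coarse.cytosol_volume),
                                     rel=1e-12)
        assert conc == pytest.approx(0.035, abs=0.002)

    def test_sustained_mode_starts_inactive(self, geom_coarse, params):
        protocol = mc.ActivationProtocol(mode="sustained_rate")
        state = mc.initialize_state(geom_coarse, mc.case_config(5), protocol, params)
        assert np.all(state.surf["FAK"] == 0.0)
        totals = mc.family_totals(state, geom_coarse)
        assert totals["FAK"] == pytest.approx(protocol.total_FAK, rel=1e-9)

    @pytest.mark.parametrize("case_id", [1, 2, 3, 4, 5])
    def test_fak_total_identical_across_cases(self, geom_coarse, params,
                                              protocol, case_id):
        state = mc.initialize_state(geom_coarse, mc.case_config(case_id),
                                    protocol, params)
        totals = mc.family_totals(state, geom_coarse)
        assert totals["FAK"] == pytest.approx(protocol.total_FAK, rel=1e-9)
        # every inactive pool at 1 uM over the cytosol
        one_um = CONV * geom_coarse.cytosol_volume
        assert totals["YAPTAZ"] == pytest.approx(one_um, rel=1e-9)
        assert totals["Actin"] == pytest.approx(one_um, rel=1e-9)

    def test_membrane_case_surface_concentration(self, geom_coarse, params, protocol):
        state = mc.initialize_state(geom_coarse, mc.case_config(3), protocol, params)
        act = geom_coarse.activation_faces
        expected = 58104.35 / (mc.SURFACE_UNIT * geom_coarse.activation_area)
        assert np.allclose(state.surf["FAK"][act], expected)
        assert np.all(state.surf["FAK"][~act] == 0.0)
        # on the uM-equivalent display scale the same molecules read ~7x
        # the cytosolic concentration: membrane-localization amplification
        display = expected * mc.SURFACE_UNIT / CONV
        assert display == pytest.approx(0.25, rel=0.05)


class TestSustainedActivationRate:
    def test_saturates_to_ksf(self, params):
        assert mc.sustained_activation_rate(params, 1e12) == \
            pytest.approx(params.K_sf, rel=1e-5)

    def test_half_rate_at_ceff(self, params):
        c_eff = params.C * params.LD
        assert mc.sustained_activation_rate(params, c_eff) == \
            pytest.approx(params.K_sf / 2.0, rel=1e-12)

    def test_zero_stiffness_zero_rate(self, params):
        assert mc.sustained_activation_rate(params, 0.0) == 0.0

    def test_negative_stiffness_raises(self, params):
        with pytest.raises(mc.ModelError):
            mc.sustained_activation_rate(params, -1.0)
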