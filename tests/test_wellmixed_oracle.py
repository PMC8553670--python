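"""Compartment-ODE reduction: structure, closed forms, and the central
equivalence between its right-hand side and the 3D rate fields."""

import numpy as np
import pytest

from yaptaz3d import model_core as mc, wellmixed_oracle as wm
from yaptaz3d.geometry import MOLECULES_PER_UM3_PER_UM as CONV


def _oracle_vector_from_state(model, state, geom):
    """Map a spatially uniform 3D state onto the oracle's state vector."""
    y = np.zeros(len(model.species))
    act = geom.activation_faces
    for i, name in enumerate(model.species):
        if name == "YTn":
            y[i] = state.ytn
        elif name.endswith("_s"):
            base = name[:-2]
            arr = state.surf[base]
            y[i] = arr[act][0] if base.startswith("FAK") else arr[0]
        elif name.endswith("_v"):
            y[i] = state.vol[name[:-2]][0]
        else:
            y[i] = state.vol[name][0]
    return y


def _pde_total_rates(state, params, case, geom):
    """Family-agnostic per-species molecule rates of the full 3D model."""
    rates = mc.volumetric_rates(state, params, case, validate=False)
    vol_flux, surf_rates = mc.boundary_fluxes(state, params, case, geom)
    nuc_rate, ytn_rate = mc.nuclear_import(state, params, geom)
    vv = geom.voxel_volume
    out = {}
    for name in state.vol:
        arr = rates[name] + vol_flux.get(name, 0.0)
        if name == "YTc":
            arr = arr + nuc_rate
        out[name] = float(arr.sum()) * vv * CONV
    for name in state.surf:
        key = name + "_s"
        out[key] = float((surf_rates[name] * geom.mem_area).sum()) * mc.SURFACE_UNIT
    out["YTn"] = ytn_rate
    return out


class TestReduce:
    def test_case1_has_no_surface_species(self, geom_coarse, params):
        model = wm.reduce(geom_coarse, mc.case_config(1), params)
        assert not any(s.endswith("_s") for s in model.species)

    def test_case5_has_three_fak_pools(self, geom_coarse, params):
        model = wm.reduce(geom_coarse, mc.case_config(5), params)
        fak_pools = [s for s in model.species if s.startswith("FAK")]
        assert sorted(fak_pools) == ["FAKci", "FAK_s", "FAKmi_s"] or \
            set(fak_pools) == {"FAKci", "FAK_s", "FAKmi_s"}

    @pytest.mark.parametrize("case_id", [1, 2, 3, 4, 5])
    def test_initial_totals_match_3d(self, geom_coarse, params, protocol, case_id):
        case = mc.case_config(case_id)
        model = wm.reduce(geom_coarse, case, params, protocol)
        y0 = wm._initial_vector(model)
        totals = wm._totals(model, y0[:, None])
        state = mc.initialize_state(geom_coarse, case, protocol, params)
        totals3d = mc.family_totals(state, geom_coarse)
        fak = totals["FAKci"][0] + totals.get("FAK", [0])[0] + totals.get("FAKmi", [0])[0]
        assert fak == pytest.approx(totals3d["FAK"], rel=1e-9)
        yt = totals["YTc"][0] + totals["YTci"][0] + totals["YTn"][0]
        assert yt == pytest.approx(totals3d["YAPTAZ"], rel=1e-9)


class TestRhsEquivalence:
    @pytest.mark.parametrize("case_id", [1, 2, 3, 4, 5])
    def test_oracle_rhs_equals_summed_3d_rates(self, geom_coarse, params,
                                               rng, case_id):
        """At any uniform state the reduction is exact, to machine precision."""
        case = mc.case_config(case_id)
        protocol = mc.ActivationProtocol()
        state = mc.initialize_state(geom_coarse, case, protocol, params)
        for name in state.vol:
            state.vol[name][:] = rng.uniform(0.05, 2.0)
        act = geom_coarse.activation_faces
        for name in state.surf:
            state.surf[name][:] = 0.0
            if name.startswith("FAK"):
                state.surf[name][act] = rng.uniform(0.05, 2.0)
            else:
                state.surf[name][:] = rng.uniform(0.05, 2.0)
        state.ytn = float(rng.uniform(0, 1e5))

        model = wm.reduce(geom_coarse, case, params, protocol)
        y = _oracle_vector_from_state(model, state, geom_coarse)
        dy = wm._rhs(0.0, y, model)
        # oracle rates -> molecule rates
        mol_rates = {}
        for i, name in enumerate(model.species):
            if name == "YTn":
                mol_rates[name] = dy[i]
            elif name.endswith("_s"):
                area = model.A_act if name.startswith("FAK") else model.A
                mol_rates[name] = dy[i] * mc.SURFACE_UNIT * area
            else:
                mol_rates[name.replace("_v", "")] = dy[i] * CONV * model.V
        pde = _pde_total_rates(state, params, case, geom_coarse)
        for name, ode_rate in mol_rates.items():
            key = name if name in pde else name + "_v"
            if key == "YTn":
                pde_rate = pde["YTn"]
            elif name.endswith("_s"):
                pde_rate = pde[name]
            else:
                pde_rate = pde.get(name, pde.get(name + "_v"))
            scale = max(abs(ode_rate), abs(pde_rate), 1e-6)
            assert abs(ode_rate - pde_rate) < 1e-9 * scale, name


class TestSolve:
    def test_no_activation_no_translocation(self, geom_coarse, params):
        protocol = mc.ActivationProtocol(initial_active_FAK=0.0)
        model = wm.reduce(geom_coarse, mc.case_config(5), params, protocol)
        res = wm.solve(model, 200.0)
        assert np.all(res.ytnf == 0.0)

    def test_fak_decay_matches_closed_form(self, geom_coarse, params, protocol):
        model = wm.reduce(geom_coarse, mc.case_config(1), params, protocol)
        res = wm.solve(model, 50.0, rtol=1e-10, atol=1e-12)
        expected = protocol.initial_active_FAK * np.exp(-params.K_df * res.times)
        assert np.allclose(res.totals["FAK"], expected, rtol=1e-7)

    def test_cases_4_and_5_overlap_with_initial_amount(self, geom_coarse, params,
                                                       protocol):
        res4 = wm.solve(wm.reduce(geom_coarse, mc.case_config(4), params, protocol),
                        300.0)
        res5 = wm.solve(wm.reduce(geom_coarse, mc.case_config(5), params, protocol),
                        300.0)
        assert np.allclose(res4.ytnf, res5.ytnf, atol=1e-9)
        for name in ("RhoA", "ROCK", "Myo", "Fcyto", "YTn"):
            a, b = res4.totals[name], res5.totals[name]
            assert np.allclose(a, b, atol=1e-6 * max(1.0, np.max(np.abs(a))))

    def test_conservation(self, geom_coarse, params, protocol):
        model = wm.reduce(geom_coarse, mc.case_config(4), params, protocol)
        res = wm.solve(model, 100.0)
        rhoa = res.totals["RhoAci"] + res.totals["RhoA"] + res.totals["RhoAmi"]
        assert np.all(np.abs(rhoa - rhoa[0]) < 1e-6 * rhoa[0])


class TestCompare:
    def test_self_comparison_is_zero(self, geom_coarse, params, protocol):
        model = wm.reduce(geom_coarse, mc.case_config(1), params, protocol)
        res = wm.solve(model, 20.0)
        rep = wm.compare(res, res, threshold=1e-12)
        assert rep["max"] == 0.0
        assert rep["pass"]
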