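"""CNS model: mass balance, steady state, closed-form oracle, monotonicity."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.linalg import expm

from brainecf import (
    ClearanceSet,
    CNSModelSpec,
    DoseEvent,
    DoseRegimen,
    DrugProperties,
    PhysiologyParams,
    PlasmaPKParameters,
    kpuu_scaled_profile,
    sensitivity_sweep,
    simulate_brain_ecf,
    steady_state_kpuu,
)
from brainecf.model import ECF, MV, N_STATES, rhs

PHYS = PhysiologyParams(
    sa_bbb=155.0, trans_fraction=0.998, v_mv=0.06, v_ecf=0.29, v_bc=0.0044,
    q_cbf=1.2, q_ecf=0.0003, ph_ecf=7.3,
)


def make_spec(cl_passive=0.1, cl_pgp=0.2, fup=0.5, cl_bc_in=0.0, cl_bc_out=0.0,
              regimen=None, plasma=None, physiology=PHYS):
    drug = DrugProperties(
        name="probe", fup=fup, pka=8.3, species="base",
        cl_bc_in=cl_bc_in, cl_bc_out=cl_bc_out,
    )
    clearances = ClearanceSet(cl_passive, cl_pgp, 1.0)
    plasma = plasma or PlasmaPKParameters(cl_cen=72.3, v_cen=11700.0)
    regimen = regimen or DoseRegimen("IV", (DoseEvent(1.0e6, 0.0, 240.0),))
    return CNSModelSpec(physiology, drug, clearances, plasma, regimen)


class TestRHS:
    def test_empty_system_is_at_equilibrium(self):
        spec = make_spec(regimen=DoseRegimen("IV", (DoseEvent(1.0, 500.0, 10.0),)))
        dy = rhs(np.zeros(N_STATES), 0.0, spec)
        assert dy == pytest.approx(np.zeros(N_STATES))

    def test_passive_equilibrium_at_unity_unbound_ratio(self):
        # no efflux, no bulk flow, no membrane terms: C_ECF = fup * C_MV is stationary
        phys = replace(PHYS, q_ecf=0.0)
        spec = make_spec(cl_pgp=0.0, fup=0.4, physiology=phys,
                         regimen=DoseRegimen("IV", (DoseEvent(1.0, 500.0, 10.0),)))
        state = np.zeros(N_STATES)
        state[MV] = 1.0 * phys.v_mv  # C_MV = 1
        state[ECF] = 0.4 * phys.v_ecf  # C_ECF = fup * C_MV
        dy = rhs(state, 0.0, spec)
        assert dy[ECF] == pytest.approx(0.0, abs=1e-14)

    def test_ecf_influx_term_by_term(self):
        # CL_passive 1, CL_Pgp 3, fup 1, C_MV 1, C_ECF 0 -> V_ECF dC_ECF/dt = 1
        spec = make_spec(cl_passive=1.0, cl_pgp=3.0, fup=1.0,
                         regimen=DoseRegimen("IV", (DoseEvent(1.0, 500.0, 10.0),)))
        state = np.zeros(N_STATES)
        state[MV] = 1.0 * PHYS.v_mv
        dy = rhs(state, 0.0, spec)
        assert dy[ECF] == pytest.approx(1.0, rel=1e-12)

    def test_nonfinite_state_aborts(self):
        spec = make_spec()
        state = np.zeros(N_STATES)
        state[MV] = np.nan
        with pytest.raises(FloatingPointError):
            rhs(state, 0.0, spec)


class TestSimulation:
    def test_doubling_dose_doubles_concentrations(self, grid240):
        spec1 = make_spec()
        spec2 = make_spec(regimen=DoseRegimen("IV", (DoseEvent(2.0e6, 0.0, 240.0),)))
        r1 = simulate_brain_ecf(spec1, grid240)
        r2 = simulate_brain_ecf(spec2, grid240)
        assert r2.c_ecf == pytest.approx(2 * r1.c_ecf, rel=1e-6, abs=1e-9)
        assert r2.c_plasma == pytest.approx(2 * r1.c_plasma, rel=1e-6, abs=1e-9)

    def test_mass_balance_during_and_after_infusion(self, grid240):
        spec = make_spec(cl_bc_in=0.05, cl_bc_out=0.01)
        res = simulate_brain_ecf(spec, grid240)
        assert res.mass_balance_error() < 1e-6

    def test_ecf_pointwise_nonincreasing_in_efflux(self, grid240):
        base = make_spec(cl_pgp=0.1)
        more = make_spec(cl_pgp=0.5)
        r_base = simulate_brain_ecf(base, grid240)
        r_more = simulate_brain_ecf(more, grid240)
        assert np.all(r_more.c_ecf <= r_base.c_ecf + 1e-12)

    def test_closed_form_matrix_exponential_oracle(self):
        # passive-only barrier, bolus dose: the LTI system has the exact
        # solution y(t) = expm(A t) y0, computed independently of the solver
        spec = make_spec(cl_pgp=0.0, regimen=DoseRegimen("IV", (DoseEvent(1.0e6, 0.0, 0.0),)))
        grid = np.linspace(0.0, 240.0, 25)
        res = simulate_brain_ecf(spec, grid)
        A = spec.system_matrix()
        y0 = np.zeros(N_STATES)
        y0[1] = 1.0e6  # bolus into central
        exact = np.column_stack([expm(A * t) @ y0 for t in grid])
        scale = np.abs(exact).max(axis=1, keepdims=True)
        occupied = scale[:, 0] > 0  # states the bolus never reaches stay identically 0
        assert np.max(np.abs(res.amounts - exact)[occupied] / scale[occupied]) < spec.rtol * 10
        assert np.all(res.amounts[~occupied] == 0)

    def test_dense_output_matches_grid(self, grid240):
        spec = make_spec()
        res = simulate_brain_ecf(spec, grid240)
        assert res.ecf_at(grid240[50]) == pytest.approx(res.c_ecf[50], rel=1e-9)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_brain_ecf(make_spec(), np.array([0.0]))


class TestSteadyState:
    @pytest.mark.parametrize(
        "cl_passive,cl_pgp,q_ecf,expected",
        [(1.0, 3.0, 0.0, 0.25), (0.7, 0.0, 0.0, 1.0), (0.1367, 0.0, 0.0003, 0.99781)],
    )
    def test_closed_form(self, cl_passive, cl_pgp, q_ecf, expected):
        assert steady_state_kpuu(cl_passive, cl_pgp, q_ecf) == pytest.approx(expected, abs=1e-5)

    def test_bounded_in_unit_interval(self):
        assert 0 < steady_state_kpuu(0.3, 5.0, 0.1) < 1
        assert steady_state_kpuu(0.3, 0.0, 0.0) == 1.0

    @pytest.mark.parametrize("membrane", [False, True])
    def test_long_infusion_reaches_closed_form_kpuu(self, membrane):
        # membrane-partitioning clearances cancel at steady state
        kwargs = dict(cl_bc_in=0.05, cl_bc_out=0.02) if membrane else {}
        t_end = 2000.0
        spec = make_spec(
            cl_passive=0.15, cl_pgp=0.3,
            regimen=DoseRegimen("IV", (DoseEvent(4166.67 * t_end, 0.0, t_end),)),
            **kwargs,
        )
        res = simulate_brain_ecf(spec, np.linspace(0.0, t_end, 201))
        expected = steady_state_kpuu(0.15, 0.3, PHYS.q_ecf)
        assert res.kpuu[-1] == pytest.approx(expected, rel=0.01)


class TestDerivedProfiles:
    def test_kpuu_scaled_profile(self):
        plasma_u = np.array([100.0, 50.0, 0.0])
        assert kpuu_scaled_profile(plasma_u, 0.147) == pytest.approx([14.7, 7.35, 0.0])
        assert kpuu_scaled_profile(plasma_u, 1.0) == pytest.approx(plasma_u)

    def test_kpuu_scaled_profile_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            kpuu_scaled_profile(np.array([1.0]), 0.0)


class TestSensitivitySweep:
    def test_unity_erc_column_is_passive_only(self, grid240):
        spec = make_spec()
        swept = sensitivity_sweep(spec, [10.0], [1.0], grid240)
        passive = ClearanceSet(10.0e-6 * PHYS.sa_bbb * 60.0, 0.0, 1.0)
        direct = simulate_brain_ecf(replace(spec, clearances=passive), grid240)
        assert swept[0].c_ecf == pytest.approx(direct.c_ecf, rel=1e-9, abs=1e-12)

    def test_results_carry_grid_coordinates(self, grid240):
        swept = sensitivity_sweep(make_spec(), [5.0, 10.0], [1.0, 2.0], grid240)
        assert [(r.papp, r.erc) for r in swept] == [
            (5.0, 1.0), (5.0, 2.0), (10.0, 1.0), (10.0, 2.0)
        ]

    def test_empty_grid_rejected(self, grid240):
        with pytest.raises(ValueError):
            sensitivity_sweep(make_spec(), [], [1.0], grid240)
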