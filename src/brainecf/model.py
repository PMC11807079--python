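"""Coupled plasma - microvasculature - brainECF - cell-membrane ODE model.

Compartment structure (all states in amounts, ng; concentrations derived
by dividing by compartment volumes):

* plasma subsystem (depot, central, 0-2 peripheral, eliminated sink),
* brain microvasculature (MV), exchanging with plasma at cerebral blood
  flow Q_CBF,
* brain extracellular fluid (ECF), exchanging with MV through passive
  clearance (unbound drug only on the vascular side: fup * C_MV in,
  C_ECF out) and losing drug to MV via P-gp efflux,
* brain cell membranes (BC), fed by the unionized ECF fraction,
* a terminal sink for ECF bulk flow Q_ECF (CSF not modelled).

The ECF mass balance is

    V_ECF dC_ECF/dt = CL_passive*fup*C_MV - (CL_Pgp + CL_passive)*C_ECF
                      - Q_ECF*C_ECF - CL_BC,in*PHF_ECF*C_ECF
                      + CL_BC,out*C_BC

and its steady-state consequence, with membrane terms cancelling, is
Kp_uu = CL_passive / (CL_passive + CL_Pgp + Q_ECF): the model has no
influx mechanism, so Kp_uu never exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from ._linode import InputEvent, delivered_dose, integrate_linear_system
from .ivive import ClearanceSet, passive_clearance, pgp_clearance
from .params import DrugProperties, PhysiologyParams
from .plasma import CENTRAL, N_PLASMA_STATES, DoseRegimen, PlasmaPKParameters

__all__ = [
    "CNSModelSpec",
    "SimulationResult",
    "rhs",
    "simulate_brain_ecf",
    "steady_state_kpuu",
    "kpuu_scaled_profile",
    "sensitivity_sweep",
]

# brain states appended after the 5 plasma states
MV = N_PLASMA_STATES
ECF = N_PLASMA_STATES + 1
BC = N_PLASMA_STATES + 2
QECF_SINK = N_PLASMA_STATES + 3
N_STATES = N_PLASMA_STATES + 4

STATE_NAMES = ("depot", "central", "per1", "per2", "eliminated", "mv", "ecf", "bc", "qecf_sink")


@dataclass(frozen=True)
class CNSModelSpec:
    """Full simulation specification for one drug and regimen."""

    physiology: PhysiologyParams
    drug: DrugProperties
    clearances: ClearanceSet
    plasma: PlasmaPKParameters
    regimen: DoseRegimen
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = float("inf")

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0 or self.max_step <= 0:
            raise ValueError("solver tolerances and max step must be positive")

    def system_matrix(self) -> np.ndarray:
        """Rate matrix over the 9 amount states; columns sum to zero."""
        phys, drug, cl = self.physiology, self.drug, self.clearances
        A = np.zeros((N_STATES, N_STATES))
        A[:N_PLASMA_STATES, :N_PLASMA_STATES] = self.plasma.system_matrix()

        # flow-limited vascular exchange (mass moves between central and MV)
        k_pl = phys.q_cbf / self.plasma.v_cen
        k_mv = phys.q_cbf / phys.v_mv
        A[CENTRAL, CENTRAL] -= k_pl
        A[MV, CENTRAL] += k_pl
        A[MV, MV] -= k_mv
        A[CENTRAL, MV] += k_mv

        # BBB exchange; fup applies on the vascular side only, P-gp efflux
        # returns drug to the microvasculature
        k_in = cl.cl_passive * drug.fup / phys.v_mv
        k_out = (cl.cl_passive + cl.cl_pgp) / phys.v_ecf
        A[MV, MV] -= k_in
        A[ECF, MV] += k_in
        A[ECF, ECF] -= k_out
        A[MV, ECF] += k_out

        # ECF bulk flow to the terminal sink
        k_sink = phys.q_ecf / phys.v_ecf
        A[ECF, ECF] -= k_sink
        A[QECF_SINK, ECF] += k_sink

        # brain-cell-membrane partitioning (unionized fraction enters)
        if drug.cl_bc_in > 0 or drug.cl_bc_out > 0:
            phf = drug.phf_ecf(phys.ph_ecf)
            k_bc_in = drug.cl_bc_in * phf / phys.v_ecf
            k_bc_out = drug.cl_bc_out / phys.v_bc
            A[ECF, ECF] -= k_bc_in
            A[BC, ECF] += k_bc_in
            A[BC, BC] -= k_bc_out
            A[ECF, BC] += k_bc_out
        return A


def rhs(state: np.ndarray, t: float, spec: CNSModelSpec) -> np.ndarray:
    """Time derivatives (ng/min) of all amount states at time ``t``."""
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise FloatingPointError(f"non-finite state at t={t}: {state}")
    u = np.zeros(N_STATES)
    target = spec.regimen.target_state
    for ev in spec.regimen.events:
        if ev.duration > 0 and ev.start <= t < ev.start + ev.duration:
            u[target] += ev.amount_ng * spec.regimen.f_bio / ev.duration
    dy = spec.system_matrix() @ state + u
    if not np.all(np.isfinite(dy)):
        raise FloatingPointError(f"non-finite derivative at t={t}; state={state}")
    return dy


@dataclass
class SimulationResult:
    """Time-course output of :func:`simulate_brain_ecf`.

    Concentrations are ng/mL: ``c_plasma`` total central plasma, ``c_mv``
    total microvascular, ``c_ecf`` unbound brainECF (microdialysis
    equivalent), ``c_bc`` brain-cell-membrane.  ``kpuu`` is the
    instantaneous unbound partition ratio c_ecf / (fup * c_plasma).
    Dense output is retained: ``ecf_at(times)`` evaluates brainECF
    concentration at arbitrary times without grid interpolation.
    """

    time: np.ndarray
    c_plasma: np.ndarray
    c_mv: np.ndarray
    c_ecf: np.ndarray
    c_bc: np.ndarray
    amounts: np.ndarray  # (N_STATES, nt)
    spec: CNSModelSpec
    _solution: object = field(repr=False, default=None)
    papp: Optional[float] = None
    erc: Optional[float] = None

    @property
    def kpuu(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                self.c_plasma > 0, self.c_ecf / (self.spec.drug.fup * self.c_plasma), np.nan
            )

    @property
    def auc_ecf(self) -> float:
        """Trapezoid AUC of the brainECF profile, ng*min/mL."""
        return float(np.trapezoid(self.c_ecf, self.time))

    def states_at(self, times) -> np.ndarray:
        return self._solution(times)

    def ecf_at(self, times) -> np.ndarray:
        """BrainECF concentration (ng/mL) at arbitrary times, dense output."""
        t_arr = np.asarray(times, dtype=float)
        vals = self._solution(np.atleast_1d(t_arr))[ECF] / self.spec.physiology.v_ecf
        return float(vals[0]) if t_arr.ndim == 0 else vals

    def mass_balance_error(self) -> float:
        """Max relative error of (compartments + sinks) vs delivered dose."""
        events = self.spec.regimen.input_events()
        delivered = delivered_dose(events, self.time)
        total = self.amounts.sum(axis=0)
        scale = max(ev.amount for ev in events)
        with np.errstate(invalid="ignore"):
            err = np.abs(total - delivered) / scale
        return float(np.nanmax(err))

    def to_frame(self):
        """Tidy long-format DataFrame (time_min, compartment, conc_ng_per_mL)."""
        import pandas as pd

        frames = []
        for name, series in (
            ("plasma", self.c_plasma),
            ("mv", self.c_mv),
            ("ecf", self.c_ecf),
            ("bc", self.c_bc),
        ):
            frames.append(
                pd.DataFrame(
                    {"time_min": self.time, "compartment": name, "conc_ng_per_mL": series}
                )
            )
        return pd.concat(frames, ignore_index=True)


def simulate_brain_ecf(spec: CNSModelSpec, grid: np.ndarray) -> SimulationResult:
    """Integrate the CNS model on ``grid`` (minutes, strictly increasing)."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0) or grid[0] < 0:
        raise ValueError("grid must be a strictly increasing 1-D array starting at >= 0")
    solution = integrate_linear_system(
        spec.system_matrix(),
        spec.regimen.input_events(),
        t_end=float(grid[-1]),
        rtol=spec.rtol,
        atol=spec.atol,
        max_step=spec.max_step,
    )
    amounts = solution(grid)
    phys = spec.physiology
    return SimulationResult(
        time=grid,
        c_plasma=amounts[CENTRAL] / spec.plasma.v_cen,
        c_mv=amounts[MV] / phys.v_mv,
        c_ecf=amounts[ECF] / phys.v_ecf,
        c_bc=amounts[BC] / phys.v_bc,
        amounts=amounts,
        spec=spec,
        _solution=solution,
    )


def steady_state_kpuu(cl_passive: float, cl_pgp: float, q_ecf: float) -> float:
    """Steady-state unbound brainECF/plasma ratio.

    Closed-form consequence of the ECF balance at steady state (membrane
    partitioning cancels): Kp_uu = CL_passive/(CL_passive + CL_Pgp + Q_ECF),
    bounded in (0, 1].
    """
    if cl_passive <= 0:
        raise ValueError("cl_passive must be positive")
    if cl_pgp < 0 or q_ecf < 0:
        raise ValueError("cl_pgp and q_ecf must be non-negative")
    return cl_passive / (cl_passive + cl_pgp + q_ecf)


def kpuu_scaled_profile(c_plasma_unbound: np.ndarray, kpuu_observed: float) -> np.ndarray:
    """Extent-only brainECF proxy: unbound plasma profile times observed Kp_uu."""
    if kpuu_observed <= 0:
        raise ValueError("kpuu_observed must be positive")
    return np.asarray(c_plasma_unbound, dtype=float) * kpuu_observed


def sensitivity_sweep(
    spec: CNSModelSpec,
    papp_grid: Sequence[float],
    erc_grid: Sequence[float],
    grid: np.ndarray,
) -> List[SimulationResult]:
    """Re-simulate over a (P_app[I], ER_c) grid at fixed REF.

    Clearances are recomputed from each grid point through the scaling
    relations (CL_passive from P_app and total BBB surface, CL_Pgp from
    ER_c, P_app, transcellular surface and the spec's REF); each result
    carries its grid coordinates in ``papp``/``erc``.
    """
    if len(papp_grid) == 0 or len(erc_grid) == 0:
        raise ValueError("sweep grids must be non-empty")
    if any(p <= 0 for p in papp_grid) or any(e <= 0 for e in erc_grid):
        raise ValueError("sweep grid values must be positive")
    phys = spec.physiology
    ref = spec.clearances.ref
    results = []
    for papp in papp_grid:
        for erc in erc_grid:
            cl = ClearanceSet(
                cl_passive=passive_clearance(papp, phys.sa_bbb),
                cl_pgp=pgp_clearance(erc, papp, phys.sa_bbb_trans, ref),
                ref=ref,
                provenance=("sweep", f"papp={papp},erc={erc}"),
            )
            res = simulate_brain_ecf(replace(spec, clearances=cl), grid)
            res.papp = papp
            res.erc = erc
            results.append(res)
    return results
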