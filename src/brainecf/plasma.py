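"""Empirical plasma pharmacokinetics driving the CNS model.

The systemic side is a 1-3 compartment mammillary model (optional
first-order absorption depot for subcutaneous dosing) parameterised by
empirical population-PK estimates; here those parameters are inputs, not
estimated.  Plasma concentration is total drug; the unbound fraction fup
is applied at the blood-brain barrier, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from ._linode import InputEvent, integrate_linear_system

__all__ = [
    "PlasmaPKParameters",
    "DoseEvent",
    "DoseRegimen",
    "infusion_rate",
    "simulate_plasma",
    "css_constant_infusion",
]

# state layout of the plasma subsystem
DEPOT, CENTRAL, PER1, PER2, ELIM = range(5)
N_PLASMA_STATES = 5


@dataclass(frozen=True)
class PlasmaPKParameters:
    """Compartmental plasma PK parameters (mL, mL/min, 1/min)."""

    cl_cen: float
    v_cen: float
    q_cen_per1: float = 0.0
    q_cen_per2: float = 0.0
    v_per1: float = 0.0
    v_per2: float = 0.0
    ka: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cl_cen <= 0 or self.v_cen <= 0:
            raise ValueError("cl_cen and v_cen must be positive")
        for q, v, tag in (
            (self.q_cen_per1, self.v_per1, "per1"),
            (self.q_cen_per2, self.v_per2, "per2"),
        ):
            if q < 0 or v < 0:
                raise ValueError(f"{tag} clearance/volume must be non-negative")
            if q > 0 and v == 0:
                raise ValueError(f"q_cen_{tag} > 0 requires v_{tag} > 0")
        if self.ka is not None and self.ka <= 0:
            raise ValueError("ka must be positive when present")

    def system_matrix(self) -> np.ndarray:
        """Rate matrix A (amounts, ng) over the 5 plasma states."""
        A = np.zeros((N_PLASMA_STATES, N_PLASMA_STATES))
        if self.ka is not None:
            A[DEPOT, DEPOT] -= self.ka
            A[CENTRAL, DEPOT] += self.ka
        ke = self.cl_cen / self.v_cen
        A[CENTRAL, CENTRAL] -= ke
        A[ELIM, CENTRAL] += ke
        for q, v, idx in (
            (self.q_cen_per1, self.v_per1, PER1),
            (self.q_cen_per2, self.v_per2, PER2),
        ):
            if q > 0:
                A[CENTRAL, CENTRAL] -= q / self.v_cen
                A[idx, CENTRAL] += q / self.v_cen
                A[idx, idx] -= q / v
                A[CENTRAL, idx] += q / v
        return A


@dataclass(frozen=True)
class DoseEvent:
    """One dosing event: ``duration == 0`` means bolus."""

    amount_ng: float
    start: float = 0.0
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.amount_ng <= 0:
            raise ValueError("dose amount must be positive")
        if self.start < 0 or self.duration < 0:
            raise ValueError("start and duration must be non-negative")

    @property
    def rate(self) -> float:
        """Zero-order rate ng/min (0 for a bolus)."""
        return 0.0 if self.duration == 0 else self.amount_ng / self.duration


@dataclass(frozen=True)
class DoseRegimen:
    """A dosing regimen: route plus a list of events.

    IV events enter the central compartment; SC events enter the
    absorption depot (bioavailability fixed at ``f_bio``, default 1).
    """

    route: str
    events: Tuple[DoseEvent, ...]
    body_weight: float = 0.25
    f_bio: float = 1.0

    def __post_init__(self) -> None:
        if self.route not in ("IV", "SC"):
            raise ValueError(f"route must be IV or SC, got {self.route!r}")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")
        if not 0 < self.f_bio <= 1:
            raise ValueError("f_bio must be in (0, 1]")
        if len(self.events) == 0:
            raise ValueError("regimen must contain at least one dose event")
        object.__setattr__(self, "events", tuple(self.events))

    @classmethod
    def from_mg_per_kg(
        cls,
        route: str,
        doses: List[Tuple[float, float, float]],
        body_weight: float = 0.25,
        f_bio: float = 1.0,
    ) -> "DoseRegimen":
        """Build a regimen from (mg/kg, start min, duration min) triples."""
        events = tuple(
            DoseEvent(mgkg * body_weight * 1e6, start, dur) for mgkg, start, dur in doses
        )
        return cls(route, events, body_weight, f_bio)

    @property
    def target_state(self) -> int:
        return DEPOT if self.route == "SC" else CENTRAL

    def input_events(self) -> List[InputEvent]:
        return [
            InputEvent(self.target_state, ev.amount_ng * self.f_bio, ev.start, ev.duration)
            for ev in self.events
        ]

    @property
    def t_last(self) -> float:
        return max(ev.start + ev.duration for ev in self.events)


def infusion_rate(regimen: DoseRegimen, t: float) -> float:
    """Total zero-order input rate (ng/min) at time ``t``.

    Bolus events are state jumps, not rates, and do not contribute.
    Simultaneous infusions superpose.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    return sum(
        ev.rate
        for ev in regimen.events
        if ev.duration > 0 and ev.start <= t < ev.start + ev.duration
    )


def simulate_plasma(
    params: PlasmaPKParameters,
    regimen: DoseRegimen,
    grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Central (total) plasma concentration, ng/mL, on ``grid`` minutes.

    Solves the linear compartmental system in amounts with the regimen's
    piecewise-constant infusions and bolus jumps, then divides by v_cen.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0) or grid[0] < 0:
        raise ValueError("grid must be strictly increasing and start at or after 0")
    sol = integrate_linear_system(
        params.system_matrix(),
        regimen.input_events(),
        t_end=float(grid[-1]),
        rtol=rtol,
        atol=atol,
    )
    amounts = sol(grid)
    return amounts[CENTRAL] / params.v_cen


def css_constant_infusion(rate: float, cl_cen: float) -> float:
    """Steady-state concentration under constant infusion: rate / CL."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if cl_cen <= 0:
        raise ValueError("cl_cen must be positive")
    return rate / cl_cen
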