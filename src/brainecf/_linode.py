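"""Piecewise integration of linear compartmental systems.

dy/dt = A y + u(t), with u piecewise constant (zero-order infusions) and
instantaneous state jumps (bolus doses).  Integration restarts at every
input discontinuity so the stiff solver never steps across one, and each
segment keeps its dense output for evaluation at arbitrary times.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

__all__ = ["InputEvent", "PiecewiseLinearSolution", "integrate_linear_system"]


@dataclass(frozen=True)
class InputEvent:
    """Dose input into one state: zero-order over ``duration`` minutes,
    or an instantaneous jump when ``duration == 0``."""

    state_index: int
    amount: float  # ng
    start: float  # min
    duration: float  # min

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.start < 0 or self.duration < 0:
            raise ValueError("start and duration must be non-negative")


class PiecewiseLinearSolution:
    """Dense solution of a piecewise-forced linear system on [0, t_end]."""

    def __init__(self, breakpoints: Sequence[float], segments: list, y_at_breaks: np.ndarray):
        self._breaks = list(breakpoints)  # len = nseg + 1
        self._segments = segments  # dense OdeSolution per segment
        self._y_at_breaks = y_at_breaks  # state just after each breakpoint

    @property
    def t_end(self) -> float:
        return self._breaks[-1]

    def __call__(self, t) -> np.ndarray:
        """Evaluate the state at time(s) ``t`` -> array (nstate,) or (nstate, nt)."""
        t_arr = np.asarray(t, dtype=float)
        scalar = t_arr.ndim == 0
        tq = np.atleast_1d(t_arr)
        if tq.min() < 0 or tq.max() > self.t_end + 1e-9:
            raise ValueError(
                f"evaluation times must lie within the simulated horizon [0, {self.t_end}]"
            )
        nstate = self._y_at_breaks.shape[1]
        out = np.empty((nstate, tq.size))
        for k, tv in enumerate(tq):
            tv = min(tv, self.t_end)
            # right-continuous at breakpoints (bolus jumps take effect at t)
            i = bisect_right(self._breaks, tv) - 1
            i = min(i, len(self._segments) - 1)
            seg = self._segments[i]
            if seg is None:  # zero-length segment guard
                out[:, k] = self._y_at_breaks[i]
            else:
                out[:, k] = seg(tv)
        return out[:, 0] if scalar else out


def integrate_linear_system(
    A: np.ndarray,
    events: Sequence[InputEvent],
    t_end: float,
    y0: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_step: float = np.inf,
    method: str = "LSODA",
) -> PiecewiseLinearSolution:
    """Integrate dy/dt = A y + u(t) on [0, t_end] with dense output."""
    n = A.shape[0]
    y = np.zeros(n) if y0 is None else np.asarray(y0, dtype=float).copy()

    breaks = {0.0, float(t_end)}
    for ev in events:
        if ev.start < t_end:
            breaks.add(float(ev.start))
        end = ev.start + ev.duration
        if ev.duration > 0 and end < t_end:
            breaks.add(float(end))
    breakpoints = sorted(breaks)

    segments: List = []
    y_at_breaks = np.empty((len(breakpoints), n))
    jac = A  # constant Jacobian

    for i, t0 in enumerate(breakpoints[:-1]):
        t1 = breakpoints[i + 1]
        for ev in events:  # bolus jumps at segment start
            if ev.duration == 0 and ev.start == t0:
                y[ev.state_index] += ev.amount
        y_at_breaks[i] = y
        u = np.zeros(n)
        for ev in events:
            if ev.duration > 0 and ev.start <= t0 and t0 < ev.start + ev.duration:
                u[ev.state_index] += ev.amount / ev.duration

        def rhs(t, yy, A=A, u=u):
            return A @ yy + u

        sol = solve_ivp(
            rhs,
            (t0, t1),
            y,
            method=method,
            dense_output=True,
            rtol=rtol,
            atol=atol,
            max_step=max_step,
            jac=(lambda t, yy, jac=jac: jac) if method in ("BDF", "Radau", "LSODA") else None,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed on [{t0}, {t1}] (rtol={rtol}, atol={atol}): "
                f"{sol.message}"
            )
        if not np.all(np.isfinite(sol.y)):
            raise RuntimeError(
                f"non-finite state encountered on [{t0}, {t1}]; last state: {sol.y[:, -1]}"
            )
        segments.append(sol.sol)
        y = sol.y[:, -1].copy()

    # terminal bolus exactly at t_end (rare) and terminal state
    for ev in events:
        if ev.duration == 0 and ev.start == breakpoints[-1]:
            y[ev.state_index] += ev.amount
    y_at_breaks[-1] = y
    return PiecewiseLinearSolution(breakpoints, segments, y_at_breaks)


def delivered_dose(events: Sequence[InputEvent], t) -> np.ndarray:
    """Cumulative dose (ng) delivered by time(s) ``t`` across all events."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    total = np.zeros_like(t_arr)
    for ev in events:
        if ev.duration == 0:
            total += np.where(t_arr >= ev.start, ev.amount, 0.0)
        else:
            frac = np.clip((t_arr - ev.start) / ev.duration, 0.0, 1.0)
            total += ev.amount * frac
    return total if np.asarray(t).ndim else total[0]
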