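"""Lumped quasi-steady release model: access + channel diffusive resistances.

Because the pore-scale diffusion time (r^2/D, sub-microsecond for
nanometre pores) is far below the 0.1 ms sampling interval, transport
through the pore is quasi-steady at every sample: the molar flow is the
well-mixed lumen concentration divided by a series diffusive resistance

    R_diff(r) = 1/(4 D_in r) + L/(pi r^2 D_out) + 1/(4 D_out r)

(lumen-side disk access, cylindrical channel, outer-side disk access).
This reduced model serves two roles: a fast forward backend for the
sequential inverse, and an independent oracle for the full PDE solver —
for a static pore the lumen content decays as a single exponential with
time constant ``tau = V_ves * R_diff``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .geometry import PoreTrajectory, VesicleGeometry
from .model import CurrentTrace, TransportParams

__all__ = [
    "diffusive_resistance",
    "quasi_steady_current",
    "QuasiSteadyState",
    "QuasiSteadyStepper",
    "radius_from_flow",
]


def diffusive_resistance(r, pore_length: float, transport: TransportParams):
    """Series diffusive resistance (s/m^3) of a pore of radius ``r``.

    Returns ``inf`` at r = 0 (closed pore carries no flow).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("pore radius must be non-negative")
    with np.errstate(divide="ignore"):
        acc_in = 1.0 / (4.0 * transport.d_in * r)
        channel = pore_length / (np.pi * transport.d_out * r ** 2)
        acc_out = 1.0 / (4.0 * transport.d_out * r)
        total = acc_in + channel + acc_out
    out = np.where(r > 0, total, np.inf)
    return float(out) if out.ndim == 0 else out


@dataclass
class QuasiSteadyState:
    """Mutable lumped state: remaining lumen moles and clock."""

    moles: float
    time: float

    def copy(self) -> "QuasiSteadyState":
        return QuasiSteadyState(self.moles, self.time)


class QuasiSteadyStepper:
    """Advances the lumped mass balance dN/dt = -(N/V) / R_diff(r(t)).

    Each substep holds the radius at its midpoint value and applies the
    exact exponential decay factor ``exp(-dt / (V R_diff))``, which is
    unconditionally stable and exact for a static pore.
    """

    def __init__(self, geometry: VesicleGeometry,
                 transport: TransportParams, c0: float) -> None:
        self.geometry = geometry
        self.transport = transport
        self.volume = geometry.lumen_volume()
        self.c0 = c0
        self.initial_moles = c0 * self.volume

    def initial_state(self) -> QuasiSteadyState:
        return QuasiSteadyState(self.initial_moles, 0.0)

    def molar_flow(self, state: QuasiSteadyState, r: float) -> float:
        """Outward molar flow N/V / R_diff at pore radius ``r`` (mol/s)."""
        if r <= 0:
            return 0.0
        rd = diffusive_resistance(r, self.geometry.pore_length, self.transport)
        return state.moles / self.volume / rd

    def current(self, state: QuasiSteadyState, r: float) -> float:
        return self.transport.nF * self.molar_flow(state, r)

    def advance(self, state: QuasiSteadyState, r_start: float, r_end: float,
                duration: float, n_sub: int = 10) -> float:
        """Advance ``state`` in place over ``duration`` with the pore radius
        ramping linearly from ``r_start`` to ``r_end``; returns the current
        at the end of the interval."""
        if duration <= 0:
            raise ValueError("duration must be positive")
        dt = duration / n_sub
        tau_inv = np.empty(n_sub)
        mids = r_start + (r_end - r_start) * (np.arange(n_sub) + 0.5) / n_sub
        rd = diffusive_resistance(mids, self.geometry.pore_length, self.transport)
        with np.errstate(divide="ignore"):
            tau_inv = 1.0 / (self.volume * rd)
        state.moles *= float(np.exp(-dt * np.sum(tau_inv)))
        state.time += duration
        return self.current(state, r_end)


def quasi_steady_current(geometry: VesicleGeometry, transport: TransportParams,
                         c0: float, traj: PoreTrajectory, t_end: float,
                         sample_dt: float = 1.0e-4,
                         n_sub: int = 10) -> CurrentTrace:
    """Current trace of the lumped model for a prescribed pore trajectory.

    Samples every ``sample_dt`` on [0, t_end] with ``n_sub`` exponential
    substeps per sample.
    """
    traj.validate_against(geometry)
    if t_end > traj.t_end * (1 + 1e-9):
        raise ValueError("trajectory does not span [0, t_end]")
    stepper = QuasiSteadyStepper(geometry, transport, c0)
    state = stepper.initial_state()
    times = np.arange(0.0, t_end + 0.5 * sample_dt, sample_dt)
    currents = np.empty_like(times)
    currents[0] = stepper.current(state, float(traj(0.0)))
    for k in range(1, times.size):
        sub_edges = np.linspace(times[k - 1], times[k], n_sub + 1)
        mids = 0.5 * (sub_edges[:-1] + sub_edges[1:])
        rd = diffusive_resistance(traj(mids), geometry.pore_length, transport)
        with np.errstate(divide="ignore"):
            decay = np.exp(-np.sum((sub_edges[1] - sub_edges[0]) /
                                   (stepper.volume * rd)))
        state.moles *= float(decay)
        state.time = times[k]
        currents[k] = stepper.current(state, float(traj(times[k])))
    return CurrentTrace(times, currents, metadata={"backend": "quasi-steady"})


def radius_from_flow(required_resistance: float, pore_length: float,
                     transport: TransportParams, r_max: float) -> float:
    """Invert ``R_diff(r) = required_resistance`` for ``r`` on (0, r_max].

    ``R_diff`` is strictly decreasing, so the root is unique; returns
    ``r_max`` if even the fully open pore cannot supply the flow (caller
    should flag the sample as clipped).
    """
    if not np.isfinite(required_resistance) or required_resistance <= 0:
        raise ValueError("required resistance must be positive and finite")
    if diffusive_resistance(r_max, pore_length, transport) >= required_resistance:
        return r_max
    r_lo = 1e-15
    while diffusive_resistance(r_lo, pore_length, transport) < required_resistance:
        r_lo *= 0.5  # pragma: no cover - required_resistance finite
    f = lambda r: diffusive_resistance(r, pore_length, transport) - required_resistance
    return float(brentq(f, r_lo, r_max, xtol=1e-15, rtol=1e-12))
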