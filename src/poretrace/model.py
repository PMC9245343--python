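"""Transport parameters and current-trace containers for the release model.

The physical picture: a vesicle lumen initially holds catecholamine at
concentration ``C_0`` fixed by the spike charge ``Q`` through Faraday's
law (n electrons per molecule); content diffuses through the open pore,
across the electrode gap, and is oxidized at the electrode held at a
diffusion-limited potential, producing the measured current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FARADAY",
    "TransportParams",
    "SimulationConfig",
    "CurrentTrace",
    "initial_concentration",
    "released_charge",
]

FARADAY = 96485.0  # C/mol


@dataclass(frozen=True)
class TransportParams:
    """Diffusion and electrochemistry constants.

    ``d_in`` applies inside the lumen (crowded vesicular matrix slows
    diffusion roughly tenfold), ``d_out`` in the pore channel and the
    external solution.  ``n_electrons`` is 2 for catecholamine oxidation.
    """

    d_in: float = 6.0e-11   # m^2/s
    d_out: float = 6.0e-10  # m^2/s
    n_electrons: int = 2
    faraday: float = FARADAY

    def __post_init__(self) -> None:
        if self.d_in <= 0 or self.d_out <= 0:
            raise ValueError("diffusion coefficients must be positive")
        if self.n_electrons < 1:
            raise ValueError("n_electrons must be >= 1")

    @property
    def nF(self) -> float:
        return self.n_electrons * self.faraday


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical knobs of the axisymmetric finite-volume solver.

    The radial and near-aperture axial grids grow geometrically away
    from the pore axis so the local cell size stays a fixed fraction of
    the radius; ``axis_cell`` is the first cell width at the axis and
    ``growth`` the geometric ratio (growth - 1 ~ local relative
    resolution).  ``dt`` is the backward-Euler step.
    """

    axis_cell: float = 2.5e-10      # m, first radial cell width
    growth: float = 1.1             # geometric grid ratio, > 1
    dt: float = 1.0e-5              # s, = sampling interval / 10
    n_gap_cells: int = 4
    n_membrane_cells: int = 5
    max_lumen_cell_fraction: float = 1 / 8.0  # cap cell size at R_ves/8
    gap_override: float | None = None  # for gap-distance sensitivity sweeps

    def __post_init__(self) -> None:
        if self.axis_cell <= 0 or self.dt <= 0:
            raise ValueError("axis_cell and dt must be positive")
        if self.growth <= 1:
            raise ValueError("growth must exceed 1")
        if self.n_gap_cells < 1 or self.n_membrane_cells < 1:
            raise ValueError("cell counts must be >= 1")

    def refined(self, factor: float = 2.0) -> "SimulationConfig":
        """Config with grid and time step refined by ``factor``."""
        return SimulationConfig(
            axis_cell=self.axis_cell / factor,
            growth=self.growth ** (1.0 / factor),
            dt=self.dt / factor,
            n_gap_cells=int(round(self.n_gap_cells * factor)),
            n_membrane_cells=int(round(self.n_membrane_cells * factor)),
            max_lumen_cell_fraction=self.max_lumen_cell_fraction / factor,
            gap_override=self.gap_override,
        )


@dataclass(frozen=True)
class CurrentTrace:
    """Faradaic current sampled on a uniform or explicit time base."""

    times: np.ndarray
    currents: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.currents, dtype=float)
        if t.shape != i.shape or t.ndim != 1:
            raise ValueError("times and currents must be 1-D and the same length")
        if np.any(i < -1e-30):
            raise ValueError("simulated currents must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "currents", i)

    @property
    def peak(self) -> float:
        return float(self.currents.max(initial=0.0))


def initial_concentration(Q: float, R_ves: float,
                          transport: TransportParams = TransportParams()) -> float:
    """Initial lumen concentration ``C_0 = Q / (n F (4/3) pi R_ves^3)``.

    ``Q`` is the total spike charge in C; the whole vesicular content is
    assumed oxidized (n electrons per molecule), so ``Q/(nF)`` moles were
    initially dissolved in the lumen volume.
    """
    if R_ves <= 0:
        raise ValueError("vesicle radius must be positive")
    if Q < 0:
        raise ValueError("charge must be non-negative")
    volume = 4.0 / 3.0 * math.pi * R_ves ** 3
    return Q / (transport.nF * volume)


def released_charge(trace: CurrentTrace) -> float:
    """Total charge of a trace by trapezoidal integration of I(t)."""
    if trace.times.size == 0:
        raise ValueError("empty trace")
    return float(np.trapezoid(trace.currents, trace.times))
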