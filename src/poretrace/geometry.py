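"""Geometric model of a vesicle adsorbed on a microdisk electrode.

A spherical vesicle of radius ``R_ves`` sits above a disk electrode.
Membrane proteins hold the vesicle membrane a small distance (the *gap*)
off the electrode surface; electroporation opens a circular pore of
time-dependent radius ``R_p(t)`` through the membrane (the *pore length*
equals the membrane thickness).  All quantities are SI (m, s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VesicleGeometry",
    "PoreTrajectory",
    "pore_radius_at",
    "spherical_cap_fraction",
    "angular_aperture_deg",
]

#: Largest allowed pore radius as a fraction of the vesicle radius.  The
#: inverse search is bounded at 0.8*R_ves; beyond that the spherical-pore
#: picture breaks down entirely.
MAX_PORE_FRACTION = 0.8


@dataclass(frozen=True)
class VesicleGeometry:
    """Fixed geometry of one vesicle-on-electrode configuration.

    Parameters
    ----------
    vesicle_radius : float
        Lumen radius ``R_ves`` in m (from resistive-pulse sizing).
    pore_length : float
        Membrane thickness / pore channel length in m (default 5 nm).
    gap : float
        Distance from the pore bottom to the electrode surface in m
        (default 20 nm), the space held open by membrane proteins.
    electrode_radius : float
        Radius of the absorbing disk electrode in m (default 2.5 um,
        i.e. a 5 um diameter microdisk).
    outer_domain_radius, outer_domain_height : float
        Extent of the closed simulation domain.  Defaults: the electrode
        radius, and 2 um.
    """

    vesicle_radius: float
    pore_length: float = 5e-9
    gap: float = 20e-9
    electrode_radius: float = 2.5e-6
    outer_domain_radius: float = field(default=0.0)
    outer_domain_height: float = field(default=2e-6)

    def __post_init__(self) -> None:
        if self.outer_domain_radius == 0.0:
            object.__setattr__(self, "outer_domain_radius", self.electrode_radius)
        for name in ("vesicle_radius", "pore_length", "gap",
                     "electrode_radius", "outer_domain_radius",
                     "outer_domain_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        # electrode must fully cover the projected pore footprint
        if self.electrode_radius < MAX_PORE_FRACTION * self.vesicle_radius:
            raise ValueError("electrode does not cover the maximum pore footprint")
        top = self.gap + self.pore_length + 2 * self.vesicle_radius
        if self.outer_domain_height < top:
            raise ValueError(
                "outer_domain_height must enclose the vesicle "
                f"(needs >= {top:.3e} m)"
            )

    @property
    def sphere_center_z(self) -> float:
        """Height of the lumen center above the electrode plane."""
        return self.gap + self.pore_length + self.vesicle_radius

    @property
    def max_pore_radius(self) -> float:
        return MAX_PORE_FRACTION * self.vesicle_radius

    def lumen_volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.vesicle_radius ** 3


@dataclass(frozen=True)
class PoreTrajectory:
    """Piecewise-linear pore radius versus time.

    ``times`` must be strictly increasing and start at 0; evaluation
    between knots is exact linear interpolation.  This is the object the
    inverse algorithm estimates, one knot per sampling interval.
    """

    times: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.radii, dtype=float)
        if t.ndim != 1 or t.shape != r.shape:
            raise ValueError("times and radii must be 1-D and the same length")
        if t.size == 0:
            raise ValueError("trajectory needs at least one knot")
        if t[0] != 0.0:
            raise ValueError("trajectory must start at t = 0")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("knot times must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("pore radii must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "radii", r)

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    @property
    def max_radius(self) -> float:
        return float(self.radii.max())

    def __call__(self, t):
        return pore_radius_at(self, t)

    def validate_against(self, geometry: VesicleGeometry) -> None:
        """Raise if any knot exceeds the 0.8*R_ves pore-radius bound."""
        bound = geometry.max_pore_radius
        if np.any(self.radii > bound * (1 + 1e-12)):
            raise ValueError(
                f"pore radius exceeds {MAX_PORE_FRACTION} * R_ves = {bound:.3e} m"
            )


def pore_radius_at(traj: PoreTrajectory, t):
    """Pore radius at time(s) ``t`` by linear interpolation between knots.

    Raises ``ValueError`` for times outside ``[0, traj.t_end]``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > traj.t_end * (1 + 1e-12)):
        raise ValueError(f"time outside trajectory domain [0, {traj.t_end:g}]")
    out = np.interp(t_arr, traj.times, traj.radii)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def spherical_cap_fraction(ratio):
    """Volume of the spherical cap below the pore chord, as a fraction of
    the whole sphere.

    The cap is cut at chord radius ``ratio * R``: with ``sin(theta) =
    ratio`` the cap height is ``h = R (1 - cos(theta))`` and ``V_cap =
    (pi/3) h^2 (3R - h)``.  This bounds the lumen volume lost when the
    vesicle bottom merges into the gap during pore opening; for pore/
    vesicle ratios below ~1/3 the loss stays under 0.8 %, which is why a
    fixed spherical lumen is an adequate simulation geometry.
    """
    x = np.asarray(ratio, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("ratio must lie in [0, 1]")
    cos_t = np.sqrt(1.0 - x ** 2)
    h = 1.0 - cos_t  # in units of R
    frac = (h ** 2 * (3.0 - h)) / 4.0  # (pi/3) h^2 (3R-h) / ((4/3) pi R^3)
    return float(frac) if np.isscalar(ratio) else frac


def angular_aperture_deg(ratio):
    """Half-angle (degrees) subtended at the vesicle center by the pore rim.

    ``arcsin(ratio)``; a pore/vesicle radius ratio of 1/3 corresponds to
    an aperture just under 19.5 degrees.
    """
    x = np.asarray(ratio, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("ratio must lie in [0, 1]")
    out = np.degrees(np.arcsin(x))
    return float(out) if np.isscalar(ratio) else out
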