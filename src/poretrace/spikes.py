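"""Amperometric spike handling: baseline correction and feature extraction.

A spike is one excised, baseline-subtracted current transient from a
single vesicle release event, uniformly sampled (0.1 ms in the standard
acquisition).  Features follow the conventions of single-vesicle
amperometry: peak current ``I_max`` and its time ``t_max``, charge ``Q``
(trapezoid), the 5-95 % rise time ``t_rise``, and a single-exponential
fit of the decay whose quality classifies the vesicle as non-dense-core
(the population the pore-reconstruction model applies to; dense-core
vesicles release in two phases and decay multi-exponentially).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import PoreTrajectory

__all__ = [
    "Spike",
    "SpikeFeatures",
    "baseline_subtract",
    "spike_features",
    "classify_decay",
    "pore_features",
]

_JITTER = 1e-9  # s, allowed sampling nonuniformity


@dataclass(frozen=True)
class Spike:
    """Baseline-subtracted, uniformly sampled current transient."""

    times: np.ndarray      # s
    currents: np.ndarray   # A
    baseline_sd: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.currents, dtype=float)
        if t.ndim != 1 or t.shape != i.shape:
            raise ValueError("times and currents must be 1-D and equal length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(i))):
            raise ValueError("spike contains non-finite values")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(np.abs(dt - dt[0]) > _JITTER):
                raise ValueError("spike sampling is not uniform")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "currents", i)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0

    @property
    def n(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class SpikeFeatures:
    i_max: float          # A
    t_max: float          # s
    q: float              # C
    t_rise: float         # s (nan if undefined)
    tau: float = float("nan")    # s, single-exponential decay constant
    r_squared: float = float("nan")
    nondense_core: bool | None = None


def baseline_subtract(times, currents, pre_window: tuple[float, float],
                      metadata: dict | None = None) -> Spike:
    """Subtract the mean current of ``pre_window`` (a (t0, t1) span that
    precedes the spike onset) and record the window SD as the noise level."""
    t = np.asarray(times, dtype=float)
    i = np.asarray(currents, dtype=float)
    t0, t1 = pre_window
    sel = (t >= t0) & (t <= t1)
    if not np.any(sel):
        raise ValueError("baseline pre-window selects no samples")
    base = float(np.mean(i[sel]))
    sd = float(np.std(i[sel], ddof=1)) if sel.sum() > 1 else 0.0
    return Spike(t, i - base, baseline_sd=sd, metadata=metadata or {})


def _upward_crossings(t: np.ndarray, y: np.ndarray, level: float) -> np.ndarray:
    """Times of upward crossings of ``level``, linearly interpolated."""
    below = y[:-1] < level
    above = y[1:] >= level
    k = np.where(below & above)[0]
    frac = (level - y[k]) / (y[k + 1] - y[k])
    return t[k] + frac * (t[k + 1] - t[k])


def rise_time(t: np.ndarray, y: np.ndarray, lo: float = 0.05,
              hi: float = 0.95, guarded: bool = True) -> float:
    """5-95 % rise time of a peaked signal, crossings by linear interpolation.

    ``guarded`` uses the *last* low-level upward crossing before the
    *first* high-level crossing, so noise re-crossings near baseline do
    not stretch the rise; ungated mode takes the first crossing of each
    level (used for pore trajectories, which are noise-free model
    output).  Returns nan if either crossing is missing.
    """
    peak = float(np.max(y))
    if peak <= 0:
        return float("nan")
    t_hi = _upward_crossings(t, y, hi * peak)
    if t_hi.size == 0:
        return float("nan")
    first_hi = t_hi[0]
    t_lo = _upward_crossings(t, y, lo * peak)
    t_lo = t_lo[t_lo <= first_hi]
    if t_lo.size == 0:
        # signal may start above the low threshold
        if y[0] >= lo * peak:
            t_lo = np.array([t[0]])
        else:
            return float("nan")
    low = t_lo[-1] if guarded else t_lo[0]
    return float(first_hi - low)


def spike_features(spike: Spike) -> SpikeFeatures:
    """Peak, charge and 5-95 % rise time of a spike.

    Requires a clear peak (``I_max`` above five baseline SDs when a
    noise estimate is available).
    """
    i = spike.currents
    if i.size < 3:
        raise ValueError("spike too short for feature extraction")
    k = int(np.argmax(i))
    i_max = float(i[k])
    if spike.baseline_sd > 0 and i_max < 5 * spike.baseline_sd:
        raise ValueError("no spike: maximum below 5 x baseline SD")
    q = float(np.trapezoid(np.maximum(i, 0.0), spike.times))
    tr = rise_time(spike.times, i, guarded=True)
    return SpikeFeatures(i_max=i_max, t_max=float(spike.times[k]), q=q,
                         t_rise=tr)


def classify_decay(spike: Spike, r2_threshold: float = 0.95):
    """Fit the falling phase to ``I_max exp(-(t - t_max)/tau)``.

    The fit is ordinary least squares in log space on the samples from
    the peak down to the first sample below 5 % of the peak; the
    goodness of fit ``r_squared`` is evaluated on the currents
    themselves (variance of I explained by the fitted exponential), so
    an early fast component missed by a single exponential is
    penalized.  Returns ``(tau, r_squared, nondense_core)``; a decay
    well described by a single exponential marks a non-dense-core
    vesicle.
    """
    i = spike.currents
    k = int(np.argmax(i))
    i_max = i[k]
    tail = i[k:]
    below = np.where(tail < 0.05 * i_max)[0]
    stop = k + (below[0] if below.size else tail.size)
    t_fall = spike.times[k:stop + 1] if stop < spike.n else spike.times[k:]
    y_fall = i[k:stop + 1] if stop < spike.n else i[k:]
    if t_fall.size < 5:
        raise ValueError("falling portion has fewer than 5 samples")
    pos = y_fall > 0
    if pos.sum() < max(5, 0.5 * y_fall.size):
        return float("nan"), float("nan"), None
    x = t_fall[pos] - spike.times[k]
    ly = np.log(y_fall[pos])
    slope, intercept = np.polyfit(x, ly, 1)
    if slope >= 0:
        return float("nan"), 0.0, False
    tau = -1.0 / slope
    y = y_fall[pos]
    resid = y - np.exp(slope * x + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    r2 = min(max(r2, 0.0), 1.0)
    return float(tau), r2, bool(r2 >= r2_threshold)


def pore_features(traj: PoreTrajectory) -> tuple[float, float]:
    """Maximum pore radius and 5-95 % expansion time of a trajectory.

    ``t_expa`` is the time between the first crossings of 5 % and 95 %
    of the maximum radius (linear interpolation between knots); zero for
    a constant trajectory.
    """
    r = traj.radii
    r_max = float(r.max())
    if r_max <= 0:
        raise ValueError("trajectory has no positive radii")
    if np.all(r == r_max):
        return r_max, 0.0
    t = traj.times
    t05 = _upward_crossings(t, r, 0.05 * r_max)
    t95 = _upward_crossings(t, r, 0.95 * r_max)
    if t05.size == 0 and r[0] >= 0.05 * r_max:
        t05 = np.array([t[0]])
    if t05.size == 0 or t95.size == 0:
        return r_max, float("nan")
    return r_max, float(t95[0] - t05[0])
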