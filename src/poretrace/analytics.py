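"""Population-level analyses of pore-opening features.

Covers the membrane-section model of maximum pore area, the log-log
scaling of maximum pore radius against vesicle radius, and the
nonparametric group comparison of expansion times.

The membrane-section model: membrane proteins partition the
vesicle-electrode contact area ``S_c = k_d * S_ves`` (``k_d`` the
deformation coefficient, ``S_ves = 4 pi R_ves^2``) into ``n_s`` small
sections of mean area ``A_s``; each section electroporates irreversibly
with probability ``p_e``, and the open sections coalesce into the final
pore, so

    S_p,max = n_e * A_s = p_e * n_s * A_s = p_e * k_d * S_ves

which with ``S_p,max = pi R_p,max^2`` gives
``R_p,max = 2 R_ves sqrt(p_e k_d)`` — a slope-1 law in log-log
coordinates when ``p_e k_d`` is constant across vesicles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SectionModelParams",
    "VesiclePopulationRecord",
    "section_model_pore_radius",
    "loglog_scaling_fit",
    "ratio_vs_size",
    "mann_whitney_u",
]


@dataclass(frozen=True)
class SectionModelParams:
    """Parameters of the membrane-section pore-area model."""

    p_e: float            # irreversible electroporation probability per section
    k_d: float            # deformation coefficient (contact/total area)
    mean_section_area: float = float("nan")  # m^2, not separately estimable

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_e <= 1.0:
            raise ValueError("p_e must lie in [0, 1]")
        if not 0.0 < self.k_d <= 1.0:
            raise ValueError("k_d must lie in (0, 1]")

    def contact_area(self, R_ves: float) -> float:
        return self.k_d * 4.0 * math.pi * R_ves ** 2

    def max_pore_area(self, R_ves: float) -> float:
        return self.p_e * self.contact_area(R_ves)


@dataclass(frozen=True)
class VesiclePopulationRecord:
    """One vesicle's size and pore-dynamics features."""

    r_ves: float     # m
    r_p_max: float   # m
    t_expa: float    # s
    t_rise: float    # s
    group: str       # "vesicle" | "liposome"

    def __post_init__(self) -> None:
        if self.r_p_max >= self.r_ves:
            raise ValueError("maximum pore radius must be below the vesicle radius")


def section_model_pore_radius(R_ves: float, p_e: float, k_d: float) -> float:
    """Maximum pore radius predicted by the membrane-section model.

    From ``pi R_p,max^2 = p_e k_d 4 pi R_ves^2``:
    ``R_p,max = 2 R_ves sqrt(p_e k_d)``.  Requires ``p_e k_d <= 0.25``
    (otherwise the pore would exceed the vesicle radius).
    """
    params = SectionModelParams(p_e=p_e, k_d=k_d)
    if p_e * k_d > 0.25:
        raise ValueError("p_e * k_d > 0.25 implies R_p,max > R_ves")
    if R_ves <= 0:
        raise ValueError("R_ves must be positive")
    return 2.0 * R_ves * math.sqrt(params.p_e * params.k_d)


def _as_arrays(records):
    if isinstance(records, pd.DataFrame):
        return records["rves_m"].to_numpy(float), records["rpmax_m"].to_numpy(float)
    rv = np.array([r.r_ves for r in records], dtype=float)
    rp = np.array([r.r_p_max for r in records], dtype=float)
    return rv, rp


def loglog_scaling_fit(records) -> tuple[float, float, float]:
    """OLS fit of ``log10 R_p,max`` on ``log10 R_ves``.

    Accepts a DataFrame with columns ``rves_m``/``rpmax_m`` or a
    sequence of :class:`VesiclePopulationRecord`.  Returns ``(slope,
    intercept, pearson_r)`` of the log-log pairs (radii in m, so the
    intercept is in log10-m units).
    """
    rv, rp = _as_arrays(records)
    if rv.size < 2:
        raise ValueError("need at least 2 records")
    if np.any(rv <= 0) or np.any(rp <= 0):
        raise ValueError("radii must be positive")
    x, y = np.log10(rv), np.log10(rp)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in R_ves: slope undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


def ratio_vs_size(records):
    """Pairs ``(R_ves, R_p,max / R_ves)`` — relative pore size vs size."""
    rv, rp = _as_arrays(records)
    if rv.size == 0:
        return np.empty((0, 2))
    if np.any(rv <= 0):
        raise ValueError("vesicle radii must be positive")
    return np.column_stack([rv, rp / rv])


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of the first sample: #(a > b) + 0.5 #(a == b) over all pairs."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def _exact_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-tailed exact p by enumeration of all group assignments."""
    pooled = np.concatenate([a, b])
    n_a = a.size
    idx = np.arange(pooled.size)
    count_le = count_ge = total = 0
    for comb in itertools.combinations(idx, n_a):
        sel = np.zeros(pooled.size, dtype=bool)
        sel[list(comb)] = True
        u = _u_statistic(pooled[sel], pooled[~sel])
        total += 1
        if u <= u_obs + 1e-12:
            count_le += 1
        if u >= u_obs - 1e-12:
            count_ge += 1
    return min(1.0, 2.0 * min(count_le, count_ge) / total)


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    Exact p by complete enumeration when both groups have at most 8
    observations (correct with ties); otherwise the tie-corrected normal
    approximation with continuity correction (scipy).  Returns ``(U,
    p)`` with U the statistic of ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = _u_statistic(a, b)
    if max(a.size, b.size) <= 8:
        return u_obs, _exact_p(a, b, u_obs)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic")
    return float(res.statistic), float(res.pvalue)
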