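"""Radiobiological outcome modelling: DVH, TCP, NTCP, UTCP and the
irradiation time that maximises UTCP.

TCP uses the Poisson / linear-quadratic form for an inhomogeneous dose
distribution,

    TCP = exp( - sum_i  rho * v_i * exp(-alpha*D_i - beta*D_i^2) ),

with voxel doses D_i in Gy-Eq, voxel volumes v_i and clonogen density rho.
NTCP is the standard logistic dose-response

    NTCP(D) = 1 / (1 + exp(4*gamma50*(1 - D/D50)))

evaluated at the dose of the healthy-tissue limiting point.  UTCP is the
uncomplicated tumor control probability TCP*(1-NTCP); treatment time is
chosen to maximise it, with dose assumed linear in time (constant dose
rates over the irradiation).

Default parameters are representative head-and-neck values (see the
package methods note); the published clinical parameterisations can be
supplied through :class:`TCPParams` / :class:`NTCPParams` when available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TCPParams:
    """Linear-quadratic radiosensitivity and clonogen density."""

    alpha: float = 0.35  # Gy^-1
    beta: float = 0.035  # Gy^-2
    clonogen_density: float = 1.0e7  # cells / cm^3

    def __post_init__(self) -> None:
        if self.alpha <= 0.0 or self.beta < 0.0 or self.clonogen_density <= 0.0:
            raise ValueError("need alpha > 0, beta >= 0, density > 0")


@dataclass(frozen=True)
class NTCPParams:
    """Logistic dose-response for the normal-tissue endpoint
    (severe mucositis, grade >= 3)."""

    d50: float = 7.0  # Gy-Eq at 50% complication probability
    gamma50: float = 2.0  # normalised slope at D50

    def __post_init__(self) -> None:
        if self.d50 <= 0.0 or self.gamma50 <= 0.0:
            raise ValueError("need D50 > 0 and gamma50 > 0")


@dataclass
class DVH:
    """Cumulative dose-volume histogram.

    ``cum_fraction[k]`` is the fraction of the structure's volume receiving
    at least ``edges[k]``; it is 1 at zero dose and non-increasing.
    """

    edges: np.ndarray
    cum_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.cum_fraction = np.asarray(self.cum_fraction, dtype=float)
        if self.edges.shape != self.cum_fraction.shape:
            raise ValueError("edges and fractions must align")
        if np.any(np.diff(self.cum_fraction) > 1e-12):
            raise ValueError("cumulative volume fraction must be non-increasing")

    def to_csv(self, path) -> None:
        pd.DataFrame({"dose_gy_eq": self.edges, "volume_fraction": self.cum_fraction}).to_csv(
            path, index=False
        )


def compute_dvh(doses: np.ndarray, mask: np.ndarray | None = None, n_bins: int = 100) -> DVH:
    """Cumulative DVH of a (masked) voxel dose field, equal voxel volumes.

    Thresholds run from 0 to the maximum dose; the fraction at each
    threshold is the share of voxels with dose >= threshold.
    """
    doses = np.asarray(doses, dtype=float)
    if mask is not None:
        doses = doses[np.asarray(mask, dtype=bool)]
    doses = doses.ravel()
    if doses.size == 0:
        raise ValueError("empty voxel selection")
    top = float(doses.max())
    edges = np.linspace(0.0, top if top > 0.0 else 1.0, n_bins + 1)
    sorted_doses = np.sort(doses)
    # voxels with dose >= edge, via binary search on the sorted doses
    n_below = np.searchsorted(sorted_doses, edges, side="left")
    fraction = (doses.size - n_below) / doses.size
    fraction[0] = 1.0  # doses are nonnegative
    return DVH(edges=edges, cum_fraction=fraction)


def tcp(doses_gy_eq, params: TCPParams, voxel_volume_cm3: float) -> float:
    """Poisson/LQ tumor control probability for voxelised doses.

    Invariant under voxel subdivision and monotone non-decreasing in every
    voxel dose.
    """
    d = np.asarray(doses_gy_eq, dtype=float)
    if np.any(d < 0.0):
        raise ValueError("doses must be nonnegative")
    survivors = params.clonogen_density * voxel_volume_cm3 * np.exp(
        -params.alpha * d - params.beta * d * d
    )
    return float(np.exp(-survivors.sum()))


def ntcp(dose_gy_eq: float, params: NTCPParams) -> float:
    """Logistic complication probability at the limiting-point dose."""
    if dose_gy_eq < 0.0:
        raise ValueError("dose must be nonnegative")
    return 1.0 / (1.0 + math.exp(4.0 * params.gamma50 * (1.0 - dose_gy_eq / params.d50)))


def utcp(tcp_value: float, ntcp_value: float) -> float:
    """Uncomplicated tumor control probability TCP * (1 - NTCP)."""
    if not (0.0 <= tcp_value <= 1.0 and 0.0 <= ntcp_value <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    return tcp_value * (1.0 - ntcp_value)


def time_for_dose_limit(rate_gy_eq_per_min: float, limit_gy_eq: float) -> float:
    """Minutes until the limiting point reaches ``limit_gy_eq`` at constant rate."""
    if rate_gy_eq_per_min <= 0.0:
        raise ZeroDivisionError("dose rate at the limiting point must be positive")
    return limit_gy_eq / rate_gy_eq_per_min


@dataclass
class OutcomeResult:
    """Outcome of the UTCP maximisation over irradiation time."""

    t_irr_min: float
    tcp: float
    ntcp: float
    utcp: float
    d_max_healthy_gy_eq: float = 0.0
    component_percentages: tuple[float, float, float, float] | None = None
    flat_tcp_warning: bool = False
    beam: str = "beam"

    def __post_init__(self) -> None:
        for p in (self.tcp, self.ntcp, self.utcp):
            if not (0.0 <= p <= 1.0 + 1e-12):
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.utcp - self.tcp * (1.0 - self.ntcp)) > 1e-9:
            raise ValueError("UTCP must equal TCP*(1-NTCP)")


_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_section_max(f: Callable[[float], float], lo: float, hi: float, tol: float = 1e-4) -> float:
    """Argmax of a unimodal function on [lo, hi]; ties resolve to smaller t."""
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:  # keep the left interval on ties
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    return a if f(a) >= f(b) else b


def maximize_utcp(
    tcp_of_t: Callable[[float], float],
    ntcp_of_t: Callable[[float], float],
    t_grid: np.ndarray,
    refine: bool = True,
) -> tuple[float, float, float, float]:
    """Maximise UTCP(t) = TCP(t)*(1-NTCP(t)) over a time grid.

    Exhaustive search over ``t_grid`` (ties broken toward smaller t via the
    first maximum), optionally followed by golden-section refinement within
    one grid step of the best grid point.  Returns ``(t, tcp, ntcp, utcp)``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("empty time grid")
    u = np.array([utcp(tcp_of_t(t), ntcp_of_t(t)) for t in t_grid])
    k = int(np.argmax(u))  # first occurrence: smallest t on ties
    t_best, u_best = float(t_grid[k]), float(u[k])
    if refine and t_grid.size > 1:
        lo = float(t_grid[max(k - 1, 0)])
        hi = float(t_grid[min(k + 1, t_grid.size - 1)])
        t_ref = _golden_section_max(lambda t: utcp(tcp_of_t(t), ntcp_of_t(t)), lo, hi)
        u_ref = utcp(tcp_of_t(t_ref), ntcp_of_t(t_ref))
        if u_ref > u_best + 1e-12 or (abs(u_ref - u_best) <= 1e-12 and t_ref < t_best):
            t_best, u_best = t_ref, u_ref
    return t_best, tcp_of_t(t_best), ntcp_of_t(t_best), u_best


def optimize_time(
    tumor_rates_gy_eq_min: np.ndarray,
    healthy_rate_gy_eq_min: float,
    tcp_params: TCPParams,
    ntcp_params: NTCPParams,
    voxel_volume_cm3: float,
    t_max_min: float = 120.0,
    t_step_min: float = 0.5,
    refine: bool = True,
) -> OutcomeResult:
    """Irradiation time maximising UTCP for constant dose rates.

    The tumor voxel doses and the healthy limiting-point dose both scale
    linearly with time.  If the tumor dose rate vanishes everywhere, TCP is
    flat at exp(-N) and the result carries a warning flag.
    """
    rates = np.asarray(tumor_rates_gy_eq_min, dtype=float).ravel()
    if np.any(rates < 0.0) or healthy_rate_gy_eq_min < 0.0:
        raise ValueError("dose rates must be nonnegative")
    flat = not np.any(rates > 0.0)

    def tcp_of_t(t: float) -> float:
        return tcp(rates * t, tcp_params, voxel_volume_cm3)

    def ntcp_of_t(t: float) -> float:
        return ntcp(healthy_rate_gy_eq_min * t, ntcp_params)

    t_grid = np.arange(0.0, t_max_min + 0.5 * t_step_min, t_step_min)
    t_best, tcp_v, ntcp_v, utcp_v = maximize_utcp(tcp_of_t, ntcp_of_t, t_grid, refine=refine)
    return OutcomeResult(
        t_irr_min=t_best,
        tcp=tcp_v,
        ntcp=ntcp_v,
        utcp=utcp_v,
        d_max_healthy_gy_eq=healthy_rate_gy_eq_min * t_best,
        flat_tcp_warning=flat,
    )


def combine_fields(fields: list[np.ndarray], weights: list[float]) -> np.ndarray:
    """Weighted sum of dose-rate maps, e.g. for a two-fraction plan.

    No inter-fraction repair is modelled: the combined map is evaluated as
    a single irradiation.
    """
    if len(fields) != len(weights) or not fields:
        raise ValueError("need one weight per field")
    out = np.zeros_like(np.asarray(fields[0], dtype=float))
    for f, w in zip(fields, weights):
        out = out + w * np.asarray(f, dtype=float)
    return out
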