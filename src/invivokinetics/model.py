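"""Kinetic model of a linear two-metabolite pathway at steady state.

The pathway is the minimal chain used to design strain panels for in vivo
enzymology: a constant influx produces the substrate pool S (e.g. GGPP made
by GGPP synthase), a Michaelis-Menten enzyme converts S into the product P
(e.g. phytoene made by phytoene synthase), and P is removed only by growth
dilution (first-order in P with rate constant mu).

    dS/dt = v_in - Vmax*S/(K + S)            [- mu*S if dilute_intermediate]
    dP/dt = Vmax*S/(K + S) - mu*P

When the substrate pool is not growth-diluted the steady state is closed
form: S* = K*v_in/(Vmax - v_in) for v_in < Vmax, the conversion flux equals
v_in, and P* = v_in/mu.  When v_in >= Vmax the substrate accumulates without
bound and no steady state exists; this is reported as an infeasible state
rather than raised, so that design scans can tabulate the infeasible region.

Units are fixed to µM and hours throughout; unit conversion from raw
measurements lives in :mod:`invivokinetics.quantify`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "PathwayModel",
    "SteadyState",
    "Timecourse",
    "IntegrationFailure",
    "simulate_timecourse",
    "steady_state",
    "design_scan",
]

# Integration / steady-state tolerances used throughout the module.
RTOL = 1e-8
ATOL = 1e-10
STEADY_TOL = 1e-9


class IntegrationFailure(RuntimeError):
    """Raised when the ODE integrator produces a non-finite state."""


@dataclass(frozen=True)
class PathwayModel:
    """Parameters of the influx -> Michaelis-Menten -> dilution chain.

    Parameters
    ----------
    v_in:
        Constant substrate-producing flux (µM/h).
    vmax:
        Maximal rate of the converting enzyme (µM/h).
    k_half:
        Half-saturation constant of the converting enzyme (µM).
    mu:
        Specific growth rate diluting the product pool (1/h).
    dilute_intermediate:
        If True the substrate pool is also diluted by growth.  The default
        (False) matches the design model in which only the end product is
        growth-diluted.
    """

    v_in: float
    vmax: float
    k_half: float
    mu: float
    dilute_intermediate: bool = False

    def __post_init__(self) -> None:
        if not self.vmax > 0:
            raise ValueError(f"vmax must be > 0, got {self.vmax}")
        if not self.k_half > 0:
            raise ValueError(f"k_half must be > 0, got {self.k_half}")
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if self.v_in < 0:
            raise ValueError(f"v_in must be >= 0, got {self.v_in}")

    def rate(self, s: float | np.ndarray) -> float | np.ndarray:
        """Michaelis-Menten conversion rate at substrate concentration ``s``."""
        return self.vmax * s / (self.k_half + s)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        s, p = y
        v = self.rate(s)
        ds = self.v_in - v
        if self.dilute_intermediate:
            ds -= self.mu * s
        dp = v - self.mu * p
        return np.array([ds, dp])


@dataclass(frozen=True)
class SteadyState:
    """Steady-state solution of a :class:`PathwayModel`.

    ``feasible`` is False when the influx exceeds the enzyme's capacity and
    the substrate pool diverges; in that case ``flux`` reports the asymptotic
    conversion flux (the enzyme's vmax) and the concentrations are NaN.
    ``p_star`` is NaN when mu == 0 with positive influx (the product pool has
    no steady state without dilution).
    """

    s_star: float
    p_star: float
    flux: float
    feasible: bool


@dataclass(frozen=True)
class Timecourse:
    t: np.ndarray
    s: np.ndarray
    p: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "S": self.s, "P": self.p})


def simulate_timecourse(
    model: PathwayModel,
    s0: float = 0.0,
    p0: float = 0.0,
    t_end: float = 100.0,
    n_points: int = 200,
) -> Timecourse:
    """Integrate the pathway ODEs from (s0, p0) to ``t_end``.

    Uses the stiff-capable LSODA integrator with rtol=1e-8, atol=1e-10.
    Negative round-off excursions are clipped to zero in the returned arrays.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if s0 < 0 or p0 < 0:
        raise ValueError("initial concentrations must be non-negative")
    t_eval = np.linspace(0.0, t_end, int(n_points))
    sol = solve_ivp(
        model.rhs,
        (0.0, t_end),
        [float(s0), float(p0)],
        method="LSODA",
        t_eval=t_eval,
        rtol=RTOL,
        atol=ATOL,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        t_reached = sol.t[-1] if sol.t.size else 0.0
        raise IntegrationFailure(
            f"integration failed at t = {t_reached:.6g} h: {sol.message}"
        )
    s = np.clip(sol.y[0], 0.0, None)
    p = np.clip(sol.y[1], 0.0, None)
    return Timecourse(t=sol.t, s=s, p=p)


def _steady_state_diluted(model: PathwayModel) -> float:
    # Substrate balance with growth dilution of the intermediate:
    #   v_in = vmax*S/(K+S) + mu*S
    # i.e. mu*S^2 + (mu*K + vmax - v_in)*S - v_in*K = 0; one non-negative root.
    mu, k, vmax, v_in = model.mu, model.k_half, model.vmax, model.v_in
    if mu == 0:
        # degenerates to the undiluted balance
        if v_in >= vmax:
            return np.nan
        return k * v_in / (vmax - v_in)
    b = mu * k + vmax - v_in
    c = -v_in * k
    disc = b * b - 4.0 * mu * c
    root = (-b + np.sqrt(disc)) / (2.0 * mu)
    return max(root, 0.0)


def steady_state(model: PathwayModel) -> SteadyState:
    """Solve for the steady state of ``model``.

    With an undiluted substrate pool the solution is closed form and exists
    only for v_in < vmax.  With ``dilute_intermediate`` the substrate balance
    is quadratic and a steady state always exists for mu > 0.
    """
    if model.dilute_intermediate:
        s_star = _steady_state_diluted(model)
        if not np.isfinite(s_star):
            return SteadyState(np.nan, np.nan, model.vmax, False)
        flux = float(model.rate(s_star))
    else:
        if model.v_in >= model.vmax:
            return SteadyState(np.nan, np.nan, model.vmax, False)
        s_star = model.k_half * model.v_in / (model.vmax - model.v_in)
        flux = model.v_in
    if model.mu > 0:
        p_star = flux / model.mu
    else:
        # no dilution: the product pool only has a steady state if flux is 0
        p_star = 0.0 if flux == 0 else np.nan
    return SteadyState(float(s_star), float(p_star), float(flux), True)


def design_scan(
    base: PathwayModel,
    vmax_levels: Sequence[float],
    v_in_grid: Sequence[float],
) -> pd.DataFrame:
    """Tabulate steady states over a grid of enzyme levels and influxes.

    Returns one row per (vmax, v_in) pair with columns vmax, v_in, s_star,
    p_star, flux, saturation_fraction and feasible.  Infeasible pairs
    (v_in >= vmax) are flagged, not dropped, so the scan shows where the
    design leaves the workable region.
    """
    if len(vmax_levels) == 0 or len(v_in_grid) == 0:
        raise ValueError("vmax_levels and v_in_grid must be non-empty")
    rows = []
    for vmax in vmax_levels:
        for v_in in v_in_grid:
            m = PathwayModel(
                v_in=float(v_in),
                vmax=float(vmax),
                k_half=base.k_half,
                mu=base.mu,
                dilute_intermediate=base.dilute_intermediate,
            )
            ss = steady_state(m)
            rows.append(
                {
                    "vmax": float(vmax),
                    "v_in": float(v_in),
                    "s_star": ss.s_star,
                    "p_star": ss.p_star,
                    "flux": ss.flux if ss.feasible else np.nan,
                    "saturation_fraction": ss.flux / vmax if ss.feasible else np.nan,
                    "feasible": ss.feasible,
                }
            )
    return pd.DataFrame(rows)
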