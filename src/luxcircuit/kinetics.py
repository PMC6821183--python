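"""Core metabolic model of the luxCDABE cassette.

The bacterial luciferase (LuxAB) oxidizes a long-chain aldehyde to the fatty
acid, emitting light; the LuxCDE enzymes (reductase, transferase, synthetase)
regenerate the aldehyde from the fatty acid.  The model tracks the aldehyde
``S`` and fatty-acid ``P`` pools, driven by the expression levels of the
forward enzyme (luciferase, ``E_F``) and the reverse enzymes (``E_R``)::

    dP/dt = K_F * E_F * S - K_R * E_R * P,      dS/dt = -dP/dt

The pool is conserved, ``S + P = S_T``.  At steady state

    P = S_T * (E_F / K_deff) / (1 + E_F / K_deff),   K_deff = K_R * E_R / K_F

so ``K_deff`` acts as an effective detection threshold: the forward-enzyme
level at which half the substrate pool has been converted.  Assuming the
reduced flavin cofactor pool ``Y_T`` is never significantly depleted, the
emitted intensity is proportional to the forward-reaction flux, which at
steady state gives

    I = (S_T * Y_T * K_R / K_d) * E_R * (E_F / K_deff) / (1 + E_F / K_deff)

Raising ``E_R`` therefore raises the detection threshold *and* the saturating
intensity at the same time — the property the split-operon circuits exploit.

Units: time in minutes, concentrations in arbitrary consistent units, signal
in a.u.; the global proportionality constant of the signal model defaults to
1 and is configurable (``signal_scale``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "LuxReactionParams",
    "EnzymeState",
    "MetaboliteState",
    "ReactionTrajectory",
    "k_deff",
    "steady_state_product",
    "bioluminescence_signal",
    "signal_from_levels",
    "simulate_reaction",
]


@dataclass(frozen=True)
class LuxReactionParams:
    """Rate and affinity constants of the forward/reverse lux reaction.

    Attributes
    ----------
    K_F : float
        Forward (luciferase) rate constant, per concentration per minute.
    K_R : float
        Reverse (reductase/transferase/synthetase) rate constant.
    K_d : float
        Dissociation constant of cofactor binding to the reverse enzymes.
    S_T : float
        Total substrate + product pool.
    Y_T : float
        Initial reduced-cofactor (FMNH2) pool.
    signal_scale : float
        Global proportionality constant of the intensity model.
    """

    K_F: float = 1.0
    K_R: float = 1.0
    K_d: float = 1.0
    S_T: float = 1.0
    Y_T: float = 1.0
    signal_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("K_F", "K_R", "K_d", "S_T", "Y_T", "signal_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class EnzymeState:
    """Expression levels of the forward (E_F) and reverse (E_R) enzymes."""

    E_F: float
    E_R: float

    def __post_init__(self) -> None:
        if self.E_F < 0 or self.E_R < 0:
            raise ValueError("enzyme levels must be non-negative")


@dataclass(frozen=True)
class MetaboliteState:
    """Aldehyde (S), fatty acid (P) and oxidized cofactor (Ystar) levels."""

    S: float
    P: float
    Ystar: float = 0.0


@dataclass
class ReactionTrajectory:
    """Sampled reaction time course: aldehyde, fatty acid and intensity."""

    t: np.ndarray
    S: np.ndarray
    P: np.ndarray
    I: np.ndarray
    params: LuxReactionParams = field(default_factory=LuxReactionParams)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_min": self.t, "S": self.S, "P": self.P, "I": self.I})

    def state(self, i: int) -> MetaboliteState:
        return MetaboliteState(S=float(self.S[i]), P=float(self.P[i]))


def k_deff(params: LuxReactionParams, E_R: float) -> float:
    """Effective detection threshold ``K_R * E_R / K_F``; linear in E_R."""
    if E_R < 0:
        raise ValueError("E_R must be non-negative")
    return params.K_R * E_R / params.K_F


def steady_state_product(params: LuxReactionParams, enzymes: EnzymeState) -> float:
    """Steady-state fatty-acid concentration.

    Returns ``S_T * (E_F/K_deff) / (1 + E_F/K_deff)``, always in ``[0, S_T]``.
    With no reverse enzyme (E_R = 0) but active luciferase the pool is fully
    converted; the analytic limit ``S_T`` is returned and a warning emitted.
    """
    E_F, E_R = enzymes.E_F, enzymes.E_R
    if E_F == 0:
        return 0.0
    if E_R == 0:
        warnings.warn(
            "E_R = 0 with E_F > 0: no reverse reaction, steady state saturates at S_T",
            stacklevel=2,
        )
        return params.S_T
    kd = k_deff(params, E_R)
    return params.S_T * E_F / (kd + E_F)


def signal_from_levels(params: LuxReactionParams, E_F, E_R):
    """Vectorized steady-state bioluminescent intensity.

    Evaluates ``C * E_R * E_F / (K_deff + E_F)`` with
    ``C = signal_scale * S_T * Y_T * K_R / K_d`` in the division-safe form
    ``C * K_F * E_F * E_R / (K_F * E_F + K_R * E_R)`` (0 when both enzyme
    levels vanish).  Accepts scalars or arrays.
    """
    E_F = np.asarray(E_F, dtype=float)
    E_R = np.asarray(E_R, dtype=float)
    if np.any(E_F < 0) or np.any(E_R < 0):
        raise ValueError("enzyme levels must be non-negative")
    C = params.signal_scale * params.S_T * params.Y_T * params.K_R / params.K_d
    num = params.K_F * E_F * E_R
    den = params.K_F * E_F + params.K_R * E_R
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, C * num / np.where(den > 0, den, 1.0), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def bioluminescence_signal(params: LuxReactionParams, enzymes: EnzymeState) -> float:
    """Steady-state intensity for a single enzyme state (a.u.)."""
    return float(signal_from_levels(params, enzymes.E_F, enzymes.E_R))


def simulate_reaction(
    params: LuxReactionParams,
    enzymes: EnzymeState,
    P0: float,
    t_grid: np.ndarray,
) -> ReactionTrajectory:
    """Integrate the forward/reverse reaction ODE on ``t_grid`` (minutes).

    The instantaneous intensity reported alongside the metabolite pools is
    the forward-reaction flux, ``I(t) = signal_scale * (Y_T/K_d) * K_F * E_F
    * S(t)``, which relaxes to the steady-state intensity model.

    The system is linear, so a stiff-capable integrator at rtol 1e-8 /
    atol 1e-10 resolves it essentially to machine precision.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a 1-D increasing array")
    if not 0 <= P0 <= params.S_T:
        raise ValueError("P0 must lie in [0, S_T]")

    kf, kr = params.K_F * enzymes.E_F, params.K_R * enzymes.E_R

    def rhs(_t, y):
        return [kf * (params.S_T - y[0]) - kr * y[0]]

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        [P0],
        t_eval=t_grid,
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:  # pragma: no cover - linear system, never expected
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    P = np.clip(sol.y[0], 0.0, params.S_T)
    S = params.S_T - P
    I = params.signal_scale * (params.Y_T / params.K_d) * kf * S
    return ReactionTrajectory(t=t_grid, S=S, P=P, I=I, params=params)
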