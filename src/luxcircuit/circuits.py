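"""Promoter layer and split-operon circuit topologies.

Builds on the steady-state intensity model in :mod:`luxcircuit.kinetics`:

* wild-type operon reporter — all five genes driven by one promoter, so
  luciferase (a LuxA-LuxB dimer) scales as the square of the common drive
  while the reverse enzymes scale linearly; the intensity then follows a
  power law ``I ~ x**n`` with ``1 < n < 2``;
* MIN fuzzy lattice — luxAB and luxCDE under different inducers, computing
  the soft minimum ``a*b/(a+b)`` of the two branches;
* protein-protein AND gate — luxA and luxB under different inducers, output
  proportional to the product of the two promoter activities;
* comparator — reverse-enzyme drive sets a programmable detection threshold;
* ODR — the gate-quality statistic min over OFF corners of log10(I_ON/I_OFF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import LuxReactionParams, signal_from_levels

__all__ = [
    "PromoterParams",
    "PPGateParams",
    "GateTruthTable",
    "DoseResponse",
    "ThresholdUndefinedError",
    "promoter_activity",
    "wildtype_operon_response",
    "local_loglog_slope",
    "soft_min",
    "min_gate_output",
    "pp_gate_output",
    "gate_truth_table",
    "odr",
    "comparator_transfer",
    "detection_threshold",
]

#: vmax multipliers standing in for plasmid copy number (low/medium/high copy)
COPY_NUMBER_SCALE = {"LCP": 1.0, "MCP": 5.0, "HCP": 20.0}


@dataclass(frozen=True)
class PromoterParams:
    """Hill-type inducible promoter: ``vmax*(basal + (1-basal)*c^n/(c^n+K^n))``.

    ``n=1`` recovers the Michaelis-Menten form used for the logic-gate
    models; ``basal`` is leaky expression as a fraction of vmax (default 2%,
    the OFF states seen in measured gates are nonzero).
    """

    vmax: float = 1.0
    K: float = 1.0
    n: float = 1.0
    basal: float = 0.02

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.K <= 0:
            raise ValueError("vmax and K must be positive")
        if not 0 <= self.basal < 1:
            raise ValueError("basal must lie in [0, 1)")
        if self.n <= 0:
            raise ValueError("Hill coefficient must be positive")


@dataclass(frozen=True)
class PPGateParams:
    """LuxA-LuxB binding dissociation constant for the protein-protein gate."""

    K_AB: float = 1.0

    def __post_init__(self) -> None:
        if self.K_AB <= 0:
            raise ValueError("K_AB must be positive")


@dataclass(frozen=True)
class GateTruthTable:
    """Intensities at the four logic corners; I11 is the intended ON state."""

    I00: float
    I01: float
    I10: float
    I11: float

    def __post_init__(self) -> None:
        if min(self.I00, self.I01, self.I10, self.I11) <= 0:
            raise ValueError("truth-table intensities must be positive")


@dataclass
class DoseResponse:
    """Input-output transfer function in arbitrary luminescence units."""

    inputs: np.ndarray
    outputs: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.outputs = np.asarray(self.outputs, dtype=float)
        if self.inputs.shape != self.outputs.shape or self.inputs.ndim != 1:
            raise ValueError("inputs and outputs must be 1-D arrays of equal length")
        if np.any(np.diff(self.inputs) <= 0):
            raise ValueError("inputs must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"input": self.inputs, "I": self.outputs})
        for key, val in self.metadata.items():
            if np.isscalar(val):
                df[key] = val
        return df


class ThresholdUndefinedError(ValueError):
    """Raised when a dose-response curve has no usable half-max threshold."""


def promoter_activity(p: PromoterParams, inducer) -> float | np.ndarray:
    """Expression level driven by ``inducer`` through a leaky Hill function."""
    c = np.asarray(inducer, dtype=float)
    if np.any(c < 0):
        raise ValueError("inducer concentration must be non-negative")
    cn = np.power(c, p.n)
    act = p.vmax * (p.basal + (1.0 - p.basal) * cn / (cn + p.K**p.n))
    return float(act) if act.ndim == 0 else act


def wildtype_operon_response(
    x_grid,
    params: LuxReactionParams | None = None,
    scale_F: float = 1.0,
    scale_R: float = 1.0,
) -> DoseResponse:
    """Wild-type operon transfer function with a common drive ``x``.

    Sets ``E_F = scale_F * x**2`` (luciferase is a LuxA-LuxB dimer) and
    ``E_R = scale_R * x`` and evaluates the steady-state intensity at each
    drive level.  The resulting local log-log slope is
    ``1 + 1/(1 + gamma*x)`` with ``gamma = K_F*scale_F/(K_R*scale_R)``,
    which stays strictly between 1 and 2.
    """
    params = params or LuxReactionParams()
    x = np.asarray(x_grid, dtype=float)
    if np.any(x <= 0):
        raise ValueError("drive levels must be strictly positive")
    I = signal_from_levels(params, scale_F * x**2, scale_R * x)
    return DoseResponse(x, I, metadata={"scale_F": scale_F, "scale_R": scale_R})


def local_loglog_slope(dr: DoseResponse) -> np.ndarray:
    """Central-difference slopes of log(output) vs log(input) (interior points)."""
    if np.any(dr.inputs <= 0) or np.any(dr.outputs <= 0):
        raise ValueError("log-log slopes require strictly positive values")
    lx, ly = np.log(dr.inputs), np.log(dr.outputs)
    return (ly[2:] - ly[:-2]) / (lx[2:] - lx[:-2])


def soft_min(a: float, b: float) -> float:
    """Soft minimum ``a*b/(a+b)``; lies between ``min(a,b)/2`` and ``min(a,b)``."""
    if a < 0 or b < 0:
        raise ValueError("soft_min arguments must be non-negative")
    if a + b == 0:
        return 0.0
    return a * b / (a + b)


def min_gate_output(
    arab: float,
    ahl: float,
    p_arab: PromoterParams,
    p_ahl: PromoterParams,
    scale: float = 1.0,
) -> float:
    """MIN fuzzy-lattice output: soft minimum of the two promoter branches."""
    return scale * soft_min(
        promoter_activity(p_arab, arab), promoter_activity(p_ahl, ahl)
    )


def pp_gate_output(
    arab: float,
    ahl: float,
    p_arab: PromoterParams,
    p_ahl: PromoterParams,
    gp: PPGateParams,
) -> float:
    """Protein-protein AND gate: product of the branch activities over K_AB."""
    return (
        promoter_activity(p_arab, arab) * promoter_activity(p_ahl, ahl) / gp.K_AB
    )


def gate_truth_table(
    gate,
    p_arab: PromoterParams,
    p_ahl: PromoterParams,
    hi_factor: float = 100.0,
) -> GateTruthTable:
    """Evaluate a two-input gate at the four logic corners.

    Logic '0' is zero added inducer (basal leak only); logic '1' is
    ``hi_factor * K`` of the respective promoter, i.e. saturating induction.
    """
    lo_a, hi_a = 0.0, hi_factor * p_arab.K
    lo_b, hi_b = 0.0, hi_factor * p_ahl.K
    return GateTruthTable(
        I00=gate(lo_a, lo_b),
        I01=gate(lo_a, hi_b),
        I10=gate(hi_a, lo_b),
        I11=gate(hi_a, hi_b),
    )


def odr(t: GateTruthTable) -> float:
    """Output dynamic range: min over OFF corners of log10(I11/I_off)."""
    return min(
        np.log10(t.I11 / t.I00),
        np.log10(t.I11 / t.I01),
        np.log10(t.I11 / t.I10),
    )


def comparator_transfer(
    arab_grid,
    ahl: float,
    design: str,
    p_bad: PromoterParams,
    p_lux: PromoterParams,
    params: LuxReactionParams | None = None,
    gp: PPGateParams | None = None,
    luxB_level: float = 1.0,
) -> DoseResponse:
    """Arabinose -> intensity transfer function at a fixed AHL co-input.

    Two split-operon topologies:

    ``luxCDE-luxAB``
        luxAB under P_BAD (so ``E_F = P_BAD(arab)**2``, dimer), all three
        reverse genes co-induced under P_lux (``E_R = P_lux(ahl)``).
    ``luxA-luxC``
        only luxA and luxC inducible; LuxB constitutive so
        ``E_F = P_BAD(arab) * luxB_level / K_AB``, and with LuxD/LuxE
        constitutive and in excess the reverse rate is set by LuxC alone,
        ``E_R = P_lux(ahl)``.
    """
    params = params or LuxReactionParams()
    gp = gp or PPGateParams()
    arab = np.asarray(arab_grid, dtype=float)
    e_bad = promoter_activity(p_bad, arab)
    e_lux = float(promoter_activity(p_lux, ahl))
    if design == "luxCDE-luxAB":
        E_F = e_bad**2
    elif design == "luxA-luxC":
        E_F = e_bad * luxB_level / gp.K_AB
    else:
        raise ValueError(f"unknown comparator design {design!r}")
    I = signal_from_levels(params, E_F, np.full_like(arab, e_lux))
    return DoseResponse(arab, I, metadata={"design": design, "ahl": ahl})


def detection_threshold(dr: DoseResponse) -> float:
    """Input at half-height of a monotone dose-response curve.

    The threshold is the input where the output crosses
    ``min + (max - min)/2``, found by linear interpolation in log-input
    space (dose grids are log-spaced).  Flat (< 2-fold span) or
    non-monotone curves have no defined threshold.
    """
    y = dr.outputs
    if np.any(dr.inputs <= 0):
        raise ThresholdUndefinedError("log-space interpolation needs positive inputs")
    if np.any(np.diff(y) < -1e-9 * max(abs(y).max(), 1.0)):
        raise ThresholdUndefinedError("threshold undefined: response not monotone")
    lo, hi = float(y.min()), float(y.max())
    if lo <= 0 or hi < 2 * lo:
        raise ThresholdUndefinedError("threshold undefined: response span below 2-fold")
    half = lo + 0.5 * (hi - lo)
    logx = np.interp(half, y, np.log10(dr.inputs))
    return float(10.0**logx)
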