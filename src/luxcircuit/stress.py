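"""Stress-promoter dynamics and the crosstalk-compensating circuit.

The delayed rise-and-decay response of a stress promoter (recA for DNA
damage, katG for oxidative stress) driving the lux cassette is, with light
generation at quasi-steady state,

    I(t) = X0 * (1 - exp(-(t - tau_D1)/tau_eff)) *
                (exp(-(t - tau_D2)/tau_1) + beta) + c

where each exponential is clamped to its pre-delay value (the rise term is 0
before ``tau_D1``; the decay exponential is 1 before ``tau_D2``), ``beta`` is
the non-degradable fraction of the chemical and ``c`` the instrument
baseline.  recA responds to both nalidixic acid (NA) and peroxide (H2O2);
the crosstalk is modelled by summing the two single-chemical responses.

The crosstalk-compensating circuit is an incoherent type-1 feedforward loop
split across sender and receiver strains: katG (H2O2-specific) drives AHL
production in the sender; in the receiver AHL induces the TetR repressor
with delay (``TetR ~ AHL(t - tau_delay)``), which represses the luxAB branch
(``luxAB = 1/(1 + (TetR/0.2)**2)``) of an AND gate whose other branch
(luxCDE) is driven by recA.  With both chemicals present the early
H2O2-driven response and the later NA-driven response are separated by a
repression trough, so the number of prominent peaks equals the number of
chemical types.  At constant inputs the receiver realizes NIMPLY logic
(stress AND NOT AHL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .circuits import GateTruthTable, PromoterParams, promoter_activity
from .kinetics import LuxReactionParams, signal_from_levels

__all__ = [
    "StressResponseParams",
    "IFFLParams",
    "TimeCourse",
    "KATG",
    "RECA_NA",
    "RECA_H2O2",
    "KATG_PULSE",
    "RECA_NA_PULSE",
    "RECA_H2O2_PULSE",
    "stress_response",
    "combined_response",
    "tetr_course",
    "ptet_activity",
    "iffl_simulate",
    "receiver_truth_table",
    "nimply_truth_table",
    "count_peaks",
]


@dataclass(frozen=True)
class StressResponseParams:
    """Parameters of the delayed stress-promoter response.

    X0 — response amplitude (a.u.); tau1 — chemical consumption time constant
    (min); tau_eff — effective protein half-life constant (min); tau_D1 —
    activation delay (min); tau_D2 — consumption delay (min); beta —
    non-degradable chemical fraction; c — basal bioluminescence (a.u.).
    """

    X0: float
    tau1: float
    tau_eff: float
    tau_D1: float = 0.0
    tau_D2: float = 0.0
    beta: float = 0.0
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau_eff <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_D1 < 0 or self.tau_D2 < 0:
            raise ValueError("delays must be non-negative")
        if self.beta < 0 or self.c < 0 or self.X0 < 0:
            raise ValueError("X0, beta and c must be non-negative")


@dataclass(frozen=True)
class IFFLParams:
    """Incoherent-feedforward-loop parameters.

    tau_delay — sender-to-repressor delay (min, default 60: places the
    repression window over the early H2O2-driven response); K_tetr —
    half-repression TetR level (0.2); h_tetr — repression Hill coefficient
    (2); er_scale — scale linking the recA-driven pulse to reverse-enzyme
    units (unit pulses by default, so the two gate branches compete).
    """

    tau_delay: float = 60.0
    K_tetr: float = 0.2
    h_tetr: float = 2.0
    er_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_delay < 0:
            raise ValueError("tau_delay must be non-negative")
        if self.K_tetr <= 0:
            raise ValueError("K_tetr must be positive")
        if self.h_tetr < 1:
            raise ValueError("h_tetr must be >= 1")


@dataclass
class TimeCourse:
    """Sampled signal trace in arbitrary units."""

    t: np.ndarray
    I: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.t.shape != self.I.shape or self.t.ndim != 1:
            raise ValueError("t and I must be 1-D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_min": self.t, "I": self.I})


# Fitted response parameters for the stress promoters.  Only the time
# constants, beta and c are published fits; the amplitude X0 is a package
# default chosen so the pulse peaks roughly an order of magnitude above the
# instrument floor c, the dynamic range lux stress reporters display.
KATG = StressResponseParams(X0=100000, tau1=20, tau_eff=20, tau_D1=0, tau_D2=0, beta=0.02, c=2000)
RECA_NA = StressResponseParams(X0=100000, tau1=60, tau_eff=25, tau_D1=60, tau_D2=100, beta=0.1, c=9000)
RECA_H2O2 = StressResponseParams(X0=100000, tau1=30, tau_eff=30, tau_D1=0, tau_D2=40, beta=0.25, c=9000)

# Unit-amplitude, baseline-free variants used inside the feedforward circuit,
# where enzyme drives must be order-unity to compete with the [0, 1]
# repressor-gated forward branch.
KATG_PULSE = StressResponseParams(X0=1, tau1=20, tau_eff=20, tau_D1=0, tau_D2=0, beta=0.02)
RECA_NA_PULSE = StressResponseParams(X0=1, tau1=60, tau_eff=25, tau_D1=60, tau_D2=100, beta=0.1)
RECA_H2O2_PULSE = StressResponseParams(X0=1, tau1=30, tau_eff=30, tau_D1=0, tau_D2=40, beta=0.25)


def _pulse(p: StressResponseParams, t) -> np.ndarray:
    """Baseline-free response ``X0 * rise(t) * decay(t)`` with delay clamps."""
    t = np.asarray(t, dtype=float)
    rise = np.where(t < p.tau_D1, 0.0, 1.0 - np.exp(-np.maximum(t - p.tau_D1, 0.0) / p.tau_eff))
    decay = np.where(t < p.tau_D2, 1.0, np.exp(-np.maximum(t - p.tau_D2, 0.0) / p.tau1)) + p.beta
    return p.X0 * rise * decay


def stress_response(p: StressResponseParams, t_grid) -> TimeCourse:
    """Stress-promoter bioluminescence trace ``X0*rise*decay + c``."""
    t = np.asarray(t_grid, dtype=float)
    return TimeCourse(t, _pulse(p, t) + p.c)


def combined_response(components, t_grid) -> TimeCourse:
    """Sum of stress-response pulses over one shared baseline.

    Models promoter crosstalk: a promoter responding to several chemicals is
    the sum of the per-chemical pulses.  The baseline ``c`` of the first
    component is used once (the instrument floor is not additive).
    """
    components = list(components)
    if not components:
        raise ValueError("combined_response needs at least one component")
    t = np.asarray(t_grid, dtype=float)
    total = np.zeros_like(t)
    for p in components:
        total += _pulse(p, t)
    return TimeCourse(t, total + components[0].c)


def tetr_course(
    katg_params: StressResponseParams, ip: IFFLParams, t_grid
) -> TimeCourse:
    """Delayed TetR level: the unit-peak katG pulse shifted by ``tau_delay``.

    The AHL level seen by the receiver is proxied by the baseline-subtracted
    katG response normalized to unit peak; TetR tracks it with delay,
    ``TetR(t) = AHL(t - tau_delay)`` (zero before the delay).  A silent
    sender (X0 = 0) gives TetR = 0 throughout.
    """
    t = np.asarray(t_grid, dtype=float)
    peak = float(np.max(_pulse(katg_params, t))) if katg_params.X0 > 0 else 0.0
    if peak == 0.0:
        return TimeCourse(t, np.zeros_like(t))
    tetr = _pulse(katg_params, t - ip.tau_delay) / peak
    return TimeCourse(t, tetr)


def ptet_activity(tetr, K_tetr: float = 0.2, h_tetr: float = 2.0):
    """P_tetO promoter activity under TetR repression: ``1/(1+(TetR/K)^h)``."""
    tetr = np.asarray(tetr, dtype=float)
    if np.any(tetr < 0):
        raise ValueError("TetR level must be non-negative")
    out = 1.0 / (1.0 + (tetr / K_tetr) ** h_tetr)
    return float(out) if out.ndim == 0 else out


def iffl_simulate(
    doses,
    recA_params: dict | None = None,
    katg_params: StressResponseParams = KATG_PULSE,
    ip: IFFLParams | None = None,
    lux: LuxReactionParams | None = None,
    t_grid=None,
    basal: float = 0.0,
) -> TimeCourse:
    """Simulate the crosstalk-compensating sender/receiver circuit.

    ``doses`` is the set of chemicals present, a subset of {"NA", "H2O2"}.
    The reverse branch E_R(t) sums the recA pulses of the chemicals present;
    the forward branch E_F(t) is the P_tetO activity under delayed
    katG-driven TetR (active only when H2O2 is present).  The output is the
    steady-state intensity of the lux reaction at each sample, plus an
    optional basal floor.
    """
    doses = set(doses)
    if not doses <= {"NA", "H2O2"}:
        raise ValueError("doses must be a subset of {'NA', 'H2O2'}")
    recA_params = recA_params or {"NA": RECA_NA_PULSE, "H2O2": RECA_H2O2_PULSE}
    ip = ip or IFFLParams()
    lux = lux or LuxReactionParams()
    t = np.arange(0.0, 601.0) if t_grid is None else np.asarray(t_grid, dtype=float)

    E_R = np.zeros_like(t)
    for chem in sorted(doses):
        E_R += _pulse(recA_params[chem], t)
    E_R *= ip.er_scale

    if "H2O2" in doses:
        tetr = tetr_course(katg_params, ip, t).I
    else:
        tetr = np.zeros_like(t)
    E_F = ptet_activity(tetr, ip.K_tetr, ip.h_tetr)

    I = signal_from_levels(lux, E_F, E_R) + basal
    return TimeCourse(t, I)


def receiver_truth_table(
    stress_on: bool,
    ahl: float,
    p_ahl: PromoterParams | None = None,
    ip: IFFLParams | None = None,
    lux: LuxReactionParams | None = None,
    recA_level: float = 1.0,
    recA_basal: float = 0.02,
) -> float:
    """Steady-state receiver output for one (stress, AHL) input corner.

    At constant inputs TetR settles at the AHL-induced promoter activity, so
    ``E_F = 1/(1+(TetR/K)^h)`` and ``E_R`` is the recA drive (leak fraction
    when stress is off).  High output requires stress AND NOT AHL.
    """
    ip = ip or IFFLParams()
    lux = lux or LuxReactionParams()
    p_ahl = p_ahl or PromoterParams(vmax=1.0, K=10.0, n=1.0, basal=0.0)
    tetr = float(promoter_activity(p_ahl, ahl))
    E_F = float(ptet_activity(tetr, ip.K_tetr, ip.h_tetr))
    E_R = recA_level if stress_on else recA_basal * recA_level
    return float(signal_from_levels(lux, E_F, E_R))


def nimply_truth_table(
    p_ahl: PromoterParams | None = None,
    ip: IFFLParams | None = None,
    lux: LuxReactionParams | None = None,
    hi_factor: float = 100.0,
    **kwargs,
) -> GateTruthTable:
    """Receiver truth table over the four (stress, AHL) logic corners.

    Index convention I[stress, ahl]; the NIMPLY ON state is I10 (stress
    present, no AHL).
    """
    p_ahl = p_ahl or PromoterParams(vmax=1.0, K=10.0, n=1.0, basal=0.0)
    hi = hi_factor * p_ahl.K
    out = {
        (s, a): receiver_truth_table(bool(s), a, p_ahl, ip, lux, **kwargs)
        for s in (0, 1)
        for a in (0.0, hi)
    }
    return GateTruthTable(
        I00=out[(0, 0.0)], I01=out[(0, hi)], I10=out[(1, 0.0)], I11=out[(1, hi)]
    )


def count_peaks(tc: TimeCourse, min_prominence_frac: float = 0.05) -> int:
    """Number of prominent strict local maxima in a trace.

    A peak counts when its prominence exceeds ``min_prominence_frac`` times
    the trace's global range; endpoints never count.  A flat trace has no
    peaks.
    """
    if len(tc.I) < 3:
        raise ValueError("need at least 3 samples to count peaks")
    span = float(tc.I.max() - tc.I.min())
    if span == 0.0:
        return 0
    peaks, _ = find_peaks(tc.I, prominence=min_prominence_frac * span)
    return int(len(peaks))
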