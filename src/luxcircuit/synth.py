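"""Plate-reader-like synthetic datasets.

Emulates the statistical structure of the measurements the circuit models
are compared against: replicate wells (triplicates), a per-well OD600 near
0.4 with ~10% spread, multiplicative unit-mean lognormal noise on the raw
signals, and OD normalization of luminescence/fluorescence.  Time courses
are simulated on a fine grid and down-sampled to the 15-min plate-reader
cadence over a 4-h default horizon.

The generator is deterministic given a seed: identical seed and
configuration produce byte-identical CSV output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PlateDataset", "generate_dose_response", "generate_time_course"]

_COLUMNS = ["well", "condition", "replicate", "t_min", "od600", "lum", "gfp"]


@dataclass
class PlateDataset:
    """Tidy plate-reader table plus the generating parameters."""

    data: pd.DataFrame
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")

    def normalized(self) -> pd.DataFrame:
        """Copy of the table with OD-normalized signal columns added."""
        df = self.data.copy()
        df["lum_norm"] = df["lum"] / df["od600"]
        df["gfp_norm"] = df["gfp"] / df["od600"]
        return df

    def write(self, csv_path, params_path=None) -> None:
        """Write the tidy CSV and a sidecar JSON of generating parameters."""
        csv_path = Path(csv_path)
        self.data.to_csv(csv_path, index=False)
        if params_path is None:
            params_path = csv_path.with_suffix(".params.json")
        Path(params_path).write_text(json.dumps(self.params, indent=2, sort_keys=True))


def _noise_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean multiplicative lognormal noise factor."""
    if cv == 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(rng.lognormal(-0.5 * sigma * sigma, sigma))


def generate_dose_response(
    model,
    input_grid,
    noise_cv: float = 0.1,
    seed: int | None = None,
    replicates: int = 3,
    gfp_model=None,
    od_mean: float = 0.4,
    od_spread: float = 0.1,
    t_min: float = 240.0,
) -> PlateDataset:
    """Replicate dose-response measurements from a circuit model.

    Each well's raw signal is ``model(x) * noise * od600`` with a per-well
    OD600 drawn uniformly in ``od_mean * (1 ± od_spread)``, so the
    OD-normalized signal is unbiased for the model value.  ``gfp_model``
    defaults to a flat unit fluorescence background.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if seed is None:
        raise ValueError("a seed is required for reproducible generation")
    rng = np.random.default_rng(seed)
    grid = np.asarray(input_grid, dtype=float)

    rows = []
    for rep in range(1, replicates + 1):
        for j, x in enumerate(grid):
            od = od_mean * (1.0 + od_spread * rng.uniform(-1.0, 1.0))
            lum = float(model(x)) * _noise_factor(rng, noise_cv) * od
            g = float(gfp_model(x)) if gfp_model is not None else 1.0
            gfp = g * _noise_factor(rng, noise_cv) * od
            rows.append((f"R{rep}W{j + 1}", x, rep, t_min, od, lum, gfp))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return PlateDataset(
        df,
        params={
            "kind": "dose_response",
            "noise_cv": noise_cv,
            "seed": seed,
            "replicates": replicates,
            "od_mean": od_mean,
            "od_spread": od_spread,
        },
    )


def generate_time_course(
    simulator,
    doses=(),
    noise_cv: float = 0.1,
    seed: int | None = None,
    replicates: int = 3,
    t_max: float = 240.0,
    cadence: float = 15.0,
    sim_dt: float = 1.0,
    od_mean: float = 0.4,
    od_spread: float = 0.1,
) -> PlateDataset:
    """Replicate time-course measurements from a temporal simulator.

    ``simulator(doses, t_grid)`` must return a TimeCourse-like object with
    ``t`` and ``I`` arrays.  The model is run on a ``sim_dt`` grid and
    down-sampled to the plate-reader ``cadence`` before noise is applied.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if seed is None:
        raise ValueError("a seed is required for reproducible generation")
    if cadence % sim_dt:
        raise ValueError("cadence must be a multiple of sim_dt")
    rng = np.random.default_rng(seed)

    fine = np.arange(0.0, t_max + sim_dt / 2, sim_dt)
    tc = simulator(doses, fine)
    stride = int(round(cadence / sim_dt))
    t_samp, i_samp = tc.t[::stride], tc.I[::stride]

    label = "+".join(sorted(doses)) if doses else "control"
    rows = []
    for rep in range(1, replicates + 1):
        od = od_mean * (1.0 + od_spread * rng.uniform(-1.0, 1.0))
        for t, val in zip(t_samp, i_samp):
            lum = float(val) * _noise_factor(rng, noise_cv) * od
            gfp = _noise_factor(rng, noise_cv) * od
            rows.append((f"R{rep}", label, rep, float(t), od, lum, gfp))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return PlateDataset(
        df,
        params={
            "kind": "time_course",
            "doses": sorted(doses),
            "noise_cv": noise_cv,
            "seed": seed,
            "replicates": replicates,
            "t_max": t_max,
            "cadence": cadence,
        },
    )
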