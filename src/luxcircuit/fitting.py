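"""Transfer-function fitting: Hill curves, power laws, threshold series.

Fits are performed on log-transformed outputs — luminescence spans orders of
magnitude and dose grids are log-spaced, so uniform weights in log space are
the natural choice.  Hill fits are reported both in the (K, n) form
``vmax * x^n / (x^n + K^n)`` and the aggregate form ``x^n / (x^n + Khat)``
with ``Khat = K^n``, the form the dose-response captions use.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

from .circuits import DoseResponse, detection_threshold

__all__ = [
    "HillFit",
    "PowerLawFit",
    "fit_hill",
    "fit_power_law",
    "threshold_series",
    "hill_recovery_study",
]


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill transfer function ``basal + vmax * x^n / (x^n + K^n)``."""

    vmax: float
    K: float
    n: float
    basal: float
    rss: float
    success: bool
    message: str = ""

    @property
    def khat(self) -> float:
        """Aggregate half-max constant ``K^n`` of the form x^n/(x^n + Khat)."""
        return self.K**self.n

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        xn = np.power(x, self.n)
        return self.basal + self.vmax * xn / (xn + self.khat)


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted power law ``y = a * x^n`` (ordinary least squares on logs)."""

    a: float
    n: float
    r2: float

    def __call__(self, x):
        return self.a * np.power(np.asarray(x, dtype=float), self.n)


def _hill_residual(params, x, logy, fit_basal):
    vmax = params["vmax"].value
    K = params["K"].value
    n = params["n"].value
    basal = params["basal"].value if fit_basal else 0.0
    xn = np.power(x, n)
    model = basal + vmax * xn / (xn + K**n)
    return np.log(np.maximum(model, 1e-300)) - logy


def fit_hill(
    dr: DoseResponse,
    fix_n: float | None = None,
    fit_basal: bool = False,
    max_restarts: int = 5,
) -> HillFit:
    """Least-squares Hill fit of a dose-response curve in log space.

    Initialization: n = 1 (or the fixed value), K = geometric median of the
    inputs, vmax = maximum output.  On convergence failure up to
    ``max_restarts`` seeded perturbed restarts are attempted; persistent
    failure is reported in the returned ``success``/``message`` fields,
    never silently.
    """
    x, y = dr.inputs, dr.outputs
    if len(x) < 4:
        raise ValueError("Hill fit needs at least 4 points")
    if np.any(y <= 0) or np.any(x <= 0):
        raise ValueError("Hill fit requires positive inputs and outputs")
    logy = np.log(y)

    def build_params(k0, v0, n0):
        p = lmfit.Parameters()
        p.add("vmax", value=v0, min=1e-12)
        p.add("K", value=k0, min=1e-12)
        p.add("n", value=n0, min=0.05, max=10.0, vary=fix_n is None)
        p.add("basal", value=float(y.min()) / 2 if fit_basal else 0.0,
              min=0.0, vary=fit_basal)
        return p

    k0 = float(np.exp(np.median(np.log(x))))
    v0 = float(y.max())
    n0 = 1.0 if fix_n is None else float(fix_n)

    result = lmfit.minimize(
        _hill_residual, build_params(k0, v0, n0), args=(x, logy, fit_basal),
        method="leastsq",
    )
    if not result.success:
        rng = np.random.default_rng(0)
        for _ in range(max_restarts):
            jitter = rng.lognormal(0.0, 0.5, size=2)
            trial = lmfit.minimize(
                _hill_residual,
                build_params(k0 * jitter[0], v0 * jitter[1], n0),
                args=(x, logy, fit_basal),
                method="leastsq",
            )
            if trial.success:
                result = trial
                break

    p = result.params
    return HillFit(
        vmax=float(p["vmax"].value),
        K=float(p["K"].value),
        n=float(p["n"].value) if fix_n is None else float(fix_n),
        basal=float(p["basal"].value) if fit_basal else 0.0,
        rss=float(np.sum(np.square(np.asarray(result.residual)))),
        success=bool(result.success),
        message=str(result.message),
    )


def fit_power_law(x, y) -> PowerLawFit:
    """OLS fit of ``log y`` on ``log x``: exponent, prefactor and R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("power-law fit needs at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive values")
    lx, ly = np.log(x), np.log(y)
    n, loga = np.polyfit(lx, ly, 1)
    resid = ly - (loga + n * lx)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return PowerLawFit(a=float(np.exp(loga)), n=float(n), r2=r2)


def threshold_series(curves) -> list[tuple[float, float]]:
    """Detection thresholds across co-input levels.

    ``curves`` maps co-input level -> DoseResponse (dict or iterable of
    pairs).  Returns (co-input, threshold) pairs sorted by co-input; a
    failing curve raises with its co-input identity attached.
    """
    items = curves.items() if isinstance(curves, dict) else list(curves)
    out = []
    for co, dr in items:
        try:
            out.append((float(co), detection_threshold(dr)))
        except ValueError as err:
            raise ValueError(f"threshold undefined at co-input {co}: {err}") from err
    return sorted(out)


def hill_recovery_study(
    true: HillFit | None = None,
    input_grid=None,
    noise_cv: float = 0.1,
    replicates: int = 3,
    n_trials: int = 200,
    seed: int = 0,
    k_rtol: float = 0.15,
    n_atol: float = 0.2,
) -> dict:
    """Monte-Carlo parameter-recovery study for the Hill fit.

    Generates noisy triplicate plate-reader datasets from a known Hill curve
    (defaults: the bioluminescence-style curve vmax=1, K^n=30, n=1.5),
    OD-normalizes, averages replicates, refits, and reports the fraction of
    trials in which K is recovered within ``k_rtol`` and n within ``n_atol``.
    """
    from .synth import generate_dose_response  # local import to avoid cycle

    if true is None:
        true = HillFit(vmax=1.0, K=30.0 ** (1 / 1.5), n=1.5, basal=0.0,
                       rss=0.0, success=True)
    if input_grid is None:
        input_grid = np.logspace(-1, 3, 9)
    input_grid = np.asarray(input_grid, dtype=float)

    hits = 0
    estimates = []
    for trial in range(n_trials):
        ds = generate_dose_response(
            true, input_grid, noise_cv=noise_cv,
            seed=seed + trial, replicates=replicates,
        )
        mean = ds.normalized().groupby("condition")["lum_norm"].mean()
        dr = DoseResponse(mean.index.to_numpy(), mean.to_numpy())
        fit = fit_hill(dr)
        estimates.append((fit.K, fit.n))
        if abs(fit.K - true.K) <= k_rtol * true.K and abs(fit.n - true.n) <= n_atol:
            hits += 1
    return {
        "n_trials": n_trials,
        "recovery_rate": hits / n_trials,
        "estimates": estimates,
        "true": {"K": true.K, "n": true.n},
    }
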