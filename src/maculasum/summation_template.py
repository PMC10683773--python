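"""Biphasic spatial-summation template and its calibration.

The template links the total retinal input of a perimetric stimulus -- the
product of stimulus area (deg^2), duration (ms), parasol-OFF RGC density
(cells/deg^2) and cone-to-RGC convergence ratio -- to perimetric sensitivity.
Below a transition input ``tau`` sensitivity rises 1:1 with input in log-log
(dB/dB) units ("complete summation"); far above it the slope falls to ``1/kappa``
("partial summation"), with a smooth Minkowski-type transition in between.

Both axes are handled in dB, i.e. ``10*log10`` units, so that a change in RGC
density shifts the operating point horizontally along the curve.  The template
is a function of ``input_db - 10*log10(tau)`` only, which makes a horizontal
shift of the curve exactly equivalent to a change of ``tau``::

    S(u + delta; alpha, tau) == S(u; alpha, tau / 10**(delta/10))

Calibration estimates the three parameters ``(alpha, log10_tau, kappa)`` by
least squares on young-healthy data, with eye-level bootstrap confidence
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "DEFAULT_TEMPLATE",
    "TemplateParameters",
    "RetinalInput",
    "CalibrationResult",
    "retinal_input",
    "template_sensitivity",
    "template_slope",
    "calibrate_template",
    "bootstrap_parameters",
]


@dataclass(frozen=True)
class TemplateParameters:
    """The three parameters of the summation template.

    Parameters
    ----------
    alpha
        Vertical offset of the template in log10 units (the curve is offset
        by ``10*alpha`` dB).
    log10_tau
        log10 of the transition point of total retinal input, i.e. the
        abscissa (in log10 units of input) where summation transitions from
        complete to partial.
    kappa
        Minkowski-type exponent, > 1.  The asymptotic partial-summation
        slope in dB/dB units is ``1/kappa``.
    """

    alpha: float
    log10_tau: float
    kappa: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.alpha, self.log10_tau, self.kappa]).all():
            raise ValueError("template parameters must be finite")
        if self.kappa <= 1.0:
            raise ValueError(f"kappa must be > 1, got {self.kappa}")

    @property
    def partial_summation_slope(self) -> float:
        """Asymptotic log-log slope of the partial-summation limb (= 1/kappa)."""
        return 1.0 / self.kappa

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.log10_tau, self.kappa])


# Calibrated values reported for the young-healthy cohort; used as the default
# generating template throughout the synthetic study.
DEFAULT_TEMPLATE = TemplateParameters(alpha=1.42, log10_tau=3.58, kappa=2.59)


@dataclass(frozen=True)
class RetinalInput:
    """Total retinal input: area x duration x P-OFF density x convergence."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("retinal input must be >= 0")

    @property
    def db(self) -> float:
        """10*log10 of the input; -inf for zero input."""
        with np.errstate(divide="ignore"):
            return float(10.0 * np.log10(self.value))


def retinal_input(stimulus, density: float, convergence: float) -> RetinalInput:
    """Total retinal input for a stimulus over a local P-OFF RGC density.

    Parameters
    ----------
    stimulus
        Object with ``area_deg2`` (deg^2) and ``duration_ms`` (ms) attributes,
        e.g. a :class:`~maculasum.synthetic_cohort.StimulusSpec`.
    density
        Local parasol-OFF RGC density in cells/deg^2.
    convergence
        Cone-to-RGC convergence ratio (cones per RGC) at the location.
    """
    area = float(stimulus.area_deg2)
    duration = float(stimulus.duration_ms)
    for name, v in (("area", area), ("duration", duration),
                    ("density", density), ("convergence", convergence)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return RetinalInput(area * duration * float(density) * float(convergence))


def template_sensitivity(input_db, params: TemplateParameters):
    """Sensitivity (dB) predicted by the template at a retinal input (dB).

    ``S(u) = 10*alpha + x - 10*(1 - 1/kappa)*log10(1 + 10^(x/10))`` with
    ``x = u - 10*log10_tau``.  Strictly increasing in ``u``; the local slope
    decreases smoothly from 1 (complete summation, ``u << tau``) to
    ``1/kappa`` (partial summation, ``u >> tau``).
    """
    u = np.asarray(input_db, dtype=float)
    x = u - 10.0 * params.log10_tau
    # log10(1 + 10^(x/10)) computed stably via logaddexp
    soft = np.logaddexp(0.0, x * (np.log(10.0) / 10.0)) / np.log(10.0)
    s = 10.0 * params.alpha + x - 10.0 * (1.0 - 1.0 / params.kappa) * soft
    if np.isscalar(input_db):
        return float(s)
    return s


def template_slope(input_db, params: TemplateParameters):
    """Analytic local dB/dB slope of the template at ``input_db``."""
    u = np.asarray(input_db, dtype=float)
    x = u - 10.0 * params.log10_tau
    sig = 1.0 / (1.0 + np.power(10.0, -x / 10.0))
    out = 1.0 - (1.0 - 1.0 / params.kappa) * sig
    if np.isscalar(input_db):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Least-squares calibration of the template on young-healthy data."""

    params: TemplateParameters
    objective: float          # residual sum of squares, dB^2
    rmse: float               # residual RMSE, dB
    n_obs: int
    converged: bool
    ci: dict[str, tuple[float, float]] | None = None
    n_boot: int = 0
    seed: int | None = None
    weakly_identified: list[str] = field(default_factory=list)


def _sse(theta: np.ndarray, u: np.ndarray, s: np.ndarray) -> float:
    alpha, log10_tau, kappa = theta
    if kappa <= 1.0:
        return np.inf
    x = u - 10.0 * log10_tau
    soft = np.logaddexp(0.0, x * (np.log(10.0) / 10.0)) / np.log(10.0)
    pred = 10.0 * alpha + x - 10.0 * (1.0 - 1.0 / kappa) * soft
    r = s - pred
    return float(r @ r)


def _initial_guess(u: np.ndarray, s: np.ndarray) -> np.ndarray:
    log10_tau0 = float(np.median(u)) / 10.0
    kappa0 = 2.5
    # set alpha so the curve passes through the data mean
    x = u - 10.0 * log10_tau0
    soft = np.logaddexp(0.0, x * (np.log(10.0) / 10.0)) / np.log(10.0)
    alpha0 = float(np.mean(s - x + 10.0 * (1.0 - 1.0 / kappa0) * soft)) / 10.0
    return np.array([alpha0, log10_tau0, kappa0])


def calibrate_template(
    young_data: pd.DataFrame,
    *,
    n_starts: int = 6,
    seed: int = 0,
    xatol: float = 1e-8,
) -> CalibrationResult:
    """Fit (alpha, log10_tau, kappa) by multistart Nelder-Mead least squares.

    ``young_data`` needs columns ``retinal_input_db`` and ``sensitivity_db``;
    censored rows (column ``censored`` truthy) are excluded -- healthy data
    should contain none or very few.
    """
    df = young_data
    if "censored" in df.columns:
        df = df.loc[df["censored"].astype(int) == 0]
    u = df["retinal_input_db"].to_numpy(dtype=float)
    s = df["sensitivity_db"].to_numpy(dtype=float)
    if u.size < 3:
        raise ValueError("calibration needs at least as many observations as parameters")
    if np.unique(np.round(u, 9)).size < 3:
        raise ValueError("calibration needs >= 3 distinct retinal-input levels")

    theta0 = _initial_guess(u, s)
    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(max(0, n_starts - 1)):
        pert = 1.0 + 0.2 * rng.uniform(-1.0, 1.0, size=3)
        starts.append(theta0 * pert)

    best = None
    any_converged = False
    for start in starts:
        res = minimize(
            _sse, start, args=(u, s), method="Nelder-Mead",
            options={"xatol": xatol, "fatol": xatol, "maxiter": 4000},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("calibration failed to converge from every start")

    params = TemplateParameters(*best.x)
    sse = float(best.fun)
    return CalibrationResult(
        params=params,
        objective=sse,
        rmse=float(np.sqrt(sse / u.size)),
        n_obs=int(u.size),
        converged=any_converged,
        seed=seed,
    )


#: bootstrap CI width (per parameter) beyond which a parameter is flagged as
#: weakly identified, e.g. kappa when no data lie on the partial limb
WEAK_ID_CI_WIDTH = 2.0


def bootstrap_parameters(
    young_data: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    *,
    eye_col: str = "eye_id",
    n_starts: int = 3,
) -> CalibrationResult:
    """Eye-level bootstrap percentile CIs (2.5-97.5%) for the template parameters.

    Eyes -- not observations -- are resampled with replacement, preserving the
    within-eye correlation structure.  Returns the point-estimate calibration
    augmented with per-parameter intervals.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    eyes = young_data[eye_col].unique()
    if eyes.size < 2:
        raise ValueError("eye-level bootstrap needs >= 2 eyes")

    point = calibrate_template(young_data, seed=seed, n_starts=n_starts)
    rng = np.random.default_rng(seed)
    groups = {e: g for e, g in young_data.groupby(eye_col)}
    draws = np.empty((B, 3))
    for b in range(B):
        chosen = rng.choice(eyes, size=eyes.size, replace=True)
        sample = pd.concat([groups[e] for e in chosen], ignore_index=True)
        try:
            fit = calibrate_template(sample, seed=seed + 1 + b, n_starts=n_starts)
            draws[b] = fit.params.as_array()
        except (ValueError, RuntimeError):
            draws[b] = np.nan

    ok = ~np.isnan(draws).any(axis=1)
    lo, hi = np.nanpercentile(draws[ok], [2.5, 97.5], axis=0)
    names = ["alpha", "log10_tau", "kappa"]
    ci = {n: (float(l), float(h)) for n, l, h in zip(names, lo, hi)}
    point.ci = ci
    point.n_boot = int(ok.sum())
    point.weakly_identified = [
        n for n, (l, h) in ci.items() if (h - l) > WEAK_ID_CI_WIDTH
    ]
    return point
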