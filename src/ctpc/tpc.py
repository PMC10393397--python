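"""Sharpe-Schoolfield cardiac thermal performance curves and trait extraction.

The cardiac thermal performance curve (cTPC) relates heart rate (bpm) to body
temperature during an acute heating ramp. It is described here with the
high-temperature-inactivation form of the Sharpe-Schoolfield model,

    r(T) = r_tref * exp(-E/k * (1/T - 1/Tref)) / (1 + exp(Eh/k * (1/Th - 1/T)))

with T in Kelvin, k the Boltzmann constant (eV/K), E the activation energy
(eV, the "slope gradient" trait), Eh the deactivation energy (eV), Th the
temperature (K) at which the rate-limiting process is half-inactivated, and
r_tref the rate at the fixed reference temperature Tref. When Eh > E > 0 the
curve is unimodal with a single interior optimum.

Five per-individual thermal traits are derived from a fitted curve and the
flatline call of :mod:`ctpc.cardiotrace`:

* slope gradient — the activation energy E (eV);
* slope curvature — 2*c2 from a quadratic fit to the upslope (T < Topt);
* HRmax — the fitted maximum heart rate (bpm);
* Topt — the temperature maximizing the fitted curve (deg C);
* ULT — the upper lethal temperature, where the heartbeat flatlines (deg C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .cardiotrace import FlatlineCall, HeartRateSeries

#: Boltzmann constant in eV / K.
K_BOLTZ = 8.617333e-5

#: Reference temperature of the parameterization (deg C). Fixed at the ramp
#: start so that r_tref is identifiable as the rate at the coolest assay
#: temperature.
TREF_C = 30.0

CELSIUS_TO_KELVIN = 273.15


@dataclass(frozen=True)
class SSParams:
    """Parameters of the Sharpe-Schoolfield curve.

    Attributes
    ----------
    r_tref : float
        Rate (bpm) at the reference temperature ``tref_C``.
    E : float
        Activation energy, eV. Must satisfy ``Eh > E > 0``.
    Eh : float
        High-temperature deactivation energy, eV.
    Th : float
        Half-inactivation temperature, Kelvin.
    tref_C : float
        Reference temperature in deg C (fixed constant, not fitted).
    """

    r_tref: float
    E: float
    Eh: float
    Th: float
    tref_C: float = TREF_C

    def __post_init__(self) -> None:
        if not self.r_tref > 0:
            raise ValueError(f"r_tref must be positive, got {self.r_tref}")
        if not (self.Eh > self.E > 0):
            raise ValueError(
                f"require Eh > E > 0 for a unimodal curve, got E={self.E}, Eh={self.Eh}"
            )


@dataclass(frozen=True)
class PolynomialUpslopeFit:
    """Quadratic fit HR = c0 + c1*T + c2*T^2 to the upslope (T < Topt)."""

    c0: float
    c1: float
    c2: float
    n_points: int

    @property
    def curvature(self) -> float:
        """Second derivative of the quadratic: 2*c2 (bpm / degC^2)."""
        return 2.0 * self.c2


@dataclass
class SSFit:
    """Result of a multi-start nonlinear least-squares Sharpe-Schoolfield fit."""

    params: Optional[SSParams]
    rss: float
    fit_ok: bool
    n_points: int
    n_starts: int
    message: str = ""


@dataclass
class CardiacTraits:
    """The five thermal traits for one individual, plus fit diagnostics."""

    slope_gradient: Optional[float]  # eV
    slope_curvature: Optional[float]  # bpm / degC^2
    hr_max: Optional[float]  # bpm
    t_opt: Optional[float]  # deg C
    ult: Optional[float]  # deg C
    fit_ok: bool
    rss: float = float("nan")
    meta: dict = field(default_factory=dict)


def ss_rate(params: SSParams, temp_C) -> np.ndarray:
    """Sharpe-Schoolfield rate (bpm) at temperature(s) in deg C."""
    T = np.asarray(temp_C, dtype=float) + CELSIUS_TO_KELVIN
    Tref = params.tref_C + CELSIUS_TO_KELVIN
    arrhenius = np.exp(-params.E / K_BOLTZ * (1.0 / T - 1.0 / Tref))
    inactivation = 1.0 + np.exp(params.Eh / K_BOLTZ * (1.0 / params.Th - 1.0 / T))
    out = params.r_tref * arrhenius / inactivation
    return out if out.ndim else float(out)


def topt_closed_form(params: SSParams) -> float:
    """Closed-form optimum temperature (deg C) of the curve.

    For the high-temperature-inactivation parameterization the maximizer is

        Topt(K) = Eh * Th / (Eh + k * Th * ln(Eh/E - 1)).
    """
    ratio = params.Eh / params.E - 1.0
    if ratio <= 0:
        raise ValueError("closed-form Topt requires Eh > E")
    topt_K = params.Eh * params.Th / (
        params.Eh + K_BOLTZ * params.Th * math.log(ratio)
    )
    return topt_K - CELSIUS_TO_KELVIN


def _fit_points(
    series: HeartRateSeries, flatline: Optional[FlatlineCall]
) -> tuple[np.ndarray, np.ndarray]:
    """Windows used for fitting: positive rate, before any flatline onset."""
    keep = series.hr_bpm > 0
    if flatline is not None:
        keep &= series.t_start < flatline.onset_time
    return series.temp_mid[keep], series.hr_bpm[keep]


def fit_ss(
    series: HeartRateSeries,
    n_starts: int = 20,
    seed: int = 0,
    flatline: Optional[FlatlineCall] = None,
) -> SSFit:
    """Fit the Sharpe-Schoolfield curve by multi-start bounded least squares.

    Flatlined windows (at or after ``flatline.onset_time``) and zero-rate
    windows are excluded: a dead heart is a different regime, not low
    performance. Starts are drawn from wide uniform boxes (E in [0.1, 2] eV,
    Eh in [1, 10] eV, Th spanning the observed temperature range) and the
    best-of-starts solution by residual sum of squares is returned; fits that
    land on Eh <= E (no interior optimum) are discarded.
    """
    temp, hr = _fit_points(series, flatline)
    if temp.size < 6:
        return SSFit(None, float("nan"), False, int(temp.size), n_starts,
                     "fewer than 6 usable windows")
    if hr.std() < 1e-3 * max(float(hr.mean()), 1.0):
        return SSFit(None, float("nan"), False, int(temp.size), n_starts,
                     "degenerate: constant-rate series")

    rng = np.random.default_rng(seed)
    t_K = temp + CELSIUS_TO_KELVIN
    hr_max_obs = float(hr.max())
    r0 = float(hr[np.argmin(np.abs(temp - TREF_C))])

    lo = np.array([1e-3, 0.05, 0.5, t_K.min() - 20.0])
    hi = np.array([5.0 * hr_max_obs, 3.0, 15.0, t_K.max() + 20.0])

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = theta
        arr = np.exp(-p[1] / K_BOLTZ * (1.0 / t_K - 1.0 / (TREF_C + CELSIUS_TO_KELVIN)))
        inact = 1.0 + np.exp(p[2] / K_BOLTZ * (1.0 / p[3] - 1.0 / t_K))
        return p[0] * arr / inact - hr

    best = None
    for _ in range(n_starts):
        start = np.array([
            max(r0 * rng.uniform(0.5, 1.5), 1e-2),
            rng.uniform(0.1, 2.0),
            rng.uniform(1.0, 10.0),
            rng.uniform(t_K.min(), t_K.max()),
        ])
        start = np.clip(start, lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(residuals, start, bounds=(lo, hi), method="trf")
        except Exception:  # pragma: no cover - defensive
            continue
        if not sol.success:
            continue
        r_tref, E, Eh, Th = sol.x
        if Eh <= E:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[1]:
            best = (SSParams(r_tref, E, Eh, Th), rss)

    if best is None:
        return SSFit(None, float("nan"), False, int(temp.size), n_starts,
                     "all starts failed or degenerate")
    return SSFit(best[0], best[1], True, int(temp.size), n_starts, "converged")


def upslope_curvature(
    series: HeartRateSeries, topt: float
) -> Optional[PolynomialUpslopeFit]:
    """OLS quadratic on windows cooler than Topt; None if fewer than 3 points."""
    keep = series.temp_mid < topt
    t, hr = series.temp_mid[keep], series.hr_bpm[keep]
    if t.size < 3:
        return None
    c2, c1, c0 = np.polyfit(t, hr, 2)
    return PolynomialUpslopeFit(float(c0), float(c1), float(c2), int(t.size))


def extract_traits(
    fit: SSFit,
    series: HeartRateSeries,
    flatline: Optional[FlatlineCall] = None,
    grid_step: float = 0.01,
) -> CardiacTraits:
    """Extract the five thermal traits from a fitted curve.

    Topt is the argmax of the fitted curve on a ``grid_step`` grid restricted
    to the observed (pre-flatline) temperature range; HRmax is the fitted rate
    there. The ULT comes from the flatline call and is absent when no flatline
    was observed — the remaining traits are still returned.
    """
    if not fit.fit_ok or fit.params is None:
        return CardiacTraits(None, None, None, None,
                             flatline.ULT if flatline else None,
                             False, fit.rss)
    temp, _ = _fit_points(series, flatline)
    grid = np.arange(temp.min(), temp.max() + grid_step, grid_step)
    rates = ss_rate(fit.params, grid)
    i = int(np.argmax(rates))
    t_opt = float(grid[i])
    hr_max = float(rates[i])
    poly = upslope_curvature(series, t_opt)
    return CardiacTraits(
        slope_gradient=fit.params.E,
        slope_curvature=poly.curvature if poly is not None else None,
        hr_max=hr_max,
        t_opt=t_opt,
        ult=flatline.ULT if flatline is not None else None,
        fit_ok=True,
        rss=fit.rss,
    )
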