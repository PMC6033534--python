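"""Biexponential decay of vaccine-induced antigen-specific T_SCM frequencies.

Cross-sectional tetramer measurements of yellow-fever-vaccine (YF-17D)
specific CD8+ T_SCM cells, taken once per subject at widely varying times
since vaccination, are described by a two-component exponential decay

    F(t) = A * ( r e^{-alpha t} + (1 - r) e^{-beta t} ),   t in years,

the natural observable of the explicit two-subpopulation kinetic model:
each vaccine-induced clonal burst splits between a fast subpopulation
(weight ``r = 1 - f``, decay ``alpha``) and a slow one (weight ``f``,
decay ``beta``), each decaying at its net clonal loss rate
``(d_si - p_si)`` converted to per-year.  ``A`` scales the initial
frequency (fraction of CD8+CD16- lymphocytes) and is a free cohort-level
parameter.

Residuals for this data type are computed on log10(frequency), since
observations span several orders of magnitude over ~35 years; values
below a configurable detection limit are treated as left-censored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .label_models import DAYS_PER_YEAR, ExplicitModelParams

__all__ = [
    "YfvDecayParams",
    "YfvCohort",
    "yfv_frequency",
    "link_explicit_to_yfv",
    "fit_yfv",
]


@dataclass(frozen=True)
class YfvDecayParams:
    """Biexponential decay parameters; fast component listed first (alpha >= beta_y)."""

    r: float
    alpha: float
    beta_y: float
    A: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r <= 1.0):
            raise ValueError(f"r must be in [0, 1], got {self.r}")
        if self.alpha < 0 or self.beta_y < 0:
            raise ValueError("decay rates must be >= 0")
        if self.alpha < self.beta_y:
            raise ValueError(
                f"convention requires alpha >= beta_y (fast first), got {self.alpha} < {self.beta_y}"
            )
        if self.A <= 0:
            raise ValueError(f"A must be > 0, got {self.A}")


@dataclass(frozen=True)
class YfvCohort:
    """Cross-sectional cohort: one (time-since-vaccination, frequency) per subject."""

    times_years: np.ndarray
    frequency: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_years, dtype=float)
        y = np.asarray(self.frequency, dtype=float)
        object.__setattr__(self, "times_years", t)
        object.__setattr__(self, "frequency", y)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("times_years and frequency must be 1-D and of equal length")
        if np.any(t <= 0):
            raise ValueError("times since vaccination must be > 0")
        if np.any(y < 0):
            raise ValueError("frequencies must be >= 0")

    def __len__(self) -> int:
        return int(self.times_years.size)


def yfv_frequency(t, params: YfvDecayParams):
    """Predicted antigen-specific T_SCM frequency at t years post-vaccination."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    out = params.A * (
        params.r * np.exp(-params.alpha * t_arr)
        + (1.0 - params.r) * np.exp(-params.beta_y * t_arr)
    )
    return out if out.ndim else float(out)


def link_explicit_to_yfv(params: ExplicitModelParams, A: float = 1.0) -> YfvDecayParams:
    """Map explicit-model kinetics onto the biexponential decay.

    Decay rates are the subpopulation net clonal loss rates converted to
    per-year; the fast-component weight is the burst fraction entering
    subpopulation 1, ``r = 1 - f`` (each vaccine-induced clone is assumed
    to split like a naive-derived burst).  Components are reordered if
    needed so the faster one carries ``alpha``.
    """
    a = params.dnet1 * DAYS_PER_YEAR
    b = params.dnet2 * DAYS_PER_YEAR
    r = 1.0 - params.f
    if a < b:
        a, b, r = b, a, 1.0 - r
    return YfvDecayParams(r=r, alpha=a, beta_y=b, A=A)


def fit_yfv(
    cohort: YfvCohort,
    detection_limit: float | None = None,
    rate_bounds: tuple[float, float] = (1e-3, 1e3),
) -> tuple[YfvDecayParams, float]:
    """Least-squares fit of the biexponential on log10(frequency).

    Returns the fitted parameters (normalised so ``alpha >= beta_y``) and
    the SSR on the log10 scale.  Observations at or below the detection
    limit contribute a residual only when the prediction exceeds the
    limit (left-censoring).  A deterministic grid of starts is polished
    by bounded least squares.
    """
    t, y = cohort.times_years, cohort.frequency
    floor = detection_limit if detection_limit is not None else max(1e-12, np.min(y[y > 0], initial=1e-12) * 1e-3)
    obs = np.log10(np.maximum(y, floor))
    censored = y <= floor if detection_limit is not None else np.zeros_like(y, dtype=bool)
    lo_r, hi_r = np.log10(rate_bounds[0]), np.log10(rate_bounds[1])

    def resid(x):
        lA, r, la, lb = x
        pred = (10.0**lA) * (r * np.exp(-(10.0**la) * t) + (1.0 - r) * np.exp(-(10.0**lb) * t))
        res = np.log10(np.maximum(pred, 1e-300)) - obs
        if censored.any():
            res = np.where(censored & (res < 0), 0.0, res)
        return res

    lA0 = float(np.log10(max(np.max(y), floor)))
    best = None
    for la0, lb0 in ((0.3, -1.0), (0.0, -0.7), (1.0, -1.5)):
        sol = least_squares(
            resid,
            x0=[lA0, 0.7, la0, lb0],
            bounds=([-12.0, 0.0, lo_r, lo_r], [0.0, 1.0, hi_r, hi_r]),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    lA, r, la, lb = best.x
    a, b = 10.0**la, 10.0**lb
    if a < b:
        a, b, r = b, a, 1.0 - r
    params = YfvDecayParams(r=float(r), alpha=float(a), beta_y=float(b), A=float(10.0**lA))
    return params, float(2.0 * best.cost)
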