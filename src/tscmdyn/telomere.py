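"""Division-counting telomere model for the naive -> T_SCM pathway.

Each cell division removes ``delta_bp`` base pairs (default 50 bp, within
the reported 35-70 bp/division range) from mean telomere length, so the
difference in mean divisional history between pools is observable as a
telomere-length difference.  With ``mu`` the mean number of divisions in
a pool, the one-pool model gives

    d(mu_TN)/dt   = 2 p_n
    d(mu_TSCM)/dt = 2 p_s - Delta 2^k (T_N / T_SCM) (mu_TSCM - mu_TN - C)

where ``C`` (0 <= C <= k) is the number of burst divisions whose telomere
cost is *not* compensated by telomerase (C = 0: full compensation during
clonal expansion; C = k: none).  The observable is

    Theta := delta_bp * (mu_TSCM - mu_TN)        [bp]

whose dynamics are a scalar linear ODE relaxing at rate
``Delta 2^k T_N / T_SCM`` to the steady state

    Theta_ss = C delta_bp + (p_s - p_n) delta_bp * T_SCM / (2^(k-1) Delta T_N).

The explicit two-subpopulation analogue applies the same pattern per
subpopulation, combining them as the steady-state-size-weighted mean.
A brute-force division-indexed compartment integrator (cells binned by
divisions undergone) is included as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .label_models import ExplicitModelParams, ImplicitModelParams

__all__ = [
    "TelomereParams",
    "ThetaObservation",
    "ThetaTrajectory",
    "OracleTheta",
    "theta_steady_state",
    "theta_dynamics",
    "theta_transient",
    "theta_explicit",
    "theta_explicit_transient",
    "theta_compartment_oracle",
]


@dataclass(frozen=True)
class TelomereParams:
    """Base pairs lost per division and telomerase compensation.

    ``delta_bp`` outside the reported 35-70 bp/division range is rejected;
    ``C`` must satisfy ``0 <= C <= k`` for the model it is paired with
    (checked at use, since k lives on the kinetic parameter set).
    """

    delta_bp: float = 50.0
    C: float = 0.0

    def __post_init__(self) -> None:
        if not (35.0 <= self.delta_bp <= 70.0):
            raise ValueError(
                f"delta_bp must lie in the plausible range [35, 70] bp, got {self.delta_bp}"
            )
        if self.C < 0:
            raise ValueError(f"C must be >= 0, got {self.C}")


@dataclass(frozen=True)
class ThetaObservation:
    """Measured mean telomere-length difference Theta = delta*(mu_TSCM - mu_TN).

    Positive when T_SCM cells have divided more than naive cells.
    """

    theta: float
    sd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.theta):
            raise ValueError("theta must be finite")
        if not (self.sd > 0):
            raise ValueError(f"measurement sd must be > 0, got {self.sd}")


def _check_C(C: float, k: int) -> None:
    if C > k:
        raise ValueError(f"telomerase compensation C={C} exceeds burst size k={k}")


def theta_steady_state(params: ImplicitModelParams, telo: TelomereParams) -> float:
    """Closed-form steady-state Theta (bp) of the one-pool model."""
    _check_C(telo.C, params.k)
    dr = params.delta_ratio
    if dr == 0:
        raise ZeroDivisionError("steady-state Theta undefined for Delta * ratio_NS = 0")
    return telo.C * telo.delta_bp + (params.p_s - params.p_n) * telo.delta_bp / (
        2.0 ** (params.k - 1) * dr
    )


@dataclass
class ThetaTrajectory:
    times: np.ndarray
    theta: np.ndarray
    theta_ss: float
    converged: bool

    @property
    def final(self) -> float:
        return float(self.theta[-1])


def theta_dynamics(
    params: ImplicitModelParams,
    telo: TelomereParams,
    t_span: tuple[float, float],
    theta0: float = 0.0,
    n_eval: int = 200,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    convergence_rtol: float = 1e-6,
) -> ThetaTrajectory:
    """Numerically integrate the Theta ODE and report convergence to steady state."""
    _check_C(telo.C, params.k)
    dr = params.delta_ratio
    lam = dr * 2.0**params.k  # relaxation rate, per day
    drive = 2.0 * (params.p_s - params.p_n) * telo.delta_bp

    def rhs(t, y):
        return [drive - lam * (y[0] - telo.C * telo.delta_bp)]

    t_eval = np.linspace(t_span[0], t_span[1], n_eval)
    sol = solve_ivp(rhs, t_span, [theta0], t_eval=t_eval, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"Theta integration failed: {sol.message}")
    ss = theta_steady_state(params, telo) if dr > 0 else np.nan
    final = float(sol.y[0, -1])
    scale = max(abs(ss), telo.delta_bp)
    converged = bool(np.isfinite(ss) and abs(final - ss) <= convergence_rtol * scale)
    return ThetaTrajectory(times=t_eval, theta=sol.y[0], theta_ss=float(ss), converged=converged)


def theta_transient(params: ImplicitModelParams, telo: TelomereParams, t: float, theta0: float = 0.0) -> float:
    """Closed-form Theta(t) of the scalar linear ODE (implicit/homogeneous model)."""
    _check_C(telo.C, params.k)
    lam = params.delta_ratio * 2.0**params.k
    ss = theta_steady_state(params, telo)
    return float(ss + (theta0 - ss) * np.exp(-lam * t))


def theta_explicit(params: ExplicitModelParams, telo: TelomereParams) -> float:
    """Bulk steady-state Theta (bp) of the explicit two-subpopulation model.

    Each subpopulation obeys the one-pool steady state with its own input
    flux (``Delta (1-f)`` or ``Delta f``) and size; substituting the
    steady-state size ties give

        Theta_i = C delta_bp + 2 (p_si - p_n) delta_bp / (d_si - p_si),

    combined as the size-weighted mean (one sorter gate measures the bulk).
    """
    _check_C(telo.C, params.k)
    th1 = telo.C * telo.delta_bp + 2.0 * (params.p_s1 - params.p_n) * telo.delta_bp / params.dnet1
    th2 = telo.C * telo.delta_bp + 2.0 * (params.p_s2 - params.p_n) * telo.delta_bp / params.dnet2
    w2 = params.relative_size_2
    return float((1.0 - w2) * th1 + w2 * th2)


def theta_explicit_transient(
    params: ExplicitModelParams, telo: TelomereParams, t: float
) -> float:
    """Closed-form bulk Theta(t) of the explicit model from Theta(0) = 0.

    Each subpopulation's Theta relaxes independently at its net clonal
    loss rate; the bulk observable is the size-weighted mean.
    """
    _check_C(telo.C, params.k)
    w2 = params.relative_size_2
    out = 0.0
    for w, ps, dnet in (
        (1.0 - w2, params.p_s1, params.dnet1),
        (w2, params.p_s2, params.dnet2),
    ):
        ss = telo.C * telo.delta_bp + 2.0 * (ps - params.p_n) * telo.delta_bp / dnet
        out += w * ss * (1.0 - np.exp(-dnet * t))
    return float(out)


# ---------------------------------------------------------------------------
# division-indexed compartment oracle
# ---------------------------------------------------------------------------


@dataclass
class OracleTheta:
    """Result of the brute-force division-indexed compartment integration."""

    theta: float
    t_end: float
    at_steady_state: bool  # True when t_end reached >= 15 relaxation times


def theta_compartment_oracle(
    params: ImplicitModelParams | ExplicitModelParams,
    telo: TelomereParams,
    n_classes: int = 200,
    t_end: float | None = None,
    tail_tol: float = 1e-9,
) -> OracleTheta:
    """Brute-force Theta via cells binned by number of divisions undergone.

    Integrates the full compartment system (naive and T_SCM cells indexed
    by divisions, truncated at ``n_classes`` classes) to ``t_end`` and
    returns ``delta_bp * (mean divisions T_SCM - mean divisions naive)``
    at that time.  Independent of the mean-division closed forms above;
    requires integer ``C``.  The naive disappearance rate is tied to
    ``p_n - Delta`` so that pool sizes are stationary.

    Because mean divisional age grows linearly without bound, the default
    ``t_end`` is capped so the truncated tail stays below ``tail_tol``;
    compare against :func:`theta_transient` /
    :func:`theta_explicit_transient` at ``.t_end`` when
    ``.at_steady_state`` is False.  Raises if the tail check fails.
    """
    C = int(round(telo.C))
    if C != telo.C:
        raise ValueError("compartment oracle requires integer telomerase compensation C")
    _check_C(C, params.k)
    twok = 2.0**params.k

    if isinstance(params, ImplicitModelParams):
        fluxes = [params.delta_ratio]  # Delta * T_N / T_SCM_i, with sizes folded in
        losses = [params.d_s]
        prolifs = [params.p_s]
        sizes = [1.0]
        # represent T_N with unit size; influx into pool i is flux_i * 2^k
    else:
        fluxes = [
            params.Delta * (1.0 - params.f) / params.size1_over_TN,
            params.Delta * params.f / params.size2_over_TN,
        ]
        losses = [params.d_s1, params.d_s2]
        prolifs = [params.p_s1, params.p_s2]
        s1, s2 = params.size1_over_TN, params.size2_over_TN
        sizes = [s1 / (s1 + s2), s2 / (s1 + s2)]

    n_pools = len(fluxes)
    lam = min(f * twok for f in fluxes)  # slowest Theta relaxation rate
    if t_end is None:
        # cap integration time so mean divisional age (growing ~ 2 p_n t)
        # plus a generous spread allowance stays inside the truncation
        offsets = [
            C + max(0.0, 2.0 * (ps - params.p_n)) / (fl * twok)
            for ps, fl in zip(prolifs, fluxes)
        ]
        s_max = (-10.0 + math.sqrt(100.0 + 4.0 * (0.9 * n_classes + 1.0))) / 2.0
        mu_cap = s_max**2 - 1.0
        head = mu_cap - max(offsets)
        if head <= 0:
            raise ValueError(
                "division classes too few for these rates; increase n_classes"
            )
        t_cap = head / (2.0 * params.p_n) if params.p_n > 0 else math.inf
        t_end = min(20.0 / lam, t_cap)

    n = n_classes
    p_n = params.p_n
    # naive per-class loss coefficient (p_n + Delta + d_n) with the stationary
    # tie d_n = p_n - Delta collapses to 2 p_n, keeping sum(T_N) constant
    naive_loss = 2.0 * p_n

    def rhs(t, y):
        dy = np.empty_like(y)
        TN = y[:n]
        dTN = np.empty(n)
        dTN[0] = -naive_loss * TN[0]
        dTN[1:] = 2.0 * p_n * TN[:-1] - naive_loss * TN[1:]
        dy[:n] = dTN
        for j in range(n_pools):
            TS = y[n * (j + 1) : n * (j + 2)]
            dTS = np.empty(n)
            ps, ds = prolifs[j], losses[j]
            dTS[0] = -(ps + ds) * TS[0]
            dTS[1:] = 2.0 * ps * TS[:-1] - (ps + ds) * TS[1:]
            # absolute influx from naive class i into T_SCM class i + C:
            # Delta_j 2^k T_N,i = (flux_j * 2^k * size_j) * TN_i in these units
            dTS[C:] += fluxes[j] * twok * sizes[j] * TN[: n - C]
            dy[n * (j + 1) : n * (j + 2)] = dTS
        return dy

    y0 = np.zeros(n * (1 + n_pools))
    y0[0] = 1.0  # all naive cells start in division class 0
    for j in range(n_pools):
        y0[n * (j + 1)] = sizes[j]
    # non-stiff: all per-capita rates are <= ~0.05/day
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="DOP853", rtol=1e-10, atol=1e-14)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"compartment integration failed: {sol.message}")
    y = sol.y[:, -1]
    idx = np.arange(n)
    TN = y[:n]
    mu_N = float(idx @ TN / TN.sum())
    total_S = 0.0
    weighted = 0.0
    tail = TN[-1] / TN.sum()
    for j in range(n_pools):
        TS = y[n * (j + 1) : n * (j + 2)]
        tail = max(tail, TS[-1] / TS.sum())
        total_S += TS.sum()
        weighted += float(idx @ TS)
    if tail > tail_tol:
        raise RuntimeError(
            f"compartment truncation tail mass {tail:.2e} exceeds {tail_tol:.0e}; "
            "increase n_classes or reduce t_end"
        )
    mu_S = weighted / total_S
    return OracleTheta(
        theta=float(telo.delta_bp * (mu_S - mu_N)),
        t_end=float(t_end),
        at_steady_state=bool(lam * t_end >= 15.0),
    )
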