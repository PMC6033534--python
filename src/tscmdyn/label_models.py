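"""Deterministic ODE models of deuterium-label kinetics in naive and T_SCM pools.

The models describe a linear differentiation pathway: naive T cells (T_N)
proliferate at rate ``p_n`` and are recruited into the stem cell-like
memory pool (T_SCM) at per-capita rate ``Delta``, each recruited cell
undergoing a clonal burst of ``k`` divisions (2^k T_SCM cells per naive
cell).  T_SCM cells self-renew at rate ``p_s`` and disappear (die or
differentiate onward) at rate ``d_s``.  Labelling experiments measure the
fraction F of deoxyadenosine nucleosides in sorted-cell DNA carrying
deuterium; at population steady state the fractions obey linear ODEs
driven by body-water enrichment U(t):

    dF_TN/dt   = p_n (c U(t) - F_TN)
    dF_TSCM/dt = (Delta T_N / T_SCM) ((2^k - 1) c U(t) + F_TN)
                 + p_s c U(t) - ds_star F_TSCM

``c`` is the subject-level amplification factor between body-water and DNA
enrichment.  Setting the disappearance rate of *labelled* T_SCM DNA
``ds_star`` equal to the bulk rate ``d_s = 2^k Delta T_N/T_SCM + p_s``
gives the *homogeneous* model; leaving ``ds_star`` free gives the
*implicit heterogeneity* model (label loss may outpace uptake when fast
subpopulations dominate the labelled cells).  The *explicit* model splits
T_SCM into two kinetically distinct subpopulations, a fraction ``f`` of
each clonal burst entering the second (slow) subpopulation.

Because the fraction equations are linear with piecewise-exponential
forcing, the default solver augments the state vector with the forcing
exponential and evaluates the exact matrix exponential at each requested
time.  ``method="ivp"`` (adaptive LSODA, rtol 1e-8 / atol 1e-10) and a
brute-force fixed-step Euler integrator are provided as independent
cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .water import BodyWaterParams, eval_U

__all__ = [
    "DAYS_PER_YEAR",
    "ImplicitModelParams",
    "ExplicitModelParams",
    "LabelCurvePrediction",
    "solve_label_implicit",
    "solve_label_explicit",
    "solve_label_euler",
    "solve_label_euler_batch",
    "derived_bulk_rates",
]

DAYS_PER_YEAR = 365.25

K_MAX = 20  # clonal bursts above 20 divisions are not biologically plausible


def _check_rate(name: str, value: float, allow_zero: bool = True) -> None:
    if value < 0 or (not allow_zero and value == 0):
        raise ValueError(f"{name} must be {'>= 0' if allow_zero else '> 0'}, got {value}")


def _check_k(k: int) -> None:
    if int(k) != k or not (0 <= k <= K_MAX):
        raise ValueError(f"k must be an integer in [0, {K_MAX}], got {k}")


@dataclass(frozen=True)
class ImplicitModelParams:
    """Parameters of the one-pool (homogeneous / implicit-heterogeneity) model.

    ``Delta`` and the pool-size ratio ``ratio_NS = T_N / T_SCM`` enter the
    fraction equations only through their product ``delta_ratio``; fits
    parameterise that product directly (``ratio_NS = 1``).

    ``ds_star=None`` selects the homogeneous variant, in which the
    labelled-DNA disappearance rate equals the bulk steady-state rate
    ``d_s = 2^k * delta_ratio + p_s``.  ``dn_star=None`` keeps the naive
    pool homogeneous (labelled naive loss rate ``p_n``); a value relaxes
    that assumption.
    """

    p_n: float
    p_s: float
    Delta: float
    ratio_NS: float = 1.0
    k: int = 5
    c: float = 1.0
    ds_star: float | None = None
    dn_star: float | None = None

    def __post_init__(self) -> None:
        _check_rate("p_n", self.p_n)
        _check_rate("p_s", self.p_s)
        _check_rate("Delta", self.Delta)
        if self.ratio_NS <= 0:
            raise ValueError(f"ratio_NS must be > 0, got {self.ratio_NS}")
        _check_k(self.k)
        if self.c <= 0:
            raise ValueError(f"c must be > 0, got {self.c}")
        if self.ds_star is not None:
            _check_rate("ds_star", self.ds_star)
        if self.dn_star is not None:
            _check_rate("dn_star", self.dn_star)

    @property
    def delta_ratio(self) -> float:
        """Delta * T_N / T_SCM (per day)."""
        return self.Delta * self.ratio_NS

    @property
    def d_s(self) -> float:
        """Bulk T_SCM disappearance rate from the steady-state constraint."""
        return 2.0**self.k * self.delta_ratio + self.p_s

    @property
    def ds_star_resolved(self) -> float:
        return self.d_s if self.ds_star is None else self.ds_star

    @property
    def dn_star_resolved(self) -> float:
        return self.p_n if self.dn_star is None else self.dn_star

    @property
    def is_homogeneous(self) -> bool:
        return self.ds_star is None


@dataclass(frozen=True)
class ExplicitModelParams:
    """Parameters of the two-subpopulation (explicit heterogeneity) model.

    Steady state of the population-size equations ties the pool-size
    ratios to the rates: ``Delta (1-f) 2^k T_N = (d_s1 - p_s1) T_SCM1``
    and ``Delta f 2^k T_N = (d_s2 - p_s2) T_SCM2``; both net loss rates
    must be positive for stationary subpopulations.  The fraction
    equations then depend on the rates only; ``Delta`` and ``f``
    additionally set absolute and relative pool sizes.
    """

    p_n: float
    p_s1: float
    d_s1: float
    p_s2: float
    d_s2: float
    f: float
    Delta: float = 1e-5
    k: int = 5
    c: float = 1.0
    dn_star: float | None = None

    def __post_init__(self) -> None:
        for name in ("p_n", "p_s1", "d_s1", "p_s2", "d_s2", "Delta"):
            _check_rate(name, getattr(self, name))
        _check_k(self.k)
        if self.c <= 0:
            raise ValueError(f"c must be > 0, got {self.c}")
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"f must be in [0, 1], got {self.f}")
        if self.d_s1 <= self.p_s1:
            raise ValueError(
                f"subpopulation 1 has no stationary size: d_s1={self.d_s1} <= p_s1={self.p_s1}"
            )
        if self.d_s2 <= self.p_s2:
            raise ValueError(
                f"subpopulation 2 has no stationary size: d_s2={self.d_s2} <= p_s2={self.p_s2}"
            )
        if self.dn_star is not None:
            _check_rate("dn_star", self.dn_star)

    @property
    def dnet1(self) -> float:
        """Net clonal loss rate d_s1 - p_s1 of the fast subpopulation (per day)."""
        return self.d_s1 - self.p_s1

    @property
    def dnet2(self) -> float:
        return self.d_s2 - self.p_s2

    @property
    def dn_star_resolved(self) -> float:
        return self.p_n if self.dn_star is None else self.dn_star

    # steady-state sizes relative to T_N -------------------------------
    @property
    def size1_over_TN(self) -> float:
        return self.Delta * (1.0 - self.f) * 2.0**self.k / self.dnet1

    @property
    def size2_over_TN(self) -> float:
        return self.Delta * self.f * 2.0**self.k / self.dnet2

    @property
    def relative_size_2(self) -> float:
        """T_SCM2 / (T_SCM1 + T_SCM2) at steady state, in (0, 1)."""
        s1, s2 = self.size1_over_TN, self.size2_over_TN
        return s2 / (s1 + s2)

    @property
    def half_life_1_years(self) -> float:
        return np.log(2.0) / self.dnet1 / DAYS_PER_YEAR

    @property
    def half_life_2_years(self) -> float:
        return np.log(2.0) / self.dnet2 / DAYS_PER_YEAR


@dataclass
class LabelCurvePrediction:
    """Predicted fractions of labelled dAs at the requested times."""

    times: np.ndarray
    F_TN: np.ndarray
    F_TSCM: np.ndarray
    F_TSCM1: np.ndarray | None = None
    F_TSCM2: np.ndarray | None = None


# ---------------------------------------------------------------------------
# matrix-exponential solver for the (linear) fraction equations
# ---------------------------------------------------------------------------


def _system(params) -> tuple[np.ndarray, np.ndarray]:
    """Coupling matrix A and forcing gains g: dF/dt = A F + g * c * U(t)."""
    if isinstance(params, ImplicitModelParams):
        dr = params.delta_ratio
        twok = 2.0**params.k
        A = np.array(
            [
                [-params.dn_star_resolved, 0.0],
                [dr, -params.ds_star_resolved],
            ]
        )
        g = np.array([params.p_n, dr * (twok - 1.0) + params.p_s])
    elif isinstance(params, ExplicitModelParams):
        twok = 2.0**params.k
        q1 = params.dnet1 / twok  # = Delta (1-f) T_N / T_SCM1
        q2 = params.dnet2 / twok
        A = np.array(
            [
                [-params.dn_star_resolved, 0.0, 0.0],
                [q1, -(params.dnet1 + params.p_s1), 0.0],
                [q2, 0.0, -(params.dnet2 + params.p_s2)],
            ]
        )
        g = np.array(
            [
                params.p_n,
                q1 * (twok - 1.0) + params.p_s1,
                q2 * (twok - 1.0) + params.p_s2,
            ]
        )
    else:  # pragma: no cover
        raise TypeError(f"unsupported parameter type {type(params)!r}")
    return A, g


def _check_times(times) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be ascending")
    return t


def _propagate(M: np.ndarray, y0: np.ndarray, dts: np.ndarray) -> np.ndarray:
    """y(dt) = expm(M dt) y0 for each dt, via eigendecomposition.

    Falls back to per-time ``expm`` when the eigenbasis is ill-conditioned
    (near-defective matrix, e.g. two rates numerically coincident).
    """
    if dts.size == 0:
        return np.empty((0, y0.size))
    lam, V = np.linalg.eig(M)
    # eigenvalue separation guard: coincident rates give a (near-)defective
    # eigenbasis, in which case fall back to the robust per-time expm
    gap = np.min(np.abs(lam[:, None] - lam[None, :]) + np.diag(np.full(lam.size, np.inf)))
    scale = np.max(np.abs(lam)) + 1e-300
    if gap > 1e-9 * scale:
        try:
            w = np.linalg.solve(V, y0.astype(complex))
            return (V @ (np.exp(np.outer(lam, dts)) * w[:, None])).real.T
        except np.linalg.LinAlgError:  # pragma: no cover
            pass
    return np.stack([expm(M * dt) @ y0 for dt in dts])


def _solve_expm(A: np.ndarray, g: np.ndarray, c: float, water: BodyWaterParams, times: np.ndarray) -> np.ndarray:
    """Exact solution via state augmentation with the forcing exponential.

    On [0, tau]:  U = f_r + (beta_s - f_r) e^{-delta_w t}; after tau the
    washout U = U(tau) e^{-delta_w (t - tau)} re-uses the same exponential
    state with a reset amplitude.
    """
    n = A.shape[0]
    m = n + 2  # states: F..., u1 = decaying exponential, u0 = constant

    def build(a_const: float, b_exp: float) -> np.ndarray:
        M = np.zeros((m, m))
        M[:n, :n] = A
        M[:n, n] = g * c * b_exp
        M[:n, n + 1] = g * c * a_const
        M[n, n] = -water.delta_w
        return M

    M1 = build(water.f_r, water.beta_s - water.f_r)
    y0 = np.zeros(m)
    y0[n] = 1.0
    y0[n + 1] = 1.0

    out = np.empty((times.size, n))
    tau = water.tau
    up = times <= tau
    n_up = int(np.count_nonzero(up))
    any_down = n_up < times.size
    dts = np.append(times[up], tau) if any_down else times[up]
    sol_up = _propagate(M1, y0, dts)
    out[up] = sol_up[:n_up, :n]
    if any_down:
        y_tau = sol_up[-1].copy()
        y_tau[n] = eval_U(tau, water)  # washout amplitude
        y_tau[n + 1] = 0.0
        M2 = build(0.0, 1.0)
        out[~up] = _propagate(M2, y_tau, times[~up] - tau)[:, :n]
    return out


def _solve_ivp_route(A, g, c, water, times, rtol=1e-8, atol=1e-10) -> np.ndarray:
    """Adaptive numerical route, integrated piecewise around the kink at tau."""

    def rhs(t, y):
        return A @ y + g * (c * eval_U(t, water))

    n = A.shape[0]
    tau = water.tau
    t_end = float(times[-1]) if times.size else 0.0
    out = np.empty((times.size, n))
    y = np.zeros(n)
    up = times[times <= min(tau, t_end)]
    if up.size:
        sol = solve_ivp(rhs, (0.0, up[-1]), y, t_eval=up, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"label ODE integration failed: {sol.message}")
        out[: up.size] = sol.y.T
    if t_end > tau:
        sol0 = solve_ivp(rhs, (0.0, tau), np.zeros(n), method="LSODA", rtol=rtol, atol=atol)
        if not sol0.success:  # pragma: no cover
            raise RuntimeError(f"label ODE integration failed: {sol0.message}")
        y_tau = sol0.y[:, -1]
        down = times[times > tau]
        sol = solve_ivp(
            rhs, (tau, down[-1]), y_tau, t_eval=down, method="LSODA", rtol=rtol, atol=atol
        )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"label ODE integration failed: {sol.message}")
        out[times.size - down.size :] = sol.y.T
    return out


def _solve(params, water, times, method):
    A, g = _system(params)
    t = _check_times(times)
    if method == "expm":
        return t, _solve_expm(A, g, params.c, water, t)
    if method == "ivp":
        return t, _solve_ivp_route(A, g, params.c, water, t)
    raise ValueError(f"unknown method {method!r}")


def solve_label_implicit(
    params: ImplicitModelParams,
    water: BodyWaterParams,
    times,
    method: str = "expm",
) -> LabelCurvePrediction:
    """Label fractions of the homogeneous / implicit-heterogeneity model.

    ``F(0) = 0`` for both pools.  The homogeneous variant is selected by
    ``params.ds_star is None`` (the labelled disappearance rate is then
    the derived bulk rate ``d_s``).
    """
    t, F = _solve(params, water, times, method)
    return LabelCurvePrediction(times=t, F_TN=F[:, 0], F_TSCM=F[:, 1])


def solve_label_explicit(
    params: ExplicitModelParams,
    water: BodyWaterParams,
    times,
    method: str = "expm",
) -> LabelCurvePrediction:
    """Label fractions of the explicit two-subpopulation model.

    The bulk observable ``F_TSCM`` (a sorter sees a single T_SCM gate) is
    the steady-state-size-weighted mean of the subpopulation fractions.
    """
    t, F = _solve(params, water, times, method)
    w2 = params.relative_size_2
    bulk = (1.0 - w2) * F[:, 1] + w2 * F[:, 2]
    return LabelCurvePrediction(
        times=t, F_TN=F[:, 0], F_TSCM=bulk, F_TSCM1=F[:, 1], F_TSCM2=F[:, 2]
    )


def solve_label_euler(params, water: BodyWaterParams, times, dt: float = 1e-3) -> LabelCurvePrediction:
    """Brute-force fixed-step explicit Euler integration (independent oracle).

    Deliberately naive; used only to cross-check the production solvers.
    """
    A, g = _system(params)
    t = _check_times(times)
    n = A.shape[0]
    t_end = float(t[-1]) if t.size else 0.0
    n_steps = int(np.ceil(t_end / dt)) if t_end > 0 else 0
    grid = np.arange(n_steps + 1) * dt
    idx = np.clip(np.round(t / dt).astype(int), 0, n_steps)
    u = params.c * eval_U(grid, water) if n_steps else np.zeros(1)
    F = np.zeros(n)
    out = np.empty((t.size, n))
    out[idx == 0] = 0.0
    want = np.zeros(n_steps + 1, dtype=bool)
    want[idx] = True
    for s in range(1, n_steps + 1):
        F = F + dt * (A @ F + g * u[s - 1])
        if want[s]:
            out[idx == s] = F
    if isinstance(params, ExplicitModelParams):
        w2 = params.relative_size_2
        bulk = (1.0 - w2) * out[:, 1] + w2 * out[:, 2]
        return LabelCurvePrediction(t, out[:, 0], bulk, out[:, 1], out[:, 2])
    return LabelCurvePrediction(t, out[:, 0], out[:, 1])


def solve_label_euler_batch(params_list, water: BodyWaterParams, times, dt: float = 1e-3) -> np.ndarray:
    """Fixed-step Euler for many parameter sets at once (vectorised oracle).

    All parameter sets must be of the same kind (implicit or explicit) and
    share one body-water forcing.  Returns raw fraction states of shape
    ``(n_params, n_times, n_states)`` — no bulk averaging is applied.
    """
    t = _check_times(times)
    systems = [_system(p) for p in params_list]
    A = np.stack([s[0] for s in systems])
    gc = np.stack([s[1] * p.c for s, p in zip(systems, params_list)])
    n = A.shape[1]
    t_end = float(t[-1]) if t.size else 0.0
    n_steps = int(np.ceil(t_end / dt)) if t_end > 0 else 0
    u = eval_U(np.arange(n_steps) * dt, water) if n_steps else np.zeros(0)
    idx = np.clip(np.round(t / dt).astype(int), 0, n_steps)
    want = np.zeros(n_steps + 1, dtype=bool)
    want[idx] = True
    F = np.zeros((len(params_list), n))
    out = np.empty((len(params_list), t.size, n))
    out[:, idx == 0, :] = 0.0
    for s in range(1, n_steps + 1):
        F = F + dt * ((A @ F[:, :, None])[:, :, 0] + gc * u[s - 1])
        if want[s]:
            out[:, idx == s, :] = F[:, None, :]
    return out


def derived_bulk_rates(params: ImplicitModelParams) -> dict[str, float]:
    """Bulk steady-state rates of the one-pool model.

    Returns the total replacement (input) rate ``d_s = 2^k * Delta *
    ratio_NS + p_s``, the fraction of newly generated T_SCM cells
    originating from naive differentiation, and its complement, the
    self-renewal fraction ``p_s T_SCM / (2^k Delta T_N + p_s T_SCM)``.
    """
    influx_naive = 2.0**params.k * params.delta_ratio
    total = influx_naive + params.p_s
    frac_naive = influx_naive / total if total > 0 else 0.0
    return {
        "d_s": total,
        "replacement_rate": total,
        "fraction_from_naive": frac_naive,
        "self_renewal_fraction": 1.0 - frac_naive,
    }
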