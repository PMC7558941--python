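"""Closed-form two-compartment linear PK model for intravenous infusion.

Concentrations follow the standard bi-exponential disposition solution with
zero-order (constant-rate) drug input.  During an infusion of rate ``R``
starting from a drug-free state,

    C(t) = R * [ A/alpha * (1 - exp(-alpha*t)) + B/beta * (1 - exp(-beta*t)) ]

and after the infusion ends at ``t_inf`` the two accumulation terms decay
mono-exponentially with elapsed time ``t - t_inf``.  The hybrid rate
constants ``alpha >= beta`` and coefficients ``A``, ``B`` derive from the
micro-rate constants ``k10 = CL/V1``, ``k12 = Q/V1``, ``k21 = Q/V2``.

Multiple doses are handled by superposition (the model is linear), and a
numerical ODE integration of the two-compartment mass-balance system is
provided as an independent oracle for verification.

Units are fixed throughout the package: mg, L, h, mg/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PKParameters",
    "MacroConstants",
    "DoseEvent",
    "Regimen",
    "derive_macro",
    "conc_single_dose",
    "conc_profile",
    "steady_state_infusion_conc",
    "ode_conc_profile",
]


@dataclass(frozen=True)
class PKParameters:
    """Structural parameters of the two-compartment model.

    Attributes
    ----------
    CL : float
        Total (elimination) clearance, L/h.
    V1 : float
        Central volume of distribution, L.
    V2 : float
        Peripheral volume of distribution, L.
    Q : float
        Intercompartmental clearance, L/h.  ``Q = 0`` collapses the model
        to one compartment and is accepted only by the explicit degenerate
        path in :func:`conc_single_dose`.
    """

    CL: float
    V1: float
    V2: float
    Q: float

    def __post_init__(self) -> None:
        if not (self.CL > 0 and self.V1 > 0 and self.V2 > 0):
            raise ValueError(f"CL, V1, V2 must be strictly positive, got {self}")
        if self.Q < 0:
            raise ValueError(f"Q must be non-negative, got Q={self.Q}")

    def as_array(self) -> np.ndarray:
        return np.array([self.CL, self.V1, self.V2, self.Q], dtype=float)

    @staticmethod
    def names() -> tuple[str, ...]:
        return ("CL", "V1", "V2", "Q")


@dataclass(frozen=True)
class MacroConstants:
    """Micro-rate constants and hybrid (macro) disposition constants."""

    k10: float
    k12: float
    k21: float
    alpha: float
    beta: float
    A: float
    B: float


@dataclass(frozen=True)
class DoseEvent:
    """A single constant-rate intravenous infusion.

    ``rate`` is derived as ``amount / duration`` (mg/h).
    """

    start_time: float
    amount: float
    duration: float

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError(f"dose amount must be positive, got {self.amount}")
        if self.duration <= 0:
            raise ValueError(f"infusion duration must be positive, got {self.duration}")
        if self.start_time < 0:
            raise ValueError(f"dose start time must be >= 0, got {self.start_time}")

    @property
    def rate(self) -> float:
        return self.amount / self.duration

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class Regimen:
    """An ordered sequence of infusion events (start times strictly increasing)."""

    doses: tuple[DoseEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        starts = [d.start_time for d in self.doses]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("dose start times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.doses)

    @staticmethod
    def q_interval(amount: float, duration: float, interval: float, n_doses: int) -> "Regimen":
        """Regimen of ``n_doses`` equal infusions every ``interval`` hours."""
        return Regimen(tuple(
            DoseEvent(start_time=k * interval, amount=amount, duration=duration)
            for k in range(n_doses)
        ))


# ---------------------------------------------------------------------------
# array-level core (supports numpy broadcasting and complex dtype, which the
# estimation layer uses for complex-step differentiation)
# ---------------------------------------------------------------------------

def macro_arrays(CL, V1, V2, Q):
    """Vectorized micro/macro constant derivation.

    Returns ``(k10, k12, k21, alpha, beta, A, B)`` with full broadcasting.
    Inputs must be strictly positive (not checked here; see
    :func:`derive_macro` for the validated scalar API).
    """
    k10 = CL / V1
    k12 = Q / V1
    k21 = Q / V2
    s = k10 + k12 + k21
    disc = s * s - 4.0 * k10 * k21
    root = np.sqrt(disc)
    alpha = 0.5 * (s + root)
    beta = (k10 * k21) / alpha  # algebraically (s - root)/2, but stable
    A = (alpha - k21) / (V1 * (alpha - beta))
    B = (k21 - beta) / (V1 * (alpha - beta))
    return k10, k12, k21, alpha, beta, A, B


def _conc_from_macro(alpha, beta, A, B, rate, t_inf, t):
    """One-infusion concentration from precomputed disposition constants.

    A single expression covers both the during- and post-infusion regimes:
    with ``te = clip(t, 0, t_inf)`` (time spent infusing) and
    ``tau = max(t - t_inf, 0)`` (time since infusion end),

        C = R * [ A/alpha (1 - e^{-alpha te}) e^{-alpha tau} + (beta term) ]

    which is continuous at ``t = t_inf`` by construction.  Negative ``t``
    (before the dose) contributes zero.
    """
    t = np.asarray(t, dtype=float)
    te = np.clip(t, 0.0, t_inf)
    tau = np.where(t > t_inf, t - t_inf, 0.0)
    c = rate * (
        A / alpha * (1.0 - np.exp(-alpha * te)) * np.exp(-alpha * tau)
        + B / beta * (1.0 - np.exp(-beta * te)) * np.exp(-beta * tau)
    )
    return c * (t >= 0.0)


def infusion_conc_arrays(CL, V1, V2, Q, rate, t_inf, t):
    """Concentration at time ``t`` since the start of one infusion, vectorized.

    Parameter arrays broadcast and may be complex (the estimation layer
    differentiates this function by complex step).
    """
    _, _, _, alpha, beta, A, B = macro_arrays(CL, V1, V2, Q)
    return _conc_from_macro(alpha, beta, A, B, rate, t_inf, t)


def regimen_conc_and_grad(params, dose_starts, dose_rates, dose_durations, t):
    """Concentrations and their parameter gradient, vectorized.

    ``params`` is ``(..., 4)`` holding (CL, V1, V2, Q); ``t`` has shape
    ``(T,)``.  Returns ``(conc, dconc)`` with shapes ``(..., T)`` and
    ``(..., T, 4)``; ``dconc[..., j]`` is the partial derivative with
    respect to parameter ``j``.  The derivatives are exact (chain rule
    through the hybrid constants) and share the per-dose exponentials with
    the concentration itself, which makes this the cheap path for
    gradient-based estimation.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    CL, V1, V2, Q = (params[..., j][..., None] for j in range(4))
    k10 = CL / V1
    k12 = Q / V1
    k21 = Q / V2
    s = k10 + k12 + k21
    P = k10 * k21
    root = np.sqrt(s * s - 4.0 * P)
    alpha = 0.5 * (s + root)
    beta = P / alpha
    D = alpha - beta
    A = (alpha - k21) / (V1 * D)
    B = (k21 - beta) / (V1 * D)

    # micro-constant partials stacked on a leading parameter axis
    zeros = np.zeros_like(CL)
    dk10 = np.stack([1.0 / V1, -CL / (V1 * V1), zeros, zeros])
    dk12 = np.stack([zeros, -Q / (V1 * V1), zeros, 1.0 / V1])
    dk21 = np.stack([zeros, zeros, -Q / (V2 * V2), 1.0 / V2])
    ds = dk10 + dk12 + dk21
    dP = dk10 * k21 + k10 * dk21
    droot = (s * ds - 2.0 * dP) / root
    dalpha = 0.5 * (ds + droot)
    dbeta = 0.5 * (ds - droot)
    dV1 = np.stack([zeros, np.ones_like(CL), zeros, zeros])
    rel = dV1 / V1 + droot / D
    dA = (dalpha - dk21) / (V1 * D) - A * rel
    dB = (dk21 - dbeta) / (V1 * D) - B * rel

    conc = 0.0
    dconc = 0.0
    for start, rate, dur in zip(dose_starts, dose_rates, dose_durations):
        td = t - start
        te = np.clip(td, 0.0, dur)
        tau = np.where(td > dur, td - dur, 0.0)
        ea = np.exp(-alpha * te)
        eat = np.exp(-alpha * tau)
        eb = np.exp(-beta * te)
        ebt = np.exp(-beta * tau)
        ua = (1.0 - ea) * eat
        ub = (1.0 - eb) * ebt
        dua = eat * (te * ea - tau * (1.0 - ea))     # du_a / d alpha
        dub = ebt * (te * eb - tau * (1.0 - eb))
        live = td >= 0.0
        conc = conc + rate * (A / alpha * ua + B / beta * ub) * live
        dconc = dconc + rate * live * (
            (dA / alpha - A * dalpha / (alpha * alpha)) * ua
            + A / alpha * dua * dalpha
            + (dB / beta - B * dbeta / (beta * beta)) * ub
            + B / beta * dub * dbeta
        )
    return conc, np.moveaxis(dconc, 0, -1)


def regimen_conc_arrays(CL, V1, V2, Q, dose_starts, dose_rates, dose_durations, t):
    """Superposition of several infusions, vectorized over parameters.

    ``t`` has shape ``(T,)``; parameter arrays broadcast against each other
    with a trailing axis added for time, so ``CL`` of shape ``(n,)`` yields
    concentrations of shape ``(n, T)``.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    CL, V1, V2, Q = (np.asarray(x)[..., None] for x in (CL, V1, V2, Q))
    _, _, _, alpha, beta, A, B = macro_arrays(CL, V1, V2, Q)
    total = 0.0
    for start, rate, dur in zip(dose_starts, dose_rates, dose_durations):
        total = total + _conc_from_macro(alpha, beta, A, B, rate, dur, t - start)
    return total


# ---------------------------------------------------------------------------
# validated scalar API
# ---------------------------------------------------------------------------

def derive_macro(params: PKParameters) -> MacroConstants:
    """Derive micro-rate and hybrid disposition constants from ``params``.

    Raises
    ------
    ValueError
        If ``Q == 0`` (degenerate one-compartment case, handled only by
        :func:`conc_single_dose`) or if the disposition quadratic has a
        repeated root (impossible for distinct positive rate constants,
        guarded regardless).
    """
    if params.Q <= 0:
        raise ValueError(
            "derive_macro requires Q > 0; the Q = 0 one-compartment limit "
            "is handled by the explicit degenerate path in conc_single_dose"
        )
    k10, k12, k21, alpha, beta, A, B = macro_arrays(
        params.CL, params.V1, params.V2, params.Q
    )
    if not alpha > beta:
        raise ValueError(
            f"repeated disposition root alpha == beta == {alpha:g}; "
            "the bi-exponential form is undefined"
        )
    return MacroConstants(k10=float(k10), k12=float(k12), k21=float(k21),
                          alpha=float(alpha), beta=float(beta),
                          A=float(A), B=float(B))


def conc_single_dose(params: PKParameters, dose: DoseEvent, t: float) -> float:
    """Concentration (mg/L) at time ``t`` hours after the start of ``dose``.

    Uses the during-infusion solution for ``0 <= t <= t_inf`` and the
    post-infusion solution (elapsed-time argument ``t - t_inf``) afterwards.
    ``Q = 0`` falls back to the one-compartment mono-exponential limit.
    """
    if t < 0:
        raise ValueError(f"time since dose start must be >= 0, got t={t}")
    rate, t_inf = dose.rate, dose.duration
    if params.Q == 0.0:
        k10 = params.CL / params.V1
        te = min(t, t_inf)
        tau = max(t - t_inf, 0.0)
        return float(rate / params.CL * (1.0 - np.exp(-k10 * te)) * np.exp(-k10 * tau))
    derive_macro(params)  # validate invariants before evaluating
    return float(infusion_conc_arrays(
        params.CL, params.V1, params.V2, params.Q, rate, t_inf, t
    ))


def conc_profile(params: PKParameters, regimen: Regimen,
                 times: Sequence[float]) -> np.ndarray:
    """Concentrations at ``times`` (hours from first-dose start) under ``regimen``.

    Superposition of time-shifted single-dose solutions; doses starting
    after a given time contribute nothing there.  ``times`` need not be
    sorted and are returned in the given order.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("observation times must be >= 0")
    if len(regimen) == 0:
        return np.zeros_like(times)
    out = regimen_conc_arrays(
        params.CL, params.V1, params.V2, params.Q,
        [d.start_time for d in regimen.doses],
        [d.rate for d in regimen.doses],
        [d.duration for d in regimen.doses],
        times,
    )
    return np.asarray(out, dtype=float).reshape(times.shape)


def steady_state_infusion_conc(params: PKParameters, rate: float) -> float:
    """Plateau concentration of a never-ending infusion: ``rate / CL``.

    Equals the ``t -> inf`` limit of the during-infusion solution,
    ``R * (A/alpha + B/beta)``, by the partial-fraction identity
    ``A/alpha + B/beta = 1/(V1 k10) = 1/CL``.
    """
    if rate <= 0:
        raise ValueError(f"infusion rate must be positive, got {rate}")
    return rate / params.CL


# ---------------------------------------------------------------------------
# numerical ODE oracle
# ---------------------------------------------------------------------------

def ode_conc_profile(params: PKParameters, regimen: Regimen,
                     times: Sequence[float], rtol: float = 1e-10,
                     atol: float = 1e-12) -> np.ndarray:
    """Concentrations by adaptive integration of the compartmental ODEs.

    Independent of the closed form: integrates the mass balance

        dA1/dt = R(t) - (k10 + k12) A1 + k21 A2
        dA2/dt = k12 A1 - k21 A2,      C = A1 / V1

    piecewise between dose on/off switch points so the discontinuous input
    never crosses an integration step.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("observation times must be >= 0")
    k10 = params.CL / params.V1
    k12 = params.Q / params.V1
    k21 = params.Q / params.V2

    events = [(d.start_time, d.end_time, d.rate) for d in regimen.doses]
    breaks = sorted({0.0, *times, *(e[0] for e in events), *(e[1] for e in events)})

    def rate_at(t: float) -> float:
        return sum(r for (s, e, r) in events if s <= t < e)

    def rhs(t, y, rate):
        a1, a2 = y
        return [rate - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

    conc_at: dict[float, float] = {}
    y = np.array([0.0, 0.0])
    t_prev = breaks[0]
    if t_prev in times:
        conc_at[t_prev] = y[0] / params.V1
    for t_next in breaks[1:]:
        rate = rate_at(0.5 * (t_prev + t_next))
        sol = solve_ivp(rhs, (t_prev, t_next), y, args=(rate,),
                        method="DOP853", rtol=rtol, atol=atol)
        if not sol.success:  # pragma: no cover - DOP853 on a linear system
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        y = sol.y[:, -1]
        if t_next in times:
            conc_at[t_next] = y[0] / params.V1
        t_prev = t_next
    return np.array([conc_at[t] for t in times])
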