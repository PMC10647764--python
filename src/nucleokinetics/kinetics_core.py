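"""Closed-form kinetics of salt-dialysis nucleosome assembly.

The assembly of histone octamers (total concentration ``Q``) onto DNA
templates (total concentration ``S``) during salt dialysis is modelled as a
single lumped reversible second-order reaction::

    dN/dt = k(t) * (Q - N) * (S - N) - k'(t) * N

where ``N`` is the nucleosome concentration, ``k`` the forward and ``k'``
the reverse rate constant. All of the time dependence of the forward rate
enters through the accumulated rate integral

    theta(T) = integral_0^T k(t) dt = kbar * (alpha + eps * T)

with ``kbar`` the mean rate constant and ``T`` the total dialysis time; the
reverse channel enters through ``gamma``, the representative (median) ratio
``k'/k``, which carries concentration units.

Three nested forms of the assembly efficiency ``N/S`` are provided:

* :func:`efficiency_implicit` — exact integral of the reversible reaction
  (``gamma >= 0``), via the partial-fraction closed form;
* :func:`efficiency_explicit` — the irreversible limit ``gamma -> 0``;
* :func:`efficiency_linear` — the low-conversion linear law
  ``N/S = Q * kbar * (alpha + eps*T)``, valid when ``|Q - S| * theta < 1``,
  which is the regime all slope fitting operates in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KineticParams",
    "ReactionSystem",
    "RegimeFlags",
    "InvalidParameterError",
    "ModelRegimeError",
    "theta",
    "efficiency_explicit",
    "efficiency_implicit",
    "efficiency_linear",
    "equilibrium_roots",
    "regime_check",
]

#: Relative |Q - S| below which the equal-concentration limit is used.
EQUAL_CONC_RTOL = 1e-9

#: Default threshold for declaring gamma/|Q - S| "small".
GAMMA_SMALL_THRESHOLD = 0.1


class InvalidParameterError(ValueError):
    """A kinetic parameter violates its domain constraint."""


class ModelRegimeError(ValueError):
    """The requested evaluation lies outside the model's valid regime."""


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the accumulated-rate parametrization theta = kbar*(alpha + eps*T).

    Attributes
    ----------
    kbar:
        Mean forward rate constant, volume·amount⁻¹·time⁻¹. Must be >= 0.
    alpha:
        Time offset of the dialysis parametrization (time units).
    eps:
        Dimensionless time coefficient.
    gamma:
        Median reverse-to-forward ratio k'/k, in concentration units
        (amount·volume⁻¹). Must be >= 0. The study's fits all use the
        irreversible regime, so the default is 0.
    """

    kbar: float
    alpha: float = 0.0
    eps: float = 1.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.kbar) or self.kbar < 0:
            raise InvalidParameterError(f"kbar must be finite and >= 0, got {self.kbar}")
        if not np.isfinite(self.gamma) or self.gamma < 0:
            raise InvalidParameterError(f"gamma must be finite and >= 0, got {self.gamma}")
        if not (np.isfinite(self.alpha) and np.isfinite(self.eps)):
            raise InvalidParameterError("alpha and eps must be finite")


@dataclass(frozen=True)
class ReactionSystem:
    """Total octamer Q, total DNA S and nucleosome N concentrations (amount·volume⁻¹)."""

    Q: float
    S: float
    N: float = 0.0

    def __post_init__(self) -> None:
        if self.Q <= 0 or self.S <= 0:
            raise InvalidParameterError(f"Q and S must be > 0, got Q={self.Q}, S={self.S}")
        if not (-1e-12 * self.S <= self.N <= min(self.Q, self.S) * (1 + 1e-12)):
            raise InvalidParameterError(
                f"N={self.N} outside [0, min(Q, S)] for Q={self.Q}, S={self.S}"
            )


@dataclass(frozen=True)
class RegimeFlags:
    """Validity flags of the model's two approximation regimes."""

    gamma_small: bool
    linear_ok: bool
    note: str = ""


def theta(params: KineticParams, T: float) -> float:
    """Accumulated forward-rate integral theta(T) = kbar*(alpha + eps*T).

    Parameters
    ----------
    params:
        Kinetic parameters.
    T:
        Total dialysis time, >= 0 (same time units as ``alpha``).

    Returns
    -------
    float
        theta in volume·amount⁻¹; strictly increasing in T when
        ``kbar * eps > 0``.
    """
    if T < 0:
        raise InvalidParameterError(f"T must be >= 0, got {T}")
    window = params.alpha + params.eps * T
    if window < 0:
        raise InvalidParameterError(
            f"alpha + eps*T = {window} < 0 (alpha={params.alpha}, eps={params.eps}, T={T})"
        )
    value = params.kbar * window
    if value < 0:  # pragma: no cover - excluded by the guards above
        raise InvalidParameterError(f"theta = {value} < 0")
    return value


def _efficiency_equal_conc(Q: float, th: float) -> float:
    # Equal-concentration limit of the irreversible law: N/S = Q*theta / (1 + Q*theta)
    x = Q * th
    return x / (1.0 + x)


def efficiency_explicit(Q: float, S: float, th: float) -> float:
    """Assembly efficiency N/S of the irreversible (gamma -> 0) reaction.

    Evaluates ``N/S = (Q/S) * (1 - e) / (1 - (Q/S) * e)`` with
    ``e = exp((Q - S) * theta)``, using whichever algebraic rearrangement
    keeps the exponent non-positive so the result is always finite.
    At ``Q == S`` (within relative tolerance) the analytic limit
    ``Q*theta / (1 + Q*theta)`` is returned.

    Parameters
    ----------
    Q, S:
        Total octamer and DNA concentrations, > 0.
    th:
        Accumulated rate integral theta, >= 0.
    """
    if Q <= 0 or S <= 0:
        raise InvalidParameterError(f"Q and S must be > 0, got Q={Q}, S={S}")
    if th < 0:
        raise InvalidParameterError(f"theta must be >= 0, got {th}")
    if th == 0.0:
        return 0.0
    d = Q - S
    if abs(d) <= EQUAL_CONC_RTOL * max(Q, S):
        return _efficiency_equal_conc(Q, th)
    r = Q / S
    x = d * th
    if x <= 0:
        e = math.exp(x)  # e <= 1, no overflow
        out = r * (1.0 - e) / (1.0 - r * e)
    else:
        # multiply through by exp(-x) < 1
        em = math.exp(-x)
        out = r * (em - 1.0) / (em - r)
    # guard against rounding just past the physical bound
    return min(max(out, 0.0), min(1.0, r))


def equilibrium_roots(Q: float, S: float, gamma: float) -> tuple[float, float]:
    """Roots (N_minus, N_plus) of (Q - N)(S - N) = gamma*N.

    ``N_minus`` is the physically reachable equilibrium nucleosome
    concentration; ``N_minus <= min(Q, S) <= N_plus``. Computed with the
    cancellation-safe quadratic formula.
    """
    b = Q + S + gamma
    disc = b * b - 4.0 * Q * S
    # disc = (Q - S)^2 + gamma^2 + 2*gamma*(Q + S) >= 0 always
    sq = math.sqrt(max(disc, 0.0))
    n_plus = 0.5 * (b + sq)
    n_minus = (Q * S) / n_plus  # product of roots = Q*S
    return n_minus, n_plus


def efficiency_implicit(Q: float, S: float, params: KineticParams, th: float) -> float:
    """Assembly efficiency N/S of the reversible reaction (gamma >= 0).

    Inverts the exact partial-fraction integral of
    ``dN/dt = k[(Q - N)(S - N) - gamma*N]``: with roots ``N- < N+`` of
    ``(Q - N)(S - N) = gamma*N``,

        theta = 1/(N+ - N-) * ln[ N-*(N+ - N) / (N+*(N- - N)) ]

    which solves to ``N = N+*N-*(L - 1) / (L*N+ - N-)`` with
    ``L = exp(theta*(N+ - N-))``, evaluated overflow-safely. The result
    increases from 0 at ``theta = 0`` toward the equilibrium root ``N-``.
    At ``gamma = 0`` this reduces algebraically to
    :func:`efficiency_explicit`.
    """
    if Q <= 0 or S <= 0:
        raise InvalidParameterError(f"Q and S must be > 0, got Q={Q}, S={S}")
    if th < 0:
        raise InvalidParameterError(f"theta must be >= 0, got {th}")
    gamma = params.gamma
    if gamma == 0.0:
        return efficiency_explicit(Q, S, th)
    if th == 0.0:
        return 0.0
    n_minus, n_plus = equilibrium_roots(Q, S, gamma)
    gap = n_plus - n_minus
    if gap <= 0:  # pragma: no cover - impossible for gamma > 0
        raise ModelRegimeError(f"degenerate roots for Q={Q}, S={S}, gamma={gamma}")
    x = th * gap
    if x < 700.0:
        L = math.exp(x)
        n = n_plus * n_minus * (L - 1.0) / (L * n_plus - n_minus)
    else:
        # exp overflow regime: N has converged to the equilibrium root
        n = n_minus * (1.0 - (1.0 - n_minus / n_plus) * math.exp(-x))
    n = min(max(n, 0.0), n_minus)
    return n / S


def efficiency_linear(Q: float, params: KineticParams, T: float) -> float:
    """Low-conversion linear law N/S = Q * kbar * (alpha + eps*T).

    Exactly proportional to ``Q``; faithful only where the linear-regime
    flag of :func:`regime_check` holds (not enforced here).
    """
    if Q < 0:
        raise InvalidParameterError(f"Q must be >= 0, got {Q}")
    return Q * theta(params, T)


def regime_check(
    Q: float,
    S: float,
    params: KineticParams,
    th: float,
    gamma_small_threshold: float = GAMMA_SMALL_THRESHOLD,
) -> RegimeFlags:
    """Evaluate the two approximation-regime flags.

    ``gamma_small`` holds when ``gamma / |Q - S| < gamma_small_threshold``
    (the irreversible closed form is then accurate); ``linear_ok`` holds
    when ``|Q - S| * theta < 1`` (the linear law is then accurate).
    ``Q == S`` makes the gamma criterion degenerate; the flag is reported
    False with an explanatory note.
    """
    d = abs(Q - S)
    note = ""
    if d == 0.0:
        gamma_small = params.gamma == 0.0
        if not gamma_small:
            note = "Q == S: gamma/|Q-S| is undefined (degenerate difference)"
    else:
        gamma_small = params.gamma / d < gamma_small_threshold
    linear_ok = d * th < 1.0
    return RegimeFlags(gamma_small=gamma_small, linear_ok=linear_ok, note=note)
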