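"""Numerical oracle: integrate the reversible assembly ODE directly.

The closed forms in :mod:`nucleokinetics.kinetics_core` assert that the
endpoint nucleosome concentration depends on the dialysis-rate history
``k(t)`` only through its integral ``theta = ∫ k dt`` (for a fixed reverse
ratio ``gamma = k'/k``). This module integrates

    dN/dt = k(t) * (Q - N) * (S - N) - gamma * k(t) * N

and its two-species competitive generalization (shared DNA pool,
independent per-species octamer pools)

    dN_A/dt = k_A(t) * (Q_A - N_A) * (S - N_A - N_Z) - gamma_A * k_A(t) * N_A
    dN_Z/dt = k_Z(t) * (Q_Z - N_Z) * (S - N_A - N_Z) - gamma_Z * k_Z(t) * N_Z

with an adaptive Runge-Kutta solver, serving as the independent oracle the
closed forms and the merged competitive ratio law are certified against.
A fixed-step RK4 integrator is included for convergence cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.integrate import quad, solve_ivp

from .kinetics_core import InvalidParameterError

__all__ = [
    "RateSchedule",
    "Trajectory",
    "SolverError",
    "schedule_theta",
    "simulate_assembly",
    "simulate_competitive",
    "rk4_endpoint",
]

#: Default solver tolerances (see module docstring of kinetics_core for scales).
DEFAULT_RTOL = 1e-9
DEFAULT_ATOL_FRACTION = 1e-15  # absolute tolerance = fraction * S

_SCHEDULE_KINDS = ("constant", "linear-ramp", "exponential-decay")


class SolverError(RuntimeError):
    """ODE integration failed or produced an unphysical state."""


@dataclass(frozen=True)
class RateSchedule:
    """Forward-rate history k(t) on [0, T] with constant reverse ratio gamma.

    kinds
    -----
    ``constant``:
        k(t) = ``k0``.
    ``linear-ramp``:
        k(t) = ``k0 + slope * t`` (clipped at 0; must stay >= 0 on [0, T]).
    ``exponential-decay``:
        k(t) = ``k0 * exp(-t / tau)``, ``tau > 0``.

    ``gamma`` is the constant reverse-to-forward ratio k'(t)/k(t) in
    concentration units.
    """

    kind: str = "constant"
    k0: float = 0.0
    slope: float = 0.0
    tau: float = math.inf
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _SCHEDULE_KINDS:
            raise InvalidParameterError(
                f"unknown schedule kind {self.kind!r}; expected one of {_SCHEDULE_KINDS}"
            )
        if self.k0 < 0:
            raise InvalidParameterError(f"k0 must be >= 0, got {self.k0}")
        if self.gamma < 0:
            raise InvalidParameterError(f"gamma must be >= 0, got {self.gamma}")
        if self.kind == "exponential-decay" and not self.tau > 0:
            raise InvalidParameterError(f"tau must be > 0, got {self.tau}")

    def rate(self, t: float | np.ndarray) -> float | np.ndarray:
        """Forward rate k(t)."""
        if self.kind == "constant":
            return self.k0 * np.ones_like(np.asarray(t, dtype=float)) if np.ndim(t) else self.k0
        if self.kind == "linear-ramp":
            return np.maximum(self.k0 + self.slope * np.asarray(t, dtype=float), 0.0)
        return self.k0 * np.exp(-np.asarray(t, dtype=float) / self.tau)

    @classmethod
    def constant_with_theta(cls, theta: float, T: float, gamma: float = 0.0) -> "RateSchedule":
        """The default schedule: constant k = theta / T."""
        if T <= 0:
            raise InvalidParameterError(f"T must be > 0, got {T}")
        return cls(kind="constant", k0=theta / T, gamma=gamma)


@dataclass
class Trajectory:
    """Time course of one- or two-species assembly with conservation bookkeeping."""

    times: np.ndarray
    N: dict[str, np.ndarray]          # species label -> N(t)
    Q: dict[str, float]               # species label -> total octamer
    S: float                          # total DNA
    meta: dict = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return list(self.N)

    def endpoint(self, label: str | None = None) -> float:
        """Final nucleosome concentration of ``label`` (sole species if None)."""
        if label is None:
            if len(self.N) != 1:
                raise KeyError("trajectory has multiple species; give a label")
            label = next(iter(self.N))
        return float(self.N[label][-1])

    def free_dna(self) -> np.ndarray:
        return self.S - sum(self.N.values())

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time, per-species N, free DNA, per-species free octamer."""
        data: dict[str, np.ndarray] = {"time": self.times}
        for label in self.N:
            data[f"N_{label}"] = self.N[label]
        data["free_DNA"] = self.free_dna()
        for label in self.N:
            data[f"free_octamer_{label}"] = self.Q[label] - self.N[label]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def schedule_theta(schedule: RateSchedule, T: float) -> float:
    """theta = ∫_0^T k(t) dt, by closed form where available else quadrature."""
    if T < 0:
        raise InvalidParameterError(f"T must be >= 0, got {T}")
    if schedule.kind == "constant":
        return schedule.k0 * T
    if schedule.kind == "exponential-decay":
        return schedule.k0 * schedule.tau * (1.0 - math.exp(-T / schedule.tau))
    value, _ = quad(schedule.rate, 0.0, T, limit=200, epsrel=1e-12, epsabs=0.0)
    return value


def _clip_state(n: np.ndarray, S: float) -> np.ndarray:
    floor = -1e-15 * S
    if np.any(n < floor):
        raise SolverError(f"negative nucleosome excursion beyond tolerance: min N = {n.min():.3e}")
    return np.maximum(n, 0.0)


def simulate_assembly(
    Q: float,
    S: float,
    schedule: RateSchedule,
    T: float,
    *,
    rtol: float = DEFAULT_RTOL,
    atol_fraction: float = DEFAULT_ATOL_FRACTION,
    n_out: int = 101,
) -> Trajectory:
    """Integrate single-species assembly over [0, T].

    Parameters
    ----------
    Q, S:
        Total octamer and DNA concentrations, > 0.
    schedule:
        Forward-rate history and reverse ratio gamma.
    T:
        Total dialysis time, > 0.
    rtol, atol_fraction:
        Solver tolerances; absolute tolerance is ``atol_fraction * S``.
    n_out:
        Number of equally spaced output times.

    Returns
    -------
    Trajectory
        With a single species labelled ``"A"``.
    """
    if Q <= 0 or S <= 0:
        raise InvalidParameterError(f"Q and S must be > 0, got Q={Q}, S={S}")
    if T <= 0:
        raise InvalidParameterError(f"T must be > 0, got {T}")
    gamma = schedule.gamma

    def rhs(t, y):
        k = schedule.rate(t)
        n = y[0]
        return [k * ((Q - n) * (S - n) - gamma * n)]

    t_eval = np.linspace(0.0, T, n_out)
    sol = solve_ivp(
        rhs, (0.0, T), [0.0], method="RK45",
        rtol=rtol, atol=atol_fraction * S, t_eval=t_eval, dense_output=False,
    )
    if not sol.success:
        raise SolverError(f"solver failed: {sol.message} (rtol={rtol}, atol={atol_fraction * S})")
    n = _clip_state(sol.y[0], S)
    return Trajectory(times=sol.t, N={"A": n}, Q={"A": Q}, S=S,
                      meta={"schedule": schedule, "rtol": rtol})


def simulate_competitive(
    QA: float,
    QZ: float,
    S: float,
    scheduleA: RateSchedule,
    scheduleZ: RateSchedule,
    T: float,
    *,
    rtol: float = DEFAULT_RTOL,
    atol_fraction: float = DEFAULT_ATOL_FRACTION,
    n_out: int = 101,
) -> Trajectory:
    """Integrate two octamer species competing for a shared DNA pool.

    Species "A" (canonical H2A octamer) and "Z" (H2A.Z octamer) deplete the
    same free-DNA pool ``S - N_A - N_Z`` with independent rate histories.
    In the low-conversion regime the endpoint ratio obeys the merged linear
    law ``N_A/N_Z = (Q_A/Q_Z) * (theta_A/theta_Z)``.
    """
    if QA < 0 or QZ < 0:
        raise InvalidParameterError(f"QA and QZ must be >= 0, got {QA}, {QZ}")
    if S <= 0:
        raise InvalidParameterError(f"S must be > 0, got {S}")
    if T <= 0:
        raise InvalidParameterError(f"T must be > 0, got {T}")

    def rhs(t, y):
        na, nz = y
        free = S - na - nz
        ka = scheduleA.rate(t)
        kz = scheduleZ.rate(t)
        return [
            ka * ((QA - na) * free - scheduleA.gamma * na),
            kz * ((QZ - nz) * free - scheduleZ.gamma * nz),
        ]

    t_eval = np.linspace(0.0, T, n_out)
    sol = solve_ivp(
        rhs, (0.0, T), [0.0, 0.0], method="RK45",
        rtol=rtol, atol=atol_fraction * S, t_eval=t_eval,
    )
    if not sol.success:
        raise SolverError(f"solver failed: {sol.message}")
    na = _clip_state(sol.y[0], S)
    nz = _clip_state(sol.y[1], S)
    return Trajectory(times=sol.t, N={"A": na, "Z": nz}, Q={"A": QA, "Z": QZ}, S=S,
                      meta={"scheduleA": scheduleA, "scheduleZ": scheduleZ, "rtol": rtol})


def rk4_endpoint(
    Q: float,
    S: float,
    schedule: RateSchedule,
    T: float,
    n_steps: int = 20000,
) -> float:
    """Fixed-step classical RK4 endpoint N(T); independent convergence check."""
    gamma = schedule.gamma
    h = T / n_steps
    n = 0.0

    def f(t: float, y: float) -> float:
        return schedule.rate(t) * ((Q - y) * (S - y) - gamma * y)

    t = 0.0
    for _ in range(n_steps):
        k1 = f(t, n)
        k2 = f(t + 0.5 * h, n + 0.5 * h * k1)
        k3 = f(t + 0.5 * h, n + 0.5 * h * k2)
        k4 = f(t + h, n + h * k3)
        n += (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return n
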