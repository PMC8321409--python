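"""Rate schedules and monomer/dimer kinetics.

The kinetic ODE system is

    dM/dt = S - kappa M - 2 nu M^2 - nu M D + 2 mu D
    dD/dt = nu M^2 - mu D - nu M D

with the trimer sink ``nu M D`` retained but no explicit higher-order
oligomer species.  Dimer equilibration is fast (~1/mu ~ seconds) and
monomer relaxation intermediate (~1/kappa ~ hours), while the rate
constants drift over decades, so away from initial transients the system
is quasi-static: M = S/kappa, D = nu M^2 / mu.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import DomainError, ParameterSet, ValidationError, YEAR_SECONDS


@dataclass(frozen=True)
class RateSchedule:
    """Age-dependent rate policies S(t), kappa(t) and optionally sigma(t).

    ``mode`` is ``"static"`` (all rates at their baseline value) or
    ``"linear"`` (S grows linearly with doubling time lambda_S, kappa
    decays linearly to zero at lambda_kappa, and, if configured,
    sigma grows linearly with doubling time lambda_sigma).  Ages are in
    years, returned rates in SI units.
    """

    params: ParameterSet
    mode: str = "linear"

    def __post_init__(self) -> None:
        if self.mode not in ("static", "linear"):
            raise ValidationError(f"mode must be 'static' or 'linear', got {self.mode!r}")

    def _check_age(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise DomainError("ages must be nonnegative")
        if self.mode == "linear" and np.any(t >= self.params.lambda_kappa):
            raise DomainError(
                "model loses validity for t near "
                f"{self.params.lambda_kappa:g} yr (clearance reaches zero)")
        return t

    def S(self, t):
        """Monomer production rate at age ``t`` years, M s^-1."""
        t = self._check_age(t)
        if self.mode == "static":
            return np.broadcast_to(self.params.S_bar, t.shape).copy() if t.shape else self.params.S_bar
        return self.params.S_bar * (1.0 + t / self.params.lambda_S)

    def kappa(self, t):
        """Monomer clearance rate at age ``t`` years, s^-1."""
        t = self._check_age(t)
        if self.mode == "static":
            return np.broadcast_to(self.params.kappa_bar, t.shape).copy() if t.shape else self.params.kappa_bar
        return self.params.kappa_bar * (1.0 - t / self.params.lambda_kappa)

    def sigma(self, t):
        """Cell-dimer damage rate at age ``t`` years, M^-1 s^-1."""
        t = self._check_age(t)
        p = self.params
        if self.mode == "linear" and p.has_toxicity_schedule:
            return p.sigma_0 * (1.0 + t / p.lambda_sigma)
        return np.broadcast_to(p.sigma_bar, t.shape).copy() if t.shape else p.sigma_bar

    @property
    def is_dynamic(self) -> bool:
        return self.mode == "linear"


def static_schedule(p: ParameterSet) -> RateSchedule:
    return RateSchedule(params=p, mode="static")


def dynamic_schedule(p: ParameterSet) -> RateSchedule:
    return RateSchedule(params=p, mode="linear")


@dataclass(frozen=True)
class KineticState:
    """Monomer/dimer concentrations at one age."""

    t: float      # age, years
    M: float      # molar
    D: float      # molar

    def __post_init__(self) -> None:
        if self.M < 0 or self.D < 0:
            raise ValidationError("concentrations must be nonnegative")


def quasi_static_state(schedule: RateSchedule, t: float) -> KineticState:
    """Quasi-static solution M = S(t)/kappa(t), D = nu M^2 / mu at age t."""
    S = schedule.S(t)
    kappa = schedule.kappa(t)
    p = schedule.params
    M = S / kappa
    D = p.nu_bar * M**2 / p.mu_bar
    return KineticState(t=float(t), M=float(M), D=float(D))


class IntegrationError(RuntimeError):
    pass


def _rhs_factory(schedule: RateSchedule, p: ParameterSet) -> Callable:
    nu, mu = p.nu_bar, p.mu_bar

    def rhs(ts: float, y: np.ndarray):
        t_years = ts / YEAR_SECONDS
        S = schedule.S(t_years)
        kappa = schedule.kappa(t_years)
        M, D = y
        dM = S - kappa * M - 2 * nu * M**2 - nu * M * D + 2 * mu * D
        dD = nu * M**2 - mu * D - nu * M * D
        return [dM, dD]

    def jac(ts: float, y: np.ndarray):
        t_years = ts / YEAR_SECONDS
        kappa = schedule.kappa(t_years)
        M, D = y
        return [[-kappa - 4 * nu * M - nu * D, -nu * M + 2 * mu],
                [2 * nu * M - nu * D, -mu - nu * M]]

    return rhs, jac


def integrate_kinetics(
    schedule: RateSchedule,
    t_span_seconds: tuple[float, float],
    initial: Optional[KineticState] = None,
    n_output: int = 200,
    rtol: float = 1e-10,
    log_spaced: bool = True,
) -> list[KineticState]:
    """Integrate the kinetic ODEs with a stiff-capable adaptive solver.

    ``t_span_seconds`` is ``(t0, t1)`` in seconds of age.  The default
    initial condition is (0, 0).  Output ages are log-spaced by default
    (the system spans dimer equilibration in seconds to drift over
    decades).  Returns a list of :class:`KineticState` (ages in years).
    """
    p = schedule.params
    t0, t1 = float(t_span_seconds[0]), float(t_span_seconds[1])
    if t1 <= t0:
        raise ValidationError("t_span must be increasing")
    if initial is None:
        y0 = [0.0, 0.0]
    else:
        y0 = [initial.M, initial.D]
    if log_spaced and t0 == 0.0:
        t_eval = np.concatenate([[0.0], np.geomspace(max(t1 * 1e-8, 1e-3), t1, n_output - 1)])
    elif log_spaced and t0 > 0:
        t_eval = np.geomspace(t0, t1, n_output)
    else:
        t_eval = np.linspace(t0, t1, n_output)

    rhs, jac = _rhs_factory(schedule, p)
    # concentrations are ~1e-8 M (monomer) and ~1e-12 M (dimer)
    sol = solve_ivp(rhs, (t0, t1), y0, method="BDF", jac=jac,
                    t_eval=t_eval, rtol=rtol, atol=[1e-20, 1e-24])
    if not sol.success:
        raise IntegrationError(f"kinetic integration failed: {sol.message}")
    if np.any(sol.y < -1e-15):
        raise IntegrationError("negative concentrations beyond tolerance")
    states = []
    for ts, M, D in zip(sol.t, sol.y[0], sol.y[1]):
        states.append(KineticState(t=ts / YEAR_SECONDS, M=max(M, 0.0), D=max(D, 0.0)))
    return states


def trajectory_frame(states: list[KineticState]):
    """Tabulate a trajectory: t_seconds, t_years, M_molar, D_molar."""
    import pandas as pd

    return pd.DataFrame({
        "t_seconds": [s.t * YEAR_SECONDS for s in states],
        "t_years": [s.t for s in states],
        "M_molar": [s.M for s in states],
        "D_molar": [s.D for s in states],
    })
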