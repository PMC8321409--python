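"""Viability, survivorship, incidence, prevalence and derived summaries.

In the quasi-static regime the neuronal damage rate is

    U(t) = sigma(t) nu S(t)^2 / (kappa(t)^2 mu) = U0 * Xi(t)

with ``U0`` its value at birth and ``Xi`` a dimensionless age-scaling
factor; the AD development rate is ``omega(t) = gamma U(t)``.  For the
linear schedules S(t) = S(0)(1 + t/lambda_S), kappa(t) =
kappa(0)(1 - t/lambda_kappa) and (optionally) sigma(t) =
sigma_0(1 + t/lambda_sigma),

    Xi(t) = (1 + t/lambda_S)^2 / (1 - t/lambda_kappa)^2
            * [1 + t/lambda_sigma]        (only if sigma drifts)

and its antiderivative is available in closed form, so every
epidemiological curve here is evaluated without numerical quadrature:

    V(t) = exp(-F U0 int_0^t Xi)         viability (hippocampal-volume proxy)
    H(t) = V(t)^gamma                    survivorship (AD-free fraction)
    I(t) = F gamma U0 Xi(t)              incidence
    P(t) = 1 - exp(-int_{t-T_D}^t I)     prevalence
    Y(t1,t2) = 1 - exp(-int_{t1}^{t2} I) lifetime risk

``F`` >= 1 is the AD-pathology damage multiplier (damage rate in the AD
subpopulation relative to the general population).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .parameters import (DomainError, ParameterSet, ValidationError,
                         YEAR_SECONDS, derived_scales)
from .kinetics import RateSchedule, dynamic_schedule, static_schedule


def _check_ages(schedule: RateSchedule, t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("ages must be nonnegative")
    if np.any(t >= schedule.params.lambda_kappa):
        raise DomainError(
            "model loses validity for t near "
            f"{schedule.params.lambda_kappa:g} yr")
    return t


def xi(schedule: RateSchedule, t):
    """Dimensionless damage-rate scaling Xi(t); Xi(0) = 1."""
    t = _check_ages(schedule, t)
    if not schedule.is_dynamic:
        return np.ones_like(t) if t.shape else 1.0
    p = schedule.params
    out = (1.0 + t / p.lambda_S) ** 2 / (1.0 - t / p.lambda_kappa) ** 2
    if p.has_toxicity_schedule:
        out = out * (1.0 + t / p.lambda_sigma)
    return out


def xi_antiderivative(schedule: RateSchedule, t):
    """Closed-form antiderivative Phi(t) = int_0^t Xi(s) ds, in years.

    Xi is a rational function of t whose antiderivative follows from the
    substitution u = 1 - t/lambda_kappa, under which the numerator becomes
    a polynomial in u over u^2; the result is normalized so Phi(0) = 0.
    """
    t = _check_ages(schedule, t)
    if not schedule.is_dynamic:
        return t.copy() if t.shape else float(t)
    p = schedule.params
    a = 1.0 / p.lambda_S
    b = 1.0 / p.lambda_kappa
    # (1 + a t) = ((a+b) - a u)/b as a polynomial in u = 1 - b t
    poly = np.polynomial.Polynomial([(a + b) / b, -a / b]) ** 2
    if p.has_toxicity_schedule:
        c = 1.0 / p.lambda_sigma
        poly = poly * np.polynomial.Polynomial([(b + c) / b, -c / b])
    n = poly.coef  # numerator coefficients in u

    def F(u):
        # -(1/b) * int (sum n_k u^k) / u^2 du
        acc = n[0] / u - n[1] * np.log(u)
        for k in range(2, len(n)):
            acc -= n[k] * u ** (k - 1) / (k - 1)
        return acc / b

    u = 1.0 - b * t
    return F(u) - F(1.0)


def xi_integral(schedule: RateSchedule, t1, t2):
    """Exact integral of Xi over [t1, t2], in years."""
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if np.any(t2 < t1):
        raise DomainError("t2 must be >= t1")
    return xi_antiderivative(schedule, t2) - xi_antiderivative(schedule, t1)


@dataclass(frozen=True)
class HazardModel:
    """Age-dependent damage/AD hazard U(t) = F U0 Xi(t), omega = gamma U.

    ``U0`` is the neuronal damage rate at birth in yr^-1; ``F`` the
    AD-pathology damage multiplier (1 for the general population).
    """

    schedule: RateSchedule
    U0: float          # yr^-1
    gamma: float
    F: float = 1.0

    def __post_init__(self) -> None:
        if self.U0 < 0:
            raise ValidationError("U0 must be nonnegative")
        if not 0 < self.gamma <= 1:
            raise ValidationError("gamma must lie in (0, 1]")
        if self.F <= 0:
            raise ValidationError("F must be positive")

    @classmethod
    def from_parameters(
        cls,
        p: ParameterSet,
        mode: str = "linear",
        F: float = 1.0,
        gamma: Optional[float] = None,
        U0_per_year: Optional[float] = None,
    ) -> "HazardModel":
        """Build the hazard from kinetic constants: U0 = sigma(0) nu S(0)^2
        / (kappa(0)^2 mu).  ``U0_per_year`` overrides the computed value
        (e.g. to pin a published rounded rate)."""
        schedule = RateSchedule(params=p, mode=mode)
        if U0_per_year is None:
            sigma0 = p.sigma_0 if (mode == "linear" and p.has_toxicity_schedule) else p.sigma_bar
            M0 = p.S_bar / p.kappa_bar
            U0_per_year = sigma0 * p.nu_bar * M0**2 / p.mu_bar * YEAR_SECONDS
        return cls(schedule=schedule, U0=U0_per_year,
                   gamma=p.gamma if gamma is None else gamma, F=F)

    @property
    def omega0(self) -> float:
        """AD development rate at birth, yr^-1 (before the F multiplier)."""
        return self.gamma * self.U0

    def U(self, t):
        """Neuronal damage rate at age t, yr^-1."""
        return self.F * self.U0 * xi(self.schedule, t)

    def incidence(self, t):
        """AD incidence I(t) = F gamma U0 Xi(t), yr^-1."""
        return self.F * self.omega0 * xi(self.schedule, t)

    def cumulative_damage(self, t):
        """int_0^t U(s) ds (dimensionless)."""
        return self.F * self.U0 * xi_antiderivative(self.schedule, t)

    def viability(self, t):
        """V(t) = exp(-int_0^t U); hippocampal-volume proxy, V(0) = 1."""
        return np.exp(-self.cumulative_damage(t))

    def survivorship(self, t):
        """H(t) = V(t)^gamma, the AD-free fraction."""
        return self.viability(t) ** self.gamma

    def hv_annual_change(self, t):
        """-V'(t)/V(t) = U(t): fractional rate of viability (HV) loss, yr^-1."""
        return self.U(t)

    def prevalence(self, t, T_D: float):
        """P(t) = 1 - exp(-int_{max(0, t-T_D)}^t I(s) ds)."""
        t = np.asarray(t, dtype=float)
        lo = np.maximum(0.0, t - T_D)
        J = (xi_antiderivative(self.schedule, t)
             - xi_antiderivative(self.schedule, lo))
        out = 1.0 - np.exp(-self.F * self.omega0 * J)
        return out if out.shape else float(out)

    def lifetime_risk(self, t1: float, t2: float) -> float:
        """Y(t1, t2) = 1 - exp(-int_{t1}^{t2} I(s) ds)."""
        J = xi_integral(self.schedule, t1, t2)
        return float(1.0 - np.exp(-self.F * self.omega0 * J))


def T_D_in_years(p: ParameterSet, choice: str = "years") -> float:
    """Select the survival-after-diagnosis duration: the year-denominated
    value or the alternate seconds-denominated one (they differ in the
    source table; callers must pick)."""
    if choice == "years":
        return p.T_D_years
    if choice == "seconds":
        return p.T_D_seconds / YEAR_SECONDS
    raise ValidationError(f"T_D choice must be 'years' or 'seconds', got {choice!r}")


@dataclass
class EpiCurves:
    """Age-indexed epidemiological curves for one scenario."""

    ages: np.ndarray       # years
    V: np.ndarray          # viability fraction
    H: np.ndarray          # survivorship fraction
    I: np.ndarray          # incidence, yr^-1
    P: np.ndarray          # prevalence fraction
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "age_years": self.ages,
            "viability": self.V,
            "survivorship": self.H,
            "incidence_per_year": self.I,
            "prevalence": self.P,
        })


def epi_curves(hazard: HazardModel, ages, T_D: Optional[float] = None,
               T_D_choice: str = "years") -> EpiCurves:
    """Evaluate V, H, I, P on an age grid via the closed-form Xi integral."""
    ages = _check_ages(hazard.schedule, ages)
    if T_D is None:
        T_D = T_D_in_years(hazard.schedule.params, T_D_choice)
    V = hazard.viability(ages)
    return EpiCurves(
        ages=ages,
        V=V,
        H=V ** hazard.gamma,
        I=np.asarray(hazard.incidence(ages), dtype=float),
        P=np.asarray(hazard.prevalence(ages, T_D), dtype=float),
        meta={"mode": hazard.schedule.mode, "F": hazard.F,
              "gamma": hazard.gamma, "U0_per_year": hazard.U0, "T_D_years": T_D},
    )


def doubling_time(ages, values, window: tuple[float, float] = (60.0, 90.0)) -> float:
    """Doubling time from an OLS fit of log2(values) against age.

    Returns 1/slope in years; +inf if the fitted slope is nonpositive.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = (ages >= window[0]) & (ages <= window[1])
    if not np.any(mask):
        raise ValueError("window contains no grid points")
    if np.any(values[mask] <= 0):
        raise ValueError("curve must be strictly positive on the fit window")
    slope = np.polyfit(ages[mask], np.log2(values[mask]), 1)[0]
    if slope <= 0:
        return float("inf")
    return float(1.0 / slope)


def incidence_doubling_time(hazard: HazardModel,
                            window: tuple[float, float] = (60.0, 90.0)) -> float:
    """Doubling time of I(t) over ``window`` on a 1-year grid."""
    ages = np.arange(window[0], window[1] + 0.5)
    return doubling_time(ages, hazard.incidence(ages), window)


def prevalence_doubling_time(hazard: HazardModel, T_D: float,
                             window: tuple[float, float] = (60.0, 90.0)) -> float:
    """Doubling time of P(t) over ``window`` on a 1-year grid."""
    ages = np.arange(window[0], window[1] + 0.5)
    return doubling_time(ages, hazard.prevalence(ages, T_D), window)


def scenario_ratio(scenario_a: HazardModel, scenario_b: HazardModel,
                   quantity: str, t, t_b=None,
                   T_D: Optional[float] = None,
                   T_D_choice: str = "years") -> float:
    """Ratio of ``quantity`` between two scenarios.

    ``quantity`` is ``"prevalence"``, ``"viability"`` or ``"incidence"``.
    ``t`` is the evaluation age for scenario A; ``t_b`` defaults to the
    same age (cross-age comparisons, e.g. viability at different mean
    cohort ages, pass both).
    """
    if t_b is None:
        t_b = t
    if quantity == "prevalence":
        if T_D is None:
            T_D = T_D_in_years(scenario_a.schedule.params, T_D_choice)
        return float(scenario_a.prevalence(t, T_D) / scenario_b.prevalence(t_b, T_D))
    if quantity == "viability":
        return float(scenario_a.viability(t) / scenario_b.viability(t_b))
    if quantity == "incidence":
        return float(scenario_a.incidence(t) / scenario_b.incidence(t_b))
    raise ValidationError(f"unknown quantity {quantity!r}")


def static_hazard(p: ParameterSet, **kwargs) -> HazardModel:
    """Hazard with all rate constants at their baseline values."""
    return HazardModel.from_parameters(p, mode="static", **kwargs)


def dynamic_hazard(p: ParameterSet, **kwargs) -> HazardModel:
    """Hazard with the linear S and kappa drifts (and sigma if configured)."""
    return HazardModel.from_parameters(p, mode="linear", **kwargs)
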