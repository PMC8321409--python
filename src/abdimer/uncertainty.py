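"""Sensitivity (elasticity) analysis and population heterogeneity in the
birth damage rate U0.

The elasticity of a response f with respect to a parameter q is
(q/f) df/dq — the percent change in f per percent change in q.  For the
birth AD-development rate omega0 = gamma sigma nu S^2 / (kappa^2 mu) the
elasticities are integers read off the power law: +2 in S, -2 in kappa,
+1 in nu, sigma and gamma, -1 in mu.

Heterogeneity: individuals carry U0 drawn from a discrete distribution
g(u) with mean U* and standard deviation Sigma*.  Conditioning on AD
status at age t (per-atom AD probability 1 - exp(-gamma u Phi(t)) with
Phi the Xi antiderivative) gives E[U0 | AD+] ~ U* + Sigma*^2/U* and
E[U0 | AD-] ~ U* for small cumulative hazard.  Because 1 - exp(-c u) is
concave in u, a mean-preserving spread of U0 lowers population prevalence
and incidence relative to the point mass at the mean (Jensen).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np

from .parameters import ParameterSet, ValidationError, derived_scales
from .epidemiology import HazardModel, xi, xi_antiderivative


def elasticity(response: Callable[[float], float], q0: float,
               method: str = "central") -> float:
    """(q0/f) df/dq at q0 by Richardson-refined central differences."""
    f0 = response(q0)
    if f0 == 0:
        raise ValueError("response must be nonzero at q0")
    if method != "central":
        raise ValidationError(f"unknown method {method!r}")
    h = 1e-6 * abs(q0)

    def cd(step):
        return (response(q0 + step) - response(q0 - step)) / (2 * step)

    d1 = cd(h)
    d2 = cd(h / 2)
    deriv = (4 * d2 - d1) / 3
    return q0 / f0 * deriv


#: analytic elasticities of omega0 with respect to each rate constant
OMEGA0_ELASTICITIES = {
    "S_bar": 2.0, "kappa_bar": -2.0, "mu_bar": -1.0,
    "nu_bar": 1.0, "sigma_bar": 1.0, "gamma": 1.0,
}


def omega0_of(p: ParameterSet) -> float:
    """omega0 = gamma sigma nu S^2 / (kappa^2 mu), s^-1."""
    return derived_scales(p).omega_bar


def omega0_elasticities_numeric(p: ParameterSet) -> dict:
    """Central-difference elasticities of omega0; should match the
    analytic integer table."""
    out = {}
    for name in OMEGA0_ELASTICITIES:
        q0 = getattr(p, name)
        out[name] = elasticity(
            lambda q, name=name: omega0_of(p.replace(**{name: q})), q0)
    return out


def prevalence_elasticity_omega0(hazard: HazardModel, t: float, T_D: float) -> float:
    """Elasticity of P(t) with respect to omega0: with J the Xi integral
    over the prevalent window, equals omega0 J e^{-omega0 J}/(1 - e^{-omega0 J})."""
    lo = max(0.0, t - T_D)
    J = hazard.F * (xi_antiderivative(hazard.schedule, t)
                    - xi_antiderivative(hazard.schedule, lo))
    x = hazard.omega0 * J
    return float(x * np.exp(-x) / (1.0 - np.exp(-x)))


@dataclass(frozen=True)
class DamageDistribution:
    """Finite discrete distribution of the birth damage rate U0 (s^-1 or
    yr^-1 — any consistent unit; the hazard context fixes it)."""

    atoms: tuple          # ((u, probability), ...)
    kind: str = "general-discrete"

    def __post_init__(self) -> None:
        atoms = tuple((float(u), float(pr)) for u, pr in self.atoms)
        if not atoms:
            raise ValidationError("distribution needs at least one atom")
        probs = np.array([pr for _, pr in atoms])
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
            raise ValidationError("probabilities must be nonnegative and sum to 1")
        if any(u < 0 for u, _ in atoms):
            raise ValidationError("U0 atoms must be nonnegative")
        object.__setattr__(self, "atoms", atoms)

    @property
    def values(self) -> np.ndarray:
        return np.array([u for u, _ in self.atoms])

    @property
    def probs(self) -> np.ndarray:
        return np.array([pr for _, pr in self.atoms])

    @property
    def U_star(self) -> float:
        """Mean."""
        return float(self.values @ self.probs)

    @property
    def Sigma_star(self) -> float:
        """Standard deviation."""
        m = self.U_star
        return float(np.sqrt(self.probs @ (self.values - m) ** 2))

    @classmethod
    def point(cls, u: float) -> "DamageDistribution":
        return cls(atoms=((u, 1.0),), kind="point")


def two_point_example(p: ParameterSet, F: float = 3.65) -> DamageDistribution:
    """The two-atom example distribution: U_bar/10 with probability 0.765
    and 3.93 U_bar with probability 0.235.  Its mean is U_bar and its
    spread satisfies Sigma*/U* ~ sqrt(F - 1) ~ 1.63 for F = 3.65 (the
    damage multiplier inferred for the AD subpopulation)."""
    U_bar = derived_scales(p).U_bar
    return DamageDistribution(
        atoms=((U_bar / 10.0, 0.765), (3.93 * U_bar, 0.235)),
        kind="two_point")


class ConditionalMeans(NamedTuple):
    ad_pos: float          # exact E[U0 | AD+]
    ad_neg: float          # exact E[U0 | AD-]
    approx_pos: float      # U* + Sigma*^2/U*
    approx_neg: float      # U*
    small_t_limit: bool    # True if AD probability was ~0 and the t->0
                           # limit E[U0^2]/E[U0] was returned for ad_pos


def conditional_damage_means(dist: DamageDistribution, hazard: HazardModel,
                             t: float) -> ConditionalMeans:
    """Mean U0 among AD+ and AD- individuals at age t by exact Bayes
    conditioning over the atoms, alongside the small-hazard approximations."""
    u = dist.values
    pr = dist.probs
    Phi = xi_antiderivative(hazard.schedule, t)
    # per-atom AD probability, with U0 rescaled to the hazard's yr^-1 unit
    p_ad = 1.0 - np.exp(-hazard.gamma * hazard.F
                        * u * _unit_factor(dist, hazard) * Phi)
    mass_pos = pr @ p_ad
    mass_neg = pr @ (1.0 - p_ad)
    U_star, Sigma_star = dist.U_star, dist.Sigma_star
    approx_pos = U_star + Sigma_star**2 / U_star
    small_t = False
    if mass_pos <= 0:
        # t -> 0 limit: P(AD | u) proportional to u
        ad_pos = float((pr @ u**2) / (pr @ u))
        small_t = True
    else:
        ad_pos = float((pr * p_ad) @ u / mass_pos)
    ad_neg = float((pr * (1.0 - p_ad)) @ u / mass_neg) if mass_neg > 0 else float("nan")
    return ConditionalMeans(ad_pos=ad_pos, ad_neg=ad_neg,
                            approx_pos=approx_pos, approx_neg=U_star,
                            small_t_limit=small_t)


def _unit_factor(dist: DamageDistribution, hazard: HazardModel) -> float:
    """Convert the distribution's U0 unit to the hazard's yr^-1 scale by
    matching means: a distribution with mean U* stands in for the
    hazard's U0."""
    if dist.U_star == 0:
        return 1.0
    return hazard.U0 / dist.U_star


class DistributionEffect(NamedTuple):
    ages: np.ndarray
    P_dist: np.ndarray
    P_fixed: np.ndarray
    I_dist: np.ndarray
    I_fixed: np.ndarray

    @property
    def P_difference(self) -> np.ndarray:
        return self.P_dist - self.P_fixed

    @property
    def I_difference(self) -> np.ndarray:
        return self.I_dist - self.I_fixed


def distribution_effect(dist: DamageDistribution, hazard: HazardModel,
                        ages, T_D: float) -> DistributionEffect:
    """Population prevalence/incidence under a U0 distribution vs the
    point mass at its mean.

    The mixture prevalence averages the per-atom prevalence; the mixture
    incidence is the hazard of the mixture survivorship (atoms weighted
    by their probability of still being AD-free).  Jensen's inequality
    gives P_dist <= P_fixed and I_dist <= I_fixed pointwise.
    """
    ages = np.asarray(ages, dtype=float)
    u = dist.values * _unit_factor(dist, hazard)   # yr^-1, mean = hazard.U0
    pr = dist.probs
    g = hazard.gamma * hazard.F
    Phi_t = xi_antiderivative(hazard.schedule, ages)
    Phi_lo = xi_antiderivative(hazard.schedule, np.maximum(0.0, ages - T_D))
    J = Phi_t - Phi_lo                              # (n_ages,)
    # per-atom curves: shape (n_atoms, n_ages)
    P_atoms = 1.0 - np.exp(-g * np.outer(u, J))
    P_dist = pr @ P_atoms
    P_fixed = 1.0 - np.exp(-g * hazard.U0 * J)
    H_atoms = np.exp(-g * np.outer(u, Phi_t))       # AD-free fraction per atom
    weights = pr[:, None] * H_atoms
    xi_t = xi(hazard.schedule, ages)
    I_dist = g * (weights * u[:, None]).sum(axis=0) / weights.sum(axis=0) * xi_t
    I_fixed = g * hazard.U0 * xi_t
    return DistributionEffect(ages=ages, P_dist=P_dist, P_fixed=P_fixed,
                              I_dist=np.asarray(I_dist), I_fixed=np.asarray(I_fixed))
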