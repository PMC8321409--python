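"""Spherically symmetric steady profile around a focal excess of monomer
production, with a finite-difference oracle.

With static rate constants, a sphere of radius ``X*`` in which monomer
production is raised from S to S(1+rho) produces the steady monomer field

    M(r) = M_bar + rho M_bar * m(lambda r),   lambda = sqrt(kappa/D_M)

where, writing q = lambda r and qs = lambda X*,

    m(q) = 1 - (1 + qs) e^{-qs} sinh(q)/q          (r <  X*)
    m(q) = e^{-q}/q * (qs cosh(qs) - sinh(qs))     (r >= X*)

(the piecewise sinh/cosh kernel solution of D_M Laplacian(M) - kappa M +
S(r) = 0 with zero flux at the origin and M -> M_bar far away; the two
branches match in value and flux at X*).  Dimers are slaved to the local
monomer concentration, D(r) = nu M(r)^2 / mu, and viability decays as
V(r, t) = exp(-sigma D(r) t) — no dimer PDE is solved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .parameters import ParameterSet, ValidationError, YEAR_SECONDS, derived_scales


@dataclass(frozen=True)
class FocalSourceSpec:
    """Focal production excess: fraction ``rho`` inside radius ``X_star``."""

    rho: float = 0.231        # fractional production excess
    X_star: float | None = None  # sphere radius, cm (default 2 x_bar)
    R_max: float | None = None   # far-field truncation, cm (default 20 x_bar)

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValidationError("rho must be nonnegative")
        if self.X_star is not None and self.X_star <= 0:
            raise ValidationError("X_star must be positive")

    def resolved(self, p: ParameterSet) -> tuple[float, float, float]:
        """(rho, X_star, R_max) with defaults filled from x_bar."""
        x_bar = derived_scales(p).x_bar
        X_star = 2.0 * x_bar if self.X_star is None else self.X_star
        R_max = 20.0 * x_bar if self.R_max is None else self.R_max
        if not 0 < X_star < R_max:
            raise ValidationError("need 0 < X_star < R_max")
        return self.rho, X_star, R_max


@dataclass
class SpatialProfile:
    """Radial monomer/dimer concentrations and viability fields."""

    radii: np.ndarray                 # cm
    M: np.ndarray                     # molar
    D: np.ndarray                     # molar
    V_at_ages: dict = field(default_factory=dict)  # age (years) -> array

    def to_frame(self):
        import pandas as pd

        data = {"radius_cm": self.radii, "M_molar": self.M, "D_molar": self.D}
        for age, V in self.V_at_ages.items():
            data[f"viability_age_{age:g}"] = V
        return pd.DataFrame(data)


DEFAULT_AGES = (40.0, 60.0, 80.0)


def _viability_fields(p: ParameterSet, D: np.ndarray, ages) -> dict:
    return {float(age): np.exp(-p.sigma_bar * D * float(age) * YEAR_SECONDS)
            for age in ages}


def analytic_profile(spec: FocalSourceSpec, p: ParameterSet, radii,
                     ages=DEFAULT_AGES) -> SpatialProfile:
    """Evaluate the closed-form piecewise profile on ``radii`` (cm)."""
    rho, X_star, _ = spec.resolved(p)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValidationError("radii must be positive")
    lam = np.sqrt(p.kappa_bar / p.D_M)
    M_bar = p.S_bar / p.kappa_bar
    q = lam * radii
    qs = lam * X_star
    inner = 1.0 - (1.0 + qs) * np.exp(-qs) * np.sinh(q) / q
    outer = np.exp(-q) / q * (qs * np.cosh(qs) - np.sinh(qs))
    m = np.where(radii < X_star, inner, outer)
    M = M_bar * (1.0 + rho * m)
    D = p.nu_bar * M**2 / p.mu_bar
    return SpatialProfile(radii=radii, M=M, D=D,
                          V_at_ages=_viability_fields(p, D, ages))


def branch_mismatch_at_interface(spec: FocalSourceSpec, p: ParameterSet) -> float:
    """Relative gap between the interior and exterior branch values at X*."""
    rho, X_star, _ = spec.resolved(p)
    lam = np.sqrt(p.kappa_bar / p.D_M)
    qs = lam * X_star
    inner = 1.0 - (1.0 + qs) * np.exp(-qs) * np.sinh(qs) / qs
    outer = np.exp(-qs) / qs * (qs * np.cosh(qs) - np.sinh(qs))
    M_bar = p.S_bar / p.kappa_bar
    a = M_bar * (1.0 + spec.rho * inner)
    b = M_bar * (1.0 + spec.rho * outer)
    return abs(a - b) / M_bar


def radial_fd_oracle(spec: FocalSourceSpec, p: ParameterSet,
                     n_points: int = 4000, ages=DEFAULT_AGES) -> SpatialProfile:
    """Second-order finite-difference solution of the steady radial problem.

    Solves D_M (1/r^2)(r^2 M')' - kappa M + S(r) = 0 via the substitution
    w = r M, which gives w'' - (kappa/D_M) w = -r S(r)/D_M with w(0) = 0
    and a Dirichlet far-field w(R_max) = R_max S_bar/kappa.  The grid is
    uniform with X* placed exactly on a node (the source is discontinuous
    there).  Independent of :func:`analytic_profile`; used to verify it.
    """
    rho, X_star, R_max = spec.resolved(p)
    x_bar = derived_scales(p).x_bar
    if n_points < 20 * R_max / x_bar:
        raise ValidationError("grid must resolve x_bar with >= 20 points")
    # align X_star with the grid
    n_in = max(1, round(n_points * X_star / R_max))
    h = X_star / n_in
    n = int(np.ceil(R_max / h))
    r = h * np.arange(n + 1)
    M_bar = p.S_bar / p.kappa_bar
    lam2 = p.kappa_bar / p.D_M

    S = np.full(n + 1, p.S_bar)
    S[r < X_star] = p.S_bar * (1.0 + rho)
    S[n_in] = p.S_bar * (1.0 + rho / 2.0)  # interface node: average of the jump

    # unknowns w_1..w_{n-1}; w_0 = 0, w_n = R_max * M_bar
    ab = np.zeros((3, n - 1))
    ab[0, 1:] = 1.0 / h**2
    ab[1, :] = -2.0 / h**2 - lam2
    ab[2, :-1] = 1.0 / h**2
    rhs = -r[1:n] * S[1:n] / p.D_M
    rhs[-1] -= (R_max * M_bar) / h**2
    w = solve_banded((1, 1), ab, rhs)
    M = np.empty(n + 1)
    M[1:n] = w / r[1:n]
    M[n] = M_bar
    # regularity at the origin: M even in r, quadratic extrapolation
    M[0] = (4.0 * M[1] - M[2]) / 3.0
    D = p.nu_bar * M**2 / p.mu_bar
    return SpatialProfile(radii=r, M=M, D=D,
                          V_at_ages=_viability_fields(p, D, ages))
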