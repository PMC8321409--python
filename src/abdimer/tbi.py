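"""Relative AD hazard after repeated traumatic brain injury (TBI).

Each TBI is assumed to raise the monomer production rate permanently by a
fixed increment A, i.e. S -> S(1 + a n) after n TBIs with a = A/S.
Because the AD development rate scales with S^2, the hazard relative to
the uninjured population is

    R(n) = (1 + a n)^2.

The one free parameter ``a`` is fitted to a hazard-ratio table by
weighted nonlinear least squares; the published fit gives a = 0.231.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .parameters import ParameterSet, ValidationError
from .kinetics import RateSchedule

#: published per-TBI fractional production increase
A_FITTED = 0.231


@dataclass(frozen=True)
class HazardTable:
    """Observed relative hazards R(n) with standard errors."""

    n: np.ndarray    # TBI counts
    R: np.ndarray    # relative hazard vs n = 0
    se: np.ndarray   # standard errors

    def __post_init__(self) -> None:
        n = np.asarray(self.n, dtype=float)
        R = np.asarray(self.R, dtype=float)
        se = np.asarray(self.se, dtype=float)
        if not (n.shape == R.shape == se.shape):
            raise ValidationError("n, R, se must have matching shapes")
        if np.any(n < 0) or np.any(n != np.round(n)):
            raise ValidationError("n must be nonnegative integers")
        if np.any(R <= 0):
            raise ValidationError("relative hazards must be positive")
        if np.any(se <= 0):
            raise ValidationError("standard errors must be positive")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "se", se)

    @classmethod
    def from_frame(cls, frame) -> "HazardTable":
        return cls(n=frame["n_tbi"].to_numpy(),
                   R=frame["relative_hazard"].to_numpy(),
                   se=frame["se"].to_numpy())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"n_tbi": self.n.astype(int),
                             "relative_hazard": self.R, "se": self.se})


def relative_hazard(n, a: float):
    """R(n) = (1 + a n)^2."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValidationError("n must be nonnegative")
    if a < 0:
        raise ValidationError("a must be nonnegative")
    out = (1.0 + a * n) ** 2
    return out if out.shape else float(out)


def fit_hazard_slope(table: HazardTable, include_anchor: bool = False
                     ) -> tuple[float, tuple[float, float]]:
    """Weighted nonlinear least-squares fit of a in R(n) = (1 + a n)^2.

    Weights are inverse-variance (1/se^2) on the hazard-ratio scale.
    ``include_anchor`` adds the definitional point (n=0, R=1) with the
    smallest tabulated standard error.  Returns the estimate and a 95%
    interval from the linearized covariance.
    """
    n, R, se = table.n, table.R, table.se
    if not include_anchor:
        keep = n >= 1
        n, R, se = n[keep], R[keep], se[keep]
    if np.unique(n[n >= 1]).size < 2:
        raise ValidationError("need >= 2 distinct n >= 1 to fit the slope")

    def model(nn, a):
        return (1.0 + a * nn) ** 2

    popt, pcov = curve_fit(model, n, R, p0=[0.2], sigma=se,
                           absolute_sigma=True, bounds=(0.0, np.inf))
    a_hat = float(popt[0])
    se_a = float(np.sqrt(pcov[0, 0]))
    return a_hat, (a_hat - 1.96 * se_a, a_hat + 1.96 * se_a)


def tbi_parameters(p: ParameterSet, n_tbi: int, a: float = A_FITTED) -> ParameterSet:
    """Scenario with production raised to S(1 + a n); in the dynamic
    schedule this becomes S(t) = S_bar (1 + a n)(1 + t/lambda_S)."""
    if n_tbi < 0:
        raise ValidationError("n_tbi must be nonnegative")
    return p.replace(S_bar=p.S_bar * (1.0 + a * n_tbi))


def tbi_schedule(p: ParameterSet, n_tbi: int, a: float = A_FITTED,
                 mode: str = "linear") -> RateSchedule:
    return RateSchedule(params=tbi_parameters(p, n_tbi, a), mode=mode)
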