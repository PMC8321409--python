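"""Calibration: oligomer toxicity sigma from viability assays, the risk
elasticity gamma from an incidence anchor, the AD-pathology factor F from
hippocampal-volume loss rates, and the age-dependent toxicity variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .parameters import ParameterSet, ValidationError
from .kinetics import RateSchedule
from .epidemiology import HazardModel, xi

#: published age-dependent toxicity configuration: sigma(t) =
#: sigma_0 (1 + t/lambda_sigma) with sigma_0 = 0.107 sigma_bar,
#: doubling time 9.01 y, and gamma refitted to 0.732
TOXICITY_LAMBDA_SIGMA = 9.01
TOXICITY_SIGMA0_FACTOR = 0.107
TOXICITY_GAMMA = 0.732


@dataclass(frozen=True)
class ViabilityAssay:
    """Rows of (oligomer concentration, exposure time, viability, se).

    The assay's oligomer concentration plays the role of the dimer
    concentration D in the hazard model V = exp(-sigma D t).
    """

    conc_molar: np.ndarray
    time_hours: np.ndarray
    viability: np.ndarray
    se: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.conc_molar, dtype=float)
        t = np.asarray(self.time_hours, dtype=float)
        v = np.asarray(self.viability, dtype=float)
        se = np.asarray(self.se, dtype=float)
        if not (c.shape == t.shape == v.shape == se.shape):
            raise ValidationError("assay columns must have matching shapes")
        if np.any(c < 0):
            raise ValidationError("concentrations must be nonnegative")
        if np.any((v < 0) | (v > 1.2)):
            raise ValidationError("viability must lie in [0, 1.2]")
        if np.any(se <= 0):
            raise ValidationError("standard errors must be positive")
        for name, arr in (("conc_molar", c), ("time_hours", t),
                          ("viability", v), ("se", se)):
            object.__setattr__(self, name, arr)

    @classmethod
    def from_frame(cls, frame) -> "ViabilityAssay":
        return cls(conc_molar=frame["conc_molar"].to_numpy(),
                   time_hours=frame["time_hours"].to_numpy(),
                   viability=frame["viability"].to_numpy(),
                   se=frame["se"].to_numpy())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"conc_molar": self.conc_molar,
                             "time_hours": self.time_hours,
                             "viability": self.viability, "se": self.se})


def fit_sigma(assay: ViabilityAssay, errors: str = "se"
              ) -> tuple[float, tuple[float, float]]:
    """Weighted NLS fit of sigma in V = exp(-sigma D t), normalized to the
    zero-concentration control.

    ``errors`` is ``"se"`` (error bars are standard errors; weights
    1/se^2) or ``"sd"`` (bars are standard deviations; same weights up to
    the overall scale, which leaves the estimate unchanged and only
    rescales the interval).  Returns (sigma in M^-1 s^-1, 95% CI).
    """
    c = assay.conc_molar
    if np.all(c == 0):
        raise ValidationError("assay must include nonzero concentrations")
    if np.unique(c).size < 3:
        raise ValidationError("need >= 3 distinct concentrations")
    control = c == c.min()
    if c.min() > 0.05 * c.max():
        raise ValidationError("assay must include a control near zero concentration")
    v0 = assay.viability[control].mean()
    if v0 <= 0:
        raise ValidationError("control viability must be positive for normalization")
    keep = ~control
    x = c[keep] * assay.time_hours[keep] * 3600.0    # D*t, M s
    y = assay.viability[keep] / v0
    se = assay.se[keep] / v0
    if errors == "sd":
        se = se.copy()   # same relative weights; CI scaling handled below

    def model(dt, sigma):
        return np.exp(-sigma * dt)

    popt, pcov = curve_fit(model, x, y, p0=[1.0], sigma=se,
                           absolute_sigma=(errors == "se"),
                           bounds=(0.0, np.inf))
    s_hat = float(popt[0])
    s_se = float(np.sqrt(pcov[0, 0]))
    return s_hat, (s_hat - 1.96 * s_se, s_hat + 1.96 * s_se)


def calibrate_gamma(target_incidence: float, age: float,
                    hazard: HazardModel) -> float:
    """gamma making the scenario's incidence match ``target_incidence``
    (yr^-1) at ``age``: gamma = target / (F U0 Xi(age)).  Values above 1
    are clamped to 1 with a warning (gamma is a probability elasticity)."""
    if target_incidence <= 0:
        raise ValidationError("target incidence must be positive")
    U_at_age = hazard.F * hazard.U0 * xi(hazard.schedule, age)
    gamma = target_incidence / U_at_age
    if gamma > 1.0:
        warnings.warn(f"calibrated gamma = {gamma:.3g} exceeds 1; clamped")
        return 1.0
    return float(gamma)


def calibrate_F(target_hv_rate_pct: float, age: float,
                hazard: HazardModel) -> float:
    """F matching an observed annual HV loss rate (percent per year) at
    ``age``: F = target / (-V'/V of the unscaled model, in %/yr)."""
    if target_hv_rate_pct <= 0:
        raise ValidationError("target HV rate must be positive")
    base = 100.0 * hazard.U0 * xi(hazard.schedule, age)  # %/yr at F = 1
    return float(target_hv_rate_pct / base)


def toxicity_parameters(p: ParameterSet,
                        lambda_sigma: float = TOXICITY_LAMBDA_SIGMA,
                        sigma0_factor: float = TOXICITY_SIGMA0_FACTOR,
                        gamma: float = TOXICITY_GAMMA) -> ParameterSet:
    """Parameter set for the age-dependent toxicity variant."""
    if sigma0_factor <= 0:
        raise ValidationError("sigma_0 must be positive")
    return p.replace(lambda_sigma=lambda_sigma,
                     sigma_0=sigma0_factor * p.sigma_bar, gamma=gamma)


def toxicity_variant(p: ParameterSet, **kwargs) -> RateSchedule:
    """Linear sigma(t) schedule folded into the dynamic model; the extra
    Xi factor sigma(t)/sigma(0) = 1 + t/lambda_sigma."""
    return RateSchedule(params=toxicity_parameters(p, **kwargs), mode="linear")
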