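"""Model parameters and derived characteristic scales.

The model tracks amyloid-beta (Abeta) monomers and dimers in brain
interstitial fluid.  Monomers are produced at rate ``S`` (M s^-1), cleared
at rate ``kappa`` (s^-1), dimerize at rate ``nu`` (M^-1 s^-1) and dimers
dissociate at rate ``mu`` (s^-1).  Dimers kill neurons at rate
``sigma * D`` and the per-percent link between neuronal loss and AD risk
is the elasticity ``gamma``.

All internal computation is SI (seconds, molar); user-facing ages and
durations are in years.  Parameter values are stored at the 3 significant
figures they are reported with; no hidden extra precision is introduced.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

#: seconds per year (365 d)
YEAR_SECONDS = 3.1536e7


class ConfigurationError(KeyError):
    """A required configuration key is missing."""


class ValidationError(ValueError):
    """A parameter value violates its physical constraints."""


class DomainError(ValueError):
    """An age outside the model's validity window was requested."""


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic and epidemiological constants of the monomer-dimer model.

    Rates are SI (molar, seconds); ``lambda_*``, ``T_D_years`` and ``T_L``
    are in years.  ``T_D_seconds`` carries the alternate seconds-denominated
    survival time, which is not the same duration as ``T_D_years`` in the
    source table; callers select one explicitly.
    """

    S_bar: float          # monomer production rate, M s^-1
    kappa_bar: float      # monomer clearance rate, s^-1
    nu_bar: float         # dimerization rate, M^-1 s^-1
    mu_bar: float         # dimer dissociation rate, s^-1
    sigma_bar: float      # cell-dimer damage rate, M^-1 s^-1
    gamma: float          # neuronal-death elasticity of AD risk
    D_M: float            # monomer diffusivity, cm^2 s^-1
    D_D: float            # dimer diffusivity, cm^2 s^-1
    lambda_S: float       # production doubling time, years
    lambda_kappa: float   # clearance zero time, years
    T_D_years: float = 7.1     # survival time after diagnosis, years
    T_D_seconds: float = 2.23e9
    T_L: float = 78.5          # life expectancy, years
    lambda_sigma: Optional[float] = None  # toxicity doubling time, years
    sigma_0: Optional[float] = None       # toxicity intercept, M^-1 s^-1
    population: str = "general"

    def __post_init__(self) -> None:
        positive = {
            "S_bar": self.S_bar, "kappa_bar": self.kappa_bar,
            "nu_bar": self.nu_bar, "mu_bar": self.mu_bar,
            "sigma_bar": self.sigma_bar, "gamma": self.gamma,
            "D_M": self.D_M, "D_D": self.D_D,
            "lambda_S": self.lambda_S, "lambda_kappa": self.lambda_kappa,
            "T_D_years": self.T_D_years, "T_D_seconds": self.T_D_seconds,
            "T_L": self.T_L,
        }
        for name, value in positive.items():
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ValidationError(f"{name} must be a finite number, got {value!r}")
            if value <= 0:
                raise ValidationError(f"{name} must be strictly positive, got {value}")
        if not 0 < self.gamma <= 1:
            raise ValidationError(f"gamma must lie in (0, 1], got {self.gamma}")
        if (self.lambda_sigma is None) != (self.sigma_0 is None):
            raise ValidationError(
                "lambda_sigma and sigma_0 must be supplied together")
        if self.lambda_sigma is not None and self.lambda_sigma <= 0:
            raise ValidationError("lambda_sigma must be strictly positive")
        if self.sigma_0 is not None and self.sigma_0 <= 0:
            raise ValidationError("sigma_0 must be strictly positive")
        if self.population not in ("general", "down"):
            raise ValidationError(
                f"population must be 'general' or 'down', got {self.population!r}")

    @property
    def has_toxicity_schedule(self) -> bool:
        return self.lambda_sigma is not None

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass(frozen=True)
class DerivedScales:
    """Characteristic scales implied by a :class:`ParameterSet`."""

    M_bar: float       # characteristic monomer concentration, M
    D_bar: float       # characteristic dimer concentration, M
    U_bar: float       # characteristic neuronal damage rate, s^-1
    omega_bar: float   # characteristic AD development rate, s^-1
    x_bar: float       # characteristic lengthscale, cm
    t_bar: float       # characteristic timescale, s

    @property
    def U_bar_per_year(self) -> float:
        return self.U_bar * YEAR_SECONDS

    @property
    def omega_bar_per_year(self) -> float:
        return self.omega_bar * YEAR_SECONDS


# Baseline constants for the two populations.  The dimerization and
# dissociation rates carry the dimensionally consistent units
# (nu in M^-1 s^-1, mu in s^-1).
TABLE_GENERAL: dict = {
    "S_bar": 3.63e-12,
    "kappa_bar": 6.15e-5,
    "nu_bar": 115.0,
    "mu_bar": 0.400,
    "sigma_bar": 4.94,
    "gamma": 0.601,
    "D_M": 5.47e-7,
    "D_D": 4.30e-7,
    "lambda_S": 154.0,
    "lambda_kappa": 114.0,
    "T_D_years": 7.1,
    "T_D_seconds": 2.23e9,
    "T_L": 78.5,
    "population": "general",
}

TABLE_DOWN: dict = {
    **TABLE_GENERAL,
    "S_bar": 5.45e-12,
    "lambda_S": 86.2,
    "population": "down",
}

#: Derived scales as reported (3 s.f.), kept for exact reproduction of
#: downstream numbers that were computed from these rounded values.
PRINTED_SCALES: dict = {
    "M_bar": 5.90e-8,            # M
    "D_bar": 1.00e-12,           # M
    "U_bar": 4.94e-12,           # s^-1
    "U_bar_per_year": 1.56e-4,   # yr^-1
    "omega_bar": 2.96e-12,       # s^-1
    "omega_bar_per_year": 9.34e-5,  # yr^-1
    "x_bar": 9.43e-2,            # cm
    "t_bar": 1.62e4,             # s
}

_REQUIRED_KEYS = (
    "S_bar", "kappa_bar", "nu_bar", "mu_bar", "sigma_bar", "gamma",
    "D_M", "D_D", "lambda_S", "lambda_kappa",
)


def default_parameters(population: str = "general") -> ParameterSet:
    """Baseline :class:`ParameterSet` for the given population."""
    if population == "general":
        return ParameterSet(**TABLE_GENERAL)
    if population == "down":
        return ParameterSet(**TABLE_DOWN)
    raise ValidationError(f"unknown population {population!r}")


def load_parameters(config, population: str | None = None) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a config document.

    ``config`` may be a mapping, a JSON/TOML file path, or ``None`` (use
    the bundled defaults).  Keys absent from the config fall back to the
    defaults of the chosen population.
    """
    if config is None:
        data = {}
    elif isinstance(config, (str, Path)):
        path = Path(config)
        text = path.read_text()
        if path.suffix.lower() == ".toml":
            import tomllib
            data = tomllib.loads(text)
        else:
            data = json.loads(text)
    elif isinstance(config, dict):
        data = dict(config)
    else:
        raise TypeError(f"unsupported config type {type(config)!r}")

    pop = population or data.get("population") or "general"
    base = TABLE_DOWN if pop == "down" else TABLE_GENERAL
    merged = {**base, **data, "population": pop}
    unknown = set(merged) - {f.name for f in dataclasses.fields(ParameterSet)}
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    for key in _REQUIRED_KEYS:
        if merged.get(key) is None:
            raise ConfigurationError(f"missing required configuration key: {key}")
    return ParameterSet(**merged)


def derived_scales(p: ParameterSet) -> DerivedScales:
    """Characteristic scales: M = S/kappa, D = nu M^2 / mu, U = sigma D,
    omega = gamma U, x = sqrt(D_M/kappa), t = 1/kappa."""
    M_bar = p.S_bar / p.kappa_bar
    D_bar = p.nu_bar * M_bar**2 / p.mu_bar
    U_bar = p.sigma_bar * D_bar
    omega_bar = p.gamma * U_bar
    x_bar = math.sqrt(p.D_M / p.kappa_bar)
    t_bar = 1.0 / p.kappa_bar
    return DerivedScales(M_bar=M_bar, D_bar=D_bar, U_bar=U_bar,
                         omega_bar=omega_bar, x_bar=x_bar, t_bar=t_bar)
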