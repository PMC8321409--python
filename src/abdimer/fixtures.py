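"""Synthetic-data generators for the fitting and simulation paths.

Every generator is a pure function of its arguments and seed, emitting
the same tabular dialects the fitting routines read.  Viability noise is
multiplicative Gaussian (error bars on these assays scale with the
percent viability); hazard-ratio noise is additive Gaussian.
"""

from __future__ import annotations

import numpy as np

from .parameters import ValidationError
from .calibration import ViabilityAssay
from .tbi import HazardTable


def gen_viability_assay(sigma_truth: float, concentrations,
                        time_hours: float = 24.0, noise_sd: float = 0.0,
                        seed: int = 0) -> ViabilityAssay:
    """Viability table from V = exp(-sigma D t) (1 + eps), eps ~ N(0, sd),
    clipped at 0.  ``concentrations`` in molar; control rows (D = 0) are
    included as given."""
    if sigma_truth <= 0:
        raise ValidationError("sigma_truth must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    c = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    v_clean = np.exp(-sigma_truth * c * time_hours * 3600.0)
    v = v_clean
    if noise_sd > 0:
        v = v_clean * (1.0 + rng.normal(0.0, noise_sd, size=c.shape))
    v = np.clip(v, 0.0, 1.2)
    # multiplicative noise: the standard error of each row is sd * V
    se = np.maximum(noise_sd, 1e-6) * v_clean
    return ViabilityAssay(conc_molar=c, time_hours=np.full(c.shape, time_hours),
                          viability=v, se=se)


def gen_tbi_table(a_truth: float, n_values=(1, 2, 3, 4),
                  noise_sd: float = 0.0, seed: int = 0) -> HazardTable:
    """Hazard-ratio table from R = (1 + a n)^2 + eps, eps ~ N(0, sd)."""
    if a_truth < 0:
        raise ValidationError("a_truth must be nonnegative")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    n = np.asarray(n_values, dtype=float)
    rng = np.random.default_rng(seed)
    R = (1.0 + a_truth * n) ** 2
    if noise_sd > 0:
        R = np.maximum(R + rng.normal(0.0, noise_sd, size=n.shape), 1e-6)
    se = np.full(n.shape, noise_sd if noise_sd > 0 else 1e-6)
    return HazardTable(n=n, R=R, se=se)
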