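"""Tensioned-beam regression: axial stress on squared wave speed.

Ordinary least squares with the axial stress (Pa) as the dependent
variable and the squared wave speed (m^2/s^2) as the independent variable,
so the slope is directly the effective density (kg/m^3) and the intercept
estimates ``-k'*mu``.  A slope deviating from the expected tissue density
by more than +/-10 % is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegressionResult",
    "fit_wave_speed_stress",
    "flag_slope_deviation",
    "results_table",
    "REFERENCE_DENSITY",
]

REFERENCE_DENSITY = 1500.0  # kg/m^3, expected slope for an ideal tensioned beam


@dataclass(frozen=True)
class RegressionResult:
    """Effective-density fit for one (cohort, twist, subtendon) condition."""

    slope: float  # kg/m^3
    intercept: float  # Pa, estimate of -k'*mu
    r_squared: float
    n: int
    subtendon: str = ""
    cohort: str = ""
    twist_deg: float = np.nan
    reference: float = REFERENCE_DENSITY

    @property
    def kprime_mu(self) -> float:
        """Lumped shear-correction term k'*mu implied by the intercept, Pa."""
        return -self.intercept

    @property
    def deviation_flag(self) -> bool:
        return flag_slope_deviation(self.slope, self.reference)


def fit_wave_speed_stress(
    speeds,
    stresses,
    subtendon: str = "",
    cohort: str = "",
    twist_deg: float = np.nan,
    reference: float = REFERENCE_DENSITY,
) -> RegressionResult:
    """OLS of stress (Pa) on squared wave speed (m^2/s^2).

    Requires at least 3 paired points, positive speeds and non-degenerate
    (non-constant) squared speeds.
    """
    c = np.asarray(speeds, dtype=float)
    sigma = np.asarray(stresses, dtype=float)
    if c.shape != sigma.shape or c.ndim != 1:
        raise ValueError("speeds and stresses must be 1-D arrays of equal length")
    if c.size < 3:
        raise ValueError("need at least 3 points for the regression")
    if np.any(c <= 0) or not np.all(np.isfinite(c)):
        raise ValueError("speeds must be positive and finite")
    c2 = c**2
    if np.ptp(c2) <= 1e-12 * max(1.0, np.max(c2)):
        raise ValueError("degenerate input: squared speeds are constant")
    slope, intercept = np.polyfit(c2, sigma, 1)
    pred = slope * c2 + intercept
    ss_res = float(np.sum((sigma - pred) ** 2))
    ss_tot = float(np.sum((sigma - sigma.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        n=int(c.size),
        subtendon=subtendon,
        cohort=cohort,
        twist_deg=twist_deg,
        reference=reference,
    )


def flag_slope_deviation(slope: float, reference: float = REFERENCE_DENSITY) -> bool:
    """True iff the slope deviates from the reference by strictly more than 10 %."""
    if reference <= 0:
        raise ValueError("reference density must be positive")
    return abs(slope - reference) / reference > 0.10


def results_table(results) -> pd.DataFrame:
    """Tidy table: one row per (cohort, twist, subtendon) fit."""
    rows = [
        {
            "cohort": r.cohort,
            "twist_deg": r.twist_deg,
            "subtendon": r.subtendon,
            "slope_kg_m3": r.slope,
            "intercept_pa": r.intercept,
            "kprime_mu_pa": r.kprime_mu,
            "r_squared": r.r_squared,
            "n": r.n,
            "deviation_flag": r.deviation_flag,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
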