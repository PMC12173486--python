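"""Transversely isotropic fibre-reinforced constitutive relations.

A tendon subtendon is modelled as longitudinal collagen fibres embedded in
an isotropic Mooney-Rivlin ground matrix.  The fibre contribution to the
axial stress is a three-branch piecewise law: slack below unit stretch,
exponential while the crimped fibres straighten, and linear once fully
engaged.  The transverse wave restoring force of the tensioned tissue is
captured by the closed-form tensioned-beam speed ``c = sqrt((sigma +
k'*mu)/rho)``.

All quantities are SI internally (Pa, kg/m^3, m/s).  The conventional
parameter table is written in MPa; use :meth:`MaterialParams.from_table`
(or :meth:`MaterialParams.default`) to ingest MPa values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

MPA = 1.0e6

__all__ = [
    "MaterialParams",
    "derive_c6",
    "fiber_stress_term",
    "matrix_shear_modulus",
    "closed_form_wave_speed",
    "stress_from_wave_speed",
]


@dataclass(frozen=True)
class MaterialParams:
    """Constitutive constants of the subtendon material (SI units).

    Attributes
    ----------
    rho : float
        Mass density, kg/m^3.
    c1, c2 : float
        Mooney-Rivlin ground-matrix coefficients, Pa.
    c3 : float
        Scale of the exponential fibre-uncrimping stress, Pa.
    c4 : float
        Dimensionless rate of fibre uncrimping.
    c5 : float
        Elastic modulus of straightened fibres, Pa.
    lambda_star : float
        Fibre engagement stretch (> 1), dimensionless.
    bulk : float
        Bulk modulus enforcing near-incompressibility, Pa.  Only consumed
        by the FEBio writer; the reduced-order dynamics never use it.
    """

    rho: float
    c1: float
    c2: float
    c3: float
    c4: float
    c5: float
    lambda_star: float
    bulk: float

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError(f"density must be positive, got {self.rho}")
        for name in ("c1", "c2", "c3", "c4", "c5", "bulk"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.lambda_star <= 1.0:
            raise ValueError(f"lambda_star must exceed 1, got {self.lambda_star}")

    @classmethod
    def from_table(
        cls,
        rho: float,
        c1_mpa: float,
        c2_mpa: float,
        c3_mpa: float,
        c4: float,
        c5_mpa: float,
        lambda_star: float,
        bulk_mpa: float | None = None,
    ) -> "MaterialParams":
        """Build from MPa-valued table entries; ``bulk`` defaults to 1000*C1."""
        if bulk_mpa is None:
            bulk_mpa = 1.0e3 * c1_mpa
        return cls(
            rho=rho,
            c1=c1_mpa * MPA,
            c2=c2_mpa * MPA,
            c3=c3_mpa * MPA,
            c4=c4,
            c5=c5_mpa * MPA,
            lambda_star=lambda_star,
            bulk=bulk_mpa * MPA,
        )

    @classmethod
    def default(cls) -> "MaterialParams":
        """Default tendon parameter set (rho=1500, C1=C2=2.05 MPa, C3=1.75 MPa,
        C4=50, C5=350 MPa, lambda*=1.03, K=1000*C1)."""
        return cls.from_table(1500.0, 2.05, 2.05, 1.75, 50.0, 350.0, 1.03)

    # -- derived quantities -------------------------------------------------

    @property
    def c6(self) -> float:
        """Continuity constant of the linear fibre branch, Pa."""
        return derive_c6(self)

    @property
    def mu(self) -> float:
        """Tangential shear modulus of the ground matrix, Pa."""
        return matrix_shear_modulus(self)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize as a flat JSON document keyed by the table symbols (MPa)."""
        doc = {
            "rho": self.rho,
            "C1": self.c1 / MPA,
            "C2": self.c2 / MPA,
            "C3": self.c3 / MPA,
            "C4": self.c4,
            "C5": self.c5 / MPA,
            "lambda_star": self.lambda_star,
            "K": self.bulk / MPA,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MaterialParams":
        """Read a flat JSON document (MPa convention, table symbol keys)."""
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        return cls.from_table(
            rho=doc["rho"],
            c1_mpa=doc["C1"],
            c2_mpa=doc["C2"],
            c3_mpa=doc["C3"],
            c4=doc["C4"],
            c5_mpa=doc["C5"],
            lambda_star=doc["lambda_star"],
            bulk_mpa=doc.get("K"),
        )

    def asdict(self) -> dict:
        return asdict(self)


def derive_c6(params: MaterialParams) -> float:
    """Constant of the linear fibre branch from stress continuity at lambda*.

    The exponential branch ``C3*(exp(C4*(l-1)) - 1)`` and the linear branch
    ``C5*l + C6`` must agree at the engagement stretch, so

        C6 = C3*(exp(C4*(lambda*-1)) - 1) - C5*lambda*

    Returned in the same stress units as C3/C5 (Pa for SI params).
    """
    if params.c5 < 0 or params.lambda_star <= 1.0:
        raise ValueError("non-physical parameters: require c5 >= 0 and lambda_star > 1")
    ls = params.lambda_star
    return params.c3 * (np.exp(params.c4 * (ls - 1.0)) - 1.0) - params.c5 * ls


def fiber_stress_term(lambda_t, params: MaterialParams):
    """Fibre stress contribution ``lambda * dF/dlambda`` at tissue stretch.

    Piecewise in the stretch ``lambda_t``:

    * ``lambda_t <= 1``            -> 0 (slack fibres)
    * ``1 < lambda_t < lambda*``   -> ``C3*(exp(C4*(lambda_t-1)) - 1)``
    * ``lambda_t >= lambda*``      -> ``C5*lambda_t + C6``

    Accepts scalars or arrays; stress is returned in the units of C3/C5.
    """
    lam = np.asarray(lambda_t, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    c6 = derive_c6(params)
    exp_branch = params.c3 * (np.exp(params.c4 * (lam - 1.0)) - 1.0)
    lin_branch = params.c5 * lam + c6
    out = np.where(lam <= 1.0, 0.0, np.where(lam < params.lambda_star, exp_branch, lin_branch))
    if np.isscalar(lambda_t):
        return float(out)
    return out


def matrix_shear_modulus(params: MaterialParams) -> float:
    """Transverse tangential shear modulus of the ground matrix, 2*(C1+C2)."""
    return 2.0 * (params.c1 + params.c2)


def closed_form_wave_speed(sigma, kprime: float, mu: float, rho: float):
    """Tensioned-beam transverse wave speed ``sqrt((sigma + k'*mu)/rho)``.

    Parameters
    ----------
    sigma : float or array
        Axial stress, Pa.
    kprime : float
        Shear correction factor (dimensionless).
    mu : float
        Tangential shear modulus, Pa.
    rho : float
        Mass density, kg/m^3.
    """
    if rho <= 0:
        raise ValueError("density must be positive")
    radicand = np.asarray(sigma, dtype=float) + kprime * mu
    if np.any(radicand < 0):
        raise ValueError(
            "negative radicand: sigma + k'*mu must be non-negative "
            "(compressive regime is outside the model scope)"
        )
    out = np.sqrt(radicand / rho)
    if np.isscalar(sigma):
        return float(out)
    return out


def stress_from_wave_speed(speed, kprime: float, mu: float, rho: float):
    """Algebraic inverse of :func:`closed_form_wave_speed`: ``rho*c^2 - k'*mu``."""
    if rho <= 0:
        raise ValueError("density must be positive")
    c = np.asarray(speed, dtype=float)
    out = rho * c**2 - kprime * mu
    if np.isscalar(speed):
        return float(out)
    return out
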