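"""Young's modulus from static macrosphere indentation.

A sphere of known weight rests on a cylindrical hydrogel specimen; the
equilibrium indentation depth delta, together with the sphere radius R and
the gel geometry (height h, diameter D), determines the elastic modulus.
Four nested models are provided:

``H``
    Classical Hertz contact on an incompressible (nu = 0.5) half-space,
    E = 9 F / (16 R^{1/2} delta^{3/2}).
``H-fh``
    Hertz corrected for the finite specimen height with the standard
    free-slip, incompressible finite-thickness series (linear material).
``NH-fh``
    Neo-Hookean material on a finite-height layer: Hertz multiplied by the
    correction factor f(R/h, omega).
``NH-fdh``
    Additionally corrected for the finite lateral diameter of the specimen
    through the polynomial factor g(delta/h, Rh/D^2) fitted to finite
    element simulations: E = E_H * f / g.

All correction factors assume frictionless (slip) contact without adhesion
and an incompressible gel.  Lab-facing units are mg / mm / kPa; conversions
to SI happen at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

__all__ = [
    "STANDARD_GRAVITY",
    "IndenterSpec",
    "GelCylinder",
    "IndentationMeasurement",
    "ModulusEstimate",
    "hertz_modulus",
    "omega",
    "finite_height_factor",
    "finite_diameter_factor",
    "dimitriadis_correction",
    "hertz_estimate",
    "dimitriadis_modulus",
    "nh_fh_modulus",
    "nh_fdh_modulus",
    "predict_indentation",
    "select_indenter",
    "check_validity",
]

STANDARD_GRAVITY = 9.81  # m/s^2

#: delta/h window inside which readings are considered comfortably readable.
STRAIN_WINDOW = (0.05, 0.40)
#: target window used by indenter selection; centre is the aim point.
SELECTION_WINDOW = (0.05, 0.45)
SELECTION_TARGET = 0.225

#: smallest depth (as a fraction of h) considered readable by eye/camera
DELTA_MIN_FRACTION = 0.02

#: g was fitted on FEM runs with delta/h <= 0.4 and Rh/D^2 <= 0.15;
#: evaluating outside that box is extrapolation.
G_FIT_MAX_STRAIN = 0.40
G_FIT_MAX_DIAMETER_GROUP = 0.15

# free-slip, incompressible finite-thickness series coefficients in
# chi = sqrt(R*delta)/h (Dimitriadis-type correction, linear material)
_DIMITRIADIS_COEFFS = (1.133, 1.283, 0.769, 0.0975)


class DomainError(ValueError):
    """An input is outside the physical domain of an operation."""


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if not value > 0:
            raise DomainError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class IndenterSpec:
    """A spherical indenter, optionally carrying an overload mass.

    The effective indentation force is the total weight
    F = (mass + overload) * g0 with g0 = 9.81 m/s^2; buoyancy and
    capillary forces are neglected.
    """

    label: str
    mass_mg: float
    radius_mm: float
    overload_mass_mg: float = 0.0
    material: str = ""

    def __post_init__(self) -> None:
        _require_positive(mass_mg=self.mass_mg, radius_mm=self.radius_mm)
        if self.overload_mass_mg < 0:
            raise DomainError("overload_mass_mg must be non-negative")

    @property
    def total_mass_mg(self) -> float:
        return self.mass_mg + self.overload_mass_mg

    @property
    def force_N(self) -> float:
        """Weight of sphere plus overload, in newtons."""
        return self.total_mass_mg * 1e-6 * STANDARD_GRAVITY

    @property
    def radius_m(self) -> float:
        return self.radius_mm * 1e-3


@dataclass(frozen=True)
class GelCylinder:
    """Cylindrical gel specimen of height h and diameter D (mm)."""

    height_mm: float
    diameter_mm: float

    def __post_init__(self) -> None:
        _require_positive(height_mm=self.height_mm, diameter_mm=self.diameter_mm)


@dataclass(frozen=True)
class IndentationMeasurement:
    """One sphere-on-gel observation: indenter, gel and measured depth."""

    indenter: IndenterSpec
    gel: GelCylinder
    delta_mm: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        _require_positive(delta_mm=self.delta_mm)
        if not self.delta_mm < self.gel.height_mm:
            raise DomainError(
                f"delta_mm={self.delta_mm} must be smaller than the gel height "
                f"{self.gel.height_mm}"
            )

    @property
    def delta_over_h(self) -> float:
        """Dimensionless indentation strain delta/h."""
        return self.delta_mm / self.gel.height_mm

    @property
    def R_over_h(self) -> float:
        return self.indenter.radius_mm / self.gel.height_mm

    @property
    def omega(self) -> float:
        """Finite-thickness contact group (R delta / h^2)^{3/2}."""
        return omega(self.indenter.radius_mm, self.delta_mm, self.gel.height_mm)

    @property
    def Rh_over_D2(self) -> float:
        """Dimensionless diameter group R h / D^2."""
        return (
            self.indenter.radius_mm
            * self.gel.height_mm
            / self.gel.diameter_mm**2
        )

    @property
    def contact_radius_mm(self) -> float:
        """Small-slope contact radius estimate a = sqrt(R delta)."""
        return math.sqrt(self.indenter.radius_mm * self.delta_mm)

    @property
    def chi(self) -> float:
        """Finite-thickness group sqrt(R delta)/h of the linear series."""
        return self.contact_radius_mm / self.gel.height_mm


@dataclass(frozen=True)
class ModulusEstimate:
    """An elastic modulus labelled by the model that produced it."""

    model: str  # one of H, H-fh, NH-fh, NH-fdh, PA
    E_kpa: float
    f_factor: float | None = None
    g_factor: float | None = None
    validity: tuple[str, ...] = field(default_factory=tuple)


def hertz_modulus(F: float, R: float, delta: float) -> float:
    """Hertz modulus (Pa) of an incompressible half-space.

    Parameters are SI: force in N, sphere radius and depth in m.  The
    9/16 prefactor already carries nu = 0.5.
    """
    _require_positive(F=F, R=R, delta=delta)
    return 9.0 * F / (16.0 * math.sqrt(R) * delta**1.5)


def omega(R: float, delta: float, h: float) -> float:
    """Dimensionless group (R delta / h^2)^{3/2} (any consistent length unit)."""
    _require_positive(R=R, h=h)
    if delta < 0:
        raise DomainError(f"delta must be non-negative, got {delta!r}")
    return (R * delta / h**2) ** 1.5


def finite_height_factor(R_over_h: float, omega: float) -> float:
    """Finite-height correction f(R/h, omega) for a neo-Hookean layer.

    f = (1 + 2.3 w) / (1 + 1.15 w^{1/3} + alpha w + beta w^2) with
    alpha = 10.05 - 0.63 sqrt(R/h) (3.1 + h^2/R^2) and
    beta = 4.8 - 4.23 h^2/R^2.  Valid for slip (frictionless, non-adhesive)
    contact; f -> 1 recovers Hertz as omega -> 0.
    """
    _require_positive(R_over_h=R_over_h)
    if omega < 0:
        raise DomainError(f"omega must be non-negative, got {omega!r}")
    h2_over_R2 = 1.0 / R_over_h**2
    alpha = 10.05 - 0.63 * math.sqrt(R_over_h) * (3.1 + h2_over_R2)
    beta = 4.8 - 4.23 * h2_over_R2
    return (1.0 + 2.3 * omega) / (
        1.0 + 1.15 * omega ** (1.0 / 3.0) + alpha * omega + beta * omega**2
    )


def finite_diameter_factor(delta_over_h: float, Rh_over_D2: float) -> float:
    """Finite-diameter correction g(delta/h, Rh/D^2).

    Polynomial regression of finite-element results for a rigid sphere on an
    incompressible neo-Hookean cylinder; g(0, 0) = 1.
    """
    if delta_over_h < 0:
        raise DomainError(f"delta_over_h must be non-negative, got {delta_over_h!r}")
    if Rh_over_D2 < 0:
        raise DomainError(f"Rh_over_D2 must be non-negative, got {Rh_over_D2!r}")
    s, q = delta_over_h, Rh_over_D2
    return (
        1.0
        + q**2 * (-0.07 - 0.22 * s)
        + (0.14 - 0.33 * s) * s
        + q * (0.007 + s) * (-1.025 + 1.42 * s)
    )


def dimitriadis_correction(chi: float) -> float:
    """Finite-thickness force amplification of the linear free-slip series.

    Returns 1 + 1.133 chi + 1.283 chi^2 + 0.769 chi^3 + 0.0975 chi^4 with
    chi = sqrt(R delta)/h; the Hertz force is multiplied by this factor on a
    thin sample, so the corrected modulus divides by it.
    """
    if chi < 0:
        raise DomainError(f"chi must be non-negative, got {chi!r}")
    c1, c2, c3, c4 = _DIMITRIADIS_COEFFS
    return 1.0 + c1 * chi + c2 * chi**2 + c3 * chi**3 + c4 * chi**4


def _hertz_kpa(m: IndentationMeasurement) -> float:
    return (
        hertz_modulus(m.indenter.force_N, m.indenter.radius_m, m.delta_mm * 1e-3)
        / 1e3
    )


def hertz_estimate(m: IndentationMeasurement) -> ModulusEstimate:
    """Classical Hertz (semi-infinite, linear) estimate, model ``H``."""
    return ModulusEstimate("H", _hertz_kpa(m), validity=tuple(check_validity(m)))


def dimitriadis_modulus(m: IndentationMeasurement) -> ModulusEstimate:
    """Linear-elastic finite-height estimate, model ``H-fh``."""
    flags = check_validity(m)
    corr = dimitriadis_correction(m.chi)
    return ModulusEstimate("H-fh", _hertz_kpa(m) / corr, validity=tuple(flags))


def nh_fh_modulus(m: IndentationMeasurement) -> ModulusEstimate:
    """Neo-Hookean finite-height estimate, model ``NH-fh``: E = E_H * f."""
    f = finite_height_factor(m.R_over_h, m.omega)
    return ModulusEstimate(
        "NH-fh", _hertz_kpa(m) * f, f_factor=f, validity=tuple(check_validity(m))
    )


def nh_fdh_modulus(m: IndentationMeasurement) -> ModulusEstimate:
    """Neo-Hookean finite-height + finite-diameter estimate, ``NH-fdh``.

    E = E_H * f(R/h, omega) / g(delta/h, Rh/D^2).
    """
    f = finite_height_factor(m.R_over_h, m.omega)
    g = finite_diameter_factor(m.delta_over_h, m.Rh_over_D2)
    flags = check_validity(m)
    if m.delta_over_h > G_FIT_MAX_STRAIN or m.Rh_over_D2 > G_FIT_MAX_DIAMETER_GROUP:
        flags.append("g_extrapolation")
    return ModulusEstimate(
        "NH-fdh",
        _hertz_kpa(m) * f / g,
        f_factor=f,
        g_factor=g,
        validity=tuple(flags),
    )


def check_validity(m: IndentationMeasurement) -> list[str]:
    """Warning flags for a measurement; never rejects.

    ``strain_out_of_range``
        delta/h outside [0.05, 0.40], the comfortably readable window.
    ``slope_violation``
        contact radius sqrt(R delta) exceeds a quarter of the gel diameter,
        straining the small-slope contact assumption.
    ``thin_gel``
        sqrt(R delta)/h > 1; the finite-thickness series degrades.
    """
    flags = []
    lo, hi = STRAIN_WINDOW
    if not lo <= m.delta_over_h <= hi:
        flags.append("strain_out_of_range")
    if m.contact_radius_mm / m.gel.diameter_mm > 0.25:
        flags.append("slope_violation")
    if m.chi > 1.0:
        flags.append("thin_gel")
    return flags


def _modulus_at_depth(
    E_kpa_unused: None, indenter: IndenterSpec, gel: GelCylinder, delta_mm: float
) -> float:
    m = IndentationMeasurement(indenter, gel, delta_mm)
    f = finite_height_factor(m.R_over_h, m.omega)
    g = finite_diameter_factor(m.delta_over_h, m.Rh_over_D2)
    return _hertz_kpa(m) * f / g


class IndenterUnsuitableError(RuntimeError):
    """The requested indenter cannot produce a usable depth on this gel."""


def predict_indentation(
    E_kpa: float, indenter: IndenterSpec, gel: GelCylinder
) -> float:
    """Equilibrium depth delta (mm) of the full NH-fdh forward model.

    Solves E_NH-fdh(delta) = E for delta in (delta_min, 0.9 h) by bracketed
    root finding, with delta_min = 0.02 h the smallest depth worth reading;
    the model modulus is strictly decreasing in delta over the bracket, so
    the root is unique.  A sphere whose equilibrium falls outside the
    bracket (too light to register, or sinking past 0.9 h) is unsuitable.
    """
    _require_positive(E_kpa=E_kpa)
    h = gel.height_mm
    lo, hi = DELTA_MIN_FRACTION * h, 0.9 * h

    def residual(delta: float) -> float:
        return _modulus_at_depth(None, indenter, gel, delta) - E_kpa

    r_lo, r_hi = residual(lo), residual(hi)
    if not (r_lo > 0 and r_hi < 0):
        raise IndenterUnsuitableError(
            f"indenter {indenter.label!r} unsuitable for E={E_kpa} kPa on this "
            f"gel: no equilibrium depth in (0, 0.9 h)"
        )
    return brentq(residual, lo, hi, xtol=1e-12 * h, rtol=8.9e-16)


def select_indenter(
    E_expected_kpa: float,
    catalog: list[IndenterSpec],
    gel: GelCylinder,
) -> tuple[IndenterSpec, float]:
    """Pick the catalog sphere whose predicted delta/h best centres the
    readable window.

    Returns the chosen spec and its predicted delta/h.  Candidates must land
    inside [0.05, 0.45]; the one closest to 0.225 wins and ties go to the
    lighter sphere (less gel damage).
    """
    if not catalog:
        raise ValueError("indenter catalog is empty")
    predictions: dict[str, float | None] = {}
    candidates: list[tuple[float, float, IndenterSpec, float]] = []
    lo, hi = SELECTION_WINDOW
    for spec in catalog:
        try:
            strain = predict_indentation(E_expected_kpa, spec, gel) / gel.height_mm
        except IndenterUnsuitableError:
            predictions[spec.label] = None
            continue
        predictions[spec.label] = strain
        if lo <= strain <= hi:
            candidates.append(
                (abs(strain - SELECTION_TARGET), spec.total_mass_mg, spec, strain)
            )
    if not candidates:
        raise IndenterUnsuitableError(
            "no suitable indenter: predicted delta/h per sphere = "
            + ", ".join(
                f"{k}={v:.4f}" if v is not None else f"{k}=out-of-bracket"
                for k, v in predictions.items()
            )
        )
    candidates.sort(key=lambda c: (c[0], c[1]))
    _, _, best, strain = candidates[0]
    return best, strain
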