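"""Young's modulus from micropipette aspiration.

A capillary of internal radius ``a`` is pressed against the gel surface and
a suction pressure ``p`` draws a bump of height ``l`` into the lumen.  For
an incompressible half-space the modulus follows from the dimensionless
aspiration ratio x = l/a:

* linear regime (x < 0.3):      E = |p| / (1.07 x)
* non-linear regime (x >= 0.3): E = |p| / (0.872 x + 0.748 x^2)

Pressures are stored as recorded (suction is negative); all formulas use
the magnitude, so sign conventions do not affect the estimate.  Readings
with x < 0.3 are flagged: resolving l reliably requires x > 0.3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PipetteSpec",
    "AspirationMeasurement",
    "AspirationEstimate",
    "AspirationSummary",
    "aspiration_modulus",
    "predict_aspiration_length",
    "aggregate_aspiration",
]

LINEAR_COEF = 1.07
NONLINEAR_COEFS = (0.872, 0.748)
REGIME_THRESHOLD = 0.3
#: aspirated lengths beyond this multiple of `a` are outside the half-space
#: model and almost certainly a reading error
MAX_PLAUSIBLE_RATIO = 2.0
#: |trend slope| * pressure range exceeding this fraction of the mean E
#: raises a pressure-trend warning
TREND_TOLERANCE = 0.10


class ImplausibleAspirationError(ValueError):
    """Aspirated length far beyond the model's validity (l/a > 2)."""


@dataclass(frozen=True)
class PipetteSpec:
    """Glass capillary with internal radius a and external radius A (mm).

    ``friction_treated`` records whether the inner surface was fluorinated
    to suppress gel-wall friction (the analysis assumes frictionless
    aspiration either way).
    """

    internal_radius_mm: float = 0.375
    external_radius_mm: float = 0.5
    friction_treated: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.internal_radius_mm < self.external_radius_mm:
            raise ValueError(
                "need 0 < internal radius < external radius, got "
                f"a={self.internal_radius_mm}, A={self.external_radius_mm}"
            )


@dataclass(frozen=True)
class AspirationMeasurement:
    """One (pressure, aspirated length) observation."""

    pressure_kpa: float  # signed as recorded; negative = suction
    length_mm: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.length_mm < 0:
            raise ValueError(f"length_mm must be non-negative, got {self.length_mm}")

    def l_over_a(self, pipette: PipetteSpec) -> float:
        return self.length_mm / pipette.internal_radius_mm


@dataclass(frozen=True)
class AspirationEstimate:
    model: str
    E_kpa: float
    regime: str  # "linear" | "nonlinear"
    l_over_a: float
    warnings: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class AspirationSummary:
    """Per-sample aggregate mirroring one row of a pressure-sweep table."""

    sample_id: str
    n: int
    E_mean_kpa: float
    E_sd_kpa: float
    l_over_a_min: float
    l_over_a_max: float
    pressure_min_kpa: float
    pressure_max_kpa: float
    warnings: tuple[str, ...]
    estimates: tuple[AspirationEstimate, ...]


def aspiration_modulus(
    m: AspirationMeasurement, pipette: PipetteSpec
) -> AspirationEstimate:
    """Modulus from one aspiration reading; regime chosen by l/a.

    The boundary l/a = 0.3 is assigned to the non-linear branch, the branch
    used for all reliable readings.
    """
    p = abs(m.pressure_kpa)
    if p == 0:
        raise ValueError("pressure must be non-zero")
    if m.length_mm <= 0:
        raise ValueError("aspirated length must be positive")
    x = m.l_over_a(pipette)
    if x > MAX_PLAUSIBLE_RATIO:
        raise ImplausibleAspirationError(
            f"l/a = {x:.3f} exceeds the plausible bound {MAX_PLAUSIBLE_RATIO}"
        )
    warnings: list[str] = []
    if x < REGIME_THRESHOLD:
        b = LINEAR_COEF * x
        regime = "linear"
        warnings.append("low_aspiration")
    else:
        c1, c2 = NONLINEAR_COEFS
        b = c1 * x + c2 * x**2
        regime = "nonlinear"
    return AspirationEstimate("PA", p / b, regime, x, tuple(warnings))


def predict_aspiration_length(E_kpa: float, p_kpa: float, pipette: PipetteSpec) -> float:
    """Aspirated length l (mm) expected for modulus E under pressure p.

    Closed-form inverse of the two-regime relation: the positive root of
    0.748 x^2 + 0.872 x = |p|/E when that root is >= 0.3, else the linear
    inverse x = |p| / (1.07 E); returns x * a.

    Because the two regime formulas disagree by ~2.5% at the switch, the
    estimator skips a narrow band of moduli around x = 0.3; ratios landing
    in that band map to the boundary x = 0.3 (nearest achievable reading).
    Composed the other way — estimate E from a reading, then predict the
    length — the round trip is exact.
    """
    p = abs(p_kpa)
    if E_kpa <= 0 or p <= 0:
        raise ValueError("E and |p| must be positive")
    ratio = p / E_kpa
    c1, c2 = NONLINEAR_COEFS
    x = (-c1 + math.sqrt(c1**2 + 4.0 * c2 * ratio)) / (2.0 * c2)
    if x < REGIME_THRESHOLD:
        x_linear = ratio / LINEAR_COEF
        x = x_linear if x_linear < REGIME_THRESHOLD else REGIME_THRESHOLD
    return x * pipette.internal_radius_mm


def aggregate_aspiration(
    series: list[AspirationMeasurement],
    pipette: PipetteSpec,
    sample_id: str = "",
) -> AspirationSummary:
    """Mean +/- SD modulus over a pressure series for one sample.

    SD uses the n-1 denominator (0 for n = 1, with a ``small_n`` warning).
    A ``pressure_trend`` warning fires when a linear fit of E against |p|
    moves E by more than 10% of its mean across the pressure range —
    estimates are expected to be constant with applied pressure.
    """
    if not series:
        raise ValueError("empty aspiration series")
    sid = sample_id or series[0].sample_id
    estimates = tuple(aspiration_modulus(m, pipette) for m in series)
    E = np.array([e.E_kpa for e in estimates])
    p = np.array([abs(m.pressure_kpa) for m in series])
    warnings: set[str] = set()
    for e in estimates:
        warnings.update(e.warnings)
    n = len(series)
    if n == 1:
        sd = 0.0
        warnings.add("small_n")
    else:
        sd = float(np.std(E, ddof=1))
        p_range = float(p.max() - p.min())
        if p_range > 0:
            slope = float(np.polyfit(p, E, 1)[0])
            if abs(slope) * p_range > TREND_TOLERANCE * float(E.mean()):
                warnings.add("pressure_trend")
    return AspirationSummary(
        sample_id=sid,
        n=n,
        E_mean_kpa=float(E.mean()),
        E_sd_kpa=sd,
        l_over_a_min=min(e.l_over_a for e in estimates),
        l_over_a_max=max(e.l_over_a for e in estimates),
        pressure_min_kpa=float(min(m.pressure_kpa for m in series)),
        pressure_max_kpa=float(max(m.pressure_kpa for m in series)),
        warnings=tuple(sorted(warnings)),
        estimates=estimates,
    )
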