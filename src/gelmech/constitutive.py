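"""Constitutive fitting of uniaxial compression curves.

Plate-compression tests record nominal (engineering) strain and stress,
compression taken positive.  Two one-parameter models are fitted:

* linear elasticity, sigma = E * eps;
* incompressible neo-Hookean, sigma = (E/3) (lambda - lambda^{-2}) in
  magnitude with stretch lambda = 1 - eps, the standard uniaxial closed
  form for an incompressible material (E = 3 mu0 = 6 C10).

Both models are linear in E, so the least-squares fit has a closed-form
solution and noise-free generated data is recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CompressionCurve",
    "ConstitutiveFit",
    "linear_stress",
    "neo_hookean_stress",
    "fit_curve",
    "compare_fits",
    "shear_to_young",
    "young_to_shear",
]

POISSON_RATIO = 0.5  # incompressible on the test timescale


@dataclass(frozen=True)
class CompressionCurve:
    """Nominal strain-stress pairs from one compression test.

    Strain is dimensionless compressive strain (positive), strictly
    increasing and below 0.5; stress is nominal stress in kPa.
    """

    strain: np.ndarray
    stress_kpa: np.ndarray
    sample_id: str = ""
    temperature_c: float | None = None

    def __post_init__(self) -> None:
        strain = np.asarray(self.strain, dtype=float)
        stress = np.asarray(self.stress_kpa, dtype=float)
        object.__setattr__(self, "strain", strain)
        object.__setattr__(self, "stress_kpa", stress)
        if strain.shape != stress.shape or strain.ndim != 1:
            raise ValueError("strain and stress must be 1-D arrays of equal length")
        if strain.size < 4:
            raise ValueError("need at least 4 points to fit")
        if np.any(np.diff(strain) <= 0):
            raise ValueError("strain must be strictly increasing")
        if np.any(strain < 0) or np.any(strain >= 0.5):
            raise ValueError("strain must lie in [0, 0.5)")


@dataclass(frozen=True)
class ConstitutiveFit:
    """A fitted one-parameter stiffness model.

    For nu = 0.5 the elastic constants are locked together:
    mu0 = 2 C10 and E = 3 mu0 = 6 C10.  ``d_incomp`` is the hyperelastic
    compressibility parameter; incompressible fits report it as None
    (not applicable).
    """

    model: str  # "linear" | "neo_hookean"
    E_kpa: float
    sse: float  # kPa^2
    r_squared: float
    sample_id: str = ""
    d_incomp: float | None = None

    @property
    def C10_kpa(self) -> float:
        return self.E_kpa / 6.0

    @property
    def mu0_kpa(self) -> float:
        return self.E_kpa / 3.0


def linear_stress(E_kpa: float, strain):
    """Nominal linear-elastic stress sigma = E * eps (kPa)."""
    strain = np.asarray(strain, dtype=float)
    if np.any(strain < 0):
        raise ValueError("strain must be non-negative")
    return E_kpa * strain


def neo_hookean_stress(E_kpa: float, strain):
    """Nominal neo-Hookean compressive stress magnitude (kPa).

    With stretch lambda = 1 - eps, sigma = (E/3) |lambda - lambda^{-2}|;
    the leading-order Taylor expansion recovers sigma ~ E eps.
    """
    strain = np.asarray(strain, dtype=float)
    if np.any(strain < 0) or np.any(strain >= 1):
        raise ValueError("strain must lie in [0, 1)")
    lam = 1.0 - strain
    return (E_kpa / 3.0) * np.abs(lam - lam**-2)


_BASES = {
    "linear": lambda eps: linear_stress(1.0, eps),
    "neo_hookean": lambda eps: neo_hookean_stress(1.0, eps),
}


def fit_curve(curve: CompressionCurve, model: str) -> ConstitutiveFit:
    """Least-squares fit of the single parameter E to a compression curve.

    Both models are of the form sigma = E * b(eps); the unweighted SSE is
    minimised exactly by projecting the stress data onto the basis b.
    """
    if model not in _BASES:
        raise ValueError(f"unknown model {model!r}")
    sigma = curve.stress_kpa
    if not np.any(sigma != 0):
        raise ValueError("degenerate curve: all stresses are zero")
    b = _BASES[model](curve.strain)
    E = float(np.dot(b, sigma) / np.dot(b, b))
    resid = sigma - E * b
    sse = float(np.dot(resid, resid))
    tss = float(np.sum((sigma - sigma.mean()) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else float("nan")
    return ConstitutiveFit(model, E, sse, r2, sample_id=curve.sample_id)


def compare_fits(curve: CompressionCurve) -> dict:
    """Fit both models; prefer the lower-SSE one.

    Returns the preferred model name, both fits and the SSE ratio
    (preferred / other, <= 1).
    """
    fits = {name: fit_curve(curve, name) for name in _BASES}
    preferred = min(fits, key=lambda name: fits[name].sse)
    other = "linear" if preferred == "neo_hookean" else "neo_hookean"
    sse_other = fits[other].sse
    ratio = fits[preferred].sse / sse_other if sse_other > 0 else float("inf")
    return {"preferred": preferred, "fits": fits, "sse_ratio": ratio}


def shear_to_young(G_kpa: float) -> float:
    """E = 2 G (1 + nu) = 3 G for an incompressible material."""
    if G_kpa <= 0:
        raise ValueError("shear modulus must be positive")
    return 2.0 * G_kpa * (1.0 + POISSON_RATIO)


def young_to_shear(E_kpa: float) -> float:
    """Inverse of :func:`shear_to_young`."""
    if E_kpa <= 0:
        raise ValueError("Young's modulus must be positive")
    return E_kpa / (2.0 * (1.0 + POISSON_RATIO))
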