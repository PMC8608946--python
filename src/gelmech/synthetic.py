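"""Ground-truthed synthetic fixtures for every analysis stage.

Renders backlit indentation silhouettes, aspiration micrographs and
two-channel immunofluorescence populations, and simulates noisy
measurement sessions and compression curves.  Every generator is
deterministic under (parameters, seed): the same call produces
bit-identical output.  Ground truth always satisfies the corresponding
forward model exactly — rasterisation and the explicit noise model are the
only lossy steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .aspiration import AspirationMeasurement, PipetteSpec, predict_aspiration_length
from .constitutive import CompressionCurve, linear_stress, neo_hookean_stress
from .indentation import (
    GelCylinder,
    IndentationMeasurement,
    IndenterSpec,
    predict_indentation,
)

__all__ = [
    "NoiseModel",
    "CLEAN",
    "REALISTIC",
    "SyntheticScene",
    "SimulatedSession",
    "IFPopulation",
    "default_indenter_catalog",
    "render_indentation_scene",
    "render_aspiration_scene",
    "simulate_compression_curve",
    "simulate_indentation_session",
    "simulate_aspiration_session",
    "render_if_population",
]

_BG = 0.92  # backlit background level
_FG = 0.08  # silhouette level

#: default scales chosen so the lab geometries fill the frame
INDENTATION_MM_PER_PX = 0.01
ASPIRATION_MM_PER_PX = 0.002
INDENTATION_CANVAS = (800, 1000)  # rows, cols
ASPIRATION_CANVAS = (600, 600)


class SceneOverflowError(ValueError):
    """The requested scene does not fit on the canvas."""


@dataclass(frozen=True)
class NoiseModel:
    """Imaging noise: Gaussian blur, additive sensor noise, illumination tilt.

    ``additive_sd`` is expressed as a fraction of the dynamic range;
    ``illumination_gradient`` is the relative brightness change across the
    image width.
    """

    blur_sigma_px: float = 0.0
    additive_sd: float = 0.0
    illumination_gradient: float = 0.0


CLEAN = NoiseModel()
REALISTIC = NoiseModel(blur_sigma_px=1.0, additive_sd=0.02)


@dataclass(frozen=True)
class SyntheticScene:
    kind: str  # "indentation" | "aspiration"
    image: np.ndarray  # uint8, (rows, cols)
    mm_per_px: float
    ground_truth: dict
    seed: int
    flags: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class SimulatedSession:
    """A repeated-measurement session around one true modulus."""

    E_true_kpa: float
    noise_sd: float
    seed: int
    measurements: tuple
    ground_truth: dict


@dataclass(frozen=True)
class IFPopulation:
    """Synthetic immunofluorescence field with per-cell ground truth."""

    yap_channel: np.ndarray
    nuclear_channel: np.ndarray
    cell_labels: np.ndarray  # int labels, 0 = background
    nuclear_labels: np.ndarray
    enrichment_factor: float
    true_categories: tuple[str, ...]
    seed: int

    def cell_mask(self, cell_id: int) -> np.ndarray:
        return self.cell_labels == cell_id

    def nuclear_mask(self, cell_id: int) -> np.ndarray:
        return self.nuclear_labels == cell_id


def default_indenter_catalog() -> list[IndenterSpec]:
    """A realistic sphere set: plastic and steel spheres of lab sizes,
    plus guided-plate entries carrying an overload mass for stiff gels."""
    spheres = [
        ("PP1.5", 0.9, 1.5, 0.0, "polypropylene"),
        ("SS1.0", 7.8, 1.0, 0.0, "steel"),
        ("SS1.5", 7.8, 1.5, 0.0, "steel"),
        ("SS2.0", 7.8, 2.0, 0.0, "steel"),
        ("SI1.5+0.5g", 7.8, 1.5, 500.0, "steel+overload"),
        ("SI1.5+2g", 7.8, 1.5, 2000.0, "steel+overload"),
        ("SI1.75+5g", 7.8, 1.75, 5000.0, "steel+overload"),
    ]
    catalog = []
    for label, density_mg_mm3, radius_mm, overload, material in spheres:
        mass = density_mg_mm3 * 4.0 / 3.0 * np.pi * radius_mm**3
        catalog.append(
            IndenterSpec(
                label=label,
                mass_mg=round(mass, 2),
                radius_mm=radius_mm,
                overload_mass_mg=overload,
                material=material,
            )
        )
    return catalog


def _finish(
    coverage: np.ndarray, noise: NoiseModel, seed: int
) -> np.ndarray:
    """Convert object coverage in [0, 1] to a noisy uint8 backlit image."""
    img = _BG + (_FG - _BG) * coverage
    if noise.illumination_gradient:
        ramp = np.linspace(
            1.0 - noise.illumination_gradient / 2.0,
            1.0 + noise.illumination_gradient / 2.0,
            img.shape[1],
        )
        img = img * ramp[None, :]
    if noise.blur_sigma_px > 0:
        img = gaussian_filter(img, noise.blur_sigma_px)
    if noise.additive_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise.additive_sd * (_BG - _FG), img.shape)
    return (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def _halfplane_below(rows: np.ndarray, boundary: float) -> np.ndarray:
    return np.clip(rows - boundary + 0.5, 0.0, 1.0)


def render_indentation_scene(
    E_kpa: float,
    indenter: IndenterSpec,
    gel: GelCylinder,
    mm_per_px: float = INDENTATION_MM_PER_PX,
    noise: NoiseModel = REALISTIC,
    seed: int = 0,
    canvas_px: tuple[int, int] = INDENTATION_CANVAS,
) -> SyntheticScene:
    """Backlit side view of a sphere resting on a gel cylinder.

    The depth delta is the exact equilibrium of the corrected-Hertz forward
    model for (E, indenter, gel); the image shows the gel rectangle (h x D)
    with the sphere's lowest point delta below the free surface.
    """
    delta_mm = predict_indentation(E_kpa, indenter, gel)
    n_rows, n_cols = canvas_px
    h_px = gel.height_mm / mm_per_px
    D_px = gel.diameter_mm / mm_per_px
    R_px = indenter.radius_mm / mm_per_px
    delta_px = delta_mm / mm_per_px

    base_row = n_rows - 20.0
    surface_row = base_row - h_px
    centre_col = n_cols / 2.0
    sphere_centre_row = surface_row + delta_px - R_px
    sphere_top = sphere_centre_row - R_px
    if D_px + 10 > n_cols or surface_row < 5 or sphere_top < 5:
        raise SceneOverflowError(
            "scene exceeds the canvas: enlarge canvas_px or coarsen mm_per_px"
        )

    rows = np.arange(n_rows, dtype=float)[:, None]
    cols = np.arange(n_cols, dtype=float)[None, :]
    gel_cov = (
        _halfplane_below(rows, surface_row)
        * (1.0 - _halfplane_below(rows, base_row))
        * np.clip(cols - (centre_col - D_px / 2.0) + 0.5, 0.0, 1.0)
        * np.clip((centre_col + D_px / 2.0) - cols + 0.5, 0.0, 1.0)
    )
    dist = np.hypot(rows - sphere_centre_row, cols - centre_col)
    sphere_cov = np.clip(R_px - dist + 0.5, 0.0, 1.0)
    coverage = np.maximum(gel_cov, sphere_cov)
    image = _finish(coverage, noise, seed)
    truth = {
        "E_kpa": E_kpa,
        "delta_mm": delta_mm,
        "h_mm": gel.height_mm,
        "D_mm": gel.diameter_mm,
        "R_mm": indenter.radius_mm,
        "F_N": indenter.force_N,
        "indenter_label": indenter.label,
        "surface_row_px": surface_row,
        "sphere_centre_px": (sphere_centre_row, centre_col),
    }
    return SyntheticScene("indentation", image, mm_per_px, truth, seed)


def render_aspiration_scene(
    E_kpa: float,
    p_kpa: float,
    pipette: PipetteSpec = PipetteSpec(),
    mm_per_px: float = ASPIRATION_MM_PER_PX,
    noise: NoiseModel = REALISTIC,
    seed: int = 0,
    canvas_px: tuple[int, int] = ASPIRATION_CANVAS,
) -> SyntheticScene:
    """Micrograph of a vertical pipette on a gel with an aspirated meniscus.

    The aspirated length l follows the closed-form forward model; the
    meniscus is drawn as a spherical cap of apex height l spanning the
    lumen (only the apex height is metrologically meaningful).  p = 0
    renders a flat interface.
    """
    l_mm = (
        predict_aspiration_length(E_kpa, p_kpa, pipette) if p_kpa != 0 else 0.0
    )
    flags: tuple[str, ...] = ()
    a_mm = pipette.internal_radius_mm
    if l_mm / a_mm > 1.0:
        flags = ("beyond_model_geometry",)

    n_rows, n_cols = canvas_px
    a_px = a_mm / mm_per_px
    A_px = pipette.external_radius_mm / mm_per_px
    l_px = l_mm / mm_per_px
    axis = n_cols / 2.0
    mouth_row = n_rows / 2.0
    if 2 * A_px + 20 > n_cols or l_px + 10 > mouth_row:
        raise SceneOverflowError(
            "scene exceeds the canvas: enlarge canvas_px or coarsen mm_per_px"
        )

    rows = np.arange(n_rows, dtype=float)[:, None]
    cols = np.arange(n_cols, dtype=float)[None, :]
    above_mouth = 1.0 - _halfplane_below(rows, mouth_row)

    def _band(lo: float, hi: float) -> np.ndarray:
        return np.clip(cols - lo + 0.5, 0.0, 1.0) * np.clip(hi - cols + 0.5, 0.0, 1.0)

    walls = (
        _band(axis - A_px, axis - a_px) + _band(axis + a_px, axis + A_px)
    ) * above_mouth
    gel = _halfplane_below(rows, mouth_row)
    if l_px > 0.25:
        cap_radius = (a_px**2 + l_px**2) / (2.0 * l_px)
        cap_centre_row = mouth_row - l_px + cap_radius
        cap_dist = np.hypot(rows - cap_centre_row, cols - axis)
        cap = np.clip(cap_radius - cap_dist + 0.5, 0.0, 1.0) * above_mouth
        gel = np.maximum(gel, cap)
    coverage = np.clip(walls + gel, 0.0, 1.0)
    image = _finish(coverage, noise, seed)
    truth = {
        "E_kpa": E_kpa,
        "p_kpa": p_kpa,
        "l_mm": l_mm,
        "a_mm": a_mm,
        "A_mm": pipette.external_radius_mm,
        "mouth_row_px": mouth_row,
        "axis_col_px": axis,
    }
    return SyntheticScene("aspiration", image, mm_per_px, truth, seed, flags)


def simulate_compression_curve(
    E_kpa: float,
    model: str = "neo_hookean",
    strain_max: float = 0.225,
    n_points: int = 14,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "",
) -> CompressionCurve:
    """Evenly spaced compression curve with multiplicative Gaussian noise.

    Defaults mirror the plate-compression protocol: about 14 points up to
    20-25% total compression.
    """
    if not 0 < strain_max < 0.5:
        raise ValueError("strain_max must lie in (0, 0.5)")
    strain = np.linspace(strain_max / n_points, strain_max, n_points)
    law = neo_hookean_stress if model == "neo_hookean" else linear_stress
    stress = law(E_kpa, strain)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stress = stress * (1.0 + rng.normal(0.0, noise_sd, stress.shape))
    return CompressionCurve(strain, stress, sample_id=sample_id)


def simulate_indentation_session(
    E_true_kpa: float,
    indenter: IndenterSpec,
    gel: GelCylinder,
    n_repeats: int = 10,
    noise_sd: float = 0.03,
    seed: int = 0,
    sample_id: str = "sim",
) -> SimulatedSession:
    """Repeated depth readings with multiplicative noise on delta only.

    The true equilibrium depth comes from the forward model; each repeat
    observes delta * (1 + eps) with eps ~ N(0, noise_sd).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    delta_true = predict_indentation(E_true_kpa, indenter, gel)
    rng = np.random.default_rng(seed)
    factors = 1.0 + rng.normal(0.0, noise_sd, n_repeats) if noise_sd > 0 else np.ones(n_repeats)
    measurements = tuple(
        IndentationMeasurement(indenter, gel, float(delta_true * f), sample_id=sample_id)
        for f in factors
    )
    return SimulatedSession(
        E_true_kpa,
        noise_sd,
        seed,
        measurements,
        {"delta_true_mm": delta_true, "sample_id": sample_id},
    )


def simulate_aspiration_session(
    E_true_kpa: float,
    pressures_kpa,
    pipette: PipetteSpec = PipetteSpec(),
    noise_sd: float = 0.05,
    seed: int = 0,
    sample_id: str = "sim",
) -> SimulatedSession:
    """Aspiration readings at a list of pressures, noisy in l only."""
    pressures = np.asarray(pressures_kpa, dtype=float)
    if pressures.size < 1:
        raise ValueError("need at least one pressure")
    rng = np.random.default_rng(seed)
    lengths = np.array(
        [predict_aspiration_length(E_true_kpa, p, pipette) for p in pressures]
    )
    if noise_sd > 0:
        lengths = lengths * (1.0 + rng.normal(0.0, noise_sd, lengths.shape))
    measurements = tuple(
        AspirationMeasurement(float(p), float(l), sample_id=sample_id)
        for p, l in zip(pressures, lengths)
    )
    return SimulatedSession(
        E_true_kpa,
        noise_sd,
        seed,
        measurements,
        {"pressures_kpa": pressures.tolist(), "sample_id": sample_id},
    )


def render_if_population(
    n_cells: int,
    enrichment_factor: float,
    seed: int = 0,
    canvas_px: tuple[int, int] = (512, 512),
    noise_sd: float = 0.02,
    max_placement_tries: int = 5000,
) -> IFPopulation:
    """Non-overlapping elliptical cells with nuclear sub-ellipses.

    The stain channel has cytoplasmic intensity ``base`` and nuclear
    intensity ``base * enrichment_factor``; the nuclear counterstain is
    bright inside nuclei only.  True categories follow the enrichment:
    > 1.2 nuclear ("in"), < 0.8 cytoplasmic ("out"), else "even".
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if enrichment_factor < 0:
        raise ValueError("enrichment_factor must be non-negative")
    rng = np.random.default_rng(seed)
    n_rows, n_cols = canvas_px
    placed: list[tuple[float, float, float, float, float]] = []
    tries = 0
    while len(placed) < n_cells:
        if tries >= max_placement_tries:
            raise ValueError(
                f"could not place {n_cells} non-overlapping cells on "
                f"{canvas_px} after {max_placement_tries} tries"
            )
        tries += 1
        sa = rng.uniform(26.0, 40.0)  # semi-major, px
        sb = rng.uniform(18.0, 26.0)
        theta = rng.uniform(0.0, np.pi)
        cy = rng.uniform(sa + 4, n_rows - sa - 4)
        cx = rng.uniform(sa + 4, n_cols - sa - 4)
        if all(np.hypot(cy - py, cx - px) > sa + pa + 4 for py, px, pa, _, _ in placed):
            placed.append((cy, cx, sa, sb, theta))

    rows = np.arange(n_rows, dtype=float)[:, None]
    cols = np.arange(n_cols, dtype=float)[None, :]
    cell_labels = np.zeros(canvas_px, dtype=np.int32)
    nuclear_labels = np.zeros(canvas_px, dtype=np.int32)
    for i, (cy, cx, sa, sb, theta) in enumerate(placed, start=1):
        u = (cols - cx) * np.cos(theta) + (rows - cy) * np.sin(theta)
        v = -(cols - cx) * np.sin(theta) + (rows - cy) * np.cos(theta)
        cell = (u / sa) ** 2 + (v / sb) ** 2 <= 1.0
        nucleus = (u / (0.45 * sa)) ** 2 + (v / (0.45 * sb)) ** 2 <= 1.0
        cell_labels[cell] = i
        nuclear_labels[nucleus] = i

    base = 0.35
    background = 0.04
    yap = np.full(canvas_px, background)
    yap[cell_labels > 0] = base
    yap[nuclear_labels > 0] = base * enrichment_factor
    yap = np.clip(yap + rng.normal(0.0, noise_sd, canvas_px), 0.0, None)
    nuclear_channel = np.where(nuclear_labels > 0, 0.9, background)
    nuclear_channel = np.clip(
        nuclear_channel + rng.normal(0.0, noise_sd, canvas_px), 0.0, None
    )

    if enrichment_factor > 1.2:
        category = "in"
    elif enrichment_factor < 0.8:
        category = "out"
    else:
        category = "even"
    return IFPopulation(
        yap_channel=yap,
        nuclear_channel=nuclear_channel,
        cell_labels=cell_labels,
        nuclear_labels=nuclear_labels,
        enrichment_factor=enrichment_factor,
        true_categories=tuple(category for _ in range(n_cells)),
        seed=seed,
    )
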