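"""Geometric metrology on indentation photographs, aspiration micrographs
and immunofluorescence images.

All raster coordinates are (row, col) with the origin at the top-left and
rows increasing downward.  Physical scale is calibrated from a known
reference inside each image — the sphere radius for indentation scenes and
the pipette external diameter (2A) for aspiration scenes — assuming square
pixels.  Every detected quantity is reported both in pixels and in mm, with
mm = px * mm_per_px exactly.

The detectors are designed for backlit silhouettes: bright background,
dark gel/sphere/pipette.  Edges are located with sub-pixel precision by
linear interpolation of the intensity crossing of the binarisation
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "IndentationImageResult",
    "AspirationImageResult",
    "CellLocalization",
    "ImageAnalysisError",
    "UndefinedRatioError",
    "analyze_indentation_image",
    "analyze_aspiration_image",
    "classify_yap_taz",
    "summarize_localization",
]

#: half-width of the contact exclusion zone, in units of sqrt(R*delta)
CONTACT_EXCLUSION = 1.5
#: minimum fraction of candidate surface columns consistent with the fitted
#: free-surface line
MIN_SURFACE_INLIERS = 0.5
#: default nuclear/cytoplasmic ratio band half-width for the YAP/TAZ call
DEFAULT_NC_THRESHOLD = 0.2


class ImageAnalysisError(RuntimeError):
    """A required feature could not be detected in the image."""


class UndefinedRatioError(ZeroDivisionError):
    """Cytoplasmic mean intensity is zero; the N/C ratio is undefined."""


@dataclass(frozen=True)
class IndentationImageResult:
    sphere_center_px: tuple[float, float]  # (row, col)
    sphere_radius_px: float
    gel_surface_row_px: float  # undeformed free-surface line at the sphere axis
    gel_base_row_px: float
    gel_left_col_px: float
    gel_right_col_px: float
    mm_per_px: float
    delta_mm: float
    h_mm: float
    D_mm: float
    circle_rms_residual_px: float
    surface_inlier_fraction: float

    @property
    def delta_px(self) -> float:
        return self.delta_mm / self.mm_per_px


@dataclass(frozen=True)
class AspirationImageResult:
    axis_col_px: float
    inner_wall_cols_px: tuple[float, float]
    outer_wall_cols_px: tuple[float, float]
    mouth_row_px: float
    apex_row_px: float
    mm_per_px: float
    l_mm: float
    a_mm: float
    A_mm: float
    surface_inlier_fraction: float


@dataclass(frozen=True)
class CellLocalization:
    cell_id: int
    nuclear_mean_intensity: float
    cytoplasmic_mean_intensity: float
    nc_ratio: float
    category: str  # "in" | "even" | "out"


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() > 1.5:  # 8/16-bit input
        img = img / img.max()
    return img


def _subpixel_top_profile(img: np.ndarray, thresh: float) -> np.ndarray:
    """First threshold crossing from the top, per column (NaN if none)."""
    return _subpixel_first_crossing(img, thresh, axis=0, reverse=False)


def _subpixel_first_crossing(
    img: np.ndarray, thresh: float, axis: int, reverse: bool
) -> np.ndarray:
    dark = img < thresh
    work = np.moveaxis(dark, axis, 0)
    vals = np.moveaxis(img, axis, 0)
    if reverse:
        work = work[::-1]
        vals = vals[::-1]
    n = work.shape[0]
    idx = np.argmax(work, axis=0).astype(float)
    none = ~work.any(axis=0)
    out = np.full(work.shape[1], np.nan)
    for j in np.nonzero(~none)[0]:
        i = int(idx[j])
        if i == 0:
            out[j] = 0.0
        else:
            prev, curr = vals[i - 1, j], vals[i, j]
            frac = (prev - thresh) / (prev - curr) if prev != curr else 0.5
            out[j] = i - 1 + float(np.clip(frac, 0.0, 1.0))
    if reverse:
        out = (n - 1) - out
    return out


def _fit_circle(cols: np.ndarray, rows: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle fit; returns (row_c, col_c, r)."""
    A = np.column_stack([2.0 * cols, 2.0 * rows, np.ones_like(cols)])
    b = cols**2 + rows**2
    (cc, cr, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    r = float(np.sqrt(c + cc**2 + cr**2))
    return float(cr), float(cc), r


def analyze_indentation_image(
    image: np.ndarray, known_sphere_radius_mm: float
) -> IndentationImageResult:
    """Measure delta, h and D from a side-view indentation silhouette.

    The sphere's visible arc is circle-fitted (with one inlier-reselection
    pass) and sets the scale; the undeformed free surface is a robust line
    fit to the gel's top edge outside a contact exclusion zone of half-width
    1.5 sqrt(R delta) around the sphere axis (one refinement iteration).
    delta is the depth of the sphere's lowest point below that line.
    """
    if known_sphere_radius_mm <= 0:
        raise ValueError("known_sphere_radius_mm must be positive")
    img = _to_gray(image)
    thresh = threshold_otsu(img)
    top = _subpixel_top_profile(img, thresh)
    cols_all = np.nonzero(~np.isnan(top))[0]
    if cols_all.size == 0:
        raise ImageAnalysisError("no silhouette found (image is uniformly bright)")

    # initial surface estimate: the modal top row of the silhouette
    surface0 = float(np.nanmedian(top[cols_all]))
    sphere_cols = cols_all[top[cols_all] < surface0 - 3.0]
    if sphere_cols.size < 10:
        raise ImageAnalysisError("no circle found above the gel surface")

    cr, cc, r = _fit_circle(sphere_cols.astype(float), top[sphere_cols])
    # one inlier-reselection pass against the fitted circle
    resid = np.abs(
        np.hypot(sphere_cols - cc, top[sphere_cols] - cr) - r
    )
    good = resid < 2.0
    if good.sum() >= 10:
        cr, cc, r = _fit_circle(
            sphere_cols[good].astype(float), top[sphere_cols[good]]
        )
        resid = resid[good]
    rms = float(np.sqrt(np.mean(resid**2)))
    if not np.isfinite(r) or r <= 0:
        raise ImageAnalysisError("circle fit failed")
    mm_per_px = known_sphere_radius_mm / r

    # robust free-surface line with contact-zone exclusion, one refinement;
    # columns under the sphere's visible silhouette never vote for the line
    not_sphere = ~np.isin(cols_all, sphere_cols)
    surface_at_axis = surface0
    slope, intercept = 0.0, surface0
    inlier_fraction = 0.0
    for _ in range(2):
        delta_px_est = max((cr + r) - surface_at_axis, 1.0)
        half_width = CONTACT_EXCLUSION * float(np.sqrt(r * delta_px_est))
        candidates = cols_all[not_sphere & (np.abs(cols_all - cc) > half_width)]
        if candidates.size < 10:
            raise ImageAnalysisError("not enough free surface outside the contact zone")
        line = np.polyfit(candidates, top[candidates], 1)
        pred = np.polyval(line, candidates)
        inliers = np.abs(top[candidates] - pred) < 2.0
        inlier_fraction = float(inliers.mean())
        if inliers.sum() >= 10:
            line = np.polyfit(candidates[inliers], top[candidates[inliers]], 1)
        slope, intercept = float(line[0]), float(line[1])
        surface_at_axis = slope * cc + intercept
    if inlier_fraction < MIN_SURFACE_INLIERS:
        raise ImageAnalysisError(
            f"free-surface line unreliable (inlier fraction {inlier_fraction:.2f})"
        )

    sphere_bottom = cr + r
    delta_px = sphere_bottom - surface_at_axis
    if delta_px < -2.0:
        raise ImageAnalysisError("sphere is not in contact with the gel surface")
    delta_px = max(delta_px, 0.0)

    # gel base: last dark row, away from the image margin
    bottom = _subpixel_first_crossing(img, thresh, axis=0, reverse=True)
    base_row = float(np.nanmedian(bottom[cols_all]))

    # gel lateral edges from a row profile below the sphere
    scan_row = int(round(surface_at_axis + 0.75 * (base_row - surface_at_axis)))
    scan_row = min(max(scan_row, 0), img.shape[0] - 1)
    row_band = img[max(scan_row - 2, 0) : scan_row + 3].mean(axis=0)
    left = _subpixel_first_crossing(row_band[None, :].T, thresh, axis=0, reverse=False)
    right = _subpixel_first_crossing(row_band[None, :].T, thresh, axis=0, reverse=True)
    gel_left, gel_right = float(left[0]), float(right[0])
    if not (np.isfinite(gel_left) and np.isfinite(gel_right)):
        raise ImageAnalysisError("gel lateral edges not found")

    return IndentationImageResult(
        sphere_center_px=(cr, cc),
        sphere_radius_px=r,
        gel_surface_row_px=float(surface_at_axis),
        gel_base_row_px=base_row,
        gel_left_col_px=gel_left,
        gel_right_col_px=gel_right,
        mm_per_px=mm_per_px,
        delta_mm=delta_px * mm_per_px,
        h_mm=(base_row - surface_at_axis) * mm_per_px,
        D_mm=(gel_right - gel_left) * mm_per_px,
        circle_rms_residual_px=rms,
        surface_inlier_fraction=inlier_fraction,
    )


def analyze_aspiration_image(
    image: np.ndarray, known_external_radius_A_mm: float
) -> AspirationImageResult:
    """Measure the aspirated length l and internal radius a from a
    micrograph of a vertical pipette pressed on the gel.

    The outer wall separation equals the known external diameter 2A and
    calibrates the scale.  l is the height of the meniscus apex on the
    pipette axis above the mouth plane, taken as the undisturbed gel
    surface seen outside the pipette.
    """
    if known_external_radius_A_mm <= 0:
        raise ValueError("known_external_radius_A_mm must be positive")
    img = _to_gray(image)
    thresh = threshold_otsu(img)
    n_rows, n_cols = img.shape

    # wall columns from a band near the top of the frame
    band = img[: max(int(0.15 * n_rows), 5)].mean(axis=0)
    dark = band < thresh
    runs: list[tuple[int, int]] = []
    j = 0
    while j < n_cols:
        if dark[j]:
            k = j
            while k + 1 < n_cols and dark[k + 1]:
                k += 1
            runs.append((j, k))
            j = k + 1
        else:
            j += 1
    runs = [r for r in runs if r[1] - r[0] >= 3]
    if len(runs) != 2:
        raise ImageAnalysisError(
            f"pipette wall pair not found ({len(runs)} dark bands in the top band)"
        )

    def _edge(profile: np.ndarray, i: int, direction: int) -> float:
        # sub-pixel crossing just outside pixel i moving against `direction`
        j = i - direction
        if j < 0 or j >= profile.size or profile[j] == profile[i]:
            return float(i)
        frac = (profile[j] - thresh) / (profile[j] - profile[i])
        return j + direction * float(np.clip(frac, 0.0, 1.0))

    (l0, l1), (r0, r1) = runs
    outer_left = _edge(band, l0, +1)
    inner_left = _edge(band, l1, -1)
    inner_right = _edge(band, r0, +1)
    outer_right = _edge(band, r1, -1)
    mm_per_px = 2.0 * known_external_radius_A_mm / (outer_right - outer_left)
    a_px = (inner_right - inner_left) / 2.0
    axis_col = (inner_left + inner_right) / 2.0

    top = _subpixel_top_profile(img, thresh)
    # mouth plane = gel surface outside the pipette
    margin = 4
    outside = np.concatenate(
        [
            np.arange(1, max(int(outer_left) - margin, 1)),
            np.arange(min(int(outer_right) + margin, n_cols - 1), n_cols - 1),
        ]
    )
    outside = outside[~np.isnan(top[outside])]
    if outside.size < 10:
        raise ImageAnalysisError("gel surface not visible outside the pipette")
    mouth_row = float(np.median(top[outside]))
    inlier_fraction = float(np.mean(np.abs(top[outside] - mouth_row) < 2.0))

    centre = np.arange(int(axis_col) - 3, int(axis_col) + 4)
    centre_tops = top[centre]
    if np.all(np.isnan(centre_tops)):
        raise ImageAnalysisError("no meniscus apex found on the pipette axis")
    apex_row = float(np.nanmedian(centre_tops))
    if apex_row > mouth_row + 2.0:
        raise ImageAnalysisError("meniscus apex lies below the mouth plane")
    l_px = max(mouth_row - apex_row, 0.0)

    return AspirationImageResult(
        axis_col_px=float(axis_col),
        inner_wall_cols_px=(float(inner_left), float(inner_right)),
        outer_wall_cols_px=(float(outer_left), float(outer_right)),
        mouth_row_px=mouth_row,
        apex_row_px=apex_row,
        mm_per_px=float(mm_per_px),
        l_mm=float(l_px * mm_per_px),
        a_mm=float(a_px * mm_per_px),
        A_mm=known_external_radius_A_mm,
        surface_inlier_fraction=inlier_fraction,
    )


def classify_yap_taz(
    nuclear_mask: np.ndarray,
    cell_mask: np.ndarray,
    yap_channel: np.ndarray,
    threshold: float = DEFAULT_NC_THRESHOLD,
    cell_id: int = 0,
) -> CellLocalization:
    """Nuclear / cytoplasmic YAP-TAZ localisation call for one cell.

    nc_ratio = mean stain intensity inside the nucleus over the mean in the
    cytoplasm (cell minus nucleus).  Category is ``in`` (nuclear) when
    nc_ratio > 1 + t, ``out`` (cytoplasmic) when nc_ratio < 1 - t, ``even``
    otherwise; t defaults to 0.2 and is a convention, not a measured
    constant.
    """
    nuc = np.asarray(nuclear_mask, dtype=bool)
    cell = np.asarray(cell_mask, dtype=bool)
    yap = np.asarray(yap_channel, dtype=float)
    if nuc.shape != cell.shape or nuc.shape != yap.shape:
        raise ValueError("masks and intensity image must share a shape")
    if np.any(nuc & ~cell):
        raise ValueError("nuclear mask must be contained in the cell mask")
    cyto = cell & ~nuc
    if not nuc.any() or not cyto.any():
        raise ValueError("empty nuclear or cytoplasmic region")
    nuc_mean = float(yap[nuc].mean())
    cyto_mean = float(yap[cyto].mean())
    if cyto_mean == 0:
        raise UndefinedRatioError("cytoplasmic mean intensity is zero")
    ratio = nuc_mean / cyto_mean
    if ratio > 1.0 + threshold:
        category = "in"
    elif ratio < 1.0 - threshold:
        category = "out"
    else:
        category = "even"
    return CellLocalization(cell_id, nuc_mean, cyto_mean, ratio, category)


def summarize_localization(cells: list[CellLocalization]) -> dict[str, int]:
    """Integer percentages of in/even/out cells, summing to exactly 100.

    Largest-remainder rounding; ties broken in the fixed order
    in, even, out.
    """
    if not cells:
        raise ValueError("no cells to summarise")
    order = ("in", "even", "out")
    n = len(cells)
    counts = {c: sum(1 for cell in cells if cell.category == c) for c in order}
    exact = {c: 100.0 * counts[c] / n for c in order}
    floors = {c: int(exact[c]) for c in order}
    shortfall = 100 - sum(floors.values())
    by_remainder = sorted(
        order, key=lambda c: (-(exact[c] - floors[c]), order.index(c))
    )
    for c in by_remainder[:shortfall]:
        floors[c] += 1
    return floors
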