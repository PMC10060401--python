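"""Fluorescence histology quantification.

The pipeline matches standard confocal intensity workflows: each z-slice
gets a rolling-ball background subtraction (radius 50 px by default, the
classical grayscale-morphology construction), the mean gray value of a
region of interest (ROI) is computed per slice, the maximum over slices
represents the stack, and the CA2 ROI maximum is divided by the corpus
callosum ROI maximum of the same section.  A brain's normalized
intensity is the average over (typically three) sections.  Cell density
converts manual counts to cells per mm³ using the ROI area and the 40 µm
section thickness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

DEFAULT_ROLLING_BALL_RADIUS = 50.0
DEFAULT_SECTION_THICKNESS_UM = 40.0


def rolling_ball_subtract(
    stack: np.ndarray,
    radius_px: float = DEFAULT_ROLLING_BALL_RADIUS,
    presmooth_sigma: float = 2.0,
) -> np.ndarray:
    """Per-slice rolling-ball background subtraction, clipped at zero.

    The background of each slice is the surface traced by a ball of the
    given radius rolled under the intensity landscape; structures smaller
    than the ball (labeled cells, fibers) survive subtraction while
    smooth shading and offsets are removed.  On noisy images the ball
    rides the noise minima and underestimates the background, so the
    background is estimated on a Gaussian-smoothed copy
    (``presmooth_sigma`` pixels; 0 disables) and subtracted from the
    original — the same convention desktop background-subtraction tools
    use.  Output is never negative.
    """
    from scipy.ndimage import gaussian_filter
    from skimage import restoration

    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim == 2:
        stack = stack[None]
    if radius_px <= 0:
        raise ValueError("radius must be positive")
    if 2 * radius_px + 1 > max(stack.shape[1], stack.shape[2]) * 2:
        raise ValueError("ball radius exceeds image extent")
    out = np.empty_like(stack)
    for z in range(stack.shape[0]):
        sl = stack[z]
        base = gaussian_filter(sl, presmooth_sigma) if presmooth_sigma > 0 else sl
        background = restoration.rolling_ball(base, radius=radius_px)
        out[z] = np.clip(sl - background, 0.0, None)
    return out


def roi_stack_intensity(stack: np.ndarray, roi: np.ndarray) -> float:
    """Maximum over z-slices of the per-slice mean intensity inside the ROI."""
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim == 2:
        stack = stack[None]
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    if roi.shape != stack.shape[1:]:
        raise ValueError("ROI mask shape must match the slice shape")
    per_slice = stack[:, roi].mean(axis=1)
    return float(per_slice.max())


@dataclass(frozen=True)
class IntensityResult:
    """Normalized intensity of a target region over one brain."""

    roi_max_means: tuple[float, ...]
    reference_max_means: tuple[float, ...]
    section_ratios: tuple[float, ...]
    section_average: float


def normalized_intensity(
    roi_values_per_section, reference_values_per_section
) -> IntensityResult:
    """Per-section target/reference ratio, averaged over sections.

    ``roi_values_per_section`` are the stack-maximum ROI means of the
    target region (e.g. CA2) and ``reference_values_per_section`` those
    of the reference (corpus callosum) for the same sections.
    """
    roi = [float(v) for v in roi_values_per_section]
    ref = [float(v) for v in reference_values_per_section]
    if len(roi) != len(ref):
        raise ValueError("need one reference value per section")
    if not roi:
        raise ValueError("need at least one section")
    if any(r <= 0 for r in ref):
        raise ZeroDivisionError("reference intensity must be positive")
    ratios = tuple(a / b for a, b in zip(roi, ref))
    return IntensityResult(
        roi_max_means=tuple(roi),
        reference_max_means=tuple(ref),
        section_ratios=ratios,
        section_average=float(np.mean(ratios)),
    )


def cell_density(
    count: int, roi_area_um2: float, section_thickness_um: float = DEFAULT_SECTION_THICKNESS_UM
) -> float:
    """Labeled-cell density in cells per mm³.

    Divides the count by ROI area × section thickness, converting µm³ to
    mm³ (1 mm³ = 1e9 µm³).
    """
    if count < 0:
        raise ValueError("count must be nonnegative")
    if roi_area_um2 <= 0 or section_thickness_um <= 0:
        raise ValueError("area and thickness must be positive")
    volume_mm3 = roi_area_um2 * section_thickness_um / 1e9
    return count / volume_mm3


def colabel_fractions(a_pos: int, b_pos: int, ab_pos: int) -> tuple[float, float]:
    """Co-labeling percentages from single- and double-positive counts.

    Returns ``(%A among B, %B among A)`` — e.g. with A = mCherry and
    B = PCP4, the fraction of PCP4+ cells that are infected and the
    fraction of infected cells that are pyramidal.
    """
    if min(a_pos, b_pos, ab_pos) < 0 or ab_pos > min(a_pos, b_pos):
        raise ValueError("inconsistent counts: need 0 <= A+B+ <= min(A+, B+)")
    pct_a_among_b = 100.0 * ab_pos / b_pos if b_pos else 0.0
    pct_b_among_a = 100.0 * ab_pos / a_pos if a_pos else 0.0
    return pct_a_among_b, pct_b_among_a


def polygon_mask(polygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside a polygon.

    ``polygon`` is a sequence of (row, col) vertices.
    """
    from skimage.draw import polygon2mask

    return polygon2mask(shape, np.asarray(polygon, dtype=float))


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF z-stack as float64 (slices, h, w)."""
    import tifffile

    stack = np.asarray(tifffile.imread(path), dtype=np.float64)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_stack(stack: np.ndarray, path: str | Path) -> Path:
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32), photometric="minisblack")
    return path


def read_rois(path: str | Path, shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Read ROI polygons from JSON {name: [[r, c], ...]} into masks."""
    data = json.loads(Path(path).read_text())
    return {name: polygon_mask(poly, shape) for name, poly in data.items()}


def write_rois(rois: dict[str, list], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(rois, indent=1))
    return path
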