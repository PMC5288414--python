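"""De-skewing and de-identification of scanned form images.

Pages are 2-D float arrays with intensities in [0, 1], origin at the top-left,
row-major; 0 is black ink and 1 is white background.  De-skewing rotates the
page by the angle that minimizes the entropy of the per-row black-pixel
profile: horizontal text lines concentrate ink into few rows, which is the
low-entropy configuration.  De-identification finds the horizontal separator
line below the personal-information header via Sobel edge energy and blanks
the region above it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "RedactionRegion",
    "SkewEstimate",
    "MarkerNotFoundError",
    "binarize",
    "rotate_image",
    "row_profile",
    "skew_entropy",
    "estimate_skew",
    "deskew",
    "sobel_edges",
    "locate_marker_line",
    "blank_region",
]

#: rows whose black fraction falls below this are ignored by the entropy:
#: -P ln P is increasing on [0, 1/e) so faint noise rows would otherwise
#: dominate, and real text rows carry well over 10% ink.
LINE_FRACTION_FLOOR = 0.10


@dataclass(frozen=True)
class RedactionRegion:
    """Half-open pixel rectangle [row_start, row_end) x [col_start, col_end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def validate(self, height: int, width: int) -> None:
        if not (0 <= self.row_start < self.row_end <= height):
            raise ValueError(f"row range [{self.row_start}, {self.row_end}) "
                             f"outside image of height {height}")
        if not (0 <= self.col_start < self.col_end <= width):
            raise ValueError(f"col range [{self.col_start}, {self.col_end}) "
                             f"outside image of width {width}")


@dataclass(frozen=True)
class SkewEstimate:
    """Corrective rotation angle, its entropy, and the profile behind it."""

    angle_deg: float
    entropy: float
    profile: np.ndarray


class MarkerNotFoundError(RuntimeError):
    """No row's edge energy clears the floor; caller should fall back to a
    manually supplied redaction region."""


def _as_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    return arr


def binarize(image: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Threshold a grayscale page to {0, 1}; pixels below the threshold are ink.

    ``threshold=None`` selects a global Otsu threshold.
    """
    arr = _as_image(image)
    if threshold is None:
        if arr.min() == arr.max():
            return (arr >= 0.5).astype(float)  # flat page: nothing to separate
        threshold = float(threshold_otsu(arr))
    elif not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return (arr >= threshold).astype(float)


def rotate_image(image: np.ndarray, angle_deg: float, *,
                 binary: bool | None = None) -> np.ndarray:
    """Rotate about the image center, keeping shape; uncovered border is white.

    Nearest-neighbour resampling for binary pages (preserves {0, 1}),
    bilinear for grayscale.
    """
    arr = _as_image(image)
    if angle_deg == 0.0:
        return arr.copy()
    if binary is None:
        binary = bool(np.isin(np.unique(arr), (0.0, 1.0)).all())
    out = ndimage.rotate(arr, angle_deg, reshape=False,
                         order=0 if binary else 1, mode="constant", cval=1.0)
    return np.clip(out, 0.0, 1.0)


def row_profile(image: np.ndarray, angle_deg: float = 0.0) -> np.ndarray:
    """Black-pixel fraction per row of the page rotated by ``angle_deg``."""
    arr = rotate_image(_as_image(image), angle_deg, binary=True)
    return (arr < 0.5).mean(axis=1)


def skew_entropy(profile: np.ndarray) -> float:
    """Entropy -sum P ln P over rows with black fraction >= 10%.

    Rows below the floor are skipped (they are either empty or pepper noise);
    a fully black row contributes 0.  Returns 0 when no row qualifies.
    """
    p = np.asarray(profile, dtype=float)
    p = p[p >= LINE_FRACTION_FLOOR]
    if p.size == 0:
        return 0.0
    return float(-np.sum(p * np.log(p)))


def estimate_skew(image: np.ndarray, range_deg: float = 20.0,
                  step_deg: float = 1.0, *,
                  refine_step_deg: float | None = 0.1) -> SkewEstimate:
    """Grid-search the corrective angle minimizing the row-profile entropy.

    Searches [-range_deg, +range_deg] at ``step_deg``; ties break toward the
    smallest |angle|, then toward the negative angle.  When
    ``refine_step_deg`` is set, a second +/-1 degree pass at that step runs
    around the coarse optimum.  A blank page yields angle 0 with a warning.
    """
    arr = _as_image(image)
    if step_deg <= 0:
        raise ValueError("step_deg must be positive")
    if not (arr < 0.5).any():
        warnings.warn("blank page: skew undefined, returning 0", stacklevel=2)
        return SkewEstimate(0.0, 0.0, row_profile(arr, 0.0))

    def best_on(grid: np.ndarray) -> tuple[float, float, np.ndarray]:
        entries = []
        for ang in grid:
            prof = row_profile(arr, ang)
            entries.append((skew_entropy(prof), abs(ang), ang, prof))
        # tie-break: smallest entropy, then smallest |angle|, then negative
        ent, _, ang, prof = min(entries, key=lambda e: (e[0], e[1], e[2]))
        return float(ang), float(ent), prof

    n = int(round(2 * range_deg / step_deg))
    grid = -range_deg + step_deg * np.arange(n + 1)
    angle, entropy, prof = best_on(np.round(grid, 10))
    if refine_step_deg is not None and refine_step_deg < step_deg:
        m = int(round(1.0 / refine_step_deg))
        fine = angle + refine_step_deg * np.arange(-m, m + 1)
        fine = fine[np.abs(fine) <= range_deg + 1e-9]
        angle, entropy, prof = best_on(np.round(fine, 10))
    return SkewEstimate(angle, entropy, prof)


def deskew(image: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate the page by the corrective angle (same convention as
    :func:`estimate_skew`: apply its ``angle_deg`` directly)."""
    return rotate_image(image, angle_deg)


# Horizontal- and vertical-derivative kernels of the Sobel operator.
SOBEL_KX = np.array([[-1.0, 0.0, 1.0],
                     [-2.0, 0.0, 2.0],
                     [-1.0, 0.0, 1.0]])
SOBEL_KY = np.array([[1.0, 2.0, 1.0],
                     [0.0, 0.0, 0.0],
                     [-1.0, -2.0, -1.0]])


def sobel_edges(image: np.ndarray) -> np.ndarray:
    """Gradient magnitude sqrt(Gx^2 + Gy^2) from the 3x3 Sobel kernel pair.

    Borders are handled by edge replication.
    """
    arr = _as_image(image)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    gx = ndimage.correlate(arr, SOBEL_KX, mode="nearest")
    gy = ndimage.correlate(arr, SOBEL_KY, mode="nearest")
    return np.sqrt(gx * gx + gy * gy)


def locate_marker_line(edges: np.ndarray, search_fraction: float = 0.5, *,
                       energy_floor: float = 2.0) -> int:
    """Row with maximal summed edge energy within the top ``search_fraction``
    of the page — the separator line below the personal-information header.

    Ties break toward the smaller row index.  Raises
    :class:`MarkerNotFoundError` when no candidate row's energy reaches
    ``energy_floor`` times the mean row energy of the searched band.
    """
    arr = _as_image(edges)
    if not 0.0 < search_fraction <= 1.0:
        raise ValueError("search_fraction must lie in (0, 1]")
    n_rows = max(1, int(round(arr.shape[0] * search_fraction)))
    energy = arr[:n_rows].sum(axis=1)
    if energy.max() <= 0 or energy.max() < energy_floor * max(energy.mean(), 1e-12):
        raise MarkerNotFoundError("no row clears the edge-energy floor")
    return int(np.argmax(energy))  # argmax returns the first maximum


def blank_region(image: np.ndarray, region: RedactionRegion,
                 fill: float = 0.0) -> np.ndarray:
    """Paint the region a uniform redaction value (black); idempotent, and
    every pixel outside the region is preserved bit-exactly."""
    arr = _as_image(image)
    region.validate(*arr.shape)
    out = arr.copy()
    out[region.row_start:region.row_end, region.col_start:region.col_end] = fill
    return out
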