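"""Colorimetric sensor-array image processing.

From a scanned before/after image pair this module recovers the array's
feature set: median filtering, threshold segmentation of the 15 dye spots,
mean R/G/B over a 15-pixel-radius disk at each spot, and the per-spot
colour differences dR/dG/dB between the exposed and unexposed images —
45 components in total (15 spots x 3 channels).  A normalized grayscale
"difference image" can be rendered for visual inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter as _ndi_median
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .cohort import ArrayGeometry, GeometryError, N_SPOTS

__all__ = [
    "SpotGrid",
    "ColorFeatureVector",
    "SegmentationError",
    "median_filter",
    "segment_spots",
    "mean_spot_rgb",
    "delta_components",
    "normalize_deltas",
    "difference_image",
    "extract_pair_features",
    "FEATURE_NAMES",
]

EXTRACTION_RADIUS = 15  # px, per-spot averaging disk

#: Column names of the 45-component feature vector, row-major over spots.
FEATURE_NAMES = [
    f"s{s + 1:02d}_d{ch}" for s in range(N_SPOTS) for ch in "RGB"
]


class SegmentationError(RuntimeError):
    """Raised when threshold segmentation does not isolate exactly 15 spots."""

    def __init__(self, n_found: int):
        self.n_found = n_found
        super().__init__(
            f"expected {N_SPOTS} spot regions, found {n_found}"
        )


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {img.shape}")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("image values must lie in [0, 255]")
    return img


@dataclass(frozen=True)
class SpotGrid:
    """Centres of the 15 dye spots in pixel coordinates (row, col),
    row-major over the 5 x 3 layout, plus the extraction radius."""

    centers: np.ndarray
    radius: float = EXTRACTION_RADIUS

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        if centers.shape != (N_SPOTS, 2):
            raise ValueError(
                f"centers must be {N_SPOTS} x 2, got {centers.shape}"
            )
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        d2 = np.sum(
            (centers[:, None, :] - centers[None, :, :]) ** 2, axis=-1
        )
        np.fill_diagonal(d2, np.inf)
        if np.any(d2 <= (2 * self.radius) ** 2):
            raise GeometryError("extraction disks overlap")
        object.__setattr__(self, "centers", centers)


@dataclass(frozen=True)
class ColorFeatureVector:
    """The 45 colour components of one sample, ordered
    (spot1 dR, dG, dB, spot2 dR, ...)."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (3 * N_SPOTS,):
            raise ValueError(f"expected {3 * N_SPOTS} components, got {v.shape}")
        object.__setattr__(self, "values", v)

    def as_matrix(self) -> np.ndarray:
        """15 x 3 view: one row per spot, columns R, G, B."""
        return self.values.reshape(N_SPOTS, 3)


def median_filter(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Channel-wise square median filter with reflect padding."""
    img = _check_rgb(img)
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window == 1:
        return img.copy()
    return _ndi_median(img, size=(window, window, 1), mode="reflect")


def segment_spots(
    img: np.ndarray,
    radius: float = EXTRACTION_RADIUS,
    min_area_fraction: float = 0.2,
) -> SpotGrid:
    """Locate the 15 dye spots by threshold segmentation.

    The background colour is estimated as the per-channel median (the
    array occupies a minority of the raster); Otsu's threshold is applied
    to the mean absolute deviation from that background, connected
    components are extracted, and regions smaller than
    ``min_area_fraction`` of the median region area are discarded as
    debris.  Exactly 15 surviving regions are required; their centroids
    are returned row-major (top-to-bottom, left-to-right).
    """
    img = _check_rgb(img).astype(float)
    background = np.median(img.reshape(-1, 3), axis=0)
    deviation = np.abs(img - background).mean(axis=2)
    if deviation.max() == deviation.min():
        raise SegmentationError(0)
    mask = deviation > threshold_otsu(deviation)
    labels = label(mask)
    regions = regionprops(labels)
    if not regions:
        raise SegmentationError(0)
    areas = np.array([r.area for r in regions])
    keep = [
        r for r in regions if r.area >= min_area_fraction * np.median(areas)
    ]
    if len(keep) != N_SPOTS:
        raise SegmentationError(len(keep))
    centroids = np.array([r.centroid for r in keep])
    # row-major ordering: sort by row, chunk into 5 rows of 3, sort each by col
    order = np.argsort(centroids[:, 0], kind="stable")
    centroids = centroids[order]
    rows = [centroids[i : i + 3] for i in range(0, N_SPOTS, 3)]
    centroids = np.vstack(
        [row[np.argsort(row[:, 1], kind="stable")] for row in rows]
    )
    return SpotGrid(centers=centroids, radius=radius)


def mean_spot_rgb(img: np.ndarray, grid: SpotGrid) -> np.ndarray:
    """Mean R/G/B over the inclusive disk (distance <= radius) at each spot.

    Returns a 15 x 3 matrix.  Raises :class:`GeometryError` if any disk
    pixel would fall outside the image.
    """
    img = _check_rgb(img)
    h, w = img.shape[:2]
    out = np.empty((N_SPOTS, 3))
    for s, (r, c) in enumerate(grid.centers):
        if (
            r - grid.radius < 0
            or c - grid.radius < 0
            or r + grid.radius > h - 1
            or c + grid.radius > w - 1
        ):
            raise GeometryError(
                f"disk at ({r:.1f}, {c:.1f}) radius {grid.radius} exits "
                f"image bounds {h} x {w}"
            )
        r0, r1 = int(r - grid.radius), int(r + grid.radius) + 2
        c0, c1 = int(c - grid.radius), int(c + grid.radius) + 2
        rr, cc = np.ogrid[r0:r1, c0:c1]
        mask = (rr - r) ** 2 + (cc - c) ** 2 <= grid.radius**2
        out[s] = img[r0:r1, c0:c1][mask].mean(axis=0, dtype=float)
    return out


def delta_components(
    before_means: np.ndarray, after_means: np.ndarray
) -> ColorFeatureVector:
    """Raw colour-shift features: after minus before, flattened row-major."""
    before_means = np.asarray(before_means, dtype=float)
    after_means = np.asarray(after_means, dtype=float)
    if before_means.shape != (N_SPOTS, 3) or after_means.shape != (N_SPOTS, 3):
        raise ValueError(
            f"expected two {N_SPOTS} x 3 matrices, got "
            f"{before_means.shape} and {after_means.shape}"
        )
    return ColorFeatureVector(
        values=(after_means - before_means).ravel(), normalized=False
    )


def normalize_deltas(v: ColorFeatureVector) -> ColorFeatureVector:
    """Per-channel min-max scaling of dR/dG/dB to [0, 1] across the 15
    spots; a degenerate channel (max = min) maps to 0.5.

    Used for the difference-image visualization; modelling uses the raw
    deltas, whose magnitude carries the analyte signal.
    """
    if v.normalized:
        return v
    mat = v.as_matrix()
    lo = mat.min(axis=0)
    hi = mat.max(axis=0)
    span = hi - lo
    out = np.empty_like(mat)
    for c in range(3):
        if span[c] == 0:
            out[:, c] = 0.5
        else:
            out[:, c] = (mat[:, c] - lo[c]) / span[c]
    return ColorFeatureVector(values=out.ravel(), normalized=True)


def difference_image(
    v: ColorFeatureVector, geometry: ArrayGeometry | None = None
) -> np.ndarray:
    """Render the normalized colour shifts as a grayscale raster.

    Each spot is drawn as a disk whose gray level is
    ``255 * mean(dR', dG', dB')`` on a black background — the recombined
    gray "difference image" used to eyeball array response patterns.
    """
    if not v.normalized:
        raise ValueError("difference_image expects a normalized vector")
    geom = geometry or ArrayGeometry()
    levels = 255.0 * v.as_matrix().mean(axis=1)
    canvas = np.zeros((geom.height, geom.width), dtype=np.uint8)
    rr, cc = np.ogrid[: geom.height, : geom.width]
    for s, (r, c) in enumerate(geom.centers()):
        mask = (rr - r) ** 2 + (cc - c) ** 2 <= geom.spot_radius**2
        canvas[mask] = int(round(levels[s]))
    return canvas


def extract_pair_features(
    before: np.ndarray,
    after: np.ndarray,
    grid: SpotGrid | None = None,
    median_window: int = 3,
    radius: float = EXTRACTION_RADIUS,
) -> ColorFeatureVector:
    """Full extraction chain for one image pair.

    Median-filters both images, segments the *after* image (unless a
    user-supplied grid is given as fallback), averages each channel over
    the 15 extraction disks in both images, and returns the raw
    45-component difference vector.
    """
    before_f = median_filter(before, median_window)
    after_f = median_filter(after, median_window)
    if grid is None:
        grid = segment_spots(after_f, radius=radius)
    b = mean_spot_rgb(before_f, grid)
    a = mean_spot_rgb(after_f, grid)
    return delta_components(b, a)
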