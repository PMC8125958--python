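"""Near-infrared spectrum container and preprocessing.

The preprocessing chain applied to every raw spectrum before chemometric
modelling is Savitzky–Golay (SG) smoothing followed by the standard normal
variate (SNV) transform.  SG smoothing suppresses high-frequency detector
noise while preserving peak shape; SNV standardizes each spectrum to zero
mean and unit standard deviation, which removes additive baseline offsets
and multiplicative scatter effects caused by variable packing density and
particle size of the sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "Spectrum",
    "DegenerateSpectrumError",
    "sg_smooth",
    "snv",
    "preprocess",
    "default_grid",
]

#: Default acquisition grid: 512 points spanning 900–1700 nm.
GRID_MIN_NM = 900.0
GRID_MAX_NM = 1700.0
GRID_POINTS = 512


def default_grid() -> np.ndarray:
    """The instrument's wavelength grid: 512 points over 900–1700 nm."""
    return np.linspace(GRID_MIN_NM, GRID_MAX_NM, GRID_POINTS)


class DegenerateSpectrumError(ValueError):
    """Raised when an operation is undefined for a constant spectrum."""


@dataclass(frozen=True)
class Spectrum:
    """A single-beam spectrum: intensities on a strictly increasing grid.

    Parameters
    ----------
    wavelengths:
        Wavelengths in nm, strictly increasing.
    intensities:
        Absorbance-like values, one per wavelength.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or it.ndim != 1:
            raise ValueError("wavelengths and intensities must be 1-D")
        if wl.shape != it.shape:
            raise ValueError(
                f"length mismatch: {wl.shape[0]} wavelengths vs "
                f"{it.shape[0]} intensities"
            )
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)

    def __len__(self) -> int:
        return self.wavelengths.size


def sg_smooth(s: Spectrum, window: int = 11, polyorder: int = 2) -> Spectrum:
    """Savitzky–Golay smoothing of a spectrum.

    Each point is replaced by the centre value of the least-squares
    polynomial of degree ``polyorder`` fitted over a ``window``-point
    sliding window; the edge regions use polynomial extrapolation of the
    terminal window fits.  Wavelengths pass through unchanged.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if polyorder >= window:
        raise ValueError(
            f"polyorder ({polyorder}) must be < window ({window})"
        )
    if window > len(s):
        raise ValueError(
            f"window ({window}) exceeds spectrum length ({len(s)})"
        )
    smoothed = savgol_filter(s.intensities, window, polyorder, mode="interp")
    return Spectrum(s.wavelengths, smoothed)


def snv(s: Spectrum) -> Spectrum:
    """Standard normal variate transform.

    Maps intensities to ``(x - mean(x)) / sd(x)`` using the sample (n-1)
    standard deviation of the single spectrum, yielding mean 0 / sd 1.
    Being invariant to affine distortions ``a*x + b`` (a > 0), SNV removes
    multiplicative and additive scatter.
    """
    x = s.intensities
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    # variation below machine precision (e.g. filter round-off on a flat
    # spectrum) is treated as constant
    if sd <= 1e-12 * max(1.0, abs(mean)):
        raise DegenerateSpectrumError(
            "SNV undefined for a constant spectrum (zero variance)"
        )
    return Spectrum(s.wavelengths, (x - mean) / sd)


def preprocess(s: Spectrum, window: int = 11, polyorder: int = 2) -> Spectrum:
    """Full preprocessing chain: SG smoothing, then SNV."""
    return snv(sg_smooth(s, window=window, polyorder=polyorder))
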