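"""Synthetic rice-storage cohorts with paired sensor images and NIR spectra.

The real study design this emulates: bagged rice stored at 25 degC is
sampled monthly (20 samples/month for 8 months, 160 samples total); free
fatty acid content (mg KOH-equivalent / 100 g, titration reference) rises
roughly linearly with storage time.  Each sample is measured by two
instruments:

* a 5 x 3 colorimetric ("olfactory visualization") sensor array, imaged
  before and after 30 min exposure to the sample headspace — dye spots
  shift colour in proportion to volatile load, hence to fatty acid;
* a 512-point NIR spectrometer over 900–1700 nm — C-H absorption bands at
  1165, 1215 and 1395 nm deepen with lipid oxidation products.

Neither modality observes the titration value perfectly: each responds to
its own correlate of fatty acid (headspace volatiles vs. bulk C-H bonds),
modelled here as an independent per-sample Gaussian nuisance added to the
effective analyte level seen by that instrument.  This is what makes the
two channels complementary rather than redundant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .spectra import Spectrum, default_grid

__all__ = [
    "CohortConfig",
    "StorageSample",
    "SensitivityMatrix",
    "SpectralSignature",
    "ArrayGeometry",
    "GeometryError",
    "generate_cohort",
    "render_sensor_pair",
    "synth_spectrum",
    "default_sensitivity",
    "default_signature",
    "sample_seeds",
    "write_cohort",
    "read_manifest",
]

N_SPOTS = 15
N_BAGS = 5


class GeometryError(ValueError):
    """Raised when an array geometry places spots outside the image or
    overlapping."""


@dataclass(frozen=True)
class CohortConfig:
    """Design of a synthetic storage cohort.

    The defaults reproduce the study conditions: 8 monthly sampling
    rounds of 20 samples each (5 bags x 4 subsamples), with the titrated
    fatty acid value following ``intercept + slope * month`` plus
    sample-level Gaussian noise, truncated to positive values.
    """

    n_months: int = 8
    samples_per_month: int = 20
    trend_intercept: float = 8.5  # mg/100 g at month 0
    trend_slope: float = 1.6  # mg/100 g per month of storage
    sample_noise_sd: float = 1.0  # mg/100 g
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_months < 1:
            raise ValueError(f"n_months must be >= 1, got {self.n_months}")
        if self.samples_per_month < 2:
            raise ValueError(
                f"samples_per_month must be >= 2, got {self.samples_per_month}"
            )
        if self.sample_noise_sd < 0:
            raise ValueError("sample_noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_months * self.samples_per_month


@dataclass(frozen=True)
class StorageSample:
    """One rice sample: identity, storage month, bag, and its reference
    fatty acid value in mg/100 g."""

    sample_id: str
    month: int
    bag: int
    fatty_acid: float

    def __post_init__(self) -> None:
        if self.fatty_acid <= 0:
            raise ValueError("fatty_acid must be > 0")


@dataclass(frozen=True)
class SensitivityMatrix:
    """Colour response of the 15-spot dye array.

    ``coefficients[s, c]`` is the shift of spot *s*'s mean intensity in
    channel *c* (R, G, B) per unit fatty acid (intensity counts per
    mg/100 g).  ``spot_noise_sd`` is per-spot-channel measurement noise
    (intensity counts); ``sample_effect_sd`` is a per-sample nuisance on
    the analyte level the array responds to (mg/100 g equivalent) —
    headspace volatiles track, but are not identical to, the titration
    value.
    """

    coefficients: np.ndarray
    spot_noise_sd: float = 1.0
    sample_effect_sd: float = 0.8

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        if coef.shape != (N_SPOTS, 3):
            raise ValueError(
                f"coefficients must be {N_SPOTS} x 3, got {coef.shape}"
            )
        if self.spot_noise_sd < 0 or self.sample_effect_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        object.__setattr__(self, "coefficients", coef)


@dataclass(frozen=True)
class SpectralSignature:
    """Forward model of the NIR spectrometer.

    intensity(lambda) = m * [baseline(lambda)
                             + sum_p gain_p * fa_eff * gauss(lambda; c_p, w_p)]
                        + a + noise

    with multiplicative scatter ``m ~ 1 + N(0, scatter_mult_sd)``, additive
    scatter ``a ~ N(0, scatter_add_sd)`` and per-point detector noise.
    ``fa_eff`` is the sample's fatty acid value plus an independent
    per-sample nuisance (``sample_effect_sd``) standing in for matrix
    effects.

    The baseline is wavelength-shaped: a constant pedestal plus fixed
    (analyte-independent) water and starch bands.  A constant baseline
    would make every spectrum an affine function of a single shape, which
    the SNV step then maps to one analyte-independent curve; the fixed
    bands are what let the preprocessed spectrum retain analyte
    information, as real rice spectra do.
    """

    grid: np.ndarray = field(default_factory=default_grid)
    peak_centers: tuple[float, ...] = (1165.0, 1215.0, 1395.0)
    peak_widths: tuple[float, ...] = (30.0, 25.0, 40.0)
    peak_gain: tuple[float, ...] = (0.0035, 0.0030, 0.0045)  # AU per mg/100 g
    baseline_level: float = 0.35  # AU pedestal
    fixed_band_centers: tuple[float, ...] = (990.0, 1450.0)
    fixed_band_widths: tuple[float, ...] = (40.0, 45.0)
    fixed_band_amplitudes: tuple[float, ...] = (0.15, 0.25)  # AU
    scatter_mult_sd: float = 0.05  # dimensionless
    scatter_add_sd: float = 0.02  # AU
    noise_sd: float = 0.002  # AU per point
    sample_effect_sd: float = 0.8  # mg/100 g equivalent

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 1 or grid.size != 512:
            raise ValueError(f"grid must have 512 points, got {grid.size}")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be strictly increasing")
        for c in self.peak_centers + self.fixed_band_centers:
            if not (grid[0] <= c <= grid[-1]):
                raise ValueError(f"peak center {c} nm outside grid range")
        if not (
            len(self.peak_centers) == len(self.peak_widths) == len(self.peak_gain)
        ):
            raise ValueError("peak centers/widths/gains must align")
        if not (
            len(self.fixed_band_centers)
            == len(self.fixed_band_widths)
            == len(self.fixed_band_amplitudes)
        ):
            raise ValueError("fixed band centers/widths/amplitudes must align")
        for sd in (
            self.scatter_mult_sd,
            self.scatter_add_sd,
            self.noise_sd,
            self.sample_effect_sd,
        ):
            if sd < 0:
                raise ValueError("noise standard deviations must be >= 0")
        object.__setattr__(self, "grid", grid)

    def baseline(self) -> np.ndarray:
        """Analyte-independent part of the spectrum (pedestal + fixed bands)."""
        base = np.full(self.grid.size, self.baseline_level)
        for c, w, amp in zip(
            self.fixed_band_centers,
            self.fixed_band_widths,
            self.fixed_band_amplitudes,
        ):
            base += amp * np.exp(-0.5 * ((self.grid - c) / w) ** 2)
        return base

    def analyte_shape(self) -> np.ndarray:
        """Spectral shape multiplying the effective analyte level (AU per
        mg/100 g)."""
        shape = np.zeros(self.grid.size)
        for c, w, g in zip(self.peak_centers, self.peak_widths, self.peak_gain):
            shape += g * np.exp(-0.5 * ((self.grid - c) / w) ** 2)
        return shape


@dataclass(frozen=True)
class ArrayGeometry:
    """Placement of the 5 x 3 dye-spot grid on the scanned raster.

    Spot centres sit at the cell centres of a uniform ``rows x cols``
    partition of the image.  The defaults (600 x 360 px, radius 30 px)
    leave the 15-px extraction radius comfortably inside every spot.
    """

    width: int = 600
    height: int = 360
    rows: int = 5
    cols: int = 3
    spot_radius: int = 30
    background: tuple[int, int, int] = (230, 230, 230)

    def __post_init__(self) -> None:
        if self.rows * self.cols != N_SPOTS:
            raise GeometryError(
                f"grid must hold {N_SPOTS} spots, got {self.rows} x {self.cols}"
            )
        pitch_r = self.height / self.rows
        pitch_c = self.width / self.cols
        if 2 * self.spot_radius >= min(pitch_r, pitch_c):
            raise GeometryError(
                f"spot radius {self.spot_radius} px overlaps neighbours for "
                f"cell pitch {min(pitch_r, pitch_c):.0f} px"
            )

    def centers(self) -> np.ndarray:
        """15 x 2 array of (row, col) pixel coordinates, row-major order."""
        rr = (np.arange(self.rows) + 0.5) * self.height / self.rows
        cc = (np.arange(self.cols) + 0.5) * self.width / self.cols
        grid = [(r, c) for r in rr for c in cc]
        return np.array(grid)


def default_sensitivity(seed: int = 734) -> SensitivityMatrix:
    """The default dye-array response used throughout the package.

    Coefficients are drawn once from U(-2.2, 2.2) counts per mg/100 g with
    a fixed seed, giving every spot a non-trivial signed response while
    keeping shifted colours inside the 8-bit range for fatty acid values
    up to ~25 mg/100 g.
    """
    rng = np.random.default_rng(seed)
    coef = rng.uniform(-2.2, 2.2, size=(N_SPOTS, 3))
    # keep responses away from zero so every spot is informative
    coef = np.where(np.abs(coef) < 0.3, np.sign(coef) * 0.3 + coef, coef)
    return SensitivityMatrix(coefficients=coef)


def default_signature() -> SpectralSignature:
    return SpectralSignature()


# fixed, midrange baseline palette for the 15 dye spots (before exposure)
_PALETTE_RNG = np.random.default_rng(1513)
BASELINE_PALETTE = _PALETTE_RNG.integers(90, 166, size=(N_SPOTS, 3)).astype(float)


def sample_seeds(config: CohortConfig) -> list[dict[str, int]]:
    """Per-sample sub-seeds derived from the master seed.

    Each sample owns three independent streams — fatty-acid noise, image
    rendering, spectrum synthesis — so regenerating any one artefact
    reproduces it bit-for-bit without consuming another's randomness.
    """
    base = np.random.SeedSequence(config.seed)
    children = base.spawn(config.n_samples)
    out = []
    for child in children:
        fa_ss, img_ss, spec_ss = child.spawn(3)
        out.append(
            {
                "fa": int(fa_ss.generate_state(1)[0] % (2**31)),
                "image": int(img_ss.generate_state(1)[0] % (2**31)),
                "spectrum": int(spec_ss.generate_state(1)[0] % (2**31)),
            }
        )
    return out


def generate_cohort(config: CohortConfig) -> list[StorageSample]:
    """Generate the sample roster with its fatty-acid reference values.

    fatty_acid = intercept + slope * month + N(0, sample_noise_sd),
    redrawn (truncated) if non-positive.  Bit-reproducible for a fixed
    ``config.seed``.
    """
    seeds = sample_seeds(config)
    samples: list[StorageSample] = []
    i = 0
    for month in range(1, config.n_months + 1):
        for j in range(config.samples_per_month):
            rng = np.random.default_rng(seeds[i]["fa"])
            mean = config.trend_intercept + config.trend_slope * month
            fa = mean + rng.normal(0.0, config.sample_noise_sd)
            while fa <= 0:  # truncate to the physical domain
                fa = mean + rng.normal(0.0, config.sample_noise_sd)
            bag = j * N_BAGS // config.samples_per_month + 1
            samples.append(
                StorageSample(
                    sample_id=f"m{month:02d}_s{j + 1:02d}",
                    month=month,
                    bag=bag,
                    fatty_acid=float(fa),
                )
            )
            i += 1
    return samples


def _paint_disk(
    img: np.ndarray, center: tuple[float, float], radius: float, color: np.ndarray
) -> None:
    """Fill an inclusive disk with a colour, touching only its bounding box."""
    r, c = center
    r0, r1 = max(int(r - radius), 0), min(int(r + radius) + 2, img.shape[0])
    c0, c1 = max(int(c - radius), 0), min(int(c + radius) + 2, img.shape[1])
    rr, cc = np.ogrid[r0:r1, c0:c1]
    mask = (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
    img[r0:r1, c0:c1][mask] = color


def render_sensor_pair(
    sample: StorageSample,
    sens: SensitivityMatrix,
    geometry: ArrayGeometry | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the before/after image pair for one sample.

    The *before* image shows the 15 dye spots at their baseline colours on
    a uniform background.  In the *after* image each spot's colour is
    shifted by ``coefficients[s, c] * fa_eff`` plus one Gaussian noise
    draw per spot and channel (constant within the spot), clipped to
    [0, 255]; ``fa_eff`` adds the per-sample modality nuisance.  Both
    images are 8-bit RGB (uint8).
    """
    geom = geometry or ArrayGeometry()
    rng = np.random.default_rng(seed)
    fa_eff = sample.fatty_acid + rng.normal(0.0, sens.sample_effect_sd)
    shifts = sens.coefficients * fa_eff + rng.normal(
        0.0, sens.spot_noise_sd, size=(N_SPOTS, 3)
    )

    before = np.empty((geom.height, geom.width, 3), dtype=np.uint8)
    before[..., :] = np.array(geom.background, dtype=np.uint8)
    after = before.copy()
    for s, (r, c) in enumerate(geom.centers()):
        base = np.clip(np.round(BASELINE_PALETTE[s]), 0, 255).astype(np.uint8)
        shifted = np.clip(
            np.round(BASELINE_PALETTE[s] + shifts[s]), 0, 255
        ).astype(np.uint8)
        _paint_disk(before, (r, c), geom.spot_radius, base)
        _paint_disk(after, (r, c), geom.spot_radius, shifted)
    return before, after


def synth_spectrum(
    fatty_acid: float,
    signature: SpectralSignature | None = None,
    seed: int = 0,
) -> Spectrum:
    """Synthesize one raw NIR spectrum for a given fatty acid value."""
    if fatty_acid <= 0:
        raise ValueError("fatty_acid must be > 0")
    sig = signature or SpectralSignature()
    rng = np.random.default_rng(seed)
    fa_eff = fatty_acid + rng.normal(0.0, sig.sample_effect_sd)
    m = 1.0 + rng.normal(0.0, sig.scatter_mult_sd)
    a = rng.normal(0.0, sig.scatter_add_sd)
    clean = sig.baseline() + sig.analyte_shape() * fa_eff
    noise = rng.normal(0.0, sig.noise_sd, size=sig.grid.size)
    return Spectrum(sig.grid, m * clean + a + noise)


# ---------------------------------------------------------------------------
# on-disk cohort layout: manifest.csv + images/ + spectra/


def write_cohort(
    out_dir: str | Path,
    config: CohortConfig,
    sens: SensitivityMatrix | None = None,
    signature: SpectralSignature | None = None,
    geometry: ArrayGeometry | None = None,
) -> pd.DataFrame:
    """Materialize a full synthetic cohort on disk.

    Layout: ``manifest.csv`` (sample_id, month, bag, fatty_acid, file
    paths), ``images/<id>_{before,after}.png``, ``spectra/<id>.csv``
    (wavelength_nm, intensity).  The manifest is the single source of
    truth linking files.  Returns the manifest frame.
    """
    sens = sens or default_sensitivity()
    signature = signature or default_signature()
    geometry = geometry or ArrayGeometry()
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "spectra").mkdir(parents=True, exist_ok=True)

    samples = generate_cohort(config)
    seeds = sample_seeds(config)
    rows = []
    for sample, sd in zip(samples, seeds):
        before, after = render_sensor_pair(sample, sens, geometry, seed=sd["image"])
        b_path = out / "images" / f"{sample.sample_id}_before.png"
        a_path = out / "images" / f"{sample.sample_id}_after.png"
        Image.fromarray(before).save(b_path)
        Image.fromarray(after).save(a_path)
        spec = synth_spectrum(sample.fatty_acid, signature, seed=sd["spectrum"])
        s_path = out / "spectra" / f"{sample.sample_id}.csv"
        pd.DataFrame(
            {"wavelength_nm": spec.wavelengths, "intensity": spec.intensities}
        ).to_csv(s_path, index=False)
        rows.append(
            {
                "sample_id": sample.sample_id,
                "month": sample.month,
                "bag": sample.bag,
                "fatty_acid": sample.fatty_acid,
                "before_image": str(b_path.relative_to(out)),
                "after_image": str(a_path.relative_to(out)),
                "spectrum": str(s_path.relative_to(out)),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV written by :func:`write_cohort`."""
    manifest = pd.read_csv(path)
    required = {"sample_id", "month", "bag", "fatty_acid"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return manifest
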