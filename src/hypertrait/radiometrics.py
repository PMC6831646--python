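"""Radiometric calibration, gravimetric water content, and VNIR/SWIR fusion.

A line-scanning hyperspectral camera records digital numbers (DN).  Converting
DN to reflectance requires a dark-current frame and a white-reference frame
recorded with the same settings:

    R = (I_raw - I_dark) / (I_white - I_dark)

Two cameras cover the optical range: VNIR (~400-1000 nm) and SWIR
(~1000-2500 nm).  Their spectra are fused per plant after mean-spectrum
extraction, dropping the overlapping bands near the 1000 nm junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import FusionError, IncompatibleCubesError, InvalidMeasurementError

logger = logging.getLogger(__name__)

#: Wavelength interval (nm, closed) common to both cameras, removed on fusion.
DEFAULT_OVERLAP_NM = (996.0, 1006.0)


@dataclass
class HyperCube:
    """A rows x cols x bands array with its band-center wavelength grid.

    Parameters
    ----------
    data:
        3-D float array, spatial dimensions first, spectral last.  Units are
        DN for ``raw``/``dark``/``white`` cubes and reflectance for
        ``calibrated`` cubes.
    grid:
        Band-center wavelengths in nm, strictly increasing, one per band.
    kind:
        One of ``raw``, ``dark``, ``white``, ``calibrated``.
    camera:
        Free-form camera label (e.g. ``vnir``, ``swir``).
    """

    data: np.ndarray
    grid: np.ndarray
    kind: str = "raw"
    camera: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        if self.grid.ndim != 1 or self.grid.size != self.data.shape[2]:
            raise ValueError("wavelength grid length must equal the band dimension")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band whose center is nearest ``wavelength_nm``.

        Ties between two equidistant centers are broken toward the lower
        wavelength.
        """
        d = np.abs(self.grid - wavelength_nm)
        return int(np.argmin(d))  # argmin returns the first (lower-nm) minimum


@dataclass
class Spectrum:
    """A 1-D reflectance (or transformed) spectrum on a wavelength grid."""

    values: np.ndarray
    grid: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.values.shape != self.grid.shape or self.values.ndim != 1:
            raise ValueError("spectrum values and grid must be 1-D and equal length")
        if self.grid.size > 1 and np.any(np.diff(self.grid) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")


def calibrate(raw: HyperCube, dark: HyperCube, white: HyperCube) -> HyperCube:
    """Convert a raw DN cube to reflectance using dark/white reference frames.

    Elements where the white and dark frames coincide have an undefined
    reflectance; they propagate as NaN (counted and logged) rather than being
    clipped, so that downstream averages stay unbiased.

    Returns
    -------
    HyperCube
        ``kind="calibrated"`` cube of the same shape and grid.
    """
    for name, ref in (("dark", dark), ("white", white)):
        if ref.data.shape != raw.data.shape:
            raise IncompatibleCubesError(
                f"{name} cube shape {ref.data.shape} != raw shape {raw.data.shape}"
            )
        if not np.array_equal(ref.grid, raw.grid):
            raise IncompatibleCubesError(f"{name} cube wavelength grid differs from raw")
    denom = white.data - dark.data
    invalid = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (raw.data - dark.data) / denom
    n_invalid = int(invalid.sum())
    if n_invalid:
        out = np.where(invalid, np.nan, out)
        logger.warning("calibrate: %d element(s) with white == dark set to NaN", n_invalid)
    return HyperCube(out, raw.grid.copy(), kind="calibrated", camera=raw.camera)


def water_content(fresh_weight: float, dry_weight: float) -> float:
    """Gravimetric water content in percent: 100 * (W_F - W_D) / W_F.

    ``W_F`` is the fresh weight and ``W_D`` the oven-dry weight of the same
    sample, in any common mass unit (the ratio is scale-invariant).
    """
    if fresh_weight <= 0:
        raise InvalidMeasurementError("fresh weight must be positive")
    if dry_weight < 0 or dry_weight > fresh_weight:
        raise InvalidMeasurementError("dry weight must lie in [0, fresh weight]")
    return 100.0 * (fresh_weight - dry_weight) / fresh_weight


@dataclass
class FusionResult:
    """Fused spectrum plus bookkeeping about the overlap removal."""

    spectrum: Spectrum
    n_removed_vnir: int
    n_removed_swir: int
    splice_shift: float = 0.0

    @property
    def n_removed(self) -> int:
        return self.n_removed_vnir + self.n_removed_swir


def combine_spectra(
    vnir: Spectrum,
    swir: Spectrum,
    overlap_nm: tuple[float, float] = DEFAULT_OVERLAP_NM,
    splice_correct: bool = False,
) -> FusionResult:
    """Fuse a VNIR and a SWIR mean spectrum into one spectrum.

    Every band whose center lies in the closed interval ``overlap_nm`` is
    dropped from both inputs before concatenation.  The two cameras have
    different optical systems, so the fused spectrum generally shows an
    additive jump at the junction; by default it is left in place (models are
    trained and validated on equally-jumped spectra).  With
    ``splice_correct=True`` the SWIR values are shifted additively so that the
    first retained SWIR band matches a linear extrapolation of the last three
    retained VNIR bands.

    Raises
    ------
    FusionError
        If the concatenated grid would not be strictly increasing.
    """
    lo, hi = overlap_nm
    keep_v = (vnir.grid < lo) | (vnir.grid > hi)
    keep_s = (swir.grid < lo) | (swir.grid > hi)
    v_vals, v_grid = vnir.values[keep_v], vnir.grid[keep_v]
    s_vals, s_grid = swir.values[keep_s], swir.grid[keep_s]
    n_rm_v = int((~keep_v).sum())
    n_rm_s = int((~keep_s).sum())
    if v_grid.size == 0 or s_grid.size == 0:
        raise FusionError("overlap removal left one camera with no bands")

    shift = 0.0
    if splice_correct:
        if v_grid.size < 3:
            raise FusionError("splice correction needs >= 3 retained VNIR bands")
        coefs = np.polyfit(v_grid[-3:], v_vals[-3:], 1)
        expected = float(np.polyval(coefs, s_grid[0]))
        shift = expected - float(s_vals[0])
        s_vals = s_vals + shift

    grid = np.concatenate([v_grid, s_grid])
    if np.any(np.diff(grid) <= 0):
        raise FusionError("fused wavelength grid is not strictly increasing")
    values = np.concatenate([v_vals, s_vals])
    logger.info(
        "combine_spectra: removed %d VNIR + %d SWIR band(s) in [%g, %g] nm",
        n_rm_v, n_rm_s, lo, hi,
    )
    return FusionResult(
        Spectrum(values, grid, source="fused"),
        n_removed_vnir=n_rm_v,
        n_removed_swir=n_rm_s,
        splice_shift=shift,
    )
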