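"""Vegetation/background segmentation and mean-spectrum extraction.

VNIR cubes are segmented with an enhanced vegetation index (EVI) threshold:
vegetation pixels have a deep red-band trough and a high NIR plateau, so
their EVI rises well above soil and pot background.  SWIR cubes lack the red
edge, so they are segmented instead in an intensity-invariant "hyper-hue"
space with a one-class support vector machine trained on known plant pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.svm import OneClassSVM

from .errors import InsufficientTrainingError, NoVegetationError
from .radiometrics import HyperCube, Spectrum

#: EVI threshold above which a pixel is classed as vegetation.
DEFAULT_EVI_THRESHOLD = 0.25


@dataclass
class VegetationMask:
    """Boolean vegetation mask with provenance."""

    mask: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def compute_evi(
    cube: HyperCube,
    red_nm: float = 670.0,
    nir_nm: float = 800.0,
    blue_nm: float = 470.0,
) -> np.ndarray:
    """Per-pixel enhanced vegetation index from three named bands.

    EVI = 2.5 (R_NIR - R_red) / (R_NIR + 6 R_red - 7.5 R_blue + 1), using for
    each role the band whose center is nearest the requested wavelength (ties
    toward the lower wavelength).  Pixels with a zero denominator are NaN.
    """
    for nm in (red_nm, nir_nm, blue_nm):
        if nm < cube.grid[0] or nm > cube.grid[-1]:
            raise ValueError(f"requested wavelength {nm} nm outside cube grid")
    r = cube.data[:, :, cube.band_index(red_nm)]
    nir = cube.data[:, :, cube.band_index(nir_nm)]
    b = cube.data[:, :, cube.band_index(blue_nm)]
    denom = nir + 6.0 * r - 7.5 * b + 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        evi = 2.5 * (nir - r) / denom
    return np.where(denom == 0, np.nan, evi)


def evi_mask(evi_image: np.ndarray, threshold: float = DEFAULT_EVI_THRESHOLD) -> VegetationMask:
    """Vegetation = pixels with EVI strictly above the threshold.

    Non-finite EVI values (zero denominator, saturated calibration) are
    treated as background.
    """
    evi = np.asarray(evi_image, dtype=float)
    with np.errstate(invalid="ignore"):
        mask = np.where(np.isfinite(evi), evi > threshold, False)
    return VegetationMask(mask, method="evi", params={"threshold": threshold})


def hyper_hue_transform(cube: HyperCube) -> tuple[HyperCube, np.ndarray]:
    """Project each pixel spectrum to its unit chromatic direction.

    The spectrum is projected onto the hyperplane orthogonal to the all-ones
    vector (removing overall intensity) and normalized to unit length — a
    many-band generalization of hue.  Spectrally flat pixels have no defined
    direction; they are returned as NaN and flagged in the achromatic mask.

    Returns
    -------
    (HyperCube, ndarray)
        The hyper-hue cube and a boolean image of achromatic pixels.
    """
    if cube.n_bands < 2:
        raise ValueError("hyper-hue needs at least 2 bands")
    centered = cube.data - cube.data.mean(axis=2, keepdims=True)
    norms = np.linalg.norm(centered, axis=2)
    achromatic = norms < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        hue = centered / norms[:, :, np.newaxis]
    hue = np.where(achromatic[:, :, np.newaxis], np.nan, hue)
    return HyperCube(hue, cube.grid.copy(), kind="calibrated", camera=cube.camera), achromatic


DEFAULT_NU_GRID = (0.01, 0.05, 0.1, 0.2)
DEFAULT_GAMMA_GRID = ("scale", 1.0, 10.0, 100.0)


def oneclass_segment(
    hyperhue: HyperCube,
    training_pixels: np.ndarray,
    nu: float | None = None,
    gamma: float | str | None = None,
    quantile: float = 1.0,
    seed: int = 0,
) -> VegetationMask:
    """Segment a hyper-hue cube with a one-class RBF support vector machine.

    ``training_pixels`` is an (n, bands) matrix of known plant-pixel hues
    (e.g. sampled from the paired VNIR EVI mask).  If ``nu``/``gamma`` are not
    given they are chosen by a small grid search maximizing the inlier rate on
    a held-out half of the training pixels.  A pixel is an inlier if its
    decision score reaches the ``quantile``-th percentile of the training
    scores — the SVM's own zero threshold rejects the tails of the vegetation
    distribution itself, so the boundary is recalibrated on the training
    cloud.  Achromatic (NaN) pixels are classed as background.
    """
    train = np.asarray(training_pixels, dtype=float)
    if train.ndim != 2 or train.shape[0] < 20:
        raise InsufficientTrainingError("need at least 20 training pixels")
    if train.shape[1] != hyperhue.n_bands:
        raise ValueError("training pixels and cube disagree in band count")

    def _threshold(model, pixels):
        return float(np.percentile(model.decision_function(pixels), quantile))

    if nu is None or gamma is None:
        fit_px, held_px = train_test_split(train, test_size=0.5, random_state=seed)
        best, best_score = (DEFAULT_NU_GRID[0], DEFAULT_GAMMA_GRID[0]), -np.inf
        for cand_nu in DEFAULT_NU_GRID:
            for cand_gamma in DEFAULT_GAMMA_GRID:
                m = OneClassSVM(kernel="rbf", nu=cand_nu, gamma=cand_gamma).fit(fit_px)
                score = float(np.mean(m.decision_function(held_px) >= _threshold(m, fit_px)))
                if score > best_score:
                    best, best_score = (cand_nu, cand_gamma), score
        nu = nu if nu is not None else best[0]
        gamma = gamma if gamma is not None else best[1]

    model = OneClassSVM(kernel="rbf", nu=nu, gamma=gamma).fit(train)
    thr = _threshold(model, train)
    h, w, b = hyperhue.shape
    flat = hyperhue.data.reshape(-1, b)
    valid = np.isfinite(flat).all(axis=1)
    pred = np.zeros(h * w, dtype=bool)
    if valid.any():
        pred[valid] = model.decision_function(flat[valid]) >= thr
    return VegetationMask(
        pred.reshape(h, w),
        method="hyperhue_oneclass",
        params={"nu": nu, "gamma": gamma, "quantile": quantile, "threshold": thr},
    )


def mean_spectrum(cube: HyperCube, mask: VegetationMask | np.ndarray) -> Spectrum:
    """Band-wise arithmetic mean over the masked pixels.

    Missing (NaN) calibration values are excluded band-wise so a saturated
    element does not bias the remaining bands.
    """
    m = mask.mask if isinstance(mask, VegetationMask) else np.asarray(mask, dtype=bool)
    if m.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube spatial shape")
    if not m.any():
        raise NoVegetationError("mask selects no pixels")
    pixels = cube.data[m]
    values = np.nanmean(pixels, axis=0)
    return Spectrum(values, cube.grid.copy(), source=cube.camera or "cube")
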