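"""Pixel-level trait prediction maps from linear models.

A linear model collapses to a coefficient vector, so it can be applied to
every vegetation pixel of a calibrated cube: the cube is unfolded to a
pixel x band matrix, each pixel spectrum is passed through the model's
frozen preprocessing and wavelength selection, and scored as
``beta . x + intercept``.  Folding the predictions back to the image grid
gives a distribution map of the trait across the plant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import GridMismatchError, NoVegetationError, UnsupportedModelError
from .radiometrics import HyperCube
from .regression import RegressionModel
from .segmentation import VegetationMask

logger = logging.getLogger(__name__)

#: Default display ranges (percent) by trait.
DEFAULT_RANGES = {"water": (60.0, 90.0), "nitrogen": (1.0, 4.5)}


@dataclass
class DistributionMap:
    """Per-pixel trait predictions under a vegetation mask."""

    values: np.ndarray  # 2-D, NaN off-mask
    mask: np.ndarray    # boolean, same shape
    trait: str = ""
    model_id: str = ""
    display_range: tuple[float, float] = (60.0, 90.0)
    flags: tuple[str, ...] = ()

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


def unfold(cube: HyperCube, mask: VegetationMask | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Masked pixels as an (n_masked, n_bands) matrix, row-major pixel order.

    Returns the matrix and the flat indices of the masked pixels, which
    ``fold`` uses to invert back to the 2-D image.
    """
    m = mask.mask if isinstance(mask, VegetationMask) else np.asarray(mask, dtype=bool)
    if m.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube spatial shape")
    if not m.any():
        raise NoVegetationError("mask selects no pixels")
    flat_idx = np.flatnonzero(m.ravel())
    matrix = cube.data.reshape(-1, cube.n_bands)[flat_idx]
    return matrix, flat_idx


def fold(values: np.ndarray, flat_idx: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Scatter per-pixel values back onto the image grid (NaN elsewhere)."""
    out = np.full(shape[0] * shape[1], np.nan)
    out[flat_idx] = values
    return out.reshape(shape)


def _match_grid(model: RegressionModel, cube: HyperCube, tol_nm: float = 1.0) -> np.ndarray:
    """Column indices of the cube bands nearest each model input band."""
    target = model.training_grid if model.training_grid is not None else model.grid
    idx = np.searchsorted(cube.grid, target)
    idx = np.clip(idx, 1, cube.grid.size - 1)
    lower = idx - 1
    choose_lower = np.abs(cube.grid[lower] - target) <= np.abs(cube.grid[idx] - target)
    idx = np.where(choose_lower, lower, idx)
    err = np.abs(cube.grid[idx] - target)
    if np.any(err > tol_nm):
        worst = float(err.max())
        raise GridMismatchError(
            f"cube grid misses model band(s) by up to {worst:.2f} nm (tol {tol_nm} nm)"
        )
    return idx


def predict_pixels(
    model: RegressionModel,
    cube: HyperCube,
    mask: VegetationMask | np.ndarray,
    trait: str = "",
    tol_nm: float = 1.0,
) -> DistributionMap:
    """Score every masked pixel of a calibrated cube with a linear model.

    Pixel spectra are matched to the model's training grid by nearest band
    (within ``tol_nm``), passed through the model's frozen preprocessing
    (training-set MSC/EMSC references), restricted to any stored wavelength
    selection, and scored with the collapsed coefficients.  Models without a
    coefficient vector are rejected.  Maps built through a non-linear
    preprocessing treatment are produced but flagged, because pixel-level and
    plant-mean predictions then need not agree.
    """
    if model.beta is None:
        raise UnsupportedModelError("pixel mapping requires a linear model with beta")
    cols = _match_grid(model, cube, tol_nm=tol_nm)
    matrix, flat_idx = unfold(cube, mask)
    matrix = matrix[:, cols]
    flags: list[str] = []
    if model.preprocess is not None:
        matrix = model.preprocess.transform(matrix)
        if not model.preprocess.spec.is_linear:
            flags.append("nonlinear-preprocessing")
            logger.info(
                "predict_pixels: treatment %s is non-linear; pixel predictions "
                "need not average to the plant-mean prediction",
                model.preprocess.spec.method,
            )
    if model.selection is not None:
        matrix = matrix[:, model.selection]
    preds = model.predict(matrix)
    m = mask.mask if isinstance(mask, VegetationMask) else np.asarray(mask, dtype=bool)
    values = fold(preds, flat_idx, m.shape)
    rng = DEFAULT_RANGES.get(trait, DEFAULT_RANGES["water"])
    return DistributionMap(
        values=values, mask=m, trait=trait,
        model_id=model.method, display_range=rng, flags=tuple(flags),
    )


def render_map(
    dmap: DistributionMap,
    path,
    palette: str = "RdYlGn_r",
    display_range: tuple[float, float] | None = None,
    dpi: int = 150,
):
    """Render a distribution map to PNG with a colorbar.

    Masked-out background is transparent; values outside the display range
    are clipped to its ends (not wrapped).  Returns the output path.
    """
    lo, hi = display_range if display_range is not None else dmap.display_range
    if not lo < hi:
        raise ValueError("display range must satisfy lo < hi")
    shown = np.ma.masked_array(np.clip(dmap.values, lo, hi), mask=~dmap.mask)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(shown, cmap=palette, vmin=lo, vmax=hi, interpolation="nearest")
    ax.set_axis_off()
    label = f"{dmap.trait} (%)" if dmap.trait else "prediction"
    fig.colorbar(im, ax=ax, shrink=0.8, label=label)
    fig.savefig(path, dpi=dpi, transparent=True, bbox_inches="tight")
    plt.close(fig)
    return path
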