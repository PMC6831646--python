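"""Synthetic glasshouse scenes for a dual-camera wheat imaging experiment.

The generator emulates the data products of a top-view hyperspectral imaging
chamber with two line-scanning cameras — VNIR (400-1000 nm, 448 bands) and
SWIR (1000-2500 nm, 288 bands) — pointed at potted wheat plants grown under a
factorial soil-nutrient x watering design.  For each pot it produces the raw
DN cube, dark and white reference frames, and ground-truth masks and per-pixel
trait maps, so every downstream stage (calibration, segmentation, regression,
mapping) can be validated against known truth.

The spectral model is phenomenological, not radiative-transfer: a smooth
vegetation baseline (low visible reflectance, sharp red edge, NIR plateau)
with Gaussian absorption troughs whose depths increase linearly in the traits
— chlorophyll features near 460/530/670 nm for nitrogen, water features at
970/1150/1425/1940 nm for water content.  Linearity of trough depth in the
trait is deliberate: it makes the pot-mean spectrum correspond exactly to the
pot-mean trait, which is what lets regression-recovery tests have a known
right answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

from .errors import EmptyPlantError
from .radiometrics import HyperCube

#: Wheat varieties included in the factorial design.
VARIETIES = ("Gladius", "Kukri", "Mace", "RAC875")

#: Soil nutrient treatments: soil id -> (N mg/kg, P mg/kg, K mg/kg,
#: secondary nutrients g/150kg).  Soil 1 is the no-nutrient control; soils
#: 2-9 are half of the full 2^4 factorial of {N: 25/100, P: 15/40,
#: K: 20/60, micro: 5/10}.
SOIL_NUTRIENTS = {
    1: (0, 0, 0, 0),
    2: (25, 15, 20, 5),
    3: (100, 15, 20, 10),
    4: (25, 40, 20, 10),
    5: (100, 40, 20, 5),
    6: (25, 15, 60, 10),
    7: (100, 15, 60, 5),
    8: (25, 40, 60, 5),
    9: (100, 40, 60, 10),
}

WATER_TREATMENTS = ("watered", "drought")


@dataclass(frozen=True)
class CameraSpec:
    """Spectral and spatial layout of one line-scanning camera."""

    name: str
    range_nm: tuple[float, float]
    n_bands: int
    spatial_px: int = 64
    band_centers: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lo, hi = self.range_nm
        if self.band_centers is None:
            centers = np.linspace(lo, hi, self.n_bands)
            object.__setattr__(self, "band_centers", centers)
        centers = np.asarray(self.band_centers, dtype=float)
        if centers.size != self.n_bands:
            raise ValueError("band_centers length must equal n_bands")
        if np.any(np.diff(centers) <= 0):
            raise ValueError("band_centers must be strictly increasing")
        if centers[0] < lo or centers[-1] > hi:
            raise ValueError("band_centers must lie within range_nm")
        object.__setattr__(self, "band_centers", centers)


def vnir_camera(spatial_px: int = 64) -> CameraSpec:
    """Default VNIR camera: 400-1000 nm, 448 uniformly spaced bands."""
    return CameraSpec("vnir", (400.0, 1000.0), 448, spatial_px=spatial_px)


def swir_camera(spatial_px: int = 64) -> CameraSpec:
    """Default SWIR camera: 1000-2500 nm, 288 uniformly spaced bands."""
    return CameraSpec("swir", (1000.0, 2500.0), 288, spatial_px=spatial_px)


def generate_design(n_replicates: int, seed: int) -> pd.DataFrame:
    """Full factorial design: 4 varieties x 9 soils x 2 water x R replicates.

    Rows are returned in a seed-randomized pot order (standing in for the
    randomized bench layout of a real trial) with ``pot_id`` assigned 1..n in
    that order.

    Returns
    -------
    pandas.DataFrame
        Columns ``pot_id, variety, soil, n_mg_kg, p_mg_kg, k_mg_kg,
        micro_g_150kg, water_treatment, replicate``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = []
    for rep in range(1, n_replicates + 1):
        for variety in VARIETIES:
            for soil, (n, p, k, micro) in SOIL_NUTRIENTS.items():
                for water in WATER_TREATMENTS:
                    rows.append(
                        dict(
                            variety=variety,
                            soil=soil,
                            n_mg_kg=n,
                            p_mg_kg=p,
                            k_mg_kg=k,
                            micro_g_150kg=micro,
                            water_treatment=water,
                            replicate=rep,
                        )
                    )
    design = pd.DataFrame(rows)
    rng = np.random.default_rng(seed)
    design = design.iloc[rng.permutation(len(design))].reset_index(drop=True)
    design.insert(0, "pot_id", np.arange(1, len(design) + 1))
    return design


@dataclass
class ChemistryParams:
    """Trait distributions for the two watering treatments and soil N levels.

    Water content (percent of fresh mass) is drawn around a treatment mean:
    well-watered plants around 80%, droughted plants around 68%, so that at
    the default sd the two groups occupy roughly 72-88% and 64-72%.  Nitrogen
    (percent of dry mass) increases linearly in the soil N dose, from 1.5% at
    zero added N through 2.0% at 25 mg/kg to 3.5% at 100 mg/kg.
    """

    watered_mean: float = 80.0
    drought_mean: float = 68.0
    water_sd: float = 2.0
    nitrogen_low_mean: float = 2.0   # at 25 mg/kg added N
    nitrogen_high_mean: float = 3.5  # at 100 mg/kg added N
    nitrogen_sd: float = 0.15

    def nitrogen_mean(self, n_mg_kg: float) -> float:
        slope = (self.nitrogen_high_mean - self.nitrogen_low_mean) / (100.0 - 25.0)
        return self.nitrogen_low_mean + slope * (n_mg_kg - 25.0)


def simulate_chemistry(
    design: pd.DataFrame,
    params: ChemistryParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ground-truth water and nitrogen content for every pot.

    Returns a DataFrame with ``pot_id, water_pct, nitrogen_pct``; water is
    truncated to [0, 100), nitrogen floored at a small positive value.
    """
    params = params or ChemistryParams()
    if params.water_sd < 0 or params.nitrogen_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    means_w = np.where(
        design["water_treatment"].to_numpy() == "watered",
        params.watered_mean,
        params.drought_mean,
    )
    water = means_w + params.water_sd * rng.standard_normal(len(design))
    water = np.clip(water, 0.0, np.nextafter(100.0, 0.0))
    means_n = np.array([params.nitrogen_mean(n) for n in design["n_mg_kg"]])
    nitrogen = means_n + params.nitrogen_sd * rng.standard_normal(len(design))
    nitrogen = np.maximum(nitrogen, 0.05)
    return pd.DataFrame(
        {
            "pot_id": design["pot_id"].to_numpy(),
            "water_pct": water,
            "nitrogen_pct": nitrogen,
        }
    )


# --- reflectance model -----------------------------------------------------

# Gaussian absorption features: (center nm, sigma nm, depth per trait unit).
# Water troughs deepen with water %, chlorophyll troughs with nitrogen %.
WATER_TROUGHS = ((970.0, 25.0, 0.0012), (1150.0, 35.0, 0.0018),
                 (1425.0, 45.0, 0.0038), (1940.0, 50.0, 0.0042))
CHLOROPHYLL_TROUGHS = ((460.0, 25.0, 0.030), (530.0, 20.0, 0.012),
                       (670.0, 25.0, 0.030))

_VIS_LEVEL = 0.24     # visible reflectance before chlorophyll absorption
_NIR_LEVEL = 0.56     # NIR plateau reflectance
_RED_EDGE_NM = 715.0  # red-edge inflection, between 680 and 750 nm
_RED_EDGE_WIDTH = 11.0
_SWIR_SLOPE = 1e-4    # gentle decline of the plateau into the SWIR, per nm


def vegetation_reflectance(
    water_pct: float | np.ndarray,
    nitrogen_pct: float | np.ndarray,
    grid: np.ndarray,
) -> np.ndarray:
    """Leaf reflectance spectrum for given trait values on a wavelength grid.

    The baseline is a logistic red edge between a low visible level and a NIR
    plateau that declines gently into the SWIR; chlorophyll and water
    absorption are Gaussian troughs whose depth is linear in the trait.
    Accepts scalars or arrays of traits (broadcast to ``(..., n_bands)``).

    Raises
    ------
    ValueError
        If water is outside [0, 100) or nitrogen is not strictly positive.
    """
    w = np.asarray(water_pct, dtype=float)
    n = np.asarray(nitrogen_pct, dtype=float)
    if np.any(w < 0) or np.any(w >= 100):
        raise ValueError("water_pct must lie in [0, 100)")
    if np.any(n <= 0):
        raise ValueError("nitrogen_pct must be strictly positive")
    grid = np.asarray(grid, dtype=float)
    lam = grid[np.newaxis, :]
    w = np.atleast_1d(w)[:, np.newaxis]
    n = np.atleast_1d(n)[:, np.newaxis]

    edge = 1.0 / (1.0 + np.exp(-(lam - _RED_EDGE_NM) / _RED_EDGE_WIDTH))
    base = _VIS_LEVEL + (_NIR_LEVEL - _VIS_LEVEL) * edge
    base = base - _SWIR_SLOPE * np.maximum(lam - 1000.0, 0.0)

    refl = base
    for center, sigma, depth in CHLOROPHYLL_TROUGHS:
        refl = refl - depth * n * np.exp(-0.5 * ((lam - center) / sigma) ** 2)
    for center, sigma, depth in WATER_TROUGHS:
        refl = refl - depth * w * np.exp(-0.5 * ((lam - center) / sigma) ** 2)
    refl = np.clip(refl, 1e-3, 1.0 - 1e-3)
    if np.isscalar(water_pct) and np.isscalar(nitrogen_pct):
        return refl[0]
    return refl.reshape(np.broadcast(np.asarray(water_pct), np.asarray(nitrogen_pct)).shape + (grid.size,))


def soil_reflectance(grid: np.ndarray) -> np.ndarray:
    """Background (soil/pot) spectrum: a flat ramp from 0.15 to 0.25.

    Spectrally featureless and nearly grey, so its enhanced vegetation index
    stays well below the 0.25 segmentation threshold.
    """
    grid = np.asarray(grid, dtype=float)
    t = (grid - grid[0]) / (grid[-1] - grid[0]) if grid.size > 1 else np.zeros_like(grid)
    return 0.15 + 0.10 * t


@dataclass
class SceneParams:
    """Rendering knobs for one pot's scene.

    ``noise_sd`` is Gaussian sensor noise in reflectance units (converted to
    DN through the white-dark span).  ``scatter_sd``/``baseline_sd`` add a
    per-scene multiplicative gain and additive offset to the plant
    reflectance, emulating the illumination/scatter differences between
    acquisitions that scatter-correction preprocessing exists to remove.
    ``water_gradient_pct`` is the total base-to-tip drop in per-pixel water
    content along each leaf.
    """

    n_leaves: int = 7
    leaf_length_frac: float = 0.42  # of image size
    leaf_width_px: float = 3.0
    noise_sd: float = 0.01
    scatter_sd: float = 0.05
    baseline_sd: float = 0.01
    water_gradient_pct: float = 12.0
    swir_offset: float = 0.03   # inter-camera additive reflectance offset
    dark_dn: float = 100.0
    white_dn: float = 4096.0


@dataclass
class Scene:
    """All data products of imaging one pot with both cameras."""

    pot_id: int
    vnir_raw: HyperCube
    vnir_dark: HyperCube
    vnir_white: HyperCube
    swir_raw: HyperCube
    swir_dark: HyperCube
    swir_white: HyperCube
    vnir_truth_mask: np.ndarray
    swir_truth_mask: np.ndarray
    truth_water_map: np.ndarray
    truth_nitrogen_map: np.ndarray


def _rosette_leaves(size: int, params: SceneParams, rng: np.random.Generator):
    """Leaf polygons (in unit coordinates) plus per-leaf axis descriptors."""
    center = np.array([0.5, 0.5])
    leaves = []
    angles = rng.uniform(0, 2 * np.pi, params.n_leaves) + np.linspace(
        0, 2 * np.pi, params.n_leaves, endpoint=False
    )
    for ang in angles:
        length = params.leaf_length_frac * rng.uniform(0.75, 1.0)
        direction = np.array([np.cos(ang), np.sin(ang)])
        normal = np.array([-direction[1], direction[0]])
        half_w = 0.5 * params.leaf_width_px / size
        tip = center + length * direction
        base_l = center + half_w * normal
        base_r = center - half_w * normal
        leaves.append((np.array([base_l, tip, base_r]), center, tip))
    return leaves


def _rasterize(leaves, size: int):
    """Per-leaf pixel coordinates and base->tip positions t in [0, 1]."""
    mask = np.zeros((size, size), dtype=bool)
    t_map = np.full((size, size), np.nan)
    for verts, base, tip in leaves:
        rr, cc = draw_polygon(verts[:, 0] * size, verts[:, 1] * size, shape=(size, size))
        axis = tip - base
        axis_len2 = float(axis @ axis)
        px = np.stack([(rr + 0.5) / size, (cc + 0.5) / size], axis=1)
        t = np.clip((px - base) @ axis / axis_len2, 0.0, 1.0)
        newly = ~mask[rr, cc]
        mask[rr, cc] = True
        # first leaf to claim a pixel keeps its axial position
        t_map[rr[newly], cc[newly]] = t[newly]
    return mask, t_map


def _render_camera(
    spec: CameraSpec,
    mask: np.ndarray,
    water_map: np.ndarray,
    nitrogen_pct: float,
    params: SceneParams,
    rng: np.random.Generator,
    gain: float,
    offset: float,
    extra_offset: float = 0.0,
) -> tuple[HyperCube, HyperCube, HyperCube]:
    size = mask.shape[0]
    grid = spec.band_centers
    refl = np.empty((size, size, spec.n_bands))
    refl[:] = soil_reflectance(grid)[np.newaxis, np.newaxis, :]
    if mask.any():
        plant = vegetation_reflectance(
            water_map[mask], np.full(int(mask.sum()), nitrogen_pct), grid
        )
        refl[mask] = gain * plant + offset + extra_offset
    dark = np.full((size, size, spec.n_bands), params.dark_dn)
    white = np.full((size, size, spec.n_bands), params.white_dn)
    span = params.white_dn - params.dark_dn
    raw = dark + refl * span
    if params.noise_sd > 0:
        raw = raw + params.noise_sd * span * rng.standard_normal(raw.shape)
    return (
        HyperCube(raw, grid.copy(), kind="raw", camera=spec.name),
        HyperCube(dark, grid.copy(), kind="dark", camera=spec.name),
        HyperCube(white, grid.copy(), kind="white", camera=spec.name),
    )


def render_scene(
    design_row: pd.Series | dict,
    chemistry_row: pd.Series | dict,
    vnir_spec: CameraSpec | None = None,
    swir_spec: CameraSpec | None = None,
    seed: int = 0,
    params: SceneParams | None = None,
) -> Scene:
    """Render one pot: rosette plant on soil, imaged by both cameras.

    The per-pixel water content follows a linear base-to-tip gradient around
    the pot mean (wheat leaves hold more water near the base than the tip);
    nitrogen is uniform within a plant.  The forward DN model is
    ``raw = dark + R * (white - dark) + noise``, so calibrating the scene with
    its own reference frames recovers the programmed reflectance up to noise.

    Raises
    ------
    EmptyPlantError
        If the leaf geometry parameters produce zero leaf area.
    """
    params = params or SceneParams()
    vnir_spec = vnir_spec or vnir_camera()
    swir_spec = swir_spec or swir_camera()
    if params.n_leaves < 1 or params.leaf_length_frac <= 0 or params.leaf_width_px <= 0:
        raise EmptyPlantError("leaf geometry parameters give zero leaf area")
    rng = np.random.default_rng(seed)
    water = float(chemistry_row["water_pct"])
    nitrogen = float(chemistry_row["nitrogen_pct"])
    pot_id = int(design_row["pot_id"])

    leaves = _rosette_leaves(max(vnir_spec.spatial_px, swir_spec.spatial_px), params, rng)
    masks, t_maps = {}, {}
    for spec in (vnir_spec, swir_spec):
        masks[spec.name], t_maps[spec.name] = _rasterize(leaves, spec.spatial_px)
    if not masks[vnir_spec.name].any():
        raise EmptyPlantError("rendered plant has no pixels")

    # base-to-tip water gradient, symmetric around the pot mean
    def water_field(t_map, mask):
        wmap = np.full(t_map.shape, np.nan)
        wmap[mask] = water + params.water_gradient_pct * (0.5 - t_map[mask])
        return np.clip(wmap, 0.0, np.nextafter(100.0, 0.0))

    water_maps = {name: water_field(t_maps[name], masks[name]) for name in masks}

    # per-scene scatter: one gain/offset shared by both cameras
    gain = float(np.exp(params.scatter_sd * rng.standard_normal()))
    offset = float(params.baseline_sd * rng.standard_normal())

    vnir_raw, vnir_dark, vnir_white = _render_camera(
        vnir_spec, masks["vnir"], water_maps["vnir"], nitrogen, params, rng, gain, offset
    )
    swir_raw, swir_dark, swir_white = _render_camera(
        swir_spec, masks["swir"], water_maps["swir"], nitrogen, params, rng,
        gain, offset, extra_offset=params.swir_offset,
    )
    nitrogen_map = np.full(masks["vnir"].shape, np.nan)
    nitrogen_map[masks["vnir"]] = nitrogen
    return Scene(
        pot_id=pot_id,
        vnir_raw=vnir_raw, vnir_dark=vnir_dark, vnir_white=vnir_white,
        swir_raw=swir_raw, swir_dark=swir_dark, swir_white=swir_white,
        vnir_truth_mask=masks["vnir"],
        swir_truth_mask=masks["swir"],
        truth_water_map=water_maps["vnir"],
        truth_nitrogen_map=nitrogen_map,
    )
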