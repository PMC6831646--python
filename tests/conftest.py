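import numpy as np
import pytest

from hypertrait import (
    CameraSpec,
    calibrate,
    generate_design,
    render_scene,
    simulate_chemistry,
    swir_camera,
    vnir_camera,
)
from hypertrait.scene import SceneParams


@pytest.fixture(scope="session")
def small_cameras():
    """Reduced-band cameras for fast scene tests."""
    return (
        CameraSpec("vnir", (400.0, 1000.0), 64, spatial_px=32),
        CameraSpec("swir", (1000.0, 2500.0), 48, spatial_px=32),
    )


@pytest.fixture(scope="session")
def design_one_rep():
    return generate_design(1, seed=101)


@pytest.fixture(scope="session")
def chemistry_one_rep(design_one_rep):
    return simulate_chemistry(design_one_rep, seed=102).set_index("pot_id")


@pytest.fixture(scope="session")
def noiseless_scene(design_one_rep, chemistry_one_rep, small_cameras):
    """A scene with every stochastic nuisance switched off."""
    vspec, sspec = small_cameras
    row = design_one_rep.iloc[0]
    params = SceneParams(noise_sd=0.0, scatter_sd=0.0, baseline_sd=0.0)
    return render_scene(
        row, chemistry_one_rep.loc[row["pot_id"]], vspec, sspec, seed=103, params=params
    )


@pytest.fixture(scope="session")
def noisy_scene(design_one_rep, chemistry_one_rep, small_cameras):
    """A scene at the default noise/scatter settings."""
    vspec, sspec = small_cameras
    row = design_one_rep.iloc[1]
    return render_scene(
        row, chemistry_one_rep.loc[row["pot_id"]], vspec, sspec, seed=104
    )


@pytest.fixture(scope="session")
def calibrated_vnir(noisy_scene):
    return calibrate(noisy_scene.vnir_raw, noisy_scene.vnir_dark, noisy_scene.vnir_white)


@pytest.fixture(scope="session")
def full_cameras():
    return vnir_camera(48), swir_camera(48)
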