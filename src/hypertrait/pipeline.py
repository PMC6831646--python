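"""End-to-end experiment runner: simulate -> calibrate -> segment -> extract
-> fuse -> preprocess -> fit -> evaluate -> select -> refit -> map.

`run_experiment` drives the whole analysis over a (simulated) pot trial and
writes tidy metric tables, serialized models, wavelength selections, and
distribution maps under one output directory.  Every stage is seeded from the
single experiment seed, so a rerun with the same configuration reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import scene as scene_mod
from .chemometrics import PreprocessSpec, Preprocessor, apply_preprocess
from .dataset import SpectralDataset
from .mapping import DistributionMap, predict_pixels, render_map
from .radiometrics import calibrate, combine_spectra
from .regression import (
    FitMetrics,
    RegressionModel,
    evaluate,
    fit_latent,
    fit_ml,
    fit_ridge,
    refit_on_selection,
    select_by_coefficients,
    select_by_features,
    split_by_replicate,
)
from .scene import (
    CameraSpec,
    ChemistryParams,
    SceneParams,
    generate_design,
    simulate_chemistry,
    swir_camera,
    vnir_camera,
)
from .segmentation import compute_evi, evi_mask, mean_spectrum

logger = logging.getLogger(__name__)

ALL_METHODS = ("plsr", "pcr", "mlr_ridge", "svr", "rf")
ALL_TREATMENTS = ("RAW", "SMO", "SGD1", "SGD2", "ASGD1", "ASGD2", "MSC", "EMSC", "SNV", "NBR")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one simulated analysis run."""

    out_dir: str | Path = "hypertrait_run"
    seed: int = 42
    n_replicates: int = 3
    varieties: tuple[str, ...] | None = None  # None = all four
    scene_size: int = 48
    scene_params: SceneParams = field(default_factory=SceneParams)
    chemistry_params: ChemistryParams = field(default_factory=ChemistryParams)
    include_swir: bool = True
    splice_correct: bool = False
    evi_threshold: float = 0.25
    traits: tuple[str, ...] = ("water", "nitrogen")
    methods: tuple[str, ...] = ALL_METHODS
    treatments: tuple[str, ...] = ALL_TREATMENTS
    validation_replicates: tuple[int, ...] | None = None  # None = last third
    selection_fraction: float = 0.30
    max_components: int = 10
    cv_folds: int = 10
    make_maps: bool = True
    map_treatments: dict = field(default_factory=lambda: {"water": "RAW", "nitrogen": "SMO"})
    write_scenes: bool = False


@dataclass
class TraitResults:
    """Per-trait outputs: metric table, models, selections, refits."""

    metrics: pd.DataFrame
    models: dict
    best_key: tuple[str, str] | None = None
    selections: dict = field(default_factory=dict)
    refit_metrics: dict = field(default_factory=dict)
    map_model: RegressionModel | None = None
    maps: list = field(default_factory=list)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    design: pd.DataFrame
    chemistry: pd.DataFrame
    traits: dict  # trait -> TraitResults
    out_dir: Path


def _scene_seed(seed: int, pot_id: int) -> int:
    return int((seed * 100003 + pot_id) % (2**31 - 1))


def _metrics_row(trait, treatment, method, m: FitMetrics) -> dict:
    return {
        "trait": trait,
        "treatment": treatment,
        "method": method,
        "partition": m.partition,
        "r2": round(m.r2, 6),
        "rmse": round(m.rmse, 6),
        "rpd": round(m.rpd, 6) if np.isfinite(m.rpd) else np.inf,
        "n": m.n,
    }


def _serialize_model(model: RegressionModel, path: Path) -> None:
    payload = {
        "method": model.method,
        "grid": model.grid.tolist(),
        "beta": None if model.beta is None else model.beta.tolist(),
        "intercept": model.intercept,
        "hyperparams": model.hyperparams,
        "preprocess": None
        if model.preprocess is None
        else {
            "method": model.preprocess.spec.method,
            "window": model.preprocess.spec.window,
            "polyorder": model.preprocess.spec.polyorder,
            "emsc_degree": model.preprocess.spec.emsc_degree,
            "per_nm": model.preprocess.spec.per_nm,
            "reference": None
            if model.preprocess.reference_ is None
            else model.preprocess.reference_.tolist(),
        },
        "selection": None if model.selection is None else model.selection.tolist(),
    }
    path.write_text(json.dumps(payload))


def simulate_pot_spectra(config: ExperimentConfig):
    """Simulate the trial and extract per-pot mean spectra.

    Returns (design, chemistry, vnir_spectra, fused_spectra, map_scenes)
    where the spectra are dicts pot_id -> Spectrum and map_scenes holds one
    watered and one drought calibrated VNIR cube with truth for mapping.
    """
    design = generate_design(config.n_replicates, seed=config.seed)
    if config.varieties is not None:
        design = design[design["variety"].isin(config.varieties)].reset_index(drop=True)
    chemistry = simulate_chemistry(design, config.chemistry_params, seed=config.seed + 1)
    chem_by_pot = chemistry.set_index("pot_id")

    vnir_spec = vnir_camera(config.scene_size)
    swir_spec = swir_camera(config.scene_size)
    vnir_spectra: dict[int, np.ndarray] = {}
    fused_spectra: dict[int, np.ndarray] = {}
    fused_grid = None
    map_scenes: dict[str, dict] = {}

    for row in design.itertuples(index=False):
        pot_id = int(row.pot_id)
        sc = scene_mod.render_scene(
            row._asdict(),
            chem_by_pot.loc[pot_id],
            vnir_spec,
            swir_spec,
            seed=_scene_seed(config.seed, pot_id),
            params=config.scene_params,
        )
        vnir_cal = calibrate(sc.vnir_raw, sc.vnir_dark, sc.vnir_white)
        mask = evi_mask(compute_evi(vnir_cal), threshold=config.evi_threshold)
        if mask.n_pixels == 0:
            logger.warning("pot %d: empty vegetation mask, skipped", pot_id)
            continue
        v_mean = mean_spectrum(vnir_cal, mask)
        vnir_spectra[pot_id] = v_mean
        if config.include_swir:
            swir_cal = calibrate(sc.swir_raw, sc.swir_dark, sc.swir_white)
            # both cameras share geometry here, so the VNIR EVI mask transfers;
            # the hyper-hue one-class route remains available via segmentation
            s_mean = mean_spectrum(swir_cal, mask.mask)
            fusion = combine_spectra(v_mean, s_mean, splice_correct=config.splice_correct)
            fused_spectra[pot_id] = fusion.spectrum
            fused_grid = fusion.spectrum.grid
        treatment = str(row.water_treatment)
        if config.make_maps and treatment not in map_scenes:
            map_scenes[treatment] = {
                "pot_id": pot_id,
                "cube": vnir_cal,
                "mask": mask,
                "truth_water": sc.truth_water_map,
                "truth_nitrogen": sc.truth_nitrogen_map,
            }
    return design, chemistry, vnir_spectra, fused_spectra, fused_grid, map_scenes


def _build_dataset(design, chemistry, spectra: dict, grid, trait: str) -> SpectralDataset:
    chem_by_pot = chemistry.set_index("pot_id")
    rows, y, reps, ids = [], [], [], []
    for r in design.itertuples(index=False):
        pot_id = int(r.pot_id)
        if pot_id not in spectra:
            continue
        if trait == "nitrogen" and int(r.soil) == 1:
            continue  # no-nutrient control plants yield no flag-leaf sample
        rows.append(spectra[pot_id].values)
        y.append(chem_by_pot.loc[pot_id, "water_pct" if trait == "water" else "nitrogen_pct"])
        reps.append(int(r.replicate))
        ids.append(pot_id)
    return SpectralDataset(
        X=np.asarray(rows),
        grid=grid,
        y=np.asarray(y),
        replicate=np.asarray(reps),
        trait=trait,
        sample_id=np.asarray(ids),
    )


def _default_validation_reps(replicates: np.ndarray) -> tuple[int, ...]:
    labels = sorted(set(int(r) for r in replicates))
    n_val = max(1, int(round(len(labels) / 3)))
    return tuple(labels[-n_val:])


def _fit_one(train, method, config, preprocessor) -> RegressionModel:
    if method in ("plsr", "pcr"):
        return fit_latent(
            train, method=method, max_components=config.max_components,
            cv_folds=config.cv_folds, seed=config.seed, preprocessor=preprocessor,
        )
    if method == "mlr_ridge":
        return fit_ridge(
            train, cv_folds=config.cv_folds, seed=config.seed, preprocessor=preprocessor
        )
    return fit_ml(train, method=method, seed=config.seed, preprocessor=preprocessor)


def fit_model_grid(dataset: SpectralDataset, config: ExperimentConfig, trait: str):
    """Fit every treatment x method combination and tabulate metrics."""
    val_reps = config.validation_replicates or _default_validation_reps(dataset.replicate)
    split_by_replicate(dataset, val_reps)  # validates the replicate set
    full = dataset.take(np.arange(dataset.n_samples))
    full.partition = np.where(np.isin(dataset.replicate, list(val_reps)), "validation", "train")

    rows, models = [], {}
    for treatment in config.treatments:
        pre_ds, pre = apply_preprocess(full, PreprocessSpec(method=treatment))
        tr = pre_ds.take(np.flatnonzero(pre_ds.partition == "train"))
        va = pre_ds.take(np.flatnonzero(pre_ds.partition == "validation"))
        for method in config.methods:
            model = _fit_one(tr, method, config, pre)
            m_tr = evaluate(model, tr, partition="train")
            m_va = evaluate(model, va, partition="validation")
            rows.append(_metrics_row(trait, treatment, method, m_tr))
            rows.append(_metrics_row(trait, treatment, method, m_va))
            models[(treatment, method)] = (model, tr, va, m_tr, m_va)
    metrics = pd.DataFrame(rows)
    return metrics, models, val_reps


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute the full analysis and write its report bundle.

    Outputs under ``config.out_dir``: ``design.csv``, ``chemistry.csv``,
    ``metrics_<trait>.csv`` (one row per treatment x method x partition),
    ``selection_<trait>.csv`` and refit metrics, serialized best models
    (JSON), rendered distribution maps (PNG), and ``run_log.json`` recording
    seeds, thresholds and stage decisions.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "evi_threshold": config.evi_threshold}

    design, chemistry, vnir_spectra, fused_spectra, fused_grid, map_scenes = (
        simulate_pot_spectra(config)
    )
    design.to_csv(out / "design.csv", index=False)
    chemistry.to_csv(out / "chemistry.csv", index=False)
    log["n_pots"] = int(len(design))
    log["n_spectra"] = len(vnir_spectra)

    if not vnir_spectra:
        raise RuntimeError("simulation produced no usable plant spectra")
    any_v = next(iter(vnir_spectra.values()))
    vnir_grid = any_v.grid
    use_fused = config.include_swir and fused_spectra
    spectra = fused_spectra if use_fused else vnir_spectra
    grid = fused_grid if use_fused else vnir_grid
    log["spectral_input"] = "vnir+swir" if use_fused else "vnir"
    log["n_bands"] = int(grid.size)

    results: dict[str, TraitResults] = {}
    for trait in config.traits:
        dataset = _build_dataset(design, chemistry, spectra, grid, trait)
        metrics, models, val_reps = fit_model_grid(dataset, config, trait)
        metrics.to_csv(out / f"metrics_{trait}.csv", index=False)
        log[f"validation_replicates_{trait}"] = list(val_reps)

        tres = TraitResults(metrics=metrics, models=models)

        # best linear model on validation R^2 drives wavelength selection
        linear_keys = [k for k in models if models[k][0].is_linear]
        if linear_keys:
            best_key = max(linear_keys, key=lambda k: models[k][4].r2)
            tres.best_key = best_key
            model, tr, va, _, _ = models[best_key]
            _serialize_model(model, out / f"model_{trait}_full.json")

            sel_coef = select_by_coefficients(model, fraction=config.selection_fraction)
            sel_feat = select_by_features(grid, trait)
            tres.selections = {"coef_fraction": sel_coef, "feature_windows": sel_feat}
            for name, sel in tres.selections.items():
                try:
                    refit_model, (m_tr, m_va) = refit_on_selection(
                        tr, va, sel, method="plsr",
                        max_components=config.max_components,
                        cv_folds=config.cv_folds, seed=config.seed,
                    )
                except ValueError as exc:
                    logger.warning("%s selection refit skipped for %s: %s", name, trait, exc)
                    continue
                tres.refit_metrics[name] = (m_tr, m_va)
                pd.DataFrame(
                    {"index": sel.indices, "wavelength_nm": sel.wavelengths}
                ).to_csv(out / f"selection_{trait}_{name}.csv", index=False)
                _serialize_model(refit_model, out / f"model_{trait}_{name}.json")
                log[f"selection_{trait}_{name}_n"] = int(sel.indices.size)

        # distribution maps from a VNIR-only model
        if config.make_maps and map_scenes:
            map_treatment = config.map_treatments.get(trait, "RAW")
            vnir_ds = _build_dataset(design, chemistry, vnir_spectra, vnir_grid, trait)
            vtrain, _vval = split_by_replicate(vnir_ds, val_reps)
            pre = Preprocessor(PreprocessSpec(method=map_treatment)).fit(vtrain.X, vnir_grid)
            vtrain_pp = vtrain.with_X(pre.transform(vtrain.X))
            map_model = fit_latent(
                vtrain_pp, method="plsr", max_components=config.max_components,
                cv_folds=config.cv_folds, seed=config.seed, preprocessor=pre,
            )
            tres.map_model = map_model
            _serialize_model(map_model, out / f"model_{trait}_map.json")
            for water_treatment, payload in map_scenes.items():
                dmap = predict_pixels(map_model, payload["cube"], payload["mask"], trait=trait)
                png = out / f"map_{trait}_{water_treatment}_pot{payload['pot_id']}.png"
                render_map(dmap, png)
                tres.maps.append((water_treatment, payload, dmap))
        results[trait] = tres

    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return ExperimentResult(
        config=config, design=design, chemistry=chemistry, traits=results, out_dir=out
    )
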