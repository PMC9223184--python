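"""Experiment orchestration: configuration, stage wiring and report bundles.

An :class:`ExperimentConfig` names every component of one experiment — the
synthetic scene parameters, the preprocessing recipe, the fusion level,
texture parameter and selector per sensor, the classifier — and
``run_experiment`` executes the stages end to end:

    simulate -> (calibrate -> segment -> extract) -> preprocess ->
    [select] -> fuse -> split -> train -> evaluate

Two data fidelities are supported: ``"table"`` (default) synthesizes
feature tables directly and scales to the full 240-sample design;
``"image"`` renders full hypercubes per sample and pushes them through the
imaging and texture modules, which is desk-scale only for small scene
counts (a 240-cube Vis-SWNIR set would exceed a gigabyte).

Grid modes reproduce the standard comparison layouts: the pixel-level grid
crosses 4 texture parameters x 2 sensors (8 rows); the feature-level grid
crosses 3 selectors x 2 sensors (6 rows).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cat_grading import assign_levels
from .fusion import FusedMatrix, feature_fuse, fit_scaling, pixel_fuse
from .imaging import (LWNIR, TRIM_RANGES, VIS_SWNIR, build_mask, correct_image,
                      extract_mean_spectrum, trim_bands)
from .modeling import SplitAssignment, stratified_split, train_knn, train_rf, train_svm
from .preprocessing import SpectraMatrix, chain
from .selection import (FeatureSelection, FitnessSpec, IrivParams, VcpaParams,
                        iriv, mvcpa_iriv, vcpa)
from .synthetic import (CatParams, FeatureTables, SceneConfig,
                        generate_feature_tables, generate_scene)
from .texture import GlcmSpec, TextureBlock, band_texture_row

logger = logging.getLogger(__name__)

SELECTORS = ("vcpa", "iriv", "mvcpa-iriv")
CLASSIFIERS = ("svm", "rf", "knn")


@dataclass
class ExperimentConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    cat: CatParams = field(default_factory=CatParams)
    recipe: str = "smooth-detrend"
    fidelity: str = "table"  # "table" or "image"
    fusion: str = "feature"  # "none", "pixel" or "feature"
    sensors: tuple[str, ...] = (VIS_SWNIR, LWNIR)
    texture_parameter: dict = field(
        default_factory=lambda: {VIS_SWNIR: "energy", LWNIR: "contrast"}
    )
    selector: str = "vcpa"
    budgets: str = "reduced"  # "reduced" or "full" selector budgets
    classifier: str = "svm"
    grid: str | None = None  # None, "pixel" or "feature"
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.fusion not in ("none", "pixel", "feature"):
            raise ValueError(f"unknown fusion level {self.fusion!r}")
        if self.fusion == "feature" and self.selector not in SELECTORS:
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.fidelity not in ("table", "image"):
            raise ValueError(f"unknown fidelity {self.fidelity!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "scene" in d and isinstance(d["scene"], dict):
            scene = dict(d["scene"])
            for k in ("levels", "spatial_size", "vis_range", "lwnir_range",
                      "level_reflectance_scale", "texture_noise_sd"):
                if k in scene and isinstance(scene[k], list):
                    scene[k] = tuple(scene[k])
            d["scene"] = SceneConfig(**scene)
        if "cat" in d and isinstance(d["cat"], dict):
            cat = {k: tuple(v) if isinstance(v, list) else v for k, v in d["cat"].items()}
            d["cat"] = CatParams(**cat)
        if isinstance(d.get("sensors"), list):
            d["sensors"] = tuple(d["sensors"])
        return cls(**d)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def render_feature_tables(config: SceneConfig, cat_params: CatParams, rng) -> FeatureTables:
    """Full-fidelity path: render, calibrate, segment and extract every sample.

    Produces the same table layout as ``generate_feature_tables`` by running
    each rendered scene through reflectance correction, Otsu masking,
    mean-spectrum extraction, per-band texture extraction and noise-band
    trimming.  Memory-bounded by one cube at a time, but intended for small
    scene counts.
    """
    from .synthetic import _as_rng, generate_cat
    from .texture import TEXTURE_PARAMS

    rng = _as_rng(rng)
    n_total = config.n_per_level * len(config.levels)
    records = pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n_total)],
            "level": np.repeat(list(config.levels), config.n_per_level),
            "culture_day": np.repeat(
                [{"healthy": 0, "mild": 2, "moderate": 4, "severe": 6}.get(lv, 0)
                 for lv in config.levels],
                config.n_per_level,
            ),
        }
    )
    records["cat_activity"] = np.concatenate(
        [generate_cat(cat_params, lv, config.n_per_level, rng) for lv in config.levels]
    )
    spectra, texture = {}, {}
    spec = GlcmSpec()
    for sensor in (VIS_SWNIR, LWNIR):
        lam_full = config.wavelengths(sensor, padded=True)
        lo, hi = TRIM_RANGES[sensor]
        S_rows, T_rows = [], {p: [] for p in TEXTURE_PARAMS}
        for lv in config.levels:
            for _ in range(config.n_per_level):
                raw, white, black, truth = generate_scene(config, lv, rng, sensor)
                cube = correct_image(raw, white, black)
                mask = build_mask(cube)
                S_rows.append(extract_mean_spectrum(cube, mask))
                rows = band_texture_row(cube.values, mask.values, spec)
                for p in TEXTURE_PARAMS:
                    T_rows[p].append(rows[p])
        S, lam = trim_bands(np.asarray(S_rows), lam_full, lo, hi)
        spectra[sensor] = SpectraMatrix(S, lam, sensor)
        texture[sensor] = {}
        for p in TEXTURE_PARAMS:
            T, lam_t = trim_bands(np.asarray(T_rows[p]), lam_full, lo, hi)
            texture[sensor][p] = TextureBlock(p, T, lam_t, sensor)
    return FeatureTables(spectra=spectra, texture=texture, records=records)


def _make_tables(config: ExperimentConfig) -> FeatureTables:
    rng = np.random.default_rng([config.seed, 11])
    if config.fidelity == "image":
        return render_feature_tables(config.scene, config.cat, rng)
    return generate_feature_tables(config.scene, config.cat, rng)


def _preprocess(spectra: SpectraMatrix, recipe: str, split: SplitAssignment) -> SpectraMatrix:
    """Fit the recipe on calibration rows only, then replay on all rows."""
    if not recipe or recipe == "original":
        return spectra
    cal = SpectraMatrix(spectra.matrix[split.calibration], spectra.wavelengths, spectra.sensor)
    fitted = chain(cal, recipe)
    return chain(spectra, recipe, context=fitted.context)


def _select(X_cal, y_cal, algorithm: str, budgets: str, seed: int,
            block_id: str, wavelengths) -> FeatureSelection:
    spec = FitnessSpec(seed=seed)
    vp = VcpaParams.reduced() if budgets == "reduced" else VcpaParams()
    ip = IrivParams.reduced() if budgets == "reduced" else IrivParams()
    if algorithm == "vcpa":
        return vcpa(X_cal, y_cal, spec, vp, block_id=block_id, wavelengths=wavelengths)
    if algorithm == "iriv":
        return iriv(X_cal, y_cal, spec, ip, block_id=block_id, wavelengths=wavelengths)
    if algorithm == "mvcpa-iriv":
        return mvcpa_iriv(X_cal, y_cal, spec, vp, ip, block_id=block_id, wavelengths=wavelengths)
    raise ValueError(f"unknown selector {algorithm!r}")


def _train(classifier: str, X, y, split: SplitAssignment, seed: int):
    if classifier == "svm":
        return train_svm(X, y, split, seed=seed)
    if classifier == "rf":
        return train_rf(X, y, split, seed=seed)
    return train_knn(X, y, split, seed=seed)


def _blocks_for(config: ExperimentConfig, tables: FeatureTables,
                split: SplitAssignment, sensors, selector=None, y=None):
    """Preprocessed spectra + chosen texture block per sensor, optionally with
    per-block selections fitted on calibration rows."""
    blocks = []
    for sensor in sensors:
        sp = _preprocess(tables.spectra[sensor], config.recipe, split)
        tx = tables.texture[sensor][config.texture_parameter[sensor]]
        if selector is None:
            blocks.extend([(sp, None), (tx, None)])
        else:
            sels = []
            for blk, kind in ((sp, "spectra"), (tx, tx.parameter)):
                sel = _select(
                    blk.matrix[split.calibration], y[split.calibration],
                    selector, config.budgets, config.seed,
                    block_id=f"{sensor}:{kind}", wavelengths=blk.wavelengths,
                )
                sels.append(sel)
            blocks.extend([(sp, sels[0]), (tx, sels[1])])
    return blocks


def _fuse_and_train(config, blocks, y, split):
    if config.fusion == "pixel":
        fused = pixel_fuse(*[b for b, _ in blocks])
    else:
        fused = feature_fuse(blocks)
    scaled = fit_scaling(fused, split.calibration)
    model, report = _train(config.classifier, scaled.matrix, y, split, config.seed)
    return fused, scaled, model, report


def spectra_only_run(config: ExperimentConfig, tables: FeatureTables,
                     split: SplitAssignment, y, sensor: str):
    """Baseline: classifier on one sensor's preprocessed spectra alone."""
    sp = _preprocess(tables.spectra[sensor], config.recipe, split)
    from .fusion import ColumnProvenance
    prov = tuple(
        ColumnProvenance(sensor, "spectra", j, float(sp.wavelengths[j]))
        for j in range(sp.matrix.shape[1])
    )
    fused = FusedMatrix(sp.matrix, prov, "pixel")
    scaled = fit_scaling(fused, split.calibration)
    model, report = _train(config.classifier, scaled.matrix, y, split, config.seed)
    return model, report


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute one experiment (or a grid) and return the report bundle.

    The bundle holds the summary table (one row per model), the full
    classifier reports, any feature selections, the sample records and a
    manifest sufficient to reproduce the run.  When ``config.output_dir`` is
    set, all artifacts are also written there as CSV/JSON/YAML.
    """
    t0 = time.time()
    tables = _make_tables(config)
    # grading labels come from the CAT assay, as in the experiment design
    y = assign_levels(tables.records["cat_activity"].to_numpy())
    split = stratified_split(y, config.seed)
    logger.info("dataset: %d samples, split %d/%d", y.size,
                split.calibration.size, split.prediction.size)

    rows, reports, selections = [], {}, {}
    if config.grid == "pixel":
        from .texture import TEXTURE_PARAMS
        for sensor in config.sensors:
            for param in TEXTURE_PARAMS:
                sub = dataclasses.replace(
                    config, grid=None, fusion="pixel",
                    texture_parameter={**config.texture_parameter, sensor: param},
                )
                blocks = _blocks_for(sub, tables, split, [sensor])
                _, _, _, rep = _fuse_and_train(sub, blocks, y, split)
                key = f"{sensor}:{config.recipe}+{param}"
                reports[key] = rep
                rows.append({"sensor": sensor, "spectra": config.recipe,
                             "texture": param, **rep.summary_row()})
    elif config.grid == "feature":
        for sensor in config.sensors:
            for alg in SELECTORS:
                sub = dataclasses.replace(config, grid=None, fusion="feature", selector=alg)
                blocks = _blocks_for(sub, tables, split, [sensor], selector=alg, y=y)
                _, _, _, rep = _fuse_and_train(sub, blocks, y, split)
                key = f"{sensor}:{alg}"
                reports[key] = rep
                selections[key] = [s for _, s in blocks]
                rows.append({
                    "sensor": sensor, "spectra": config.recipe,
                    "texture": config.texture_parameter[sensor], "selector": alg,
                    "n_spectra_features": int(blocks[0][1].indices.size),
                    "n_texture_features": int(blocks[1][1].indices.size),
                    **rep.summary_row(),
                })
    elif config.fusion == "none":
        # spectra-only baseline, one model per sensor
        for sensor in config.sensors:
            _, rep = spectra_only_run(config, tables, split, y, sensor)
            reports[sensor] = rep
            rows.append({"sensors": sensor, "fusion": "none", "selector": "-",
                         **rep.summary_row()})
    else:
        selector = config.selector if config.fusion == "feature" else None
        blocks = _blocks_for(config, tables, split, config.sensors,
                             selector=selector, y=y)
        _, _, _, rep = _fuse_and_train(config, blocks, y, split)
        key = "+".join(config.sensors)
        reports[key] = rep
        selections[key] = [s for _, s in blocks if s is not None]
        rows.append({"sensors": key, "fusion": config.fusion,
                     "selector": selector or "-", **rep.summary_row()})

    summary = pd.DataFrame(rows)
    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "moldscan_version": __version__,
        "n_samples": int(y.size),
        "runtime_s": round(time.time() - t0, 2),
    }
    bundle = {
        "summary": summary,
        "reports": reports,
        "selections": selections,
        "records": tables.records,
        "split": split,
        "manifest": manifest,
        "tables": tables,
    }
    if config.output_dir:
        _write_bundle(config, bundle)
    return bundle


def _write_bundle(config: ExperimentConfig, bundle: dict) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["summary"].to_csv(out / "summary.csv", index=False)
    bundle["records"].to_csv(out / "sample_records.csv", index=False)
    config.save(out / "config.yaml")
    manifest = dict(bundle["manifest"])
    manifest.pop("runtime_s", None)  # keep rerun artifacts byte-identical
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    for key, rep in bundle["reports"].items():
        safe = key.replace(":", "_").replace("+", "_")
        pd.DataFrame(rep.confusion, index=rep.class_order,
                     columns=rep.class_order).to_csv(out / f"confusion_{safe}.csv")
        (out / f"report_{safe}.json").write_text(json.dumps({
            "classifier": rep.classifier,
            "hyperparameters": rep.hyperparameters,
            "calibration_accuracy": rep.calibration_accuracy,
            "prediction_accuracy": rep.prediction_accuracy,
            "per_class_accuracy": rep.per_class_accuracy,
            "moldy_as_healthy": rep.moldy_as_healthy,
            "seed": rep.seed,
        }, indent=1))
    for key, sels in bundle["selections"].items():
        for s in sels:
            if s is None:
                continue
            safe = f"{key}_{s.block_id}".replace(":", "_").replace("+", "_")
            (out / f"selection_{safe}.json").write_text(s.to_json())
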