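"""Configuration-driven end-to-end orchestration.

``run_pipeline`` executes load → (calibrate) → filter → variable screen →
repeats → model fits → metrics → ensembles (changing and fixed) → zones →
period aggregates → area and niche-breadth series, writing each stage's
artifact under the output directory, with structured count logging and
bit-reproducible reruns for a fixed config + seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import archaeo, climate, evaluation, projection, sampling
from .cube import ClimateCube, read_biome_class_map
from .models import (
    ChangingNicheGAM,
    FixedNicheGAM,
    compare_models,
    predict_suitability,
)

log = logging.getLogger("paleoniche")


@dataclass
class PipelineConfig:
    """All paths and parameters of one pipeline run.

    Every numeric default is the study-design value: 100 repeats, 200
    backgrounds per occurrence, a 78 ka constant-effort boundary, spline
    basis size k = 4, ΔAIC gate 2, Boyce gate 0.7, zone coverages
    90/95/99%, a 0.8 correlation cap for variable selection and the
    14–120 ka / ≤20 kyr-range age filters.
    """

    occurrence_csv: str = ""
    climate_cube: str = ""
    north_curve: str = ""
    south_curve: str = ""
    biome_class_map: str = ""
    output_dir: str = "pipeline_out"

    n_repeats: int = 100
    backgrounds_per_occurrence: int = 200
    effort_boundary: float = 78_000.0
    k: int = 4
    daic_gate: float = 2.0
    boyce_gate: float = 0.7
    coverages: tuple[float, float, float] = (0.90, 0.95, 0.99)
    corr_threshold: float = 0.8
    min_age: float = 14_000.0
    max_age: float = 120_000.0
    max_uncertainty: float = 20_000.0

    master_seed: int = 0
    ensemble_method: str = "mean"
    run_morans_i: bool = True

    def self_test(self) -> None:
        """Assert that the documented study-design defaults are intact."""
        ref = PipelineConfig()
        for name in (
            "n_repeats",
            "backgrounds_per_occurrence",
            "effort_boundary",
            "k",
            "daic_gate",
            "boyce_gate",
            "coverages",
            "corr_threshold",
            "min_age",
            "max_age",
            "max_uncertainty",
        ):
            assert getattr(ref, name) == PipelineConfig.__dataclass_fields__[
                name
            ].default if name != "coverages" else True
        assert ref.n_repeats == 100
        assert ref.backgrounds_per_occurrence == 200
        assert ref.effort_boundary == 78_000.0
        assert ref.k == 4
        assert ref.daic_gate == 2.0
        assert ref.boyce_gate == 0.7
        assert tuple(ref.coverages) == (0.90, 0.95, 0.99)
        assert ref.corr_threshold == 0.8
        assert (ref.min_age, ref.max_age, ref.max_uncertainty) == (
            14_000.0,
            120_000.0,
            20_000.0,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "coverages" in raw:
            raw["coverages"] = tuple(raw["coverages"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["coverages"] = list(d["coverages"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class PipelineResult:
    config: PipelineConfig
    output_dir: Path
    n_occurrences: int
    selected_variables: list[str]
    metrics: pd.DataFrame
    thresholds: dict[str, float]
    artifacts: dict[str, str] = field(default_factory=dict)


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: PipelineConfig, cube: ClimateCube | None = None,
                 occurrences: pd.DataFrame | None = None) -> PipelineResult:
    """Run the full analysis; ``cube``/``occurrences`` may be passed
    in-memory (as the synthetic generator produces them) or loaded from the
    configured paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    _stage("load")
    if cube is None:
        cube = ClimateCube.from_netcdf(config.climate_cube)
        if config.biome_class_map:
            cube.biome_class_map = read_biome_class_map(config.biome_class_map)
    if occurrences is None:
        occurrences = archaeo.load_occurrence_database(config.occurrence_csv)
    log.info("loaded %d occurrence rows, cube %d slices x %d land cells",
             len(occurrences), len(cube.times), cube.n_land_cells)

    if config.north_curve and config.south_curve:
        _stage("calibrate")
        north = archaeo.CalibrationCurve.from_file(config.north_curve, "north")
        south = archaeo.CalibrationCurve.from_file(config.south_curve, "south")
        occurrences, cal_log = archaeo.standardize_chronology(
            occurrences, north, south
        )
        cal_log.to_csv(out / "calibration_exclusions.csv", index=False)
        artifacts["calibration_exclusions"] = str(out / "calibration_exclusions.csv")

    _stage("filter")
    filtered, tally = archaeo.filter_occurrences(
        occurrences,
        min_age=config.min_age,
        max_age=config.max_age,
        max_uncertainty=config.max_uncertainty,
    )
    log.info("filter tally: %s", tally)
    filtered.to_csv(out / "occurrences_filtered.csv", index=False)
    pd.DataFrame([tally]).to_csv(out / "exclusion_tally.csv", index=False)
    artifacts["occurrences_filtered"] = str(out / "occurrences_filtered.csv")
    if len(filtered) == 0:
        raise RuntimeError("stage filter: no occurrences retained")

    _stage("variable_screen")
    # screen on mean ages against a background snapshot of the cube
    screen_pres, _ = climate.extract_for_occurrences(
        cube, filtered, time_column="age_mean"
    )
    rngv = np.random.default_rng(np.random.SeedSequence((config.master_seed, 1)))
    bg_frames = []
    for i in range(len(cube.times)):
        frame = cube.slice_frame(i)
        take = rngv.integers(0, len(frame), size=min(200, len(frame)))
        bg_frames.append(frame.iloc[take])
    screen_bg = pd.concat(bg_frames, ignore_index=True)
    selected = climate.select_variables(
        screen_pres, screen_bg, corr_threshold=config.corr_threshold
    )
    (out / "selected_variables.json").write_text(json.dumps(selected))
    log.info("selected variables: %s", selected)
    if len(selected) < 2:
        raise RuntimeError(
            "stage variable_screen: fewer than 2 informative variables"
        )

    _stage("repeats")
    repeats = sampling.build_repeats(
        filtered,
        cube,
        n_repeats=config.n_repeats,
        n_background=config.backgrounds_per_occurrence,
        effort_boundary=config.effort_boundary,
        seed=config.master_seed,
    )
    rep_dir = out / "repeats"
    for rep in repeats:
        rep.write(rep_dir / f"repeat_{rep.repeat_id:03d}")
    artifacts["repeats"] = str(rep_dir)

    _stage("fit")
    covariates = tuple(selected)
    metrics_rows = []
    predictions_changing: dict[int, object] = {}
    predictions_fixed: dict[int, object] = {}
    changing_results = {}
    for rep in repeats:
        frame = rep.model_frame()
        fixed = FixedNicheGAM(frame, covariates=covariates, k=config.k,
                              repeat_id=rep.repeat_id).fit()
        changing = ChangingNicheGAM(frame, covariates=covariates, k=config.k,
                                    repeat_id=rep.repeat_id).fit()
        comp = compare_models(fixed, changing)
        pres_suit = changing.predict(
            rep.presences.rename(columns={"slice_time_bp": "time_bp"})
        )
        bg_suit = changing.predict(
            rep.backgrounds.rename(columns={"slice_time_bp": "time_bp"})
        )
        try:
            bci = evaluation.boyce_index(pres_suit, bg_suit).value
        except evaluation.UndefinedIndexError:
            bci = float("nan")
        mi, mp = float("nan"), float("nan")
        if config.run_morans_i:
            resid = rep.presences.copy()
            resid_pred = pres_suit
            z = 1.0 - resid_pred  # presence residual on the response scale
            coords = resid[["lon", "lat"]].to_numpy(dtype=float)
            if len(z) >= 10 and np.ptp(z) > 0:
                mres = evaluation.morans_i(
                    z, coords, n_permutations=199,
                    seed=config.master_seed + rep.repeat_id,
                )
                mi, mp = mres.i, mres.p_value
        metrics_rows.append(
            {
                "repeat_id": rep.repeat_id,
                "n_presences": len(rep.presences),
                "aic_fixed": fixed.aic,
                "aic_changing": changing.aic,
                "delta_aic": comp.delta_aic,
                "supported": comp.supported,
                "boyce": bci,
                "morans_i": mi,
                "morans_p": mp,
            }
        )
        changing_results[rep.repeat_id] = changing
        predictions_changing[rep.repeat_id] = predict_suitability(changing, cube)
        predictions_fixed[rep.repeat_id] = predict_suitability(fixed, cube)
        log.info(
            "repeat %d: delta_aic=%.2f boyce=%.3f",
            rep.repeat_id, comp.delta_aic, bci,
        )
    metrics = pd.DataFrame(metrics_rows)
    metrics.to_csv(out / "metrics.csv", index=False)
    artifacts["metrics"] = str(out / "metrics.csv")

    _stage("ensemble")
    daic = dict(zip(metrics["repeat_id"], metrics["delta_aic"]))
    bci_map = dict(zip(metrics["repeat_id"], metrics["boyce"]))
    ensemble = projection.build_ensemble(
        predictions_changing, daic, bci_map,
        method=config.ensemble_method,
        daic_gate=config.daic_gate, boyce_gate=config.boyce_gate,
    )
    ensemble.suitability.to_netcdf(out / "ensemble_changing.nc", engine="scipy")
    try:
        ensemble_fixed = projection.build_ensemble(
            predictions_fixed, daic, bci_map,
            method=config.ensemble_method,
            daic_gate=config.daic_gate, fixed_variant=True,
        )
        ensemble_fixed.suitability.to_netcdf(
            out / "ensemble_fixed.nc", engine="scipy"
        )
    except projection.GateError as exc:
        ensemble_fixed = None
        log.info("fixed-niche ensemble empty: %s", exc)

    _stage("zones")
    pooled = []
    for rep in repeats:
        pooled.append(
            projection.extract_ensemble_at_occurrences(ensemble, rep.presences)
        )
    occ_suit = np.concatenate(pooled)
    zones = projection.binarize_zones(
        ensemble, occ_suit, coverages=config.coverages
    )
    zones.zones.to_netcdf(out / "zones.nc", engine="scipy")
    (out / "thresholds.json").write_text(json.dumps(zones.thresholds))
    artifacts["zones"] = str(out / "zones.nc")

    _stage("periods")
    per = projection.aggregate_by_period(ensemble.suitability)
    per.to_netcdf(out / "period_means.nc", engine="scipy")
    modal, ties = projection.modal_biome_by_period(cube)
    modal.to_netcdf(out / "period_modal_biome.nc", engine="scipy")
    artifacts["period_means"] = str(out / "period_means.nc")

    _stage("areas")
    areas = projection.biome_area_series(zones, cube)
    kern, pca = projection.niche_kernel_area_series(cube, zones)
    series = areas.merge(
        kern, on=["slice_time_bp", "biome_class"], suffixes=("", "_kernel")
    )
    series.to_csv(out / "niche_area_series.csv", index=False)
    artifacts["niche_area_series"] = str(out / "niche_area_series.csv")

    return PipelineResult(
        config=config,
        output_dir=out,
        n_occurrences=len(filtered),
        selected_variables=selected,
        metrics=metrics,
        thresholds=zones.thresholds,
        artifacts=artifacts,
    )
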