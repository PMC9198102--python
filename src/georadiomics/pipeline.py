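"""Pipeline orchestration: phantom -> ROIs -> features -> grid -> report.

A run directory caches each stage's outputs together with a hash of the
resolved configuration; re-running skips completed stages unless forced.
All stage seeds derive deterministically from one master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_table import FeatureTable
from .features import ENSEMBLE_DEFINITIONS, ExtractionSettings, build_ensembles, extract_all
from .image import PointLabel
from .image_io import read_feature_table, write_feature_table
from .model_grid import (
    GridResult,
    default_classifier_specs,
    default_fs_specs,
    run_grid,
)
from .phantom import CohortConfig, PhantomConfig, PhantomSample, generate_cohort
from .report import write_report
from .roi import ROISpec, default_roi_set, rasterize

__all__ = ["PipelineConfig", "extract_cohort_tables", "run_pipeline", "stage_seeds"]

logger = logging.getLogger(__name__)


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from one master seed."""
    states = np.random.SeedSequence(master_seed).generate_state(4) % (2**31)
    return {
        "phantom": int(states[0]),
        "split": int(states[1]),
        "model": int(states[2]),
        "extra": int(states[3]),
    }


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run (JSON-serializable)."""

    n_patients: int = 60
    bm_fraction: float = 0.5
    lesions_per_patient: int = 3
    hb_points_per_patient: int = 4
    test_fraction: float = 0.3
    cv_folds: int = 5
    group_by_patient: bool = False
    clip_threshold: float = 0.5
    master_seed: int = 0
    fs_names: list[str] | None = None  # None = all 14
    classifier_names: list[str] | None = None  # None = all 12
    roi_names: list[str] | None = None  # None = all 9 (+ 4 ensembles)
    phantom_overrides: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _select_named(specs, names, label):
    if names is None:
        return list(specs)
    by_name = {s.name: s for s in specs}
    missing = [n for n in names if n not in by_name]
    if missing:
        raise KeyError(f"unknown {label} names: {missing}; known: {list(by_name)}")
    return [by_name[n] for n in names]


def extract_cohort_tables(
    samples: list[PhantomSample] | list[tuple],
    roi_specs: list[ROISpec] | None = None,
    settings: ExtractionSettings = ExtractionSettings(),
    clip_threshold: float = 0.5,
    ensembles: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, FeatureTable]:
    """Extract per-ROI and ensemble feature tables for a cohort.

    ``samples`` are phantom samples or ``(volume, points)`` pairs.  A point
    whose ROI set includes a mask clipped beyond ``clip_threshold`` is
    excluded from *all* tables (logged), keeping rows aligned across the
    single-ROI and ensemble feature spaces.
    """
    roi_specs = default_roi_set() if roi_specs is None else roi_specs
    roi_names = [s.name for s in roi_specs]
    if ensembles is None:
        ensembles = {
            name: members
            for name, members in ENSEMBLE_DEFINITIONS.items()
            if all(m in roi_names for m in members)
        }

    rows: dict[str, list[dict]] = {name: [] for name in [*roi_names, *ensembles]}
    n_excluded = 0
    for sample in samples:
        volume, points = (
            (sample.volume, sample.points)
            if isinstance(sample, PhantomSample)
            else sample
        )
        for point in points:
            per_roi: dict[str, dict[str, float]] = {}
            excluded = False
            for spec in roi_specs:
                mask = rasterize(spec, point.position, volume.grid)
                if mask.clipped_fraction > clip_threshold:
                    logger.warning(
                        "excluding point %s: %s clipped %.0f%% (> %.0f%%)",
                        point.point_id, spec.name,
                        100 * mask.clipped_fraction, 100 * clip_threshold,
                    )
                    excluded = True
                    break
                per_roi[spec.name] = extract_all(volume, mask, settings)
            if excluded:
                n_excluded += 1
                continue
            meta = {
                "patient_id": point.patient_id,
                "point_id": point.point_id,
                "label": point.label.value,
            }
            for name in roi_names:
                rows[name].append({**meta, "roi": name, **per_roi[name]})
            for name, vec in build_ensembles(per_roi, ensembles).items():
                rows[name].append({**meta, "roi": name, **vec})
    if n_excluded:
        logger.info("excluded %d point(s) due to heavy clipping", n_excluded)
    return {name: FeatureTable(pd.DataFrame(r)) for name, r in rows.items() if r}


def _stage_done(stage_dir: Path, cfg_hash: str) -> bool:
    marker = stage_dir / "stage.json"
    if not marker.exists():
        return False
    with open(marker) as fh:
        return json.load(fh).get("config_hash") == cfg_hash


def _mark_done(stage_dir: Path, cfg_hash: str, **extra) -> None:
    with open(stage_dir / "stage.json", "w") as fh:
        json.dump({"config_hash": cfg_hash, **extra}, fh, indent=2)


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path, force: bool = False
) -> GridResult:
    """Execute all stages into ``out_dir``; completed stages are skipped.

    Stage order: cohort generation -> feature extraction (tables CSV) ->
    model grid (JSON/CSV) -> report figures.  A failing stage raises with
    its name; earlier outputs stay on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash
    (out / "config.json").write_text(config.to_json())
    seeds = stage_seeds(config.master_seed)

    roi_specs = _select_named(default_roi_set(), config.roi_names, "ROI")
    fs_specs = _select_named(default_fs_specs(), config.fs_names, "FS")
    clf_specs = _select_named(default_classifier_specs(), config.classifier_names, "classifier")

    # stage 1+2: cohort + feature tables (cached as CSV per table)
    tables_dir = out / "tables"
    tables_dir.mkdir(exist_ok=True)
    if force or not _stage_done(tables_dir, cfg_hash):
        logger.info("stage features: generating cohort of %d patients", config.n_patients)
        phantom_cfg = PhantomConfig(seed=seeds["phantom"], **config.phantom_overrides)
        cohort_cfg = CohortConfig(
            phantom=phantom_cfg,
            lesions_per_patient=config.lesions_per_patient,
            hb_points_per_patient=config.hb_points_per_patient,
        )
        samples = generate_cohort(
            cohort_cfg, config.n_patients, config.bm_fraction, master_seed=seeds["phantom"]
        )
        tables = extract_cohort_tables(
            samples, roi_specs, clip_threshold=config.clip_threshold
        )
        for name, table in tables.items():
            write_feature_table(table, tables_dir / f"features_{name}.csv")
        _mark_done(tables_dir, cfg_hash, tables=list(tables))
    else:
        logger.info("stage features: cached, skipping")
    with open(tables_dir / "stage.json") as fh:
        table_names = json.load(fh)["tables"]
    tables = {
        name: read_feature_table(tables_dir / f"features_{name}.csv")
        for name in table_names
    }

    # stage 3: model grid
    grid_dir = out / "grid"
    grid_dir.mkdir(exist_ok=True)
    grid_csv = grid_dir / "grid_cells.csv"
    if force or not _stage_done(grid_dir, cfg_hash):
        logger.info(
            "stage grid: %d tables x %d FS x %d classifiers",
            len(tables), len(fs_specs), len(clf_specs),
        )
        grid = run_grid(
            tables, fs_specs, clf_specs,
            test_fraction=config.test_fraction,
            cv_folds=config.cv_folds,
            seed=seeds["split"],
            group_by_patient=config.group_by_patient,
        )
        grid.provenance["config_hash"] = cfg_hash
        grid.to_dataframe().to_csv(grid_csv, index=False)
        with open(grid_dir / "provenance.json", "w") as fh:
            json.dump(grid.provenance, fh, indent=2)
        _mark_done(grid_dir, cfg_hash)
    else:
        logger.info("stage grid: cached, skipping")
        from .model_grid import GridCell

        df = pd.read_csv(grid_csv).fillna({"reason": "", "confusion": "[]"})
        cells = []
        for rec in df.to_dict("records"):
            rec["confusion"] = json.loads(rec["confusion"]) if isinstance(rec["confusion"], str) else []
            cells.append(GridCell(**rec))
        with open(grid_dir / "provenance.json") as fh:
            grid = GridResult(cells=cells, provenance=json.load(fh))

    # stage 4: report
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    if force or not _stage_done(report_dir, cfg_hash):
        write_report(grid, report_dir, roi_specs)
        _mark_done(report_dir, cfg_hash)
    return grid
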