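"""End-to-end orchestration: simulate -> detect -> features -> train ->
evaluate -> stats, from a single seeded configuration.

Every run is driven by a :class:`RunConfig` (typically loaded from YAML),
produces a deterministic artifact tree under the output directory and writes
a ``manifest.json`` recording the configuration hash, the seed and every
emitted file, so any numeric artifact is traceable to its seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .classify import BoostConfig, windows_from_cohort
from .cnn import CNNSpec
from .evaluate import cross_validate, cross_validate_cnn, repeated_cv
from .features import cohort_features
from .peaks import DetectorConfig
from .stats import bland_altman, feature_screen, pca_relevance
from .synthetic import CohortSpec, GroupEffects, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("ecgms")


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    method: str = "svm"  # svm | robustboost | adaboost | cnn
    boost: BoostConfig = field(default_factory=BoostConfig)
    cnn: CNNSpec = field(default_factory=CNNSpec)
    k: int = 10
    n_reps: int = 0  # >0 enables the repeated-CV accuracy histogram
    n_windows: int = 300
    stage: str | None = "basal"  # stage used for classification
    seed: int = 0
    out_dir: str = "ecgms_run"
    write_records: bool = False
    record_format: str = "csv"  # csv | wfdb

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    return obj


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file with per-stage sections."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    if "cohort" in raw:
        cohort = dict(raw["cohort"])
        if "effects" in cohort:
            cohort["effects"] = GroupEffects(**cohort["effects"])
        if "stages" in cohort:
            cohort["stages"] = tuple(cohort["stages"])
        if "lead_names" in cohort:
            cohort["lead_names"] = tuple(cohort["lead_names"])
        kwargs["cohort"] = CohortSpec(**cohort)
    if "detector" in raw:
        kwargs["detector"] = DetectorConfig(**raw["detector"])
    if "boost" in raw:
        kwargs["boost"] = BoostConfig(**raw["boost"])
    if "cnn" in raw:
        cnn = dict(raw["cnn"])
        for key in ("conv1_kernel", "conv2_kernel", "pool"):
            if key in cnn:
                cnn[key] = tuple(cnn[key])
        kwargs["cnn"] = CNNSpec(**cnn)
    for key in (
        "method",
        "k",
        "n_reps",
        "n_windows",
        "stage",
        "seed",
        "out_dir",
        "write_records",
        "record_format",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


def _stage_timer(name: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.2f s", name, time.perf_counter() - self.t0)

    return _T()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to disk).

    Raises with the failing stage named; partial artifacts of completed
    stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _as_jsonable(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "artifacts": {},
        "summary": {},
    }

    def _emit(key: str, path: Path):
        manifest["artifacts"][key] = str(path)

    try:
        with _stage_timer("simulate"):
            cohort = generate_cohort(config.cohort)
            log.info("simulate: %d records", len(cohort))
            if config.write_records:
                rec_dir = out / "records"
                rec_dir.mkdir(exist_ok=True)
                for rec, ann in cohort:
                    stem = f"{rec.subject_id}_{rec.stage}"
                    if config.record_format == "wfdb":
                        _io.write_wfdb_record(rec, rec_dir)
                    else:
                        _io.write_csv_record(rec, rec_dir / f"{stem}.csv")
                    _io.write_annotations(ann, rec_dir / f"{stem}_truth_ann.csv")
                _emit("records", rec_dir)
    except Exception as err:
        raise RuntimeError("pipeline failed at stage 'simulate'") from err

    try:
        with _stage_timer("detect+features"):
            feats = cohort_features(cohort, from_annotations=False, detector_config=config.detector)
            log.info("features: %d rows x %d cols", *feats.shape)
            fpath = out / "features.csv"
            feats.to_csv(fpath, index=False)
            _emit("features", fpath)
    except Exception as err:
        raise RuntimeError("pipeline failed at stage 'features'") from err

    try:
        with _stage_timer("agreement"):
            from .peaks import delineate_record

            diffs = []
            for rec, truth in cohort[: min(len(cohort), 10)]:
                det = delineate_record(rec)["I"]
                ba = bland_altman(truth.r_idx, det.r_idx, sample_rate=rec.sample_rate)
                diffs.append(ba.mean_difference)
            manifest["summary"]["r_peak_mean_difference_ms"] = float(np.mean(diffs))
    except Exception as err:
        raise RuntimeError("pipeline failed at stage 'agreement'") from err

    stage_feats = feats if config.stage is None else feats[feats["stage"] == config.stage]
    try:
        with _stage_timer("evaluate"):
            if config.method == "cnn":
                wins = windows_from_cohort(cohort, n_windows=config.n_windows, stage=config.stage)
                sres, wres = cross_validate_cnn(
                    wins, spec=config.cnn, k=config.k, seed=config.seed
                )
                res = sres
                manifest["summary"]["cnn_window_accuracy"] = wres.mean_accuracy
            else:
                kwargs = {"config": config.boost} if config.method in ("robustboost", "adaboost") else {}
                res = cross_validate(
                    stage_feats, method=config.method, k=config.k, seed=config.seed, **kwargs
                )
            rpath = out / "cv_report.csv"
            res.summary().to_csv(rpath)
            _emit("cv_report", rpath)
            manifest["summary"]["cv_mean_accuracy"] = res.mean_accuracy
            if config.n_reps > 0 and config.method != "cnn":
                accs, hist = repeated_cv(
                    stage_feats,
                    method=config.method,
                    n_reps=config.n_reps,
                    k=config.k,
                    seed=config.seed,
                )
                hpath = out / "accuracy_histogram.csv"
                hist.to_csv(hpath, index=False)
                _emit("accuracy_histogram", hpath)
                manifest["summary"]["repeated_cv_mean_accuracy"] = float(np.mean(accs))
    except Exception as err:
        raise RuntimeError("pipeline failed at stage 'evaluate'") from err

    try:
        with _stage_timer("stats"):
            screen = feature_screen(feats)
            spath = out / "feature_screen.csv"
            screen.to_csv(spath, index=False)
            _emit("feature_screen", spath)
            pca = pca_relevance(feats)
            manifest["summary"]["pca_retained_features"] = len(pca.retained_features)
            manifest["summary"]["mw_significant_fraction"] = float(screen["mw_significant"].mean())
    except Exception as err:
        raise RuntimeError("pipeline failed at stage 'stats'") from err

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    manifest["artifacts"]["manifest"] = str(mpath)
    return manifest
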