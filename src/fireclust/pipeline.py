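"""End-to-end pipeline: simulate/read -> cluster -> link -> metrics -> compare.

Stages run in a fixed order, each writing its outputs to the run directory
through a ``.partial`` temporary that is renamed only on stage success, so
an interrupted run leaves its partial products visible but never a
half-written final file. The manifest records the configuration hash, the
seed, the package version and per-file row counts, and contains no
timestamps: a rerun with the same configuration and seed is byte-identical.

All randomness comes from the single run seed through named child streams
(see :mod:`fireclust.synthetic`), so adding a stage never perturbs the
draws of an earlier one.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import NOISE
from .firms_io import (
    read_bases_csv,
    read_firms_csv,
    write_bases_csv,
    write_clusters_geojson,
    write_firms_csv,
    write_links_csv,
)
from .geodesy import medoid
from .linkage import (
    DEFAULT_D_FLOOR_KM,
    DEFAULT_RADIUS_KM,
    base_proximity_groups,
    base_summary,
    exposure_metrics,
    instrument_comparison,
    link_clusters_to_bases,
    persistence_timeline,
)
from .synthetic import (
    MODIS,
    VIIRS,
    SceneConfig,
    scene_bases,
    simulate_detections,
    simulate_sources,
)
from .tuning import DEFAULT_MAX_SHARE, annual_clustering

__all__ = ["RunConfig", "PipelineError", "load_config", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names the culprit."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    With ``fires`` unset, the synthetic scene in ``scene`` is simulated
    (and synthetic bases derived from it unless ``bases`` is given); with
    ``fires`` set, that FIRMS-dialect CSV is read and ``bases`` is
    required at the link stage.
    """

    out_dir: str = "fireclust_run"
    seed: int = 0
    fires: str | None = None
    bases: str | None = None
    k_min: int = 2
    k_max: int = 8
    max_share: float = DEFAULT_MAX_SHARE
    radius_km: float = DEFAULT_RADIUS_KM
    d_floor: float = DEFAULT_D_FLOOR_KM
    window_start: _dt.date | None = None
    window_end: _dt.date | None = None
    compare: bool = True
    log_level: str = "INFO"
    scene: SceneConfig = field(default_factory=SceneConfig)

    def __post_init__(self) -> None:
        if self.radius_km <= 0:
            raise ValueError("radius_km must be positive")
        if self.k_min < 2:
            raise ValueError("k range must start at 2 or above")


def _coerce_date(v):
    return v if (v is None or isinstance(v, _dt.date)) else _dt.date.fromisoformat(str(v))


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a flat key-value YAML config; keyword overrides win.

    Scene parameters use a ``scene_`` prefix (e.g. ``scene_n_flares: 2``);
    everything else maps straight onto :class:`RunConfig` fields.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    scene_kwargs = {}
    run_kwargs = {}
    scene_fields = {f.name for f in dataclasses.fields(SceneConfig)}
    run_fields = {f.name for f in dataclasses.fields(RunConfig)}
    for key, value in raw.items():
        if key.startswith("scene_") and key[6:] in scene_fields:
            scene_kwargs[key[6:]] = value
        elif key in run_fields:
            run_kwargs[key] = value
        else:
            raise ValueError(f"unknown config key: {key}")
    for k in ("start", "end"):
        if k in scene_kwargs:
            scene_kwargs[k] = _coerce_date(scene_kwargs[k])
    if "bbox" in scene_kwargs:
        scene_kwargs["bbox"] = tuple(scene_kwargs["bbox"])
    for k in ("window_start", "window_end"):
        if k in run_kwargs:
            run_kwargs[k] = _coerce_date(run_kwargs[k])
    run_kwargs["scene"] = SceneConfig(**scene_kwargs)
    return RunConfig(**run_kwargs)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if isinstance(o, _dt.date):
            return o.isoformat()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(type(o))

    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _commit(partial: Path) -> Path:
    final = partial.with_suffix("")
    os.replace(partial, final)
    return final


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    partial = path.with_suffix(path.suffix + ".partial")
    df.to_csv(partial, index=False, float_format="%.6g")
    return _commit(partial)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    def record(stage: str, files: dict[str, int]) -> None:
        manifest["stages"][stage] = {"files": {Path(f).name: n for f, n in files.items()}}

    # --- stage: simulate (or read) -------------------------------------
    stage = "simulate"
    try:
        if config.fires is None:
            sources = simulate_sources(config.scene, config.seed)
            detections, truth = simulate_detections(
                sources,
                MODIS,
                (config.scene.start, config.scene.end),
                config.seed,
                bbox=config.scene.bbox,
                background_rate_per_day=config.scene.background_rate_per_day,
                background_frp_median=config.scene.background_frp_median,
                background_frp_sigma=config.scene.background_frp_sigma,
            )
            fires_path = out / "fires.csv"
            partial = fires_path.with_suffix(".csv.partial")
            write_firms_csv(detections, partial)
            _commit(partial)
            truth_df = pd.DataFrame({"detection_index": range(len(truth)), "source_id": truth})
            _write_csv(truth_df, out / "truth.csv")
            if config.bases is None:
                bases = scene_bases(sources, config.seed)
                bpartial = (out / "bases.csv").with_suffix(".csv.partial")
                write_bases_csv(bases, bpartial)
                _commit(bpartial)
            record(stage, {"fires.csv": len(detections), "truth.csv": len(truth)})
        else:
            result = read_firms_csv(config.fires)
            detections = result.detections
            record(stage, {config.fires: len(detections)})
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: cluster -------------------------------------------------
    stage = "cluster"
    try:
        clusterings = annual_clustering(
            detections, (config.k_min, config.k_max), config.max_share
        )
        sweep_rows = []
        label_rows = []
        cluster_rows = []
        for year, yc in sorted(clusterings.items()):
            for r in yc.sweep or []:
                sweep_rows.append(
                    {
                        "year": year,
                        "k": r.k,
                        "n_clusters": r.n_clusters,
                        "n_noise": r.n_noise,
                        "noise_fraction": round(r.noise_fraction, 6),
                        "median_cluster_size": r.median_cluster_size,
                        "largest_cluster_share": round(r.largest_cluster_share, 6),
                        "selected": r.k == yc.k,
                    }
                )
            idx = yc.indices if yc.indices is not None else range(len(yc.labels))
            for pos, gi in enumerate(idx):
                d = detections[gi]
                label_rows.append(
                    {
                        "detection_index": int(gi),
                        "year": year,
                        "cluster": int(yc.labels[pos]),
                        "membership_prob": round(float(yc.membership_prob[pos]), 6),
                        "latitude": d.lat,
                        "longitude": d.lon,
                        "acq_date": d.acq_date.isoformat(),
                        "frp": d.frp,
                        "confidence": d.confidence,
                    }
                )
            for label in range(yc.n_clusters):
                pos = yc.cluster_members(label)
                pts = [detections[int(np.asarray(idx)[p])].point for p in pos]
                med = medoid(pts)
                frp = [detections[int(np.asarray(idx)[p])].frp for p in pos]
                cluster_rows.append(
                    {
                        "year": year,
                        "cluster": label,
                        "n_fires": len(pos),
                        "medoid_lat": round(med.lat, 6),
                        "medoid_lon": round(med.lon, 6),
                        "median_frp": float(pd.Series(frp).median()),
                    }
                )
        _write_csv(pd.DataFrame(sweep_rows), out / "sweeps.csv")
        _write_csv(pd.DataFrame(label_rows), out / "labels.csv")
        _write_csv(pd.DataFrame(cluster_rows), out / "clusters.csv")
        gpartial = (out / "clusters.geojson").with_suffix(".geojson.partial")
        write_clusters_geojson(clusterings, detections, gpartial)
        _commit(gpartial)
        record(stage, {"labels.csv": len(label_rows), "clusters.csv": len(cluster_rows),
                       "sweeps.csv": len(sweep_rows)})
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: link ----------------------------------------------------
    stage = "link"
    try:
        if config.bases is not None:
            bases = read_bases_csv(config.bases)
        elif config.fires is None:
            bases = read_bases_csv(out / "bases.csv")
        else:
            raise FileNotFoundError("no bases file configured")
        links = link_clusters_to_bases(clusterings, detections, bases, config.radius_km)
        lpartial = (out / "links.csv").with_suffix(".csv.partial")
        write_links_csv(links, lpartial)
        _commit(lpartial)
        groups = base_proximity_groups(bases, config.radius_km)
        group_rows = [
            {"group": gi, "base_id": bid} for gi, g in enumerate(groups) for bid in g
        ]
        _write_csv(pd.DataFrame(group_rows), out / "base_groups.csv")
        per_base, rollup = base_summary(links, detections, bases)
        _write_csv(per_base, out / "base_summary.csv")
        _write_csv(rollup, out / "base_rollup.csv")
        record(stage, {"links.csv": len(links), "base_summary.csv": len(per_base)})
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: timelines ----------------------------------------------
    stage = "timelines"
    try:
        timelines = persistence_timeline(links, detections)
        tl_rows = [
            {
                "base_id": t.base_id,
                "years": ";".join(str(y) for y in t.years_with_clusters),
                "n_years": t.n_years,
                "total_linked_fires": t.total_linked_fires,
                "total_clusters": t.total_clusters,
                "median_frp": t.median_frp,
                "iqr_frp": t.iqr_frp,
                "median_confidence": t.median_confidence,
                "iqr_confidence": t.iqr_confidence,
                "median_membership_prob": t.median_membership_prob,
                "iqr_membership_prob": t.iqr_membership_prob,
            }
            for t in timelines
        ]
        _write_csv(pd.DataFrame(tl_rows), out / "timelines.csv")
        record(stage, {"timelines.csv": len(tl_rows)})
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: exposure -------------------------------------------------
    stage = "exposure"
    try:
        if config.window_start is not None and config.window_end is not None:
            window = (config.window_start, config.window_end)
        elif detections:
            window = (min(d.acq_date for d in detections), max(d.acq_date for d in detections))
        else:
            window = (config.scene.start, config.scene.end)
        records = exposure_metrics(links, detections, window, config.d_floor, config.radius_km)
        exp_rows = [
            {
                "base_id": r.base_id,
                "window_start": r.window[0].isoformat(),
                "window_end": r.window[1].isoformat(),
                "presence": r.presence,
                "fire_count": r.fire_count,
                "idw_sum": round(r.idw_sum, 6),
                "median_frp": r.median_frp,
            }
            for r in records
        ]
        _write_csv(pd.DataFrame(exp_rows), out / "exposure.csv")
        record(stage, {"exposure.csv": len(exp_rows)})
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: compare --------------------------------------------------
    stage = "compare"
    try:
        if config.compare and config.fires is None:
            pits = [s for s in sources if s.kind == "burn_pit"]
            if pits:
                site = pits[0].location
                viirs_dets, _ = simulate_detections(
                    pits[:1], VIIRS, (config.scene.start, config.scene.end), config.seed
                )
                modis_pit = [
                    d for d, t in zip(detections, truth) if t == pits[0].source_id
                ]
                comp = instrument_comparison(
                    {"MODIS": modis_pit, "VIIRS": viirs_dets},
                    site,
                    config.radius_km,
                    (config.k_min, config.k_max),
                    config.max_share,
                )
                comp_rows = [
                    {"instrument": name, **stats} for name, stats in sorted(comp.stats.items())
                ]
                for row in comp_rows:
                    row["ratio_viirs_over_modis"] = (
                        round(comp.ratio, 6) if comp.ratio is not None else ""
                    )
                _write_csv(pd.DataFrame(comp_rows), out / "compare.csv")
                record(stage, {"compare.csv": len(comp_rows)})
            else:
                record(stage, {})
        else:
            record(stage, {})
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # conservation check: every detection is clustered or noise, once
    n_labeled = sum(len(yc.labels) for yc in clusterings.values())
    n_noise = sum(int((yc.labels == NOISE).sum()) for yc in clusterings.values())
    manifest["counts"] = {
        "detections": len(detections),
        "labeled": n_labeled,
        "clustered": n_labeled - n_noise,
        "noise": n_noise,
        "links": len(links),
    }
    if n_labeled != len(detections):  # pragma: no cover - invariant guard
        raise PipelineError("cluster", "label count does not match detection count")

    mpartial = (out / "manifest.json").with_suffix(".json.partial")
    mpartial.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    _commit(mpartial)
    return manifest
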