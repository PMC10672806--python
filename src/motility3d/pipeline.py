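"""End-to-end orchestration: load -> resample -> metrics -> group statistics.

:func:`run_analysis` reproduces the full analysis surface of a multi-tissue
motility study on any track table: per-cell metrics, per-tissue median
summaries, persistence tables, turning-angle histograms and speed-vs-angle
profiles, pairwise p-value matrices (rank-sum per metric, plus a KS matrix
for the patrolled-volume distribution), intra-/inter-tissue ANOVA with
greedy outlier-frame reduction, and a machine-readable run manifest.  All
outputs are deterministic for a fixed input and configuration.
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
import yaml

from . import __version__
from .io import TrackSet, read_tracks
from .metrics import (
    MetricParams,
    angle_histogram,
    compute_all,
    fraction_below,
    persistence_table,
    speed_angle_profile,
)
from .resample import ResampleSpec, resample_trackset, timestep_summary
from .stats import intra_inter_anova, pairwise_ks, pairwise_ranksum, reduce_outlier_frames

__all__ = ["RunConfig", "run_analysis", "summarize_medians", "PAIRWISE_METRICS"]

log = logging.getLogger(__name__)

#: per-cell metrics compared pairwise between tissues with the rank-sum test
PAIRWISE_METRICS = (
    "cell_speed",
    "displacement_speed",
    "msd_slope",
    "meandering_ratio",
    "confined_ratio",
    "confined_time_min",
    "volume_rate",
    "angle_frac_below_90",
)

MEDIAN_COLUMNS = (
    "cell_speed",
    "displacement_speed",
    "meandering_ratio",
    "msd_slope",
    "confined_ratio",
    "confined_time_min",
    "volume_rate",
)


@dataclass
class RunConfig:
    """Everything a run needs; round-trips through YAML.

    All thresholds carry the standard defaults (90 s step, 1 µm/min angle
    exclusion, 9° bins, 10.5 min MSD cap, 5 µm / 150 s confinement, 2.5 µm
    voxels with 5 µm reach in a 400 µm domain); nothing is hidden.
    """

    input: str = ""
    dialect: dict = field(default_factory=dict)
    target_dt: float = 90.0
    dt_tolerance: float = 10.0
    min_speed: float = 1.0
    angle_bin: float = 9.0
    msd_cap_min: float = 10.5
    confine_radius: float = 5.0
    confine_dwell_s: float = 150.0
    voxel: float = 2.5
    reach: float = 5.0
    domain: float = 400.0
    persistence_max_bin: float = 12.0
    correction: str = "bonferroni"
    anova_metric: str = "cell_speed"
    reduction_p_threshold: float = 1e-4
    reduction_max_frac: float = 0.55
    outdir: str = "motility3d_out"
    seed: int = 0
    log_level: str = "INFO"

    def metric_params(self) -> MetricParams:
        return MetricParams(
            min_speed=self.min_speed,
            angle_bin=self.angle_bin,
            msd_cap_min=self.msd_cap_min,
            confine_radius=self.confine_radius,
            confine_dwell_s=self.confine_dwell_s,
            voxel=self.voxel,
            reach=self.reach,
            domain=self.domain,
        )

    def resample_spec(self) -> ResampleSpec:
        return ResampleSpec(target_dt=self.target_dt, tolerance=self.dt_tolerance)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def summarize_medians(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue medians of all per-cell metrics, over defined values only.

    Reports the number of cells and, per metric, the count of defined
    (non-missing) values entering the median.  Empty tissues are omitted.
    """
    rows = []
    for tissue, grp in metrics.groupby("tissue", sort=True):
        row: dict = {"tissue": tissue, "n_cells": int(len(grp))}
        for col in MEDIAN_COLUMNS:
            vals = grp[col].dropna()
            row[f"median_{col}"] = float(vals.median()) if len(vals) else float("nan")
            row[f"n_{col}"] = int(len(vals))
        rows.append(row)
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def run_analysis(cfg: RunConfig, tracks: TrackSet | None = None) -> dict:
    """Run the full pipeline and write the report bundle to ``cfg.outdir``.

    ``tracks`` may be passed directly (e.g. a freshly simulated cohort);
    otherwise ``cfg.input`` is loaded.  Returns the bundle as a dict of
    in-memory objects keyed by output name.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if tracks is None:
        if not cfg.input:
            raise ValueError("stage load: no input path configured and no TrackSet given")
        log.info("stage load: %s", cfg.input)
        tracks = read_tracks(cfg.input, dialect=cfg.dialect or None)

    log.info("stage resample: target %.0f s", cfg.target_dt)
    resampled = resample_trackset(tracks, cfg.resample_spec())
    steps_summary = timestep_summary(resampled)
    _write_csv(steps_summary, outdir / "timestep_summary.csv")

    log.info("stage metrics: %d tracks", len(resampled))
    params = cfg.metric_params()
    metrics, steps = compute_all(resampled, params)
    _write_csv(metrics, outdir / "cell_metrics.csv")
    _write_csv(steps, outdir / "step_table.csv")

    medians = summarize_medians(metrics)
    _write_csv(medians, outdir / "tissue_medians.csv")

    log.info("stage distributions")
    persistence = {}
    angle_hist = {}
    profile = {}
    for tissue in resampled.tissues:
        sub = resampled.subset(tissue=tissue)
        tsteps = steps[steps["tissue"] == tissue]
        try:
            pt = persistence_table(sub, max_bin=cfg.persistence_max_bin)
            persistence[tissue] = pt
            _write_csv(pt.table, outdir / f"persistence_{tissue}.csv")
        except ValueError as e:
            log.warning("persistence skipped for %s: %s", tissue, e)
        if tsteps["included"].any():
            angle_hist[tissue] = angle_histogram(tsteps, cfg.angle_bin)
            profile[tissue] = speed_angle_profile(tsteps, cfg.angle_bin)
            _write_csv(angle_hist[tissue], outdir / f"angle_histogram_{tissue}.csv")
            _write_csv(profile[tissue], outdir / f"speed_angle_profile_{tissue}.csv")

    log.info("stage pairwise tests")
    frac = fraction_below(steps, threshold=90.0)
    per_cell = metrics.merge(
        frac.rename(columns={"fraction": "angle_frac_below_90"}),
        on=["cell_id", "frame_id", "tissue"],
        how="left",
    )
    pairwise = {}
    if len(resampled.tissues) >= 2:
        for metric in PAIRWISE_METRICS:
            groups = {
                t: g[metric].dropna().to_numpy()
                for t, g in per_cell.groupby("tissue", sort=True)
            }
            groups = {t: v for t, v in groups.items() if v.size > 0}
            if len(groups) < 2:
                continue
            pm = pairwise_ranksum(groups, correction=cfg.correction)
            pairwise[metric] = pm
            pm.to_dataframe().to_csv(outdir / f"pairwise_ranksum_{metric}.csv")
        vol_groups = {
            t: g["volume_rate"].dropna().to_numpy()
            for t, g in per_cell.groupby("tissue", sort=True)
        }
        vol_groups = {t: v for t, v in vol_groups.items() if v.size > 0}
        if len(vol_groups) >= 2:
            km = pairwise_ks(vol_groups, correction=cfg.correction)
            pairwise["volume_rate_ks"] = km
            km.to_dataframe().to_csv(outdir / "pairwise_ks_volume_rate.csv")

    log.info("stage anova/reduction on %s", cfg.anova_metric)
    intra, inter = intra_inter_anova(metrics, cfg.anova_metric)
    anova_rows = []
    for tissue, res in intra.items():
        anova_rows.append(
            {"scope": "intra", "group": tissue, "F": res.F, "p": res.p,
             "n_groups": len(res.group_sizes), "n_values": sum(res.group_sizes.values())}
        )
    if inter is not None:
        anova_rows.append(
            {"scope": "inter", "group": "all", "F": inter.F, "p": inter.p,
             "n_groups": len(inter.group_sizes), "n_values": sum(inter.group_sizes.values())}
        )
    anova_df = pd.DataFrame(anova_rows)
    _write_csv(anova_df, outdir / "anova.csv")

    reductions = {}
    reduction_rows = []
    kept_tracks = []
    for tissue in resampled.tissues:
        n_frames = metrics.loc[metrics["tissue"] == tissue, "frame_id"].nunique()
        if n_frames < 3:
            log.info("reduction skipped for %s (%d frames)", tissue, n_frames)
            kept_tracks.extend(resampled.subset(tissue=tissue).tracks)
            continue
        kept_frames, report = reduce_outlier_frames(
            metrics,
            cfg.anova_metric,
            tissue,
            p_threshold=cfg.reduction_p_threshold,
            max_removed_frac=cfg.reduction_max_frac,
        )
        reductions[tissue] = report
        kept_tracks.extend(resampled.subset(tissue=tissue, frame_ids=kept_frames).tracks)
        reduction_rows.append(
            {
                "tissue": tissue,
                "n_removed": len(report.removed),
                "removed_frames": ";".join(report.removed),
                "p_initial": report.p_trajectory[0],
                "p_final": report.p_trajectory[-1],
                "retained_cells": report.retained_cells,
                "converged": report.converged,
            }
        )
    reduction_df = pd.DataFrame(
        reduction_rows,
        columns=["tissue", "n_removed", "removed_frames", "p_initial", "p_final",
                 "retained_cells", "converged"],
    )
    _write_csv(reduction_df, outdir / "frame_reduction.csv")

    reduced_metrics = None
    inter_reduced = None
    if reductions:
        kept = {(tr.frame_id, tr.cell_id) for tr in kept_tracks}
        reduced_metrics = metrics[
            [(f, c) in kept for f, c in zip(metrics["frame_id"], metrics["cell_id"])]
        ]
        if reduced_metrics["tissue"].nunique() >= 2:
            _, inter_reduced = intra_inter_anova(reduced_metrics, cfg.anova_metric)

    cfg_dict = dataclasses.asdict(cfg)
    manifest = {
        "package": "motility3d",
        "version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "n_tracks_in": len(tracks),
        "n_tracks_resampled": len(resampled),
        "n_dropped_short_tracks": tracks.metadata.get("n_dropped_short_tracks", 0),
        "n_dropped_resample": resampled.metadata.get("n_dropped_resample", 0),
        "n_msd_undefined": metrics.attrs.get("n_msd_undefined", 0),
        "n_volume_excluded": metrics.attrs.get("n_volume_excluded", 0),
        "n_zero_length_steps": metrics.attrs.get("n_zero_steps", 0),
        "n_steps_excluded_slow": int((~steps["included"]).sum()) if len(steps) else 0,
        "inter_anova_p_reduced": None if inter_reduced is None else inter_reduced.p,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "trackset": resampled,
        "timestep_summary": steps_summary,
        "metrics": metrics,
        "steps": steps,
        "medians": medians,
        "per_cell": per_cell,
        "persistence": persistence,
        "angle_histogram": angle_hist,
        "speed_angle_profile": profile,
        "pairwise": pairwise,
        "anova_intra": intra,
        "anova_inter": inter,
        "reductions": reductions,
        "reduced_metrics": reduced_metrics,
        "anova_inter_reduced": inter_reduced,
        "manifest": manifest,
    }
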