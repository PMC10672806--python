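"""Time-step normalisation to a common nominal sampling interval.

Different imaging sessions acquire at different rates (e.g. 45 s vs 90 s
between volumes).  To make step-based metrics comparable across tissues the
positions are re-sampled to a nominal step (default 90 s).  Data already at
the target step are passed through unchanged.

For a series acquired faster than the target, *phase-complete subsampling*
is used: with native step d and stride k = round(target/d), the series
{t0, t1, t2, ...} is split into k interleaved subsamples {t0, tk, t2k, ...},
{t1, tk+1, ...}, ..., so that every observation is used exactly once and no
data are discarded.  Each phase becomes its own track (cell id suffixed with
the phase index).  Selection is greedy nearest-time from each phase anchor,
which also accommodates jittered acquisition clocks; positions are never
interpolated — every output point is an input point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Track, TrackSet

__all__ = ["ResampleSpec", "resample_track", "resample_trackset", "timestep_summary"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResampleSpec:
    """Target nominal time step and the deviation tolerated when matching samples.

    target_dt : seconds, > 0 (default 90, the common two-photon volume rate)
    tolerance : seconds, >= 0; a track whose median native step is within
        ``tolerance`` of ``target_dt`` is passed through unchanged.
    """

    target_dt: float = 90.0
    tolerance: float = 10.0

    def __post_init__(self) -> None:
        if not self.target_dt > 0:
            raise ValueError("target_dt must be positive")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")


def resample_track(tr: Track, spec: ResampleSpec = ResampleSpec()) -> list[Track]:
    """Resample one track to the nominal step.

    Returns the track unchanged (singleton list) if its median native step
    already matches ``spec.target_dt`` within tolerance; otherwise one track
    per phase offset (stride k = round(target/native median)), each greedily
    selecting the available sample nearest to successive multiples of the
    target step.  Phases yielding fewer than 2 points are dropped; an empty
    list means the track was too short to resample.
    """
    steps = np.diff(tr.t)
    native = float(np.median(steps))
    if abs(native - spec.target_dt) <= spec.tolerance:
        return [tr]
    k = max(1, int(round(spec.target_dt / native)))
    out: list[Track] = []
    for phase in range(min(k, tr.n_points)):
        idx = [phase]
        while True:
            last = idx[-1]
            rest = np.arange(last + 1, tr.n_points)
            if rest.size == 0:
                break
            target_t = tr.t[last] + spec.target_dt
            j = int(rest[np.argmin(np.abs(tr.t[rest] - target_t))])
            if abs(tr.t[j] - target_t) > spec.tolerance:
                break  # no sample near the next nominal time: phase ends
            idx.append(j)
        if len(idx) >= 2:
            sel = np.asarray(idx)
            out.append(
                Track(
                    cell_id=f"{tr.cell_id}.p{phase}",
                    frame_id=tr.frame_id,
                    tissue=tr.tissue,
                    t=tr.t[sel],
                    xyz=tr.xyz[sel],
                )
            )
    return out


def resample_trackset(ts: TrackSet, spec: ResampleSpec = ResampleSpec()) -> TrackSet:
    """Apply :func:`resample_track` to every track, keeping group structure.

    Dropped-track counts are recorded in ``metadata['n_dropped_resample']``.
    """
    tracks: list[Track] = []
    n_dropped = 0
    for tr in ts:
        res = resample_track(tr, spec)
        if not res:
            n_dropped += 1
            log.info("resample dropped track %s/%s (too short)", tr.frame_id, tr.cell_id)
        tracks.extend(res)
    meta = dict(ts.metadata)
    meta.update(nominal_dt_s=spec.target_dt, n_dropped_resample=n_dropped)
    return TrackSet(tracks, meta)


def timestep_summary(ts: TrackSet) -> pd.DataFrame:
    """Per-tissue mean and standard deviation of realised time steps (seconds).

    Pooled over all consecutive point pairs of all tracks of a tissue; the
    standard deviation is the population (ddof=0) value over the pooled steps.
    Tissues contributing no steps are omitted.
    """
    rows = []
    by_tissue: dict[str, list[np.ndarray]] = {}
    for tr in ts:
        by_tissue.setdefault(tr.tissue, []).append(np.diff(tr.t))
    for tissue in sorted(by_tissue):
        steps = np.concatenate(by_tissue[tissue])
        if steps.size == 0:
            log.warning("tissue %s has no time steps; omitted from summary", tissue)
            continue
        rows.append(
            {
                "tissue": tissue,
                "n_steps": int(steps.size),
                "mean_step_s": float(steps.mean()),
                "sd_step_s": float(steps.std(ddof=0)),
            }
        )
    return pd.DataFrame(rows, columns=["tissue", "n_steps", "mean_step_s", "sd_step_s"])
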