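"""Per-cell and per-step motility metrics for 3D cell trajectories.

All positions are in micrometres and times in seconds; speeds are reported
in µm/min and volumes in µm³.  The metrics:

* **cell speed** — total path length over total elapsed time.
* **displacement speed** — straight-line first-to-last distance over
  elapsed time; always ≤ cell speed.
* **meandering ratio** — net displacement over path length, in [0, 1];
  1 means perfectly straight motion.  Satisfies the algebraic identity
  ``meandering_ratio × cell_speed = displacement_speed``.
* **turning angle** — angle between consecutive displacement vectors,
  0–180°; a peak near 180° signals "back and forth" reversing motion.
  Angles whose associated speed (mean of incoming and outgoing step speeds)
  is below a threshold (default 1 µm/min) are flagged excluded: a nearly
  stopped cell's turning angle is dominated by localisation noise and the
  pixel grid.
* **persistence likelihood** — fold increase in the probability that a
  step's speed falls in a 1 µm/min bin given the previous step's speed fell
  in the same bin, relative to the marginal probability of that bin.
  Ratios of 1 mean consecutive speeds are independent; ratios above 1 mean
  the cell tends to persist at its speed.
* **MSD exponent** — slope of log squared displacement from the starting
  point versus log elapsed time (capped by default at 10.5 min): ≈1
  diffusive/Brownian, in (1, 2] superdiffusive (Lévy-like), < 1
  subdiffusive, exactly 2 for straight constant-speed motion.
* **confinement** — anchor-scan dwell analysis in a 5 µm ball:
  *confined ratio* is the fraction of tracked time spent in dwells longer
  than 150 s; *confined time* is the mean time to first exit the ball
  around each position.
* **patrolled-volume rate** — volume of 2.5 µm voxels whose centres pass
  within 5 µm of the cell (including along straight segments joining
  successive positions) per second of tracking.

Metrics that are undefined for a track (e.g. MSD slope on 2 points) are
returned as NaN markers and excluded pairwise downstream, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import Track, TrackSet

__all__ = [
    "MetricParams",
    "PersistenceTable",
    "step_distances",
    "step_speeds",
    "cell_speed",
    "displacement_speed",
    "meandering_ratio",
    "turning_angles",
    "step_table",
    "angle_histogram",
    "fraction_below",
    "speed_angle_profile",
    "persistence_table",
    "persistence_from_speeds",
    "msd_slope",
    "confinement",
    "volume_rate",
    "compute_all",
]

log = logging.getLogger(__name__)

SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class MetricParams:
    """All metric thresholds, surfaced with their standard defaults.

    min_speed        µm/min; turning angles below this associated speed are excluded
    angle_bin        degrees; histogram/profile bin width
    msd_cap_min      minutes; maximum elapsed time entering the MSD regression
    confine_radius   µm; ball radius for confinement
    confine_dwell_s  seconds; minimum dwell counted as confined
    voxel            µm; patrolled-volume voxel edge
    reach            µm; distance within which a voxel centre counts as patrolled
    domain           µm; cubic domain edge for the voxel grid
    """

    min_speed: float = 1.0
    angle_bin: float = 9.0
    msd_cap_min: float = 10.5
    confine_radius: float = 5.0
    confine_dwell_s: float = 150.0
    voxel: float = 2.5
    reach: float = 5.0
    domain: float = 400.0


# ---------------------------------------------------------------------------
# step-level primitives


def step_distances(tr: Track) -> np.ndarray:
    """Euclidean 3D distances between consecutive positions (µm), length n-1."""
    return np.linalg.norm(np.diff(tr.xyz, axis=0), axis=1)


def step_speeds(tr: Track) -> np.ndarray:
    """Per-step speeds in µm/min, length n-1."""
    return step_distances(tr) / np.diff(tr.t) * SECONDS_PER_MINUTE


def cell_speed(tr: Track) -> float:
    """Total path length over total elapsed time, µm/min (NaN if zero duration)."""
    dt = tr.duration_s
    if dt <= 0:
        return float("nan")
    return float(step_distances(tr).sum() / dt * SECONDS_PER_MINUTE)


def displacement_speed(tr: Track) -> float:
    """First-to-last straight-line distance over elapsed time, µm/min."""
    dt = tr.duration_s
    if dt <= 0:
        return float("nan")
    d = float(np.linalg.norm(tr.xyz[-1] - tr.xyz[0]))
    return d / dt * SECONDS_PER_MINUTE


def meandering_ratio(tr: Track) -> float:
    """Net displacement over path length, in [0, 1] (NaN for zero path length)."""
    path = float(step_distances(tr).sum())
    if path <= 0:
        return float("nan")
    return float(np.linalg.norm(tr.xyz[-1] - tr.xyz[0]) / path)


def turning_angles(tr: Track, min_speed: float = 1.0) -> pd.DataFrame:
    """Turning angles between consecutive displacement vectors.

    For each interior position the angle (degrees, [0, 180]) between the
    incoming vector v1 and outgoing vector v2 is
    ``arccos(v1·v2 / (|v1||v2|))``: 0° is straight-ahead motion, 180° a full
    reversal.  Triples with a zero-length v1 or v2 are skipped (angle
    undefined); the skip count is in ``df.attrs['n_zero_steps']``.

    The *associated speed* of an angle is the mean of the incoming and
    outgoing step speeds; records with associated speed below ``min_speed``
    are kept but flagged ``included=False``.
    """
    vec = np.diff(tr.xyz, axis=0)
    norms = np.linalg.norm(vec, axis=1)
    spd = step_speeds(tr)
    rows = []
    n_zero = 0
    for i in range(len(vec) - 1):
        if norms[i] == 0 or norms[i + 1] == 0:
            n_zero += 1
            continue
        cosang = np.dot(vec[i], vec[i + 1]) / (norms[i] * norms[i + 1])
        ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        assoc = 0.5 * (spd[i] + spd[i + 1])
        rows.append(
            {
                "cell_id": tr.cell_id,
                "frame_id": tr.frame_id,
                "tissue": tr.tissue,
                "angle_deg": ang,
                "speed_in": float(spd[i]),
                "speed_out": float(spd[i + 1]),
                "step_speed": float(assoc),
                "included": bool(assoc >= min_speed),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "frame_id",
            "tissue",
            "angle_deg",
            "speed_in",
            "speed_out",
            "step_speed",
            "included",
        ],
    )
    df.attrs["n_zero_steps"] = n_zero
    return df


def step_table(ts: TrackSet, min_speed: float = 1.0) -> pd.DataFrame:
    """Pooled per-step turning-angle records for all tracks with ≥3 points."""
    parts = []
    n_zero = 0
    for tr in ts:
        if tr.n_points < 3:
            continue
        df = turning_angles(tr, min_speed=min_speed)
        n_zero += df.attrs["n_zero_steps"]
        if len(df):
            parts.append(df)
    if parts:
        out = pd.concat(parts, ignore_index=True)
    else:
        out = pd.DataFrame(
            columns=[
                "cell_id",
                "frame_id",
                "tissue",
                "angle_deg",
                "speed_in",
                "speed_out",
                "step_speed",
                "included",
            ]
        )
    out.attrs["n_zero_steps"] = n_zero
    return out


def _angle_bins(bin_width: float) -> np.ndarray:
    n = int(np.ceil(180.0 / bin_width))
    return np.linspace(0.0, n * bin_width, n + 1)


def angle_histogram(steps: pd.DataFrame, bin_width: float = 9.0) -> pd.DataFrame:
    """Relative frequency of included turning angles per bin (frequencies sum to 1)."""
    ang = steps.loc[steps["included"], "angle_deg"].to_numpy()
    if ang.size == 0:
        raise ValueError("no included turning angles to histogram")
    edges = _angle_bins(bin_width)
    counts, _ = np.histogram(ang, bins=edges)
    # np.histogram's last bin is closed, so 180° lands in the final bin
    return pd.DataFrame(
        {
            "bin_lo_deg": edges[:-1],
            "bin_hi_deg": edges[1:],
            "count": counts,
            "frequency": counts / counts.sum(),
        }
    )


def fraction_below(steps: pd.DataFrame, threshold: float = 90.0) -> pd.DataFrame:
    """Per-cell proportion of included turning angles below ``threshold`` degrees.

    Cells without any included angle are omitted.
    """
    inc = steps[steps["included"]]
    if len(inc) == 0:
        return pd.DataFrame(columns=["cell_id", "frame_id", "tissue", "fraction"])
    grp = inc.groupby(["frame_id", "cell_id", "tissue"], sort=True)["angle_deg"]
    out = grp.apply(lambda a: float(np.mean(a < threshold))).reset_index(name="fraction")
    return out[["cell_id", "frame_id", "tissue", "fraction"]]


def speed_angle_profile(steps: pd.DataFrame, bin_width: float = 9.0) -> pd.DataFrame:
    """Mean associated step speed per turning-angle bin.

    Returns per bin the mean speed (µm/min), population standard deviation,
    sd/8 (the conventional half-error-bar for these crowded profiles) and
    count; empty bins are reported with count 0 and NaN statistics.
    """
    inc = steps[steps["included"]]
    edges = _angle_bins(bin_width)
    idx = np.clip(np.digitize(inc["angle_deg"].to_numpy(), edges) - 1, 0, len(edges) - 2)
    spd = inc["step_speed"].to_numpy()
    rows = []
    for b in range(len(edges) - 1):
        sel = spd[idx == b]
        rows.append(
            {
                "bin_lo_deg": edges[b],
                "bin_hi_deg": edges[b + 1],
                "count": int(sel.size),
                "mean_speed": float(sel.mean()) if sel.size else float("nan"),
                "sd_speed": float(sel.std(ddof=0)) if sel.size else float("nan"),
                "sd_over_8": float(sel.std(ddof=0) / 8) if sel.size else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence likelihood


@dataclass
class PersistenceTable:
    """Per-speed-bin persistence likelihood ratios.

    For bin i (width 1 µm/min, top bin open-ended), over m pooled pairs of
    consecutive step speeds (s_before, s_after):

    * ``m_b`` — pairs with s_before in bin i,
    * ``m_a`` — pairs with s_after in bin i,
    * ``m_ab`` — pairs with both in bin i,
    * ``ratio`` — (m · m_ab) / (m_a · m_b) = P(after in i | before in i) / P(after in i),

    NaN where ``m_a · m_b`` is zero.  Ratio 1 means speed at one step carries
    no information about the next; above 1, the cell persists at that speed.
    """

    table: pd.DataFrame
    m: int
    bin_width: float = 1.0

    def __post_init__(self) -> None:
        bad = self.table.dropna(subset=["ratio"])
        assert (bad["m_ab"] <= np.minimum(bad["m_a"], bad["m_b"])).all()


def _persistence_from_pairs(
    s_before: np.ndarray, s_after: np.ndarray, bin_width: float, max_bin: float
) -> PersistenceTable:
    if s_before.size == 0:
        raise ValueError("no consecutive speed pairs")
    n_bins = int(np.ceil(max_bin / bin_width))
    bi = np.minimum((s_before / bin_width).astype(int), n_bins - 1)
    ai = np.minimum((s_after / bin_width).astype(int), n_bins - 1)
    m = s_before.size
    rows = []
    for b in range(n_bins):
        m_b = int(np.sum(bi == b))
        m_a = int(np.sum(ai == b))
        m_ab = int(np.sum((bi == b) & (ai == b)))
        ratio = m * m_ab / (m_a * m_b) if m_a * m_b > 0 else float("nan")
        rows.append(
            {
                "bin_lo": b * bin_width,
                "bin_hi": (b + 1) * bin_width if b < n_bins - 1 else float("inf"),
                "m_b": m_b,
                "m_a": m_a,
                "m_ab": m_ab,
                "ratio": ratio,
            }
        )
    return PersistenceTable(pd.DataFrame(rows), m=m, bin_width=bin_width)


def persistence_from_speeds(
    speeds: np.ndarray, bin_width: float = 1.0, max_bin: float = 12.0
) -> PersistenceTable:
    """Persistence table from a single ordered speed sequence (pairs = consecutive)."""
    speeds = np.asarray(speeds, dtype=float)
    return _persistence_from_pairs(speeds[:-1], speeds[1:], bin_width, max_bin)


def persistence_table(
    ts: TrackSet, bin_width: float = 1.0, max_bin: float = 12.0
) -> PersistenceTable:
    """Persistence likelihood over all consecutive same-cell step-speed pairs in ``ts``."""
    before, after = [], []
    for tr in ts:
        s = step_speeds(tr)
        if s.size >= 2:
            before.append(s[:-1])
            after.append(s[1:])
    if not before:
        raise ValueError("no track contributes a consecutive speed pair")
    return _persistence_from_pairs(
        np.concatenate(before), np.concatenate(after), bin_width, max_bin
    )


# ---------------------------------------------------------------------------
# MSD exponent


def msd_slope(tr: Track, max_elapsed_min: float = 10.5) -> float:
    """Log-log slope of squared displacement from the starting point vs elapsed time.

    Only displacements from the first position enter (no time-averaged
    overlapping windows); elapsed times are capped at ``max_elapsed_min``
    minutes; zero displacements are excluded (log undefined).  Returns NaN
    when fewer than 3 usable points remain.  The slope is invariant to the
    logarithm base and to rigid-body motions of the track.
    """
    elapsed = (tr.t[1:] - tr.t[0]) / SECONDS_PER_MINUTE
    d2 = np.sum((tr.xyz[1:] - tr.xyz[0]) ** 2, axis=1)
    ok = (elapsed > 0) & (elapsed <= max_elapsed_min) & (d2 > 0)
    if np.sum(ok) < 3:
        return float("nan")
    res = sps.linregress(np.log(elapsed[ok]), np.log(d2[ok]))
    return float(res.slope)


# ---------------------------------------------------------------------------
# confinement


def confinement(
    tr: Track, radius: float = 5.0, min_dwell_s: float = 150.0
) -> tuple[float, float]:
    """Confined ratio and confined time of one track.

    *Confined ratio* — anchor scan: starting from the first position, the
    cell dwells while it stays within ``radius`` of the anchor; if the dwell
    (anchor entry to last position still inside) exceeds ``min_dwell_s`` the
    entire dwell counts as confined.  When the cell exits, the scan restarts
    at the exit position.  Ratio = confined time / total tracked time.

    *Confined time* — for every position as anchor, the time until the track
    first leaves the ball around it (censored at track end for anchors never
    exited), averaged over all positions; reported in **minutes**.
    """
    t, xyz = tr.t, tr.xyz
    n = tr.n_points
    total = tr.duration_s
    confined_s = 0.0
    i = 0
    while i < n - 1:
        j = i + 1
        while j < n and np.linalg.norm(xyz[j] - xyz[i]) < radius:
            j += 1
        dwell = t[j - 1] - t[i]
        if dwell > min_dwell_s:
            confined_s += dwell
        i = j  # restart the scan at the exit position
    ratio = confined_s / total if total > 0 else float("nan")

    exit_times = np.empty(n)
    for a in range(n):
        d = np.linalg.norm(xyz[a + 1 :] - xyz[a], axis=1)
        out = np.nonzero(d >= radius)[0]
        exit_times[a] = (t[a + 1 + out[0]] - t[a]) if out.size else (t[-1] - t[a])
    confined_time_min = float(exit_times.mean() / SECONDS_PER_MINUTE)
    return float(ratio), confined_time_min


# ---------------------------------------------------------------------------
# patrolled volume


def _sample_polyline(xyz: np.ndarray, spacing: float) -> np.ndarray:
    """Vertices plus points every ``spacing`` µm along each straight segment."""
    pts = [xyz[0]]
    for a, b in zip(xyz[:-1], xyz[1:]):
        seg = b - a
        length = float(np.linalg.norm(seg))
        if length > 0:
            n = int(np.ceil(length / spacing))
            frac = np.arange(1, n + 1) / n
            pts.extend(a + frac[:, None] * seg)
        else:
            pts.append(b)
    return np.asarray(pts)


def volume_rate(
    tr: Track,
    voxel: float = 2.5,
    reach: float = 5.0,
    domain: float = 400.0,
) -> float:
    """Rate of volume patrolled, µm³/s.

    The cubic domain is divided into ``voxel``-edge cubes; the track is
    translated so its bounding box is centred in the domain (the voxel grid
    stays registered to the domain origin, voxel centres at (i+½)·voxel).  A
    voxel is patrolled when its centre lies within ``reach`` of any observed
    position or any point sampled every voxel/2 along the straight segments
    joining successive positions.  Volume = patrolled count × voxel³; rate =
    volume / tracked time.
    """
    if tr.duration_s <= 0:
        raise ValueError(f"track {tr.cell_id!r}: zero tracked time")
    lo = tr.xyz.min(axis=0)
    hi = tr.xyz.max(axis=0)
    if np.any(hi - lo > domain):
        raise ValueError(
            f"track {tr.cell_id!r}: extent {np.round(hi - lo, 2)} exceeds "
            f"{domain} µm domain"
        )
    shift = domain / 2 - (lo + hi) / 2
    pts = _sample_polyline(tr.xyz + shift, spacing=voxel / 2.0)

    n_vox = int(round(domain / voxel))
    r = int(np.floor(reach / voxel)) + 1
    off = np.arange(-r, r + 1)
    offsets = np.stack(np.meshgrid(off, off, off, indexing="ij"), axis=-1).reshape(-1, 3)

    centre_idx = np.floor(pts / voxel).astype(int)  # voxel containing each point
    cand = centre_idx[:, None, :] + offsets[None, :, :]  # (P, O, 3)
    valid = np.all((cand >= 0) & (cand < n_vox), axis=-1)
    centres = (cand + 0.5) * voxel
    dist2 = np.sum((centres - pts[:, None, :]) ** 2, axis=-1)
    hit = valid & (dist2 < reach**2)
    flat = (
        cand[hit][:, 0] * n_vox * n_vox + cand[hit][:, 1] * n_vox + cand[hit][:, 2]
    )
    count = np.unique(flat).size
    return float(count * voxel**3 / tr.duration_s)


# ---------------------------------------------------------------------------
# per-cell assembly


def compute_all(
    ts: TrackSet, params: MetricParams = MetricParams()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All per-cell metrics plus the pooled step table.

    Returns ``(cell_metrics, steps)``: one row per cell with NaN markers for
    undefined metrics, and the pooled turning-angle step table.  Exclusion
    counts (zero-length steps, undefined MSD slopes, tracks exceeding the
    volume domain) are stored in ``cell_metrics.attrs``.
    """
    rows = []
    n_msd_undef = 0
    n_vol_excluded = 0
    for tr in sorted(ts.tracks, key=lambda tr: tr.key):
        ratio, ctime = confinement(tr, params.confine_radius, params.confine_dwell_s)
        slope = msd_slope(tr, params.msd_cap_min)
        if np.isnan(slope):
            n_msd_undef += 1
        try:
            vrate = volume_rate(tr, params.voxel, params.reach, params.domain)
        except ValueError as err:
            log.warning("volume_rate undefined: %s", err)
            vrate = float("nan")
            n_vol_excluded += 1
        rows.append(
            {
                "cell_id": tr.cell_id,
                "frame_id": tr.frame_id,
                "tissue": tr.tissue,
                "n_points": tr.n_points,
                "duration_min": tr.duration_s / SECONDS_PER_MINUTE,
                "cell_speed": cell_speed(tr),
                "displacement_speed": displacement_speed(tr),
                "meandering_ratio": meandering_ratio(tr),
                "msd_slope": slope,
                "confined_ratio": ratio,
                "confined_time_min": ctime,
                "volume_rate": vrate,
            }
        )
    metrics = pd.DataFrame(rows)
    steps = step_table(ts, min_speed=params.min_speed)
    metrics.attrs["n_msd_undefined"] = n_msd_undef
    metrics.attrs["n_volume_excluded"] = n_vol_excluded
    metrics.attrs["n_zero_steps"] = steps.attrs.get("n_zero_steps", 0)
    return metrics, steps
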