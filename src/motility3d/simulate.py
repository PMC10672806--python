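"""Seedable 3D random-walker populations with known ground truth.

The generators emulate the motility phenotypes seen in intravital T cell
imaging so that every pipeline stage can be exercised without real
two-photon data:

* ``ballistic`` — fixed heading; meandering ratio 1, MSD exponent 2.
* ``brownian`` — i.i.d. isotropic headings; MSD exponent ≈ 1 and a
  sin(θ)-shaped turning-angle distribution.
* ``persistent`` — each heading is a von Mises–Fisher perturbation of the
  previous one (concentration ``kappa``); superdiffusive at moderate kappa.
* ``back_and_forth`` — with probability ``reversal_prob`` the heading
  reverses (with angular jitter), producing the near-180° turning-angle
  mode characteristic of cells shuttling inside constrained spaces.
* ``confined`` — isotropic proposals rejected outside a tether ball around
  the starting point; subdiffusive at matched duration.

Step lengths are speed·dt with per-step speeds drawn from a normal
distribution truncated at zero; optionally each cell's mean speed is itself
drawn from a population distribution (cell-level heterogeneity).  Cohorts
organise walkers into tissues and imaging frames, with a per-frame speed
offset to create the frame-level heterogeneity that the ANOVA and
outlier-frame machinery consume.  Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import Track, TrackSet

__all__ = [
    "WalkerSpec",
    "TissueSpec",
    "CohortSpec",
    "generate_track",
    "generate_cohort",
    "study_cohort_spec",
    "cohort_spec_from_dict",
    "cohort_spec_to_dict",
]

MODELS = ("ballistic", "brownian", "persistent", "confined", "back_and_forth")


@dataclass(frozen=True)
class WalkerSpec:
    """Parameters of one walker population.

    speed_mean, speed_sd : µm/min; per-step speed ~ N(mean, sd) truncated at 0.
    cell_speed_sd : µm/min; if > 0, each cell's own mean speed is drawn from
        N(speed_mean, cell_speed_sd) truncated at 0.1 (cell heterogeneity).
    kappa : von Mises–Fisher concentration of the direction-change
        distribution (persistent / back_and_forth); 0 = isotropic.
    reversal_prob : probability per step of reversing the heading
        (back_and_forth only).
    tether_radius : µm; maximum distance from the start (confined only).
    dt : seconds between observations.
    n_steps : steps per track (points = n_steps + 1); a (lo, hi) tuple draws
        the count uniformly per cell, matching the short, variable-length
        tracks of intravital imaging.
    """

    model: str
    speed_mean: float = 6.0
    speed_sd: float = 2.0
    cell_speed_sd: float = 0.0
    kappa: float = 0.0
    reversal_prob: float = 0.0
    tether_radius: float = 5.0
    dt: float = 90.0
    n_steps: "int | tuple[int, int]" = (5, 29)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown walker model {self.model!r}; choose from {MODELS}")
        if self.speed_mean <= 0 or self.speed_sd < 0 or self.dt <= 0:
            raise ValueError("speed_mean and dt must be positive, speed_sd non-negative")
        if not 0 <= self.reversal_prob <= 1:
            raise ValueError("reversal_prob must be in [0, 1]")
        if self.kappa < 0 or self.tether_radius <= 0 or self.cell_speed_sd < 0:
            raise ValueError("kappa/cell_speed_sd non-negative, tether_radius positive")


@dataclass(frozen=True)
class TissueSpec:
    """One tissue: a (possibly mixed) walker population in several frames.

    walkers : the population mixture as (weight, WalkerSpec) pairs; each cell
        samples its model from the mixture.
    frame_speed_sd : µm/min; a per-frame offset added to every cell's mean
        speed in that frame (drawn once per frame), creating frame-level
        heterogeneity.
    """

    label: str
    walkers: tuple[tuple[float, WalkerSpec], ...]
    n_frames: int = 1
    cells_per_frame: int = 10
    frame_speed_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.cells_per_frame < 1:
            raise ValueError("n_frames and cells_per_frame must be >= 1")
        if not self.walkers or any(w <= 0 for w, _ in self.walkers):
            raise ValueError("walkers must be non-empty with positive weights")


@dataclass(frozen=True)
class CohortSpec:
    tissues: tuple[TissueSpec, ...]
    seed: int = 0


# ---------------------------------------------------------------------------
# sampling primitives


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n == 0:  # pragma: no cover - probability zero
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _sample_vmf(rng: np.random.Generator, mu: np.ndarray, kappa: float) -> np.ndarray:
    """One draw from the von Mises–Fisher distribution on the unit sphere."""
    if kappa == 0:
        return _random_unit(rng)
    # inverse-CDF sampling of the cosine of the polar angle about mu
    u = rng.uniform()
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0.0, 2.0 * np.pi)
    # orthonormal frame around mu
    a = np.array([1.0, 0.0, 0.0]) if abs(mu[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    s = np.sqrt(max(0.0, 1.0 - w * w))
    return w * mu + s * (np.cos(phi) * e1 + np.sin(phi) * e2)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float = 0.0) -> float:
    """Normal(mean, sd) truncated below at ``lo`` by rejection."""
    if sd == 0:
        return max(mean, lo)
    for _ in range(200):
        v = rng.normal(mean, sd)
        if v >= lo:
            return v
    return lo


# ---------------------------------------------------------------------------
# track and cohort generation


def generate_track(
    spec: WalkerSpec,
    cell_id: str,
    frame_id: str,
    tissue: str,
    rng: np.random.Generator,
    origin: "Sequence[float] | None" = None,
    speed_offset: float = 0.0,
) -> Track:
    """Generate one walker track (deterministic given the generator state).

    ``speed_offset`` shifts the cell's mean speed (frame-level heterogeneity);
    the shifted mean is floored at 0.1 µm/min.
    """
    if isinstance(spec.n_steps, tuple):
        n_steps = int(rng.integers(spec.n_steps[0], spec.n_steps[1] + 1))
    else:
        n_steps = int(spec.n_steps)
    mean = spec.speed_mean + speed_offset
    if spec.cell_speed_sd > 0:
        mean = _trunc_normal(rng, mean, spec.cell_speed_sd, lo=0.1)
    mean = max(mean, 0.1)

    pos = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    xyz = np.empty((n_steps + 1, 3))
    xyz[0] = pos
    start = pos.copy()
    heading = _random_unit(rng)
    for i in range(n_steps):
        speed = _trunc_normal(rng, mean, spec.speed_sd)  # µm/min
        length = speed * spec.dt / 60.0  # µm per step
        if spec.model == "ballistic":
            d = heading
        elif spec.model == "brownian":
            d = _random_unit(rng)
        elif spec.model == "persistent":
            d = _sample_vmf(rng, heading, spec.kappa)
        elif spec.model == "back_and_forth":
            base = -heading if rng.uniform() < spec.reversal_prob else heading
            d = _sample_vmf(rng, base, spec.kappa)
        else:  # confined
            d = _random_unit(rng)
            for _ in range(50):
                if np.linalg.norm(pos + d * length - start) <= spec.tether_radius:
                    break
                d = _random_unit(rng)
            else:
                length = 0.0  # no admissible step: the cell stalls
        pos = pos + d * length
        heading = d
        xyz[i + 1] = pos
    t = np.arange(n_steps + 1, dtype=float) * spec.dt
    return Track(cell_id=cell_id, frame_id=frame_id, tissue=tissue, t=t, xyz=xyz)


def generate_cohort(spec: CohortSpec) -> TrackSet:
    """Generate a full multi-tissue cohort TrackSet (bit-reproducible by seed)."""
    rng = np.random.default_rng(spec.seed)
    tracks: list[Track] = []
    for tissue in spec.tissues:
        weights = np.array([w for w, _ in tissue.walkers], dtype=float)
        weights /= weights.sum()
        walkers = [w for _, w in tissue.walkers]
        for f in range(tissue.n_frames):
            frame_id = f"{tissue.label}_f{f:02d}"
            offset = rng.normal(0.0, tissue.frame_speed_sd) if tissue.frame_speed_sd else 0.0
            for c in range(tissue.cells_per_frame):
                wspec = walkers[int(rng.choice(len(walkers), p=weights))]
                tracks.append(
                    generate_track(
                        wspec,
                        cell_id=f"c{c:04d}",
                        frame_id=frame_id,
                        tissue=tissue.label,
                        rng=rng,
                        speed_offset=offset,
                    )
                )
    return TrackSet(tracks, metadata={"source": "synthetic cohort", "seed": spec.seed})


# ---------------------------------------------------------------------------
# the default study-like cohort


def study_cohort_spec(seed: int = 0, scale: float = 1.0) -> CohortSpec:
    """Four-tissue cohort mirroring the structure of a multi-tissue imaging study.

    * ``LN`` — fast persistent walkers with strong cell- and frame-level
      heterogeneity: 40 frames × 110 cells, 90 s steps.
    * ``villi`` — fast persistent walkers sampled at 45 s (exercises
      phase-complete resampling): 10 frames × 43 cells.
    * ``lung_flu`` — slow reversing ("back and forth") walkers, turning-angle
      mode near 160°: 5 frames × 71 cells.
    * ``lung_lps`` — slow near-Brownian walkers mixed with tether-confined
      walkers and negligible frame heterogeneity: 3 frames × 64 cells.

    ``scale`` multiplies cells per frame (floored at 2) so tests can run the
    same structure at reduced size.
    """

    def n(x: int) -> int:
        return max(2, int(round(x * scale)))

    ln = TissueSpec(
        label="LN",
        walkers=(
            (0.85, WalkerSpec("persistent", speed_mean=7.0, speed_sd=2.0,
                              cell_speed_sd=2.5, kappa=4.0, dt=90.0)),
            (0.15, WalkerSpec("confined", speed_mean=4.3, speed_sd=1.5,
                              cell_speed_sd=1.0, tether_radius=6.5, dt=90.0)),
        ),
        n_frames=40,
        cells_per_frame=n(110),
        frame_speed_sd=1.5,
    )
    villi = TissueSpec(
        label="villi",
        walkers=(
            (0.8, WalkerSpec("persistent", speed_mean=8.0, speed_sd=2.0,
                             cell_speed_sd=2.5, kappa=3.5, dt=45.0,
                             n_steps=(10, 58))),
            (0.2, WalkerSpec("confined", speed_mean=4.5, speed_sd=1.5,
                             cell_speed_sd=1.0, tether_radius=6.0, dt=45.0,
                             n_steps=(10, 58))),
        ),
        n_frames=10,
        cells_per_frame=n(43),
        frame_speed_sd=1.0,
    )
    lung_flu = TissueSpec(
        label="lung_flu",
        walkers=(
            (0.6, WalkerSpec("back_and_forth", speed_mean=5.5, speed_sd=1.5,
                             cell_speed_sd=1.5, kappa=12.0, reversal_prob=0.75,
                             dt=90.0)),
            (0.4, WalkerSpec("confined", speed_mean=5.0, speed_sd=1.5,
                             cell_speed_sd=1.0, tether_radius=5.5, dt=90.0)),
        ),
        n_frames=5,
        cells_per_frame=n(71),
        frame_speed_sd=0.8,
    )
    lung_lps = TissueSpec(
        label="lung_lps",
        walkers=(
            (0.5, WalkerSpec("confined", speed_mean=5.0, speed_sd=1.5,
                             cell_speed_sd=1.2, tether_radius=5.5, dt=90.0)),
            (0.5, WalkerSpec("brownian", speed_mean=5.5, speed_sd=1.5,
                             cell_speed_sd=1.2, dt=90.0)),
        ),
        n_frames=3,
        cells_per_frame=n(64),
        frame_speed_sd=0.1,
    )
    return CohortSpec(tissues=(ln, villi, lung_flu, lung_lps), seed=seed)


# ---------------------------------------------------------------------------
# plain-dict (YAML-friendly) serialisation


def _walker_to_dict(w: WalkerSpec) -> dict:
    d = {
        "model": w.model,
        "speed_mean": w.speed_mean,
        "speed_sd": w.speed_sd,
        "cell_speed_sd": w.cell_speed_sd,
        "kappa": w.kappa,
        "reversal_prob": w.reversal_prob,
        "tether_radius": w.tether_radius,
        "dt": w.dt,
        "n_steps": list(w.n_steps) if isinstance(w.n_steps, tuple) else w.n_steps,
    }
    return d


def cohort_spec_to_dict(spec: CohortSpec) -> dict:
    return {
        "seed": spec.seed,
        "tissues": [
            {
                "label": t.label,
                "n_frames": t.n_frames,
                "cells_per_frame": t.cells_per_frame,
                "frame_speed_sd": t.frame_speed_sd,
                "walkers": [
                    {"weight": w, **_walker_to_dict(ws)} for w, ws in t.walkers
                ],
            }
            for t in spec.tissues
        ],
    }


def cohort_spec_from_dict(d: dict) -> CohortSpec:
    tissues = []
    for t in d["tissues"]:
        walkers = []
        for w in t["walkers"]:
            w = dict(w)
            weight = float(w.pop("weight", 1.0))
            if isinstance(w.get("n_steps"), list):
                w["n_steps"] = tuple(w["n_steps"])
            walkers.append((weight, WalkerSpec(**w)))
        tissues.append(
            TissueSpec(
                label=str(t["label"]),
                walkers=tuple(walkers),
                n_frames=int(t.get("n_frames", 1)),
                cells_per_frame=int(t.get("cells_per_frame", 10)),
                frame_speed_sd=float(t.get("frame_speed_sd", 0.0)),
            )
        )
    return CohortSpec(tissues=tuple(tissues), seed=int(d.get("seed", 0)))
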