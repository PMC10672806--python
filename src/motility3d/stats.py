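"""Group comparison layer: pairwise nonparametric tests, one-way ANOVA over
frames and tissues, and greedy outlier-frame reduction.

Cells are the sampling unit throughout.  Pairwise comparisons between
tissues use the two-sided (unpaired) Mann–Whitney U test — or the
two-sample Kolmogorov–Smirnov test for distribution-shape comparisons —
with Bonferroni correction over the number of unordered pairs actually
tested.  Intra-tissue heterogeneity is assessed with one-way ANOVA using
imaging frames as groups; inter-tissue differences pool frames within each
tissue.  Frames that dominate the intra-tissue variance can be removed by a
greedy procedure that repeatedly drops the frame whose exclusion most
increases the intra-tissue ANOVA p-value.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairwiseMatrix",
    "AnovaResult",
    "ReductionReport",
    "pairwise_ranksum",
    "pairwise_ks",
    "anova_oneway",
    "intra_inter_anova",
    "reduce_outlier_frames",
]

log = logging.getLogger(__name__)

#: below this per-group size the Mann–Whitney U p-value is computed exactly
#: (when the data are tie-free); larger groups use the normal approximation
#: with continuity and tie correction.
EXACT_MWU_MAX_N = 50


@dataclass
class PairwiseMatrix:
    """Symmetric matrix of Bonferroni-corrected p-values with unit diagonal."""

    labels: list[str]
    p: np.ndarray
    test_name: str
    n_comparisons: int

    def __post_init__(self) -> None:
        assert np.allclose(self.p, self.p.T)
        assert np.all((self.p >= 0) & (self.p <= 1))
        assert np.allclose(np.diag(self.p), 1.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=self.labels, columns=self.labels)


@dataclass
class AnovaResult:
    """One-way ANOVA F statistic and p-value with the grouping used."""

    description: str
    F: float
    p: float
    group_sizes: dict[str, int] = field(default_factory=dict)


@dataclass
class ReductionReport:
    """Trajectory of a greedy outlier-frame reduction within one tissue."""

    tissue: str
    removed: list[str]
    #: intra-tissue ANOVA p-values: initial value followed by the value after
    #: each accepted removal (non-decreasing by construction)
    p_trajectory: list[float]
    retained_frames: list[str]
    retained_cells: int
    converged: bool


def _check_groups(values_by_group: dict[str, np.ndarray], min_size: int = 1) -> None:
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups")
    for name, vals in values_by_group.items():
        if len(vals) < min_size:
            raise ValueError(f"group {name!r} has fewer than {min_size} values")


def _pairwise(
    values_by_group: dict[str, "np.ndarray | list[float]"],
    statfun,
    test_name: str,
    correction: str,
) -> PairwiseMatrix:
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    groups = {k: v[~np.isnan(v)] for k, v in groups.items()}
    _check_groups(groups)
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    labels = list(groups)
    pairs = list(itertools.combinations(range(len(labels)), 2))
    n_comp = len(pairs) if correction == "bonferroni" else 1
    p = np.eye(len(labels))
    np.fill_diagonal(p, 1.0)
    for i, j in pairs:
        raw = statfun(groups[labels[i]], groups[labels[j]])
        p[i, j] = p[j, i] = min(1.0, raw * n_comp)
    return PairwiseMatrix(labels, p, test_name, n_comp)


def _mwu_p(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    small = max(x.size, y.size) < EXACT_MWU_MAX_N
    method = "exact" if (small and not ties) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def pairwise_ranksum(
    values_by_group: dict[str, "np.ndarray | list[float]"],
    correction: str = "bonferroni",
) -> PairwiseMatrix:
    """Two-sided Mann–Whitney U on every unordered pair of groups.

    Raw p-values are multiplied by the number of pairs tested (Bonferroni)
    and capped at 1.  NaN values are dropped per group before testing.
    """
    return _pairwise(values_by_group, _mwu_p, "mann-whitney-u", correction)


def pairwise_ks(
    values_by_group: dict[str, "np.ndarray | list[float]"],
    correction: str = "bonferroni",
) -> PairwiseMatrix:
    """Two-sample Kolmogorov–Smirnov on every unordered pair of groups.

    Sensitive to any distributional difference (shape as well as location),
    unlike the rank-sum test, which targets stochastic ordering.
    """

    def ks_p(x: np.ndarray, y: np.ndarray) -> float:
        return float(sps.ks_2samp(x, y).pvalue)

    return _pairwise(values_by_group, ks_p, "kolmogorov-smirnov", correction)


def anova_oneway(
    values_by_group: dict[str, "np.ndarray | list[float]"],
    description: str = "",
) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA (between/within mean-square ratio).

    Requires ≥2 groups, each with ≥2 values, and nonzero pooled within-group
    variance (otherwise the F ratio is degenerate and an error is raised).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    groups = {k: v[~np.isnan(v)] for k, v in groups.items()}
    _check_groups(groups, min_size=2)
    within = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups.values())
    if within == 0.0:
        raise ValueError("degenerate input: zero within-group variance")
    res = sps.f_oneway(*groups.values())
    return AnovaResult(
        description=description,
        F=float(res.statistic),
        p=float(res.pvalue),
        group_sizes={k: int(v.size) for k, v in groups.items()},
    )


def _frame_groups(
    metrics: pd.DataFrame, metric_name: str, tissue: str
) -> dict[str, np.ndarray]:
    sub = metrics[metrics["tissue"] == tissue].dropna(subset=[metric_name])
    return {
        str(f): g[metric_name].to_numpy() for f, g in sub.groupby("frame_id", sort=True)
    }


def intra_inter_anova(
    metrics: pd.DataFrame, metric_name: str
) -> tuple[dict[str, AnovaResult], AnovaResult | None]:
    """Frame-level and tissue-level one-way ANOVAs of a per-cell metric.

    Intra-tissue: for each tissue the groups are its imaging frames (tissues
    with fewer than two frames are skipped with a warning).  Inter-tissue:
    the groups are the tissues with frames pooled (None if fewer than two
    tissues are present).
    """
    intra: dict[str, AnovaResult] = {}
    for tissue in sorted(metrics["tissue"].unique()):
        groups = _frame_groups(metrics, metric_name, tissue)
        groups = {k: v for k, v in groups.items() if v.size >= 2}
        if len(groups) < 2:
            warnings.warn(f"tissue {tissue!r}: fewer than 2 frames; intra-tissue ANOVA skipped")
            continue
        intra[tissue] = anova_oneway(groups, description=f"intra:{tissue}:{metric_name}")
    tissue_groups = {
        str(t): g.dropna(subset=[metric_name])[metric_name].to_numpy()
        for t, g in metrics.groupby("tissue", sort=True)
    }
    tissue_groups = {k: v for k, v in tissue_groups.items() if v.size >= 2}
    inter = None
    if len(tissue_groups) >= 2:
        inter = anova_oneway(tissue_groups, description=f"inter:{metric_name}")
    else:
        warnings.warn("fewer than 2 tissues; inter-tissue ANOVA skipped")
    return intra, inter


def reduce_outlier_frames(
    metrics: pd.DataFrame,
    metric_name: str,
    tissue: str,
    p_threshold: float = 1e-4,
    max_removed_frac: float = 0.55,
) -> tuple[list[str], ReductionReport]:
    """Greedy removal of the most variable frames within one tissue.

    At each step, the frame whose exclusion most increases the intra-tissue
    ANOVA p-value is removed (ties broken by frame_id order); iteration
    stops once p ≥ ``p_threshold``, when ``max_removed_frac`` of the frames
    have been removed, or when no removal can raise the p-value further
    (best-effort, ``converged=False``).  Returns the retained frame_ids and
    a :class:`ReductionReport`; the p-value trajectory is non-decreasing.
    """
    groups = _frame_groups(metrics, metric_name, tissue)
    groups = {k: v for k, v in groups.items() if v.size >= 2}
    if len(groups) < 3:
        raise ValueError(f"tissue {tissue!r}: need at least 3 frames to reduce")
    n_frames0 = len(groups)
    max_removed = int(np.floor(max_removed_frac * n_frames0))
    p_now = anova_oneway(groups).p
    removed: list[str] = []
    trajectory = [p_now]
    converged = p_now >= p_threshold
    while not converged and len(removed) < max_removed and len(groups) > 2:
        best_frame, best_p = None, -np.inf
        for f in sorted(groups):  # sorted -> deterministic tie-break on frame_id
            trial = {k: v for k, v in groups.items() if k != f}
            p_trial = anova_oneway(trial).p
            if p_trial > best_p:
                best_frame, best_p = f, p_trial
        if best_frame is None or best_p < p_now:
            break  # no removal helps; best-effort stop
        groups.pop(best_frame)
        removed.append(best_frame)
        p_now = best_p
        trajectory.append(p_now)
        converged = p_now >= p_threshold
    report = ReductionReport(
        tissue=tissue,
        removed=removed,
        p_trajectory=trajectory,
        retained_frames=sorted(groups),
        retained_cells=int(sum(v.size for v in groups.values())),
        converged=bool(converged),
    )
    if not converged:
        log.warning(
            "tissue %s: reduction stopped before p ≥ %.1e (final p=%.3g, %d removed)",
            tissue,
            p_threshold,
            p_now,
            len(removed),
        )
    return sorted(groups), report
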