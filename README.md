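# motility3d

Quantitative motility analysis for 3D cell trajectories, built for
intravital (two-photon) T cell imaging: per-cell trajectory metrics,
time-step normalisation across acquisition protocols, and the group
statistics needed to compare cell behaviour between tissues and imaging
fields.

Immune cells search tissue for targets, and how efficiently they search
depends on *how* they move: lymph-node T cells tend to run fast and
straight, while cells in inflamed lung shuttle back and forth inside
confined pockets.  Given a table of tracked cell positions — one row per
cell per time point, with cell/frame/tissue identity — this package
computes the standard vocabulary of motility statistics and the
comparisons between tissues, frames and conditions.

## Metrics

For a track with positions (x_i, y_i, z_i) at times t_i and step distances
d_{i,i+1} = ‖p_{i+1} − p_i‖:

| metric | definition |
|---|---|
| cell-based speed | s_cell = Σ d_{i,i+1} / (t_n − t_1) |
| displacement speed | s_disp = d_{1,n} / (t_n − t_1) |
| meandering ratio | M = d_{1,n} / Σ d_{i,i+1} ∈ [0, 1]; satisfies M·s_cell = s_disp |
| turning angle | θ = arccos(v₁·v₂ / ‖v₁‖‖v₂‖) ∈ [0°, 180°] between consecutive displacement vectors; angles with associated speed < 1 µm/min are excluded |
| persistence likelihood | P(A_i\|B_i)/P(A_i) = (m·m_ab)/(m_a·m_b) per 1 µm/min speed bin: the fold-increase in the probability of staying in a speed bin from one step to the next |
| MSD exponent | slope of log d_{1,k}² vs log (t_k − t_1) for elapsed times ≤ 10.5 min: ≈1 Brownian, (1, 2] superdiffusive, <1 subdiffusive |
| confined ratio / time | dwell analysis in a 5 µm ball with a 150 s minimum dwell; mean time to exit the ball around each position |
| patrolled-volume rate | 2.5 µm voxels of a 400 µm cube whose centres pass within 5 µm of the cell (including along segments between positions), × voxel³ / tracked time |

Group comparisons use the two-sided Mann–Whitney U (or two-sample KS for
distribution shape) with Bonferroni correction, and one-way ANOVA over
imaging frames within a tissue (intra) and over tissues (inter), with a
greedy reduction that removes the most variable frames.

Because acquisition intervals differ between experiments, tracks are first
normalised to a nominal 90 s step.  Faster series are split into
phase-complete subsamples (a 45 s series becomes two interleaved 90 s
tracks) so that no observation is discarded and no position is ever
interpolated.

A seedable generator of 3D walker populations (ballistic, Brownian,
persistent, tether-confined, reversing, and mixtures, organised into
tissues and frames) provides ground-truth data for every pipeline stage.

## Worked example

Simulate a four-tissue cohort and run the full analysis:

```sh
motility3d simulate --preset study --scale 0.1 --seed 7 --out tracks.csv
motility3d analyze --input tracks.csv --out out
```

`out/tissue_medians.csv` then contains (abridged):

```
  tissue  n_cells  median_cell_speed  median_meandering_ratio  median_msd_slope  median_volume_rate
      LN      440               6.87                     0.55              1.64                9.34
lung_flu       35               3.52                     0.14              0.34                2.91
lung_lps       18               3.50                     0.15              0.87                3.09
   villi       80               6.48                     0.35              1.44                8.46
```

Lymph-node and villus walkers are fast (median cell speed ≈ 6.5–6.9
µm/min), directional (meandering ratio ≈ 0.35–0.55) and superdiffusive
(MSD exponent > 1), so they patrol the most volume (≈ 8.5–9.3 µm³/s);
the two lung phenotypes are slower, reversing/confined and sub-Brownian,
and patrol a third as much.  The Bonferroni-corrected rank-sum matrix on
cell speed (`out/pairwise_ranksum_cell_speed.csv`) separates both lung
tissues from LN and villi (p < 0.01) but not LN from villi (p = 0.39),
and the frame-reduction report (`out/frame_reduction.csv`) shows one
variable frame removed from LN and villi, raising their intra-tissue
ANOVA p-values (e.g. 5.4×10⁻⁵ → 1.8×10⁻³).

The same operations are available as a library:

```python
import motility3d as m

ts = m.generate_cohort(m.study_cohort_spec(seed=7, scale=0.1))
resampled = m.resample_trackset(ts)          # 90 s normalisation
metrics, steps = m.compute_all(resampled)    # per-cell metrics + step table
pm = m.pairwise_ranksum(
    {t: metrics.loc[metrics.tissue == t, "cell_speed"] for t in resampled.tissues}
)
```

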