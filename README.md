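# fmip

Analysis stack for **FRET-biosensor cell-microarray time-lapse experiments**:
plasmids encoding ratiometric kinase/GTPase activity reporters are printed as
a grid of spots (up to 16 × 24 = 384) on a single imaging dish, cells growing
on each spot take up one biosensor, and the whole array is imaged every few
minutes across several hours. The package covers everything between the raw
multi-channel TIFF stacks and condition-level biology:

- **Image quantification** — Triangle-threshold background subtraction,
  median smoothing, Huang fuzzy-threshold cell masks with NaN background,
  nucleus-seeded watershed segmentation, per-ROI FRET/CFP ratios, greedy
  nearest-centroid tracking, and a 700–8 000 a.u. CFP expression gate.
- **Trajectory normalization** — each cell's ratio trace is divided by its
  own pre-stimulation mean and by the per-time-point mean of vehicle-treated
  cells, removing expression drift and photobleaching; condition summaries
  are mean ± SEM over all cells pooled across replicates, with replicate
  reproducibility reported as a coefficient of variation over time and
  expression–response association as Kendall's τ.
- **Dynamic signatures** — hierarchical (Euclidean/Ward) clustering of
  response fingerprints, and K-means clustering of pooled single-cell
  trajectories into K representative temporal patterns; each condition is
  summarised by its vector of cluster proportions.
- **Condition-level PCA** — response traces stacked into a
  (groups × time points) × biosensors matrix, centered and scaled per column
  (`prcomp`-style), with empirical coverage ellipses around each group.
- **Synergy scoring** — for stimuli A and B, each cell is reduced to the
  area under its centered normalized response; the synergy score
  `Ss = mean(AUC_AB) − (mean(AUC_A) + mean(AUC_B))` is 0 under additivity,
  > 0 for synergism, < 0 for antagonism. The additive expectation's SEM is
  propagated as `√(SEM_A² + SEM_B²)`, tested with a Welch-type t statistic,
  corrected for multiple testing (Benjamini–Hochberg), scaled to [−1, 1]
  per biosensor, masked where insignificant, and Ward-clustered into a
  synergy map.

Because public deposits of such array experiments do not exist, the package
ships a first-class **synthetic-data generator**: biosensors respond with
Hill-dose-scaled rise-and-decay kinetics `a(t) = A·H(c)·(1−e^(−Δt/τr))·e^(−Δt/τd)`,
the true ratio is `R(t) = R₀(1 + a(t))`, channel intensities drift upward
while the ratio stays flat, and combined stimuli can carry a known injected
non-additivity. Every generated cell records its ground truth, so
segmentation, quantification, tracking, clustering and the synergy
statistics are all validated against exact answers.

## Worked example

Score a two-stimulus experiment carrying a known antagonistic interaction
(combined response shifted by −0.5 × the mean single-stimulus response):

```python
import pandas as pd
import fmip

model = fmip.BiosensorModel("S6K", "strong")
df = fmip.simulate_interaction_experiment(
    model, stim_a=("EGF", 100.0), stim_b=("IGF1", 100.0),
    gamma=-0.5, n_cells_per_arm=200, seed=42)

norm = fmip.normalize_trajectories(df, stimulation_time=30.0,
                                   vehicle_condition="vehicle")
rows = []
for (cond, cell), sub in norm[norm.condition_id != "vehicle"].groupby(
        ["condition_id", "cell_id"]):
    sub = sub.sort_values("time_min")
    rows.append({"biosensor_id": "S6K", "condition_id": cond,
                 "auc": fmip.auc(sub["time_min"].to_numpy(),
                                 sub["normalized"].to_numpy() - 1.0, 30.0)})
result = fmip.synergy_analysis(pd.DataFrame(rows),
                               {"EGF+IGF1": ("A", "B", "AB")})
print(result[["biosensor_id", "pair_id", "mean_observed", "mean_expected",
              "ss_raw", "p_adj", "ss_scaled", "masked"]].round(4)
      .to_string(index=False))
```

```
biosensor_id  pair_id  mean_observed  mean_expected  ss_raw  p_adj  ss_scaled  masked
         S6K EGF+IGF1        18.3926        24.4815 -6.0889    0.0       -1.0   False
```

The observed combined-treatment mean AUC (18.39 dimensionless·min) falls
short of the additive expectation (24.48), giving a significantly negative
raw synergy score — the injected antagonism is recovered with the correct
sign, and the scaled score −1.0 marks it as this biosensor's strongest
interaction.

The same analysis runs end-to-end from rendered images via the CLI:

```bash
fmip run --config config.yaml           # simulate → segment → … → synergy
fmip segment --cfp spot_CFP.tif --fret spot_FRET.tif --nuc spot_NUC.tif \
             --out measurements.csv
```

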