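# Methods

## The measurement model

A ratiometric FRET biosensor reports protein activity as the ratio of its
acceptor (FRET/YFP) to donor (CFP) emission over a cell region of interest.
The package models a cell's true state as a fractional activity change
`a(t)` around a resting ratio `R₀`:

    R(t) = R₀ · (1 + a(t)),          a(t) = 0 before stimulation.

Channel intensities are proportional to the expression level `E(t)·c₀`
(biosensor expression keeps rising over a multi-hour movie), so the
foreground pixels of a noiseless frame satisfy

    CFP  = E(t)·c₀,      FRET = E(t)·c₀·R₀·(1 + a(t)),

and the pixelwise FRET/CFP ratio is independent of expression and drift.
This separation is what the whole normalization strategy exploits, and it is
preserved *exactly* through the image pipeline: background subtraction
removes a per-channel scalar, and the median filter is an order statistic,
which commutes with the positive per-cell scaling `FRET = R₀(1+a)·CFP`.
Consequently, on noiseless renders the measured ROI ratio equals
`R₀(1+a(t))` to machine precision — the basis of the quantification
acceptance check (tolerance 1e−6).

## Synthetic experiments

The generator emulates a printed cell-microarray experiment:

- **Layout** — a regular `n_rows × n_cols` grid of spots (default
  16 × 24 = 384, diameter 200 µm, pitch 1125 µm), each spot carrying one
  biosensor; replicate indices count repeated prints of the same biosensor.
  (A printed pitch of "1.125" in the source protocol is physically
  inconsistent with 200–400 µm spots and is read as millimetres.)
- **Kinetics** — `a(t) = A·H(c)·(1−e^(−Δt/τr))·e^(−Δt/τd)` per stimulus,
  with Hill occupancy `H(c) = cⁿ/(cⁿ + EC₅₀ⁿ)`. Response-class presets set
  the saturating amplitude `A`: strong 0.40, middle 0.15, weak 0.05
  fractional ratio change, nonresponding 0 — the three kinetic classes that
  hierarchical clustering of fingerprints should separate. Defaults
  τr = 12 min, τd = 45 min, EC₅₀ = 10 ng/mL, n = 1 give a transient
  growth-factor-like response peaking ~20–30 min after stimulation.
- **Cell-to-cell variability** — a per-cell log-normal amplitude multiplier
  (σ = 0.25), an optional pulsatile subpopulation (sinusoidal modulation,
  period 30 min, depth 0.5, random phase), and multiplicative per-time-point
  ratio noise.
- **Combined stimuli** — responses add across stimuli; an interaction term
  `γ · mean(single-stimulus activities)` injects known non-additivity, so
  γ = ±0.5 shifts the combined response by exactly half the single-stimulus
  scale. γ = 0 yields additivity *by construction*, which is what the
  type-I-error calibration of the synergy test relies on.
- **Rendering** — cells are filled ellipses (semi-axis ~12 px, aspect drawn
  in [0.8, 1.2]) with a concentric 5-px nuclear disc in a third channel;
  expression drift `E(t) = 1 + 0.002·t` makes both emission channels rise
  ~60 % over a 300-min movie while the true ratio is unchanged. The camera
  adds offset 100 a.u., Gaussian read noise and (by default) rounds to
  16-bit counts; quantization is itself a noise source, so "noiseless"
  renders disable it. Frames default to 3-min intervals over 300 min.

What the generator does *not* emulate: optics (PSF blur, bleed-through),
photobleaching beyond the shared drift term, cell migration (beyond an
optional centroid jitter), division, death, or spatial signaling gradients
within cells. Passing tests therefore demonstrate the correctness of the
algorithms under the stated statistical structure, not robustness to every
artifact of real microscopy.

## Image pipeline choices

- Both histogram thresholds operate on an explicit 256-bin histogram of the
  finite pixels spanning [min, max]; thresholds are bin indices, making the
  decisions exactly reproducible and cheap to verify by exhaustive search.
  Triangle uses integer cross-product arithmetic (exact); Huang minimises
  the count-weighted fuzzy entropy with membership
  `u = 1/(1 + |i−μ|/C)`.
- The background estimate is the mean of pixels at or below the Triangle
  threshold, subtracted per channel. "Close to background" pixels are those
  below the Huang threshold of the smoothed CFP channel; they become NaN and
  never enter any ROI statistic. Deriving one mask from the CFP channel and
  applying it to both channels keeps numerator and denominator pixel sets
  identical.
- A constant image is treated as all-foreground if positive, all-background
  otherwise (the threshold criterion is undefined there).
- Segmentation: Triangle-thresholded nuclei seed a watershed on the negated
  Euclidean distance transform of the cell mask (4-connectivity); regions
  under 50 px are discarded. Each frame is segmented independently and ROIs
  are linked by greedy nearest-centroid matching (max displacement 15 px).
- The expression gate keeps cells whose mean pre-stimulus CFP lies in
  [700, 8 000] a.u.

## Statistics

- **Normalization** — baseline (own pre-stimulus mean, ≥ 2 points required)
  then vehicle (per-time-point mean of baseline-normalized vehicle cells of
  the same biosensor, identical grids enforced). For generated data the two
  operations commute and recover `1 + a(t)` exactly in the noiseless limit.
- **Summaries** — mean ± SEM with SEM = sd/√n over all cells pooled across
  replicates (sample sd, ddof = 1; a single cell gets SEM 0 by convention).
  Replicate CV is computed per time point over replicate mean traces and
  averaged over time; zero-mean points are excluded with a warning.
- **Kendall τ-b** between pre-stimulus CFP and maximal normalized ratio,
  exact p for < 50 untied pairs, normal approximation otherwise.
- **Clustering** — fingerprints: Euclidean metric with Ward linkage (the
  one stated choice in the source analyses; configurable). Trajectories:
  best-of-25 k-means++ restarts, squared-Euclidean objective, default
  K = 6, clustered per biosensor across pooled treatments, deterministic
  given the seed. Trajectories on differing grids are linearly interpolated
  onto the common span first.
- **PCA** — columns centered and scaled to unit sample variance, then SVD;
  deterministic sign convention (largest-|loading| element of each
  component positive). Coverage ellipses use the *empirical* Mahalanobis
  quantile of the group's own points — the stated fraction refers to actual
  time points covered, not a parametric χ² approximation.
- **Synergy** — per-cell AUC is the signed trapezoid integral of the
  centered normalized trace over the post-stimulation span. Shapiro–Wilk
  normality of each observed AUC sample is logged, not branched on. Because
  the additive "expected" value is a derived mean rather than a sample, the
  difference is tested with a Welch-type statistic
  `t = Ss/√(SEM_obs² + SEM_exp²)` whose degrees of freedom follow
  Welch–Satterthwaite over the three contributing samples' (n, SEM);
  without arm sizes it falls back to `n_obs − 1`. Multiple-testing
  correction defaults to Benjamini–Hochberg (Holm and Bonferroni
  available), and the significance mask applies to *adjusted* p values for
  consistency with the correction. Scaled scores divide by the largest
  |Ss| within each biosensor (all-zero biosensors stay zero). In the
  clustered synergy map, masked entries are imputed as 0 so they contribute
  no distance.

## Problem sizes and tolerances

The validation suite runs entirely on generated data at desk scale:
quantification accuracy uses 20 cells × 100 frames (420² px); synergy
calibration uses 200 simulated experiments of 200 cells/arm on a 51-point
grid (type-I fraction compared against 5 % plus three binomial standard
errors; sign recovery and power at γ = ±0.5); signature recovery uses two
conditions of 300 cells over six planted patterns with a 3·√(p(1−p)/n)
per-cluster band; the score-consistency check fits the log-RMSE slope over
n ∈ {25, 50, 100, 200} with 40 replicates each. All randomness flows
through explicit seeds; repeated runs are bitwise-identical.

## Known limitations

- Per-frame thresholding means very low-contrast frames can segment
  differently from their neighbours; tracking bridges identity but the
  pipeline does not re-threshold jointly across the movie.
- Greedy nearest-centroid linking has no gap closing or split/merge
  handling; it is adequate for adherent, slowly moving cells.
- The additive-AUC interaction model is the only one implemented; Bliss or
  Loewe dose–response surfaces are out of scope.
- The headline reproducibility and correlation figures of the original
  array experiments depend on undeposited microscopy data; the package
  validates the *procedures* against synthetic ground truth instead.
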