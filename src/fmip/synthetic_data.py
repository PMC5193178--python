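"""Synthetic cell-microarray experiments with known ground truth.

Emulates a FRET-biosensor cell microarray: plasmid spots printed on a grid,
each spot carrying cells that express one ratiometric biosensor.  Cells
respond to growth-factor stimulation with first-order rise-and-decay
kinetics scaled by a Hill dose term; the acceptor/donor intensity ratio is
R(t) = R0 * (1 + a(t)) where a(t) is the fractional activity change.
Channel intensities drift upward over the movie (continuing biosensor
expression) while the ratio stays put, so normalisation and drift-removal
steps can be validated against known answers.

Everything is deterministic given a seed, and every generated cell carries
its ground-truth activity, ratio and position so segmentation,
quantification, tracking, clustering and synergy statistics can all be
scored against the truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .image_pipeline import FrameSet

logger = logging.getLogger("fmip")

#: Default peak fractional ratio change per response class.
CLASS_AMPLITUDES = {
    "strong": 0.40,
    "middle": 0.15,
    "weak": 0.05,
    "nonresponding": 0.0,
}


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# Array layout
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Spot:
    row_index: int
    col_index: int
    center_xy_um: tuple[float, float]
    diameter_um: float
    biosensor_id: str
    replicate_index: int

    @property
    def spot_id(self) -> str:
        return f"r{self.row_index:02d}c{self.col_index:02d}"


@dataclass
class ArrayLayout:
    """Regular grid of printed biosensor spots."""

    spots: list[Spot]
    pitch_um: float
    n_rows: int
    n_cols: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "spot_id": s.spot_id,
            "row": s.row_index,
            "col": s.col_index,
            "x_um": s.center_xy_um[0],
            "y_um": s.center_xy_um[1],
            "diameter_um": s.diameter_um,
            "biosensor_id": s.biosensor_id,
            "replicate_index": s.replicate_index,
        } for s in self.spots])


def default_assignment(n_rows: int, n_cols: int,
                       n_biosensors: int = 40) -> dict[tuple[int, int], str]:
    """Row-major round-robin assignment of a default biosensor panel."""
    return {(r, c): f"BS{(r * n_cols + c) % n_biosensors + 1:02d}"
            for r in range(n_rows) for c in range(n_cols)}


def make_layout(
    n_rows: int,
    n_cols: int,
    spot_diameter_um: float = 200.0,
    pitch_um: float = 1125.0,
    biosensor_assignment: dict[tuple[int, int], str] | None = None,
) -> ArrayLayout:
    """Build a regular printed-spot grid.

    Each grid position carries exactly one biosensor; the replicate index
    counts repeated occurrences of the same biosensor in row-major order.
    The default 16 x 24 geometry gives the platform's full 384-spot print.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("n_rows and n_cols must be >= 1")
    if spot_diameter_um <= 0:
        raise ValueError("spot_diameter_um must be > 0")
    if pitch_um < spot_diameter_um:
        raise ValueError("pitch_um must be >= spot_diameter_um")
    if biosensor_assignment is None:
        biosensor_assignment = default_assignment(n_rows, n_cols)
    if len(biosensor_assignment) != n_rows * n_cols:
        raise ValueError(
            f"biosensor_assignment has {len(biosensor_assignment)} entries, "
            f"expected {n_rows * n_cols}")
    spots: list[Spot] = []
    counts: dict[str, int] = {}
    for r in range(n_rows):
        for c in range(n_cols):
            try:
                bs = biosensor_assignment[(r, c)]
            except KeyError as exc:
                raise ValueError(f"no biosensor assigned to position "
                                 f"({r}, {c})") from exc
            rep = counts.get(bs, 0)
            counts[bs] = rep + 1
            spots.append(Spot(r, c, (c * pitch_um, r * pitch_um),
                              spot_diameter_um, bs, rep))
    return ArrayLayout(spots, pitch_um, n_rows, n_cols)


# --------------------------------------------------------------------------
# Kinetic models
# --------------------------------------------------------------------------


@dataclass
class BiosensorModel:
    """Response kinetics of one FRET biosensor.

    amplitude is the peak fractional ratio change at saturating dose;
    rise_tau / decay_tau (minutes) set activation and relaxation speed;
    hill_ec50 (ng/mL) and hill_n give the dose dependence; a
    pulsatile_fraction of cells superimpose a periodic modulation on the
    response; baseline_ratio R0 is the resting FRET/CFP ratio.
    """

    biosensor_id: str
    response_class: str = "middle"
    amplitude: float | None = None
    rise_tau: float = 12.0
    decay_tau: float = 45.0
    hill_ec50: float = 10.0
    hill_n: float = 1.0
    pulsatile_fraction: float = 0.0
    baseline_ratio: float = 1.2

    def __post_init__(self) -> None:
        if self.response_class not in CLASS_AMPLITUDES:
            raise ValueError(f"unknown response_class {self.response_class!r}")
        if self.amplitude is None:
            self.amplitude = CLASS_AMPLITUDES[self.response_class]
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("time constants must be > 0")
        if not 0 <= self.pulsatile_fraction <= 1:
            raise ValueError("pulsatile_fraction must be in [0, 1]")
        if self.baseline_ratio <= 0:
            raise ValueError("baseline_ratio must be > 0")


@dataclass
class ConditionSpec:
    """One stimulation condition: stimuli, timing and injected interaction.

    interaction_gamma injects a known non-additivity for combined stimuli:
    gamma = 0 makes the combined response exactly the sum of the single
    responses; gamma = +/-g adds g times the mean single-stimulus activity
    (synergy for g > 0, antagonism for g < 0).
    """

    condition_id: str
    stimuli: tuple[tuple[str, float], ...] = ()
    stimulation_time: float = 30.0
    is_vehicle: bool = False
    interaction_gamma: float = 0.0

    def __post_init__(self) -> None:
        self.stimuli = tuple((str(n), float(c)) for n, c in self.stimuli)
        if any(c < 0 for _, c in self.stimuli):
            raise ValueError("concentrations must be >= 0")
        if self.is_vehicle and self.stimuli:
            raise ValueError("vehicle conditions must have empty stimuli")


@dataclass
class CellNoise:
    """Cell-to-cell and measurement variability.

    amplitude_sigma: sigma of the per-cell log-normal amplitude multiplier;
    ratio_noise_sd: multiplicative per-time-point noise on the ratio;
    pulse_period / pulse_depth: modulation of pulsatile cells (minutes,
    fraction).
    """

    amplitude_sigma: float = 0.25
    ratio_noise_sd: float = 0.0
    pulse_period: float = 30.0
    pulse_depth: float = 0.5


def hill(concentration: float, ec50: float, n: float) -> float:
    """Hill occupancy c^n / (c^n + ec50^n); 0 at zero dose."""
    if concentration <= 0:
        return 0.0
    cn = concentration ** n
    return cn / (cn + ec50 ** n)


def _deterministic_activity(model: BiosensorModel, condition: ConditionSpec,
                            time_grid: np.ndarray) -> np.ndarray:
    """Population-mean activity: Hill-scaled rise-times-decay per stimulus,
    summed, plus the gamma cross-term for combined stimuli."""
    dt = time_grid - condition.stimulation_time
    post = dt > 0
    shape = np.zeros_like(time_grid, dtype=float)
    shape[post] = ((1.0 - np.exp(-dt[post] / model.rise_tau))
                   * np.exp(-dt[post] / model.decay_tau))
    singles = [model.amplitude * hill(c, model.hill_ec50, model.hill_n) * shape
               for _, c in condition.stimuli]
    if not singles:
        return np.zeros_like(time_grid, dtype=float)
    total = np.sum(singles, axis=0)
    if len(singles) > 1 and condition.interaction_gamma != 0.0:
        total = total + condition.interaction_gamma * np.mean(singles, axis=0)
    return total


def simulate_trajectory(
    model: BiosensorModel,
    condition: ConditionSpec,
    cell_noise: CellNoise,
    time_grid: np.ndarray,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Simulate one cell's fractional activity a(t).

    a(t) is exactly zero before the stimulation time; afterwards it is the
    deterministic Hill/rise-decay response scaled by a per-cell log-normal
    amplitude, with an optional sinusoidal modulation for pulsatile cells.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.size == 0:
        raise ValueError("time_grid must be non-empty")
    if time_grid.size > 1 and np.any(np.diff(time_grid) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    rng = _rng(seed)
    # fixed draw order keeps the stream identical across conditions
    multiplier = float(np.exp(rng.normal(0.0, cell_noise.amplitude_sigma)))
    is_pulsatile = rng.uniform() < model.pulsatile_fraction
    phase = rng.uniform(0.0, 2.0 * np.pi)
    a = multiplier * _deterministic_activity(model, condition, time_grid)
    if is_pulsatile:
        dt = time_grid - condition.stimulation_time
        post = dt > 0
        a[post] *= 1.0 + cell_noise.pulse_depth * np.sin(
            2.0 * np.pi * dt[post] / cell_noise.pulse_period + phase)
    return a


def simulate_ratio_cells(
    model: BiosensorModel,
    condition: ConditionSpec,
    n_cells: int,
    cell_noise: CellNoise,
    time_grid: np.ndarray,
    seed: int | np.random.Generator | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a population; returns (activities, ratios), each (n, T).

    ratio = R0 * (1 + a(t)) * (1 + eps) with eps ~ N(0, ratio_noise_sd).
    """
    rng = _rng(seed)
    time_grid = np.asarray(time_grid, dtype=float)
    activities = np.stack([
        simulate_trajectory(model, condition, cell_noise, time_grid, rng)
        for _ in range(n_cells)])
    ratios = model.baseline_ratio * (1.0 + activities)
    if cell_noise.ratio_noise_sd > 0:
        ratios = ratios * (1.0 + rng.normal(
            0.0, cell_noise.ratio_noise_sd, size=ratios.shape))
    return activities, ratios


def _long_frame(ratios: np.ndarray, time_grid: np.ndarray, biosensor_id: str,
                condition_id: str, cell_offset: int) -> pd.DataFrame:
    n, T = ratios.shape
    return pd.DataFrame({
        "cell_id": np.repeat(np.arange(cell_offset, cell_offset + n), T),
        "biosensor_id": biosensor_id,
        "condition_id": condition_id,
        "time_min": np.tile(time_grid, n),
        "ratio": ratios.ravel(),
    })


def simulate_interaction_experiment(
    model: BiosensorModel,
    stim_a: tuple[str, float] = ("EGF", 100.0),
    stim_b: tuple[str, float] = ("IGF1", 100.0),
    gamma: float = 0.0,
    n_cells_per_arm: int = 200,
    n_vehicle: int = 100,
    cell_noise: CellNoise | None = None,
    time_grid: np.ndarray | None = None,
    stimulation_time: float = 30.0,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Simulate the four arms of a two-stimulus interaction experiment.

    Returns a long trajectory table (vehicle, A, B and combined arms) with
    the combined arm's non-additivity set by ``gamma``: 0 makes the mean
    combined response exactly the sum of the single responses, +/-g shifts
    it by g times the mean single-stimulus response.
    """
    rng = _rng(seed)
    cell_noise = cell_noise or CellNoise(ratio_noise_sd=0.02)
    if time_grid is None:
        time_grid = np.arange(0.0, 150.0 + 1e-9, 3.0)
    conditions = [
        ConditionSpec("vehicle", (), stimulation_time, is_vehicle=True),
        ConditionSpec("A", (stim_a,), stimulation_time),
        ConditionSpec("B", (stim_b,), stimulation_time),
        ConditionSpec("AB", (stim_a, stim_b), stimulation_time,
                      interaction_gamma=gamma),
    ]
    frames = []
    offset = 0
    for cond in conditions:
        n = n_vehicle if cond.is_vehicle else n_cells_per_arm
        _, ratios = simulate_ratio_cells(model, cond, n, cell_noise,
                                         time_grid, rng)
        frames.append(_long_frame(ratios, time_grid, model.biosensor_id,
                                  cond.condition_id, offset))
        offset += n
    return pd.concat(frames, ignore_index=True)


def planted_pattern_mixture(
    patterns: np.ndarray,
    weights: np.ndarray,
    n_cells: int,
    noise_sd: float = 0.01,
    seed: int | np.random.Generator | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample cell trajectories from a known mixture of temporal patterns.

    Each cell copies one of the K ``patterns`` rows (chosen with
    ``weights``) plus i.i.d. Gaussian noise.  Returns (trajectories
    (n_cells, T), true pattern labels) — the ground truth for dynamic-
    signature recovery tests.
    """
    rng = _rng(seed)
    patterns = np.asarray(patterns, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if patterns.shape[0] != weights.size:
        raise ValueError("one weight per pattern required")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    labels = rng.choice(patterns.shape[0], size=n_cells, p=weights)
    X = patterns[labels] + rng.normal(0.0, noise_sd,
                                      size=(n_cells, patterns.shape[1]))
    return X, labels


# --------------------------------------------------------------------------
# Ground truth and rendering
# --------------------------------------------------------------------------


@dataclass
class CellGroundTruth:
    """True state of one rendered cell across the movie."""

    cell_id: int
    x: np.ndarray            # centroid per frame (pixels)
    y: np.ndarray
    radius_x: float          # ellipse semi-axes (pixels)
    radius_y: float
    nucleus_radius: float
    expression_c0: float     # CFP foreground level at t = 0 (a.u.)
    baseline_ratio: float
    activity: np.ndarray     # a(t)
    drift: np.ndarray        # E(t), monotone non-decreasing


@dataclass
class GroundTruth:
    """All rendered cells of one spot's field of view."""

    spot_id: str
    time_grid: np.ndarray
    cells: list[CellGroundTruth]
    image_shape: tuple[int, int] = (256, 256)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cell in self.cells:
            for f, t in enumerate(self.time_grid):
                rows.append({
                    "spot_id": self.spot_id,
                    "cell_id": cell.cell_id,
                    "frame": f,
                    "time_min": float(t),
                    "x": float(cell.x[f]),
                    "y": float(cell.y[f]),
                    "a_true": float(cell.activity[f]),
                    "ratio_true": float(cell.baseline_ratio
                                        * (1.0 + cell.activity[f])),
                    "E": float(cell.drift[f]),
                })
        return pd.DataFrame(
            rows, columns=["spot_id", "cell_id", "frame", "time_min",
                           "x", "y", "a_true", "ratio_true", "E"])


@dataclass
class CameraModel:
    """Idealised CCD: offset + gain * signal + Gaussian read noise.

    With quantize=True the output is clipped and rounded to unsigned
    ``bit_depth``-bit counts (the default); quantize=False returns float
    images, which is what a truly noiseless render requires since rounding
    itself perturbs the ratio.
    """

    offset: float = 100.0
    gain: float = 1.0
    read_noise_sd: float = 2.0
    bit_depth: int = 16
    quantize: bool = True

    def __post_init__(self) -> None:
        if self.offset < 0 or self.gain < 0 or self.read_noise_sd < 0:
            raise ValueError("camera parameters must be >= 0")


def place_cells(
    n_cells: int,
    image_shape: tuple[int, int],
    cell_radius: float,
    min_separation: float,
    rng: np.random.Generator,
    max_tries: int = 5000,
) -> np.ndarray:
    """Random non-overlapping cell centres inside the field (n, 2) = (x, y)."""
    h, w = image_shape
    margin = cell_radius + 3
    centres: list[tuple[float, float]] = []
    tries = 0
    while len(centres) < n_cells:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n_cells} cells with separation "
                f"{min_separation} in a {image_shape} field")
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if all(np.hypot(x - cx, y - cy) >= min_separation
               for cx, cy in centres):
            centres.append((x, y))
    return np.array(centres)


def make_ground_truth(
    model: BiosensorModel,
    condition: ConditionSpec,
    n_cells: int,
    time_grid: np.ndarray,
    cell_noise: CellNoise | None = None,
    seed: int | np.random.Generator | None = 0,
    spot_id: str = "r00c00",
    image_shape: tuple[int, int] = (256, 256),
    cell_radius: float = 12.0,
    nucleus_radius: float = 5.0,
    min_separation: float = 40.0,
    expression_range: tuple[float, float] = (1000.0, 6000.0),
    drift_slope: float = 0.002,
    jitter_sd: float = 0.0,
) -> GroundTruth:
    """Generate the true cells of one spot: positions, kinetics, expression.

    Expression levels are drawn log-uniformly within ``expression_range``
    (a.u., within the downstream 700-8000 CFP gate by default); the
    expression drift is E(t) = 1 + drift_slope * t, so channel intensities
    rise over the movie while the true ratio is unaffected.  jitter_sd > 0
    adds per-frame centroid jitter for tracking stress tests.
    """
    rng = _rng(seed)
    cell_noise = cell_noise or CellNoise()
    time_grid = np.asarray(time_grid, dtype=float)
    centres = place_cells(n_cells, image_shape, cell_radius,
                          min_separation, rng)
    drift = 1.0 + drift_slope * time_grid
    cells = []
    for i in range(n_cells):
        activity = simulate_trajectory(model, condition, cell_noise,
                                       time_grid, rng)
        c0 = float(np.exp(rng.uniform(np.log(expression_range[0]),
                                      np.log(expression_range[1]))))
        aspect = rng.uniform(0.8, 1.2)
        x = np.full(time_grid.size, centres[i, 0])
        y = np.full(time_grid.size, centres[i, 1])
        if jitter_sd > 0:
            x = x + rng.normal(0.0, jitter_sd, size=time_grid.size)
            y = y + rng.normal(0.0, jitter_sd, size=time_grid.size)
        cells.append(CellGroundTruth(
            cell_id=i, x=x, y=y,
            radius_x=cell_radius * aspect, radius_y=cell_radius / aspect,
            nucleus_radius=nucleus_radius, expression_c0=c0,
            baseline_ratio=model.baseline_ratio,
            activity=activity, drift=drift.copy()))
    return GroundTruth(spot_id, time_grid, cells, image_shape)


def _fill_ellipse(img: np.ndarray, cx: float, cy: float,
                  rx: float, ry: float, value: float) -> None:
    h, w = img.shape
    y0, y1 = max(int(cy - ry) - 1, 0), min(int(cy + ry) + 2, h)
    x0, x1 = max(int(cx - rx) - 1, 0), min(int(cx + rx) + 2, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2) <= 1.0
    img[y0:y1, x0:x1][inside] = value


def render_frames(
    ground_truth: GroundTruth,
    camera: CameraModel | None = None,
    seed: int | np.random.Generator | None = 0,
    nuclear_intensity: float = 3000.0,
) -> list[FrameSet]:
    """Render the three channels of every frame from the ground truth.

    Foreground per cell: CFP = E(t) * c0, FRET = E(t) * c0 * R0 * (1 + a(t)),
    nuclear marker = a bright concentric disc; so the noiseless foreground
    ratio is R0 * (1 + a(t)) regardless of expression level or drift.
    """
    camera = camera or CameraModel()
    rng = _rng(seed)
    h, w = ground_truth.image_shape
    for cell in ground_truth.cells:
        if (np.any(cell.x - cell.radius_x < 0) or np.any(cell.y - cell.radius_y < 0)
                or np.any(cell.x + cell.radius_x >= w)
                or np.any(cell.y + cell.radius_y >= h)):
            raise ValueError(f"cell {cell.cell_id} extends outside the "
                             f"{ground_truth.image_shape} image bounds")
    frames = []
    for f, t in enumerate(ground_truth.time_grid):
        cfp = np.zeros((h, w))
        fret = np.zeros((h, w))
        nuc = np.zeros((h, w))
        for cell in ground_truth.cells:
            level = cell.expression_c0 * cell.drift[f]
            ratio = cell.baseline_ratio * (1.0 + cell.activity[f])
            _fill_ellipse(cfp, cell.x[f], cell.y[f],
                          cell.radius_x, cell.radius_y, level)
            _fill_ellipse(fret, cell.x[f], cell.y[f],
                          cell.radius_x, cell.radius_y, level * ratio)
            _fill_ellipse(nuc, cell.x[f], cell.y[f],
                          cell.nucleus_radius, cell.nucleus_radius,
                          nuclear_intensity)
        channels = []
        for img in (cfp, fret, nuc):
            out = camera.gain * img + camera.offset
            if camera.read_noise_sd > 0:
                out = out + rng.normal(0.0, camera.read_noise_sd,
                                       size=out.shape)
            if camera.quantize:
                out = np.clip(np.round(out), 0,
                              2 ** camera.bit_depth - 1).astype(np.uint16)
            channels.append(out)
        frames.append(FrameSet(channels[0], channels[1], channels[2],
                               time_min=float(t)))
    return frames


# --------------------------------------------------------------------------
# Whole-experiment simulation to disk
# --------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Full specification of one simulated dish (layout + one condition)."""

    layout: ArrayLayout
    models: dict[str, BiosensorModel]
    condition: ConditionSpec
    n_cells_per_spot: int = 10
    t_end_min: float = 300.0
    frame_interval_min: float = 3.0
    cell_noise: CellNoise = field(default_factory=CellNoise)
    camera: CameraModel = field(default_factory=CameraModel)
    image_shape: tuple[int, int] = (256, 256)
    seed: int = 0

    @property
    def time_grid(self) -> np.ndarray:
        return np.arange(0.0, self.t_end_min + 1e-9, self.frame_interval_min)


def simulate_experiment(config: ExperimentConfig, outdir) -> pd.DataFrame:
    """Render and write a whole simulated experiment.

    Writes one multi-page TIFF per channel per spot
    (``<spot_id>_<CFP|FRET|NUC>.tif``), ``ground_truth.csv``,
    ``layout.csv`` and ``config.yaml``; returns the ground-truth table.
    Deterministic: identical config + seed give identical files.
    """
    import tifffile
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    spot_seeds = master.spawn(len(config.layout.spots))
    truth_frames = []
    for spot, seq in zip(config.layout.spots, spot_seeds):
        model = config.models[spot.biosensor_id]
        rng = np.random.default_rng(seq)
        gt = make_ground_truth(
            model, config.condition, config.n_cells_per_spot,
            config.time_grid, config.cell_noise, rng,
            spot_id=spot.spot_id, image_shape=config.image_shape)
        frames = render_frames(gt, config.camera, rng)
        for channel, attr in (("CFP", "cfp"), ("FRET", "fret"),
                              ("NUC", "nuclear")):
            stack = np.stack([getattr(fs, attr) for fs in frames])
            tifffile.imwrite(outdir / f"{spot.spot_id}_{channel}.tif", stack)
        truth_frames.append(gt.to_frame())
    truth = (pd.concat(truth_frames, ignore_index=True) if truth_frames
             else GroundTruth("", config.time_grid, []).to_frame())
    truth.to_csv(outdir / "ground_truth.csv", index=False)
    config.layout.to_frame().to_csv(outdir / "layout.csv", index=False)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump({
            "seed": config.seed,
            "condition": {
                "condition_id": config.condition.condition_id,
                "stimuli": [list(s) for s in config.condition.stimuli],
                "stimulation_time": config.condition.stimulation_time,
                "is_vehicle": config.condition.is_vehicle,
                "interaction_gamma": config.condition.interaction_gamma,
            },
            "n_cells_per_spot": config.n_cells_per_spot,
            "t_end_min": config.t_end_min,
            "frame_interval_min": config.frame_interval_min,
            "image_shape": list(config.image_shape),
        }, fh)
    logger.info("simulated %d spots -> %s", len(config.layout.spots), outdir)
    return truth
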