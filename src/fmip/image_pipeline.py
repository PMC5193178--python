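"""Ratiometric FRET image quantification.

The chain mirrors a classic ImageJ/Fiji ratio-imaging macro: per-channel
background subtraction using the Triangle histogram threshold, median
smoothing, a Huang fuzzy-threshold cell mask with NaN background, Triangle
nucleus detection on the nuclear-marker channel, nucleus-seeded watershed
segmentation, per-ROI mean intensities and FRET/CFP ratios, greedy
nearest-centroid tracking, and an expression gate on pre-stimulus CFP
intensity.

Both histogram thresholds operate on an explicit 256-bin histogram of the
finite pixel values (bins span [min, max]); they return a *bin index* so the
decision is exactly reproducible from the histogram alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import disk
from skimage.segmentation import watershed

logger = logging.getLogger("fmip")

N_BINS = 256

# --------------------------------------------------------------------------
# Frame containers
# --------------------------------------------------------------------------


@dataclass
class FrameSet:
    """One time point: CFP (donor), FRET (acceptor) and nuclear-marker images.

    All channels must share a shape; intensities are camera counts (a.u.).
    """

    cfp: np.ndarray
    fret: np.ndarray
    nuclear: np.ndarray
    time_min: float = 0.0

    def __post_init__(self) -> None:
        if not (self.cfp.shape == self.fret.shape == self.nuclear.shape):
            raise ValueError("channel images must have identical dimensions")


@dataclass
class LabelMap:
    """Cell segmentation for one frame: nucleus mask and integer ROI labels."""

    nucleus_mask: np.ndarray
    cell_labels: np.ndarray
    roi_count: int


# --------------------------------------------------------------------------
# Histogram thresholds
# --------------------------------------------------------------------------


def _bin_indices(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign each finite pixel a bin in 0..255; returns (indices, edges)."""
    values = np.asarray(img, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("image has no finite pixels")
    lo, hi = float(finite.min()), float(finite.max())
    edges = np.linspace(lo, hi if hi > lo else lo + 1.0, N_BINS + 1)
    if hi > lo:
        idx = np.floor((values - lo) / (hi - lo) * N_BINS).astype(np.int64)
    else:
        idx = np.zeros(values.shape, dtype=np.int64)
    return np.clip(idx, 0, N_BINS - 1), edges


def histogram_256(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """256-bin histogram of the finite pixels; returns (counts, bin edges)."""
    idx, edges = _bin_indices(img)
    counts = np.bincount(idx[np.isfinite(np.asarray(img, dtype=float))],
                         minlength=N_BINS)
    return counts.astype(np.int64), edges


def triangle_threshold(counts: np.ndarray) -> int:
    """Triangle threshold on a histogram; returns the threshold bin index.

    A line is drawn from the histogram peak to the furthest non-empty bin
    (on the longer-tailed side); the threshold is the bin whose point
    (bin, count) lies furthest from that line.  All arithmetic is integer
    cross products, so the result is exact.
    """
    counts = np.asarray(counts, dtype=np.int64)
    nz = np.flatnonzero(counts)
    if nz.size == 0:
        raise ValueError("empty histogram")
    low, high = int(nz[0]), int(nz[-1])
    peak = int(np.argmax(counts))
    if low == high:
        return low
    if high - peak >= peak - low:
        x1, x2 = peak, high
    else:
        x1, x2 = low, peak
    y1, y2 = counts[x1], counts[x2]
    xs = np.arange(x1, x2 + 1, dtype=np.int64)
    # |cross product| is proportional to the point-line distance
    cross = np.abs((y2 - y1) * (xs - x1) - (x2 - x1) * (counts[xs] - y1))
    return int(xs[np.argmax(cross)])


def huang_threshold(counts: np.ndarray) -> int:
    """Huang & Wang minimal-fuzziness threshold; returns the bin index.

    For each candidate threshold the histogram splits into background
    (bins <= t) and foreground (> t); membership of bin i to its region mean
    is u = 1/(1 + |i - mu|/C) with C the occupied histogram range, and the
    threshold minimises the count-weighted Shannon entropy of u.
    """
    counts = np.asarray(counts, dtype=np.int64)
    nz = np.flatnonzero(counts)
    if nz.size == 0:
        raise ValueError("empty histogram")
    first, last = int(nz[0]), int(nz[-1])
    if first == last:
        return first
    c_range = float(last - first)
    bins = np.arange(counts.size, dtype=float)
    s0 = np.cumsum(counts)
    s1 = np.cumsum(counts * bins)
    total0, total1 = s0[-1], s1[-1]

    best_t, best_f = first, np.inf
    occupied = counts > 0
    for t in range(first, last):
        n_bg = s0[t]
        n_fg = total0 - n_bg
        if n_bg == 0 or n_fg == 0:
            continue
        mu0 = s1[t] / n_bg
        mu1 = (total1 - s1[t]) / n_fg
        mu = np.where(bins <= t, mu0, mu1)
        u = 1.0 / (1.0 + np.abs(bins - mu) / c_range)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -u * np.log(u) - (1.0 - u) * np.log(1.0 - u)
        ent[~np.isfinite(ent)] = 0.0  # u == 1 contributes zero entropy
        fuzz = float(np.sum(counts[occupied] * ent[occupied]))
        if fuzz < best_f:
            best_f, best_t = fuzz, t
    return best_t


def triangle_background(img: np.ndarray) -> tuple[float, np.ndarray]:
    """Estimate the background level and subtract it from every pixel.

    The background mean is the mean of all pixels in histogram bins at or
    below the Triangle threshold.  Returns (background_mean, corrected
    image); corrected values may be negative until masking.
    """
    idx, _ = _bin_indices(img)
    counts = np.bincount(idx.ravel(), minlength=N_BINS).astype(np.int64)
    t = triangle_threshold(counts)
    values = np.asarray(img, dtype=float)
    background_mean = float(values[idx <= t].mean())
    return background_mean, values - background_mean


def preprocess(img: np.ndarray, radius: int = 2) -> np.ndarray:
    """Median-smooth with a circular neighbourhood; returns a float image."""
    return ndi.median_filter(np.asarray(img, dtype=float),
                             footprint=disk(radius))


def huang_mask(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Cell mask via Huang thresholding; sub-threshold pixels become NaN.

    Returns (mask, masked image, threshold intensity).  Pixels whose
    intensity stays close to the background fall below the Huang threshold
    and are excluded from every downstream ROI statistic.
    """
    idx, edges = _bin_indices(img)
    counts = np.bincount(idx.ravel(), minlength=N_BINS).astype(np.int64)
    t = huang_threshold(counts)
    values = np.asarray(img, dtype=float)
    if np.count_nonzero(counts) == 1:
        # constant image: foreground iff it sits above zero background
        mask = np.isfinite(values) & (values > 0)
    else:
        mask = idx > t
    if not mask.any():
        warnings.warn("huang_mask: no foreground pixels found", stacklevel=2)
    masked = np.where(mask, np.asarray(img, dtype=float), np.nan)
    return mask, masked, float(edges[t + 1])


# --------------------------------------------------------------------------
# Segmentation and measurement
# --------------------------------------------------------------------------

_CROSS = ndi.generate_binary_structure(2, 1)  # 4-connectivity


def nucleus_mask_from(nuclear_img: np.ndarray) -> np.ndarray:
    """Binary nucleus mask: Triangle threshold on the nuclear-marker image."""
    idx, _ = _bin_indices(nuclear_img)
    counts = np.bincount(idx.ravel(), minlength=N_BINS).astype(np.int64)
    return idx > triangle_threshold(counts)


def segment_cells(
    nuclear_img: np.ndarray,
    cell_mask: np.ndarray,
    min_area: int = 50,
    min_nucleus_area: int = 10,
) -> LabelMap:
    """Nucleus-seeded watershed segmentation of the cell mask.

    Nuclei are Triangle-thresholded from the nuclear channel and used as
    seeds for a watershed on the negated distance transform of the cell
    mask, splitting touching cells along the midline between seeds.
    Regions smaller than ``min_area`` pixels are discarded (the particle
    filter step) and the survivors relabelled 1..n.
    """
    nucleus_mask = nucleus_mask_from(nuclear_img)
    seeds, n_seeds = ndi.label(nucleus_mask, structure=_CROSS)
    if n_seeds and min_nucleus_area > 1:
        areas = np.bincount(seeds.ravel())
        too_small = np.flatnonzero(areas < min_nucleus_area)
        seeds[np.isin(seeds, too_small[too_small > 0])] = 0
        seeds, n_seeds = ndi.label(seeds > 0, structure=_CROSS)
    if n_seeds == 0:
        warnings.warn("segment_cells: no nuclei found", stacklevel=2)
        return LabelMap(nucleus_mask, np.zeros_like(seeds), 0)

    distance = ndi.distance_transform_edt(cell_mask)
    labels = watershed(-distance, markers=seeds, mask=cell_mask,
                       connectivity=1)
    # particle filter: drop small regions, relabel sequentially
    out = np.zeros_like(labels)
    next_label = 0
    for lab in range(1, labels.max() + 1):
        region = labels == lab
        if region.sum() >= min_area:
            next_label += 1
            out[region] = next_label
    return LabelMap(nucleus_mask, out, next_label)


def measure_rois(
    label_map: LabelMap,
    cfp_masked: np.ndarray,
    fret_masked: np.ndarray,
) -> pd.DataFrame:
    """Per-ROI mean CFP, mean FRET, FRET/CFP ratio and centroid.

    Means are taken over pixels that are non-NaN in both channels; an ROI
    with no valid pixels is kept with NaN measurements and ``all_nan`` set.
    """
    if not (label_map.cell_labels.shape == cfp_masked.shape
            == fret_masked.shape):
        raise ValueError("images and labels must share a shape")
    rows = []
    labels = label_map.cell_labels
    valid = np.isfinite(cfp_masked) & np.isfinite(fret_masked)
    for roi in range(1, label_map.roi_count + 1):
        region = labels == roi
        ys, xs = np.nonzero(region)
        sel = region & valid
        n_valid = int(sel.sum())
        if n_valid:
            mean_cfp = float(cfp_masked[sel].mean())
            mean_fret = float(fret_masked[sel].mean())
            ratio = mean_fret / mean_cfp if mean_cfp != 0 else np.nan
        else:
            mean_cfp = mean_fret = ratio = np.nan
        rows.append({
            "roi_id": roi,
            "mean_cfp": mean_cfp,
            "mean_fret": mean_fret,
            "ratio": ratio,
            "x": float(xs.mean()),
            "y": float(ys.mean()),
            "n_pixels": n_valid,
            "all_nan": n_valid == 0,
        })
    return pd.DataFrame(
        rows, columns=["roi_id", "mean_cfp", "mean_fret", "ratio",
                       "x", "y", "n_pixels", "all_nan"])


def quantify_frameset(fs: FrameSet, min_area: int = 50) -> pd.DataFrame:
    """Run the full per-frame chain and return ROI measurements.

    Background subtraction and median smoothing are applied per channel;
    the Huang cell mask is derived from the smoothed CFP (expression)
    channel and applied to both emission channels so that every ROI mean
    uses the identical pixel set in numerator and denominator.
    """
    _, cfp_corr = triangle_background(fs.cfp)
    _, fret_corr = triangle_background(fs.fret)
    cfp_f = preprocess(cfp_corr)
    fret_f = preprocess(fret_corr)
    mask, cfp_masked, _ = huang_mask(cfp_f)
    fret_masked = np.where(mask, fret_f, np.nan)
    label_map = segment_cells(fs.nuclear, mask, min_area=min_area)
    df = measure_rois(label_map, cfp_masked, fret_masked)
    df.insert(0, "time_min", fs.time_min)
    return df


# --------------------------------------------------------------------------
# Tracking and expression gate
# --------------------------------------------------------------------------


def link_rois(
    measurements: pd.DataFrame,
    max_displacement: float = 15.0,
    min_length: int = 1,
) -> pd.DataFrame:
    """Link per-frame ROIs into cell tracks by greedy nearest-centroid.

    Candidate (track, ROI) pairs between consecutive frames are assigned in
    order of increasing centroid distance, discarding pairs beyond
    ``max_displacement`` pixels.  Unmatched ROIs start new tracks; tracks
    shorter than ``min_length`` frames are dropped.  Adds a ``cell_id``
    column.
    """
    required = {"frame", "roi_id", "x", "y"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = measurements.sort_values(["frame", "roi_id"]).copy()
    df["cell_id"] = -1
    frames = sorted(df["frame"].unique())
    next_track = 0
    prev_pos: dict[int, np.ndarray] = {}
    for fr in frames:
        sel = df["frame"] == fr
        cur = df.loc[sel, ["x", "y"]].to_numpy(dtype=float)
        cur_index = df.index[sel]
        assigned = np.full(len(cur), -1, dtype=int)
        if prev_pos and len(cur):
            track_ids = list(prev_pos)
            prev = np.array([prev_pos[t] for t in track_ids])
            d = np.hypot(prev[:, None, 0] - cur[None, :, 0],
                         prev[:, None, 1] - cur[None, :, 1])
            order = np.dstack(np.unravel_index(np.argsort(d, axis=None),
                                               d.shape))[0]
            used_tracks: set[int] = set()
            used_rois: set[int] = set()
            for ti, ri in order:
                if d[ti, ri] > max_displacement:
                    break
                if ti in used_tracks or ri in used_rois:
                    continue
                assigned[ri] = track_ids[ti]
                used_tracks.add(ti)
                used_rois.add(ri)
        for ri in range(len(cur)):
            if assigned[ri] < 0:
                assigned[ri] = next_track
                next_track += 1
        df.loc[cur_index, "cell_id"] = assigned
        prev_pos = {assigned[ri]: cur[ri] for ri in range(len(cur))}
    if min_length > 1:
        lengths = df.groupby("cell_id")["frame"].size()
        keep = lengths.index[lengths >= min_length]
        df = df[df["cell_id"].isin(keep)]
    return df.reset_index(drop=True)


def filter_expression(
    trajectories: pd.DataFrame,
    cfp_min: float = 700.0,
    cfp_max: float = 8000.0,
    stimulation_time: float | None = None,
) -> pd.DataFrame:
    """Keep cells whose mean pre-stimulus CFP lies within [cfp_min, cfp_max].

    The expression gate removes low-expressing cells (unreliable ratios)
    and saturating ones.  ``stimulation_time`` selects the pre-stimulus
    frames; when None the whole track is used.
    """
    df = trajectories
    pre = df if stimulation_time is None else df[
        df["time_min"] < stimulation_time]
    levels = pre.groupby("cell_id")["mean_cfp"].mean()
    keep = levels.index[(levels >= cfp_min) & (levels <= cfp_max)]
    out = df[df["cell_id"].isin(keep)].reset_index(drop=True)
    if out.empty and not df.empty:
        warnings.warn("filter_expression: no cells within the expression "
                      "window", stacklevel=2)
    return out


def quantify_stack(
    cfp_stack: np.ndarray,
    fret_stack: np.ndarray,
    nuc_stack: np.ndarray,
    times_min: np.ndarray,
    spot_id: str = "spot",
    min_area: int = 50,
    max_displacement: float = 15.0,
    min_length: int = 1,
) -> pd.DataFrame:
    """Quantify a whole movie: per-frame segmentation + measurement, then
    tracking.  Returns the long measurements table (one row per cell and
    frame) with ``spot_id``, ``cell_id`` and ratio columns."""
    if not (len(cfp_stack) == len(fret_stack) == len(nuc_stack)
            == len(times_min)):
        raise ValueError("stacks and time vector must have equal length")
    frames = []
    for i, t in enumerate(times_min):
        df = quantify_frameset(
            FrameSet(cfp_stack[i], fret_stack[i], nuc_stack[i], float(t)),
            min_area=min_area)
        df.insert(0, "frame", i)
        frames.append(df)
    measurements = pd.concat(frames, ignore_index=True)
    linked = link_rois(measurements, max_displacement=max_displacement,
                       min_length=min_length)
    linked.insert(0, "spot_id", spot_id)
    return linked
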