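"""Raw-trace conditioning: resampling, smoothing, gap filling, background
subtraction, motion correction, gastrulation-time estimation and trace
selection."""
from __future__ import annotations

import logging
import math

import numpy as np
from scipy import ndimage
from scipy.stats import gaussian_kde

from .datatypes import BackgroundModel, EmbryoDataset

logger = logging.getLogger(__name__)


def interpolate_trace(
    t: np.ndarray, values: np.ndarray, target_interval: float = 20.0
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly resample a trace onto a uniform grid (seconds interval).

    The grid is anchored at the first timepoint and never extends beyond the
    last, so re-interpolating an already-resampled trace is a no-op.
    """
    if len(t) < 2:
        raise ValueError("need at least two frames to interpolate")
    dt = target_interval / 60.0  # minutes
    n = int(math.floor((t[-1] - t[0]) / dt + 1e-9)) + 1
    t_new = t[0] + np.arange(n) * dt
    return t_new, np.interp(t_new, t, values)


def smoothing_window_frames(frame_interval: float, window_min: float = 4.0) -> int:
    """Odd number of frames spanning a centered moving window."""
    n = int(round(window_min * 60.0 / frame_interval))
    return n + 1 if n % 2 == 0 else n


def smooth_trace(
    values: np.ndarray, frame_interval: float, window_min: float = 4.0
) -> np.ndarray:
    """Centered moving mean, window truncated at the trace edges.

    NaN frames (nucleus absent) are excluded from the local mean and stay NaN
    in the output.
    """
    w = smoothing_window_frames(frame_interval, window_min)
    finite = np.isfinite(values)
    v = np.where(finite, values, 0.0)
    kernel = np.ones(w)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(finite.astype(float), kernel, mode="same")
    out = np.full_like(v, np.nan, dtype=float)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    out[~finite] = np.nan
    return out


def fill_trace_gaps(spot: np.ndarray) -> np.ndarray:
    """Close 1-2 frame dips in a spot trace (grayscale closing, 3-frame
    structuring element); gaps of three or more frames survive."""
    if len(spot) < 3:
        return spot.copy()
    closed = ndimage.grey_erosion(
        ndimage.grey_dilation(spot, size=3, mode="nearest"), size=3, mode="nearest"
    )
    # closing is extensive; the maximum guards the boundary frames
    return np.maximum(closed, spot)


def local_movement_time(
    t: np.ndarray, y: np.ndarray, frame_interval: float, window_min: float = 4.0
) -> float | None:
    """Time of the last strict local extremum of the smoothed y-trace.

    Plateaus count at their last frame. Returns None when y is monotone.
    """
    ys = smooth_trace(y, frame_interval, window_min)
    d = np.diff(ys)
    s = np.sign(d)
    # propagate through plateaus so ties resolve at the plateau's last frame
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    flips = np.flatnonzero(s[:-1] * s[1:] < 0)
    if len(flips) == 0:
        return None
    return float(t[flips[-1] + 1])


def determine_gastrulation_time(
    embryo: EmbryoDataset, window_min: float = 4.0, grid_s: float = 1.0
) -> tuple[float, dict[int, float]]:
    """Embryo gastrulation time from the mode of per-nucleus movement times.

    Each nucleus contributes the time of the last extremum of its (smoothed)
    y-coordinate; a Gaussian kernel density (Silverman bandwidth) is fitted
    over those local movement times and its global mode, located on a
    1-second grid, is the gastrulation time.
    """
    times = {}
    for nid, tr in embryo.traces.items():
        lm = local_movement_time(embryo.t, tr.y, embryo.frame_interval, window_min)
        if lm is not None:
            times[nid] = lm
    if len(times) < 5:
        raise ValueError("no directed movement found (fewer than 5 usable nuclei)")
    vals = np.array(list(times.values()))
    if np.ptp(vals) == 0:
        return float(vals[0]), times
    kde = gaussian_kde(vals, bw_method="silverman")
    step = grid_s / 60.0
    grid = np.arange(vals.min(), vals.max() + step, step)
    mode = float(grid[int(np.argmax(kde(grid)))])
    return mode, times


def tukey_median(values: np.ndarray) -> float:
    """Median after excluding points beyond 1.5x IQR from the quartiles."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    keep = (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)
    return float(np.median(v[keep]))


def fit_background_model(
    bg_1x_means: list[float],
    bg_2x_means: list[float],
    control_1x_medians: list[float],
    control_2x_medians: list[float],
) -> BackgroundModel:
    """Background levels and copy-number thresholds from control embryos.

    bg_*x_means: mean nuclear GFP at gastrulation in background-construct
    embryos. control_*x_medians: AB-median protein at gastrulation in
    control embryos of known GFP copy number. T_lower = mean - SD of the 1x
    control medians; T_upper = mean + SD of the 2x control medians.
    """
    if min(len(control_1x_medians), len(control_2x_medians)) < 2:
        raise ValueError("need at least 2 control embryos per genotype")
    lo = np.asarray(control_1x_medians, dtype=float)
    hi = np.asarray(control_2x_medians, dtype=float)
    return BackgroundModel(
        bg_1x=float(np.mean(bg_1x_means)),
        bg_2x=float(np.mean(bg_2x_means)),
        t_lower=float(lo.mean() - lo.std(ddof=1)),
        t_upper=float(hi.mean() + hi.std(ddof=1)),
    )


def assign_gfp_copy_number(median_ab_at_gastrulation: float, model: BackgroundModel) -> str:
    """'1x' below T_lower, '2x' above T_upper, otherwise 'excluded'.

    Medians exactly at a threshold are excluded (conservative).
    """
    if median_ab_at_gastrulation < model.t_lower:
        return "1x"
    if median_ab_at_gastrulation > model.t_upper:
        return "2x"
    return "excluded"


def subtract_background(values: np.ndarray, background: float) -> np.ndarray:
    """Elementwise background subtraction; values are not clipped at zero so
    ensemble means stay unbiased."""
    if background < 0:
        raise ValueError("background must be nonnegative")
    return values - background


def engrailed_background(
    embryo: EmbryoDataset, assignment, n_final_frames: int = 1
) -> float:
    """Background from the anterior neighbors of AB nuclei at the video end."""
    ab = set(assignment.ab)
    donors = set()
    for a in ab:
        xa = np.nanmean(embryo.traces[a].x)
        for j in embryo.neighbors.get(a, ()):
            if j in ab or assignment.classes.get(j) in ("PB", "stripe"):
                continue
            if np.nanmean(embryo.traces[j].x) < xa:
                donors.add(j)
    if not donors:
        raise ValueError("no anterior neighbors of AB nuclei found")
    vals = [embryo.traces[j].protein[-n_final_frames:] for j in sorted(donors)]
    return float(np.nanmean(np.concatenate(vals)))


def correct_motion(protein: np.ndarray, marker: np.ndarray) -> np.ndarray:
    """Divide the protein trace by the marker trace normalized to its first
    timepoint, compensating z-movement (and partially bleaching)."""
    first = np.flatnonzero(np.isfinite(marker))
    if len(first) == 0 or marker[first[0]] <= 0:
        raise ValueError("marker trace must be strictly positive at the start")
    factor = marker / marker[first[0]]
    out = np.full_like(protein, np.nan, dtype=float)
    ok = np.isfinite(factor) & (factor != 0)
    out[ok] = protein[ok] / factor[ok]
    return out


def select_complete_traces(embryo: EmbryoDataset) -> list[int]:
    """Nuclei tracked without gaps from the video start to the manual
    gastrulation time."""
    end = embryo.frame_of(embryo.manual_gastrulation)
    keep = []
    for nid, tr in embryo.traces.items():
        if np.all(np.isfinite(tr.protein[: end + 1])):
            keep.append(nid)
    return sorted(keep)


def preprocess_embryo(
    embryo: EmbryoDataset,
    background: float = 0.0,
    target_interval: float = 20.0,
    smooth_window_min: float = 4.0,
    motion_correct: bool = False,
    marker: dict[int, np.ndarray] | None = None,
) -> EmbryoDataset:
    """Standard conditioning: resample to the target interval, smooth the
    protein traces, fill spot-trace gaps, subtract background and estimate
    gastrulation times. Returns a new dataset."""
    out = embryo.copy()
    t_new = None
    for nid, tr in out.traces.items():
        t_new, prot = interpolate_trace(out.t, tr.protein, target_interval)
        _, spot = interpolate_trace(out.t, tr.spot, target_interval)
        _, xx = interpolate_trace(out.t, tr.x, target_interval)
        _, yy = interpolate_trace(out.t, tr.y, target_interval)
        if motion_correct and marker is not None and nid in marker:
            _, mk = interpolate_trace(out.t, marker[nid], target_interval)
            prot = correct_motion(prot, mk)
        prot = smooth_trace(prot, target_interval, smooth_window_min)
        prot = subtract_background(prot, background)
        spot = fill_trace_gaps(spot)
        tr.x, tr.y, tr.protein, tr.spot = xx, yy, prot, spot
        if tr.spot2 is not None:
            _, sp2 = interpolate_trace(out.t, tr.spot2, target_interval)
            tr.spot2 = fill_trace_gaps(sp2)
    if t_new is not None:
        out.t = t_new
        out.frame_interval = target_interval
    g, per_nucleus = determine_gastrulation_time(out)
    out.computed_gastrulation = g
    out.local_movement_times = per_nucleus
    return out
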