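"""Synthetic embryo generator with known ground truth.

Emulates the statistical structure of time-lapse boundary-nucleus data: a
quasi-hexagonal nuclear lattice with stripe bands (posterior-boundary PB and
anterior-boundary AB rows at each stripe's anterior edge), smooth protein
traces that diverge between PB and AB before gastrulation, two-mode bursty
transcription gated by a timer or a concentration threshold, directed nuclear
movement at gastrulation onset, optional heat-shock protein pulses and a
second timer-gated transcription unit.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.spatial import Delaunay

from .config import HeatShockParams, ModeParams, SimConfig
from .datatypes import ConfigError, EmbryoDataset, NucleusTrace

logger = logging.getLogger(__name__)

# Protein-shape anchors (minutes -> a.u.). AB and PB share the early history
# and separate after -20 min; values are scaled so the AB trace passes through
# ab_level_at_gastrulation at t=0 and the PB trace through ratio x that level.
_SHARED_T = np.array([-75.0, -60.0, -35.0, -20.0])
_SHARED_V = np.array([0.75, 0.80, 1.00, 0.85])
_AB_TAIL_T = np.array([-10.0, 0.0, 20.0])
_AB_TAIL_V = np.array([0.68, 0.50, 0.42])
# PB protein keeps rising after gastrulation (autoregulation maintains the
# high state), which the misclassification diagnostics rely on
_PB_TAIL_T = np.array([-15.0, -8.0, 0.0, 10.0, 20.0])
_PB_TAIL_V = np.array([1.20, 1.80, 2.00, 2.40, 2.60])

_LATTICE_DX = 20.0  # px, anterior-posterior spacing
_LATTICE_DY = 17.3  # px, row spacing (hexagonal packing)
# Dorsal-ventral drift reverses at gastrulation onset; equal speeds keep the
# smoothed-trace extremum centered on the true onset.
_V_PRE = 3.0  # px/min, pre-gastrulation drift (y decreasing)
_V_POST = 3.0  # px/min, directed movement after gastrulation onset


def protein_shape(kind: str, ab_level: float, ratio: float) -> PchipInterpolator:
    """Monotone-spline protein trace shape for a nucleus class.

    kind: 'AB' | 'PB' | 'interior' | 'non-stripe'.
    """
    ab_scale = ab_level / 0.5
    if kind in ("AB", "non-stripe"):
        t = np.concatenate([_SHARED_T, _AB_TAIL_T])
        v = np.concatenate([_SHARED_V, _AB_TAIL_V]) * ab_scale
        if kind == "non-stripe":
            v = v * 0.9
    elif kind in ("PB", "interior"):
        pb_scale = ratio * ab_level / 2.0
        t = np.concatenate([_SHARED_T, _PB_TAIL_T])
        v = np.concatenate([_SHARED_V * ab_scale, _PB_TAIL_V * pb_scale])
        if kind == "interior":
            v = np.concatenate([_SHARED_V * ab_scale, _PB_TAIL_V * pb_scale * 1.05])
    else:
        raise ValueError(f"unknown nucleus class {kind!r}")
    interp = PchipInterpolator(t, v)
    lo, hi = t[0], t[-1]

    def shape(x):
        return interp(np.clip(x, lo, hi))

    shape.t_range = (lo, hi)
    return shape


def truncated_exponential(rng: np.random.Generator, mean: float, upper: float, size=None):
    """Exponential(mean) truncated at `upper` by inverse-CDF sampling."""
    u = rng.random(size)
    return -mean * np.log1p(-u * (1.0 - math.exp(-upper / mean)))


@dataclass
class GroundTruth:
    """Per-nucleus classes and per-burst labels the generator knows."""

    nuclei: pd.DataFrame  # nucleus_id, cls, stripe, activation_time,
    #                       activation_time_2, gastrulation, fade_time
    bursts: pd.DataFrame  # nucleus_id, unit, start, end, mode, mean_intensity

    def class_of(self, nucleus_id: int) -> str:
        return self._by_id().loc[nucleus_id, "cls"]

    def _by_id(self) -> pd.DataFrame:
        return self.nuclei.set_index("nucleus_id")

    def ids_of(self, cls: str) -> list[int]:
        sel = self.nuclei[self.nuclei["cls"] == cls]
        return sorted(sel["nucleus_id"].tolist())


def _lattice(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Hexagonal nucleus lattice with stripe bands painted along x.

    Each stripe occupies three columns; the anterior-most stripe column is
    the PB row and the non-stripe column just anterior of it is the AB row.
    """
    rows, cols = config.rows, config.nuclei_per_row
    span = (cols - 2) // config.n_stripes  # columns per stripe unit
    pb_cols = [2 + s * span for s in range(config.n_stripes)]
    recs = []
    nid = 0
    for r in range(rows):
        for c in range(cols):
            cls, stripe = "non-stripe", 0
            for s, c0 in enumerate(pb_cols):
                if c == c0:
                    cls, stripe = "PB", s + 1
                elif c in (c0 + 1, c0 + 2):
                    cls, stripe = "interior", s + 1
                elif c == c0 - 1:
                    cls, stripe = "AB", s + 1
            x = c * _LATTICE_DX + (r % 2) * (_LATTICE_DX / 2.0)
            y = r * _LATTICE_DY
            recs.append((nid, r, c, x, y, cls, stripe))
            nid += 1
    df = pd.DataFrame(
        recs, columns=["nucleus_id", "row", "col", "x0", "y0", "cls", "stripe"]
    )
    df["x0"] += rng.uniform(-1.0, 1.0, len(df))
    df["y0"] += rng.uniform(-1.0, 1.0, len(df))
    return df


def _neighbor_graph(xy: np.ndarray) -> dict[int, set[int]]:
    """Quasi-hexagonal adjacency from a Delaunay triangulation.

    Long convex-hull slivers are dropped by an edge-length cutoff at 1.6x the
    median edge length.
    """
    tri = Delaunay(xy)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = simplex[a], simplex[(a + 1) % 3]
            edges.add((min(i, j), max(i, j)))
    edges = np.array(sorted(edges))
    lengths = np.linalg.norm(xy[edges[:, 0]] - xy[edges[:, 1]], axis=1)
    keep = edges[lengths <= 1.6 * np.median(lengths)]
    nb: dict[int, set[int]] = {i: set() for i in range(len(xy))}
    for i, j in keep:
        nb[int(i)].add(int(j))
        nb[int(j)].add(int(i))
    return nb


def simulate_burst_train(
    mode: ModeParams,
    active_window: tuple[float, float],
    frame_grid: np.ndarray,
    rng: np.random.Generator,
    start_on: bool = False,
    intensity_noise_sd: float = 0.0,
    dropout_prob: float = 0.0,
) -> tuple[np.ndarray, list[dict]]:
    """Alternating on/off transcription episodes inside a time window.

    Returns the per-frame intensity trace (zeros outside bursts) and the list
    of generated bursts (clean of dropout) with their frame spans and mean
    intensities. On-episode durations follow a truncated exponential bounded
    by the mode's burst_duration_max; off episodes have a floor of
    interburst_min so distinct bursts stay separable after gap filling.
    """
    trace = np.zeros(len(frame_grid))
    bursts: list[dict] = []
    w0, w1 = active_window
    if w1 <= w0:
        return trace, bursts
    dt = frame_grid[1] - frame_grid[0] if len(frame_grid) > 1 else 1.0
    t = w0
    if not start_on:
        t += mode.interburst_min + rng.exponential(mode.interburst_mean)
    while t < w1:
        dur = float(truncated_exponential(rng, mode.burst_duration_mean, mode.burst_duration_max))
        t_on, t_off = t, min(t + dur, w1)
        idx = np.flatnonzero((frame_grid >= t_on - dt / 2) & (frame_grid < t_off - dt / 2))
        if len(idx):
            b = max(0.05, rng.normal(mode.mean_intensity, mode.intensity_sd))
            vals = b + rng.normal(0.0, intensity_noise_sd, len(idx))
            trace[idx] = np.maximum(vals, 0.05)
            bursts.append(
                {
                    "start": int(idx[0]),
                    "end": int(idx[-1]),
                    "mean_intensity": float(b),
                }
            )
        t = t_off + mode.interburst_min + rng.exponential(mode.interburst_mean)
    if dropout_prob > 0:
        on = trace > 0
        drop = on & (rng.random(len(trace)) < dropout_prob)
        trace[drop] = 0.0
    return trace, bursts


def simulate_heat_shock(
    embryo: EmbryoDataset, hs: HeatShockParams
) -> EmbryoDataset:
    """Add an ectopic protein pulse to every nucleus (in place).

    The pulse is Gaussian in time with width at half-maximum equal to
    hs.pulse_duration, peaking peak_delay minutes after the shock starts.
    """
    if hs.amplitude == 0:
        return embryo
    if hs.start > embryo.t[-1]:
        logger.warning("heat shock start %.1f min is after the video ends", hs.start)
        return embryo
    sigma = hs.pulse_duration / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    t_peak = hs.start + hs.peak_delay
    pulse = hs.amplitude * np.exp(-0.5 * ((embryo.t - t_peak) / sigma) ** 2)
    for tr in embryo.traces.values():
        tr.protein = tr.protein + pulse
    embryo.heat_shock_start = hs.start
    return embryo


def _activation_times(
    config: SimConfig,
    clean_protein: np.ndarray,
    t: np.ndarray,
    rng: np.random.Generator,
) -> float:
    """Per-nucleus activation time under the configured model.

    timer: drawn from Normal(timer_mean, timer_sd). threshold: the first
    frame at which the clean (noise-free, background-free) protein signal
    reaches threshold_level; NaN if it never does.
    """
    if config.activation_model == "timer":
        return float(rng.normal(config.timer_mean, config.timer_sd))
    above = np.flatnonzero(clean_protein >= config.threshold_level)
    return float(t[above[0]]) if len(above) else float("nan")


def simulate_embryo(config: SimConfig, embryo_id: str = "sim0") -> tuple[EmbryoDataset, GroundTruth]:
    """Generate one embryo dataset and its ground truth."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed))
    noise = config.noise
    t = config.t_start + np.arange(config.n_frames) * config.dt_min
    lat = _lattice(config, rng)
    n = len(lat)
    nb = _neighbor_graph(lat[["x0", "y0"]].to_numpy())

    shapes = {
        k: protein_shape(k, config.ab_level_at_gastrulation, config.protein_ratio_pb_ab)
        for k in ("AB", "PB", "interior", "non-stripe")
    }
    amp = np.maximum(0.3, 1.0 + rng.normal(0.0, noise.protein_amp_sd, n))
    shift = rng.normal(0.0, noise.time_shift_sd, n)
    g_i = rng.normal(0.0, config.gastrulation_jitter_sd, n)

    hs_on = config.construct == "heatshock" and config.heat_shock is not None
    hs_late = hs_on and config.heat_shock.start >= -15.0

    traces: dict[int, NucleusTrace] = {}
    truth_rows = []
    burst_rows = []
    for k in range(n):
        row = lat.iloc[k]
        nid = int(row["nucleus_id"])
        cls = row["cls"]
        clean = amp[k] * shapes[cls](t - shift[k])

        # transcription windows by construct and class
        spot = np.zeros_like(t)
        spot2 = None
        t_act = float("nan")
        t_act2 = float("nan")
        fade = float("nan")
        nucleus_bursts: list[tuple[int, str, list[dict]]] = []  # (unit, mode name, bursts)
        low, high = config.low_mode, config.high_mode

        def train(mode, window, start_on=False):
            return simulate_burst_train(
                mode, window, t, rng, start_on=start_on,
                intensity_noise_sd=noise.spot_sd, dropout_prob=0.0,
            )

        if cls in ("AB", "non-stripe"):
            fade = config.divergence_time + rng.exponential(config.ab_fade_mean)
            if config.construct in ("endogenous", "zebra"):
                spot, bl = train(low, (config.t_start, fade))
                nucleus_bursts.append((1, "low", bl))
            elif hs_late and rng.random() < config.ectopic_fraction:
                w0 = config.heat_shock.start + 5.0
                spot, bl = train(high, (w0, config.t_end), start_on=True)
                nucleus_bursts.append((1, "high", bl))
        else:  # PB / interior
            t_act = _activation_times(config, clean, t, rng)
            if config.construct == "endogenous":
                t_switch = t_act if np.isfinite(t_act) else config.t_end
                s1, b1 = train(low, (config.t_start, t_switch))
                s2, b2 = train(high, (t_switch, config.t_end), start_on=True)
                spot = np.where(t >= t_switch, s2, s1)
                nucleus_bursts.append((1, "low", b1))
                nucleus_bursts.append((1, "high", b2))
            elif config.construct == "zebra":
                pb_fade = config.timer_mean + rng.exponential(config.ab_fade_mean)
                spot, bl = train(low, (config.t_start, pb_fade))
                fade = pb_fade
                nucleus_bursts.append((1, "low", bl))
            elif config.construct in ("autoregulatory", "heatshock"):
                if np.isfinite(t_act):
                    spot, bh = train(high, (t_act, config.t_end), start_on=True)
                    nucleus_bursts.append((1, "high", bh))
            elif config.construct == "engrailed":
                t_act2 = t_act + config.second_gene_offset
                spot, bh = train(high, (t_act2, config.t_end), start_on=True)
                nucleus_bursts.append((1, "high", bh))
            if config.second_gene and config.construct != "engrailed":
                t_act2 = t_act + config.second_gene_offset
                if np.isfinite(t_act2):
                    spot2, b2g = train(high, (t_act2, config.t_end), start_on=True)
                    nucleus_bursts.append((2, "high", b2g))

        # dropout applied to the observed traces only, after burst bookkeeping
        if noise.detection_dropout_prob > 0:
            for arr in (spot, spot2):
                if arr is None:
                    continue
                on = arr > 0
                arr[on & (rng.random(len(arr)) < noise.detection_dropout_prob)] = 0.0

        protein = clean + config.background + rng.normal(0.0, noise.protein_sd, len(t))

        # nuclear movement: slow downward drift, directed upward after onset
        pre = t <= g_i[k]
        y = np.where(
            pre,
            row["y0"] - _V_PRE * (t - config.t_start),
            row["y0"] - _V_PRE * (g_i[k] - config.t_start) + _V_POST * (t - g_i[k]),
        )
        y = y + rng.normal(0.0, noise.position_sd, len(t))
        x = row["x0"] + rng.normal(0.0, noise.position_sd / 2.0, len(t))

        traces[nid] = NucleusTrace(nid, x, y, protein, spot, spot2)
        truth_rows.append(
            (nid, cls, int(row["stripe"]), t_act, t_act2, float(g_i[k]), fade)
        )
        for unit, mode_name, bl in nucleus_bursts:
            for b in bl:
                burst_rows.append(
                    (nid, unit, b["start"], b["end"], mode_name, b["mean_intensity"])
                )

    embryo = EmbryoDataset(
        embryo_id=embryo_id,
        construct=config.construct,
        frame_interval=config.frame_interval,
        t=t,
        traces=traces,
        neighbors=nb,
        manual_gastrulation=0.0,
    )
    if hs_on:
        simulate_heat_shock(embryo, config.heat_shock)

    truth = GroundTruth(
        nuclei=pd.DataFrame(
            truth_rows,
            columns=[
                "nucleus_id", "cls", "stripe", "activation_time",
                "activation_time_2", "gastrulation", "fade_time",
            ],
        ),
        bursts=pd.DataFrame(
            burst_rows,
            columns=["nucleus_id", "unit", "start", "end", "mode", "mean_intensity"],
        ),
    )
    return embryo, truth


def simulate_dataset(
    config: SimConfig, n_embryos: int, base_seed: int | None = None
) -> list[tuple[EmbryoDataset, GroundTruth]]:
    """Simulate several embryos with per-embryo derived seeds."""
    base = config.rng_seed if base_seed is None else base_seed
    out = []
    for i in range(n_embryos):
        cfg = SimConfig(**{**config.__dict__, "rng_seed": int(base) + i})
        out.append(simulate_embryo(cfg, embryo_id=f"sim{i}"))
    return out
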