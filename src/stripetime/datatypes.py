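"""Core containers shared across the pipeline.

Traces live on a single uniform time grid per embryo (minutes relative to
gastrulation for synthetic data; arbitrary origin for real recordings until
re-alignment). Per-nucleus arrays are aligned to that grid, with NaN marking
frames where the nucleus was not tracked.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    """Raised when a configuration document violates the schema."""


@dataclass
class NucleusTrace:
    """One tracked nucleus: position, protein and transcription-spot signals."""

    nucleus_id: int
    x: np.ndarray
    y: np.ndarray
    protein: np.ndarray
    spot: np.ndarray
    spot2: Optional[np.ndarray] = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.x)
        for arr in (self.y, self.protein, self.spot):
            if len(arr) != n:
                raise ValueError("per-frame vectors must have equal length")
        if self.spot2 is not None and len(self.spot2) != n:
            raise ValueError("per-frame vectors must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.x)

    def copy(self) -> "NucleusTrace":
        return NucleusTrace(
            self.nucleus_id,
            self.x.copy(),
            self.y.copy(),
            self.protein.copy(),
            self.spot.copy(),
            None if self.spot2 is None else self.spot2.copy(),
            dict(self.flags),
        )


@dataclass
class EmbryoDataset:
    """All traces of one embryo plus its timeline and metadata."""

    embryo_id: str
    construct: str
    frame_interval: float  # seconds
    t: np.ndarray  # minutes
    traces: dict[int, NucleusTrace]
    neighbors: dict[int, set[int]]
    manual_gastrulation: float  # minutes, on the t axis
    computed_gastrulation: Optional[float] = None
    local_movement_times: dict[int, float] = field(default_factory=dict)
    gfp_copies: str = "unknown"  # '1x' | '2x' | 'unknown' | 'excluded'
    heat_shock_start: Optional[float] = None

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")
        if not (self.t[0] <= self.manual_gastrulation <= self.t[-1]):
            raise ValueError("manual gastrulation outside timeline")

    @property
    def dt_min(self) -> float:
        return self.frame_interval / 60.0

    def frame_of(self, t_min: float) -> int:
        """Index of the frame nearest to a time in minutes."""
        return int(np.argmin(np.abs(self.t - t_min)))

    def copy(self) -> "EmbryoDataset":
        return EmbryoDataset(
            self.embryo_id,
            self.construct,
            self.frame_interval,
            self.t.copy(),
            {i: tr.copy() for i, tr in self.traces.items()},
            {i: set(v) for i, v in self.neighbors.items()},
            self.manual_gastrulation,
            self.computed_gastrulation,
            dict(self.local_movement_times),
            self.gfp_copies,
            self.heat_shock_start,
        )

    @classmethod
    def from_table(
        cls,
        df: pd.DataFrame,
        construct: str = "endogenous",
        frame_interval: float | None = None,
        manual_gastrulation: float = 0.0,
        neighbors: dict[int, set[int]] | None = None,
    ) -> "EmbryoDataset":
        """Rebuild an embryo from a long trace table.

        Expected columns: embryo, nucleus, frame, t_min, x, y, protein,
        spot (and optionally spot2). Frames a nucleus misses are NaN.
        When no neighbor graph is supplied one is derived from the mean
        nucleus positions by Delaunay triangulation.
        """
        t = np.sort(df["t_min"].unique())
        index = {v: i for i, v in enumerate(t)}
        if frame_interval is None:
            frame_interval = float(np.median(np.diff(t)) * 60.0) if len(t) > 1 else 20.0
        traces: dict[int, NucleusTrace] = {}
        for nid, grp in df.groupby("nucleus"):
            arrs = {}
            cols = ["x", "y", "protein", "spot"] + (
                ["spot2"] if "spot2" in df.columns else []
            )
            rows = [index[v] for v in grp["t_min"]]
            for col in cols:
                a = np.full(len(t), np.nan)
                a[rows] = grp[col].to_numpy(dtype=float)
                if col in ("spot", "spot2"):
                    a = np.nan_to_num(a)
                arrs[col] = a
            traces[int(nid)] = NucleusTrace(
                int(nid), arrs["x"], arrs["y"], arrs["protein"], arrs["spot"],
                arrs.get("spot2"),
            )
        if neighbors is None:
            from scipy.spatial import Delaunay

            ids = sorted(traces)
            xy = np.array(
                [[np.nanmean(traces[i].x), np.nanmean(traces[i].y)] for i in ids]
            )
            neighbors = {i: set() for i in ids}
            if len(ids) >= 4:
                tri = Delaunay(xy)
                edges = set()
                for simplex in tri.simplices:
                    for a in range(3):
                        u, v = simplex[a], simplex[(a + 1) % 3]
                        edges.add((min(u, v), max(u, v)))
                lengths = {
                    e: float(np.linalg.norm(xy[e[0]] - xy[e[1]])) for e in edges
                }
                cutoff = 1.6 * np.median(list(lengths.values()))
                for (u, v), d in lengths.items():
                    if d <= cutoff:
                        neighbors[ids[u]].add(ids[v])
                        neighbors[ids[v]].add(ids[u])
        return cls(
            embryo_id=str(df["embryo"].iloc[0]),
            construct=construct,
            frame_interval=frame_interval,
            t=t,
            traces=traces,
            neighbors=neighbors,
            manual_gastrulation=manual_gastrulation,
        )

    def to_table(self) -> pd.DataFrame:
        rows = []
        for nid in sorted(self.traces):
            tr = self.traces[nid]
            frame = np.arange(tr.n_frames)
            df = pd.DataFrame(
                {
                    "embryo": self.embryo_id,
                    "nucleus": nid,
                    "frame": frame,
                    "t_min": self.t,
                    "x": tr.x,
                    "y": tr.y,
                    "protein": tr.protein,
                    "spot": tr.spot,
                }
            )
            if tr.spot2 is not None:
                df["spot2"] = tr.spot2
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


@dataclass
class Burst:
    """A contiguous transcription episode in one nucleus."""

    nucleus_id: int
    start: int  # frame index
    end: int  # inclusive frame index
    t_start: float  # minutes
    t_end: float
    duration: float  # minutes, (end - start + 1) * frame interval
    mean_intensity: float
    mode: str = "unassigned"  # 'low' | 'high' | 'unassigned'


@dataclass
class ActivationEvent:
    """(time, protein level) at a nucleus's first transcription burst."""

    nucleus_id: int
    stripe: Optional[int]
    t_first: float  # minutes relative to gastrulation
    level: float  # a.u.


@dataclass
class BackgroundModel:
    """Nuclear GFP background levels and GFP-copy decision thresholds."""

    bg_1x: float
    bg_2x: float
    t_lower: float
    t_upper: float

    def __post_init__(self):
        if not (self.bg_1x < self.bg_2x):
            raise ValueError("bg_1x must be below bg_2x")
        if not (self.t_lower < self.t_upper):
            raise ValueError("T_lower must be below T_upper")


@dataclass
class BoundaryAssignment:
    """Per-nucleus boundary classes and stripe numbers."""

    classes: dict[int, str]  # 'stripe' | 'non-stripe' | 'AB' | 'PB'
    stripe_number: dict[int, int] = field(default_factory=dict)
    ab_partner: dict[int, int] = field(default_factory=dict)  # AB id -> PB id
    history: list = field(default_factory=list)

    def ids_of(self, cls: str) -> list[int]:
        return sorted(i for i, c in self.classes.items() if c == cls)

    @property
    def pb(self) -> list[int]:
        return self.ids_of("PB")

    @property
    def ab(self) -> list[int]:
        return self.ids_of("AB")


@dataclass
class AlignedEnsemble:
    """Gastrulation-aligned ensemble statistics of one quantity."""

    quantity: str
    t_rel: np.ndarray  # minutes, t=0 at per-nucleus gastrulation
    mean: np.ndarray
    sd: Optional[np.ndarray]
    n: np.ndarray
    min_participation: int

    def at(self, t_min: float) -> float:
        return float(self.mean[int(np.argmin(np.abs(self.t_rel - t_min)))])


@dataclass
class KSResult:
    """One-sided two-sample Kolmogorov-Smirnov outcome."""

    d: float
    p: float
    alpha: float
    reject: bool
    alternative: str = "available_smaller"
    method: str = "asymp"
    n_observed: int = 0
    n_available: int = 0


@dataclass
class ShuffleNull:
    """Permutation-constructed null lists for the timer/threshold test."""

    observed_levels: np.ndarray
    observed_times: np.ndarray
    available_times: np.ndarray
    available_levels: np.ndarray
    n_permutations_times: int
    n_permutations_levels: int
    tolerance: float
    max_permutations: int
    seed: Optional[int] = None


@dataclass
class SpotRecord:
    """One detected transcription spot linked to a nucleus."""

    frame: int
    nucleus_id: int
    intensity: float  # background-subtracted peak amplitude
    z: int
    x: float
    y: float
    fallback: bool = False  # Gaussian fit failed; raw peak minus local median
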