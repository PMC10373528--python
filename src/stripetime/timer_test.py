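"""Shuffling-based timer-vs-threshold test for enhancer activation.

For each transcribing PB nucleus the observed pair is (time of first burst,
protein level at that time). Permuting levels across nuclei and locating the
permuted level on each nucleus's protein trace yields the null distribution
of "available" activation times; permuting times and reading the trace value
yields the "available" levels. One-sided two-sample Kolmogorov-Smirnov tests
(alternative: the available distribution has smaller values, i.e. earlier
times or lower levels) then discriminate the two activation models: a timer
rejects on times only, a threshold on levels only.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .bursts import call_bursts
from .datatypes import ActivationEvent, BoundaryAssignment, EmbryoDataset, KSResult, ShuffleNull

logger = logging.getLogger(__name__)


def extract_first_burst_events(
    embryo: EmbryoDataset,
    assignment: BoundaryAssignment,
    pre_gastrulation_only: bool = True,
    unit: int = 1,
) -> list[ActivationEvent]:
    """One event per transcribing PB nucleus: its first burst's start time
    (minutes relative to the computed gastrulation) and the protein level at
    that frame. PB nuclei without transcription contribute nothing; for the
    endogenous/zebra/autoregulatory constructs only pre-gastrulation events
    count (engrailed transcription may be post-gastrulation)."""
    g = embryo.computed_gastrulation
    if g is None:
        g = embryo.manual_gastrulation
    events = []
    for p in assignment.pb:
        tr = embryo.traces[p]
        spot = tr.spot if unit == 1 else tr.spot2
        if spot is None:
            continue
        bursts = call_bursts(spot, embryo.frame_interval, nucleus_id=p, t=embryo.t)
        if not bursts:
            continue
        first = bursts[0]
        t_first = float(embryo.t[first.start] - g)
        if pre_gastrulation_only and t_first >= 0:
            continue
        events.append(
            ActivationEvent(
                nucleus_id=p,
                stripe=assignment.stripe_number.get(p),
                t_first=t_first,
                level=float(tr.protein[first.start]),
            )
        )
    return events


def _valid_span(embryo: EmbryoDataset, pre_gastrulation_only: bool) -> np.ndarray:
    g = embryo.computed_gastrulation
    if g is None:
        g = embryo.manual_gastrulation
    t_rel = embryo.t - g
    return t_rel < 0 if pre_gastrulation_only else np.ones_like(t_rel, bool)


def _trace_matrix(
    embryo: EmbryoDataset, events: list[ActivationEvent], pre_gastrulation_only: bool
) -> tuple[np.ndarray, np.ndarray]:
    """(n_events x n_frames) protein matrix over the usable span, and the
    relative time of each frame."""
    g = embryo.computed_gastrulation
    if g is None:
        g = embryo.manual_gastrulation
    mask = _valid_span(embryo, pre_gastrulation_only)
    t_rel = (embryo.t - g)[mask]
    traces = np.stack([embryo.traces[e.nucleus_id].protein[mask] for e in events])
    return traces, t_rel


def _n_rounds(n: int, max_perm: int) -> tuple[int, bool]:
    """Number of permutation rounds and whether to enumerate exhaustively."""
    if n <= 12 and math.factorial(n) <= max_perm:
        return math.factorial(n), True
    return max_perm, False


def _permutation_matrix(n: int, rounds: int, enumerate_all: bool, rng) -> np.ndarray:
    if enumerate_all:
        return np.array(list(permutations(range(n))), dtype=np.int64)
    return rng.permuted(np.tile(np.arange(n), (rounds, 1)), axis=1)


def shuffle_levels_to_available_times(
    events: list[ActivationEvent],
    traces: np.ndarray,
    t_rel: np.ndarray,
    tolerance: float = 0.05,
    max_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, int]:
    """Available activation times from shuffled levels.

    Each round permutes the observed levels across nuclei; a nucleus
    registers a uniformly chosen frame where its trace matches the assigned
    level within the relative tolerance (|trace - L| <= tolerance*L), or
    nothing when no frame matches. Rounds are enumerated exhaustively when
    n! <= max_perm and sampled uniformly otherwise. Returns the pooled
    available times and the number of rounds.
    """
    n = len(events)
    if n < 2:
        raise ValueError("need at least two events")
    rng = rng or np.random.default_rng()
    levels = np.array([e.level for e in events])
    # match sets per (trace i, level j) pair, CSR-style
    match = np.abs(traces[:, None, :] - levels[None, :, None]) <= tolerance * np.abs(
        levels[None, :, None]
    )
    counts = match.sum(axis=2)
    flat_frames = np.flatnonzero(match.reshape(n * n, -1).ravel())
    # frame index within each (i, j) cell
    width = traces.shape[1]
    cell = flat_frames // width
    frame_in_cell = flat_frames % width
    offsets = np.zeros(n * n + 1, dtype=np.int64)
    np.add.at(offsets[1:], cell, 1)
    offsets = np.cumsum(offsets)
    order = np.argsort(cell, kind="stable")
    flat_sorted = frame_in_cell[order]

    rounds, exhaustive = _n_rounds(n, max_perm)
    perms = _permutation_matrix(n, rounds, exhaustive, rng)
    rows = np.broadcast_to(np.arange(n), perms.shape)
    cells = rows * n + perms
    c = counts.ravel()[cells]
    has = c > 0
    if not has.any():
        raise ValueError("no permutation produced any matching timepoint")
    if exhaustive:
        pick = np.zeros(has.sum(), dtype=np.int64)  # deterministic when unique
        multi = c[has] > 1
        if multi.any():
            pick = (rng.random(has.sum()) * c[has]).astype(np.int64)
    else:
        pick = (rng.random(has.sum()) * c[has]).astype(np.int64)
    idx = offsets[cells[has]] + np.minimum(pick, c[has] - 1)
    times = t_rel[flat_sorted[idx]]
    return times, int(rounds)


def shuffle_times_to_available_levels(
    events: list[ActivationEvent],
    traces: np.ndarray,
    t_rel: np.ndarray,
    target_count: int,
    comparable_fraction: float = 0.05,
    max_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, int]:
    """Available protein levels from shuffled times.

    Each round permutes the observed times across nuclei and reads each
    nucleus's trace at its assigned time (nearest frame); times outside a
    trace's span register nothing. Rounds continue until the pooled count is
    comparable to target_count (within comparable_fraction) or the
    permutation budget is exhausted.
    """
    n = len(events)
    if n < 2:
        raise ValueError("need at least two events")
    if target_count <= 0:
        logger.warning("target_count is zero; returning no available levels")
        return np.array([]), 0
    rng = rng or np.random.default_rng()
    times = np.array([e.t_first for e in events])
    in_span = (times >= t_rel[0]) & (times <= t_rel[-1])
    frame_of_time = np.clip(
        np.searchsorted(t_rel, times - (t_rel[1] - t_rel[0]) / 2.0), 0, len(t_rel) - 1
    )
    rounds_cap, exhaustive = _n_rounds(n, max_perm)
    per_round = max(int(in_span.sum()), 1)
    needed = int(math.ceil(target_count * (1.0 - comparable_fraction) / per_round))
    rounds = min(rounds_cap, max(needed, 1))
    perms = _permutation_matrix(n, rounds_cap if exhaustive else rounds, exhaustive, rng)
    if exhaustive:
        perms = perms[:rounds] if rounds < len(perms) else perms
    rows = np.broadcast_to(np.arange(n), perms.shape)
    ok = in_span[perms]
    levels = traces[rows[ok], frame_of_time[perms][ok]]
    if len(levels) > target_count * (1.0 + comparable_fraction):
        levels = levels[:target_count]  # keep the pooled counts comparable
    return levels, int(perms.shape[0])


def ks_one_sided(
    observed: np.ndarray,
    available: np.ndarray,
    alpha: float = 0.05,
    method: str = "asymp",
    n_exact: int = 2000,
    rng: np.random.Generator | None = None,
) -> KSResult:
    """One-sided two-sample KS test of available-smaller.

    D- = sup_x [F_available(x) - F_observed(x)]; the asymptotic p-value is
    exp(-2 D^2 m n / (m + n)). method='exact' uses a label-permutation null
    instead (n_exact resamples).
    """
    obs = np.sort(np.asarray(observed, dtype=float))
    avail = np.sort(np.asarray(available, dtype=float))
    m, nn = len(obs), len(avail)
    if m < 2 or nn < 2:
        raise ValueError("both samples need at least two values")

    def d_stat(o: np.ndarray, a: np.ndarray) -> float:
        xs = np.concatenate([o, a])
        f_o = np.searchsorted(o, xs, side="right") / len(o)
        f_a = np.searchsorted(a, xs, side="right") / len(a)
        return float(np.max(f_a - f_o))

    d = d_stat(obs, avail)
    if method == "exact":
        rng = rng or np.random.default_rng()
        pool = np.concatenate([obs, avail])
        hits = 0
        for _ in range(n_exact):
            rng.shuffle(pool)
            if d_stat(np.sort(pool[:m]), np.sort(pool[m:])) >= d:
                hits += 1
        p = (hits + 1) / (n_exact + 1)
    else:
        p = min(1.0, math.exp(-2.0 * d * d * m * nn / (m + nn)))
    return KSResult(
        d=d, p=p, alpha=alpha, reject=p < alpha, method=method,
        n_observed=m, n_available=nn,
    )


@dataclass
class TimerThresholdReport:
    """Pooled shuffle null, the two KS tests, and the verdict."""

    stripe: int | None
    construct: str
    null: ShuffleNull
    ks_times: KSResult
    ks_levels: KSResult
    verdict: str
    n_embryos: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "stripe": self.stripe,
            "construct": self.construct,
            "verdict": self.verdict,
            "n_embryos": self.n_embryos,
            "n_events": len(self.null.observed_times),
            "n_available_times": len(self.null.available_times),
            "n_available_levels": len(self.null.available_levels),
            "seed": self.seed,
            "ks_times": {"D": self.ks_times.d, "p": self.ks_times.p, "reject": self.ks_times.reject},
            "ks_levels": {"D": self.ks_levels.d, "p": self.ks_levels.p, "reject": self.ks_levels.reject},
            "tolerance": self.null.tolerance,
            "max_permutations": self.null.max_permutations,
        }


def run_timer_threshold_analysis(
    embryos: list[tuple[EmbryoDataset, BoundaryAssignment]],
    stripe: int | None = None,
    construct: str = "autoregulatory",
    tolerance: float = 0.05,
    max_perm: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
    unit: int = 1,
) -> TimerThresholdReport:
    """Pool per-embryo shuffle nulls for one stripe and render a verdict.

    'timer-consistent' when the times test rejects and the levels test does
    not; 'threshold-consistent' for the mirror outcome; 'inconclusive'
    otherwise.
    """
    rng = np.random.default_rng(seed)
    pre_only = construct != "engrailed"
    obs_t, obs_l, av_t, av_l = [], [], [], []
    rounds_t = rounds_l = 0
    used = 0
    for embryo, assignment in embryos:
        events = extract_first_burst_events(embryo, assignment, pre_only, unit=unit)
        if stripe is not None:
            events = [e for e in events if e.stripe == stripe]
        if len(events) < 2:
            continue
        traces, t_rel = _trace_matrix(embryo, events, pre_only)
        times, r_t = shuffle_levels_to_available_times(
            events, traces, t_rel, tolerance, max_perm, rng
        )
        levels, r_l = shuffle_times_to_available_levels(
            events, traces, t_rel, target_count=len(times), max_perm=max_perm, rng=rng
        )
        obs_t.extend(e.t_first for e in events)
        obs_l.extend(e.level for e in events)
        av_t.append(times)
        av_l.append(levels)
        rounds_t += r_t
        rounds_l += r_l
        used += 1
    if used == 0:
        raise ValueError("no embryo contributed enough events")
    null = ShuffleNull(
        observed_levels=np.array(obs_l),
        observed_times=np.array(obs_t),
        available_times=np.concatenate(av_t),
        available_levels=np.concatenate(av_l) if av_l else np.array([]),
        n_permutations_times=rounds_t,
        n_permutations_levels=rounds_l,
        tolerance=tolerance,
        max_permutations=max_perm,
        seed=seed,
    )
    ks_t = ks_one_sided(null.observed_times, null.available_times, alpha)
    ks_l = ks_one_sided(null.observed_levels, null.available_levels, alpha)
    if ks_t.reject and not ks_l.reject:
        verdict = "timer-consistent"
    elif ks_l.reject and not ks_t.reject:
        verdict = "threshold-consistent"
    else:
        verdict = "inconclusive"
    return TimerThresholdReport(
        stripe=stripe,
        construct=construct,
        null=null,
        ks_times=ks_t,
        ks_levels=ks_l,
        verdict=verdict,
        n_embryos=used,
        seed=seed,
    )
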