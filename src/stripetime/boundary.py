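"""Boundary-cell classification: stripe/non-stripe sorting, PB/AB rows,
stripe numbering and diagnostic refinement rounds.

PB (posterior boundary) nuclei are stripe nuclei sitting on the stripe's
anterior edge: they have at least one non-stripe neighbor and all their
non-stripe neighbors lie anterior (smaller x). AB (anterior boundary) nuclei
are the non-stripe anterior neighbors of the PB nuclei. Manual curation of
refinement suggestions is replaced by an injectable acceptor predicate.
"""
from __future__ import annotations

import logging
from typing import Callable, Iterable

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .datatypes import BoundaryAssignment, EmbryoDataset
from .traces import select_complete_traces

logger = logging.getLogger(__name__)

Acceptor = Callable[[int, str], bool]


def accept_all(nucleus_id: int, diagnostic: str) -> bool:
    return True


def accept_none(nucleus_id: int, diagnostic: str) -> bool:
    return False


def otsu_threshold_exact(values: np.ndarray) -> float:
    """Otsu's criterion evaluated on the sorted data directly.

    Histogram-based Otsu returns a bin center, which can fall below data
    points belonging to the low class when clusters are much narrower than a
    bin; the exact split avoids that by placing the threshold midway between
    the two data values that maximize the between-class variance.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n < 2 or np.ptp(v) == 0:
        raise ValueError("need at least two distinct values")
    k = np.arange(1, n)
    csum = np.cumsum(v)
    m0 = csum[:-1] / k
    m1 = (csum[-1] - csum[:-1]) / (n - k)
    var = k * (n - k) * (m0 - m1) ** 2
    var[v[1:] == v[:-1]] = -np.inf  # a threshold cannot separate equal values
    kb = int(np.argmax(var)) + 1
    return float(0.5 * (v[kb - 1] + v[kb]))


def classify_stripe_nonstripe(levels: dict[int, float]) -> dict[int, str]:
    """Otsu threshold on protein levels at manual gastrulation; brighter
    nuclei are 'stripe'."""
    ids = sorted(i for i, v in levels.items() if np.isfinite(v))
    if len(ids) < 2:
        raise ValueError("need at least two nuclei with finite levels")
    vals = np.array([levels[i] for i in ids], dtype=float)
    if np.ptp(vals) == 0:
        raise ValueError("all protein levels equal; no stripe separation")
    thr = otsu_threshold_exact(vals)
    return {i: ("stripe" if levels[i] > thr else "non-stripe") for i in ids}


def identify_pb_ab(
    labels: dict[int, str],
    neighbors: dict[int, set[int]],
    x: dict[int, float],
) -> BoundaryAssignment:
    """Apply the anterior-edge rules to a stripe/non-stripe labelling.

    A stripe nucleus is PB when it has non-stripe neighbors and every one of
    them is anterior (smaller x). AB nuclei are non-stripe anterior neighbors
    of PB nuclei; each AB nucleus is paired with a single PB partner (lowest
    PB id) so it is never counted twice downstream.
    """
    classes = dict(labels)
    pb = []
    for i, c in labels.items():
        if c != "stripe":
            continue
        ns = [j for j in neighbors.get(i, ()) if labels.get(j) == "non-stripe"]
        if ns and all(x[j] < x[i] for j in ns):
            pb.append(i)
    if not pb:
        logger.warning("no PB nuclei found; assignment left without boundary rows")
    ab_partner: dict[int, int] = {}
    for p in sorted(pb):
        for j in sorted(neighbors.get(p, ())):
            if labels.get(j) == "non-stripe" and x[j] < x[p]:
                ab_partner.setdefault(j, p)
    for p in pb:
        classes[p] = "PB"
    for a in ab_partner:
        classes[a] = "AB"
    return BoundaryAssignment(classes=classes, ab_partner=ab_partner)


def _stripe_bands_from_positions(stripe_x: np.ndarray) -> list[tuple[float, float]]:
    """1D stripe bands: split sorted x positions where the gap exceeds 2.5x
    the median spacing. Bands are returned anterior to posterior."""
    xs = np.sort(stripe_x)
    if len(xs) == 1:
        return [(xs[0], xs[0])]
    gaps = np.diff(xs)
    # split gaps into intra-band and inter-band groups with Otsu's
    # criterion; accept only a clear separation (inter-band gaps at least
    # 3x the widest intra-band gap), otherwise everything is one band
    cuts = np.array([], dtype=int)
    if np.ptp(gaps) > 0:
        thr = otsu_threshold_exact(gaps)
        large = gaps > thr
        if large.any() and (~large).any() and (
            gaps[large].min() > 3.0 * max(gaps[~large].max(), 1e-12)
        ):
            cuts = np.flatnonzero(large)
    starts = np.concatenate([[0], cuts + 1])
    ends = np.concatenate([cuts, [len(xs) - 1]])
    return [(float(xs[a]), float(xs[b])) for a, b in zip(starts, ends)]


def assign_stripe_numbers(
    assignment: BoundaryAssignment,
    x: dict[int, float],
    projection: np.ndarray | None = None,
    positions_yx: dict[int, tuple[float, float]] | None = None,
    expected_stripes: int | None = None,
) -> BoundaryAssignment:
    """Number stripes 1..k anterior to posterior and assign each AB/PB
    nucleus the nearest stripe's number (ties to the lower number).

    With a projection image, stripe regions come from Otsu-thresholded
    connected components; otherwise bands are derived from the x positions
    of the stripe (and PB) nuclei.
    """
    members = [i for i, c in assignment.classes.items() if c in ("stripe", "PB")]
    if not members:
        return assignment
    if projection is not None:
        thr = threshold_otsu(projection)
        lab = cc_label(projection > thr)
        regions = sorted(regionprops(lab), key=lambda r: r.centroid[1])
        bands = []
        for r in regions:
            cols = np.flatnonzero((lab == r.label).any(axis=0))
            bands.append((float(cols.min()), float(cols.max())))
    else:
        bands = _stripe_bands_from_positions(np.array([x[i] for i in members]))
    if expected_stripes is not None and len(bands) != expected_stripes:
        logger.warning("found %d stripe regions, expected %d", len(bands), expected_stripes)
    for i, c in assignment.classes.items():
        if c not in ("AB", "PB"):
            continue
        xi = x[i]
        best, best_d = None, np.inf
        for k, (lo, hi) in enumerate(bands, start=1):
            d = 0.0 if lo <= xi <= hi else min(abs(xi - lo), abs(xi - hi))
            if d < best_d - 1e-12:  # strict improvement: ties keep lower number
                best, best_d = k, d
        assignment.stripe_number[i] = best
    return assignment


def diagnose_misclassified(
    assignment: BoundaryAssignment,
    embryo: EmbryoDataset,
    diag1_increase_fraction: float = 0.25,
    second_round: bool = False,
) -> list[tuple[int, str]]:
    """Suggest possibly misclassified nuclei.

    Diagnostic 1 (round 1 only): a non-stripe nucleus whose protein rises
    after manual gastrulation by more than diag1_increase_fraction of the
    mean AB level. Diagnostic 2: an AB nucleus strictly more than one SD
    brighter than the mean AB nucleus at manual gastrulation.
    """
    g_idx = embryo.frame_of(embryo.manual_gastrulation)
    ab = assignment.ab
    if not ab:
        return []
    ab_levels = np.array([embryo.traces[i].protein[g_idx] for i in ab])
    ab_mean = float(np.nanmean(ab_levels))
    ab_sd = float(np.nanstd(ab_levels))
    suggestions: list[tuple[int, str]] = []
    if not second_round and g_idx + 1 < len(embryo.t):
        for i, c in assignment.classes.items():
            # AB nuclei are members of the non-stripe list, so the
            # post-gastrulation-increase diagnostic covers them as well
            if c not in ("non-stripe", "AB"):
                continue
            post = embryo.traces[i].protein[g_idx:]
            if not np.any(np.isfinite(post)):
                continue
            rise = np.nanmax(post) - embryo.traces[i].protein[g_idx]
            if rise > diag1_increase_fraction * ab_mean:
                suggestions.append((i, "diag1"))
    for i in ab:
        if embryo.traces[i].protein[g_idx] > ab_mean + ab_sd:
            suggestions.append((i, "diag2"))
    return suggestions


def _trace_error_flags(
    embryo: EmbryoDataset, ids: Iterable[int], jump_px: float = 20.0
) -> list[tuple[int, str]]:
    """Obvious trace errors: missing-value runs or jumps beyond the tracking
    search radius."""
    flags = []
    for i in ids:
        tr = embryo.traces[i]
        if np.any(~np.isfinite(tr.protein)):
            flags.append((i, "trace_gap"))
            continue
        step = np.hypot(np.diff(tr.x), np.diff(tr.y))
        if np.any(step > jump_px):
            flags.append((i, "trace_jump"))
    return flags


def classify_boundary(
    embryo: EmbryoDataset,
    acceptor: Acceptor = accept_none,
    diag1_increase_fraction: float = 0.25,
    expected_stripes: int | None = None,
    refine: bool = True,
) -> BoundaryAssignment:
    """Full classification: Otsu sort, PB/AB rules, stripe numbers and (by
    default) the two refinement rounds, restricted to complete traces."""
    g_idx = embryo.frame_of(embryo.manual_gastrulation)
    complete = set(select_complete_traces(embryo))
    levels = {
        i: float(tr.protein[g_idx]) for i, tr in embryo.traces.items() if i in complete
    }
    x = {i: float(np.nanmean(tr.x)) for i, tr in embryo.traces.items()}
    labels = classify_stripe_nonstripe(levels)
    assignment = identify_pb_ab(labels, embryo.neighbors, x)
    assign_stripe_numbers(assignment, x, expected_stripes=expected_stripes)
    if refine:
        assignment = refine_classification(
            embryo, assignment, acceptor, x,
            diag1_increase_fraction=diag1_increase_fraction,
            expected_stripes=expected_stripes,
        )
    return assignment


def refine_classification(
    embryo: EmbryoDataset,
    assignment: BoundaryAssignment,
    acceptor: Acceptor,
    x: dict[int, float] | None = None,
    diag1_increase_fraction: float = 0.25,
    expected_stripes: int | None = None,
) -> BoundaryAssignment:
    """Two refinement rounds.

    Round 1 applies both diagnostics; accepted nuclei move to the stripe
    list and the PB/AB rules re-run. Round 2 applies only diagnostic 2 plus
    trace-error flags (flagged nuclei are dropped from the boundary rows).
    The assignment is finally restricted to complete traces.
    """
    if x is None:
        x = {i: float(np.nanmean(tr.x)) for i, tr in embryo.traces.items()}
    labels = {
        i: ("stripe" if c in ("stripe", "PB") else "non-stripe")
        for i, c in assignment.classes.items()
    }
    for rnd in (1, 2):
        suggestions = diagnose_misclassified(
            assignment, embryo, diag1_increase_fraction, second_round=(rnd == 2)
        )
        accepted = [(i, d) for i, d in suggestions if acceptor(i, d)]
        assignment.history.append(
            {"round": rnd, "suggested": suggestions, "accepted": accepted}
        )
        if rnd == 2:
            errors = _trace_error_flags(
                embryo, assignment.pb + assignment.ab
            )
            assignment.history[-1]["trace_errors"] = errors
            for i, _ in errors:
                assignment.classes[i] = (
                    "stripe" if assignment.classes[i] == "PB" else "non-stripe"
                )
                assignment.stripe_number.pop(i, None)
                assignment.ab_partner.pop(i, None)
        if accepted:
            for i, _ in accepted:
                labels[i] = "stripe"
            new = identify_pb_ab(labels, embryo.neighbors, x)
            new.history = assignment.history
            assignment = new
            assign_stripe_numbers(assignment, x, expected_stripes=expected_stripes)
    complete = set(select_complete_traces(embryo))
    for i in list(assignment.classes):
        if i not in complete and assignment.classes[i] in ("AB", "PB"):
            assignment.classes[i] = (
                "stripe" if assignment.classes[i] == "PB" else "non-stripe"
            )
            assignment.stripe_number.pop(i, None)
            assignment.ab_partner.pop(i, None)
    return assignment
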