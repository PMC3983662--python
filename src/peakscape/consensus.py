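"""Consensus peak construction across replicates and subunits.

Combines per-subunit peak sets into complex-level consensus intervals
(base-wise k-of-n coverage), calls summits on an enrichment track, and splits
multi-summit peaks with a valley rule controlled by a separation fraction.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from peakscape.core import (
    CoverageTrack,
    Interval,
    Peak,
    PeakSet,
    hit_flags,
    merge_intervals,
)

logger = logging.getLogger(__name__)


def majority_replicate_filter(
    combined: Sequence[Interval] | PeakSet,
    replicates: Sequence[Sequence[Interval] | PeakSet],
) -> list[Interval]:
    """Keep combined peaks present (>= 1 bp overlap) in a strict majority of replicates.

    With an even replicate count a tie at exactly half is excluded; with two
    replicates a peak must therefore hit both.
    """
    if not replicates:
        raise ValueError("majority_replicate_filter needs at least one replicate set")
    combined_ivs = combined.intervals if isinstance(combined, PeakSet) else list(combined)
    votes = np.zeros(len(combined_ivs), dtype=int)
    for rep in replicates:
        rep_ivs = rep.intervals if isinstance(rep, PeakSet) else list(rep)
        votes += hit_flags(combined_ivs, rep_ivs)
    keep = votes * 2 > len(replicates)
    kept = [iv for iv, k in zip(combined_ivs, keep) if k]
    logger.info(
        "majority_replicate_filter: kept %d/%d peaks (%d replicates)",
        len(kept),
        len(combined_ivs),
        len(replicates),
    )
    return kept


def consensus_k_of_n(
    peaksets: Sequence[Sequence[Interval] | PeakSet], k: int
) -> list[Interval]:
    """Maximal runs of bases covered by the peaks of at least ``k`` of ``n`` sets.

    Each set contributes at most one unit of coverage per base (its intervals
    are merged first).  Implemented as a boundary-event sweep, so no per-base
    arrays are built; k=1 reduces to the plain union.
    """
    n = len(peaksets)
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= {n}, got k={k}")
    events: dict[str, list[tuple[int, int]]] = {}
    for ps in peaksets:
        ivs = ps.intervals if isinstance(ps, PeakSet) else list(ps)
        for iv in merge_intervals(ivs, book_ended=True):
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events.setdefault(iv.chrom, []).append((iv.end, -1))
    out: list[Interval] = []
    for chrom in sorted(events):
        evs = sorted(events[chrom])
        depth = 0
        run_start: int | None = None
        i = 0
        while i < len(evs):
            pos = evs[i][0]
            while i < len(evs) and evs[i][0] == pos:
                depth += evs[i][1]
                i += 1
            if depth >= k and run_start is None:
                run_start = pos
            elif depth < k and run_start is not None:
                if pos > run_start:
                    out.append(Interval(chrom, run_start, pos))
                run_start = None
    return merge_intervals(out, book_ended=True)


def call_summits(
    intervals: Sequence[Interval], track: CoverageTrack
) -> PeakSet:
    """Summit = argmax of the enrichment track within each interval (ties -> leftmost)."""
    peaks = []
    n_flat = 0
    for i, iv in enumerate(intervals):
        values = track.region_values(iv)
        if values.size == 0:
            raise ValueError(f"interval {iv.chrom}:{iv.start}-{iv.end} has no track data")
        offset = int(np.argmax(values))  # np.argmax returns the first maximum
        if np.all(values == values[0]):
            n_flat += 1
        peaks.append(
            Peak(
                iv.chrom,
                iv.start,
                iv.end,
                summit=iv.start + offset,
                summit_score=float(values[offset]),
                name=iv.name or f"peak_{i + 1}",
            )
        )
    if n_flat:
        logger.info("call_summits: %d intervals had flat signal (leftmost base used)", n_flat)
    return PeakSet(peaks)


def summit_score_median(peakset: PeakSet) -> float:
    """Median of summit scores; the published minimum-height choice for splitting."""
    if len(peakset) == 0:
        raise ValueError("empty peak set")
    return float(np.median([p.summit_score for p in peakset]))


def _local_maxima(values: np.ndarray) -> list[int]:
    """Indices of local maxima; a plateau contributes its leftmost index."""
    n = len(values)
    maxima = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        left_ok = i == 0 or values[i - 1] < values[i]
        right_ok = j == n - 1 or values[j + 1] < values[i]
        if left_ok and right_ok:
            maxima.append(i)
        i = j + 1
    return maxima


def split_peaks(
    peaks: PeakSet,
    track: CoverageTrack,
    min_height: float,
    separation_float: float = 0.85,
) -> PeakSet:
    """Split multi-summit peaks at sufficiently deep valleys.

    Within each peak, local maxima with height >= ``min_height`` are candidate
    summits.  Between each adjacent pair of candidates the lowest valley is
    found; the peak is cut there iff
    ``valley < separation_float * min(height_left, height_right)``, otherwise
    the pair stays merged.  Sub-peaks partition the parent exactly (union of
    sub-peaks equals the parent) and each gets its own summit.
    """
    if min_height <= 0:
        raise ValueError("min_height must be positive")
    if not 0 < separation_float < 1:
        raise ValueError("separation_float must be in (0, 1)")
    out: list[Peak] = []
    n_unsplit_flagged = 0
    for p in peaks:
        values = track.data[p.chrom][p.start : p.end]
        maxima = [m for m in _local_maxima(values) if values[m] >= min_height]
        if not maxima:
            n_unsplit_flagged += 1
            out.append(p)
            continue
        cuts: list[int] = []  # local offsets where a new sub-peak begins
        for left, right in zip(maxima, maxima[1:]):
            between = values[left + 1 : right]
            valley_off = left + 1 + int(np.argmin(between))
            valley = values[valley_off]
            if valley < separation_float * min(values[left], values[right]):
                cuts.append(valley_off)
        bounds = [0, *cuts, len(values)]
        for i, (s, e) in enumerate(zip(bounds, bounds[1:])):
            seg = values[s:e]
            off = int(np.argmax(seg))
            out.append(
                Peak(
                    p.chrom,
                    p.start + s,
                    p.start + e,
                    summit=p.start + s + off,
                    summit_score=float(seg[off]),
                    name=f"{p.name}.{i + 1}" if cuts and p.name else p.name,
                )
            )
    if n_unsplit_flagged:
        logger.info(
            "split_peaks: %d peaks had no local maximum >= min_height; kept unsplit",
            n_unsplit_flagged,
        )
    return PeakSet(out)
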