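"""Anchored signal aggregation: summit/TSS profile matrices, expression-class
metagene curves with confidence bands, and sliding-window GC profiles."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from peakscape.core import (
    AnnotationSet,
    CoverageTrack,
    GenomeModel,
    PeakSet,
)

logger = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    """Anchors x offset-bins matrix of aggregated signal.

    ``values[i, j]`` is the per-bin statistic for anchor ``i`` at offset bin
    ``j``; bins cover [-flank, +flank) in steps of ``bin_size`` and read 5'->3'
    for stranded anchors.  NaN marks bins falling off the chromosome.
    """

    values: np.ndarray
    anchors: list[tuple[str, int, str]]  # (chrom, position, strand)
    flank: int
    bin_size: int
    row_order: str = "input"

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank, self.bin_size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.offsets)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def anchored_matrix(
    track: CoverageTrack,
    anchors: Sequence[tuple[str, int, str]],
    flank: int,
    bin_size: int,
    stat: str = "median",
) -> ProfileMatrix:
    """Per-anchor per-bin statistic (median by default) of per-base signal.

    Minus-strand anchors are reversed so columns read 5'->3'.  Bins extending
    past chromosome ends are NaN (excluded downstream, never zero-filled).
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin_size")
    n_bins = 2 * flank // bin_size
    func = {"median": np.nanmedian, "mean": np.nanmean}[stat]
    out = np.full((len(anchors), n_bins), np.nan)
    for i, (chrom, pos, strand) in enumerate(anchors):
        arr = track.data[chrom]
        window = np.full(2 * flank, np.nan)
        s, e = pos - flank, pos + flank
        cs, ce = max(0, s), min(len(arr), e)
        if cs < ce:
            window[cs - s : ce - s] = arr[cs:ce]
        if strand == "-":
            window = window[::-1]
        binned = window.reshape(n_bins, bin_size)
        with np.errstate(all="ignore"):
            valid = ~np.all(np.isnan(binned), axis=1)
            out[i, valid] = func(binned[valid], axis=1)
    return ProfileMatrix(out, list(anchors), flank, bin_size)


def order_by_summit_score(matrix: ProfileMatrix, peakset: PeakSet) -> ProfileMatrix:
    """Rows sorted by summit score descending (ties broken by chrom, start)."""
    if len(peakset) != matrix.values.shape[0]:
        raise ValueError("matrix rows and peak set size differ")
    order = sorted(
        range(len(peakset)),
        key=lambda i: (-peakset[i].summit_score, peakset[i].chrom, peakset[i].start),
    )
    return ProfileMatrix(
        matrix.values[order],
        [matrix.anchors[i] for i in order],
        matrix.flank,
        matrix.bin_size,
        row_order="summit_score_desc",
    )


def expression_quantile_classes(
    expression: Mapping[str, float], quantiles: Sequence[float] = (0.25, 0.75)
) -> dict[str, str]:
    """Label genes 'low' (bottom quantile), 'high' (top quantile) or 'mid'."""
    names = list(expression)
    vals = np.array([expression[g] for g in names], dtype=float)
    lo, hi = np.quantile(vals, quantiles[0]), np.quantile(vals, quantiles[1])
    out = {}
    for g, v in zip(names, vals):
        out[g] = "low" if v <= lo else ("high" if v >= hi else "mid")
    return out


def tss_profile(
    track: CoverageTrack,
    genes: AnnotationSet,
    expression: Mapping[str, float],
    flank: int = 750,
    bin_size: int = 50,
    band: str = "normal",
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mean TSS-anchored curve with a 95% band per expression class.

    Genes are split into top/bottom expression quartiles ('high'/'low').
    ``band='normal'`` gives mean +/- 1.96*SE; ``band='bootstrap'`` resamples
    genes.  Classes with < 2 genes get no band (logged).
    """
    classes = expression_quantile_classes(expression)
    rows = []
    for label in ("high", "low"):
        members = [g for g in genes if g.name in classes and classes[g.name] == label]
        if not members:
            continue
        anchors = [(g.chrom, g.tss, g.strand) for g in members]
        mat = anchored_matrix(track, anchors, flank, bin_size).values
        with np.errstate(all="ignore"):
            mean = np.nanmean(mat, axis=0)
            n_per_bin = np.sum(~np.isnan(mat), axis=0)
        if len(members) < 2:
            logger.info("tss_profile: class %r has <2 genes; band omitted", label)
            lo = hi = np.full_like(mean, np.nan)
        elif band == "normal":
            with np.errstate(all="ignore"):
                se = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(np.maximum(n_per_bin, 1))
            lo, hi = mean - 1.96 * se, mean + 1.96 * se
        elif band == "bootstrap":
            if rng is None:
                rng = np.random.default_rng(0)
            boots = np.empty((n_boot, mat.shape[1]))
            for b in range(n_boot):
                idx = rng.integers(0, len(members), len(members))
                with np.errstate(all="ignore"):
                    boots[b] = np.nanmean(mat[idx], axis=0)
            lo, hi = np.quantile(boots, [0.025, 0.975], axis=0)
        else:
            raise ValueError(f"unknown band type {band!r}")
        offsets = np.arange(-flank, flank, bin_size)
        for j, off in enumerate(offsets):
            rows.append(
                {
                    "class": label,
                    "offset": int(off),
                    "mean": mean[j],
                    "lo": lo[j],
                    "hi": hi[j],
                    "n_genes": len(members),
                    "band": band,
                }
            )
    return pd.DataFrame(rows)


def gc_track(sequence: str, window: int = 15) -> np.ndarray:
    """Sliding-window GC fraction assigned to each window's mid base.

    ``window`` must be odd so the mid base is unique.  At sequence ends the
    window is truncated to the available bases.  Non-ACGT characters count as
    non-GC (their count is logged).
    """
    if window % 2 == 0:
        raise ValueError("gc window must be odd")
    seq = sequence.upper()
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = ((codes == ord("G")) | (codes == ord("C"))).astype(float)
    is_acgt = np.isin(codes, np.frombuffer(b"ACGT", dtype=np.uint8))
    n_other = int((~is_acgt).sum())
    if n_other:
        logger.info("gc_track: %d non-ACGT characters counted as non-GC", n_other)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(is_gc)])
    n = len(seq)
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def gc_coverage_track(
    sequences: Mapping[str, str], genome: GenomeModel, window: int = 15
) -> CoverageTrack:
    return CoverageTrack(
        {c: gc_track(seq, window) for c, seq in sequences.items()},
        genome,
        state="raw",
        provenance=[{"op": "gc_track", "window": window}],
    )


def gc_summit_profile(
    sequences: Mapping[str, str],
    genome: GenomeModel,
    summits: Sequence[tuple[str, int]],
    flank: int = 750,
    bin_size: int = 50,
    gc_window: int = 15,
    n_random: int = 1500,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mean GC per offset bin over summits, with a random-coordinate control."""
    if rng is None:
        rng = np.random.default_rng(0)
    gc = gc_coverage_track(sequences, genome, window=gc_window)
    rows = []
    chroms = [c for c in genome.included_chroms if c in sequences]
    lengths = np.array([genome.length(c) for c in chroms], dtype=float)
    ci = rng.choice(len(chroms), size=n_random, p=lengths / lengths.sum())
    random_pos = [
        (chroms[k], int(rng.integers(0, genome.length(chroms[k])))) for k in ci
    ]
    for label, positions in (("summits", list(summits)), ("random", random_pos)):
        anchors = [(c, p, "+") for c, p in positions]
        mat = anchored_matrix(gc, anchors, flank, bin_size, stat="mean").values
        with np.errstate(all="ignore"):
            mean = np.nanmean(mat, axis=0)
        for j, off in enumerate(np.arange(-flank, flank, bin_size)):
            rows.append({"set": label, "offset": int(off), "mean_gc": float(mean[j])})
    return pd.DataFrame(rows)
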