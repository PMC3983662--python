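"""Coverage-track algebra: median normalization, input subtraction, replicate
merging, background z-scoring, X/autosome split processing and per-region
mutant/wild-type ratios.

All operations return new :class:`~peakscape.core.CoverageTrack` objects and
append a provenance entry; state transitions follow
raw -> median_normalized -> input_subtracted -> (zscored).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from peakscape.core import (
    CoverageTrack,
    GenomeModel,
    Interval,
    PeakscapeError,
    ValidationError,
    merge_intervals,
)

logger = logging.getLogger(__name__)


class DegenerateTrackError(PeakscapeError):
    """A normalization divisor (median or background sd) is zero."""


def _require_state(track: CoverageTrack, *states: str) -> None:
    if track.state not in states:
        raise ValidationError(f"track state {track.state!r}, expected one of {states}")


def _same_genome(a: CoverageTrack, b: CoverageTrack) -> None:
    if set(a.data) != set(b.data) or a.genome.chrom_lengths != b.genome.chrom_lengths:
        raise ValidationError("tracks are on different chromosome sets")


def median_normalize(track: CoverageTrack, genome: GenomeModel) -> CoverageTrack:
    """Divide every base by the genome-wide per-base median over non-excluded chromosomes.

    The median is computed over ALL bases of the included chromosomes,
    including zeros.  A zero median is an error (degenerate track) rather than
    a silent fallback.
    """
    _require_state(track, "raw")
    chroms = [c for c in genome.included_chroms if c in track.data]
    med = float(np.median(track.values(chroms)))
    if med == 0.0:
        raise DegenerateTrackError("genome-wide median coverage is 0")
    out = {c: v / med for c, v in track.data.items()}
    prov = track.provenance + [
        {"op": "median_normalize", "median": med, "chroms": chroms}
    ]
    return CoverageTrack(out, track.genome, state="median_normalized", provenance=prov)


def subtract_input(chip: CoverageTrack, control: CoverageTrack) -> CoverageTrack:
    """Per-base ChIP minus input.  Negative values are retained, not clipped."""
    _require_state(chip, "median_normalized")
    _require_state(control, "median_normalized")
    _same_genome(chip, control)
    out = {c: chip.data[c] - control.data[c] for c in chip.data}
    n_negative = int(sum(int((v < 0).sum()) for v in out.values()))
    prov = chip.provenance + [{"op": "subtract_input", "negative_bases": n_negative}]
    return CoverageTrack(out, chip.genome, state="input_subtracted", provenance=prov)


def merge_replicates(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Average coverage at each base position over replicate tracks."""
    if not tracks:
        raise ValueError("merge_replicates needs at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        _same_genome(first, t)
        if t.state != first.state:
            raise ValidationError("replicates must share normalization state")
    out = {
        c: np.mean([t.data[c] for t in tracks], axis=0) for c in first.data
    }
    prov = [{"op": "merge_replicates", "n": len(tracks)}]
    return CoverageTrack(out, first.genome, state=first.state, provenance=prov)


def background_stats(
    track: CoverageTrack, peak_regions: Iterable[Interval]
) -> tuple[float, float]:
    """Mean and sd of per-base signal outside ``peak_regions`` (the presumed background)."""
    masked: list[np.ndarray] = []
    regions_by_chrom: dict[str, list[Interval]] = {}
    for iv in merge_intervals(list(peak_regions)):
        regions_by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, arr in track.data.items():
        mask = np.ones(len(arr), dtype=bool)
        for iv in regions_by_chrom.get(chrom, ()):
            mask[iv.start : iv.end] = False
        masked.append(arr[mask])
    bg = np.concatenate(masked)
    if bg.size == 0:
        raise ValidationError("peak regions cover the entire genome; no background left")
    return float(bg.mean()), float(bg.std())


def zscore_standardize(
    track: CoverageTrack, peak_regions: Iterable[Interval]
) -> CoverageTrack:
    """z-transform all bases using mean/sd of the bases outside ``peak_regions``."""
    mu, sigma = background_stats(track, peak_regions)
    if sigma == 0.0:
        raise DegenerateTrackError("background standard deviation is 0")
    out = {c: (v - mu) / sigma for c, v in track.data.items()}
    prov = track.provenance + [{"op": "zscore_standardize", "bg_mean": mu, "bg_sd": sigma}]
    return CoverageTrack(out, track.genome, state="zscored", provenance=prov)


def split_median_normalize(track: CoverageTrack, genome: GenomeModel) -> CoverageTrack:
    """Median-normalize the X chromosome and the autosomes separately, then recombine.

    Used for samples where X read depth differs systematically from autosomal
    depth; each group is divided by its own per-base median.
    """
    if genome.x_chrom is None:
        raise ValidationError("genome has no X chromosome defined")
    _require_state(track, "raw")
    groups = {
        "X": [genome.x_chrom] if genome.x_chrom in track.data else [],
        "autosomes": [c for c in genome.autosomes if c in track.data],
    }
    out: dict[str, np.ndarray] = {}
    medians: dict[str, float] = {}
    for label, chroms in groups.items():
        if not chroms:
            continue
        med = float(np.median(track.values(chroms)))
        if med == 0.0:
            raise DegenerateTrackError(f"median coverage of {label} group is 0")
        medians[label] = med
        for c in chroms:
            out[c] = track.data[c] / med
    for c in track.data:  # excluded chromosomes pass through untouched
        out.setdefault(c, track.data[c].copy())
    prov = track.provenance + [{"op": "split_median_normalize", "medians": medians}]
    return CoverageTrack(out, track.genome, state="median_normalized", provenance=prov)


def ratio_in_regions(
    mutant: CoverageTrack,
    wildtype: CoverageTrack,
    regions: Sequence[Interval],
    classes: Mapping[int, str] | Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-region ratio of mean mutant vs wild-type enrichment, grouped by class label.

    Both tracks must be z-scored.  Regions whose wild-type mean is <= 0 are
    excluded (ratio undefined) and counted in the log.  Returns a DataFrame with
    columns chrom/start/end/label/mutant_mean/wildtype_mean/ratio.
    """
    _require_state(mutant, "zscored")
    _require_state(wildtype, "zscored")
    _same_genome(mutant, wildtype)
    rows = []
    excluded = 0
    for i, iv in enumerate(regions):
        label = classes[i] if classes is not None else "all"
        m = float(mutant.region_values(iv).mean())
        w = float(wildtype.region_values(iv).mean())
        if w <= 0:
            excluded += 1
            continue
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "label": label,
                "mutant_mean": m,
                "wildtype_mean": w,
                "ratio": m / w,
            }
        )
    if excluded:
        logger.info("ratio_in_regions: excluded %d regions with non-positive WT mean", excluded)
    return pd.DataFrame(rows)


def ratio_summary(ratios: pd.DataFrame) -> pd.DataFrame:
    """Quartile summary of per-region ratios per class label."""
    return (
        ratios.groupby("label")["ratio"]
        .describe(percentiles=[0.25, 0.5, 0.75])
        .loc[:, ["count", "25%", "50%", "75%", "mean"]]
        .rename(columns={"25%": "q1", "50%": "median", "75%": "q3"})
    )
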