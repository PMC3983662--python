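"""Binding/transcription integration: promoter signal, binding-expression
correlation, bound-gene classification and the DE-by-binding contingency table."""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from peakscape.core import (
    AnnotationSet,
    CoverageTrack,
    GenomeModel,
    Interval,
    PeakSet,
    clamp,
    hit_flags,
)
from peakscape.enrichment import summit_windows

logger = logging.getLogger(__name__)


def load_expression_table(path) -> pd.DataFrame:
    """Read a tab-delimited expression table (gene, rep1..repN[, median]).

    The median column is recomputed from the replicate columns regardless of
    what the file carries — it must equal the median of the replicates.
    """
    df = pd.read_csv(path, sep="\t")
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if not rep_cols:
        raise ValueError("expression table has no replicate columns (rep*)")
    df["median"] = df[rep_cols].median(axis=1)
    return df


def promoter_signal(
    track: CoverageTrack,
    genes: AnnotationSet,
    genome: GenomeModel,
    upstream: int = 500,
) -> dict[str, float]:
    """Per gene, the median per-base enrichment over the strand-aware upstream window."""
    out: dict[str, float] = {}
    skipped = 0
    for g in genes:
        if g.strand == "+":
            s, e = g.start - upstream, g.start
        else:
            s, e = g.end, g.end + upstream
        s, e = clamp(s, e, genome.length(g.chrom))
        if s >= e:
            skipped += 1
            continue
        out[g.name] = float(np.median(track.data[g.chrom][s:e]))
    if skipped:
        logger.info("promoter_signal: %d genes skipped (window off-chromosome)", skipped)
    return out


def binding_expression_correlation(
    signal: Mapping[str, float],
    expression: Mapping[str, float],
    genes: AnnotationSet | None = None,
    scope: str = "genome",
    x_chrom: str | None = None,
) -> float:
    """Spearman rank correlation between promoter signal and expression level.

    ``scope='X'`` restricts to genes on ``x_chrom`` (requires ``genes``).
    """
    names = sorted(set(signal) & set(expression))
    if scope == "X":
        if genes is None or x_chrom is None:
            raise ValueError("scope='X' needs the annotation set and the X chromosome name")
        on_x = {g.name for g in genes if g.chrom == x_chrom}
        names = [n for n in names if n in on_x]
    if len(names) < 10:
        raise ValueError(f"need >= 10 genes in scope, have {len(names)}")
    x = np.array([signal[n] for n in names])
    y = np.array([expression[n] for n in names])
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector; Spearman correlation undefined")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def classify_bound_genes(
    genes: AnnotationSet,
    peaks: PeakSet,
    genome: GenomeModel,
    window: int = 1000,
    summit_halfwidth: int = 200,
    upstream_only: bool = False,
) -> dict[str, bool]:
    """Gene -> bound flag: any peak summit window within ``window`` bp of the TSS.

    Default is a symmetric [TSS - window, TSS + window) region;
    ``upstream_only`` restricts to the upstream side.
    """
    windows = summit_windows(peaks, genome, halfwidth=summit_halfwidth)
    tss_regions = []
    for g in genes:
        tss = g.tss
        if upstream_only:
            s, e = (tss - window, tss + 1) if g.strand == "+" else (tss, tss + window + 1)
        else:
            s, e = tss - window, tss + window
        s, e = clamp(s, e, genome.length(g.chrom))
        tss_regions.append(Interval(g.chrom, s, e, name=g.name))
    flags = hit_flags(tss_regions, windows)
    return {g.name: bool(f) for g, f in zip(genes, flags)}


def de_binding_table(
    de_genes: pd.DataFrame,
    bound_flags: Mapping[str, bool],
) -> pd.DataFrame:
    """2x2 counts and row percentages of {bound, unbound} x {increased, decreased}.

    ``de_genes`` needs columns ``gene`` and ``direction`` ('up'/'down'), or
    ``lfc`` from which direction is derived.
    """
    if len(de_genes) == 0:
        raise ValueError("empty differential-expression gene list")
    df = de_genes.copy()
    if "direction" not in df.columns:
        if "lfc" not in df.columns:
            raise ValueError("need a 'direction' or 'lfc' column")
        df["direction"] = np.where(df["lfc"] > 0, "up", "down")
    df["bound"] = df["gene"].map(lambda g: bool(bound_flags.get(g, False)))
    rows = []
    for bound in (True, False):
        sub = df[df["bound"] == bound]
        n = len(sub)
        n_up = int((sub["direction"] == "up").sum())
        n_down = int((sub["direction"] == "down").sum())
        rows.append(
            {
                "bound": bound,
                "n": n,
                "n_up": n_up,
                "n_down": n_down,
                "pct_up": 100.0 * n_up / n if n else np.nan,
                "pct_down": 100.0 * n_down / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
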