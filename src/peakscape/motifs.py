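"""PWM log-odds scanning and motif-context statistics.

A position weight matrix is scanned on both strands for hits above a log-odds
threshold; downstream statistics measure what fraction of hits fall inside
peaks, how chromatin context conditions that fraction, and whether motif
clustering within fixed windows predicts binding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from peakscape.core import GenomeModel, Interval, PeakSet, hit_flags

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class PositionWeightMatrix:
    """Per-position base probabilities plus background frequencies.

    ``probs`` has shape (width, 4) ordered A, C, G, T; rows sum to 1.
    """

    probs: np.ndarray
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must have shape (width, 4)")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def default_threshold(self, fraction: float = 0.8) -> float:
        """Threshold at a fraction of the maximal log-odds score."""
        return fraction * self.max_score

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        pseudocount: float = 0.25,
        background: np.ndarray | None = None,
    ) -> "PositionWeightMatrix":
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(counts / counts.sum(axis=1, keepdims=True), background)

    @classmethod
    def from_sequences(
        cls, seqs: Sequence[str], pseudocount: float = 0.25,
        background: np.ndarray | None = None,
    ) -> "PositionWeightMatrix":
        width = len(seqs[0])
        if any(len(s) != width for s in seqs):
            raise ValueError("hit sequences must share one width")
        counts = np.zeros((width, 4))
        for s in seqs:
            for i, ch in enumerate(s.upper()):
                counts[i, _BASE_INDEX[ch]] += 1
        return cls.from_counts(counts, pseudocount, background)

    @classmethod
    def from_consensus(
        cls, consensus: str, strength: float = 0.9,
        background: np.ndarray | None = None,
    ) -> "PositionWeightMatrix":
        """IUPAC consensus string -> PWM placing ``strength`` mass on allowed bases."""
        width = len(consensus)
        probs = np.empty((width, 4))
        for i, ch in enumerate(consensus.upper()):
            allowed = _IUPAC.get(ch)
            if allowed is None:
                raise ValueError(f"bad consensus character {ch!r}")
            row = np.full(4, (1 - strength) / (4 - len(allowed)) if len(allowed) < 4 else 0.0)
            for b in allowed:
                row[_BASE_INDEX[b]] = strength / len(allowed)
            if len(allowed) == 4:
                row[:] = 0.25
            probs[i] = row
        return cls(probs, background)

    @classmethod
    def read(cls, path) -> "PositionWeightMatrix":
        """Simple whitespace matrix format: one row per position, columns A C G T."""
        mat = np.loadtxt(path)
        if mat.ndim == 1:
            mat = mat.reshape(1, -1)
        if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-3):
            mat = mat / mat.sum(axis=1, keepdims=True)
        return cls(mat)

    def write(self, path) -> None:
        np.savetxt(path, self.probs, fmt="%.6f", header="A C G T")


def _encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(codes), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[codes == ord(base)] = idx
    return out


def _scan_one_strand(pwm: PositionWeightMatrix, encoded: np.ndarray) -> np.ndarray:
    """Log-odds score at every start position; -inf where a window has non-ACGT."""
    w = pwm.width
    n = len(encoded) - w + 1
    if n <= 0:
        return np.empty(0)
    lo = pwm.log_odds
    scores = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    for offset in range(w):
        col = encoded[offset : offset + n]
        bad |= col < 0
        scores += lo[offset, np.clip(col, 0, 3)]
    scores[bad] = -np.inf
    return scores


def scan_pwm(
    pwm: PositionWeightMatrix,
    sequence: str,
    threshold: float,
    chrom: str = "seq",
) -> list[Interval]:
    """All positions on either strand scoring >= ``threshold`` (log-odds, base 2).

    Reverse-complement hits are reported on the '-' strand at forward
    coordinates; overlapping hits are retained.
    """
    if len(sequence) < pwm.width:
        return []
    fwd = _encode(sequence)
    rev = _encode(sequence.upper().translate(_COMPLEMENT)[::-1])
    hits: list[Interval] = []
    n = len(sequence)
    for strand, scores in (("+", _scan_one_strand(pwm, fwd)), ("-", _scan_one_strand(pwm, rev))):
        for pos in np.flatnonzero(scores >= threshold):
            if strand == "+":
                start = int(pos)
            else:
                start = n - int(pos) - pwm.width
            hits.append(
                Interval(chrom, start, start + pwm.width, strand=strand,
                         score=float(scores[pos]))
            )
    return sorted(hits, key=lambda iv: (iv.start, iv.strand))


def scan_genome(
    pwm: PositionWeightMatrix,
    sequences: Mapping[str, str],
    threshold: float,
) -> list[Interval]:
    out: list[Interval] = []
    for chrom in sequences:
        out.extend(scan_pwm(pwm, sequences[chrom], threshold, chrom=chrom))
    return sorted(out, key=lambda iv: (iv.chrom, iv.start, iv.strand))


def motif_bound_fraction(
    motif_hits: Sequence[Interval],
    peaks: Sequence[Interval] | PeakSet,
) -> float:
    """Fraction of motif hits sharing >= 1 bp with any peak."""
    if not motif_hits:
        raise ValueError("no motif hits")
    peak_ivs = peaks.intervals if isinstance(peaks, PeakSet) else list(peaks)
    return float(hit_flags(list(motif_hits), peak_ivs).mean())


def context_conditioned_fraction(
    motif_hits: Sequence[Interval],
    peaks: Sequence[Interval] | PeakSet,
    mark_windows: Sequence[Interval],
) -> dict:
    """Bound fraction among hits inside chromatin-mark windows vs all hits."""
    hits = list(motif_hits)
    overall = motif_bound_fraction(hits, peaks)
    in_marks = hit_flags(hits, list(mark_windows))
    subset = [h for h, f in zip(hits, in_marks) if f]
    result = {
        "overall_fraction": overall,
        "n_hits": len(hits),
        "n_in_marks": len(subset),
        "conditioned_fraction": None,
    }
    if not subset:
        logger.warning("context_conditioned_fraction: no motif hits in marked windows")
        return result
    result["conditioned_fraction"] = motif_bound_fraction(subset, peaks)
    return result


def clustering_effect(
    motif_hits: Sequence[Interval],
    peaks: Sequence[Interval] | PeakSet,
    genome: GenomeModel,
    window: int = 1000,
) -> dict:
    """Fold by which multi-motif windows are more likely bound than single-motif ones.

    The genome is tiled into contiguous non-overlapping windows; a window is
    'bound' iff it intersects a peak.  fold = P(bound | >= 2 motifs) /
    P(bound | exactly 1 motif).
    """
    tiles: list[Interval] = []
    for chrom in genome.included_chroms:
        length = genome.length(chrom)
        for s in range(0, length, window):
            tiles.append(Interval(chrom, s, min(s + window, length)))
    # count motifs per tile by midpoint assignment so a hit belongs to one window
    counts = np.zeros(len(tiles), dtype=int)
    tile_index = {
        (t.chrom, t.start // window): i for i, t in enumerate(tiles)
    }
    for h in motif_hits:
        mid = (h.start + h.end) // 2
        key = (h.chrom, mid // window)
        if key in tile_index:
            counts[tile_index[key]] += 1
    peak_ivs = peaks.intervals if isinstance(peaks, PeakSet) else list(peaks)
    bound = hit_flags(tiles, peak_ivs)
    single = counts == 1
    multi = counts >= 2
    if not single.any():
        raise ValueError("no single-motif windows; clustering fold undefined")
    p_single = float(bound[single].mean())
    p_multi = float(bound[multi].mean()) if multi.any() else np.nan
    fold = p_multi / p_single if p_single > 0 else np.inf
    return {
        "fold": float(fold),
        "p_bound_multi": p_multi,
        "p_bound_single": p_single,
        "n_multi_windows": int(multi.sum()),
        "n_single_windows": int(single.sum()),
    }
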