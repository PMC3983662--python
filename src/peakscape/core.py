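"""Genome model, interval/track data types, standard-format I/O and interval algebra.

Coordinate convention: 0-based, half-open everywhere.  BED and bedGraph are
native; GFF3 (1-based, closed) and wiggle (1-based) are converted at the
parsing boundary and converted back on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: annotation classes; short/long ncRNA split uses NCRNA_LENGTH_CUTOFF
GENE = "gene"
TRNA = "tRNA"
NCRNA_SHORT = "ncRNA_short"
NCRNA_LONG = "ncRNA_long"
ANNOTATION_CLASSES = (GENE, TRNA, NCRNA_SHORT, NCRNA_LONG)

NCRNA_LENGTH_CUTOFF = 200


class PeakscapeError(Exception):
    """Base class for all package errors."""


class ParseError(PeakscapeError):
    """A standard-format file failed to parse; message carries the line number."""


class ValidationError(PeakscapeError):
    """Data violates a documented invariant (coordinates, chromosomes, state)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names and lengths; the coordinate universe for everything else.

    Parameters
    ----------
    chrom_lengths
        Ordered mapping of chromosome name to length in bp.
    x_chrom
        Name of the X chromosome, or ``None`` for genomes without one.
    excluded_chroms
        Chromosomes dropped from genome-wide statistics and from random
        placement (e.g. the mitochondrial chromosome).
    """

    chrom_lengths: dict[str, int]
    x_chrom: str | None = None
    excluded_chroms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")
        if self.x_chrom is not None and self.x_chrom not in self.chrom_lengths:
            raise ValidationError(f"x_chrom {self.x_chrom!r} not among chromosomes")
        unknown = set(self.excluded_chroms) - set(self.chrom_lengths)
        if unknown:
            raise ValidationError(f"excluded_chroms not in genome: {sorted(unknown)}")
        object.__setattr__(self, "excluded_chroms", frozenset(self.excluded_chroms))

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def included_chroms(self) -> list[str]:
        return [c for c in self.chrom_lengths if c not in self.excluded_chroms]

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.included_chroms if c != self.x_chrom]

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    @classmethod
    def from_chromsizes(
        cls,
        path: str | Path,
        x_chrom: str | None = None,
        excluded_chroms: Iterable[str] = (),
    ) -> "GenomeModel":
        """Build from a two-column ``<chrom>\\t<length>`` text file."""
        lengths: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise ParseError(f"{path}:{lineno}: expected two columns")
                try:
                    lengths[fields[0]] = int(fields[1])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: bad length {fields[1]!r}") from None
        return cls(lengths, x_chrom=x_chrom, excluded_chroms=frozenset(excluded_chroms))

    def write_chromsizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chrom_lengths.items():
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = field(default=None, compare=False)
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"bad interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        """Number of shared bases (0 when on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted(self, offset: int) -> "Interval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class Peak:
    """An interval with a called summit (absolute bp) and summit score."""

    chrom: str
    start: int
    end: int
    summit: int
    summit_score: float = 0.0
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"bad peak {self.chrom}:{self.start}-{self.end}")
        if not (self.start <= self.summit < self.end):
            raise ValidationError(
                f"summit {self.summit} outside peak {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, score=self.summit_score, name=self.name)


class PeakSet:
    """An ordered collection of :class:`Peak`, sorted by (chrom, start)."""

    def __init__(self, peaks: Iterable[Peak], genome: GenomeModel | None = None):
        self.peaks: list[Peak] = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
        if genome is not None:
            for p in self.peaks:
                if p.chrom not in genome:
                    raise ValidationError(f"peak on unknown chromosome {p.chrom!r}")
                if p.end > genome.length(p.chrom):
                    raise ValidationError(
                        f"peak {p.chrom}:{p.start}-{p.end} beyond chromosome end"
                    )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]

    @property
    def intervals(self) -> list[Interval]:
        return [p.interval for p in self.peaks]

    @property
    def summits(self) -> list[tuple[str, int]]:
        return [(p.chrom, p.summit) for p in self.peaks]


@dataclass(frozen=True)
class AnnotationRecord:
    """A stranded gene-like record with a class label."""

    chrom: str
    start: int
    end: int
    strand: str
    cls: str
    name: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"annotation {self.name!r} must be stranded")
        if self.cls not in ANNOTATION_CLASSES:
            raise ValidationError(f"unknown annotation class {self.cls!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(f"bad record {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start: leftmost base on +, rightmost base on -."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, strand=self.strand, name=self.name)


class AnnotationSet:
    """Stranded gene-like records; promoters/3' regions are derived from these."""

    def __init__(self, records: Iterable[AnnotationRecord], genome: GenomeModel | None = None):
        self.records: list[AnnotationRecord] = sorted(
            records, key=lambda r: (r.chrom, r.start, r.end)
        )
        if genome is not None:
            for r in self.records:
                if r.chrom not in genome:
                    raise ValidationError(f"record {r.name!r} on unknown chromosome {r.chrom!r}")
                if r.end > genome.length(r.chrom):
                    raise ValidationError(f"record {r.name!r} beyond chromosome end")
        for r in self.records:
            if r.cls == NCRNA_SHORT and len(r) > NCRNA_LENGTH_CUTOFF:
                raise ValidationError(f"{r.name!r}: short ncRNA longer than cutoff")
            if r.cls == NCRNA_LONG and len(r) <= NCRNA_LENGTH_CUTOFF:
                raise ValidationError(f"{r.name!r}: long ncRNA within cutoff")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AnnotationRecord]:
        return iter(self.records)

    def of_class(self, *classes: str) -> "AnnotationSet":
        return AnnotationSet([r for r in self.records if r.cls in classes])

    @property
    def intervals(self) -> list[Interval]:
        return [r.interval for r in self.records]


NORMALIZATION_STATES = ("raw", "median_normalized", "input_subtracted", "zscored")


class CoverageTrack:
    """Per-base numeric signal per chromosome, with recorded normalization state.

    ``data`` maps chromosome name to a float array whose length equals the
    chromosome length.  ``provenance`` records each applied operation.
    """

    def __init__(
        self,
        data: dict[str, np.ndarray],
        genome: GenomeModel,
        state: str = "raw",
        provenance: list[dict] | None = None,
    ):
        if state not in NORMALIZATION_STATES:
            raise ValidationError(f"unknown normalization state {state!r}")
        self.data = {c: np.asarray(v, dtype=float) for c, v in data.items()}
        self.genome = genome
        self.state = state
        self.provenance: list[dict] = list(provenance or [])
        for chrom, arr in self.data.items():
            if chrom not in genome:
                raise ValidationError(f"track chromosome {chrom!r} not in genome")
            if arr.ndim != 1 or len(arr) != genome.length(chrom):
                raise ValidationError(
                    f"track length {len(arr)} != chromosome {chrom!r} "
                    f"length {genome.length(chrom)}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite values on chromosome {chrom!r}")

    @classmethod
    def zeros(cls, genome: GenomeModel, state: str = "raw") -> "CoverageTrack":
        return cls(
            {c: np.zeros(genome.length(c)) for c in genome.chrom_names}, genome, state=state
        )

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            {c: v.copy() for c, v in self.data.items()},
            self.genome,
            state=self.state,
            provenance=[dict(p) for p in self.provenance],
        )

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def values(self, chroms: Sequence[str] | None = None) -> np.ndarray:
        """Concatenated per-base values over the given chromosomes (genome order)."""
        if chroms is None:
            chroms = [c for c in self.genome.chrom_names if c in self.data]
        return np.concatenate([self.data[c] for c in chroms]) if chroms else np.array([])

    def region_values(self, interval: Interval) -> np.ndarray:
        return self.data[interval.chrom][interval.start : interval.end]


@dataclass
class AnalysisConfig:
    """Numeric parameters of the downstream analyses (defaults as published)."""

    n_permutations: int = 10_000
    summit_window: int = 200
    promoter_len: int = 1_000
    promoter_signal_len: int = 500
    gc_window: int = 15
    heatmap_flank: int = 750
    heatmap_bin: int = 50
    corr_window: int = 1_000
    ml_window: int = 250
    separation_float: float = 0.85
    consensus_k: int = 2
    min_overlap: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "summit_window",
            "promoter_len",
            "promoter_signal_len",
            "gc_window",
            "heatmap_flank",
            "heatmap_bin",
            "corr_window",
            "ml_window",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.separation_float < 1:
            raise ValidationError("separation_float must be in (0, 1)")
        if self.min_overlap < 1:
            raise ValidationError("min_overlap must be >= 1")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def sort_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(intervals: Iterable[Interval], book_ended: bool = True) -> list[Interval]:
    """Merge overlapping (and, by default, book-ended) intervals per chromosome.

    Strand, score and name are dropped; output is sorted by (chrom, start).
    """
    merged: list[Interval] = []
    cur: list | None = None
    for iv in sort_intervals(intervals):
        if cur is not None and iv.chrom == cur[0] and (
            iv.start < cur[2] or (book_ended and iv.start == cur[2])
        ):
            cur[2] = max(cur[2], iv.end)
        else:
            if cur is not None:
                merged.append(Interval(cur[0], cur[1], cur[2]))
            cur = [iv.chrom, iv.start, iv.end]
    if cur is not None:
        merged.append(Interval(cur[0], cur[1], cur[2]))
    return merged


def total_bases(intervals: Iterable[Interval]) -> int:
    """Union size in bp (overlaps counted once)."""
    return sum(len(iv) for iv in merge_intervals(list(intervals)))


class _ChromIndex:
    """Merged, sorted interval arrays per chromosome for fast overlap queries."""

    def __init__(self, intervals: Iterable[Interval]):
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        for iv in merge_intervals(list(intervals), book_ended=False):
            self.starts.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[attr-defined]
            self.ends.setdefault(iv.chrom, []).append(iv.end)  # type: ignore[attr-defined]
        for c in self.starts:
            self.starts[c] = np.asarray(self.starts[c])
            self.ends[c] = np.asarray(self.ends[c])

    def hits(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Boolean: does each query interval share >= 1 bp with any indexed interval?

        Relies on the indexed intervals being merged, hence both starts and
        ends strictly increasing.
        """
        if chrom not in self.starts:
            return np.zeros(len(starts), dtype=bool)
        idx = np.searchsorted(self.starts[chrom], ends, side="left")
        out = np.zeros(len(starts), dtype=bool)
        nz = idx > 0
        out[nz] = self.ends[chrom][idx[nz] - 1] > starts[nz]
        return out


def intersect(
    a: Sequence[Interval],
    b: Sequence[Interval],
    min_overlap: int = 1,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """All (i, j) index pairs with >= ``min_overlap`` shared bases, plus a-side hit flags.

    Overlap is strand-blind.  Returns ``(pairs, flags)`` where ``flags[i]`` is
    True iff ``a[i]`` overlaps at least one interval of ``b``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    by_chrom: dict[str, list[tuple[int, Interval]]] = {}
    for j, iv in enumerate(b):
        by_chrom.setdefault(iv.chrom, []).append((j, iv))
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t[1].start)
    pairs: list[tuple[int, int]] = []
    flags = np.zeros(len(a), dtype=bool)
    for i, iv in enumerate(a):
        for j, other in by_chrom.get(iv.chrom, ()):
            if other.start >= iv.end:
                break
            if iv.overlap(other) >= min_overlap:
                pairs.append((i, j))
                flags[i] = True
    return pairs, flags


def hit_flags(a: Sequence[Interval], b: Sequence[Interval], min_overlap: int = 1) -> np.ndarray:
    """Per-``a`` boolean overlap flags (convenience wrapper around :func:`intersect`)."""
    if min_overlap == 1:
        index = _ChromIndex(b)
        flags = np.zeros(len(a), dtype=bool)
        for i, iv in enumerate(a):
            flags[i] = bool(
                index.hits(iv.chrom, np.array([iv.start]), np.array([iv.end]))[0]
            )
        return flags
    return intersect(a, b, min_overlap=min_overlap)[1]


def clamp(start: int, end: int, chrom_length: int) -> tuple[int, int]:
    return max(0, start), min(end, chrom_length)


def derive_promoters(
    annotations: AnnotationSet | Iterable[AnnotationRecord],
    upstream_len: int,
    genome: GenomeModel,
) -> list[Interval]:
    """Strand-aware windows of ``upstream_len`` bp upstream of each TSS.

    ``+`` strand record [s, e) yields [s - L, s); ``-`` strand yields [e, e + L),
    truncated at chromosome boundaries (empty results are dropped and logged).
    """
    out: list[Interval] = []
    dropped = 0
    for r in annotations:
        if r.strand == "+":
            s, e = r.start - upstream_len, r.start
        else:
            s, e = r.end, r.end + upstream_len
        s, e = clamp(s, e, genome.length(r.chrom))
        if s < e:
            out.append(Interval(r.chrom, s, e, strand=r.strand, name=r.name))
        else:
            dropped += 1
    if dropped:
        logger.info("derive_promoters: %d records had no on-chromosome window", dropped)
    return sort_intervals(out)


def derive_3prime(
    annotations: AnnotationSet | Iterable[AnnotationRecord],
    downstream_len: int,
    genome: GenomeModel,
) -> list[Interval]:
    """Strand-aware windows downstream of each transcription end site."""
    out: list[Interval] = []
    dropped = 0
    for r in annotations:
        if r.strand == "+":
            s, e = r.end, r.end + downstream_len
        else:
            s, e = r.start - downstream_len, r.start
        s, e = clamp(s, e, genome.length(r.chrom))
        if s < e:
            out.append(Interval(r.chrom, s, e, strand=r.strand, name=r.name))
        else:
            dropped += 1
    if dropped:
        logger.info("derive_3prime: %d records had no on-chromosome window", dropped)
    return sort_intervals(out)


def flank_both(
    annotations: AnnotationSet | Iterable[AnnotationRecord],
    flank_len: int,
    genome: GenomeModel,
) -> list[Interval]:
    """Windows of ``flank_len`` bp around both the TSS and the TES of each record.

    Used for short gene-like records (ncRNAs) where upstream/downstream regions
    are considered jointly.
    """
    out: list[Interval] = []
    for r in annotations:
        for anchor in (r.tss, r.tes):
            s, e = clamp(anchor - flank_len, anchor + flank_len + 1, genome.length(r.chrom))
            if s < e:
                out.append(Interval(r.chrom, s, e, name=r.name))
    return merge_intervals(out)


def collapse_transcripts(records: Iterable[AnnotationRecord]) -> list[AnnotationRecord]:
    """Collapse per-transcript records sharing a name to outmost gene coordinates."""
    grouped: dict[tuple[str, str, str, str], list[AnnotationRecord]] = {}
    for r in records:
        grouped.setdefault((r.name, r.chrom, r.strand, r.cls), []).append(r)
    out = []
    for (name, chrom, strand, cls), lst in grouped.items():
        out.append(
            AnnotationRecord(
                chrom,
                min(r.start for r in lst),
                max(r.end for r in lst),
                strand,
                cls,
                name,
            )
        )
    return sorted(out, key=lambda r: (r.chrom, r.start))


# ---------------------------------------------------------------------------
# Standard-format I/O
# ---------------------------------------------------------------------------


def read_intervals(
    path: str | Path,
    fmt: str = "bed",
    genome: GenomeModel | None = None,
) -> list[Interval]:
    """Read BED3/BED6 or GFF3 into a sorted interval list (0-based half-open).

    GFF coordinates (1-based closed) are shifted on input.  Records on
    chromosomes absent from ``genome`` raise :class:`ValidationError`.
    """
    fmt = fmt.lower()
    if fmt == "bed":
        out = _read_bed(path)
    elif fmt in ("gff", "gff3"):
        out = [r.interval for r in read_gff(path)]
    else:
        raise ValueError(f"unknown interval format {fmt!r}")
    if genome is not None:
        for iv in out:
            if iv.chrom not in genome:
                raise ValidationError(f"{path}: unknown chromosome {iv.chrom!r}")
            if iv.end > genome.length(iv.chrom):
                raise ValidationError(f"{path}: {iv.chrom}:{iv.start}-{iv.end} beyond end")
    return sort_intervals(out)


def _read_bed(path: str | Path) -> list[Interval]:
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(Interval(fields[0], start, end, strand=strand, score=score, name=name))
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return out


def write_intervals(intervals: Iterable[Interval], path: str | Path, fmt: str = "bed") -> None:
    fmt = fmt.lower()
    if fmt != "bed":
        raise ValueError(f"unsupported write format {fmt!r}")
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


_GFF_CLASS_MAP = {
    "gene": GENE,
    "mrna": GENE,
    "protein_coding_gene": GENE,
    "trna": TRNA,
    "trna_gene": TRNA,
    "ncrna": None,  # resolved by length cutoff
    "ncrna_gene": None,
}


def read_gff(path: str | Path, genome: GenomeModel | None = None) -> AnnotationSet:
    """Read a GFF3 annotation file into an :class:`AnnotationSet`.

    Feature types map onto the internal classes (gene/mRNA -> gene,
    tRNA -> tRNA, ncRNA -> short/long by the 200 bp cutoff); other types are
    skipped.  1-based closed coordinates are converted to 0-based half-open.
    """
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: fewer than 9 GFF columns")
            ftype = fields[2].lower()
            if ftype not in _GFF_CLASS_MAP:
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            start, end = start1 - 1, end1
            strand = fields[6]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: annotation records must be stranded")
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            name = attrs.get("ID") or attrs.get("Name") or f"{fields[2]}_{lineno}"
            cls = _GFF_CLASS_MAP[ftype]
            if cls is None:
                cls = NCRNA_SHORT if (end - start) <= NCRNA_LENGTH_CUTOFF else NCRNA_LONG
            try:
                records.append(AnnotationRecord(fields[0], start, end, strand, cls, name))
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return AnnotationSet(records, genome=genome)


_GFF_TYPE_OUT = {GENE: "gene", TRNA: "tRNA", NCRNA_SHORT: "ncRNA", NCRNA_LONG: "ncRNA"}


def write_gff(annotations: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in annotations:
            fh.write(
                f"{r.chrom}\tpeakscape\t{_GFF_TYPE_OUT[r.cls]}\t{r.start + 1}\t{r.end}\t.\t"
                f"{r.strand}\t.\tID={r.name}\n"
            )


def read_peaks(path: str | Path, genome: GenomeModel | None = None) -> PeakSet:
    """Read peaks from BED6+1 where column 7 is the absolute summit position.

    Falls back to the interval midpoint when the summit column is absent.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            start, end = int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            summit = int(fields[6]) if len(fields) > 6 else (start + end) // 2
            try:
                peaks.append(Peak(fields[0], start, end, summit, score, name))
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return PeakSet(peaks, genome=genome)


def write_peaks(peakset: PeakSet, path: str | Path) -> None:
    """Write BED6+1 (columns: chrom start end name summit_score strand summit)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peakset):
            name = p.name if p.name is not None else f"peak_{i + 1}"
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.summit_score:g}\t.\t{p.summit}\n"
            )


def read_track(path: str | Path, genome: GenomeModel, fmt: str = "bedgraph") -> CoverageTrack:
    """Read a bedGraph or wiggle (fixedStep/variableStep) file into per-base arrays.

    Unspecified positions are zero-filled; positions beyond the declared
    chromosome end raise :class:`ValidationError`.
    """
    fmt = fmt.lower()
    data = {c: np.zeros(genome.length(c)) for c in genome.chrom_names}
    if fmt == "bedgraph":
        _fill_bedgraph(path, genome, data)
    elif fmt in ("wiggle", "wig"):
        _fill_wiggle(path, genome, data)
    else:
        raise ValueError(f"unknown track format {fmt!r}")
    return CoverageTrack(data, genome, state="raw", provenance=[{"op": "read", "path": str(path)}])


def _fill_bedgraph(path: str | Path, genome: GenomeModel, data: dict[str, np.ndarray]) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: fewer than 4 bedGraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in data:
                raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end > genome.length(chrom):
                raise ValidationError(f"{path}:{lineno}: position beyond chromosome end")
            data[chrom][start:end] = value


def _fill_wiggle(path: str | Path, genome: GenomeModel, data: dict[str, np.ndarray]) -> None:
    mode: str | None = None
    chrom: str | None = None
    pos = 0
    step = 1
    span = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                params = dict(kv.split("=") for kv in line.split()[1:])
                mode, chrom = "fixed", params["chrom"]
                pos = int(params["start"]) - 1  # wiggle is 1-based
                step = int(params.get("step", 1))
                span = int(params.get("span", 1))
                if chrom not in data:
                    raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                continue
            if line.startswith("variableStep"):
                params = dict(kv.split("=") for kv in line.split()[1:])
                mode, chrom = "variable", params["chrom"]
                span = int(params.get("span", 1))
                if chrom not in data:
                    raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                continue
            if mode is None or chrom is None:
                raise ParseError(f"{path}:{lineno}: data before any step declaration")
            if mode == "fixed":
                value = float(line)
                if pos + span > genome.length(chrom):
                    raise ValidationError(f"{path}:{lineno}: position beyond chromosome end")
                data[chrom][pos : pos + span] = value
                pos += step
            else:
                fields = line.split()
                if len(fields) != 2:
                    raise ParseError(f"{path}:{lineno}: expected '<pos> <value>'")
                p = int(fields[0]) - 1
                if p + span > genome.length(chrom):
                    raise ValidationError(f"{path}:{lineno}: position beyond chromosome end")
                data[chrom][p : p + span] = float(fields[1])


def write_track(track: CoverageTrack, path: str | Path, fmt: str = "bedgraph") -> None:
    """Write a track as run-length-compressed bedGraph or fixedStep wiggle.

    Values are written at full float precision so write-then-read is the
    identity; zero runs are omitted from bedGraph (the read side zero-fills).
    """
    import pandas as pd

    fmt = fmt.lower()
    if fmt not in ("bedgraph", "wiggle", "wig"):
        raise ValueError(f"unknown track format {fmt!r}")
    with open(path, "w") as fh:
        for chrom in track.genome.chrom_names:
            if chrom not in track.data:
                continue
            arr = track.data[chrom]
            if fmt == "bedgraph":
                boundaries = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate([[0], boundaries])
                ends = np.concatenate([boundaries, [len(arr)]])
                vals = arr[starts]
                keep = vals != 0.0
                pd.DataFrame(
                    {0: chrom, 1: starts[keep], 2: ends[keep], 3: vals[keep]}
                ).to_csv(fh, sep="\t", header=False, index=False)
            else:
                fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
                pd.Series(arr).to_csv(fh, header=False, index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Chromosome name -> uppercase sequence string."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
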