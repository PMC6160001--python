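"""Reading, validation and writing of peak/interval files.

All coordinates are 0-based half-open (BED convention). A peak carries a
single summit position (the base of maximal ChIP signal) and, optionally, a
fold-enrichment (FE) score from the peak caller.

Supported on-disk formats:

* ENCODE narrowPeak (10 columns): FE taken from column 7 (signalValue),
  summit from the column-10 offset (-1 means unknown -> midpoint fallback).
* Plain BED (3-6 columns): summit = floor((start+end)/2), FE missing.
* "summit BED" (exactly 7 columns, written by :func:`write_peaks`):
  BED6 + summit-offset column, with ``.`` as the missing-FE sentinel in the
  score column. Round-trips all peak fields exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeLayout",
    "GenomicPeak",
    "Cistrome",
    "BlacklistRegions",
    "PeakFileError",
    "read_peaks",
    "write_peaks",
    "filter_blacklist",
    "read_blacklist",
]


class PeakFileError(ValueError):
    """Raised for malformed peak/interval files; message names the line."""


@dataclass(frozen=True)
class GenomeLayout:
    """Coordinate universe: ordered chromosome names and lengths in bp."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be strictly positive")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths)


@dataclass(frozen=True)
class GenomicPeak:
    """A scored, summit-bearing genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    summit: int
    name: str = "."
    fold_enrichment: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak {self.name}: start must be < end "
                             f"({self.chrom}:{self.start}-{self.end})")
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"peak {self.name}: summit {self.summit} outside "
                             f"[{self.start}, {self.end})")
        if self.fold_enrichment is not None and self.fold_enrichment < 0:
            raise ValueError(f"peak {self.name}: negative fold enrichment")


@dataclass
class Cistrome:
    """A named collection of peaks from one factor/condition.

    ``factor_label`` names the transcription factor (e.g. GR, REVERBa);
    ``source_label`` records provenance (timepoint, accession, pool).
    """

    factor_label: str
    peaks: list[GenomicPeak] = field(default_factory=list)
    source_label: str = ""
    layout: GenomeLayout | None = None

    def __post_init__(self) -> None:
        if self.layout is not None:
            lens = self.layout.lengths
            for p in self.peaks:
                if p.chrom not in lens:
                    raise ValueError(f"peak {p.name}: chromosome {p.chrom} "
                                     "absent from genome layout")
                if p.end > lens[p.chrom]:
                    raise ValueError(f"peak {p.name}: extends beyond "
                                     f"{p.chrom} length {lens[p.chrom]}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[GenomicPeak]:
        return iter(self.peaks)

    def chroms(self) -> set[str]:
        return {p.chrom for p in self.peaks}


@dataclass
class BlacklistRegions:
    """Artifact-prone regions to exclude, as (chrom, start, end) half-open."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if not start < end:
                raise ValueError(f"blacklist interval {chrom}:{start}-{end} "
                                 "has start >= end")

    def __len__(self) -> int:
        return len(self.intervals)

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees for overlap queries."""
        by_chrom: dict[str, IntervalTree] = {}
        for chrom, start, end in self.intervals:
            by_chrom.setdefault(chrom, IntervalTree()).addi(start, end)
        return by_chrom


def _parse_int(token: str, what: str, lineno: int, path: str) -> int:
    try:
        value = int(token)
    except ValueError:
        raise PeakFileError(
            f"{path}, line {lineno}: {what} is not an integer: {token!r}"
        ) from None
    if value < 0 and what != "summit offset":
        raise PeakFileError(f"{path}, line {lineno}: negative {what}: {value}")
    return value


def _is_header(line: str) -> bool:
    return line.startswith(("#", "track", "browser"))


def read_peaks(path: str | Path, format_hint: str = "auto") -> Cistrome:
    """Read a peak file into a :class:`Cistrome`.

    ``format_hint`` is one of ``bed``, ``narrowPeak``, ``auto``. With
    ``auto``, 10 columns -> narrowPeak, 7 columns -> summit BED
    (the :func:`write_peaks` output), 3-6 columns -> plain BED.
    """
    path = Path(path)
    if format_hint not in ("bed", "narrowPeak", "auto"):
        raise PeakFileError(f"unknown format hint: {format_hint!r}")
    peaks: list[GenomicPeak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or _is_header(line):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate whitespace-separated files
                fields = line.split()
            n = len(fields)
            if format_hint == "narrowPeak" and n != 10:
                raise PeakFileError(f"{path}, line {lineno}: narrowPeak "
                                    f"requires 10 columns, got {n}")
            if n < 3:
                raise PeakFileError(f"{path}, line {lineno}: fewer than 3 "
                                    "columns")
            chrom = fields[0]
            start = _parse_int(fields[1], "start", lineno, str(path))
            end = _parse_int(fields[2], "end", lineno, str(path))
            if end <= start:
                raise PeakFileError(f"{path}, line {lineno}: end <= start")
            name = fields[3] if n >= 4 else f"peak_{lineno}"
            fe: float | None = None
            if n == 10 and format_hint in ("narrowPeak", "auto"):
                try:
                    fe = float(fields[6])
                except ValueError:
                    raise PeakFileError(f"{path}, line {lineno}: bad "
                                        f"signalValue {fields[6]!r}") from None
                offset = _parse_int(fields[9], "summit offset", lineno,
                                    str(path))
                summit = start + offset if offset >= 0 else (start + end) // 2
            elif n == 7 and format_hint == "auto":
                # summit BED: col5 = FE or ".", col7 = summit offset
                if fields[4] != ".":
                    try:
                        fe = float(fields[4])
                    except ValueError:
                        raise PeakFileError(
                            f"{path}, line {lineno}: bad score {fields[4]!r}"
                        ) from None
                offset = _parse_int(fields[6], "summit offset", lineno,
                                    str(path))
                summit = start + offset
            else:
                summit = (start + end) // 2
            if not (start <= summit < end):
                raise PeakFileError(f"{path}, line {lineno}: summit {summit} "
                                    f"outside [{start}, {end})")
            peaks.append(GenomicPeak(chrom, start, end, summit, name, fe))
    return Cistrome(factor_label=path.stem, peaks=peaks,
                    source_label=str(path))


def write_peaks(cistrome: Cistrome, path: str | Path) -> None:
    """Write a cistrome as summit BED (BED6 + summit-offset column).

    ``read_peaks(write_peaks(c))`` reproduces coordinates, summits and FE
    exactly; missing FE is written as the ``.`` sentinel in the score column.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for p in cistrome:
            score = "." if p.fold_enrichment is None else (
                repr(p.fold_enrichment))
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{score}\t.\t"
                     f"{p.summit - p.start}\n")


def read_blacklist(path: str | Path) -> BlacklistRegions:
    """Read a blacklist BED (first three columns used)."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or _is_header(line):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise PeakFileError(f"{path}, line {lineno}: fewer than 3 "
                                    "columns")
            intervals.append((fields[0],
                              _parse_int(fields[1], "start", lineno, str(path)),
                              _parse_int(fields[2], "end", lineno, str(path))))
    return BlacklistRegions(intervals)


def filter_blacklist(items, blacklist: BlacklistRegions):
    """Remove items overlapping (>= 1 bp) any blacklist interval.

    ``items`` is a :class:`Cistrome` or a sequence of objects with
    ``chrom``/``start``/``end`` attributes or ``(chrom, start, end, ...)``
    tuples; the same kind is returned, survivor order preserved. Chromosome
    names are matched by exact string equality; a warning is logged when the
    name sets are disjoint (likely a "chr" prefix mismatch).
    """
    trees = blacklist.trees()

    def _coords(item) -> tuple[str, int, int]:
        if hasattr(item, "chrom"):
            return item.chrom, item.start, item.end
        chrom, start, end = item[0], item[1], item[2]
        return chrom, start, end

    if isinstance(items, Cistrome):
        seq: Sequence = items.peaks
    else:
        seq = list(items)

    if trees and seq:
        item_chroms = {_coords(it)[0] for it in seq}
        if item_chroms.isdisjoint(trees):
            logger.warning(
                "blacklist and input share no chromosome names "
                "(%s vs %s); nothing will be filtered",
                sorted(item_chroms)[:3], sorted(trees)[:3])

    survivors = [it for it in seq
                 if not (lambda c: c[0] in trees
                         and trees[c[0]].overlaps(c[1], c[2]))(_coords(it))]

    if isinstance(items, Cistrome):
        return Cistrome(factor_label=items.factor_label, peaks=survivors,
                        source_label=items.source_label, layout=items.layout)
    return survivors
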