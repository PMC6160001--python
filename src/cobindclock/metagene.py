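"""TSS-anchored metagene profiling of binned read coverage.

Reads are counted in fixed-width genomic bins (default 100 bp). For a gene
list, symmetric windows of +/- 2 kb around each TSS are formed, windows (or
their baselines) overlapping blacklisted regions or truncated by chromosome
edges are dropped, and per-window signal is expressed as fold change over
the mean read count in the 1 kb preceding the window. The profile is the
unweighted mean of these fold changes over all surviving sites.

"Preceding" is interpreted on the gene-oriented axis by default: for a
- strand gene the baseline lies at higher genomic coordinates and the
window is mirrored so the position axis runs in transcription direction.
``strand_oriented=False`` selects the purely genomic alternative (baseline
always upstream in genome coordinates, no mirroring).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .gene_annotation import DeGeneSet, TssRecord
from .peak_io import BlacklistRegions, GenomeLayout

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageTrack",
    "MetageneWindow",
    "MetageneProfile",
    "bin_coverage",
    "read_bedgraph",
    "build_tss_windows",
    "fold_change_profile",
]


@dataclass
class CoverageTrack:
    """Per-chromosome read counts in fixed-width bins."""

    bin_width: int
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        for chrom, vec in self.counts.items():
            vec = np.asarray(vec)
            if (vec < 0).any():
                raise ValueError(f"negative counts on {chrom}")
            self.counts[chrom] = vec

    def total(self) -> int:
        return int(sum(v.sum() for v in self.counts.values()))


@dataclass(frozen=True)
class MetageneWindow:
    """A symmetric TSS window plus its oriented 1-kb baseline."""

    gene_id: str
    chrom: str
    start: int            # window start, genomic
    end: int              # window end, genomic (= start + 2*flank)
    strand: str
    baseline_start: int
    baseline_end: int
    oriented: bool = True  # True -> mirror - strand windows in the profile


@dataclass
class MetageneProfile:
    positions: np.ndarray   # bin centers relative to the TSS, bp
    fold_change: np.ndarray
    n_sites: int
    n_zero_baseline: int = 0


def bin_coverage(reads: Mapping[str, Sequence[int]],
                 layout: GenomeLayout,
                 bin_width: int = 100) -> CoverageTrack:
    """Count read start positions per half-open bin of each chromosome.

    ``reads`` maps chromosome name to 5' read-start positions (bp). Total
    counts are conserved: the sum over all bins equals the read count.
    Positions outside [0, chrom_length) raise an error.
    """
    lens = layout.lengths
    counts: dict[str, np.ndarray] = {}
    for chrom, length in lens.items():
        n_bins = -(-length // bin_width)  # ceil
        counts[chrom] = np.zeros(n_bins, dtype=np.int64)
    for chrom, positions in reads.items():
        if chrom not in lens:
            raise ValueError(f"chromosome {chrom} absent from layout")
        pos = np.asarray(positions, dtype=np.int64)
        if pos.size == 0:
            continue
        if pos.min() < 0 or pos.max() >= lens[chrom]:
            raise ValueError(f"read position outside {chrom} bounds "
                             f"[0, {lens[chrom]})")
        np.add.at(counts[chrom], pos // bin_width, 1)
    return CoverageTrack(bin_width=bin_width, counts=counts)


def read_bedgraph(path, layout: GenomeLayout,
                  bin_width: int = 100) -> CoverageTrack:
    """Read pre-binned counts from a bedGraph aligned to the bin grid.

    Interval boundaries must be multiples of ``bin_width``; unlisted bins
    are zero.
    """
    counts = {chrom: np.zeros(-(-length // bin_width), dtype=np.int64)
              for chrom, length in layout.lengths.items()}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split()[:4]
            start, end = int(start), int(end)
            if chrom not in counts:
                raise ValueError(f"{path}, line {lineno}: chromosome "
                                 f"{chrom} absent from layout")
            if start % bin_width or (end % bin_width
                                     and end != layout.lengths[chrom]):
                raise ValueError(f"{path}, line {lineno}: interval not "
                                 f"aligned to {bin_width}-bp grid")
            counts[chrom][start // bin_width:-(-end // bin_width)] = \
                int(float(value))
    return CoverageTrack(bin_width=bin_width, counts=counts)


def build_tss_windows(genes: DeGeneSet | Iterable[str],
                      annotation: Sequence[TssRecord],
                      blacklist: BlacklistRegions | None = None,
                      layout: GenomeLayout | None = None,
                      flank: int = 2000,
                      baseline_bp: int = 1000,
                      strand_oriented: bool = True
                      ) -> tuple[list[MetageneWindow], int]:
    """Build +/- ``flank`` TSS windows with oriented baselines for a gene set.

    Returns (windows, n_dropped). A gene is dropped (with a warning for
    missing TSS records) when it has no TSS, when the window or baseline
    would extend past a chromosome edge, or when either overlaps the
    blacklist — full geometry is required so every profile bin is backed by
    real sequence.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    gene_ids = sorted(genes.genes) if isinstance(genes, DeGeneSet) \
        else sorted(set(genes))
    tss_by_gene = {r.gene_id: r for r in annotation}
    trees = blacklist.trees() if blacklist is not None else {}
    lens = layout.lengths if layout is not None else None

    windows: list[MetageneWindow] = []
    n_dropped = 0
    for gid in gene_ids:
        rec = tss_by_gene.get(gid)
        if rec is None:
            logger.warning("gene %s has no TSS record; skipped", gid)
            n_dropped += 1
            continue
        w_start, w_end = rec.tss - flank, rec.tss + flank
        upstream = strand_oriented and rec.strand == "-"
        if upstream:
            b_start, b_end = w_end, w_end + baseline_bp
        else:
            b_start, b_end = w_start - baseline_bp, w_start
        lo, hi = min(w_start, b_start), max(w_end, b_end)
        if lo < 0 or (lens is not None and rec.chrom in lens
                      and hi > lens[rec.chrom]):
            n_dropped += 1
            continue
        tree = trees.get(rec.chrom)
        if tree is not None and (tree.overlaps(w_start, w_end)
                                 or tree.overlaps(b_start, b_end)):
            n_dropped += 1
            continue
        windows.append(MetageneWindow(
            gene_id=gid, chrom=rec.chrom, start=w_start, end=w_end,
            strand=rec.strand, baseline_start=b_start, baseline_end=b_end,
            oriented=strand_oriented))
    return windows, n_dropped


def fold_change_profile(windows: Sequence[MetageneWindow],
                        track: CoverageTrack) -> MetageneProfile:
    """Mean fold-change-over-baseline profile across TSS windows.

    Per site, the baseline is the mean count of the baseline bins; sites
    with a zero baseline are excluded (counted in ``n_zero_baseline``).
    Each window's bins are divided by its own baseline, minus-strand
    windows are mirrored when strand-oriented, and the profile is the
    unweighted mean over surviving sites. Window edges are snapped down to
    the track's bin grid.
    """
    if not windows:
        raise ValueError("no metagene windows supplied")
    w = track.bin_width
    flank = (windows[0].end - windows[0].start) // 2
    n_bins = 2 * flank // w
    profiles: list[np.ndarray] = []
    n_zero = 0
    for win in windows:
        vec = track.counts.get(win.chrom)
        if vec is None:
            raise ValueError(f"no coverage for chromosome {win.chrom}")
        wb = win.start // w
        bb = win.baseline_start // w
        n_base = (win.baseline_end - win.baseline_start) // w
        if wb < 0 or wb + n_bins > len(vec) or bb < 0 \
                or bb + n_base > len(vec):
            raise ValueError(f"window for {win.gene_id} outside track")
        baseline = float(vec[bb:bb + n_base].mean())
        if baseline == 0.0:
            n_zero += 1
            continue
        fc = vec[wb:wb + n_bins].astype(float) / baseline
        if win.oriented and win.strand == "-":
            fc = fc[::-1]
        profiles.append(fc)
    if not profiles:
        raise ValueError("all sites had zero baseline coverage")
    if n_zero:
        logger.info("%d sites excluded for zero baseline", n_zero)
    positions = np.arange(-flank + w // 2, flank, w, dtype=np.int64)
    return MetageneProfile(positions=positions,
                           fold_change=np.mean(profiles, axis=0),
                           n_sites=len(profiles),
                           n_zero_baseline=n_zero)
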