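"""Summit-proximity co-binding statistics between two cistromes.

The central quantity is the summit-to-summit distance from each peak of a
query cistrome (e.g. GR) to the nearest peak of a reference cistrome (e.g.
REVERBa). Query peaks closer than a threshold (default 120 bp) are counted
as co-binding events; the co-binding ratio is the count of proximal events
divided by the count of non-proximal events. Because it compares relative
abundances, the ratio is insensitive to the total number of peaks in either
cistrome.

Conventions: a distance strictly below the threshold is proximal; a tie at
exactly the threshold is non-proximal. Distances are unsigned. Query peaks
with no same-chromosome reference peak ("orphans") are excluded from the
distance set and counted separately.
"""

from __future__ import annotations

import math
import logging
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .peak_io import Cistrome, GenomicPeak

logger = logging.getLogger(__name__)

__all__ = [
    "CobindConfig",
    "DistanceSet",
    "CobindSummary",
    "CoboundPair",
    "DistanceHistogram",
    "OverlapSummary",
    "filter_by_fe",
    "pool_cistromes",
    "nearest_summit_distances",
    "cobinding_ratio",
    "distance_histogram",
    "extract_cobound_pairs",
    "cistrome_overlap",
    "background_proximal_rate",
]


@dataclass(frozen=True)
class CobindConfig:
    """Parameters of the co-binding analysis.

    proximal_threshold_bp
        Summit separation below which two peaks count as co-bound (bp).
    fe_stringencies
        Fold-enrichment cutoffs defining low/mid/high stringency tiers.
    histogram_bin_bp, histogram_max_bp
        Bin width and right edge of the distance histogram.
    """

    proximal_threshold_bp: int = 120
    fe_stringencies: tuple[float, ...] = (10.0, 20.0, 30.0)
    histogram_bin_bp: int = 20
    histogram_max_bp: int = 3000

    def __post_init__(self) -> None:
        if self.proximal_threshold_bp <= 0:
            raise ValueError("proximal_threshold_bp must be > 0")
        s = self.fe_stringencies
        if any(x < 0 for x in s) or list(s) != sorted(s):
            raise ValueError("fe_stringencies must be non-negative ascending")
        if self.histogram_bin_bp <= 0:
            raise ValueError("histogram_bin_bp must be > 0")
        if self.histogram_max_bp % self.histogram_bin_bp != 0:
            raise ValueError("histogram_bin_bp must divide histogram_max_bp")


@dataclass
class DistanceSet:
    """Nearest-reference-summit distances, one per non-orphan query peak."""

    query_label: str
    ref_label: str
    distances: np.ndarray  # non-negative bp, dtype int64
    n_orphans: int = 0

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.int64)
        if (self.distances < 0).any():
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.distances)


@dataclass(frozen=True)
class CobindSummary:
    n_proximal: int
    n_nonproximal: int
    ratio: float  # math.inf sentinel when n_nonproximal == 0
    median_proximal_bp: float | None
    median_all_bp: float | None


@dataclass(frozen=True)
class CoboundPair:
    query_peak: GenomicPeak
    ref_peak: GenomicPeak
    distance_bp: int


@dataclass(frozen=True)
class DistanceHistogram:
    bin_edges: np.ndarray  # length n_bins + 1
    counts: np.ndarray     # length n_bins
    overflow: int          # distances >= last edge


@dataclass(frozen=True)
class OverlapSummary:
    """Interval-overlap (>= 1 bp) comparison of two cistromes."""
    a_only: int
    b_only: int
    shared_a: int  # peaks of a intersecting >= 1 peak of b
    shared_b: int


def filter_by_fe(cistrome: Cistrome, fe_cutoff: float) -> Cistrome:
    """Keep peaks with fold_enrichment >= cutoff (inclusive), order kept.

    Raises ValueError naming the offending peaks if any lacks an FE score.
    """
    missing = [p.name for p in cistrome if p.fold_enrichment is None]
    if missing:
        shown = ", ".join(missing[:10])
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        raise ValueError(
            f"peaks missing fold enrichment: {shown}{more}")
    kept = [p for p in cistrome if p.fold_enrichment >= fe_cutoff]
    return Cistrome(factor_label=cistrome.factor_label, peaks=kept,
                    source_label=f"{cistrome.source_label}|FE>={fe_cutoff:g}",
                    layout=cistrome.layout)


def pool_cistromes(cistromes: list[Cistrome], label: str) -> Cistrome:
    """Concatenate cistromes into one (duplicates retained).

    Mirrors pooling of one factor's peak sets from multiple circadian
    timepoints into a single reference cistrome.
    """
    if not cistromes:
        raise ValueError("cannot pool an empty list of cistromes")
    peaks: list[GenomicPeak] = []
    for c in cistromes:
        peaks.extend(c.peaks)
    return Cistrome(factor_label=label, peaks=peaks,
                    source_label="+".join(c.source_label for c in cistromes),
                    layout=cistromes[0].layout)


def _summits_by_chrom(cistrome: Cistrome):
    """chrom -> (sorted summit array, names in summit order, peaks)."""
    by_chrom: dict[str, list[GenomicPeak]] = {}
    for p in cistrome:
        by_chrom.setdefault(p.chrom, []).append(p)
    out = {}
    for chrom, plist in by_chrom.items():
        summits = np.array([p.summit for p in plist], dtype=np.int64)
        order = np.argsort(summits, kind="stable")
        out[chrom] = (summits[order], [plist[i] for i in order])
    return out


def _nearest(query: Cistrome, ref: Cistrome):
    """Per query peak: (distance, ref_peak) or None for orphans.

    Uses binary search on per-chromosome sorted summit arrays. When query
    and ref are the same object, a candidate whose name equals the query
    peak's name is skipped so a peak never matches itself (other peaks at
    zero distance still count).
    """
    if len(ref) == 0:
        raise ValueError("reference cistrome is empty")
    if len(query) == 0:
        raise ValueError("query cistrome is empty")
    self_mode = query is ref
    ref_idx = _summits_by_chrom(ref)
    results: list[tuple[int, GenomicPeak] | None] = []
    for qp in query:
        if qp.chrom not in ref_idx:
            results.append(None)
            continue
        summits, peaks = ref_idx[qp.chrom]
        i = int(np.searchsorted(summits, qp.summit))
        best: tuple[int, GenomicPeak] | None = None
        # nearest non-self lies within two slots either side of the
        # insertion point (self can occupy at most one of the inner slots)
        for j in range(max(0, i - 2), min(len(summits), i + 2)):
            cand = peaks[j]
            if self_mode and cand.name == qp.name:
                continue
            d = abs(int(summits[j]) - qp.summit)
            if best is None or d < best[0]:
                best = (d, cand)
        results.append(best)
    return results


def nearest_summit_distances(query: Cistrome, ref: Cistrome) -> DistanceSet:
    """Distance from each query summit to the nearest reference summit.

    Query peaks on chromosomes absent from the reference are counted as
    orphans rather than contributing a distance.
    """
    matched = _nearest(query, ref)
    distances = [m[0] for m in matched if m is not None]
    n_orphans = sum(1 for m in matched if m is None)
    return DistanceSet(query_label=query.factor_label,
                       ref_label=ref.factor_label,
                       distances=np.array(distances, dtype=np.int64),
                       n_orphans=n_orphans)


def cobinding_ratio(dset: DistanceSet,
                    config: CobindConfig = CobindConfig()) -> CobindSummary:
    """Proximal/non-proximal counts, co-binding ratio and medians.

    A distance strictly below the threshold is proximal; exactly the
    threshold is non-proximal. If no distance reaches the threshold the
    ratio is reported as the ``inf`` sentinel (logged, not an error).
    """
    if len(dset) == 0:
        raise ValueError("distance set is empty (all query peaks orphaned?)")
    d = dset.distances
    t = config.proximal_threshold_bp
    n_prox = int((d < t).sum())
    n_non = len(d) - n_prox
    if n_non == 0:
        logger.info("no non-proximal distances (%s vs %s); ratio is infinite",
                    dset.query_label, dset.ref_label)
        ratio = math.inf
    else:
        ratio = n_prox / n_non
    prox = d[d < t]
    return CobindSummary(
        n_proximal=n_prox,
        n_nonproximal=n_non,
        ratio=ratio,
        median_proximal_bp=float(np.median(prox)) if len(prox) else None,
        median_all_bp=float(np.median(d)),
    )


def distance_histogram(dset: DistanceSet,
                       config: CobindConfig = CobindConfig()
                       ) -> DistanceHistogram:
    """Histogram of nearest-summit distances in half-open bins.

    Bins are [k*w, (k+1)*w) up to ``histogram_max_bp``; distances at or
    beyond the right edge go to the overflow count, so counts + overflow
    equals the distance-set size.
    """
    w, mx = config.histogram_bin_bp, config.histogram_max_bp
    edges = np.arange(0, mx + w, w, dtype=np.int64)
    d = dset.distances
    in_range = d[d < mx]
    counts, _ = np.histogram(in_range, bins=edges)
    return DistanceHistogram(bin_edges=edges, counts=counts,
                             overflow=int((d >= mx).sum()))


def extract_cobound_pairs(query: Cistrome, ref: Cistrome,
                          config: CobindConfig = CobindConfig()
                          ) -> list[CoboundPair]:
    """Query peaks whose nearest reference summit is below the threshold.

    One pair per proximal query peak, carrying the nearest reference peak
    and the summit separation; sorted by chromosome then query start.
    """
    matched = _nearest(query, ref)
    pairs = [
        CoboundPair(query_peak=qp, ref_peak=m[1], distance_bp=m[0])
        for qp, m in zip(query, matched)
        if m is not None and m[0] < config.proximal_threshold_bp
    ]
    pairs.sort(key=lambda p: (p.query_peak.chrom, p.query_peak.start))
    return pairs


def cistrome_overlap(a: Cistrome, b: Cistrome) -> OverlapSummary:
    """Count peaks of each cistrome intersecting (>= 1 bp) the other.

    Computed symmetrically: one peak of ``a`` spanning two peaks of ``b``
    contributes 1 to shared_a and 2 to shared_b.
    """
    def trees(c: Cistrome) -> dict[str, IntervalTree]:
        t: dict[str, IntervalTree] = {}
        for p in c:
            t.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
        return t

    tb = trees(b)
    shared_a = sum(1 for p in a
                   if p.chrom in tb and tb[p.chrom].overlaps(p.start, p.end))
    ta = trees(a)
    shared_b = sum(1 for p in b
                   if p.chrom in ta and ta[p.chrom].overlaps(p.start, p.end))
    return OverlapSummary(a_only=len(a) - shared_a, b_only=len(b) - shared_b,
                          shared_a=shared_a, shared_b=shared_b)


def background_proximal_rate(threshold_bp: float, n_ref: int,
                             genome_bp: int) -> float:
    """Chance proximal rate for uniformly placed reference summits.

    With reference summits dropped uniformly at density rho = n_ref /
    genome_bp, the nearest-summit distance from a random position is
    approximately exponential and P(distance < t) = 1 - exp(-2 t rho).
    Used to correct an observed proximal fraction for coincidental
    proximity when estimating a planted co-bound fraction.
    """
    rho = n_ref / genome_bp
    return 1.0 - math.exp(-2.0 * threshold_bp * rho)
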