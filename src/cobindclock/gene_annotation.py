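"""Peak-to-gene assignment and time-of-day target stratification.

Peaks are associated to genes by nearest transcription start site (TSS) on
the same chromosome, with the signed distance reported in the gene's
transcription orientation (positive = downstream of the TSS). Condition-
labelled differential-expression (DE) gene sets — genotype (WT/KO) crossed
with time of administration (day/night) — are stratified by proximity to
co-bound sites: for each genotype, the day-exclusive co-bound targets are
the genes responsive by day but not by night whose nearest peak assignment
is a co-bound site, and analogously for night.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cobinding import CoboundPair
from .peak_io import GenomicPeak

__all__ = [
    "TssRecord",
    "TssAssignment",
    "DeGeneSet",
    "StratifiedGeneSets",
    "CONDITION_KEYS",
    "read_tss_bed",
    "read_de_set",
    "assign_peak_to_nearest_tss",
    "genes_near_cobound",
    "stratify_time_specific_targets",
]

CONDITION_KEYS = ("wt_day", "wt_night", "ko_day", "ko_night")


@dataclass(frozen=True)
class TssRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class TssAssignment:
    """Nearest-TSS gene for a peak; distance signed in gene orientation."""
    gene_id: str
    signed_distance: int


@dataclass
class DeGeneSet:
    """A condition-labelled differential-expression gene set."""
    label: str
    genes: set[str] = field(default_factory=set)
    direction: dict[str, str] = field(default_factory=dict)  # gene -> up/down


@dataclass
class StratifiedGeneSets:
    """Co-bound, condition-exclusive target gene sets (Fig-5-style)."""
    wt_day_exclusive_cobound: set[str]
    ko_day_exclusive_cobound: set[str]
    wt_night_exclusive_cobound: set[str]
    ko_night_exclusive_cobound: set[str]
    lost_plus_gained_day: set[str]
    lost_plus_gained_night: set[str]

    def counts(self) -> dict[str, int]:
        return {k: len(getattr(self, k)) for k in (
            "wt_day_exclusive_cobound", "ko_day_exclusive_cobound",
            "wt_night_exclusive_cobound", "ko_night_exclusive_cobound",
            "lost_plus_gained_day", "lost_plus_gained_night")}


def read_tss_bed(path: str | Path) -> list[TssRecord]:
    """Read a TSS table from BED6 (name = gene id).

    The TSS is taken as ``start`` for + strand genes and ``end - 1`` for
    - strand genes (identical for 1-bp records).
    """
    records = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 4:
                raise ValueError(f"{path}, line {lineno}: need >= 4 columns")
            strand = f[5] if len(f) >= 6 else "+"
            start, end = int(f[1]), int(f[2])
            tss = start if strand == "+" else end - 1
            if f[3] in seen:
                raise ValueError(f"{path}, line {lineno}: duplicate gene id "
                                 f"{f[3]}")
            seen.add(f[3])
            records.append(TssRecord(f[3], f[0], tss, strand))
    return records


def read_de_set(path: str | Path, label: str) -> DeGeneSet:
    """Read a DE gene set from a two-column TSV (gene_id, direction)."""
    genes: set[str] = set()
    direction: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            genes.add(f[0])
            if len(f) > 1 and f[1] in ("up", "down"):
                direction[f[0]] = f[1]
    return DeGeneSet(label=label, genes=genes, direction=direction)


class _TssIndex:
    """Per-chromosome sorted TSS positions for nearest queries."""

    def __init__(self, annotation: Sequence[TssRecord]):
        by_chrom: dict[str, list[TssRecord]] = {}
        for r in annotation:
            by_chrom.setdefault(r.chrom, []).append(r)
        self._index: dict[str, tuple[np.ndarray, list[TssRecord]]] = {}
        for chrom, recs in by_chrom.items():
            pos = np.array([r.tss for r in recs], dtype=np.int64)
            order = np.argsort(pos, kind="stable")
            self._index[chrom] = (pos[order], [recs[i] for i in order])

    def nearest(self, chrom: str, position: int) -> TssRecord | None:
        if chrom not in self._index:
            return None
        pos, recs = self._index[chrom]
        i = int(np.searchsorted(pos, position))
        lo, hi = max(0, i - 1), min(len(pos), i + 1)
        best_d = min(abs(int(pos[j]) - position) for j in range(lo, hi + 1)
                     if j < len(pos))
        # collect all records at the minimal distance, break tie by gene id
        ties = [r for p, r in zip(pos, recs) if abs(int(p) - position) == best_d]
        return min(ties, key=lambda r: r.gene_id)


def assign_peak_to_nearest_tss(
        peak: GenomicPeak,
        annotation: Sequence[TssRecord] | _TssIndex) -> TssAssignment | None:
    """Assign a peak to the gene whose TSS is nearest its summit.

    The signed distance is summit - tss for + strand genes and tss - summit
    for - strand genes, so a positive value always means downstream of the
    TSS. Equidistant TSSs are broken toward the lexicographically smallest
    gene id. Returns None when the peak's chromosome has no TSS.
    """
    if not annotation:
        raise ValueError("annotation is empty")
    index = annotation if isinstance(annotation, _TssIndex) \
        else _TssIndex(annotation)
    rec = index.nearest(peak.chrom, peak.summit)
    if rec is None:
        return None
    d = peak.summit - rec.tss
    if rec.strand == "-":
        d = -d
    return TssAssignment(gene_id=rec.gene_id, signed_distance=d)


def genes_near_cobound(pairs: Iterable[CoboundPair],
                       annotation: Sequence[TssRecord]) -> set[str]:
    """Deduplicated nearest-TSS genes of the query peaks of co-bound pairs."""
    pairs = list(pairs)
    if not pairs:
        return set()
    index = _TssIndex(annotation)
    genes: set[str] = set()
    for pair in pairs:
        assignment = assign_peak_to_nearest_tss(pair.query_peak, index)
        if assignment is not None:
            genes.add(assignment.gene_id)
    return genes


def stratify_time_specific_targets(
        de_sets: Mapping[str, DeGeneSet],
        cobound_genes: set[str]) -> StratifiedGeneSets:
    """Stratify DE gene sets by time-exclusivity and co-bound proximity.

    For each genotype g and time t, the t-exclusive co-bound set is
    (genes responsive at t) minus (genes responsive at the other time),
    intersected with ``cobound_genes``. The lost-plus-gained set for time t
    combines genes whose t-exclusive co-bound response is present in one
    genotype but absent from the other genotype's t-responsive set — the
    genes that lose or gain their glucocorticoid response at that time.
    """
    missing = [k for k in CONDITION_KEYS if k not in de_sets]
    if missing:
        raise ValueError(f"missing DE conditions: {', '.join(missing)}")
    wt_day = de_sets["wt_day"].genes
    wt_night = de_sets["wt_night"].genes
    ko_day = de_sets["ko_day"].genes
    ko_night = de_sets["ko_night"].genes

    wt_day_x = (wt_day - wt_night) & cobound_genes
    ko_day_x = (ko_day - ko_night) & cobound_genes
    wt_night_x = (wt_night - wt_day) & cobound_genes
    ko_night_x = (ko_night - ko_day) & cobound_genes

    return StratifiedGeneSets(
        wt_day_exclusive_cobound=wt_day_x,
        ko_day_exclusive_cobound=ko_day_x,
        wt_night_exclusive_cobound=wt_night_x,
        ko_night_exclusive_cobound=ko_night_x,
        lost_plus_gained_day=(wt_day_x - ko_day) | (ko_day_x - wt_day),
        lost_plus_gained_night=(wt_night_x - ko_night) | (ko_night_x - wt_night),
    )
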