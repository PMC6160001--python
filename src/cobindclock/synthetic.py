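"""Synthetic cistromes, gene sets and coverage with recorded ground truth.

Emulates the statistical structure the co-binding analysis assumes, on a
small toy genome, so every pipeline stage can be exercised and checked
against planted truth without any sequencing downloads:

* two cistromes — reference summits uniform on the genome; a planted
  fraction ``f`` of query summits placed at a randomly chosen reference
  summit plus a discretized Laplace offset (heavy-tailed, like observed
  summit scatter), the rest uniform; per-peak fold-enrichment scores drawn
  lognormal with a higher location for co-bound peaks;
* a TSS table on the coverage bin grid;
* four condition-labelled differential-expression gene sets (WT/KO x
  day/night) with planted, disjoint co-bound exclusive subsets so the
  stratification bookkeeping can be verified exactly;
* Poisson read coverage with planted enrichment around chosen TSSs.

Every generator is a pure function of its configuration; the same seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cobinding import DistanceSet, background_proximal_rate
from .gene_annotation import DeGeneSet, TssRecord, _TssIndex, \
    assign_peak_to_nearest_tss, CONDITION_KEYS
from .metagene import CoverageTrack
from .peak_io import Cistrome, GenomeLayout, GenomicPeak

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_cistromes",
    "simulate_tss",
    "simulate_de_sets",
    "simulate_coverage",
    "estimate_cobound_fraction",
    "write_simulation",
]

PEAK_HALF_WIDTH = 150  # bp; typical TF ChIP peak half-width
_MIN_SPACING = 300     # bp per peak required of the genome

# rng stream tags so the stages draw from independent substreams
_STAGE_CISTROME, _STAGE_TSS, _STAGE_DE, _STAGE_COVERAGE = 11, 23, 37, 53


def _default_genome() -> GenomeLayout:
    return GenomeLayout(("chr1", "chr2"), (5_000_000, 5_000_000))


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    ``cobound_fraction`` is the planted fraction of query peaks placed near
    a reference summit; ``offset_scale_bp`` the Laplace scale of planted
    summit offsets. ``de_overlap`` is the fraction of co-bound genes
    planted as condition-exclusive differential-expression targets (per
    condition). Coverage rates are Poisson means per 100-bp bin.
    """

    seed: int = 0
    genome: GenomeLayout = field(default_factory=_default_genome)
    n_ref_peaks: int = 1000
    n_query_peaks: int = 2000
    cobound_fraction: float = 0.3
    offset_scale_bp: float = 40.0
    fe_mu_cobound: float = 3.6     # lognormal location, exp(3.6) ~ 37
    fe_mu_background: float = 2.6  # exp(2.6) ~ 13
    fe_sigma: float = 0.5
    n_genes: int = 400
    de_overlap: float = 0.2
    coverage_lambda_bg: float = 5.0
    coverage_lambda_tss: float = 15.0
    coverage_bin_bp: int = 100

    def __post_init__(self) -> None:
        for name in ("n_ref_peaks", "n_query_peaks", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cobound_fraction", "de_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("offset_scale_bp", "fe_sigma", "coverage_lambda_bg",
                     "coverage_lambda_tss"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genome_chroms"] = ",".join(self.genome.chrom_names)
        d["genome_lengths"] = ",".join(str(x) for x in
                                       self.genome.chrom_lengths)
        del d["genome"]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "genome_chroms" in d:
            names = tuple(d.pop("genome_chroms").split(","))
            lengths = tuple(int(x) for x in d.pop("genome_lengths").split(","))
            d["genome"] = GenomeLayout(names, lengths)
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth recorded while generating a synthetic study."""

    is_cobound: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=bool))
    planted_offsets: dict[str, int] = field(default_factory=dict)
    cobound_genes: set[str] = field(default_factory=set)
    planted_exclusive: dict[str, set[str]] = field(default_factory=dict)
    expected_counts: dict[str, int] = field(default_factory=dict)
    enriched_genes: set[str] = field(default_factory=set)

    def to_json_dict(self) -> dict:
        return {
            "is_cobound": [bool(x) for x in self.is_cobound],
            "planted_offsets": self.planted_offsets,
            "cobound_genes": sorted(self.cobound_genes),
            "planted_exclusive": {k: sorted(v) for k, v
                                  in self.planted_exclusive.items()},
            "expected_counts": self.expected_counts,
            "enriched_genes": sorted(self.enriched_genes),
        }


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _uniform_summits(rng: np.random.Generator, layout: GenomeLayout,
                     n: int, margin: int) -> list[tuple[str, int]]:
    lengths = np.array(layout.chrom_lengths, dtype=float)
    chrom_idx = rng.choice(len(lengths), size=n, p=lengths / lengths.sum())
    out = []
    for ci in chrom_idx:
        length = layout.chrom_lengths[ci]
        pos = int(rng.integers(margin, length - margin))
        out.append((layout.chrom_names[ci], pos))
    return out


def simulate_cistromes(config: SimConfig
                       ) -> tuple[Cistrome, Cistrome, SimTruth]:
    """Generate (reference, query, truth) cistromes with planted co-binding.

    round(f * n_query) query summits are placed at a uniformly chosen
    reference summit plus a signed discretized-Laplace offset; the rest
    are uniform. Peak intervals are summit +/- 150 bp. Raises if the
    genome cannot hold the requested peaks at >= 300 bp per peak.
    """
    layout = config.genome
    n_max = max(config.n_ref_peaks, config.n_query_peaks)
    if layout.total_bp < _MIN_SPACING * n_max:
        raise ValueError(
            f"genome ({layout.total_bp} bp) too small for {n_max} peaks at "
            f">= {_MIN_SPACING} bp spacing")
    rng = _rng(config, _STAGE_CISTROME)
    margin = PEAK_HALF_WIDTH

    ref_sites = _uniform_summits(rng, layout, config.n_ref_peaks, margin)
    ref_peaks = [
        GenomicPeak(chrom, s - margin, s + margin, s, f"ref_{i:05d}",
                    float(rng.lognormal(config.fe_mu_background,
                                        config.fe_sigma)))
        for i, (chrom, s) in enumerate(ref_sites)
    ]

    n_cobound = round(config.cobound_fraction * config.n_query_peaks)
    lens = layout.lengths
    entries: list[tuple[str, int, bool, int]] = []  # chrom, summit, cb, off
    if n_cobound:
        src = rng.integers(0, config.n_ref_peaks, size=n_cobound)
        offsets = np.rint(rng.laplace(0.0, config.offset_scale_bp,
                                      size=n_cobound)).astype(int)
        for si, off in zip(src, offsets):
            chrom, ref_s = ref_sites[si]
            summit = int(np.clip(ref_s + off, margin,
                                 lens[chrom] - margin - 1))
            entries.append((chrom, summit, True, summit - ref_s))
    for chrom, s in _uniform_summits(
            rng, layout, config.n_query_peaks - n_cobound, margin):
        entries.append((chrom, s, False, 0))

    # FE drawn in entry order, then peaks sorted by coordinate for output
    fe_vals = [
        float(rng.lognormal(
            config.fe_mu_cobound if cb else config.fe_mu_background,
            config.fe_sigma))
        for _, _, cb, _ in entries
    ]
    order = sorted(range(len(entries)),
                   key=lambda i: (entries[i][0], entries[i][1], i))
    query_peaks, is_cobound, planted = [], [], {}
    for rank, i in enumerate(order):
        chrom, summit, cb, off = entries[i]
        name = f"q_{rank:05d}"
        query_peaks.append(GenomicPeak(chrom, summit - margin,
                                       summit + margin, summit, name,
                                       fe_vals[i]))
        is_cobound.append(cb)
        if cb:
            planted[name] = off

    truth = SimTruth(is_cobound=np.array(is_cobound, dtype=bool),
                     planted_offsets=planted)
    ref = Cistrome("REF", ref_peaks, source_label="synthetic", layout=layout)
    query = Cistrome("QUERY", query_peaks, source_label="synthetic",
                     layout=layout)
    return ref, query, truth


def simulate_tss(config: SimConfig) -> list[TssRecord]:
    """Uniform TSS table on the coverage bin grid, random strands.

    TSS positions are multiples of the coverage bin width and keep a
    3.5-kb margin from chromosome ends so every metagene window and
    baseline fits.
    """
    rng = _rng(config, _STAGE_TSS)
    layout = config.genome
    w = config.coverage_bin_bp
    margin_bins = 3500 // w + 1
    lengths = np.array(layout.chrom_lengths, dtype=float)
    chrom_idx = rng.choice(len(lengths), size=config.n_genes,
                           p=lengths / lengths.sum())
    records = []
    for i, ci in enumerate(chrom_idx):
        n_bins = layout.chrom_lengths[ci] // w
        b = int(rng.integers(margin_bins, n_bins - margin_bins))
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(TssRecord(f"g{i:04d}", layout.chrom_names[ci],
                                 b * w, strand))
    return records


def simulate_de_sets(config: SimConfig, truth: SimTruth,
                     annotation: list[TssRecord], query: Cistrome
                     ) -> tuple[dict[str, DeGeneSet], SimTruth]:
    """Four condition-labelled DE gene sets with planted co-bound overlap.

    The co-bound gene set is the nearest-TSS assignment of the planted
    co-bound query peaks. Per condition, round(de_overlap * n_cobound)
    of those genes are planted as exclusive targets, the four planted
    subsets mutually disjoint; shared day/night and condition-specific
    filler genes are drawn from non-co-bound genes. Planted exclusive
    sets and their counts are recorded in the returned truth.
    """
    rng = _rng(config, _STAGE_DE)
    index = _TssIndex(annotation)
    cobound_genes: set[str] = set()
    for peak, cb in zip(query, truth.is_cobound):
        if cb:
            a = assign_peak_to_nearest_tss(peak, index)
            if a is not None:
                cobound_genes.add(a.gene_id)
    truth.cobound_genes = cobound_genes

    all_genes = {r.gene_id for r in annotation}
    cob = sorted(cobound_genes)
    non = sorted(all_genes - cobound_genes)
    rng.shuffle(cob)
    rng.shuffle(non)

    k = round(config.de_overlap * len(cob))
    if 4 * k > len(cob):
        raise ValueError(
            f"de_overlap={config.de_overlap} requires 4 x {k} planted genes "
            f"but only {len(cob)} co-bound genes exist")
    planted = {key: set(cob[i * k:(i + 1) * k])
               for i, key in enumerate(CONDITION_KEYS)}

    m = min(max(5, config.n_genes // 20), len(non) // 6)
    chunks = [set(non[i * m:(i + 1) * m]) for i in range(6)]
    shared_wt, shared_ko, f_wd, f_wn, f_kd, f_kn = chunks

    members = {
        "wt_day": planted["wt_day"] | shared_wt | f_wd,
        "wt_night": planted["wt_night"] | shared_wt | f_wn,
        "ko_day": planted["ko_day"] | shared_ko | f_kd,
        "ko_night": planted["ko_night"] | shared_ko | f_kn,
    }
    de_sets = {}
    for key, genes in members.items():
        direction = {g: ("up" if rng.random() < 0.5 else "down")
                     for g in sorted(genes)}
        de_sets[key] = DeGeneSet(label=key, genes=genes, direction=direction)

    truth.planted_exclusive = {f"{k}_exclusive_cobound": v
                               for k, v in planted.items()}
    truth.expected_counts = {
        "wt_day_exclusive_cobound": k,
        "ko_day_exclusive_cobound": k,
        "wt_night_exclusive_cobound": k,
        "ko_night_exclusive_cobound": k,
        "lost_plus_gained_day": 2 * k,
        "lost_plus_gained_night": 2 * k,
    }
    truth.enriched_genes = {g for g in de_sets["wt_day"].genes
                            if de_sets["wt_day"].direction.get(g) == "up"}
    return de_sets, truth


def simulate_coverage(config: SimConfig, truth: SimTruth,
                      annotation: list[TssRecord]) -> CoverageTrack:
    """Poisson bin counts with planted enrichment around enriched TSSs.

    Background bins ~ Poisson(coverage_lambda_bg); bins within +/- 500 bp
    of the TSS of any gene in ``truth.enriched_genes`` ~
    Poisson(coverage_lambda_tss).
    """
    rng = _rng(config, _STAGE_COVERAGE)
    layout = config.genome
    w = config.coverage_bin_bp
    counts: dict[str, np.ndarray] = {}
    for chrom, length in layout.lengths.items():
        n_bins = -(-length // w)
        counts[chrom] = rng.poisson(config.coverage_lambda_bg,
                                    size=n_bins).astype(np.int64)
    half = 500
    for rec in annotation:
        if rec.gene_id not in truth.enriched_genes:
            continue
        vec = counts[rec.chrom]
        lo = max(0, (rec.tss - half) // w)
        hi = min(len(vec), -(-(rec.tss + half) // w))
        vec[lo:hi] = rng.poisson(config.coverage_lambda_tss, size=hi - lo)
    return CoverageTrack(bin_width=w, counts=counts)


def estimate_cobound_fraction(dset: DistanceSet, config: SimConfig,
                              threshold_bp: int = 120) -> float:
    """Estimate the planted co-bound fraction from a distance set.

    Observed proximal fraction minus the closed-form chance-proximity rate
    1 - exp(-2 t rho) for uniformly placed reference summits at density
    rho = n_ref / genome bp.
    """
    p_obs = float((dset.distances < threshold_bp).mean())
    p_bg = background_proximal_rate(threshold_bp, config.n_ref_peaks,
                                    config.genome.total_bp)
    return p_obs - p_bg


def write_simulation(outdir: str | Path, config: SimConfig) -> dict:
    """Run every generator and write the study to ``outdir``.

    Writes ref.bed and query.narrowPeak, tss.bed, de_<condition>.tsv,
    coverage.bedgraph and truth.json; returns a small manifest of paths.
    """
    from .peak_io import write_peaks

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref, query, truth = simulate_cistromes(config)
    annotation = simulate_tss(config)
    de_sets, truth = simulate_de_sets(config, truth, annotation, query)
    track = simulate_coverage(config, truth, annotation)

    paths = {"ref": outdir / "ref.bed",
             "query": outdir / "query.narrowPeak",
             "tss": outdir / "tss.bed",
             "coverage": outdir / "coverage.bedgraph",
             "truth": outdir / "truth.json"}
    write_peaks(ref, paths["ref"])
    with open(paths["query"], "w") as fh:
        for p in query:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t"
                     f"{p.fold_enrichment:.4f}\t-1\t-1\t"
                     f"{p.summit - p.start}\n")
    with open(paths["tss"], "w") as fh:
        for r in annotation:
            fh.write(f"{r.chrom}\t{r.tss}\t{r.tss + 1}\t{r.gene_id}\t0\t"
                     f"{r.strand}\n")
    for key, ds in de_sets.items():
        p = outdir / f"de_{key}.tsv"
        paths[f"de_{key}"] = p
        with open(p, "w") as fh:
            for g in sorted(ds.genes):
                fh.write(f"{g}\t{ds.direction.get(g, '.')}\n")
    with open(paths["coverage"], "w") as fh:
        w = track.bin_width
        for chrom in config.genome.chrom_names:
            vec = track.counts[chrom]
            for i, c in enumerate(vec):
                if c:
                    fh.write(f"{chrom}\t{i * w}\t{(i + 1) * w}\t{int(c)}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
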