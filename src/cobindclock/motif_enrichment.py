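"""Known-motif scanning and observed/expected enrichment ranking.

A position weight matrix (PWM) is scanned over target and background
sequence sets with a log-odds score on both strands. Per motif, the
observed fraction (target regions with >= 1 hit) over the expected
fraction (same in background regions) gives the %Ratio used to rank
motifs; rows with %Ratio < 1.5 or coverage (observed fraction as a
percentage) < 5% are removed, and duplicate motifs — identical IUPAC
consensus after degenerate-base collapse — are collapsed to the
highest-%Ratio member.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PositionWeightMatrix",
    "read_motifs",
    "scan_pwm",
    "motif_coverage_and_ratio",
    "build_rank_table",
    "filter_and_rank_motifs",
    "sample_background_regions",
    "MIN_PERCENT_RATIO",
    "MIN_COVERAGE_PERCENT",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# filtering thresholds for ranked motif tables
MIN_PERCENT_RATIO = 1.5
MIN_COVERAGE_PERCENT = 5.0

# two-base IUPAC codes, checked in fixed order for determinism
_IUPAC2 = {("A", "C"): "M", ("A", "G"): "R", ("A", "T"): "W",
           ("C", "G"): "S", ("C", "T"): "Y", ("G", "T"): "K"}


@dataclass
class PositionWeightMatrix:
    """A probability matrix over A/C/G/T with a log-odds hit threshold.

    ``matrix`` has one row per motif position, columns in A, C, G, T
    order, each row summing to 1. ``score_threshold`` defaults to 80% of
    the maximal attainable log-odds score for the motif.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    score_threshold: float | None = None
    _pseudo: float = 1e-3

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be L x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError(f"{self.motif_id}: motif length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: position probabilities must "
                             "each sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        p = self.matrix + self._pseudo
        p = p / p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def threshold(self) -> float:
        if self.score_threshold is not None:
            return self.score_threshold
        return 0.8 * self.max_score

    def consensus(self, degenerate_cutoff: float = 0.6) -> str:
        """IUPAC consensus: single base if its probability reaches the
        cutoff, else the two-base code whose summed probability does,
        else N."""
        letters = []
        for row in self.matrix:
            order = np.argsort(-row, kind="stable")
            if row[order[0]] >= degenerate_cutoff:
                letters.append(_BASES[order[0]])
                continue
            pair = tuple(sorted((_BASES[order[0]], _BASES[order[1]])))
            if row[order[0]] + row[order[1]] >= degenerate_cutoff:
                letters.append(_IUPAC2[pair])
            else:
                letters.append("N")
        return "".join(letters)


def read_motifs(path: str | Path) -> list[PositionWeightMatrix]:
    """Read motifs from HOMER-style probability text.

    Each motif is a ``>`` header line (``>consensus<TAB>motif_id[<TAB>...]``
    or just ``>motif_id``) followed by one whitespace-separated row of four
    A/C/G/T probabilities per motif position.
    """
    motifs: list[PositionWeightMatrix] = []
    header: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        if header is None:
            return
        if not rows:
            raise ValueError(f"motif {header} has no matrix rows")
        parts = header.split("\t")
        motif_id = parts[1] if len(parts) > 1 else parts[0]
        motifs.append(PositionWeightMatrix(motif_id=motif_id,
                                           matrix=np.array(rows)))

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                rows = []
            else:
                values = [float(x) for x in line.split()]
                if len(values) != 4:
                    raise ValueError(f"{path}: matrix row must have 4 "
                                     f"values, got {len(values)}")
                rows.append(values)
    flush()
    return motifs


def _encode(seq: str) -> np.ndarray:
    """Sequence -> integer codes; 4 marks N/unknown."""
    return np.frombuffer(
        seq.upper().encode().translate(
            bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))),
        dtype=np.uint8).copy()


def _count_hits(codes: np.ndarray, lods: np.ndarray,
                lods_rc: np.ndarray, thr: float) -> int:
    L = lods.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return 0
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = ~(windows >= 4).any(axis=1)
    if not valid.any():
        return 0
    win = windows[valid].astype(np.int64)
    fwd = lods[np.arange(L), win].sum(axis=1)
    rev = lods_rc[np.arange(L), win].sum(axis=1)
    return int((np.maximum(fwd, rev) >= thr).sum())


def scan_pwm(sequences: Mapping[str, str],
             pwm: PositionWeightMatrix) -> dict[str, int]:
    """Count motif hits per sequence, scanning both strands.

    A hit is an offset where the log-odds score on either strand reaches
    the motif threshold (a palindromic match counts once); offsets
    containing N are skipped. Sequences shorter than the motif yield 0
    hits.
    """
    lods = pwm.log_odds
    # scoring the reverse strand at an offset = scoring the forward window
    # with the reverse-complemented matrix
    lods_rc = lods[::-1, ::-1]
    thr = pwm.threshold
    return {label: _count_hits(_encode(seq), lods, lods_rc, thr)
            for label, seq in sequences.items()}


def motif_coverage_and_ratio(motif_id: str,
                             target_hits: Mapping[str, int],
                             background_hits: Mapping[str, int],
                             consensus: str = "") -> dict:
    """One rank-table row: observed/expected fractions, %Ratio, coverage.

    observed_fraction = targets with >= 1 hit / n_targets (likewise for
    background); percent_ratio = observed/expected (``inf`` sentinel when
    the background fraction is 0); coverage = observed fraction as %.
    """
    if not target_hits or not background_hits:
        raise ValueError("target and background region sets must be "
                         "non-empty")
    obs = sum(1 for v in target_hits.values() if v > 0) / len(target_hits)
    exp = sum(1 for v in background_hits.values() if v > 0) \
        / len(background_hits)
    ratio = math.inf if exp == 0 else obs / exp
    return {"motif_id": motif_id, "consensus": consensus,
            "observed_fraction": obs, "expected_fraction": exp,
            "percent_ratio": ratio, "coverage_percent": 100.0 * obs}


def build_rank_table(rows: Sequence[dict]) -> pd.DataFrame:
    columns = ["motif_id", "consensus", "observed_fraction",
               "expected_fraction", "percent_ratio", "coverage_percent"]
    return pd.DataFrame(list(rows), columns=columns)


def filter_and_rank_motifs(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the %Ratio / coverage filters, deduplicate, rank.

    Drops rows with percent_ratio < 1.5 or coverage < 5%, collapses rows
    sharing a non-empty consensus to the highest-%Ratio member, and sorts
    the table by descending %Ratio. Idempotent.
    """
    kept = table[(table["percent_ratio"] >= MIN_PERCENT_RATIO)
                 & (table["coverage_percent"] >= MIN_COVERAGE_PERCENT)]
    kept = kept.sort_values("percent_ratio", ascending=False,
                            kind="stable")
    has_consensus = kept["consensus"].astype(bool)
    deduped = pd.concat([
        kept[has_consensus].drop_duplicates(subset="consensus", keep="first"),
        kept[~has_consensus],
    ]).sort_values("percent_ratio", ascending=False, kind="stable")
    return deduped.reset_index(drop=True)


def sample_background_regions(genome_seqs: Mapping[str, str],
                              lengths: Sequence[int],
                              exclude: Sequence[tuple[str, int, int]] = (),
                              rng: np.random.Generator | None = None
                              ) -> dict[str, str]:
    """Sample length-matched background sequences uniformly from a genome.

    Draws one region per requested length from random chromosomes/offsets,
    rejecting draws overlapping the ``exclude`` intervals (e.g. the target
    regions themselves). Used to build the expected-frequency denominator
    when no explicit background set is supplied.
    """
    rng = rng if rng is not None else np.random.default_rng()
    chroms = sorted(genome_seqs)
    excl: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in exclude:
        excl.setdefault(chrom, []).append((s, e))
    out: dict[str, str] = {}
    for i, length in enumerate(lengths):
        for _ in range(1000):
            chrom = chroms[rng.integers(len(chroms))]
            seq = genome_seqs[chrom]
            if len(seq) < length:
                continue
            start = int(rng.integers(0, len(seq) - length + 1))
            if any(start < e and start + length > s
                   for s, e in excl.get(chrom, ())):
                continue
            out[f"bg_{i}"] = seq[start:start + length]
            break
        else:
            raise ValueError("could not place a background region; genome "
                             "too small or exclusions too dense")
    return out
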