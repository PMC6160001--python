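import math

import numpy as np
import pytest

from cobindclock.motif_enrichment import (
    PositionWeightMatrix, build_rank_table, filter_and_rank_motifs,
    motif_coverage_and_ratio, read_motifs, sample_background_regions,
    scan_pwm)

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def consensus_pwm(consensus, motif_id="m"):
    rows = np.zeros((len(consensus), 4))
    for i, base in enumerate(consensus):
        rows[i, _BASES.index(base)] = 1.0
    return PositionWeightMatrix(motif_id, rows)


def brute_force_hits(seq, pwm):
    """Naive per-offset rescoring: best of both strands at each offset."""
    lods = pwm.log_odds
    L = len(pwm)
    total = 0
    for i in range(len(seq) - L + 1):
        window = seq[i:i + L]
        if any(b not in _BASES for b in window):
            continue
        fwd = sum(lods[j, _BASES.index(b)] for j, b in enumerate(window))
        rc = window.translate(_COMPLEMENT)[::-1]
        rev = sum(lods[j, _BASES.index(b)] for j, b in enumerate(rc))
        total += max(fwd, rev) >= pwm.threshold
    return total


class TestScan:
    def test_exact_consensus_found_once(self):
        pwm = consensus_pwm("ACGT")
        # ACGT is its own reverse complement; the offset counts once
        assert scan_pwm({"s": "TTACGTTT"}, pwm)["s"] == 1

    def test_non_palindromic_consensus(self):
        pwm = consensus_pwm("ACGG")
        assert scan_pwm({"s": "TTACGGTT"}, pwm)["s"] == 1

    def test_absent_motif_gives_zero(self):
        pwm = consensus_pwm("ACGT")
        assert scan_pwm({"s": "A" * 30}, pwm)["s"] == 0

    def test_sequence_shorter_than_motif(self):
        pwm = consensus_pwm("ACGTACGT")
        assert scan_pwm({"s": "ACG"}, pwm)["s"] == 0

    def test_n_containing_offsets_skipped(self):
        pwm = consensus_pwm("ACGG")
        assert scan_pwm({"s": "ACNG" * 5}, pwm)["s"] == 0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_per_offset_rescoring_oracle(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(4) * 0.4, size=6)
        pwm = PositionWeightMatrix("rand", probs)
        seqs = {f"s{i}": "".join(rng.choice(list(_BASES), size=200))
                for i in range(100)}
        got = scan_pwm(seqs, pwm)
        for label, seq in seqs.items():
            assert got[label] == brute_force_hits(seq, pwm)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(3)
        pwm = PositionWeightMatrix("rand",
                                   rng.dirichlet(np.ones(4), size=5))
        seqs = {f"s{i}": "".join(rng.choice(list(_BASES), size=150))
                for i in range(30)}
        rc = {k: v.translate(_COMPLEMENT)[::-1] for k, v in seqs.items()}
        assert scan_pwm(seqs, pwm) == scan_pwm(rc, pwm)


class TestRatioRow:
    def test_observed_expected_arithmetic(self):
        t = {f"t{i}": int(i < 10) for i in range(100)}
        b = {f"b{i}": int(i < 2) for i in range(100)}
        row = motif_coverage_and_ratio("m", t, b)
        assert row["percent_ratio"] == pytest.approx(5.0)
        assert row["coverage_percent"] == pytest.approx(10.0)

    def test_equal_fractions_give_unit_ratio(self):
        hits = {"a": 1, "b": 0}
        row = motif_coverage_and_ratio("m", hits, hits)
        assert row["percent_ratio"] == 1.0

    def test_zero_expected_gives_infinite_sentinel(self):
        row = motif_coverage_and_ratio("m", {"a": 3}, {"b": 0})
        assert math.isinf(row["percent_ratio"])

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            motif_coverage_and_ratio("m", {}, {"b": 1})

    def test_planted_enrichment_recovered(self):
        # motif planted in 40% of targets, 5% of background
        rng = np.random.default_rng(8)
        pwm = consensus_pwm("ACGGTCAT")

        def region(planted):
            seq = list(rng.choice(list(_BASES), size=200))
            if planted:
                i = rng.integers(0, 192)
                seq[i:i + 8] = "ACGGTCAT"
            return "".join(seq)

        targets = {f"t{i}": region(i < 80) for i in range(200)}
        background = {f"b{i}": region(i < 10) for i in range(200)}
        row = motif_coverage_and_ratio(
            "m", scan_pwm(targets, pwm), scan_pwm(background, pwm))
        assert 5.0 < row["percent_ratio"] < 12.0


class TestFilterRank:
    def build(self, ratios, coverages, consensi=None):
        consensi = consensi or [""] * len(ratios)
        return build_rank_table([
            {"motif_id": f"m{i}", "consensus": c, "observed_fraction": 0.0,
             "expected_fraction": 0.0, "percent_ratio": r,
             "coverage_percent": cov}
            for i, (r, cov, c) in enumerate(zip(ratios, coverages, consensi))
        ])

    def test_threshold_filtering(self):
        table = self.build([5.0, 1.4, 2.0], [10.0, 20.0, 4.0])
        out = filter_and_rank_motifs(table)
        assert len(out) == 1
        assert out.iloc[0]["percent_ratio"] == 5.0

    def test_empty_input_gives_empty_output(self):
        out = filter_and_rank_motifs(self.build([], []))
        assert len(out) == 0

    def test_duplicate_consensus_keeps_higher_ratio(self):
        table = self.build([3.0, 2.0], [10.0, 10.0], ["ACGT", "ACGT"])
        out = filter_and_rank_motifs(table)
        assert len(out) == 1
        assert out.iloc[0]["percent_ratio"] == 3.0

    def test_idempotent_and_sorted(self):
        table = self.build([2.0, 8.0, 3.0], [10.0, 10.0, 10.0])
        once = filter_and_rank_motifs(table)
        assert once["percent_ratio"].tolist() == [8.0, 3.0, 2.0]
        twice = filter_and_rank_motifs(once)
        assert twice.equals(once)


class TestPwm:
    def test_column_sums_validated(self):
        bad = np.full((5, 4), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            PositionWeightMatrix("m", bad)

    def test_minimum_length(self):
        with pytest.raises(ValueError, match="length"):
            PositionWeightMatrix("m", np.full((3, 4), 0.25))

    def test_consensus_degenerate_collapse(self):
        rows = np.array([[1.0, 0, 0, 0],
                         [0.5, 0, 0.4, 0.1],
                         [0.25, 0.25, 0.25, 0.25],
                         [0, 0.7, 0.3, 0]])
        pwm = PositionWeightMatrix("m", rows)
        assert pwm.consensus() == "ARNC"

    def test_read_motifs_parses_homer_style(self, tmp_path):
        path = tmp_path / "known.motifs"
        path.write_text(
            ">ACGT\tmotifA\t0\n"
            "0.97 0.01 0.01 0.01\n0.01 0.97 0.01 0.01\n"
            "0.01 0.01 0.97 0.01\n0.01 0.01 0.01 0.97\n"
            ">NNNN\tmotifB\t0\n"
            + "0.25 0.25 0.25 0.25\n" * 4)
        motifs = read_motifs(path)
        assert [m.motif_id for m in motifs] == ["motifA", "motifB"]
        assert len(motifs[0]) == 4


class TestBackgroundSampling:
    def test_length_matched_and_excludes_targets(self):
        rng = np.random.default_rng(5)
        genome = {"chr1": "".join(rng.choice(list(_BASES), size=5000))}
        out = sample_background_regions(
            genome, [200, 300], exclude=[("chr1", 0, 2000)], rng=rng)
        assert sorted(len(s) for s in out.values()) == [200, 300]

    def test_impossible_placement_rejected(self):
        genome = {"chr1": "ACGT" * 100}
        with pytest.raises(ValueError):
            sample_background_regions(genome, [200],
                                      exclude=[("chr1", 0, 400)],
                                      rng=np.random.default_rng(0))
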