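"""Instance relocation, conservation statistics and known-motif matching."""

import numpy as np
import pytest

from trawlerlite.annotation import (
    MotifInstance,
    conservation_stats,
    family_conservation_summary,
    locate_instances,
    match_known_pwms,
    position_histogram,
    pwm_alignment_score,
    read_jaspar_library,
)
from trawlerlite.clustering import MotifFamily
from trawlerlite.discovery import MotifPattern, MotifScore, count_occurrences, revcomp
from trawlerlite.genome_io import ConservationTrack, GenomicInterval


def _score(word, z=5.0):
    return MotifScore(MotifPattern(word), 10, 0.0, 1.0, z, 10)


def _family(words):
    return MotifFamily("family1", [_score(w, z) for w, z in words])


class TestLocateInstances:
    def test_offset_arithmetic(self):
        family = _family([("AAGGTTCC", 5.0)])
        seqs = ["T" * 20 + "AAGGTTCC" + "T" * 72]
        peaks = [GenomicInterval("chr1", 1000, 1100)]
        [inst] = locate_instances(family, seqs, peaks)
        assert (inst.interval.start, inst.interval.end) == (1020, 1028)
        assert inst.interval.strand == "+"
        assert inst.matched_word == "AAGGTTCC"

    def test_reverse_strand_instance(self):
        family = _family([("AAGGTTCC", 5.0)])
        seqs = ["T" * 20 + revcomp("AAGGTTCC") + "T" * 72]
        peaks = [GenomicInterval("chr1", 1000, 1100)]
        [inst] = locate_instances(family, seqs, peaks)
        assert (inst.interval.start, inst.interval.end) == (1020, 1028)
        assert inst.interval.strand == "-"
        assert inst.matched_word == "AAGGTTCC"  # pattern-oriented

    def test_fasta_only_mode_flags_relative_coordinates(self):
        family = _family([("AAGGTTCC", 5.0)])
        [inst] = locate_instances(family, ["AAGGTTCC"], None)
        assert not inst.genomic
        assert inst.interval.start == 0

    def test_instance_count_equals_discovery_count(self, mini_fixture):
        """Cross-module conservation: no instance lost or duplicated."""
        from trawlerlite.genome_io import extract_sequences, merge_intervals

        genome, genes, peaks, truth, _ = mini_fixture
        merged = merge_intervals(peaks)
        seqs = [s for _, s in extract_sequences(genome, merged, True)]
        family = _family([("AAGGTTCC", 5.0), ("A.GGTTCC", 4.0)])
        instances = locate_instances(family, seqs, merged)
        expected = sum(
            count_occurrences(m.pattern, seqs)[0] for m in family.members
        )
        assert len(instances) == expected

    def test_instances_reextract_to_matching_words(self, mini_fixture):
        """Round trip: genomic coordinates re-extract to the matched word."""
        genome, genes, peaks, truth, _ = mini_fixture
        from trawlerlite.genome_io import extract_sequences, merge_intervals

        merged = merge_intervals(peaks)
        seqs = [s for _, s in extract_sequences(genome, merged, True)]
        family = _family([("AAGGTTCC", 5.0)])
        for inst in locate_instances(family, seqs, merged):
            raw = genome[inst.interval.chrom][
                inst.interval.start : inst.interval.end
            ].upper()
            oriented = raw if inst.interval.strand == "+" else revcomp(raw)
            assert oriented == inst.matched_word
            assert all(
                p == "." or p == c
                for p, c in zip(inst.pattern.word, oriented)
            )


def _instance(chrom="chr1", start=100, k=4, strand="+"):
    return MotifInstance(
        family_id="family1",
        pattern=MotifPattern("A" * k),
        interval=GenomicInterval(chrom, start, start + k, strand=strand),
        matched_word="A" * k,
        peak_index=0,
    )


class TestConservationStats:
    def test_constant_track(self):
        track = ConservationTrack()
        track.add("chr1", 100, np.full(4, 0.5))
        assert conservation_stats(_instance(), track) == (0.5, 0.5)

    def test_mean_over_covered_bases_only(self):
        track = ConservationTrack()
        track.add("chr1", 100, np.array([0.2, 0.4]))
        track.add("chr1", 103, np.array([0.6]))  # base 102 missing
        avg, mx = conservation_stats(_instance(), track)
        assert avg == pytest.approx(0.4)
        assert mx == pytest.approx(0.6)

    def test_uncovered_instance_is_absent_not_zero(self):
        assert conservation_stats(_instance(), ConservationTrack()) == (None, None)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        track = ConservationTrack()
        values = rng.uniform(0, 1, 200)
        values[rng.random(200) < 0.2] = np.nan
        present = np.flatnonzero(~np.isnan(values))
        for run in np.split(present, np.flatnonzero(np.diff(present) > 1) + 1):
            if run.size:
                track.add("chr1", int(run[0]), values[run[0] : run[-1] + 1])
        for _ in range(20):
            start = int(rng.integers(0, 190))
            k = int(rng.integers(4, 10))
            inst = _instance(start=start, k=k)
            got_avg, got_max = conservation_stats(inst, track)
            # brute-force per-base loop
            per_base = [
                values[p] if p < 200 and not np.isnan(values[p]) else None
                for p in range(start, start + k)
            ]
            covered = [v for v in per_base if v is not None]
            if not covered:
                assert (got_avg, got_max) == (None, None)
            else:
                assert got_avg == pytest.approx(np.mean(covered), abs=1e-9)
                assert got_max == pytest.approx(max(covered), abs=1e-9)


class TestFamilySummary:
    def test_max_over_instances(self):
        a, b = _instance(start=10), _instance(start=50)
        a.cons_avg, a.cons_max = 0.05, 0.1
        b.cons_avg, b.cons_max = 0.7, 0.9
        mx, avg = family_conservation_summary([a, b])
        assert mx == 0.9
        assert avg == pytest.approx(0.375)

    def test_no_covered_instances(self):
        assert family_conservation_summary([_instance()]) == (None, None)

    def test_single_instance(self):
        a = _instance()
        a.cons_avg, a.cons_max = 0.3, 0.4
        assert family_conservation_summary([a]) == (0.4, 0.3)


class TestPositionHistogram:
    def test_centered_instance_maps_to_zero(self):
        peak = GenomicInterval("chr1", 0, 100)
        inst = _instance(start=48, k=4)  # midpoint 50 == peak midpoint
        hist = position_histogram([inst], [peak], n_bins=20)
        center_bin = np.flatnonzero(hist.counts)[0]
        assert hist.edges[center_bin] <= 0 <= hist.edges[center_bin + 1]

    def test_counts_sum_to_instance_count(self):
        peak = GenomicInterval("chr1", 0, 100)
        instances = [_instance(start=s) for s in (0, 20, 48, 90)]
        hist = position_histogram(instances, [peak], n_bins=10)
        assert hist.counts.sum() == 4

    def test_all_centered_fills_single_bin(self):
        peak = GenomicInterval("chr1", 0, 100)
        instances = [_instance(start=48) for _ in range(5)]
        hist = position_histogram(instances, [peak], n_bins=20)
        assert hist.counts.max() == 5
        assert (hist.counts > 0).sum() == 1


def _one_hot_pwm(word):
    pwm = np.full((4, len(word)), 1e-9)
    for i, c in enumerate(word):
        pwm["ACGT".index(c), i] = 1.0
    return pwm / pwm.sum(axis=0, keepdims=True)


class TestKnownPwmMatching:
    def test_self_match_scores_one(self):
        pwm = _one_hot_pwm("AAGGTTCC")
        hits = match_known_pwms(pwm, [("SELF", pwm)])
        assert hits and hits[0][0] == "SELF"
        assert hits[0][1] == pytest.approx(1.0)
        assert hits[0][2] == 0

    def test_uniform_pwm_never_hits(self):
        pwm = _one_hot_pwm("AAGGTTCC")
        uniform = np.full((4, 8), 0.25)
        assert match_known_pwms(pwm, [("FLAT", uniform)]) == []

    def test_shifted_copy_found_at_offset(self):
        pwm = _one_hot_pwm("AAGGTTCC")
        shifted = _one_hot_pwm("GGTTCC")  # suffix starting at column 2
        score, offset, orient = pwm_alignment_score(pwm, shifted)
        assert score == pytest.approx(1.0)
        assert offset == 2
        assert orient == "+"

    def test_reverse_complement_orientation_detected(self):
        pwm = _one_hot_pwm("AAGGTTCC")
        rc = _one_hot_pwm(revcomp("AAGGTTCC"))
        score, _, orient = pwm_alignment_score(pwm, rc)
        assert score == pytest.approx(1.0)
        assert orient == "-"

    def test_jaspar_library_roundtrip(self, tmp_path):
        text = (
            ">M1\tTF1\n"
            "A [ 10 0 0 ]\nC [ 0 10 0 ]\nG [ 0 0 10 ]\nT [ 0 0 0 ]\n"
        )
        path = tmp_path / "lib.jaspar"
        path.write_text(text)
        [(name, pwm)] = read_jaspar_library(path)
        np.testing.assert_allclose(pwm[:, 0], [1, 0, 0, 0])
        np.testing.assert_allclose(pwm.sum(axis=0), 1.0)
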