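"""Motif similarity, family clustering and PWM construction."""

import itertools

import numpy as np
import pytest

from trawlerlite.clustering import (
    build_family_pwm,
    kmeans_cluster,
    motif_similarity,
    pwm_to_jaspar,
    scc_cluster,
)
from trawlerlite.discovery import MotifPattern, MotifScore


def _score(word, z):
    return MotifScore(MotifPattern(word), 10, 0.0, 1.0, z, 10)


class TestMotifSimilarity:
    def test_identical_words(self):
        assert motif_similarity(MotifPattern("AAGGTTCC"), MotifPattern("AAGGTTCC")) == 100.0

    def test_disjoint_words(self):
        assert motif_similarity(MotifPattern("AAAAAAAA"), MotifPattern("CCCCCCCC")) == 0.0

    def test_one_base_shift_is_full_overlap_identity(self):
        # the 7-column overlap matches 7/7 at offset 1
        a, b = MotifPattern("AAGGTTCC"), MotifPattern("AGGTTCCA")
        assert motif_similarity(a, b) == 100.0

    def test_exhaustive_offset_oracle(self):
        """Best identity equals a brute-force scan over all placements."""
        from trawlerlite.discovery import revcomp

        def oracle(a, b):
            best = 0.0
            for bw in (b, revcomp(b)):
                for off in range(-(len(bw) - 1), len(a)):
                    lo, hi = max(0, off), min(len(a), off + len(bw))
                    if (hi - lo) * 2 < min(len(a), len(b)):
                        continue
                    m = sum(
                        a[i] == bw[i - off] or "." in (a[i], bw[i - off])
                        for i in range(lo, hi)
                    )
                    best = max(best, 100.0 * m / (hi - lo))
            return best

        rng = np.random.default_rng(4)
        for _ in range(30):
            a = "".join(rng.choice(list("ACGT"), rng.integers(6, 10)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(6, 10)))
            got = motif_similarity(MotifPattern(a), MotifPattern(b))
            assert got == pytest.approx(oracle(a, b))

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = MotifPattern("".join(rng.choice(list("ACGT"), 8)))
            b = MotifPattern("".join(rng.choice(list("ACGT"), 10)))
            assert motif_similarity(a, b) == motif_similarity(b, a)

    def test_wildcard_matches_anything(self):
        assert motif_similarity(MotifPattern("A..T"), MotifPattern("AGCT")) == 100.0


def _union_find_families(scores, threshold):
    """Independent oracle: connected components via union-find."""
    parent = list(range(len(scores)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(scores)), 2):
        if motif_similarity(scores[i].pattern, scores[j].pattern) >= threshold:
            parent[find(i)] = find(j)
    groups = {}
    for i in range(len(scores)):
        groups.setdefault(find(i), set()).add(scores[i].pattern.word)
    return sorted(map(frozenset, groups.values()), key=sorted)


class TestSccCluster:
    def test_shifted_words_form_one_family(self):
        scores = [
            _score("AAGGTTCC", 5.0),
            _score("AGGTTCCA", 4.0),
            _score("GGTTCCAA", 3.0),
        ]
        fams = scc_cluster(scores, overlap_threshold=70)
        assert len(fams) == 1
        assert len(fams[0].members) == 3

    def test_threshold_100_separates_distinct_words(self):
        # chosen so no pair reaches 100% identity at any admissible overlap,
        # in either orientation
        scores = [_score("AAAAAAAA", 3.0), _score("ACACACAC", 2.0),
                  _score("CCGGCCGG", 1.0)]
        fams = scc_cluster(scores, overlap_threshold=100)
        assert len(fams) == 3

    def test_empty_input(self):
        assert scc_cluster([], 70) == []

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(12)
        scores = [
            _score("".join(rng.choice(list("ACGT"), 8)), float(z))
            for z in range(12)
        ]
        fams = scc_cluster(scores, 70)
        got = sorted(
            (frozenset(m.pattern.word for m in f.members) for f in fams),
            key=sorted,
        )
        assert got == _union_find_families(scores, 70)

    def test_invariant_to_input_order(self):
        scores = [_score("AAGGTTCC", 5.0), _score("AGGTTCCA", 4.0),
                  _score("TTTTACGT", 3.0), _score("CCCCGGGG", 2.0)]
        a = scc_cluster(scores, 70)
        b = scc_cluster(scores[::-1], 70)
        assert [{m.pattern.word for m in f.members} for f in a] == [
            {m.pattern.word for m in f.members} for f in b
        ]

    def test_families_partition_the_motifs(self):
        rng = np.random.default_rng(3)
        scores = [
            _score("".join(rng.choice(list("ACGT"), 8)), float(z))
            for z in range(15)
        ]
        fams = scc_cluster(scores, 60)
        seen = [m.pattern.word for f in fams for m in f.members]
        assert sorted(seen) == sorted(s.pattern.word for s in scores)

    def test_raising_threshold_only_refines(self):
        rng = np.random.default_rng(7)
        scores = [
            _score("".join(rng.choice(list("ACGT"), 8)), float(z))
            for z in range(10)
        ]
        coarse = scc_cluster(scores, 50)
        fine = scc_cluster(scores, 80)
        coarse_sets = [frozenset(m.pattern.word for m in f.members) for f in coarse]
        for f in fine:
            words = frozenset(m.pattern.word for m in f.members)
            assert any(words <= c for c in coarse_sets)

    def test_families_ordered_by_z(self):
        scores = [_score("AAAAAAAA", 1.0), _score("GGGGGGGG", 9.0)]
        fams = scc_cluster(scores, 100)
        assert [f.family_z for f in fams] == [9.0, 1.0]
        assert fams[0].family_id == "family1"


class TestKmeansCluster:
    def _two_groups(self):
        return [
            _score("AAGGTTCC", 5.0), _score("AGGTTCCA", 4.5),
            _score("AAGGTTCA", 4.0),
            _score("CGCGCGAT", 2.0), _score("GCGCGATA", 1.5),
            _score("CGCGCGAA", 1.0),
        ]

    def test_n_equals_motifs_gives_singletons(self):
        scores = self._two_groups()
        fams = kmeans_cluster(scores, len(scores), seed=0)
        assert all(len(f.members) == 1 for f in fams)

    def test_single_cluster_holds_all(self):
        scores = self._two_groups()
        [fam] = kmeans_cluster(scores, 1, seed=0)
        assert len(fam.members) == len(scores)

    def test_matches_exhaustive_two_partition_oracle(self):
        """k=2 equals the exhaustive minimum within-cluster sum of squares."""
        from trawlerlite.clustering import embed_motifs

        scores = self._two_groups()
        nodes, X = embed_motifs(scores)

        def wcss(labels):
            total = 0.0
            for lab in set(labels):
                pts = X[[i for i, l in enumerate(labels) if l == lab]]
                total += ((pts - pts.mean(axis=0)) ** 2).sum()
            return total

        best = min(
            (tuple((i >> j) & 1 for j in range(len(nodes)))
             for i in range(1, 2 ** len(nodes) - 1)),
            key=wcss,
        )
        oracle_groups = sorted(
            sorted(nodes[i].pattern.word for i in range(len(nodes))
                   if best[i] == lab)
            for lab in (0, 1)
        )
        fams = kmeans_cluster(scores, 2, seed=0)
        got = sorted(sorted(m.pattern.word for m in f.members) for f in fams)
        assert got == oracle_groups

    def test_seed_reproducibility(self):
        scores = self._two_groups()
        a = kmeans_cluster(scores, 3, seed=5)
        b = kmeans_cluster(scores, 3, seed=5)
        assert [
            [m.pattern.word for m in f.members] for f in a
        ] == [[m.pattern.word for m in f.members] for f in b]

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            kmeans_cluster(self._two_groups(), 7, seed=0)


class TestFamilyPwm:
    def test_degenerate_identical_instances(self):
        members = [_score("AAGG", 5.0)]
        pwm, consensus = build_family_pwm(members, {"AAGG": ["AAGG"] * 10})
        assert consensus == "AAGG"
        expected = np.array(
            [[1, 1, 0, 0], [0, 0, 0, 0], [0, 0, 1, 1], [0, 0, 0, 0]], float
        )
        np.testing.assert_allclose(pwm, (expected * 10 + 0.01) / (10 + 0.04))

    def test_mixed_column_gets_iupac_code(self):
        members = [_score("AAGG", 5.0)]
        instances = {"AAGG": ["AAGG"] * 5 + ["CAGG"] * 5}
        pwm, consensus = build_family_pwm(members, instances)
        assert consensus[0] == "M"  # A/C ~ 0.5 each
        assert pwm[0, 0] == pytest.approx(0.5, abs=0.01)
        assert pwm[1, 0] == pytest.approx(0.5, abs=0.01)

    def test_columns_sum_to_one(self):
        members = [_score("AAGGTTCC", 5.0), _score("AGGTTCCA", 4.0)]
        instances = {
            "AAGGTTCC": ["AAGGTTCC"] * 4,
            "AGGTTCCA": ["AGGTTCCA"] * 3,
        }
        pwm, _ = build_family_pwm(members, instances)
        np.testing.assert_allclose(pwm.sum(axis=0), 1.0, atol=1e-9)

    def test_member_without_instances_excluded(self):
        members = [_score("AAGG", 5.0), _score("CCCC", 1.0)]
        pwm, consensus = build_family_pwm(members, {"AAGG": ["AAGG"] * 3})
        assert consensus == "AAGG"

    def test_jaspar_export_shape(self):
        members = [_score("AAGG", 5.0)]
        pwm, _ = build_family_pwm(members, {"AAGG": ["AAGG"] * 3})
        text = pwm_to_jaspar("family1", pwm)
        assert text.startswith(">family1\n")
        assert text.count("[") == 4
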