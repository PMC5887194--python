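"""Candidate motif enumeration and over-representation scoring.

Motifs are fixed-length words over {A,C,G,T,.} where '.' is an interior
wildcard matching any unambiguous base (N never matches).  Enumeration is
sample-anchored: only exact words observed at least ``min_occurrence`` times
in the input (both strands, canonical form) seed the candidate set, and each
exact candidate contributes its interior-wildcard generalizations.

Over-representation is a z-score against the matched background: the
background sequences (8x the input by default) are partitioned round-robin
into ``multiplier`` pseudo-replicates, each replicate's motif count is one
draw, and z = (sample_count - bg_mean) / bg_sd with the sample SD (ddof=1)
floored at max(1, 0.1 * bg_mean) so background-absent motifs get a finite
score.

Two counting routes exist on purpose: ``count_occurrences`` is a direct
regex scan that also reports positions (used to place instances), while
``KmerCountIndex`` serves enumeration and scoring by looking wildcard
patterns up as sums over their matching exact words.  Both agree exactly;
the test suite asserts it.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MotifPattern",
    "MotifScore",
    "revcomp",
    "canonical",
    "count_occurrences",
    "enumerate_candidates",
    "score_motifs",
    "take_top",
    "percent_occurrence",
    "KmerCountIndex",
]

DEFAULT_K_MIN = 8
DEFAULT_K_MAX = 20
DEFAULT_WILDCARDS = 2
DEFAULT_MIN_OCCURRENCE = 10
DEFAULT_N_MOTIFS = 200

_COMPLEMENT = str.maketrans("ACGT.", "TGCA.")
_PATTERN_CHARS = frozenset("ACGT.")


def revcomp(word: str) -> str:
    """Reverse complement over {A,C,G,T,.}; wildcards are self-complementary."""
    return word.translate(_COMPLEMENT)[::-1]


def canonical(word: str) -> str:
    """Lexicographically smaller of a word and its reverse complement."""
    rc = revcomp(word)
    return word if word <= rc else rc


@dataclass(frozen=True)
class MotifPattern:
    """A fixed-length word over {A,C,G,T,.}; '.' wildcards are interior only."""

    word: str

    def __post_init__(self) -> None:
        if len(self.word) < 2:
            raise ValueError(f"motif word too short: {self.word!r}")
        bad = set(self.word) - _PATTERN_CHARS
        if bad:
            raise ValueError(f"invalid motif characters {sorted(bad)!r} in {self.word!r}")
        if self.word[0] == "." or self.word[-1] == ".":
            raise ValueError(
                f"wildcards must be interior (a terminal wildcard is a shorter "
                f"motif): {self.word!r}"
            )

    @property
    def length(self) -> int:
        return len(self.word)

    @property
    def n_wildcards(self) -> int:
        return self.word.count(".")

    def matching_words(self) -> Iterable[str]:
        """All exact ACGT words the pattern matches (4**n_wildcards of them)."""
        slots = [("ACGT" if c == "." else c) for c in self.word]
        for combo in itertools.product(*slots):
            yield "".join(combo)

    def __str__(self) -> str:
        return self.word


@dataclass(frozen=True)
class MotifScore:
    """A motif with its sample/background counts and over-representation z."""

    pattern: MotifPattern
    sample_count: int
    bg_mean: float
    bg_sd: float
    z: float
    n_seq_with_hit: int


def _regex(word: str) -> re.Pattern:
    # lookahead so overlapping matches all count; '.' matches ACGT only
    return re.compile("(?=(" + word.replace(".", "[ACGT]") + "))")


def _forward_positions(word: str, seq: str) -> list[int]:
    return [m.start() for m in _regex(word).finditer(seq)]


def count_occurrences(
    pattern: MotifPattern, sequences: Sequence[str]
) -> tuple[int, list[bool], list[tuple[int, int, str]]]:
    """Scan sequences for the pattern on both strands.

    Returns (total count, per-sequence hit flags, positions).  Positions are
    (sequence index, offset, strand); a position matching on both strands
    (palindromic pattern) counts once, as '+'.  Overlapping matches all
    count; N never matches.
    """
    word = pattern.word
    rc = revcomp(word)
    total = 0
    flags: list[bool] = []
    positions: list[tuple[int, int, str]] = []
    for i, seq in enumerate(sequences):
        fwd = set(_forward_positions(word, seq))
        rev = set() if rc == word else set(_forward_positions(rc, seq))
        hits = sorted(fwd | rev)
        for p in hits:
            positions.append((i, p, "+" if p in fwd else "-"))
        total += len(hits)
        flags.append(bool(hits))
    return total, flags, positions


class KmerCountIndex:
    """Exact k-mer counts per length, per sequence and per background replicate.

    A wildcard pattern's both-strand count is the sum of forward-window
    counts of every exact word matching the pattern or its reverse
    complement (counted once when a word matches both, which is exactly the
    palindromic dedup rule of ``count_occurrences``).
    """

    def __init__(self, sequences: Sequence[str], lengths: Iterable[int]):
        self.sequences = list(sequences)
        self.lengths = sorted(set(lengths))
        self._totals: dict[int, Counter] = {}
        # built lazily: word -> set of sequence indices / per-replicate counters
        self._postings: dict[int, dict[str, set[int]]] = {}
        self._replicates: dict[tuple[int, int], list[Counter]] = {}
        for k in self.lengths:
            total: Counter = Counter()
            for seq in self.sequences:
                for i in range(len(seq) - k + 1):
                    w = seq[i : i + k]
                    if "N" not in w:
                        total[w] += 1
            self._totals[k] = total

    def _match_set(self, pattern: MotifPattern) -> set[str]:
        words = set(pattern.matching_words())
        words.update(revcomp(w) for w in words.copy())
        return words

    def total_count(self, pattern: MotifPattern) -> int:
        total = self._totals[pattern.length]
        return sum(total[w] for w in self._match_set(pattern))

    def _posting_table(self, k: int) -> dict[str, set[int]]:
        table = self._postings.get(k)
        if table is None:
            table = {}
            for i, seq in enumerate(self.sequences):
                for j in range(len(seq) - k + 1):
                    w = seq[j : j + k]
                    if "N" not in w:
                        table.setdefault(w, set()).add(i)
            self._postings[k] = table
        return table

    def hit_flags(self, pattern: MotifPattern) -> list[bool]:
        table = self._posting_table(pattern.length)
        hit: set[int] = set()
        for w in self._match_set(pattern):
            hit |= table.get(w, set())
        return [i in hit for i in range(len(self.sequences))]

    def per_sequence_counts(self, pattern: MotifPattern) -> list[int]:
        words = self._match_set(pattern)
        out = []
        k = pattern.length
        for seq in self.sequences:
            out.append(
                sum(1 for i in range(len(seq) - k + 1) if seq[i : i + k] in words)
            )
        return out

    def _replicate_table(self, k: int, n_replicates: int) -> list[Counter]:
        key = (k, n_replicates)
        reps = self._replicates.get(key)
        if reps is None:
            reps = [Counter() for _ in range(n_replicates)]
            for i, seq in enumerate(self.sequences):
                c = reps[i % n_replicates]
                for j in range(len(seq) - k + 1):
                    w = seq[j : j + k]
                    if "N" not in w:
                        c[w] += 1
            self._replicates[key] = reps
        return reps

    def replicate_counts(self, pattern: MotifPattern, n_replicates: int) -> np.ndarray:
        """Round-robin partition of sequences into replicates; count per replicate."""
        reps = self._replicate_table(pattern.length, n_replicates)
        words = self._match_set(pattern)
        return np.array(
            [sum(c[w] for w in words) for c in reps], dtype=np.int64
        )

    def exact_words_with_min_count(self, k: int, min_occurrence: int) -> list[str]:
        """Canonical exact k-mers whose both-strand count reaches the threshold."""
        total = self._totals[k]
        canon: Counter = Counter()
        for w, c in total.items():
            canon[canonical(w)] += c
        return sorted(w for w, c in canon.items() if c >= min_occurrence)


def _interior_generalizations(word: str, max_wildcards: int) -> Iterable[str]:
    interior = range(1, len(word) - 1)
    for n in range(1, max_wildcards + 1):
        for combo in itertools.combinations(interior, n):
            chars = list(word)
            for i in combo:
                chars[i] = "."
            yield "".join(chars)


def enumerate_candidates(
    sample_sequences: Sequence[str],
    k_min: int = DEFAULT_K_MIN,
    k_max: int = DEFAULT_K_MAX,
    wildcards: int = DEFAULT_WILDCARDS,
    min_occurrence: int = DEFAULT_MIN_OCCURRENCE,
    index: KmerCountIndex | None = None,
) -> list[MotifPattern]:
    """Sample-anchored candidate enumeration.

    For each length k in [k_min, k_max], every exact k-mer with at least
    ``min_occurrence`` both-strand occurrences in the sample is a candidate
    (canonical form), along with every interior-wildcard generalization
    carrying at most ``wildcards`` '.' positions.  Words containing N are
    excluded.  Deterministic output order: (length, word).
    """
    if k_min > k_max:
        raise ValueError(f"k_min ({k_min}) must not exceed k_max ({k_max})")
    if k_min < 4:
        raise ValueError("k_min must be at least 4")
    if wildcards < 0:
        raise ValueError("wildcards must be non-negative")
    if index is None:
        index = KmerCountIndex(sample_sequences, range(k_min, k_max + 1))
    seen: set[str] = set()
    for k in range(k_min, k_max + 1):
        for word in index.exact_words_with_min_count(k, min_occurrence):
            seen.add(word)
            for g in _interior_generalizations(word, wildcards):
                seen.add(canonical(g))
    ordered = sorted(seen, key=lambda w: (len(w), w))
    return [MotifPattern(w) for w in ordered]


def sd_floor(bg_mean: float) -> float:
    """Lower bound on the background SD: max(1, 0.1 * bg_mean)."""
    return max(1.0, 0.1 * bg_mean)


def score_motifs(
    candidates: Sequence[MotifPattern],
    sample_sequences: Sequence[str],
    background_sequences: Sequence[str],
    multiplier: int = 8,
    sample_index: KmerCountIndex | None = None,
    background_index: KmerCountIndex | None = None,
) -> list[MotifScore]:
    """Score candidates by z against background pseudo-replicates.

    The background is partitioned round-robin into ``multiplier`` replicates;
    each replicate count is one draw for the background mean and SD (ddof=1,
    floored).  Scores are sorted by z descending, ties by word.
    """
    if multiplier < 2:
        raise ValueError("multiplier must be >= 2: background SD is undefined "
                         "from a single replicate")
    lengths = {p.length for p in candidates}
    if sample_index is None:
        sample_index = KmerCountIndex(sample_sequences, lengths)
    if background_index is None:
        background_index = KmerCountIndex(background_sequences, lengths)
    scores: list[MotifScore] = []
    for pattern in candidates:
        sample_count = sample_index.total_count(pattern)
        n_hit = sum(sample_index.hit_flags(pattern))
        reps = background_index.replicate_counts(pattern, multiplier)
        bg_mean = float(np.mean(reps))
        bg_sd = max(float(np.std(reps, ddof=1)), sd_floor(bg_mean))
        z = (sample_count - bg_mean) / bg_sd
        scores.append(
            MotifScore(pattern, sample_count, bg_mean, bg_sd, z, n_hit)
        )
    scores.sort(key=lambda s: (-s.z, s.pattern.word))
    return scores


def take_top(scores: Sequence[MotifScore], n_motifs: int = DEFAULT_N_MOTIFS) -> list[MotifScore]:
    """Top-N scores by the (z descending, word) sort order."""
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    return list(scores[:n_motifs])


def percent_occurrence(score: MotifScore, n_input_sequences: int) -> float:
    """Share of input sequences containing the motif, as a percentage."""
    if n_input_sequences < 1:
        raise ValueError("n_input_sequences must be >= 1")
    return 100.0 * score.n_seq_with_hit / n_input_sequences
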