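"""Grouping top-ranked motifs into families and summarizing each as a PWM.

Discovered words are highly redundant (shifts, reverse complements, wildcard
variants of the same binding site), so the top-ranked motifs are clustered
into families before reporting.  The default groups motifs whose best
ungapped alignment identity reaches a percentage-overlap threshold (70 by
default) via strongly connected components of the similarity graph; since
the similarity is symmetric, these coincide with connected components.
Alternatively, a fixed family count can be requested, in which case k-means
runs on one-hot embeddings of the aligned words.

Each family's PWM is built from the genomic instance sequences of its member
patterns, aligned at each member's best offset to the family's top-scoring
member, with a small pseudocount; the consensus is the per-column IUPAC code
of bases at probability >= 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.cluster import KMeans

from .discovery import MotifPattern, MotifScore, revcomp

__all__ = [
    "MotifFamily",
    "motif_similarity",
    "best_alignment",
    "scc_cluster",
    "embed_motifs",
    "kmeans_cluster",
    "build_family_pwm",
    "pwm_to_jaspar",
]

DEFAULT_OVERLAP_PCT = 70.0
DEFAULT_PSEUDOCOUNT = 0.01
_BASES = "ACGT"

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H", frozenset("AGT"): "D",
    frozenset("CGT"): "B", frozenset("ACGT"): "N",
}


@dataclass
class MotifFamily:
    """A cluster of similar motifs reported as one PWM."""

    family_id: str
    members: list[MotifScore]
    pwm: np.ndarray | None = None  # shape (4, width), columns sum to 1
    consensus: str | None = None
    conservation_max: float | None = None
    conservation_avg: float | None = None

    @property
    def family_z(self) -> float:
        return max(m.z for m in self.members)

    @property
    def top_member(self) -> MotifScore:
        return max(self.members, key=lambda m: (m.z, m.pattern.word))


def _column_match(a: str, b: str) -> bool:
    return a == "." or b == "." or a == b


def _identity_at_offset(a: str, b: str, offset: int) -> tuple[int, int]:
    """(matches, overlap length) aligning b shifted by `offset` against a."""
    start = max(0, offset)
    end = min(len(a), offset + len(b))
    matches = sum(
        1 for i in range(start, end) if _column_match(a[i], b[i - offset])
    )
    return matches, end - start


def best_alignment(a: str, b: str) -> tuple[float, int, str]:
    """Best ungapped alignment of b (either orientation) against a.

    Returns (identity %, offset of b's start relative to a's start,
    orientation '+'/'-'), requiring overlap >= min(|a|,|b|)/2; identity 0
    and offset 0 when no offset is admissible.  Ties prefer higher overlap,
    then forward orientation, then the smaller offset.
    """
    min_overlap = min(len(a), len(b)) / 2
    best = (0.0, 0, "+")
    best_key: tuple = (-1.0,)
    for orient, bw in (("+", b), ("-", revcomp(b))):
        for offset in range(-(len(b) - 1), len(a)):
            matches, overlap = _identity_at_offset(a, bw, offset)
            if overlap < min_overlap:
                continue
            pct = 100.0 * matches / overlap
            key = (pct, overlap, 1 if orient == "+" else 0, -abs(offset))
            if key > best_key:
                best_key = key
                best = (pct, offset, orient)
    return best


def motif_similarity(a: MotifPattern, b: MotifPattern) -> float:
    """Best ungapped alignment identity (%) over all offsets and orientations.

    A wildcard column matches anything; overlap must reach half the shorter
    word.  Symmetric by construction.
    """
    # the offset scan is symmetric: identity(a, b@off) == identity(b, a@-off)
    # and the reverse orientation mirrors likewise, so one direction suffices
    return best_alignment(a.word, b.word)[0]


def _families_from_groups(
    groups: Sequence[Sequence[MotifScore]],
) -> list[MotifFamily]:
    ordered = sorted(
        (sorted(g, key=lambda m: (-m.z, m.pattern.word)) for g in groups),
        key=lambda g: (-g[0].z, g[0].pattern.word),
    )
    return [
        MotifFamily(family_id=f"family{i + 1}", members=list(g))
        for i, g in enumerate(ordered)
    ]


def scc_cluster(
    scores: Sequence[MotifScore],
    overlap_threshold: float = DEFAULT_OVERLAP_PCT,
) -> list[MotifFamily]:
    """Families as strongly connected components of the similarity graph.

    An edge a->b exists iff similarity >= threshold; similarity is symmetric
    so edges come in pairs and SCCs equal connected components.  Families are
    ordered by family z descending.  Invariant to input order.
    """
    if not (0 <= overlap_threshold <= 100):
        raise ValueError("overlap_threshold must be within [0, 100]")
    if not scores:
        return []
    nodes = sorted(scores, key=lambda m: (-m.z, m.pattern.word))
    graph = nx.DiGraph()
    graph.add_nodes_from(range(len(nodes)))
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if motif_similarity(nodes[i].pattern, nodes[j].pattern) >= overlap_threshold:
                graph.add_edge(i, j)
                graph.add_edge(j, i)
    groups = [
        [nodes[i] for i in comp] for comp in nx.strongly_connected_components(graph)
    ]
    return _families_from_groups(groups)


def _one_hot(word: str) -> np.ndarray:
    m = np.zeros((4, len(word)))
    for i, c in enumerate(word):
        if c == ".":
            m[:, i] = 0.25
        else:
            m[_BASES.index(c), i] = 1.0
    return m


def embed_motifs(
    scores: Sequence[MotifScore],
) -> tuple[list[MotifScore], np.ndarray]:
    """One-hot embedding of motifs aligned at best offset to the top-z motif.

    Wildcards become uniform 0.25 columns; matrices are zero-padded to a
    common width and flattened.  Returns (motifs in z order, feature matrix).
    """
    nodes = sorted(scores, key=lambda m: (-m.z, m.pattern.word))
    ref = nodes[0].pattern.word
    placed: list[tuple[int, str]] = []  # (offset vs ref, oriented word)
    for m in nodes:
        _, offset, orient = best_alignment(ref, m.pattern.word)
        word = m.pattern.word if orient == "+" else revcomp(m.pattern.word)
        placed.append((offset, word))
    lo = min(off for off, _ in placed)
    width = max(off + len(w) for off, w in placed) - lo
    X = np.zeros((len(nodes), 4 * width))
    for r, (off, w) in enumerate(placed):
        m = np.zeros((4, width))
        m[:, off - lo : off - lo + len(w)] = _one_hot(w)
        X[r] = m.ravel()
    return nodes, X


def kmeans_cluster(
    scores: Sequence[MotifScore],
    n_clusters: int,
    seed: int = 0,
) -> list[MotifFamily]:
    """Partition motifs into exactly n_clusters families by k-means.

    Each motif is embedded as its one-hot matrix (wildcard = uniform 0.25
    column) placed at its best-offset alignment to the top-z motif and
    zero-padded to a common width; k-means runs with 10 restarts and a fixed
    seed, so the outcome is reproducible.
    """
    if not (1 <= n_clusters <= len(scores)):
        raise ValueError(
            f"n_clusters ({n_clusters}) must be within [1, number of motifs "
            f"({len(scores)})]"
        )
    nodes, X = embed_motifs(scores)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    groups: dict[int, list[MotifScore]] = {}
    for m, lab in zip(nodes, labels):
        groups.setdefault(int(lab), []).append(m)
    return _families_from_groups(list(groups.values()))


def build_family_pwm(
    family_members: Sequence[MotifScore],
    instance_sequences: Mapping[str, Sequence[str]],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[np.ndarray, str]:
    """PWM + IUPAC consensus from the instances of a family's member patterns.

    ``instance_sequences`` maps each member word to its pattern-oriented
    genomic instance strings.  Every instance is placed at its member's
    best-offset alignment to the top-z member (reverse-complemented when the
    member aligns in reverse orientation); per-column base counts plus a
    pseudocount are normalized to probabilities.  Members with zero
    instances are excluded.
    """
    members = sorted(family_members, key=lambda m: (-m.z, m.pattern.word))
    ref = members[0].pattern.word
    placements: list[tuple[int, list[str]]] = []
    for m in members:
        strings = list(instance_sequences.get(m.pattern.word, []))
        if not strings:
            continue
        _, offset, orient = best_alignment(ref, m.pattern.word)
        if orient == "-":
            strings = [revcomp(s) for s in strings]
        placements.append((offset, strings))
    if not placements:
        raise ValueError("family has no member with instances")
    lo = min(off for off, _ in placements)
    width = max(
        off + len(s) for off, strings in placements for s in strings
    ) - lo
    counts = np.zeros((4, width))
    for off, strings in placements:
        col0 = off - lo
        for s in strings:
            for i, c in enumerate(s):
                if c in _BASES:
                    counts[_BASES.index(c), col0 + i] += 1
    pwm = counts + pseudocount
    pwm /= pwm.sum(axis=0, keepdims=True)
    consensus = "".join(
        _IUPAC[frozenset(b for b, p in zip(_BASES, col) if p >= 0.25)]
        for col in pwm.T
    )
    return pwm, consensus


def pwm_to_jaspar(name: str, pwm: np.ndarray) -> str:
    """Render a PWM in JASPAR minimal text format."""
    lines = [f">{name}"]
    for row, base in zip(pwm, _BASES):
        vals = " ".join(f"{v:.4f}" for v in row)
        lines.append(f"{base} [ {vals} ]")
    return "\n".join(lines) + "\n"
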