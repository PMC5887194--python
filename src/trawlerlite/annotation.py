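"""Genomic relocation of motif instances, conservation scoring, and known-motif matching.

Evolutionarily constrained binding sites tend to be conserved across
species, so per-instance conservation (e.g. phastCons probabilities) is a
useful proxy for picking motifs worth validating.  This module maps every
match of a family's member patterns back to genomic coordinates, attaches
the mean and maximum conservation over the covered bases of each instance
(bases without data are excluded from the mean, and both statistics are
absent when no base is covered), summarizes conservation per family, builds
peak-center-anchored positional histograms, and optionally compares family
PWMs against a local JASPAR-format motif library by mean per-column Pearson
correlation over the best ungapped alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import motifs as bio_motifs

from .clustering import MotifFamily
from .discovery import MotifPattern, count_occurrences, revcomp
from .genome_io import ConservationTrack, GenomicInterval

__all__ = [
    "MotifInstance",
    "PositionHistogram",
    "locate_instances",
    "conservation_stats",
    "family_conservation_summary",
    "position_histogram",
    "match_known_pwms",
    "read_jaspar_library",
]

DEFAULT_N_BINS = 20
DEFAULT_MIN_PWM_OVERLAP = 4
DEFAULT_PWM_SCORE_THRESHOLD = 0.8


@dataclass
class MotifInstance:
    """One genomic occurrence of a family member pattern.

    ``matched_word`` is pattern-oriented (reverse-complemented relative to
    the forward genome strand when strand is '-').  Conservation fields are
    None, not 0, when no covered base exists.  When input was plain FASTA
    (no intervals), ``genomic`` is False and coordinates are
    sequence-relative.
    """

    family_id: str
    pattern: MotifPattern
    interval: GenomicInterval
    matched_word: str
    peak_index: int
    genomic: bool = True
    cons_avg: float | None = None
    cons_max: float | None = None


@dataclass
class PositionHistogram:
    """Counts of instance positions relative to peak centers, in [-1, 1]."""

    edges: np.ndarray
    counts: np.ndarray


def locate_instances(
    family: MotifFamily,
    peak_sequences: Sequence[str],
    peak_intervals: Sequence[GenomicInterval] | None,
) -> list[MotifInstance]:
    """Every match of every member pattern, in genomic coordinates.

    With ``peak_intervals`` None (FASTA-only input), coordinates stay
    sequence-relative under a synthetic per-sequence chromosome name and the
    ``genomic`` flag is cleared so conservation is skipped downstream.
    """
    instances: list[MotifInstance] = []
    for member in family.members:
        pattern = member.pattern
        k = pattern.length
        _, _, positions = count_occurrences(pattern, peak_sequences)
        for seq_idx, offset, strand in positions:
            word = peak_sequences[seq_idx][offset : offset + k]
            if strand == "-":
                word = revcomp(word)
            if peak_intervals is not None:
                peak = peak_intervals[seq_idx]
                interval = GenomicInterval(
                    peak.chrom, peak.start + offset, peak.start + offset + k,
                    strand=strand,
                )
                genomic = True
            else:
                interval = GenomicInterval(
                    f"seq{seq_idx}", offset, offset + k, strand=strand
                )
                genomic = False
            instances.append(
                MotifInstance(
                    family_id=family.family_id,
                    pattern=pattern,
                    interval=interval,
                    matched_word=word,
                    peak_index=seq_idx,
                    genomic=genomic,
                )
            )
    instances.sort(key=lambda m: (m.interval.chrom, m.interval.start, m.interval.end,
                                  m.interval.strand, m.pattern.word))
    return instances


def conservation_stats(
    instance: MotifInstance, track: ConservationTrack
) -> tuple[float | None, float | None]:
    """(mean, max) conservation over the covered bases of the instance.

    Bases without data are excluded from the mean; both values are None when
    nothing is covered.
    """
    scores = track.scores(instance.interval.chrom, instance.interval.start,
                          instance.interval.end)
    covered = scores[~np.isnan(scores)]
    if covered.size == 0:
        return None, None
    return float(covered.mean()), float(covered.max())


def annotate_conservation(
    instances: Sequence[MotifInstance], track: ConservationTrack
) -> None:
    """Fill cons_avg/cons_max in place for genomic instances."""
    for inst in instances:
        if inst.genomic:
            inst.cons_avg, inst.cons_max = conservation_stats(inst, track)


def family_conservation_summary(
    instances: Sequence[MotifInstance],
) -> tuple[float | None, float | None]:
    """(max of instance cons_max, mean of instance cons_avg) over covered instances."""
    maxima = [i.cons_max for i in instances if i.cons_max is not None]
    means = [i.cons_avg for i in instances if i.cons_avg is not None]
    if not maxima:
        return None, None
    return float(max(maxima)), float(np.mean(means))


def position_histogram(
    instances: Sequence[MotifInstance],
    peak_intervals: Sequence[GenomicInterval],
    n_bins: int = DEFAULT_N_BINS,
) -> PositionHistogram:
    """Histogram of instance midpoints relative to peak centers.

    Position = (instance midpoint - peak midpoint) / peak half-length, so
    peaks of different sizes are comparable; clipped to [-1, 1].
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rel = []
    for inst in instances:
        peak = peak_intervals[inst.peak_index]
        half = peak.length / 2
        rel.append((inst.interval.midpoint - peak.midpoint) / half)
    counts, edges = np.histogram(np.clip(rel, -1, 1), bins=n_bins, range=(-1, 1))
    return PositionHistogram(edges=edges, counts=counts)


def read_jaspar_library(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Parse a JASPAR-format PWM file into (name, 4 x width probability matrix)."""
    out: list[tuple[str, np.ndarray]] = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            sums = counts.sum(axis=0)
            if np.any(sums <= 0):
                raise ValueError(
                    f"{path}: motif {m.name or m.matrix_id}: column with no counts"
                )
            out.append((str(m.name or m.matrix_id), counts / sums))
    return out


def _pwm_revcomp(pwm: np.ndarray) -> np.ndarray:
    return pwm[::-1, ::-1]  # complement = row reversal (A<->T, C<->G), then 3'->5'


def _column_correlation(x: np.ndarray, y: np.ndarray) -> float:
    # a constant column (e.g. uniform 0.25) has zero variance: treated as 0
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return 0.0 if math.isnan(r) else r


def pwm_alignment_score(
    a: np.ndarray, b: np.ndarray, min_overlap: int = DEFAULT_MIN_PWM_OVERLAP
) -> tuple[float, int, str]:
    """Best mean per-column Pearson correlation over offsets/orientations.

    Returns (score, offset of b relative to a, orientation); score is -inf
    when no offset reaches the minimum overlap.
    """
    best = (-math.inf, 0, "+")
    for orient, bm in (("+", b), ("-", _pwm_revcomp(b))):
        wa, wb = a.shape[1], bm.shape[1]
        for offset in range(-(wb - 1), wa):
            start, end = max(0, offset), min(wa, offset + wb)
            if end - start < min_overlap:
                continue
            cols = [
                _column_correlation(a[:, i], bm[:, i - offset])
                for i in range(start, end)
            ]
            score = float(np.mean(cols))
            if score > best[0]:
                best = (score, offset, orient)
    return best


def match_known_pwms(
    family_pwm: np.ndarray,
    library: Sequence[tuple[str, np.ndarray]],
    score_threshold: float = DEFAULT_PWM_SCORE_THRESHOLD,
    min_overlap: int = DEFAULT_MIN_PWM_OVERLAP,
) -> list[tuple[str, float, int, str]]:
    """Rank library PWMs matching the family PWM.

    Hits with best-alignment score >= threshold, sorted by score descending
    (ties by name), as (name, score, offset, orientation).
    """
    hits = []
    for name, pwm in library:
        score, offset, orient = pwm_alignment_score(family_pwm, pwm, min_overlap)
        if score >= score_threshold:
            hits.append((name, score, offset, orient))
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits
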