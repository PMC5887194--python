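"""Genomic input/output: BED intervals, FASTA genomes, gene annotation, conservation tracks.

All coordinates are 0-based half-open internally.  BED is native to that
convention; fixedStep WIG is converted from its 1-based convention on read.
Soft-masked (lowercase) genome bases mark repeats and can be converted to N
at sequence extraction so they are excluded from motif matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "GenomeSequence",
    "GeneRecord",
    "GeneAnnotation",
    "ConservationTrack",
    "BedParseError",
    "read_bed",
    "merge_intervals",
    "read_fasta_genome",
    "extract_sequences",
    "read_gene_annotation",
    "read_conservation_track",
]

_GENOME_ALPHABET = frozenset("ACGTNacgtn")


class BedParseError(ValueError):
    """Raised when a BED / annotation file cannot be parsed."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open, 0-based chromosome span with optional strand and label."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # used as FASTA header / instance key
        return f"{self.chrom}:{self.start}-{self.end}"


class GenomeSequence:
    """A multi-chromosome genome with soft-masking preserved as lowercase."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs = dict(sequences)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    @property
    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])


@dataclass(frozen=True)
class GeneRecord:
    """A gene body with mandatory strand; the TSS is the strand-dependent 5' end."""

    interval: GenomicInterval
    gene_id: str

    @property
    def tss(self) -> int:
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def strand(self) -> str:
        return self.interval.strand


class GeneAnnotation:
    """Gene records indexed per chromosome for nearest-TSS queries."""

    def __init__(self, genes: Iterable[GeneRecord]):
        self.genes: list[GeneRecord] = list(genes)
        self._by_chrom: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.interval.chrom, []).append(g)
        # sorted TSS arrays make the nearest query O(log n)
        self._tss_arrays: dict[str, np.ndarray] = {}
        for chrom, gs in self._by_chrom.items():
            gs.sort(key=lambda g: (g.tss, g.gene_id))
            self._tss_arrays[chrom] = np.array([g.tss for g in gs], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.genes)

    def on_chromosome(self, chrom: str) -> list[GeneRecord]:
        return self._by_chrom.get(chrom, [])

    def nearest(self, chrom: str, position: int) -> GeneRecord:
        """Gene whose TSS is nearest |position - TSS|; ties by smallest gene_id."""
        gs = self._by_chrom.get(chrom)
        if not gs:
            raise ValueError(f"no gene annotated on chromosome {chrom!r}")
        tss = self._tss_arrays[chrom]
        i = int(np.searchsorted(tss, position))
        candidates = {j for j in (i - 1, i, i + 1) if 0 <= j < len(gs)}
        best = min(abs(int(tss[j]) - position) for j in candidates)
        # widen to every gene at the winning distance, then break ties by id
        tied = [g for g in gs if abs(g.tss - position) == best]
        return min(tied, key=lambda g: g.gene_id)


def _data_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            yield lineno, line


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals, preserving order of appearance.

    Track/browser/comment lines are skipped.  The strand column, if present,
    is read but peak processing ignores it (peaks are unstranded).
    """
    intervals: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise BedParseError(f"{path}: line {lineno}: fewer than 3 tab-separated fields")
        chrom, start_s, end_s = fields[0], fields[1], fields[2]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise BedParseError(
                f"{path}: line {lineno}: non-integer coordinates {start_s!r}, {end_s!r}"
            ) from None
        if not (0 <= start < end):
            raise BedParseError(
                f"{path}: line {lineno}: invalid span start={start} end={end}"
            )
        name = fields[3] if len(fields) > 3 and fields[3] != "" else None
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
        intervals.append(GenomicInterval(chrom, start, end, strand=strand, name=name))
    if not intervals:
        raise BedParseError(f"{path}: no regions found")
    return intervals


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals per chromosome, BEDtools-merge default semantics.

    Overlapping or book-ended (end == start) intervals merge; strand is
    ignored; output sorted by (chrom, start).
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def read_fasta_genome(path: str | Path) -> GenomeSequence:
    """Load a multi-FASTA genome; header token before whitespace names the chromosome."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in seqs:
            raise ValueError(f"{path}: duplicate chromosome name {name!r}")
        seq = str(record.seq)
        bad = set(seq) - _GENOME_ALPHABET
        if bad:
            raise ValueError(
                f"{path}: chromosome {name!r} contains invalid character(s) "
                f"{sorted(bad)!r}; allowed: ACGTN upper/lowercase"
            )
        seqs[name] = seq
    if not seqs:
        raise ValueError(f"{path}: no FASTA records")
    return GenomeSequence(seqs)


def extract_sequences(
    genome: GenomeSequence,
    intervals: Iterable[GenomicInterval],
    mask_repeats: bool = True,
) -> list[tuple[str, str]]:
    """Extract (name, sequence) pairs for intervals from the genome.

    With ``mask_repeats`` soft-masked lowercase bases become N (excluded from
    motif matching); otherwise they are uppercased.  The name encodes
    ``chrom:start-end`` so motif instances can be relocated genomically.
    """
    out: list[tuple[str, str]] = []
    for iv in intervals:
        if iv.chrom not in genome:
            raise ValueError(f"interval {iv} on unknown chromosome {iv.chrom!r}")
        if iv.end > genome.length(iv.chrom):
            raise ValueError(
                f"interval {iv} out of bounds (chromosome length "
                f"{genome.length(iv.chrom)})"
            )
        raw = genome[iv.chrom][iv.start : iv.end]
        if mask_repeats:
            seq = "".join("N" if c.islower() else c for c in raw)
        else:
            seq = raw.upper()
        out.append((str(iv), seq))
    return out


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Read a strand-aware BED6 gene table (chrom, start, end, gene_id, score, strand)."""
    genes: list[GeneRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise BedParseError(
                f"{path}: line {lineno}: gene annotation requires 6 columns "
                f"(got {len(fields)}); strand is mandatory"
            )
        chrom, start_s, end_s, gene_id, _score, strand = fields[:6]
        if strand not in ("+", "-"):
            raise BedParseError(
                f"{path}: line {lineno}: strand must be '+' or '-', got {strand!r}"
            )
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise BedParseError(
                f"{path}: line {lineno}: non-integer coordinates"
            ) from None
        genes.append(
            GeneRecord(GenomicInterval(chrom, start, end, strand=strand), gene_id)
        )
    if not genes:
        raise BedParseError(f"{path}: no gene records found")
    return GeneAnnotation(genes)


class ConservationTrack:
    """Per-base conservation scores with explicit missing data (NaN)."""

    def __init__(self) -> None:
        self._arrays: dict[str, np.ndarray] = {}

    def _ensure(self, chrom: str, upto: int) -> np.ndarray:
        arr = self._arrays.get(chrom)
        if arr is None:
            arr = np.full(max(upto, 1024), np.nan)
            self._arrays[chrom] = arr
        elif len(arr) < upto:
            grown = np.full(max(upto, 2 * len(arr)), np.nan)
            grown[: len(arr)] = arr
            self._arrays[chrom] = grown
            arr = grown
        return self._arrays[chrom]

    def add(self, chrom: str, start: int, values: np.ndarray) -> None:
        arr = self._ensure(chrom, start + len(values))
        target = arr[start : start + len(values)]
        if np.any(~np.isnan(target)):
            raise ValueError(
                f"overlapping conservation records on {chrom} near base {start}"
            )
        arr[start : start + len(values)] = values

    def scores(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base scores over [start, end); NaN where no data."""
        out = np.full(end - start, np.nan)
        arr = self._arrays.get(chrom)
        if arr is None:
            return out
        hi = min(end, len(arr))
        if hi > start:
            out[: hi - start] = arr[start:hi]
        return out

    def score_at(self, chrom: str, pos: int) -> float:
        """Score at a single base, NaN if missing."""
        return float(self.scores(chrom, pos, pos + 1)[0])


_FIXEDSTEP_RE = re.compile(r"^fixedStep\s+(.*)$")


def _parse_fixedstep_header(line: str, lineno: int, path) -> tuple[str, int, int, int]:
    kv: dict[str, str] = {}
    for tok in line.split()[1:]:
        if "=" not in tok:
            raise ValueError(f"{path}: line {lineno}: malformed fixedStep token {tok!r}")
        k, v = tok.split("=", 1)
        kv[k] = v
    try:
        chrom = kv["chrom"]
        start = int(kv["start"])
        step = int(kv["step"])
        span = int(kv.get("span", "1"))
    except (KeyError, ValueError):
        raise ValueError(f"{path}: line {lineno}: malformed fixedStep header") from None
    if start < 1 or step < 1 or span < 1:
        raise ValueError(f"{path}: line {lineno}: malformed fixedStep header")
    return chrom, start, step, span


def read_conservation_track(path: str | Path) -> ConservationTrack:
    """Read a fixedStep WIG or 4-column bedGraph into a per-base score track.

    WIG positions are 1-based and converted to the internal 0-based
    convention; overlapping records are an error.  A ``.bw``/``.bigwig``
    suffix is read through pyBigWig when that optional dependency is
    installed.
    """
    path = Path(path)
    if path.suffix.lower() in (".bw", ".bigwig"):
        return _read_bigwig(path)
    track = ConservationTrack()
    state: tuple[str, int, int, int] | None = None  # chrom, next0, step, span
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            if line.startswith("variableStep"):
                raise ValueError(f"{path}: line {lineno}: variableStep not supported")
            if _FIXEDSTEP_RE.match(line):
                chrom, start1, step, span = _parse_fixedstep_header(line, lineno, path)
                state = (chrom, start1 - 1, step, span)
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) == 1:
                if state is None:
                    raise ValueError(
                        f"{path}: line {lineno}: value outside any fixedStep block"
                    )
                chrom, pos0, step, span = state
                try:
                    value = float(fields[0])
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno}: non-numeric value {fields[0]!r}"
                    ) from None
                track.add(chrom, pos0, np.full(span, value))
                state = (chrom, pos0 + step, step, span)
            elif len(fields) >= 4:
                chrom, start_s, end_s, val_s = fields[:4]
                try:
                    start, end, value = int(start_s), int(end_s), float(val_s)
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno}: malformed bedGraph record"
                    ) from None
                if not (0 <= start < end):
                    raise ValueError(f"{path}: line {lineno}: invalid bedGraph span")
                track.add(chrom, start, np.full(end - start, value))
                state = None
            else:
                raise ValueError(f"{path}: line {lineno}: unrecognized record {line!r}")
    return track


def _read_bigwig(path: Path) -> ConservationTrack:
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading BigWig requires the optional pyBigWig dependency; "
            "supply fixedStep WIG or bedGraph instead"
        ) from exc
    track = ConservationTrack()
    bw = pyBigWig.open(str(path))
    try:
        for chrom, length in bw.chroms().items():
            vals = np.asarray(bw.values(chrom, 0, length), dtype=float)
            covered = ~np.isnan(vals)
            if covered.any():
                # add in runs so the overlap check stays meaningful
                idx = np.flatnonzero(covered)
                splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
                for run in splits:
                    track.add(chrom, int(run[0]), vals[run[0] : run[-1] + 1])
    finally:
        bw.close()
    return track
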