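"""Synthetic genomes, peaks, conservation tracks and motif libraries.

Everything the pipeline consumes can be generated here with no downloads: a
uniform-random (optionally GC-skewed) soft-masked genome with non-overlapping
gene bodies, ChIP-seq-like peaks whose TSS-distance distribution is a stated
mixture (half within +/-5 kb of a TSS, half uniform), a planted motif
implanted into a chosen fraction of peaks on random strands, a conservation
track that boosts the planted positions (so conservation-based ranking has
signal to find), and a small JASPAR library containing the planted motif.

What these fixtures emulate — and what they do not: real peaks carry GC and
repeat structure, positional motif enrichment at peak centers and degenerate
binding sites; here the sequence is i.i.d., the planted word exact, and
conservation noise uniform.  Passing tests therefore demonstrate the
machinery (counting, matching, ranking), not performance on real genomes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .discovery import revcomp
from .genome_io import (
    ConservationTrack,
    GeneAnnotation,
    GeneRecord,
    GenomeSequence,
    GenomicInterval,
)

__all__ = [
    "FixtureSpec",
    "generate_genome",
    "generate_peaks",
    "generate_conservation",
    "generate_known_motifs",
    "write_fixture",
    "PRESETS",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic study; defaults give a 100-kb, 100-peak run."""

    n_chroms: int = 1
    chrom_length: int = 100_000
    n_genes: int = 50
    gene_length: int = 1_000
    n_peaks: int = 100
    peak_length: int = 200
    planted_motif: str = "AAGGTTCC"
    plant_fraction: float = 0.6
    masked_fraction: float = 0.05
    conserved_boost: float = 0.7
    missing_fraction: float = 0.05
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.plant_fraction <= 1):
            raise ValueError("plant_fraction must be in [0, 1]")
        if not (0 <= self.masked_fraction <= 1):
            raise ValueError("masked_fraction must be in [0, 1]")
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")


def _rng(spec: FixtureSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stage])


def _chrom_names(spec: FixtureSpec) -> list[str]:
    return [f"chr{i + 1}" for i in range(spec.n_chroms)]


def _free_gaps(
    placed: list[tuple[int, int]], length: int, size: int
) -> list[tuple[int, int]]:
    """Half-open ranges of admissible start positions for a `size`-bp body."""
    gaps = []
    cursor = 0
    for s, e in sorted(placed):
        if s - cursor >= size:
            gaps.append((cursor, s - size + 1))
        cursor = max(cursor, e)
    if length - cursor >= size:
        gaps.append((cursor, length - size + 1))
    return gaps


def generate_genome(spec: FixtureSpec) -> tuple[GenomeSequence, GeneAnnotation]:
    """Random soft-masked genome plus non-overlapping, stranded gene bodies."""
    rng = _rng(spec, 1)
    seqs: dict[str, str] = {}
    genes: list[GeneRecord] = []
    for ci, chrom in enumerate(_chrom_names(spec)):
        arr = rng.choice(_BASES, size=spec.chrom_length, p=list(spec.base_probs))
        # soft-mask contiguous blocks until the requested fraction is reached
        target = int(spec.masked_fraction * spec.chrom_length)
        masked = np.zeros(spec.chrom_length, dtype=bool)
        while masked.sum() < target:
            length = int(rng.integers(200, 1000))
            start = int(rng.integers(0, max(1, spec.chrom_length - length)))
            masked[start : start + length] = True
        seq = "".join(
            c.lower() if m else c for c, m in zip(arr, masked)
        )
        seqs[chrom] = seq
        # genes: non-overlapping bodies, random strands; each start drawn
        # uniformly over the positions still admissible given earlier genes
        placed: list[tuple[int, int]] = []
        for gi in range(spec.n_genes):
            gaps = _free_gaps(placed, spec.chrom_length, spec.gene_length)
            n_positions = sum(hi - lo for lo, hi in gaps)
            if n_positions == 0:
                raise RuntimeError(
                    f"no room for gene {gi} on {chrom}: chromosome too short "
                    "for the requested gene count and length"
                )
            r = int(rng.integers(n_positions))
            for lo, hi in gaps:
                if r < hi - lo:
                    start = lo + r
                    break
                r -= hi - lo
            end = start + spec.gene_length
            placed.append((start, end))
            strand = "+" if rng.integers(2) == 0 else "-"
            genes.append(
                GeneRecord(
                    GenomicInterval(chrom, start, end, strand=strand),
                    gene_id=f"gene{ci:02d}_{gi:03d}",
                )
            )
    return GenomeSequence(seqs), GeneAnnotation(genes)


def generate_peaks(
    spec: FixtureSpec, genome: GenomeSequence, genes: GeneAnnotation
) -> tuple[list[GenomicInterval], pd.DataFrame, GenomeSequence]:
    """Peaks with a TSS-anchored location mixture and planted motif instances.

    Half the peaks center within +/-5 kb of a random TSS, half uniformly.
    ``round(plant_fraction * n_peaks)`` peaks receive the planted motif at a
    uniform internal offset on a random strand; planting overwrites the
    genome (uppercase, so masking cannot erase it) and the returned genome
    carries the implants.  The truth table records every planted position.
    """
    rng = _rng(spec, 2)
    chroms = genome.chromosomes
    word = spec.planted_motif.upper()
    k = len(word)
    if k > spec.peak_length:
        raise ValueError("planted motif longer than peak length")
    editable = {c: list(genome[c]) for c in chroms}
    peaks: list[GenomicInterval] = []
    for i in range(spec.n_peaks):
        chrom = chroms[int(rng.integers(len(chroms)))]
        if rng.random() < 0.5 and genes.on_chromosome(chrom):
            gs = genes.on_chromosome(chrom)
            gene = gs[int(rng.integers(len(gs)))]
            mid = gene.tss + int(rng.integers(-5000, 5000))
        else:
            mid = int(rng.integers(genome.length(chrom)))
        start = mid - spec.peak_length // 2
        start = min(max(start, 0), genome.length(chrom) - spec.peak_length)
        peaks.append(
            GenomicInterval(chrom, start, start + spec.peak_length,
                            name=f"peak{i:04d}")
        )
    n_plant = round(spec.plant_fraction * spec.n_peaks)
    chosen = rng.permutation(spec.n_peaks)[:n_plant]
    truth_rows = []
    for pi in sorted(int(i) for i in chosen):
        peak = peaks[pi]
        offset = int(rng.integers(0, spec.peak_length - k + 1))
        strand = "+" if rng.integers(2) == 0 else "-"
        inserted = word if strand == "+" else revcomp(word)
        gstart = peak.start + offset
        editable[peak.chrom][gstart : gstart + k] = list(inserted)
        truth_rows.append(
            {
                "peak_index": pi,
                "chrom": peak.chrom,
                "start": gstart,
                "end": gstart + k,
                "strand": strand,
                "word": word,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["peak_index", "chrom", "start", "end", "strand", "word"],
    )
    planted_genome = GenomeSequence({c: "".join(chars) for c, chars in editable.items()})
    return peaks, truth, planted_genome


def generate_conservation(
    spec: FixtureSpec, genome: GenomeSequence, truth: pd.DataFrame
) -> ConservationTrack:
    """Uniform(0, 0.3) baseline, boosted over planted bases, with missing gaps."""
    rng = _rng(spec, 3)
    track = ConservationTrack()
    boosts: dict[str, list[tuple[int, int]]] = {}
    for _, row in truth.iterrows():
        boosts.setdefault(row["chrom"], []).append((row["start"], row["end"]))
    for chrom in genome.chromosomes:
        n = genome.length(chrom)
        values = rng.uniform(0.0, 0.3, size=n)
        for s, e in boosts.get(chrom, []):
            values[s:e] = np.minimum(values[s:e] + spec.conserved_boost, 1.0)
        missing = rng.random(n) < spec.missing_fraction
        values[missing] = np.nan
        present = np.flatnonzero(~missing)
        if present.size:
            runs = np.split(present, np.flatnonzero(np.diff(present) > 1) + 1)
            for run in runs:
                track.add(chrom, int(run[0]), values[run[0] : run[-1] + 1])
    return track


def generate_known_motifs(spec: FixtureSpec) -> str:
    """A tiny JASPAR-format library: the planted motif plus two random decoys."""
    rng = _rng(spec, 4)
    buf = io.StringIO()

    def emit(name: str, counts: np.ndarray) -> None:
        buf.write(f">{name}\t{name}\n")
        for base, row in zip("ACGT", counts):
            vals = " ".join(str(int(v)) for v in row)
            buf.write(f"{base} [ {vals} ]\n")

    word = spec.planted_motif.upper()
    planted = np.zeros((4, len(word)), dtype=int)
    for i, c in enumerate(word):
        planted["ACGT".index(c), i] = 20
    emit("PLANTED_TF", planted)
    for d in range(2):
        decoy = rng.integers(0, 20, size=(4, 10))
        decoy[int(rng.integers(4))] += 5  # avoid all-zero columns
        emit(f"DECOY_{d + 1}", decoy + 1)
    return buf.getvalue()


# ---------------------------------------------------------------- file output

def _wrap(seq: str, width: int = 80) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_genome_fasta(genome: GenomeSequence, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chromosomes:
            fh.write(f">{chrom}\n{_wrap(genome[chrom])}\n")


def write_genes_bed(genes: GeneAnnotation, path: Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes.genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            iv = g.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\n")


def write_peaks_bed(peaks: Sequence[GenomicInterval], path: Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name or '.'}\n")


def write_wig(track: ConservationTrack, genome: GenomeSequence, path: Path) -> None:
    """fixedStep WIG (1-based starts), one block per contiguous covered run."""
    with open(path, "w") as fh:
        for chrom in genome.chromosomes:
            scores = track.scores(chrom, 0, genome.length(chrom))
            present = np.flatnonzero(~np.isnan(scores))
            if present.size == 0:
                continue
            runs = np.split(present, np.flatnonzero(np.diff(present) > 1) + 1)
            for run in runs:
                fh.write(f"fixedStep chrom={chrom} start={int(run[0]) + 1} step=1\n")
                fh.writelines(f"{scores[i]:.5f}\n" for i in run)


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the complete fixture bundle; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes = generate_genome(spec)
    peaks, truth, genome = generate_peaks(spec, genome, genes)
    track = generate_conservation(spec, genome, truth)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.bed",
        "peaks": outdir / "peaks.bed",
        "truth": outdir / "truth.tsv",
        "conservation": outdir / "conservation.wig",
        "known_motifs": outdir / "known_motifs.jaspar",
    }
    write_genome_fasta(genome, paths["genome"])
    write_genes_bed(genes, paths["genes"])
    write_peaks_bed(peaks, paths["peaks"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    write_wig(track, genome, paths["conservation"])
    paths["known_motifs"].write_text(generate_known_motifs(spec))
    return paths


PRESETS: dict[str, FixtureSpec] = {
    "default": FixtureSpec(),
    "gc-skew": FixtureSpec(base_probs=(0.2, 0.3, 0.3, 0.2)),
    "no-plant": FixtureSpec(plant_fraction=0.0),
}
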