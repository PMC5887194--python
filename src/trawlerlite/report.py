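"""Pipeline assembly and the flat-file results bundle.

The full run is: merge peaks -> extract masked sequences -> build the
TSS-distance table -> sample the matched background -> enumerate and score
candidates -> keep the top N -> cluster into families -> build family PWMs
-> relocate instances -> conservation -> known-motif matches -> bundle.  The
bundle is a directory of TSV/BED/FASTA/JSON files plus a zip archive of the
lot; the summary table is sorted by family conservation maximum descending
(families without conservation last, ties by family z) so the most
evolutionarily constrained families surface first.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from Bio import SeqIO

from . import annotation as ann
from . import background as bg
from . import clustering as cl
from . import discovery as disc
from . import genome_io as gio

__all__ = [
    "RunConfig",
    "PipelineInputs",
    "ResultBundle",
    "NoSignificantResultsError",
    "run_pipeline",
    "write_bundle",
    "sort_summary",
]

logger = logging.getLogger("trawlerlite")

SUMMARY_COLUMNS = [
    "family_id", "consensus", "n_members", "top_motif", "family_z",
    "sample_count", "percent_occurrence", "conservation_max",
    "conservation_avg", "known_hits",
]


class NoSignificantResultsError(RuntimeError):
    """Raised when no motif family survives; maps to CLI exit status 3."""


@dataclass(frozen=True)
class RunConfig:
    """All pipeline options; recorded verbatim into the run metadata."""

    min_length: int = disc.DEFAULT_K_MIN
    max_length: int = disc.DEFAULT_K_MAX
    wildcards: int = disc.DEFAULT_WILDCARDS
    overlap_pct: float = cl.DEFAULT_OVERLAP_PCT
    occurrence: int = disc.DEFAULT_MIN_OCCURRENCE
    n_motifs: int = disc.DEFAULT_N_MOTIFS
    n_clusters: int = 0  # 0 = SCC clustering
    multiplier: int = bg.DEFAULT_MULTIPLIER
    bin_width: int = bg.DEFAULT_BIN_WIDTH
    seed: int = 0
    mask_repeats: bool = True
    exclude_input: bool = False
    histogram_bins: int = ann.DEFAULT_N_BINS
    pseudocount: float = cl.DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0 (0 selects SCC clustering)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


@dataclass(frozen=True)
class PipelineInputs:
    """Input file paths; either peaks BED + genome + genes, or FASTA-only."""

    peaks_bed: Path | None = None
    input_fasta: Path | None = None
    genome_fasta: Path | None = None
    genes_bed: Path | None = None
    background_fasta: Path | None = None
    conservation: Path | None = None
    known_motifs: Path | None = None


@dataclass
class ResultBundle:
    """Everything a run produced, ready for writing or inspection."""

    config: RunConfig
    summary: pd.DataFrame
    families: list[cl.MotifFamily]
    instances: dict[str, list[ann.MotifInstance]]
    histograms: dict[str, ann.PositionHistogram]
    input_table: bg.DistanceFrequencyTable | None
    achieved_table: bg.DistanceFrequencyTable | None
    background_regions: list[gio.GenomicInterval] | None
    background_sequences: list[tuple[str, str]]
    peak_intervals: list[gio.GenomicInterval] | None
    n_sample_sequences: int = 0
    known_hits: dict[str, list[tuple[str, float, int, str]]] = field(default_factory=dict)


def _read_plain_fasta(path: Path, mask_repeats: bool) -> list[tuple[str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if mask_repeats:
            seq = "".join("N" if c.islower() else c for c in seq)
        else:
            seq = seq.upper()
        out.append((rec.id, seq))
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


def run_pipeline(config: RunConfig, inputs: PipelineInputs) -> ResultBundle:
    """Execute the whole discovery pipeline; deterministic given the seed."""
    peak_intervals: list[gio.GenomicInterval] | None = None
    input_table = achieved_table = None
    background_regions = None
    genome = genes = None

    if inputs.peaks_bed is not None:
        if inputs.genome_fasta is None or inputs.genes_bed is None:
            raise ValueError("BED input requires a genome FASTA and a gene BED6 table")
        raw = gio.read_bed(inputs.peaks_bed)
        peak_intervals = gio.merge_intervals(raw)
        logger.info("input regions: %d raw, %d after merge", len(raw), len(peak_intervals))
        genome = gio.read_fasta_genome(inputs.genome_fasta)
        genes = gio.read_gene_annotation(inputs.genes_bed)
        sample = gio.extract_sequences(genome, peak_intervals, config.mask_repeats)
    elif inputs.input_fasta is not None:
        sample = _read_plain_fasta(inputs.input_fasta, config.mask_repeats)
        logger.info("input sequences: %d (FASTA mode)", len(sample))
    else:
        raise ValueError("either peaks_bed or input_fasta must be given")

    sample_seqs = [s for _, s in sample]

    if inputs.background_fasta is not None:
        bg_pairs = _read_plain_fasta(inputs.background_fasta, config.mask_repeats)
    elif peak_intervals is not None:
        input_table = bg.build_frequency_table(peak_intervals, genes, config.bin_width)
        spec = bg.BackgroundSpec(
            multiplier=config.multiplier,
            seed=config.seed,
            exclude_input=config.exclude_input,
        )
        background_regions = bg.sample_background_regions(
            input_table, genes, genome, spec, peak_intervals
        )
        achieved_table = bg.build_frequency_table(
            background_regions, genes, config.bin_width
        )
        bg_pairs = gio.extract_sequences(genome, background_regions, config.mask_repeats)
        logger.info("background: %d regions (%dx input)",
                    len(background_regions), config.multiplier)
    else:
        raise ValueError("FASTA-only input requires a background FASTA")
    bg_seqs = [s for _, s in bg_pairs]

    lengths = range(config.min_length, config.max_length + 1)
    sample_index = disc.KmerCountIndex(sample_seqs, lengths)
    candidates = disc.enumerate_candidates(
        sample_seqs,
        k_min=config.min_length,
        k_max=config.max_length,
        wildcards=config.wildcards,
        min_occurrence=config.occurrence,
        index=sample_index,
    )
    logger.info("candidates: %d", len(candidates))
    if not candidates:
        raise NoSignificantResultsError(
            "no candidate motif reached the occurrence threshold "
            f"({config.occurrence}); lower the occurrence option"
        )
    bg_index = disc.KmerCountIndex(bg_seqs, {p.length for p in candidates})
    scores = disc.score_motifs(
        candidates, sample_seqs, bg_seqs, config.multiplier,
        sample_index=sample_index, background_index=bg_index,
    )
    top = disc.take_top(scores, config.n_motifs)
    logger.info("scored: %d, entering clustering: %d", len(scores), len(top))

    if config.n_clusters == 0:
        families = cl.scc_cluster(top, config.overlap_pct)
    else:
        families = cl.kmeans_cluster(top, config.n_clusters, seed=config.seed)
    if not families:
        raise NoSignificantResultsError("no motif family found")
    logger.info("families: %d", len(families))

    track = None
    if inputs.conservation is not None and peak_intervals is not None:
        track = gio.read_conservation_track(inputs.conservation)
    library = None
    if inputs.known_motifs is not None:
        library = ann.read_jaspar_library(inputs.known_motifs)

    instances: dict[str, list[ann.MotifInstance]] = {}
    histograms: dict[str, ann.PositionHistogram] = {}
    known_hits: dict[str, list] = {}
    for family in families:
        fam_instances = ann.locate_instances(family, sample_seqs, peak_intervals)
        by_word: dict[str, list[str]] = {}
        for inst in fam_instances:
            by_word.setdefault(inst.pattern.word, []).append(inst.matched_word)
        family.pwm, family.consensus = cl.build_family_pwm(
            family.members, by_word, config.pseudocount
        )
        if track is not None:
            ann.annotate_conservation(fam_instances, track)
            family.conservation_max, family.conservation_avg = (
                ann.family_conservation_summary(fam_instances)
            )
        instances[family.family_id] = fam_instances
        if peak_intervals is not None:
            histograms[family.family_id] = ann.position_histogram(
                fam_instances, peak_intervals, config.histogram_bins
            )
        if library is not None:
            known_hits[family.family_id] = ann.match_known_pwms(family.pwm, library)

    rows = []
    for family in families:
        top_member = family.top_member
        hits = known_hits.get(family.family_id, [])
        rows.append(
            {
                "family_id": family.family_id,
                "consensus": family.consensus,
                "n_members": len(family.members),
                "top_motif": top_member.pattern.word,
                "family_z": family.family_z,
                "sample_count": top_member.sample_count,
                "percent_occurrence": disc.percent_occurrence(
                    top_member, len(sample_seqs)
                ),
                "conservation_max": family.conservation_max,
                "conservation_avg": family.conservation_avg,
                "known_hits": ";".join(f"{n}:{s:.3f}" for n, s, _, _ in hits),
            }
        )
    summary = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    summary = sort_summary(summary, "conservation_max")
    total_instances = sum(len(v) for v in instances.values())
    logger.info("instances: %d across %d families", total_instances, len(families))

    return ResultBundle(
        config=config,
        summary=summary,
        families=families,
        instances=instances,
        histograms=histograms,
        input_table=input_table,
        achieved_table=achieved_table,
        background_regions=background_regions,
        background_sequences=bg_pairs,
        peak_intervals=peak_intervals,
        n_sample_sequences=len(sample_seqs),
        known_hits=known_hits,
    )


def sort_summary(rows: pd.DataFrame, key: str = "conservation_max") -> pd.DataFrame:
    """Stable sort of the summary table by one column.

    Numeric columns sort descending with missing values last; string columns
    ascending.  The default key is the family conservation maximum, with
    family_z breaking ties.
    """
    if key not in rows.columns:
        raise KeyError(
            f"unknown sort key {key!r}; valid keys: {', '.join(rows.columns)}"
        )
    numeric = pd.api.types.is_numeric_dtype(rows[key]) or rows[key].isna().all()
    if key == "conservation_max":
        out = rows.sort_values(
            ["conservation_max", "family_z"],
            ascending=[False, False],
            na_position="last",
            kind="stable",
        )
    elif numeric:
        out = rows.sort_values(key, ascending=False, na_position="last", kind="stable")
    else:
        out = rows.sort_values(key, ascending=True, na_position="last", kind="stable")
    return out.reset_index(drop=True)


def _format_opt(x: float | None) -> str:
    return "." if x is None else f"{x:.5f}"


def _bed_score(z: float) -> int:
    return int(np.clip(round(10 * z), 0, 1000))


def write_bundle(bundle: ResultBundle, out_dir: str | Path) -> Path:
    """Write the results bundle as flat files plus a zip of the directory.

    Zip entries carry a fixed timestamp so byte-identical runs produce
    byte-identical archives.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    summary = bundle.summary.copy()
    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False, float_format="%.5f")

    for family in bundle.families:
        path = out_dir / f"{family.family_id}_instances.bed"
        with open(path, "w") as fh:
            for inst in bundle.instances[family.family_id]:
                iv = inst.interval
                member_z = next(
                    m.z for m in family.members if m.pattern == inst.pattern
                )
                fh.write(
                    "\t".join(
                        [
                            iv.chrom, str(iv.start), str(iv.end),
                            f"{family.family_id}:{inst.pattern.word}",
                            str(_bed_score(member_z)), iv.strand,
                            _format_opt(inst.cons_avg), _format_opt(inst.cons_max),
                        ]
                    )
                    + "\n"
                )

    with open(out_dir / "families.jaspar", "w") as fh:
        for family in bundle.families:
            fh.write(cl.pwm_to_jaspar(family.family_id, family.pwm))

    with open(out_dir / "background.fa", "w") as fh:
        for name, seq in bundle.background_sequences:
            fh.write(f">{name}\n{seq}\n")

    with open(out_dir / "frequency_tables.tsv", "w") as fh:
        fh.write("table\tbin_start_bp\tbin_end_bp\tcount\n")
        for label, table in (("input", bundle.input_table),
                             ("background", bundle.achieved_table)):
            if table is None:
                continue
            for lo, hi, count in table.as_rows():
                fh.write(f"{label}\t{lo}\t{hi}\t{count}\n")

    for family_id, hist in bundle.histograms.items():
        with open(out_dir / f"{family_id}_histogram.tsv", "w") as fh:
            fh.write("bin_left\tbin_right\tcount\n")
            for left, right, count in zip(hist.edges[:-1], hist.edges[1:], hist.counts):
                fh.write(f"{left:.3f}\t{right:.3f}\t{int(count)}\n")

    (out_dir / "config.json").write_text(
        json.dumps(bundle.config.to_dict(), indent=2, sort_keys=True) + "\n"
    )

    zip_path = out_dir / "results.zip"
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for path in sorted(out_dir.iterdir()):
            if path.name == "results.zip":
                continue
            info = zipfile.ZipInfo(path.name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, path.read_bytes())
    return zip_path
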