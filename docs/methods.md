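# Methods

## Coordinates and input handling

All coordinates are 0-based half-open internally. BED is read natively;
fixedStep WIG is converted from its 1-based convention at parse time;
bedGraph is native. Input peaks are merged with BEDtools-default semantics
(overlapping *or book-ended* intervals union; strand ignored) before
sequence extraction, so duplicated or abutting peak calls cannot inflate
counts. Chromosome names are validated at extraction time, not at BED
parse time, so peak lists can be inspected without a genome present.

Repeat handling follows the soft-masking convention of UCSC/EnsEMBL
assemblies: lowercase bases mark repeats and low-complexity sequence.
With masking on (default) they become `N` in extracted sequences, and `N`
never matches any motif position, wildcards included — repeats cannot seed
or extend motifs. `--no-mask` uppercases instead, for factors known to
bind repeats.

## The input-matched background

For each (merged) peak, the signed distance from the peak midpoint to the
nearest TSS is computed; the sign follows gene orientation (negative =
upstream), and ties between equidistant TSSs go to the lexicographically
smallest gene id so the statistic is deterministic. Distances are floored
into fixed-width bins (default 5000 bp) to form the input frequency table.

Background sampling is *quota* sampling, not multinomial: for each bin,
exactly `multiplier × count` regions are drawn (default multiplier 8), each
draw picking a uniform random gene, a uniform signed distance within the
bin applied along gene orientation, and a length resampled with replacement
from the input region lengths. A draw is rejected and redrawn (up to 1000
attempts) when the region would leave chromosome bounds **or when its
realized nearest-TSS bin differs from the target bin** — the chosen gene's
TSS need not be the nearest one once other genes are considered, and
without this check the achieved distance table would only approximately
match the input. With it, the achieved table equals `multiplier ×` the
input table exactly, by construction, which is also asserted in the test
suite. Distance from the *midpoint* (rather than an edge) was chosen
because it is symmetric and independent of region length.

Background regions may overlap input peaks by default; excluding them
(`--exclude-input`) is available but distorts the matched distribution near
dense peak clusters, so it is off unless requested. No GC- or
dinucleotide-matched backgrounds are provided: matching genomic location
is this method's mechanism for absorbing compositional bias, and the
GC-skewed synthetic preset exists to exercise exactly that.

## Candidate enumeration and the z-score

Enumeration is sample-anchored: for every length k in [8, 20], every exact
k-mer occurring at least `occurrence` (default 10) times in the peaks —
counting both strands, with a word and its reverse complement collapsed to
the lexicographically smaller canonical form, and palindromic matches
counted once — is a candidate, together with all its interior-wildcard
generalizations up to the wildcard limit (default 2). Exhaustive 4^k
enumeration at k = 20 is neither feasible nor useful; a motif absent from
the sample cannot be over-represented in it. Wildcards are interior-only
because a terminal wildcard is just a shorter motif.

The z-score is defined through background pseudo-replicates: the background
sequences are partitioned round-robin into `multiplier` groups, each
group's candidate count is one draw, and

    z = (sample_count − bg_mean) / max(bg_sd, max(1, 0.1 · bg_mean))

with `bg_sd` the sample SD (ddof = 1) across draws. The floor keeps
motifs absent from the background at finite z (a sample count of 20 with an
empty background gives z = 20) and damps spuriously tiny SDs for rare
words. Counts are *total occurrences*, not per-sequence presence; the
per-sequence hit count is carried separately and reported as percent
occurrence. Scores sort by z descending with lexicographic tie-break, and
the top 200 (configurable) enter clustering.

Two counting routes exist by design: a regex scan
(`count_occurrences`) that reports positions and backs instance location,
and a k-mer-table index used for enumeration and scoring (a wildcard
pattern's count is the sum over the ≤ 4^w exact words matching it or its
reverse complement). The test suite asserts their exact agreement; the
fast path never substitutes for the reference in position-level output.

## Clustering and PWMs

Similarity between two motif words is the best ungapped-alignment identity
over all relative offsets and both orientations, requiring overlap of at
least half the shorter word; a wildcard column matches anything. The
default family construction thresholds this symmetric similarity at 70 %
and takes strongly connected components of the resulting graph (identical
to connected components here, since edges come in pairs). The 70 default
groups single-base shifts of 8-mers (7/7 = 100 % in the overlap) and 1-2
mismatch variants while keeping unrelated words apart; the option exists
precisely because datasets with diffuse motifs may need a lower value.
Raising the threshold only refines the partition (asserted as a property).

When a fixed family count n is requested, motifs are embedded as one-hot
matrices (wildcard = uniform 0.25 column) placed at their best-offset
alignment to the top-z motif, zero-padded to a common width, and k-means
(scikit-learn, 10 restarts, fixed seed) partitions them. Whether the
original family-count clustering operated on PWMs or instance sets is an
open design point; the embedding here is documented as this package's
choice, and on small inputs it reproduces the exhaustive
minimum-within-cluster-variance 2-partition (tested).

A family PWM is built from the genomic instance strings of all member
patterns, each member aligned at its best offset/orientation to the
family's top-z member; per-column base counts plus a pseudocount of 0.01
are normalized to probabilities. The consensus is the per-column IUPAC
code of bases with probability ≥ 0.25 (so a uniform column reads `N`).
Members with zero instances are skipped. PWMs export in JASPAR minimal
text format.

## Conservation and known-motif matching

Per-instance conservation is the mean and maximum of the track over the
instance's bases *that have data*; uncovered bases are excluded from the
mean rather than zero-filled (zero-filling penalizes assembly gaps, not
biology), and an instance with no covered base carries absent — not 0 —
values. Family-level conservation is the maximum of instance maxima (the
reported sort key) and the mean of instance means. The default summary
ordering is conservation-max descending, conservation-less families last,
ties by family z; keying on the maximum rather than the mean is a
documented choice — the summary column reported is the maximum. Positional
histograms place each instance at
(instance midpoint − peak midpoint)/peak half-length ∈ [−1, 1] so peaks of
different widths are comparable, with 20 equal bins by default.

Known-motif matching runs against a user-supplied local JASPAR-format
library (no database access): for each library PWM, over all offsets and
orientations with ≥ 4 overlapping columns, the score is the mean
per-column Pearson correlation between aligned probability columns; a
constant column (e.g. uniform 0.25) has undefined correlation and counts
as 0. Hits at score ≥ 0.8 are reported. Threshold and minimum overlap are
this package's choices.

## Synthetic studies

The fixture generator emulates a ChIP-seq study end to end: an i.i.d.
random genome (optionally GC-skewed) with contiguous soft-masked blocks;
non-overlapping stranded gene bodies (placed by exact gap sampling, so
dense configurations remain feasible); peaks whose midpoints follow a 50/50
mixture of "within ±5 kb of a TSS" and uniform; a planted motif written
into `round(plant_fraction × n_peaks)` peaks at random internal offsets and
strands (overwriting the genome in uppercase, so masking cannot erase the
implant); a conservation track with Uniform(0, 0.3) baseline, a +0.7 boost
over planted bases, and 5 % of bases missing; and a three-entry JASPAR
library holding the planted motif and two decoys. Everything derives
deterministically from (spec, seed).

What the fixtures do **not** model: real repeat families, CpG islands,
nucleosome-driven positional bias, degenerate (mismatch-bearing) binding
sites, and inter-peak correlation. Green tests demonstrate the machinery —
counting, matching, background matching, ranking — not discovery
performance on real genomes.

Default study sizes — a 100-kb chromosome with 50 genes and 100 peaks of
200 bp (the standard study), and a 30-kb/20-gene/40-peak variant used
where many runs are needed — are sized so a full pipeline run completes in
seconds while keeping the planted word's support (60 occurrences) an order
of magnitude above the occurrence threshold.

## Numerical and degenerate-input choices

- SD floor `max(1, 0.1·bg_mean)`: configurable in code; prevents division
  by ~0 for rare or absent words.
- Scoring requires `multiplier ≥ 2` (SD undefined from one replicate).
- Zero candidates, or zero families, end the run with an explicit
  "no significant results" status (CLI exit 3), distinct from errors (1).
- Similarity/alignment tie-breaks prefer higher overlap, then forward
  orientation, then the smallest |offset|, making clustering and PWM
  construction order-independent and reproducible.
- Zip archives are written with fixed timestamps so identical runs produce
  byte-identical bundles.
- FASTA-only input (no genome/intervals) keeps sequence-relative
  coordinates, requires a user-supplied background FASTA, and skips
  conservation — matching the degraded-information mode of operation.

## Known limitations

- The enumeration cannot find motifs whose every exact occurrence is below
  the occurrence floor yet whose wildcard envelope is common; candidates
  are seeded from exact words only.
- Total-count z-scores favour multi-copy peaks; a per-sequence-presence
  variant is a known alternative and is not implemented.
- Pearson-correlation PWM matching treats columns independently and can
  score short degenerate overlaps optimistically; the ≥ 4-column floor
  mitigates but does not remove this.
- Background sampling needs genes whose neighbourhoods can realize every
  populated distance bin; a bin is abandoned with an error after 1000
  rejected draws per region (pathological only when the annotation is
  tiny or the chromosome short relative to the bin).
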