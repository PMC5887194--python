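import pytest

from trawlerlite.fixtures import (
    FixtureSpec,
    generate_conservation,
    generate_genome,
    generate_peaks,
    write_fixture,
)

# Small but complete study: 40 peaks of 100 bp on a 30-kb chromosome, with
# the planted motif in 60% of peaks (24 >= the default occurrence of 10).
MINI_SPEC = FixtureSpec(
    chrom_length=30_000,
    n_genes=20,
    n_peaks=40,
    peak_length=100,
    seed=11,
)


@pytest.fixture(scope="session")
def mini_spec():
    return MINI_SPEC


@pytest.fixture(scope="session")
def mini_fixture():
    """In-memory (genome, genes, peaks, truth, track) for the mini study."""
    genome, genes = generate_genome(MINI_SPEC)
    peaks, truth, genome = generate_peaks(MINI_SPEC, genome, genes)
    track = generate_conservation(MINI_SPEC, genome, truth)
    return genome, genes, peaks, truth, track


@pytest.fixture(scope="session")
def mini_paths(tmp_path_factory):
    """The same mini study written to disk as pipeline input files."""
    outdir = tmp_path_factory.mktemp("mini_fixture")
    return write_fixture(MINI_SPEC, outdir)
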