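import pytest

from pestop.genome_model import build_cds_map
from pestop.synthetic_fixtures import build_fixture, make_genome

FIXTURE_SPEC = {"PESTOP": 4, "ISTOP": 3, "ISILENCE": 2}
FIXTURE_KW = dict(
    n_genes=6, planted_spec=FIXTURE_SPEC, seed=7, desert_gene=True, decoys=True
)


@pytest.fixture(scope="session")
def fixture_genome():
    """Shared in-memory fixture: genome, transcripts, planted-site truth."""
    return build_fixture(**FIXTURE_KW)


@pytest.fixture(scope="session")
def fixture_files(tmp_path_factory):
    """The same fixture written to FASTA/GFF3 on disk."""
    outdir = tmp_path_factory.mktemp("fixture")
    fasta, gff, truth = make_genome(outdir, **FIXTURE_KW)
    return fasta, gff, truth


@pytest.fixture(scope="session")
def cds_maps(fixture_genome):
    genome, transcripts, _ = fixture_genome
    return {t.transcript_id: build_cds_map(genome, t) for t in transcripts}
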