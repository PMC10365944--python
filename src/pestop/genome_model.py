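"""Genome sequence + annotation model: spliced CDS maps, frames, exons, ORFs.

Coordinates are 0-based half-open internally; GFF3 input (1-based inclusive)
is converted on load and reported output coordinates are converted back to
1-based where files are written.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


@dataclass
class GenomeAssembly:
    """Contig name -> uppercase nucleotide sequence."""

    contigs: dict[str, str]

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    @classmethod
    def from_fasta(cls, path) -> "GenomeAssembly":
        with _open_text(path) as fh:
            contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
        if not contigs:
            raise ValueError(f"no FASTA records in {path}")
        return cls(contigs)


@dataclass
class TranscriptModel:
    """One protein-coding transcript: exon/CDS intervals in genomic coordinates.

    ``exons`` and ``cds_intervals`` are lists of 0-based half-open (start, end)
    tuples sorted by genomic start; transcript (5'→3') order is derived from
    ``strand`` where needed.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]]
    start_codon_pos: int | None = None  # genomic coord of start codon's first base
    start_confident: bool = True

    def __post_init__(self):
        self.exons = sorted(self.exons)
        self.cds_intervals = sorted(self.cds_intervals)
        if self.start_codon_pos is None and self.cds_intervals:
            # frame anchored at the first CDS base in transcript orientation
            if self.strand == "+":
                self.start_codon_pos = self.cds_intervals[0][0]
            else:
                self.start_codon_pos = self.cds_intervals[-1][1] - 1
            self.start_confident = False

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons (genomic order)."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exons_5to3(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def start_codon_exon_index(self) -> int:
        """0-based index (5'→3') of the exon containing the start codon."""
        for i, (s, e) in enumerate(self.exons_5to3()):
            if s <= self.start_codon_pos < e:
                return i
        raise ValueError(
            f"start codon of {self.transcript_id} not inside any exon"
        )

    def exon_number(self, genomic_pos: int) -> int | None:
        """Exon number with the start-codon exon defined as exon 1.

        Exons 5' of the start-codon exon get numbers <= 0.  None when the
        position is not exonic.
        """
        anchor = self.start_codon_exon_index()
        for i, (s, e) in enumerate(self.exons_5to3()):
            if s <= genomic_pos < e:
                return i - anchor + 1
        return None


@dataclass
class CDSMap:
    """Spliced coding-strand CDS with a bidirectional genomic<->CDS coordinate map."""

    transcript: TranscriptModel
    sequence: str
    genomic_coords: list[int]  # genomic position of CDS base i (coding order)
    junction_offsets: set[int] = field(default_factory=set)  # junction between i and i+1
    _to_cds: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._to_cds:
            self._to_cds = {g: i for i, g in enumerate(self.genomic_coords)}

    def __len__(self) -> int:
        return len(self.sequence)

    def genomic_pos(self, cds_offset: int) -> int:
        return self.genomic_coords[cds_offset]

    def cds_offset(self, genomic_pos: int) -> int | None:
        return self._to_cds.get(genomic_pos)

    def codon(self, index: int) -> str:
        return self.sequence[3 * index : 3 * index + 3]

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    def codon_genomic_coords(self, index: int) -> tuple[int, int, int]:
        i = 3 * index
        return tuple(self.genomic_coords[i : i + 3])  # type: ignore[return-value]

    def codon_spans_junction(self, index: int) -> bool:
        i = 3 * index
        return bool(self.junction_offsets & {i, i + 1})


def build_cds_map(genome: GenomeAssembly, transcript: TranscriptModel) -> CDSMap:
    """Splice the CDS intervals into a coding-strand sequence with coordinate maps.

    A CDS whose length is not a multiple of 3 is trimmed at its 3' end with a
    warning (tolerates sloppy annotations).
    """
    if not transcript.cds_intervals:
        raise ValueError(f"{transcript.transcript_id} has no CDS intervals")
    contig_seq = genome[transcript.contig]
    pieces: list[str] = []
    coords: list[int] = []
    junctions: set[int] = set()
    ivs = (
        transcript.cds_intervals
        if transcript.strand == "+"
        else list(reversed(transcript.cds_intervals))
    )
    for s, e in ivs:
        if coords:
            junctions.add(len(coords) - 1)
        piece = contig_seq[s:e]
        if transcript.strand == "+":
            pieces.append(piece)
            coords.extend(range(s, e))
        else:
            pieces.append(revcomp(piece))
            coords.extend(range(e - 1, s - 1, -1))
    seq = "".join(pieces)
    remainder = len(seq) % 3
    if remainder:
        warnings.warn(
            f"CDS of {transcript.transcript_id} has length {len(seq)} "
            f"(not a multiple of 3); trimming {remainder} trailing base(s)",
            stacklevel=2,
        )
        seq = seq[: len(seq) - remainder]
        coords = coords[: len(seq)]
        junctions = {j for j in junctions if j < len(seq) - 1}
    if len(seq) < 3:
        raise ValueError(f"CDS of {transcript.transcript_id} shorter than one codon")
    return CDSMap(transcript, seq, coords, junctions)


_CODING_BIOTYPES = {"protein_coding", "mRNA", "protein-coding"}


def load_annotated_genome(fasta_path, gff_path):
    """Load a FASTA + GFF3 pair into a GenomeAssembly and TranscriptModels.

    Only protein-coding transcripts are returned: genes whose biotype
    attribute marks them as pseudogenes or noncoding are dropped, as are
    non-mRNA transcript features.  CDS features lacking a parent mRNA are
    skipped with a warning.
    """
    genome = GenomeAssembly.from_fasta(fasta_path)
    with _open_text(gff_path) as fh:
        gff_text = fh.read()
    for lineno, line in enumerate(gff_text.splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise ValueError(
                f"malformed GFF3 line {lineno} in {gff_path}: expected 9 "
                f"tab-separated columns"
            )
    db = gffutils.create_db(
        gff_text,
        ":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    transcripts: list[TranscriptModel] = []
    for gene in db.features_of_type("gene"):
        biotype = (
            gene.attributes.get("gene_biotype")
            or gene.attributes.get("biotype")
            or [None]
        )[0]
        if biotype is not None and biotype not in _CODING_BIOTYPES:
            continue
        if gene.seqid not in genome:
            raise ValueError(f"contig {gene.seqid!r} in GFF absent from FASTA")
        for mrna in db.children(gene, featuretype=("mRNA", "transcript")):
            exons = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")]
            cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
            if not cds:
                continue
            if not exons:
                exons = list(cds)
            start_pos = None
            start_feats = list(db.children(mrna, featuretype="start_codon"))
            if start_feats:
                f = start_feats[0]
                start_pos = f.start - 1 if mrna.strand == "+" else f.end - 1
            transcripts.append(
                TranscriptModel(
                    transcript_id=mrna.id,
                    gene_id=gene.id,
                    contig=gene.seqid,
                    strand=mrna.strand,
                    exons=exons,
                    cds_intervals=cds,
                    start_codon_pos=start_pos,
                )
            )
    # orphan CDS features (no mRNA parent) -> warn and skip
    for cds in db.features_of_type("CDS"):
        if not any(True for _ in db.parents(cds, featuretype=("mRNA", "transcript"))):
            warnings.warn(f"CDS feature {cds.id} has no parent mRNA; skipped", stacklevel=2)
    return genome, transcripts


def early_exon_count(transcript: TranscriptModel) -> int:
    """Number of 'early' exons: ceil(E/5) with E the transcript's exon count.

    Early exons are counted from the exon harbouring the start codon
    (defined as exon 1).
    """
    if transcript.n_exons < 1:
        raise ValueError("transcript has no exons")
    return math.ceil(transcript.n_exons / 5)


@dataclass(frozen=True)
class OrfRecord:
    """An open reading frame: ATG start through the first in-frame stop."""

    contig: str
    strand: str
    start: int  # genomic 0-based, half-open [start, end) on the + strand
    end: int
    sequence: str  # coding-strand sequence, includes the stop codon

    @property
    def orf_id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}({self.strand})"


def find_orfs(
    sequence: str,
    min_len: int = 75,
    contig: str = "seq",
    longest_only: bool = True,
) -> list[OrfRecord]:
    """Six-frame ORF scan: ATG starts, ending at the first in-frame stop codon.

    ``min_len`` counts nucleotides including the stop codon and must be a
    multiple of 3 (default 75, a common ORF-finder default).  With
    ``longest_only`` nested ORFs sharing a stop codon report only the
    longest (5'-most ATG).
    """
    if min_len < 3 or min_len % 3:
        raise ValueError("min_len must be >=3 and divisible by 3")
    sequence = sequence.upper()
    stops = {"TAA", "TAG", "TGA"}
    n = len(sequence)
    orfs: list[OrfRecord] = []
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        for frame in range(3):
            used_stops: set[int] = set()
            i = frame
            while i + 3 <= n:
                if seq[i : i + 3] == "ATG":
                    j = i
                    stop_at = None
                    while j + 3 <= n:
                        if seq[j : j + 3] in stops:
                            stop_at = j
                            break
                        j += 3
                    if stop_at is not None:
                        if not (longest_only and stop_at in used_stops):
                            used_stops.add(stop_at)
                            length = stop_at + 3 - i
                            if length >= min_len:
                                if strand == "+":
                                    s, e = i, stop_at + 3
                                else:
                                    s, e = n - (stop_at + 3), n - i
                                orfs.append(
                                    OrfRecord(contig, strand, s, e, seq[i : stop_at + 3])
                                )
                        if longest_only:
                            # skip ahead: later ATGs before this stop share it
                            i = stop_at
                i += 3
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def orfs_to_transcripts(orfs: list[OrfRecord]) -> list[TranscriptModel]:
    """View ORFs as single-exon transcript models so scanners/coverage apply."""
    return [
        TranscriptModel(
            transcript_id=o.orf_id,
            gene_id=o.orf_id,
            contig=o.contig,
            strand=o.strand,
            exons=[(o.start, o.end)],
            cds_intervals=[(o.start, o.end)],
            start_codon_pos=o.start if o.strand == "+" else o.end - 1,
        )
        for o in orfs
    ]
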