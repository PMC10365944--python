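"""Deliberately naive reference enumerators for validating the scanners.

Everything here slides base-by-base over the raw contig sequence and applies
the geometric rules (PAM, windows, reading frame, exon junctions) with
explicit per-base arithmetic, sharing no code path with
:mod:`pestop.site_finder`.  The scanners are required to agree with these
enumerators exactly on small genomes; the fixture generator also uses them
to derive ground-truth coverage tables.
"""

from __future__ import annotations

from .genetic_code import STOP_CODONS, cbe_stop_routes, stops_reachable
from .genome_model import GenomeAssembly, TranscriptModel, revcomp

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _cds_coords(genome: GenomeAssembly, t: TranscriptModel):
    """(coding-strand CDS string, per-base genomic coords), trimmed to codons."""
    seq = genome[t.contig]
    bases: list[str] = []
    coords: list[int] = []
    if t.strand == "+":
        for s, e in sorted(t.cds_intervals):
            for g in range(s, e):
                bases.append(seq[g])
                coords.append(g)
    else:
        for s, e in sorted(t.cds_intervals, reverse=True):
            for g in range(e - 1, s - 1, -1):
                bases.append(_COMP[seq[g]])
                coords.append(g)
    n = len(bases) - len(bases) % 3
    return "".join(bases[:n]), coords[:n]


def _introns(t: TranscriptModel):
    ex = sorted(t.exons)
    return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]


def _in_any(pos: int, intervals) -> bool:
    return any(a <= pos < b for a, b in intervals)


def _span_ok(start: int, end: int, introns) -> bool:
    return not any(_in_any(g, introns) for g in range(start, end))


def _pam_sites(seq: str):
    """Yield (strand, span_start) for every NGG protospacer+PAM 23-mer."""
    for i in range(len(seq) - 22):
        mer = seq[i : i + 23]
        if mer[21:23] == "GG":
            yield "+", i
        if revcomp(mer)[21:23] == "GG":
            yield "-", i


def _offset(strand: str, span_start: int, g: int) -> int | None:
    """+n nick offset of genomic base g for the protospacer+PAM at span_start."""
    n = g - (span_start + 17) + 1 if strand == "+" else (span_start + 6) - g
    return n if n >= 1 else None


def _proto_pos(strand: str, span_start: int, g: int) -> int | None:
    if not span_start <= g < span_start + 23:
        return None
    return g - span_start + 1 if strand == "+" else span_start + 23 - g


def reference_pestop(
    genome: GenomeAssembly,
    transcripts: list[TranscriptModel],
    window: tuple[int, int] = (1, 6),
    max_subs: int = 3,
) -> set[tuple]:
    """Signatures (tid, (span_start, span_end), strand, codon_index) of all
    prime-editing stop sites, by exhaustive 23-mer enumeration."""
    out = set()
    lo_w, hi_w = window
    for t in transcripts:
        seq = genome[t.contig]
        cds, coords = _cds_coords(genome, t)
        introns = _introns(t)
        for strand, i in _pam_sites(seq):
            if not _span_ok(i, i + 23, introns):
                continue
            for k in range(len(cds) // 3):
                codon = cds[3 * k : 3 * k + 3]
                if codon in STOP_CODONS:
                    continue
                cc = coords[3 * k : 3 * k + 3]
                if max(cc) - min(cc) != 2:  # codon split across a junction
                    continue
                offs = [_offset(strand, i, g) for g in cc]
                if any(o is None or not lo_w <= o <= hi_w for o in offs):
                    continue
                if not stops_reachable(codon, 3)[0].n_subs <= max_subs:
                    continue
                out.add((t.transcript_id, (i, i + 23), strand, k))
    return out


def reference_istop(
    genome: GenomeAssembly,
    transcripts: list[TranscriptModel],
    be_window: tuple[int, int] = (4, 8),
) -> set[tuple]:
    """Signatures of CBE stop-conversion sites (CAG/CAA/CGA coding-strand,
    TGG template-strand), exhaustively."""
    out = set()
    lo_w, hi_w = be_window
    for t in transcripts:
        seq = genome[t.contig]
        cds, coords = _cds_coords(genome, t)
        introns = _introns(t)
        for strand, i in _pam_sites(seq):
            if not _span_ok(i, i + 23, introns):
                continue
            for k in range(len(cds) // 3):
                codon = cds[3 * k : 3 * k + 3]
                cc = coords[3 * k : 3 * k + 3]
                if max(cc) - min(cc) != 2:
                    continue
                if codon in ("CAG", "CAA", "CGA"):
                    if strand != t.strand:
                        continue
                    anchor = cc[0]
                elif codon == "TGG":
                    if strand == t.strand:
                        continue
                    anchor = cc[2]
                else:
                    continue
                p = _proto_pos(strand, i, anchor)
                if p is None or not lo_w <= p <= hi_w:
                    continue
                ok_route = any(
                    all(
                        (q := _proto_pos(strand, i, cc[j])) is not None
                        and lo_w <= q <= hi_w
                        for j in r.positions
                    )
                    for r in cbe_stop_routes(codon)
                )
                if not ok_route:
                    continue
                out.add((t.transcript_id, (i, i + 23), strand, k))
    return out


def reference_isilence(
    genome: GenomeAssembly,
    transcripts: list[TranscriptModel],
    be_window: tuple[int, int] = (4, 8),
    accept_template_adenine: bool = True,
) -> set[tuple]:
    """Signatures (tid, span, strand, edited genomic pos) of ABE start-codon
    disruption sites, exhaustively."""
    out = set()
    lo_w, hi_w = be_window
    for t in transcripts:
        cds, coords = _cds_coords(genome, t)
        if cds[:3] != "ATG":
            continue
        # start codon must sit in the transcript's first (5'-most) exon
        first = sorted(t.exons)[0] if t.strand == "+" else sorted(t.exons)[-1]
        if not first[0] <= t.start_codon_pos < first[1]:
            continue
        cc = coords[:3]
        if max(cc) - min(cc) != 2:
            continue
        introns = _introns(t)
        seq = genome[t.contig]
        anchors = [(cc[0], t.strand)]
        if accept_template_adenine:
            anchors.append((cc[1], "-" if t.strand == "+" else "+"))
        for strand, i in _pam_sites(seq):
            if not _span_ok(i, i + 23, introns):
                continue
            for g, need in anchors:
                if strand != need:
                    continue
                p = _proto_pos(strand, i, g)
                if p is not None and lo_w <= p <= hi_w:
                    out.add((t.transcript_id, (i, i + 23), strand, g))
    return out


REFERENCE_SCANNERS = {
    "PESTOP": reference_pestop,
    "ISTOP": reference_istop,
    "ISILENCE": reference_isilence,
}


def reference_variant_pe(contig_seq: str, v: int, window=(1, 9)) -> bool:
    lo_w, hi_w = window
    for i in range(max(0, v - 40), min(len(contig_seq) - 22, v + 40)):
        mer = contig_seq[i : i + 23]
        if mer[21:23] == "GG":
            n = _offset("+", i, v)
            if n is not None and lo_w <= n <= hi_w:
                return True
        if revcomp(mer)[21:23] == "GG":
            n = _offset("-", i, v)
            if n is not None and lo_w <= n <= hi_w:
                return True
    return False


def reference_variant_istop(
    contig_seq: str, v: int, ref: str, alt: str, window=(4, 8)
) -> bool:
    if (ref, alt) == ("C", "T"):
        need = "+"
    elif (ref, alt) == ("G", "A"):
        need = "-"
    else:
        return False
    lo_w, hi_w = window
    for i in range(max(0, v - 30), min(len(contig_seq) - 22, v + 30)):
        mer = contig_seq[i : i + 23]
        strands = []
        if mer[21:23] == "GG":
            strands.append("+")
        if revcomp(mer)[21:23] == "GG":
            strands.append("-")
        for strand in strands:
            if strand != need:
                continue
            p = _proto_pos(strand, i, v)
            if p is not None and lo_w <= p <= hi_w:
                return True
    return False


def hit_signature(hit) -> tuple:
    """Canonical signature of a scanner hit, comparable to the reference sets."""
    if hit.editor == "ISILENCE":
        return (hit.transcript_id, hit.span, hit.strand, hit.substitutions[0].pos)
    return (hit.transcript_id, hit.span, hit.strand, hit.codon_cds_index)
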