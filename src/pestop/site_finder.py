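"""Editor-specific target-site scanners over annotated CDS space.

Three DSB-free gene-inactivation chemistries are modelled, each with its
own geometry relative to an NGG PAM:

* PE-STOP (prime editor): the nick falls 3 nt upstream of the NGG, between
  protospacer positions 17 and 18; any in-frame sense codon lying wholly
  within the +1..+6 window downstream of the nick (on the PAM strand) can be
  rewritten into a stop codon by up to three arbitrary substitutions.
* iSTOP (CBE): CAG/CAA/CGA codons whose C sits at protospacer positions 4-8
  of a coding-strand protospacer, or TGG codons whose template-strand
  complement (CCA) starts at positions 4-8 of a template-strand protospacer.
* i-Silence (ABE): the annotated start codon, first exon only, with an
  editable adenine (the coding-strand A of ATG, or the template-strand A
  opposite its T) at protospacer positions 4-8.

Hits whose protospacer+PAM span or target codon crosses an exon junction
are excluded: such motifs exist only in the spliced transcript, not in the
genome the editor actually sees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .genetic_code import (
    STOP_CODONS,
    SubstitutionPlan,
    cbe_stop_routes,
    min_plan,
    stops_reachable,
)
from .genome_model import (
    CDSMap,
    GenomeAssembly,
    TranscriptModel,
    build_cds_map,
    early_exon_count,
    revcomp,
)

PESTOP = "PESTOP"
ISTOP = "ISTOP"
ISILENCE = "ISILENCE"

_COMP = str.maketrans("ACGT", "TGCA")

#: default prime-editing window in +n nick-relative units (conservative)
PE_WINDOW = (1, 6)
#: extended window used for fixed-location (variant) queries
PE_WINDOW_WIDE = (1, 9)
#: base-editor activity window in protospacer positions
BE_WINDOW = (4, 8)

ISTOP_CODING_CODONS = ("CAG", "CAA", "CGA")


@dataclass(frozen=True)
class EditWindow:
    start: int
    end: int

    def __contains__(self, n: int | None) -> bool:
        return n is not None and self.start <= n <= self.end


@dataclass(frozen=True)
class Protospacer:
    """A 20-nt protospacer plus its NGG PAM on one genomic strand.

    ``start``/``end`` delimit the full 23-nt protospacer+PAM span in
    + strand coordinates regardless of ``strand``.
    """

    contig: str
    strand: str
    start: int
    end: int

    @property
    def nick_pos(self) -> int:
        """0-based boundary of the nCas9 nick (3 nt upstream of the PAM)."""
        return self.start + 17 if self.strand == "+" else self.start + 6

    def sequences(self, contig_seq: str) -> tuple[str, str]:
        """(protospacer, pam) read 5'→3' on the PAM strand."""
        span = contig_seq[self.start : self.end]
        if self.strand == "-":
            span = revcomp(span)
        return span[:20], span[20:]

    def position_of(self, gpos: int) -> int | None:
        """1-based protospacer position (1..20; PAM = 21..23) of a genomic base."""
        if not self.start <= gpos < self.end:
            return None
        return gpos - self.start + 1 if self.strand == "+" else self.end - gpos

    def offset_of(self, gpos: int) -> int | None:
        """+n offset relative to the nick on the PAM strand (None if 5' of it)."""
        n = gpos - self.nick_pos + 1 if self.strand == "+" else self.nick_pos - gpos
        return n if n >= 1 else None

    def genomic_at_offset(self, n: int) -> int:
        return self.nick_pos + n - 1 if self.strand == "+" else self.nick_pos - n


def enumerate_protospacers(
    contig_seq: str, contig: str, start: int = 0, end: int | None = None
) -> list[Protospacer]:
    """All NGG-adjacent protospacers on both strands overlapping [start, end)."""
    if end is None:
        end = len(contig_seq)
    lo = max(0, start - 25)
    hi = min(len(contig_seq), end + 25)
    out = []
    for i in range(lo, hi - 1):
        pair = contig_seq[i : i + 2]
        if pair == "GG":
            s = i - 21  # PAM at [i-1, i+2), protospacer 20 nt upstream
            if s >= 0 and s + 23 <= len(contig_seq):
                out.append(Protospacer(contig, "+", s, s + 23))
        if pair == "CC":
            if i >= 0 and i + 23 <= len(contig_seq):
                out.append(Protospacer(contig, "-", i, i + 23))
    return out


@dataclass(frozen=True)
class GenomicSubstitution:
    """A single-base change in + strand genomic terms."""

    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class TargetHit:
    """One editable site: a protospacer, its target codon and the edit plan."""

    editor: str
    contig: str
    strand: str  # genomic strand bearing the protospacer+NGG
    transcript_id: str
    gene_id: str
    protospacer: str
    pam: str
    span: tuple[int, int]  # protospacer+PAM genomic span, + strand coords
    nick_pos: int
    codon_cds_index: int
    codon: str
    plan: SubstitutionPlan | None
    substitutions: tuple[GenomicSubstitution, ...]
    coding_strand: str
    exon_number: int | None = None

    @property
    def pam_strand(self) -> str:
        """Orientation of the PAM strand relative to the coding strand."""
        return "+" if self.strand == self.coding_strand else "-"

    @property
    def n_subs(self) -> int:
        return len(self.substitutions)

    def hit_id(self) -> str:
        return (
            f"{self.editor}:{self.transcript_id}:c{self.codon_cds_index}"
            f":{self.contig}:{self.span[0]}{self.strand}"
        )


def _span_crosses_junction(start: int, end: int, transcript: TranscriptModel) -> bool:
    return any(start < ie and ib < end for ib, ie in transcript.introns)


def _codon_spans_junction(coords: tuple[int, ...]) -> bool:
    return max(coords) - min(coords) != len(coords) - 1


def _genomic_subs(
    plan: SubstitutionPlan, coords: tuple[int, ...], coding_strand: str
) -> tuple[GenomicSubstitution, ...]:
    subs = []
    for pos, src, dst in zip(plan.positions, plan.from_bases, plan.to_bases):
        if coding_strand == "+":
            subs.append(GenomicSubstitution(coords[pos], src, dst))
        else:
            subs.append(
                GenomicSubstitution(
                    coords[pos], src.translate(_COMP), dst.translate(_COMP)
                )
            )
    return tuple(sorted(subs, key=lambda s: s.pos))


def _transcript_protospacers(
    genome: GenomeAssembly, transcript: TranscriptModel, pad: int = 30
) -> list[Protospacer]:
    seq = genome[transcript.contig]
    lo = min(s for s, _ in transcript.cds_intervals) - pad
    hi = max(e for _, e in transcript.cds_intervals) + pad
    return enumerate_protospacers(seq, transcript.contig, max(0, lo), hi)


def scan_pestop(
    genome: GenomeAssembly,
    transcripts: list[TranscriptModel],
    window: tuple[int, int] = PE_WINDOW,
    max_subs: int = 3,
    whole_codon: bool = True,
) -> list[TargetHit]:
    """Find all prime-editing stop-codon installation sites.

    Every in-frame sense codon lying (wholly, by default) within the
    nick-relative window of some NGG protospacer is reported with its
    minimal stop-conversion plan.  With ``whole_codon=False`` only the
    substituted bases must fall in the window.
    """
    win = EditWindow(*window)
    hits: list[TargetHit] = []
    for t in transcripts:
        cmap = build_cds_map(genome, t)
        contig_seq = genome[t.contig]
        for ps in _transcript_protospacers(genome, t):
            if _span_crosses_junction(ps.start, ps.end, t):
                continue
            window_coords = {
                ps.genomic_at_offset(n) for n in range(win.start, win.end + 1)
            }
            cand_codons = {
                off // 3
                for g in window_coords
                if (off := cmap.cds_offset(g)) is not None
            }
            for k in sorted(cand_codons):
                codon = cmap.codon(k)
                if len(codon) < 3 or codon in STOP_CODONS:
                    continue
                coords = cmap.codon_genomic_coords(k)
                if _codon_spans_junction(coords):
                    continue
                if whole_codon:
                    if not set(coords) <= window_coords:
                        continue
                    try:
                        plan = min_plan(codon, max_subs=max_subs)
                    except ValueError:
                        continue
                else:
                    plan = next(
                        (
                            p
                            for p in stops_reachable(codon, max_subs=max_subs)
                            if all(coords[i] in window_coords for i in p.positions)
                        ),
                        None,
                    )
                    if plan is None:
                        continue
                proto, pam = ps.sequences(contig_seq)
                hits.append(
                    TargetHit(
                        editor=PESTOP,
                        contig=t.contig,
                        strand=ps.strand,
                        transcript_id=t.transcript_id,
                        gene_id=t.gene_id,
                        protospacer=proto,
                        pam=pam,
                        span=(ps.start, ps.end),
                        nick_pos=ps.nick_pos,
                        codon_cds_index=k,
                        codon=codon,
                        plan=plan,
                        substitutions=_genomic_subs(plan, coords, t.strand),
                        coding_strand=t.strand,
                        exon_number=t.exon_number(coords[0]),
                    )
                )
    return hits


def scan_istop(
    genome: GenomeAssembly,
    transcripts: list[TranscriptModel],
    be_window: tuple[int, int] = BE_WINDOW,
) -> list[TargetHit]:
    """Find CBE-convertible stop sites: in-frame CAG/CAA/CGA and TGG codons.

    Coding-strand hits need the codon's C at protospacer positions 4-8 of a
    coding-strand NGG protospacer; TGG hits need the template-strand CCA
    (whose first C pairs the codon's final G) starting at positions 4-8 of a
    template-strand protospacer.  The chosen route's edited bases must all
    sit inside the window.
    """
    win = EditWindow(*be_window)
    hits: list[TargetHit] = []
    for t in transcripts:
        cmap = build_cds_map(genome, t)
        contig_seq = genome[t.contig]
        protos = _transcript_protospacers(genome, t)
        for k in range(cmap.n_codons):
            codon = cmap.codon(k)
            if codon in ISTOP_CODING_CODONS:
                anchor_pos, ps_strand = 0, t.strand
            elif codon == "TGG":
                anchor_pos, ps_strand = 2, "-" if t.strand == "+" else "+"
            else:
                continue
            coords = cmap.codon_genomic_coords(k)
            if _codon_spans_junction(coords):
                continue
            for ps in protos:
                if ps.strand != ps_strand:
                    continue
                if ps.position_of(coords[anchor_pos]) not in win:
                    continue
                if _span_crosses_junction(ps.start, ps.end, t):
                    continue
                route = next(
                    (
                        r
                        for r in cbe_stop_routes(codon)
                        if all(ps.position_of(coords[i]) in win for i in r.positions)
                    ),
                    None,
                )
                if route is None:
                    continue
                proto, pam = ps.sequences(contig_seq)
                hits.append(
                    TargetHit(
                        editor=ISTOP,
                        contig=t.contig,
                        strand=ps.strand,
                        transcript_id=t.transcript_id,
                        gene_id=t.gene_id,
                        protospacer=proto,
                        pam=pam,
                        span=(ps.start, ps.end),
                        nick_pos=ps.nick_pos,
                        codon_cds_index=k,
                        codon=codon,
                        plan=route,
                        substitutions=_genomic_subs(route, coords, t.strand),
                        coding_strand=t.strand,
                        exon_number=t.exon_number(coords[0]),
                    )
                )
    return hits


def scan_isilence(
    genome: GenomeAssembly,
    transcripts: list[TranscriptModel],
    be_window: tuple[int, int] = BE_WINDOW,
    accept_template_adenine: bool = True,
) -> list[TargetHit]:
    """Find ABE start-codon disruption sites (annotated ATG, first exon only).

    The coding-strand A of ATG (A→G gives GTG) or, optionally, the
    template-strand A opposite its T (giving ACG) must fall at protospacer
    positions 4-8.
    """
    win = EditWindow(*be_window)
    hits: list[TargetHit] = []
    for t in transcripts:
        cmap = build_cds_map(genome, t)
        contig_seq = genome[t.contig]
        if cmap.codon(0) != "ATG":
            warnings.warn(
                f"{t.transcript_id}: CDS does not begin with ATG; skipped by "
                "start-codon scan",
                stacklevel=2,
            )
            continue
        if t.start_codon_exon_index() != 0:
            continue  # start codon not in the first exon
        coords = cmap.codon_genomic_coords(0)
        if _codon_spans_junction(coords):
            continue
        routes = [(0, t.strand, "A", "G")]  # coding-strand A of ATG
        if accept_template_adenine:
            routes.append((1, "-" if t.strand == "+" else "+", "T", "C"))
        for anchor, ps_strand, ref_coding, alt_coding in routes:
            for ps in _transcript_protospacers(genome, t):
                if ps.strand != ps_strand:
                    continue
                if ps.position_of(coords[anchor]) not in win:
                    continue
                if _span_crosses_junction(ps.start, ps.end, t):
                    continue
                if t.strand == "+":
                    sub = GenomicSubstitution(coords[anchor], ref_coding, alt_coding)
                else:
                    sub = GenomicSubstitution(
                        coords[anchor],
                        ref_coding.translate(_COMP),
                        alt_coding.translate(_COMP),
                    )
                proto, pam = ps.sequences(contig_seq)
                hits.append(
                    TargetHit(
                        editor=ISILENCE,
                        contig=t.contig,
                        strand=ps.strand,
                        transcript_id=t.transcript_id,
                        gene_id=t.gene_id,
                        protospacer=proto,
                        pam=pam,
                        span=(ps.start, ps.end),
                        nick_pos=ps.nick_pos,
                        codon_cds_index=0,
                        codon="ATG",
                        plan=None,
                        substitutions=(sub,),
                        coding_strand=t.strand,
                        exon_number=t.exon_number(coords[0]),
                    )
                )
    return hits


SCANNERS = {PESTOP: scan_pestop, ISTOP: scan_istop, ISILENCE: scan_isilence}

COVERAGE_LEVELS = ("gene", "transcript", "exon", "early_exon", "orf")


@dataclass
class CoverageReport:
    """Targetable/total record counts per editor at one aggregation level."""

    level: str
    records: list
    targetable: dict[str, set] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return len(self.records)

    def count(self, editor: str) -> int:
        return len(self.targetable.get(editor, set()))

    def percent(self, editor: str) -> float:
        return 100.0 * self.count(editor) / self.total if self.total else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "level": self.level,
                "editor": ed,
                "targetable": self.count(ed),
                "total": self.total,
                "percent": round(self.percent(ed), 4),
            }
            for ed in sorted(self.targetable)
        ]
        return pd.DataFrame(rows)


def coverage_report(
    hits: list[TargetHit], transcripts: list[TranscriptModel], level: str
) -> CoverageReport:
    """Aggregate hits into targetable/total counts at the requested level.

    Levels: gene, transcript, exon (per coding exon, numbered from the
    start-codon exon), early_exon (per transcript, hits restricted to exons
    1..ceil(E/5)), orf (transcript-level over ORF-derived models).
    """
    if level not in COVERAGE_LEVELS:
        raise ValueError(f"unknown coverage level {level!r}; expected {COVERAGE_LEVELS}")
    editors = sorted({h.editor for h in hits}) or [PESTOP]
    by_tid = {t.transcript_id: t for t in transcripts}
    report: CoverageReport

    if level == "gene":
        records = sorted({t.gene_id for t in transcripts})
        targ = {ed: {h.gene_id for h in hits if h.editor == ed} for ed in editors}
    elif level in ("transcript", "orf"):
        records = sorted(by_tid)
        targ = {
            ed: {h.transcript_id for h in hits if h.editor == ed} for ed in editors
        }
    elif level == "exon":
        records = []
        for t in transcripts:
            anchor = t.start_codon_exon_index()
            for i, (s, e) in enumerate(t.exons_5to3()):
                has_cds = any(s < ce and cs < e for cs, ce in t.cds_intervals)
                if has_cds:
                    records.append((t.transcript_id, i - anchor + 1))
        targ = {
            ed: {
                (h.transcript_id, h.exon_number)
                for h in hits
                if h.editor == ed and h.exon_number is not None
            }
            for ed in editors
        }
    else:  # early_exon
        records = sorted(by_tid)
        targ = {}
        for ed in editors:
            ok = set()
            for h in hits:
                if h.editor != ed or h.exon_number is None:
                    continue
                t = by_tid.get(h.transcript_id)
                if t is not None and 1 <= h.exon_number <= early_exon_count(t):
                    ok.add(h.transcript_id)
            targ[ed] = ok
    report = CoverageReport(level, records, targ)
    # guard the invariant targetable <= total
    for ed, s in report.targetable.items():
        report.targetable[ed] = s & set(report.records)
    return report


# ---------------------------------------------------------------------------
# variant-table targetability (ClinVar-style nonsense SNVs)
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = ["contig", "pos", "ref", "alt", "gene", "consequence"]

PE_AND_ISTOP = "PE_and_iSTOP"
PE_ONLY = "PE_only"
ISTOP_ONLY = "ISTOP_only"
NEITHER = "neither"
FILTERED = "filtered"
REF_MISMATCH = "ref_mismatch"
DUPLICATE = "duplicate"


def read_variant_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "alt": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    return df


def read_clinvar_variant_summary(path) -> pd.DataFrame:
    """Map a ClinVar variant_summary-style TSV onto the minimal variant schema."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    colmap = {
        "Chromosome": "contig",
        "PositionVCF": "pos",
        "ReferenceAlleleVCF": "ref",
        "AlternateAlleleVCF": "alt",
        "GeneSymbol": "gene",
        "MolecularConsequence": "consequence",
    }
    missing = [c for c in colmap if c not in raw.columns]
    if missing:
        raise ValueError(f"variant_summary file missing columns: {missing}")
    df = raw[list(colmap)].rename(columns=colmap)
    df["pos"] = df["pos"].astype(int)
    return df


def _pe_targetable(contig_seq, contig, v, window) -> bool:
    win = EditWindow(*window)
    for ps in enumerate_protospacers(contig_seq, contig, v - 35, v + 35):
        if ps.offset_of(v) in win:
            return True
    return False


def _istop_targetable(contig_seq, contig, v, ref, alt, window) -> bool:
    if (ref, alt) == ("C", "T"):
        need = "+"
    elif (ref, alt) == ("G", "A"):
        need = "-"
    else:
        return False
    win = EditWindow(*window)
    for ps in enumerate_protospacers(contig_seq, contig, v - 30, v + 30):
        if ps.strand == need and ps.position_of(v) in win:
            return True
    return False


def variant_targetability(
    variants: pd.DataFrame,
    genome: GenomeAssembly,
    pe_window: tuple[int, int] = PE_WINDOW_WIDE,
    be_window: tuple[int, int] = BE_WINDOW,
) -> pd.DataFrame:
    """Classify nonsense SNVs for installability by PE-STOP and/or iSTOP.

    A record is PE-targetable when some NGG protospacer on either strand
    places the variant base at +1..+9 of the nick; iSTOP-targetable when it
    is a C→T (or G→A) change with the edited base at protospacer positions
    4-8.  Non-nonsense or malformed records are labelled ``filtered``; ref
    mismatches ``ref_mismatch``; repeated gene locations ``duplicate`` --
    none of these enter coverage denominators.
    """
    df = variants.copy().reset_index(drop=True)
    labels: list[str] = []
    seen: set[tuple] = set()
    for row in df.itertuples(index=False):
        cons = str(row.consequence).lower()
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if "nonsense" not in cons or len(ref) != 1 or len(alt) != 1 or ref == alt:
            labels.append(FILTERED)
            continue
        if row.contig not in genome:
            labels.append(REF_MISMATCH)
            continue
        contig_seq = genome[row.contig]
        v = int(row.pos) - 1
        if not (0 <= v < len(contig_seq)) or contig_seq[v] != ref:
            labels.append(REF_MISMATCH)
            continue
        key = (row.gene, row.contig, v)
        if key in seen:
            labels.append(DUPLICATE)
            continue
        seen.add(key)
        pe = _pe_targetable(contig_seq, row.contig, v, pe_window)
        istop = _istop_targetable(contig_seq, row.contig, v, ref, alt, be_window)
        if pe and istop:
            labels.append(PE_AND_ISTOP)
        elif pe:
            labels.append(PE_ONLY)
        elif istop:
            labels.append(ISTOP_ONLY)
        else:
            labels.append(NEITHER)
    df["classification"] = labels
    return df


# ---------------------------------------------------------------------------
# tabular / BED output
# ---------------------------------------------------------------------------


def hits_to_dataframe(hits: list[TargetHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        rows.append(
            {
                "hit_id": h.hit_id(),
                "editor": h.editor,
                "contig": h.contig,
                "strand": h.strand,
                "span_start": h.span[0] + 1,  # 1-based for reporting
                "span_end": h.span[1],
                "nick_pos": h.nick_pos + 1,
                "transcript_id": h.transcript_id,
                "gene_id": h.gene_id,
                "protospacer": h.protospacer,
                "pam": h.pam,
                "codon_index": h.codon_cds_index,
                "codon": h.codon,
                "plan": str(h.plan) if h.plan else "A>G start-codon disruption",
                "n_subs": h.n_subs,
                "exon_number": h.exon_number,
                "substitutions": ";".join(
                    f"{s.pos + 1}{s.ref}>{s.alt}" for s in h.substitutions
                ),
            }
        )
    return pd.DataFrame(rows)


def hits_to_bed(hits: list[TargetHit]) -> pd.DataFrame:
    """BED6+ (0-based half-open) over the protospacer+PAM span; score = n_subs."""
    rows = []
    for h in hits:
        rows.append(
            {
                "chrom": h.contig,
                "chromStart": h.span[0],
                "chromEnd": h.span[1],
                "name": h.hit_id(),
                "score": h.n_subs,
                "strand": h.strand,
                "editor": h.editor,
                "codon": h.codon,
                "plan": str(h.plan) if h.plan else ".",
            }
        )
    return pd.DataFrame(rows)
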