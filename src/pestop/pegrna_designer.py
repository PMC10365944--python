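"""Turn a target hit into reagents: pegRNA, PE3 nicking sgRNA, cloning oligos.

Sizing rules: 13-nt PBS; RTT extends 14 nt past the most distal encoded
edit, growing further while the scaffold-adjacent (5'-most) RTT base would
be a C.  The nicking sgRNA cuts the opposite strand 50-90 bp away, preferring
the candidate closest to 70 bp.  All RNA segments are emitted in the DNA
alphabet (T not U), matching oligo-ordering practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from ._sequences import APPENDICES, SPCAS9_SCAFFOLD
from .genetic_code import STOP_CODONS, SubstitutionPlan, min_plan
from .genome_model import CDSMap, GenomeAssembly, revcomp
from .site_finder import (
    GenomicSubstitution,
    Protospacer,
    TargetHit,
    enumerate_protospacers,
)

DEFAULT_PBS_LEN = 13
DEFAULT_RTT_EXT = 14
NICK_DISTANCE_RANGE = (50, 90)
_NICK_DISTANCE_MIDPOINT = 70


def _downstream(contig_seq: str, nick: int, strand: str, length: int) -> str:
    """PAM-strand sequence 3' of the nick (offsets +1..+length)."""
    if strand == "+":
        return contig_seq[nick : nick + length]
    return revcomp(contig_seq[nick - length : nick])


def _upstream(contig_seq: str, nick: int, strand: str, length: int) -> str:
    """PAM-strand sequence immediately 5' of the nick."""
    if strand == "+":
        return contig_seq[nick - length : nick]
    return revcomp(contig_seq[nick : nick + length])


def _sub_offset(sub: GenomicSubstitution, nick: int, strand: str) -> int:
    return sub.pos - nick + 1 if strand == "+" else nick - sub.pos


def _sub_alt_on_pam_strand(sub: GenomicSubstitution, strand: str) -> str:
    return sub.alt if strand == "+" else str(Seq(sub.alt).complement())


@dataclass(frozen=True)
class MultiStopPlan:
    """Edits converting 1-3 consecutive in-frame codons into stop codons."""

    codon_indices: tuple[int, ...]
    plans: tuple[SubstitutionPlan, ...]
    substitutions: tuple[GenomicSubstitution, ...]

    @property
    def n_stops(self) -> int:
        return len(self.codon_indices)


def plan_multi_stop(
    cds_map: CDSMap,
    hit: TargetHit,
    n_stops: int,
    forced_stops: tuple[str | None, ...] | None = None,
) -> MultiStopPlan:
    """Extend a PE-STOP hit to 2x/3x adjacent stop codons.

    Extra codons are taken moving away from the nick along the PAM strand
    (so the single RTT can encode them); each receives its minimal stop plan
    unless a forced stop codon is supplied.  Spacer and PBS are unaffected.
    """
    if n_stops not in (1, 2, 3):
        raise ValueError("n_stops must be 1, 2 or 3")
    if hit.editor != "PESTOP":
        raise ValueError("multi-stop planning applies to PESTOP hits")
    step = 1 if hit.pam_strand == "+" else -1
    indices = [hit.codon_cds_index + step * i for i in range(n_stops)]
    t = cds_map.transcript
    plans: list[SubstitutionPlan] = [hit.plan]  # type: ignore[list-item]
    subs: list[GenomicSubstitution] = list(hit.substitutions)
    for j, k in enumerate(indices):
        if not 0 <= k < cds_map.n_codons:
            raise ValueError(
                f"insufficient CDS around codon {hit.codon_cds_index} for {n_stops} stops"
            )
        if j == 0:
            continue
        codon = cds_map.codon(k)
        if codon in STOP_CODONS:
            raise ValueError(f"adjacent codon {k} ({codon}) is already a stop codon")
        forced = forced_stops[j] if forced_stops else None
        plan = min_plan(codon, forced_stop=forced)
        plans.append(plan)
        coords = cds_map.codon_genomic_coords(k)
        for pos, src, dst in zip(plan.positions, plan.from_bases, plan.to_bases):
            if t.strand == "+":
                subs.append(GenomicSubstitution(coords[pos], src, dst))
            else:
                comp = str.maketrans("ACGT", "TGCA")
                subs.append(
                    GenomicSubstitution(coords[pos], src.translate(comp), dst.translate(comp))
                )
    subs.sort(key=lambda s: s.pos)
    return MultiStopPlan(tuple(indices), tuple(plans), tuple(subs))


@dataclass(frozen=True)
class PegRNA:
    """A complete pegRNA: spacer + scaffold + RTT + PBS (+ optional 3' appendix)."""

    spacer: str
    scaffold: str
    rtt: str
    pbs: str
    appendix_name: str | None = None
    appendix_seq: str = ""
    contig: str = ""
    strand: str = "+"  # genomic strand of the protospacer/PAM
    nick_pos: int = 0
    substitutions: tuple[GenomicSubstitution, ...] = ()

    @property
    def extension(self) -> str:
        """The 3' extension cloned as one cassette: RTT then PBS (then appendix)."""
        return self.rtt + self.pbs + self.appendix_seq

    @property
    def full_sequence(self) -> str:
        return self.spacer + self.scaffold + self.extension


def build_pegrna(
    genome: GenomeAssembly,
    hit: TargetHit,
    plan: MultiStopPlan | None = None,
    pbs_len: int = DEFAULT_PBS_LEN,
    rtt_ext: int = DEFAULT_RTT_EXT,
    appendix: str | None = None,
    g_prepend: bool = True,
    scaffold: str = SPCAS9_SCAFFOLD,
) -> PegRNA:
    """Assemble the pegRNA encoding a hit's (or multi-stop plan's) edits.

    RTT length = offset of the most 3' edited base + ``rtt_ext``, grown one
    base at a time while its scaffold-adjacent 5' base is a C (reverse
    transcriptase initiates poorly there).  PBS is the reverse complement of
    the ``pbs_len`` bases immediately 5' of the nick on the PAM strand.
    """
    contig_seq = genome[hit.contig]
    subs = plan.substitutions if plan is not None else hit.substitutions
    nick, strand = hit.nick_pos, hit.strand
    offsets = [_sub_offset(s, nick, strand) for s in subs]
    if min(offsets) < 1:
        raise ValueError("an edited base lies 5' of the nick; not encodable in the RTT")
    rtt_len = max(offsets) + rtt_ext
    while True:
        if strand == "+" and nick + rtt_len > len(contig_seq):
            raise ValueError("RTT would run off the contig")
        if strand == "-" and nick - rtt_len < 0:
            raise ValueError("RTT would run off the contig")
        segment = list(_downstream(contig_seq, nick, strand, rtt_len))
        for s, n in zip(subs, offsets):
            segment[n - 1] = _sub_alt_on_pam_strand(s, strand)
        edited = "".join(segment)
        rtt = revcomp(edited)
        if rtt[0] != "C":
            break
        rtt_len += 1  # grow until the scaffold-adjacent base is not a C
    pbs_off_contig = (nick - pbs_len < 0) if strand == "+" else (nick + pbs_len > len(contig_seq))
    if pbs_off_contig:
        raise ValueError("PBS window runs off the contig")
    pbs = revcomp(_upstream(contig_seq, nick, strand, pbs_len))
    spacer = hit.protospacer
    if g_prepend and spacer[0] != "G":
        spacer = "G" + spacer
    app_seq = ""
    if appendix is not None:
        if appendix not in APPENDICES:
            raise ValueError(f"unknown appendix {appendix!r}; known: {sorted(APPENDICES)}")
        app_seq = APPENDICES[appendix]
    return PegRNA(
        spacer=spacer,
        scaffold=scaffold,
        rtt=rtt,
        pbs=pbs,
        appendix_name=appendix,
        appendix_seq=app_seq,
        contig=hit.contig,
        strand=strand,
        nick_pos=nick,
        substitutions=tuple(subs),
    )


@dataclass(frozen=True)
class NickSgRNA:
    """PE3 nicking sgRNA on the strand opposite the pegRNA's PAM strand."""

    spacer: str
    pam: str
    strand: str
    nick_pos: int
    distance: int


def select_nick_sgrna(
    genome: GenomeAssembly,
    contig: str,
    pegrna_nick_pos: int,
    pegrna_strand: str,
    distance_range: tuple[int, int] = NICK_DISTANCE_RANGE,
    search_pad: int = 200,
) -> NickSgRNA | None:
    """Pick the opposite-strand nicking sgRNA whose nick-to-nick distance is
    within ``distance_range``, preferring the candidate closest to 70 bp
    (ties broken toward the smaller distance).  None (with a warning) when
    no NGG protospacer qualifies.
    """
    contig_seq = genome[contig]
    opposite = "-" if pegrna_strand == "+" else "+"
    lo, hi = distance_range
    candidates = []
    for ps in enumerate_protospacers(
        contig_seq, contig, pegrna_nick_pos - search_pad, pegrna_nick_pos + search_pad
    ):
        if ps.strand != opposite:
            continue
        d = abs(ps.nick_pos - pegrna_nick_pos)
        if lo <= d <= hi:
            candidates.append((abs(d - _NICK_DISTANCE_MIDPOINT), d, ps))
    if not candidates:
        warnings.warn(
            f"no opposite-strand NGG protospacer nicks within {distance_range} bp "
            f"of position {pegrna_nick_pos} on {contig}",
            stacklevel=2,
        )
        return None
    _, d, ps = min(candidates, key=lambda c: (c[0], c[1], c[2].start))
    proto, pam = ps.sequences(contig_seq)
    return NickSgRNA(spacer=proto, pam=pam, strand=ps.strand, nick_pos=ps.nick_pos, distance=d)


@dataclass
class ValidationReport:
    """Outcome of applying a pegRNA to its locus in silico."""

    ok: bool
    hamming: int
    expected_subs: int
    pbs_matches: bool
    pam_intact: bool
    stop_indices: tuple[int, ...] = ()
    stops_correct: bool | None = None
    edited_contig: str = ""
    messages: list[str] = field(default_factory=list)


def apply_pegrna(contig_seq: str, pegrna: PegRNA) -> str:
    """Splice the pegRNA-templated edited strand over the nick; return the
    edited contig sequence (+ strand)."""
    edited_downstream = revcomp(pegrna.rtt)  # PAM-strand 5'->3' from the nick
    b, L = pegrna.nick_pos, len(pegrna.rtt)
    if pegrna.strand == "+":
        return contig_seq[:b] + edited_downstream + contig_seq[b + L :]
    return contig_seq[: b - L] + pegrna.rtt + contig_seq[b:]


def validate_pegrna(
    genome: GenomeAssembly,
    hit: TargetHit,
    pegrna: PegRNA,
    cds_map: CDSMap | None = None,
    planned_codon_indices: tuple[int, ...] | None = None,
) -> ValidationReport:
    """In-silico round trip: apply the pegRNA and check it changes exactly the
    planned bases, keeps (or not) the PAM GG, and installs stops where planned."""
    contig_seq = genome[hit.contig]
    msgs: list[str] = []
    pbs_ref = revcomp(_upstream(contig_seq, pegrna.nick_pos, pegrna.strand, len(pegrna.pbs)))
    pbs_ok = pegrna.pbs == pbs_ref
    if not pbs_ok:
        msgs.append("PBS does not match the 13 nt 5' of the nick")
    edited = apply_pegrna(contig_seq, pegrna)
    hamming = sum(a != b for a, b in zip(contig_seq, edited))
    expected = len(pegrna.substitutions)
    if hamming != expected:
        msgs.append(f"Hamming distance {hamming} != planned substitutions {expected}")
    # PAM GG sits at +5/+6 relative to the nick on the PAM strand
    g5 = pegrna.nick_pos + 4 if pegrna.strand == "+" else pegrna.nick_pos - 5
    g6 = pegrna.nick_pos + 5 if pegrna.strand == "+" else pegrna.nick_pos - 6
    pam_intact = all(contig_seq[g] == edited[g] for g in (g5, g6))
    stop_indices: tuple[int, ...] = ()
    stops_correct: bool | None = None
    if cds_map is not None:
        planned = planned_codon_indices or (hit.codon_cds_index,)
        edited_cds = "".join(
            edited[g]
            if cds_map.transcript.strand == "+"
            else str(Seq(edited[g]).complement())
            for g in cds_map.genomic_coords
        )
        protein = str(Seq(edited_cds).translate())
        stop_indices = tuple(i for i, aa in enumerate(protein) if aa == "*")
        stops_correct = all(k in stop_indices for k in planned)
        if not stops_correct:
            msgs.append(f"planned stop codon indices {planned} not all installed")
    ok = pbs_ok and hamming == expected and (stops_correct is not False)
    return ValidationReport(
        ok=ok,
        hamming=hamming,
        expected_subs=expected,
        pbs_matches=pbs_ok,
        pam_intact=pam_intact,
        stop_indices=stop_indices,
        stops_correct=stops_correct,
        edited_contig=edited,
        messages=msgs,
    )


@dataclass(frozen=True)
class CloningOligoSet:
    """Annealing oligos for golden-gate assembly of spacer and 3' extension."""

    spacer_top: str
    spacer_bottom: str
    extension_top: str
    extension_bottom: str

    def reconstruct_spacer(self) -> str:
        return self.spacer_top[4:-5]

    def reconstruct_extension(self) -> str:
        return self.extension_top[4:]


def emit_oligos(pegrna: PegRNA) -> CloningOligoSet:
    """Cloning oligos with the fixed vector overhangs.

    Spacer duplex: top 5'-ACCG + spacer + GTTTC-3'; bottom 5'-CTCTGAAAC +
    revcomp(spacer)-3' (leaves ACCG / CTCT 5' overhangs).  Extension duplex:
    top 5'-GTGC + RTT+PBS(+appendix); bottom 5'-GACA + its reverse complement.
    """
    spacer, ext = pegrna.spacer, pegrna.extension
    return CloningOligoSet(
        spacer_top="ACCG" + spacer + "GTTTC",
        spacer_bottom="CTCTGAAAC" + revcomp(spacer),
        extension_top="GTGC" + ext,
        extension_bottom="GACA" + revcomp(ext),
    )


@dataclass
class DesignRecord:
    """Full reagent set for one target hit."""

    hit: TargetHit
    plan: MultiStopPlan
    pegrna: PegRNA
    nick_sgrna: NickSgRNA | None
    oligos: CloningOligoSet
    validation: ValidationReport


def design_for_hit(
    genome: GenomeAssembly,
    hit: TargetHit,
    cds_map: CDSMap | None = None,
    n_stops: int = 1,
    pbs_len: int = DEFAULT_PBS_LEN,
    rtt_ext: int = DEFAULT_RTT_EXT,
    appendix: str | None = None,
    g_prepend: bool = True,
) -> DesignRecord:
    """One-call design: multi-stop plan, pegRNA, nicking sgRNA, oligos, check."""
    if n_stops > 1 and cds_map is None:
        raise ValueError("multi-stop design needs the transcript's CDS map")
    if n_stops > 1:
        plan = plan_multi_stop(cds_map, hit, n_stops)
    else:
        plan = MultiStopPlan(
            (hit.codon_cds_index,),
            (hit.plan,) if hit.plan else (),
            tuple(hit.substitutions),
        )
    pegrna = build_pegrna(
        genome, hit, plan, pbs_len=pbs_len, rtt_ext=rtt_ext,
        appendix=appendix, g_prepend=g_prepend,
    )
    nick = select_nick_sgrna(genome, hit.contig, hit.nick_pos, hit.strand)
    oligos = emit_oligos(pegrna)
    validation = validate_pegrna(
        genome, hit, pegrna, cds_map=cds_map, planned_codon_indices=plan.codon_indices
    )
    return DesignRecord(hit, plan, pegrna, nick, oligos, validation)


def designs_to_dataframe(designs: list[DesignRecord]) -> pd.DataFrame:
    rows = []
    for d in designs:
        rows.append(
            {
                "hit_id": d.hit.hit_id(),
                "editor": d.hit.editor,
                "contig": d.hit.contig,
                "strand": d.hit.strand,
                "nick_pos": d.hit.nick_pos + 1,
                "n_stops": d.plan.n_stops,
                "codon_indices": ",".join(map(str, d.plan.codon_indices)),
                "spacer": d.pegrna.spacer,
                "pbs": d.pegrna.pbs,
                "rtt": d.pegrna.rtt,
                "appendix": d.pegrna.appendix_name or "",
                "nick_sgrna_spacer": d.nick_sgrna.spacer if d.nick_sgrna else "",
                "nick_sgrna_distance": d.nick_sgrna.distance if d.nick_sgrna else "",
                "n_subs": len(d.plan.substitutions),
                "valid": d.validation.ok,
                "pam_intact": d.validation.pam_intact,
            }
        )
    return pd.DataFrame(rows)


def oligos_to_dataframe(designs: list[DesignRecord]) -> pd.DataFrame:
    rows = []
    for d in designs:
        o = d.oligos
        for name, seq in (
            ("spacer_top", o.spacer_top),
            ("spacer_bottom", o.spacer_bottom),
            ("extension_top", o.extension_top),
            ("extension_bottom", o.extension_bottom),
        ):
            rows.append({"hit_id": d.hit.hit_id(), "oligo": name, "sequence": seq})
    return pd.DataFrame(rows)
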