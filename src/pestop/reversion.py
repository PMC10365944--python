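"""Precise reversion of installed nonsense mutations, and rescue-route taxonomy.

A prime-editing-installed stop codon can often be reverted by a second
pegRNA using the very same PAM, because the edits frequently spare the GG at
nick offsets +5/+6; otherwise an alternative PAM on the edited allele must
place the edited bases back inside the editing window.  CBE-installed stops
(iSTOP) can only be reverted by a different chemistry: an ABE (precise only
when the rescuing protospacer window holds no bystander adenine) or a PE.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome_model import GenomeAssembly, revcomp
from .pegrna_designer import (
    DesignRecord,
    NickSgRNA,
    PegRNA,
    apply_pegrna,
    build_pegrna,
    select_nick_sgrna,
)
from .site_finder import (
    BE_WINDOW,
    PE_WINDOW,
    EditWindow,
    GenomicSubstitution,
    TargetHit,
    enumerate_protospacers,
)

PE_PRECISE = "PE_precise"
ABE_PRECISE = "ABE_precise"
ABE_BYSTANDER = "ABE_bystander"
PE_UNREACHABLE = "PE_unreachable"

#: rescue classes from best to worst for transcript-level summaries
RESCUE_ORDER = (PE_PRECISE, ABE_PRECISE, ABE_BYSTANDER, PE_UNREACHABLE)


class PEUnreachableError(ValueError):
    """No PAM on the edited allele places the edited bases in-window."""


def apply_substitutions(contig_seq: str, subs) -> str:
    out = list(contig_seq)
    for s in subs:
        if out[s.pos] != s.ref:
            raise ValueError(f"reference base mismatch at {s.pos}: {out[s.pos]} != {s.ref}")
        out[s.pos] = s.alt
    return "".join(out)


def _edited_genome(genome: GenomeAssembly, contig: str, subs) -> GenomeAssembly:
    contigs = dict(genome.contigs)
    contigs[contig] = apply_substitutions(contigs[contig], subs)
    return GenomeAssembly(contigs)


def _pam_gg_coords(nick_pos: int, strand: str) -> tuple[int, int]:
    """Genomic + strand coordinates of the PAM GG (nick offsets +5 and +6)."""
    if strand == "+":
        return nick_pos + 4, nick_pos + 5
    return nick_pos - 5, nick_pos - 6


def _sgrna_span(nick: NickSgRNA) -> tuple[int, int]:
    if nick.strand == "+":
        return nick.nick_pos - 17, nick.nick_pos + 6
    return nick.nick_pos - 6, nick.nick_pos + 17


@dataclass
class ReversionDesign:
    """Forward design plus the pegRNA that restores the reference allele."""

    forward: DesignRecord
    reverse_hit: TargetHit
    reverse_pegrna: PegRNA
    reverse_nick_sgrna: NickSgRNA | None
    same_pam: bool
    nick_sgrna_shared: bool

    def restores_reference(self, genome: GenomeAssembly) -> bool:
        """Forward-then-reverse in-silico application is the identity."""
        original = genome[self.forward.hit.contig]
        edited = apply_substitutions(original, self.forward.plan.substitutions)
        return apply_pegrna(edited, self.reverse_pegrna) == original


def _reverse_subs(subs) -> tuple[GenomicSubstitution, ...]:
    return tuple(GenomicSubstitution(s.pos, s.alt, s.ref) for s in subs)


def _offsets_in_window(ps, subs, win: EditWindow) -> bool:
    return all(ps.offset_of(s.pos) in win for s in subs)


def design_reversion(
    genome: GenomeAssembly,
    forward: DesignRecord,
    window: tuple[int, int] = PE_WINDOW,
    pbs_len: int | None = None,
    rtt_ext: int | None = None,
) -> ReversionDesign:
    """Design the pegRNA reverting a forward design's edits on the edited allele.

    When the forward edits spare the PAM GG (+5/+6) the reverse pegRNA reuses
    the forward protospacer location (its spacer read from the edited allele),
    with the RTT templating the reference bases.  Otherwise the edited allele
    is searched for an alternative NGG placing every edited base in-window.
    The forward nicking sgRNA is reused when its site is untouched and still
    within 50-90 bp of the reverse nick.
    """
    hit = forward.hit
    subs = forward.plan.substitutions
    contig_seq = genome[hit.contig]
    edited_seq = apply_substitutions(contig_seq, subs)
    edited_genome = _edited_genome(genome, hit.contig, subs)
    rev_subs = _reverse_subs(subs)
    gg = set(_pam_gg_coords(hit.nick_pos, hit.strand))
    same_pam = not any(s.pos in gg for s in subs)
    win = EditWindow(*window)

    if same_pam:
        span, strand, nick = hit.span, hit.strand, hit.nick_pos
    else:
        best = None
        for ps in enumerate_protospacers(
            edited_seq, hit.contig, min(s.pos for s in subs) - 30, max(s.pos for s in subs) + 30
        ):
            if not _offsets_in_window(ps, rev_subs, win):
                continue
            max_off = max(ps.offset_of(s.pos) for s in rev_subs)
            key = (max_off, ps.start, ps.strand)
            if best is None or key < best[0]:
                best = (key, ps)
        if best is None:
            raise PEUnreachableError(
                "no PAM on the edited allele places the edited bases in-window"
            )
        ps = best[1]
        span, strand, nick = (ps.start, ps.end), ps.strand, ps.nick_pos

    ps_span = edited_seq[span[0] : span[1]]
    if strand == "-":
        ps_span = revcomp(ps_span)
    reverse_hit = TargetHit(
        editor="PESTOP",
        contig=hit.contig,
        strand=strand,
        transcript_id=hit.transcript_id,
        gene_id=hit.gene_id,
        protospacer=ps_span[:20],
        pam=ps_span[20:],
        span=span,
        nick_pos=nick,
        codon_cds_index=hit.codon_cds_index,
        codon=hit.codon,
        plan=None,
        substitutions=rev_subs,
        coding_strand=hit.coding_strand,
        exon_number=hit.exon_number,
    )
    kwargs = {}
    if pbs_len is not None:
        kwargs["pbs_len"] = pbs_len
    if rtt_ext is not None:
        kwargs["rtt_ext"] = rtt_ext
    reverse_pegrna = build_pegrna(
        edited_genome,
        reverse_hit,
        appendix=forward.pegrna.appendix_name,
        **kwargs,
    )

    shared = False
    reverse_nick = None
    if forward.nick_sgrna is not None:
        s, e = _sgrna_span(forward.nick_sgrna)
        untouched = edited_seq[s:e] == contig_seq[s:e]
        d = abs(forward.nick_sgrna.nick_pos - nick)
        if untouched and 50 <= d <= 90 and forward.nick_sgrna.strand != strand:
            shared = True
            reverse_nick = forward.nick_sgrna
    if reverse_nick is None:
        reverse_nick = select_nick_sgrna(edited_genome, hit.contig, nick, strand)
    return ReversionDesign(
        forward=forward,
        reverse_hit=reverse_hit,
        reverse_pegrna=reverse_pegrna,
        reverse_nick_sgrna=reverse_nick,
        same_pam=same_pam,
        nick_sgrna_shared=shared,
    )


def _abe_rescue_class(
    edited_seq: str, contig: str, subs, be_window: tuple[int, int]
) -> str | None:
    """ABE_precise / ABE_bystander / None for a CBE-installed edit.

    The rescuing protospacer must place every edited base (reading A on the
    protospacer strand of the edited allele) at positions 4-8; a bystander is
    any additional in-window adenine on that strand.
    """
    win = EditWindow(*be_window)
    # ABE edits adenines on the protospacer strand: pick the strand where the
    # installed base reads A
    strands = {("+" if s.alt == "A" else "-") if s.alt in "AT" else None for s in subs}
    if None in strands or len(strands) != 1:
        return None
    (need,) = strands
    sub_pos = {s.pos for s in subs}
    found_window = False
    for ps in enumerate_protospacers(
        edited_seq, contig, min(sub_pos) - 30, max(sub_pos) + 30
    ):
        if ps.strand != need:
            continue
        if not all(ps.position_of(p) in win for p in sub_pos):
            continue
        found_window = True
        bystander = False
        for pos in range(win.start, win.end + 1):
            g = ps.start + pos - 1 if ps.strand == "+" else ps.end - pos
            if g in sub_pos:
                continue
            base = edited_seq[g] if ps.strand == "+" else revcomp(edited_seq[g])
            if base == "A":
                bystander = True
                break
        if not bystander:
            return ABE_PRECISE
    return ABE_BYSTANDER if found_window else None


def _pe_rescue_possible(
    genome: GenomeAssembly, contig: str, subs, window: tuple[int, int]
) -> bool:
    """Can a PE place all the reverse edits in-window on the edited allele?"""
    edited = apply_substitutions(genome[contig], subs)
    rev = _reverse_subs(subs)
    win = EditWindow(*window)
    lo = min(s.pos for s in subs) - 30
    hi = max(s.pos for s in subs) + 30
    return any(
        _offsets_in_window(ps, rev, win)
        for ps in enumerate_protospacers(edited, contig, lo, hi)
    )


def classify_rescue(
    genome: GenomeAssembly,
    forward: "DesignRecord | TargetHit",
    primary_editor: str | None = None,
    be_window: tuple[int, int] = BE_WINDOW,
    pe_window: tuple[int, int] = PE_WINDOW,
) -> set[str]:
    """Rescue routes available after installing a nonsense edit.

    ``forward`` may be a full design or a bare hit.  PESTOP primaries:
    PE_precise iff some NGG on the edited allele places the reverse edits
    in-window (always true when the forward edits spare the PAM GG).  ISTOP
    primaries: additionally classified for ABE rescue -- precise when some
    protospacer holds the edited adenine(s) at positions 4-8 with no
    bystander adenine in the window, bystander-prone otherwise; PE rescue is
    evaluated the same way as for PESTOP.
    """
    if isinstance(forward, TargetHit):
        hit, subs = forward, forward.substitutions
    else:
        hit, subs = forward.hit, forward.plan.substitutions
    editor = primary_editor or hit.editor
    classes: set[str] = set()
    if _pe_rescue_possible(genome, hit.contig, subs, pe_window):
        classes.add(PE_PRECISE)
    if editor == "ISTOP":
        edited_seq = apply_substitutions(genome[hit.contig], subs)
        abe = _abe_rescue_class(edited_seq, hit.contig, subs, be_window)
        if abe is not None:
            classes.add(abe)
    if not classes:
        classes.add(PE_UNREACHABLE)
    return classes


def best_rescue_class(classes: set[str]) -> str:
    """Best class under the fixed order PE_precise > ABE_precise > ABE_bystander
    > PE_unreachable (for transcript-level summaries)."""
    for c in RESCUE_ORDER:
        if c in classes:
            return c
    raise ValueError(f"no known rescue class in {classes}")


def reversions_to_dataframe(designs: list[ReversionDesign]) -> pd.DataFrame:
    rows = []
    for d in designs:
        rows.append(
            {
                "forward_hit_id": d.forward.hit.hit_id(),
                "same_pam": d.same_pam,
                "nick_sgrna_shared": d.nick_sgrna_shared,
                "reverse_spacer": d.reverse_pegrna.spacer,
                "reverse_pbs": d.reverse_pegrna.pbs,
                "reverse_rtt": d.reverse_pegrna.rtt,
                "reverse_nick_pos": d.reverse_pegrna.nick_pos + 1,
                "reverse_nick_sgrna": (
                    d.reverse_nick_sgrna.spacer if d.reverse_nick_sgrna else ""
                ),
            }
        )
    return pd.DataFrame(rows)
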