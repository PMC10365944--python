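"""pegRNA assembly rules, nicking-sgRNA selection, oligos, in-silico validation."""

import numpy as np
import pytest

from pestop.genome_model import GenomeAssembly, revcomp
from pestop.pegrna_designer import (
    PegRNA,
    apply_pegrna,
    build_pegrna,
    design_for_hit,
    emit_oligos,
    plan_multi_stop,
    select_nick_sgrna,
    validate_pegrna,
)
from pestop.site_finder import GenomicSubstitution, TargetHit, scan_pestop


def _hit_on(seq, nick, strand="+", subs=(), contig="c"):
    """Hand-built PESTOP hit with the given nick and genomic substitutions."""
    if strand == "+":
        span = (nick - 17, nick + 6)
        proto_pam = seq[span[0] : span[1]]
    else:
        span = (nick - 6, nick + 17)
        proto_pam = revcomp(seq[span[0] : span[1]])
    return TargetHit(
        editor="PESTOP", contig=contig, strand=strand, transcript_id="t1",
        gene_id="g1", protospacer=proto_pam[:20], pam=proto_pam[20:], span=span,
        nick_pos=nick, codon_cds_index=0, codon="NNN", plan=None,
        substitutions=tuple(subs), coding_strand="+",
    )


class TestBuildPegRNA:
    def test_pbs_is_thirteen_and_complementary(self, fixture_genome):
        genome, ts, _ = fixture_genome
        contig = genome["ctgA"]
        for h in scan_pestop(genome, ts)[:25]:
            peg = build_pegrna(genome, h)
            assert len(peg.pbs) == 13
            if h.strand == "+":
                upstream = contig[h.nick_pos - 13 : h.nick_pos]
            else:
                upstream = revcomp(contig[h.nick_pos : h.nick_pos + 13])
            assert peg.pbs == revcomp(upstream)

    def test_rtt_templates_the_edits_and_reference_elsewhere(self, fixture_genome):
        genome, ts, _ = fixture_genome
        contig = genome["ctgA"]
        for h in scan_pestop(genome, ts)[:25]:
            peg = build_pegrna(genome, h)
            flap = revcomp(peg.rtt)  # PAM-strand 5'->3' from the nick
            if h.strand == "+":
                ref = contig[h.nick_pos : h.nick_pos + len(flap)]
            else:
                ref = revcomp(contig[h.nick_pos - len(flap) : h.nick_pos])
            diff = [i for i in range(len(flap)) if flap[i] != ref[i]]
            assert len(diff) == len(h.substitutions)

    def test_scaffold_adjacent_base_never_c(self):
        # reference downstream of the nick ends in Gs, so the naive 15-nt RTT
        # would start with C; the designer must grow it
        seq = "AT" * 20 + "A" * 13 + "T" * 14 + "GG" + "AT" * 20
        # make nick such that +15/+16 are G (RTT first base would be C)
        seq = list("AT" * 40)
        nick = 40
        seq[nick + 14] = "G"  # +15
        seq[nick + 15] = "G"  # +16
        seq[nick + 16] = "A"  # +17 ends the growth
        genome = GenomeAssembly({"c": "".join(seq)})
        hit = _hit_on(genome["c"], nick, subs=[GenomicSubstitution(nick, seq[nick], "G")])
        peg = build_pegrna(genome, hit)
        assert peg.rtt[0] != "C"
        assert len(peg.rtt) == 17  # grown past the two Gs

    def test_g_prepend(self, fixture_genome):
        genome, ts, _ = fixture_genome
        hits = scan_pestop(genome, ts)
        h = next(h for h in hits if h.protospacer[0] != "G")
        assert build_pegrna(genome, h).spacer == "G" + h.protospacer
        assert build_pegrna(genome, h, g_prepend=False).spacer == h.protospacer

    def test_appendix_attached(self, fixture_genome):
        genome, ts, _ = fixture_genome
        h = scan_pestop(genome, ts)[0]
        peg = build_pegrna(genome, h, appendix="xrRNA")
        assert peg.full_sequence.endswith(peg.appendix_seq)
        assert len(peg.appendix_seq) == 80
        with pytest.raises(ValueError):
            build_pegrna(genome, h, appendix="nope")


class TestMultiStop:
    def test_n1_plan_equals_hit_plan(self, fixture_genome, cds_maps):
        genome, ts, _ = fixture_genome
        h = scan_pestop(genome, ts)[0]
        plan = plan_multi_stop(cds_maps[h.transcript_id], h, 1)
        assert plan.substitutions == h.substitutions

    def test_triple_stop_translates_to_three_stops(self, fixture_genome, cds_maps):
        genome, ts, _ = fixture_genome
        done = 0
        for h in scan_pestop(genome, ts):
            cmap = cds_maps[h.transcript_id]
            try:
                d = design_for_hit(genome, h, cds_map=cmap, n_stops=3)
            except ValueError:
                continue
            assert d.validation.stops_correct
            assert set(d.plan.codon_indices) <= set(d.validation.stop_indices)
            done += 1
            if done >= 5:
                break
        assert done >= 5

    def test_substitution_count_monotone_in_n_stops(self, fixture_genome, cds_maps):
        genome, ts, _ = fixture_genome
        h = scan_pestop(genome, ts)[0]
        cmap = cds_maps[h.transcript_id]
        counts = []
        for n in (1, 2, 3):
            counts.append(len(plan_multi_stop(cmap, h, n).substitutions))
        assert counts[0] <= counts[1] <= counts[2]

    def test_spacer_and_pbs_unchanged_across_n_stops(self, fixture_genome, cds_maps):
        genome, ts, _ = fixture_genome
        h = scan_pestop(genome, ts)[0]
        cmap = cds_maps[h.transcript_id]
        d1 = design_for_hit(genome, h, cds_map=cmap, n_stops=1)
        d2 = design_for_hit(genome, h, cds_map=cmap, n_stops=2)
        assert d1.pegrna.spacer == d2.pegrna.spacer
        assert d1.pegrna.pbs == d2.pegrna.pbs
        assert d1.pegrna.rtt != d2.pegrna.rtt

    def test_insufficient_cds_raises(self, fixture_genome, cds_maps):
        genome, ts, _ = fixture_genome
        # a hit on the first codon stepping backwards, or last codons stepping
        # forwards, runs out of CDS
        for h in scan_pestop(genome, ts):
            cmap = cds_maps[h.transcript_id]
            step = 1 if h.pam_strand == "+" else -1
            edge = h.codon_cds_index + 2 * step
            if not 0 <= edge < cmap.n_codons or cmap.codon(edge) in ("TAA", "TAG", "TGA"):
                with pytest.raises(ValueError):
                    plan_multi_stop(cmap, h, 3)
                return
        pytest.skip("no edge hit in fixture")


class TestNickSgRNA:
    @staticmethod
    def _genome_with_candidates(distances):
        # pegRNA nick on '+' at 300; opposite-strand candidates are CC PAMs at
        # q = nick + d - 6 (their nicks land at q + 6)
        seq = list("AT" * 350)
        nick = 300
        for d in distances:
            q = nick + d - 6
            seq[q] = seq[q + 1] = "C"
        return GenomeAssembly({"c": "".join(seq)}), nick

    def test_only_in_range_candidate_selected(self):
        genome, nick = self._genome_with_candidates([40, 72, 95])
        sg = select_nick_sgrna(genome, "c", nick, "+")
        assert sg.distance == 72

    def test_tie_break_toward_seventy(self):
        genome, nick = self._genome_with_candidates([55, 88])
        sg = select_nick_sgrna(genome, "c", nick, "+")
        assert sg.distance == 55  # |55-70| < |88-70|

    def test_no_candidate_returns_none_with_warning(self):
        genome = GenomeAssembly({"c": "AT" * 350})
        with pytest.warns(UserWarning, match="no opposite-strand"):
            assert select_nick_sgrna(genome, "c", 300, "+") is None

    def test_selected_distance_always_in_range(self, fixture_genome):
        genome, ts, _ = fixture_genome
        for h in scan_pestop(genome, ts)[:30]:
            sg = select_nick_sgrna(genome, h.contig, h.nick_pos, h.strand)
            if sg is not None:
                assert 50 <= sg.distance <= 90
                assert sg.strand != h.strand


class TestValidation:
    def test_no_edit_pegrna_is_identity(self, fixture_genome):
        genome, ts, _ = fixture_genome
        h = scan_pestop(genome, ts)[0]
        contig = genome[h.contig]
        if h.strand == "+":
            ref = contig[h.nick_pos : h.nick_pos + 15]
        else:
            ref = revcomp(contig[h.nick_pos - 15 : h.nick_pos])
        peg = PegRNA(
            spacer=h.protospacer, scaffold="", rtt=revcomp(ref), pbs="",
            contig=h.contig, strand=h.strand, nick_pos=h.nick_pos,
        )
        assert apply_pegrna(contig, peg) == contig

    def test_hamming_equals_planned_substitutions(self, fixture_genome, cds_maps):
        genome, ts, _ = fixture_genome
        rng = np.random.default_rng(0)
        hits = scan_pestop(genome, ts)
        for i in rng.choice(len(hits), size=min(30, len(hits)), replace=False):
            h = hits[i]
            d = design_for_hit(genome, h, cds_map=cds_maps[h.transcript_id])
            assert d.validation.ok
            assert d.validation.hamming == len(d.plan.substitutions)
            assert d.validation.stops_correct

    def test_validation_flags_inconsistent_pbs(self, fixture_genome):
        genome, ts, _ = fixture_genome
        h = scan_pestop(genome, ts)[0]
        peg = build_pegrna(genome, h)
        broken = PegRNA(
            spacer=peg.spacer, scaffold=peg.scaffold, rtt=peg.rtt,
            pbs="A" * 13, contig=peg.contig, strand=peg.strand,
            nick_pos=peg.nick_pos, substitutions=peg.substitutions,
        )
        rep = validate_pegrna(genome, h, broken)
        assert not rep.pbs_matches and not rep.ok


class TestOligos:
    def test_spacer_oligo_overhangs(self):
        peg = PegRNA(
            spacer="GACGTTCACGGTAATGACCA", scaffold="X", rtt="AATT", pbs="CCGG"
        )
        o = emit_oligos(peg)
        assert o.spacer_top == "ACCG" + "GACGTTCACGGTAATGACCA" + "GTTTC"
        assert o.spacer_bottom.startswith("CTCTGAAAC")
        assert o.extension_top.startswith("GTGC")
        assert o.extension_bottom.startswith("GACA")

    def test_annealing_reconstruction(self, fixture_genome):
        genome, ts, _ = fixture_genome
        for h in scan_pestop(genome, ts)[:10]:
            peg = build_pegrna(genome, h, appendix="xrRNA")
            o = emit_oligos(peg)
            assert o.reconstruct_spacer() == peg.spacer
            assert o.reconstruct_extension() == peg.extension
            # bottom strands are exact reverse complements of the duplex parts
            assert revcomp(o.spacer_bottom[9:]) == peg.spacer
            assert revcomp(o.extension_bottom[4:]) == peg.extension
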