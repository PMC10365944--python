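"""Scanner geometry on hand-built loci, coverage aggregation, variant classes."""

import pandas as pd
import pytest

from pestop.genome_model import GenomeAssembly, TranscriptModel, revcomp
from pestop.site_finder import (
    coverage_report,
    scan_isilence,
    scan_istop,
    scan_pestop,
    variant_targetability,
)


def single_gene(cds, strand="+", contig="c", utr5="AT" * 10, utr3="TA" * 10):
    """One single-exon transcript; UTRs are AT-repeats (PAM-free)."""
    gene = utr5 + cds + utr3
    seq = gene if strand == "+" else revcomp(gene)
    genome = GenomeAssembly({contig: seq})
    if strand == "+":
        cds_iv = (len(utr5), len(utr5) + len(cds))
        start = cds_iv[0]
    else:
        cds_iv = (len(gene) - len(utr5) - len(cds), len(gene) - len(utr5))
        start = cds_iv[1] - 1
    t = TranscriptModel(
        "t1", "g1", contig, strand, exons=[(0, len(gene))],
        cds_intervals=[cds_iv], start_codon_pos=start,
    )
    return genome, [t]


class TestScanPestop:
    # CGA codon at nick offsets +1..+3, NGG PAM at +4..+6
    CDS = "ATG" + "ATT" * 6 + "CGA" + "AGG" + "ATT" * 2 + "TAA"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_planted_cga_yields_single_substitution_opal_plan(self, strand):
        genome, ts = single_gene(self.CDS, strand=strand)
        hits = [h for h in scan_pestop(genome, ts) if h.codon_cds_index == 7]
        assert len(hits) == 1
        (h,) = hits
        assert h.codon == "CGA"
        assert h.plan.n_subs == 1 and h.plan.product == "TGA"
        assert h.pam.endswith("GG")

    def test_window_containment_boundary(self):
        # PAM moved 5' so the CGA codon sits at +7..+9
        cds = "ATG" + "ATT" * 5 + "AGG" + "CGA" + "ATT" + "TAA"
        genome, ts = single_gene(cds)
        near = [h for h in scan_pestop(genome, ts, window=(1, 6)) if h.codon_cds_index == 7]
        wide = [h for h in scan_pestop(genome, ts, window=(1, 9)) if h.codon_cds_index == 7]
        assert near == []
        assert len(wide) == 1 and wide[0].codon == "CGA"

    def test_window_monotonicity(self, fixture_genome):
        genome, ts, _ = fixture_genome
        sig = lambda h: (h.transcript_id, h.span, h.strand, h.codon_cds_index)  # noqa: E731
        narrow = {sig(h) for h in scan_pestop(genome, ts, window=(1, 6))}
        wide = {sig(h) for h in scan_pestop(genome, ts, window=(1, 9))}
        assert narrow <= wide

    def test_every_hit_satisfies_invariants(self, fixture_genome):
        genome, ts, _ = fixture_genome
        by_tid = {t.transcript_id: t for t in ts}
        for h in scan_pestop(genome, ts):
            assert h.pam[1:] == "GG"
            assert len(h.protospacer) == 20
            t = by_tid[h.transcript_id]
            # span does not overlap any intron
            assert not any(
                h.span[0] < ie and ib < h.span[1] for ib, ie in t.introns
            )
            # nick 3 nt upstream of the PAM on the PAM strand
            expected_nick = h.span[0] + 17 if h.strand == "+" else h.span[0] + 6
            assert h.nick_pos == expected_nick
            # planned edits stay inside the +1..+6 window
            for s in h.substitutions:
                n = (
                    s.pos - h.nick_pos + 1
                    if h.strand == "+"
                    else h.nick_pos - s.pos
                )
                assert 1 <= n <= 6


class TestScanIstop:
    def test_cag_with_c_at_position_four(self):
        cds = "ATG" + "ATT" * 2 + "CAG" + "ATT" * 5 + "GGA" + "ATT" + "TAA"
        genome, ts = single_gene(cds)
        hits = scan_istop(genome, ts)
        assert len(hits) == 1
        (h,) = hits
        assert h.codon == "CAG" and h.codon_cds_index == 3
        assert h.plan.product == "TAG" and h.plan.n_subs == 1

    def test_c_at_position_nine_is_outside_window(self):
        cds = "ATG" + "ATT" * 2 + "CAG" + "ATT" * 3 + "AGG" + "ATT" + "TAA"
        genome, ts = single_gene(cds)
        assert scan_istop(genome, ts) == []

    def test_tgg_uses_template_strand_protospacer(self, fixture_genome):
        genome, ts, truth = fixture_genome
        planted = [s for s in truth.planted_sites if s.codon == "TGG" and s.decoy is None]
        hits = [h for h in scan_istop(genome, ts) if h.codon == "TGG"]
        for s in planted:
            matches = [
                h
                for h in hits
                if h.transcript_id == s.transcript_id
                and h.codon_cds_index == s.codon_cds_index
            ]
            assert matches
            # protospacer sits on the strand opposite the coding strand
            assert all(h.pam_strand == "-" for h in matches)


class TestScanIsilence:
    def test_internal_atg_ignored(self):
        cds = "ATG" + "ATT" * 5 + "ATG" + "ATT" * 5 + "GGT" + "TAA"
        genome, ts = single_gene(cds)
        assert scan_isilence(genome, ts) == []

    def test_start_codon_with_pam(self):
        cds = "ATG" + "ATT" * 5 + "GGT" + "ATT" * 4 + "TAA"
        genome, ts = single_gene(cds)
        hits = scan_isilence(genome, ts)
        assert hits
        start_a = ts[0].start_codon_pos
        assert all(h.substitutions[0].pos in (start_a, start_a + 1) for h in hits)

    def test_start_codon_in_second_exon_excluded(self):
        cds = "ATG" + "ATT" * 5 + "GGT" + "ATT" * 4 + "TAA"
        utr5, utr3 = "AT" * 5, "TA" * 10
        intron = "GT" + "AT" * 48 + "AG"
        seq = "AT" * 20 + intron + utr5 + cds + utr3
        exon1 = (0, 40)
        exon2_start = 40 + len(intron)
        exon2 = (exon2_start, len(seq))
        cds_iv = (exon2_start + len(utr5), exon2_start + len(utr5) + len(cds))
        t = TranscriptModel(
            "t1", "g1", "c", "+", exons=[exon1, exon2],
            cds_intervals=[cds_iv], start_codon_pos=cds_iv[0],
        )
        genome = GenomeAssembly({"c": seq})
        assert scan_isilence(genome, [t]) == []


class TestCoverage:
    def test_empty_hits_zero_everywhere(self, fixture_genome):
        _, ts, _ = fixture_genome
        for level in ("gene", "transcript", "exon", "early_exon"):
            rep = coverage_report([], ts, level)
            assert rep.total > 0
            assert rep.percent("PESTOP") == 0.0

    def test_matches_reference_truth(self, fixture_genome):
        genome, ts, truth = fixture_genome
        hits = scan_pestop(genome, ts) + scan_istop(genome, ts)
        rep_t = coverage_report(hits, ts, "transcript")
        rep_g = coverage_report(hits, ts, "gene")
        for editor in ("PESTOP", "ISTOP"):
            assert rep_t.count(editor) == truth.coverage_truth[editor]["n_transcripts"]
            assert rep_g.count(editor) == truth.coverage_truth[editor]["n_genes"]
            assert sorted(rep_t.targetable[editor]) == truth.coverage_truth[editor]["transcripts"]

    def test_istop_targetable_subset_of_union(self, fixture_genome):
        genome, ts, _ = fixture_genome
        istop = scan_istop(genome, ts)
        union = istop + scan_pestop(genome, ts)
        rep_i = coverage_report(istop, ts, "gene")
        rep_u = coverage_report(union, ts, "gene")
        merged = rep_u.targetable["ISTOP"] | rep_u.targetable["PESTOP"]
        assert rep_i.targetable["ISTOP"] <= merged

    def test_early_exon_restricts_to_leading_exons(self, fixture_genome):
        genome, ts, _ = fixture_genome
        hits = scan_pestop(genome, ts)
        early = coverage_report(hits, ts, "early_exon")
        full = coverage_report(hits, ts, "transcript")
        assert early.targetable["PESTOP"] <= full.targetable["PESTOP"]

    def test_unknown_level_rejected(self, fixture_genome):
        _, ts, _ = fixture_genome
        with pytest.raises(ValueError):
            coverage_report([], ts, "chromosome")

    def test_percentages_recompute_from_counts(self, fixture_genome):
        genome, ts, _ = fixture_genome
        rep = coverage_report(scan_pestop(genome, ts), ts, "exon")
        df = rep.to_frame()
        for row in df.itertuples():
            assert row.percent == pytest.approx(100 * row.targetable / row.total, abs=1e-3)


class TestVariants:
    @pytest.fixture()
    def toy(self):
        seq = list("AT" * 100)
        # v1=50: C ref; GG at 52/53 puts it at +3 of a nick; GG at 67/68 puts
        # it at protospacer position 5 -> PE and iSTOP
        seq[50] = "C"
        seq[52] = seq[53] = "G"
        seq[67] = seq[68] = "G"
        # v2=120: A ref with GG at 122/123 -> PE only (A>T is not a CBE change)
        seq[122] = seq[123] = "G"
        # v3=180: PAM desert (AT background) -> neither
        genome = GenomeAssembly({"c": "".join(seq)})
        variants = pd.DataFrame(
            [
                {"contig": "c", "pos": 51, "ref": "C", "alt": "T", "gene": "g1",
                 "consequence": "nonsense"},
                {"contig": "c", "pos": 121, "ref": "A", "alt": "T", "gene": "g2",
                 "consequence": "nonsense"},
                {"contig": "c", "pos": 181, "ref": "A", "alt": "T", "gene": "g3",
                 "consequence": "nonsense"},
                {"contig": "c", "pos": 31, "ref": "T", "alt": "C", "gene": "g4",
                 "consequence": "missense"},
                {"contig": "c", "pos": 35, "ref": "G", "alt": "A", "gene": "g5",
                 "consequence": "nonsense"},
                {"contig": "c", "pos": 51, "ref": "C", "alt": "T", "gene": "g1",
                 "consequence": "nonsense"},
            ]
        )
        return genome, variants

    def test_toy_table_classifications(self, toy):
        genome, variants = toy
        out = variant_targetability(variants, genome)
        assert list(out["classification"]) == [
            "PE_and_iSTOP", "PE_only", "neither", "filtered", "ref_mismatch",
            "duplicate",
        ]

    def test_window_boundary_plus_nine(self):
        seq = list("AT" * 100)
        seq[96] = seq[97] = "G"  # nick at 92; position 100 is offset +9
        genome = GenomeAssembly({"c": "".join(seq)})
        v = pd.DataFrame(
            [{"contig": "c", "pos": 101, "ref": "A", "alt": "T", "gene": "g",
              "consequence": "nonsense"}]
        )
        wide = variant_targetability(v, genome, pe_window=(1, 9))
        narrow = variant_targetability(v, genome, pe_window=(1, 6))
        assert wide["classification"][0] == "PE_only"
        assert narrow["classification"][0] == "neither"

    def test_g_to_a_at_protospacer_position_three_not_istop(self):
        seq = list("AT" * 100)
        seq[100] = "G"
        seq[80] = seq[81] = "C"  # '-' protospacer placing 100 at position 3
        genome = GenomeAssembly({"c": "".join(seq)})
        v = pd.DataFrame(
            [{"contig": "c", "pos": 101, "ref": "G", "alt": "A", "gene": "g",
              "consequence": "nonsense"}]
        )
        out = variant_targetability(v, genome)
        assert out["classification"][0] == "neither"

    def test_fixture_variant_table_agrees_with_reference(self, fixture_genome):
        from pestop.synthetic_fixtures import make_variant_table

        genome, ts, _ = fixture_genome
        variants, expected = make_variant_table(genome, ts, n_variants=8, seed=2)
        out = variant_targetability(variants, genome)
        assert list(out["classification"]) == list(expected["expected"])
        # the PAM-desert variant really classifies as unreachable
        desert = expected[expected["gene"] == "desert"]
        assert (desert["expected"] == "neither").all()
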