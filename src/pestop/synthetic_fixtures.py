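"""Deterministic synthetic genomes with planted, ground-truth-known edit sites.

Genes are assembled on their coding sense (5' UTR + CDS + 3' UTR, introns
inserted at chosen cut points), then placed on a contig on either strand
with >=200 bp intergenic spacing.  Editable sites are planted by inverse
motif synthesis: the target codon and the NGG PAM are written into the CDS
at the exact geometry each editor requires.  Decoy near-miss sites (wrong
frame, outside the editing window, protospacer crossing an exon junction)
are planted and recorded as excluded.  Regeneration with the same seed and
configuration is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bruteforce
from .genome_model import GenomeAssembly, TranscriptModel, build_cds_map, revcomp
from .genetic_code import SENSE_CODONS, cbe_stop_routes, min_plan

UTR5_LEN = 30
UTR3_LEN = 20

#: codon slots (CDS codon indices) far enough apart that planted spans never
#: overlap each other or the start/stop codons
_SLOTS = (9, 17, 25, 33)

_PESTOP_TARGETS = ("CGA", "CAC", "GAC", "CCC")  # rotated across plants
_ISTOP_TARGETS = ("CAG", "CAA", "CGA", "TGG")


@dataclass
class PlantedSite:
    editor: str
    gene_id: str
    transcript_id: str
    contig: str
    codon_cds_index: int
    cds_offset: int
    codon: str
    expected_edit: str
    genomic_coords: tuple[int, ...] = ()
    decoy: str | None = None  # None = real site; else the exclusion reason


@dataclass
class FixtureTruth:
    planted_sites: list[PlantedSite]
    coverage_truth: dict = field(default_factory=dict)
    variant_truth: pd.DataFrame | None = None
    config: dict = field(default_factory=dict)

    def real_sites(self, editor: str | None = None) -> list[PlantedSite]:
        return [
            s
            for s in self.planted_sites
            if s.decoy is None and (editor is None or s.editor == editor)
        ]

    def decoy_sites(self) -> list[PlantedSite]:
        return [s for s in self.planted_sites if s.decoy is not None]


def _random_bases(rng: np.random.Generator, n: int, gc: float = 0.45) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=n, p=p))


def _random_sense_codons(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(SENSE_CODONS, size=n))


@dataclass
class _GenePlan:
    gene_id: str
    strand: str
    n_exons: int
    cds: list[str]  # mutable per-base CDS (coding sense)
    plants: list[PlantedSite] = field(default_factory=list)
    protected: list[tuple[int, int]] = field(default_factory=list)  # CDS spans no cut may enter
    forced_cuts: list[int] = field(default_factory=list)  # CDS offsets for junction decoys
    free_slots: list[int] = field(default_factory=list)


def _plant_pestop(gp: _GenePlan, slot: int, codon: str, decoy: str | None = None):
    c = 3 * slot
    if decoy == "out_of_window":
        # codon at +7..+9: PAM triplet immediately 5' of the codon; the codon
        # 3' of the target is sanitized so no incidental PAM pulls the target
        # back inside the +1..+6 window
        gp.cds[c : c + 3] = list(codon)
        gp.cds[c - 2] = "G"
        gp.cds[c - 1] = "G"
        gp.cds[c + 3 : c + 6] = list("ATT")
        gp.protected.append((c - 23, c + 6))
    else:
        # codon at +1..+3: nick right before the codon, PAM at +4..+6
        gp.cds[c : c + 3] = list(codon)
        gp.cds[c + 4] = "G"
        gp.cds[c + 5] = "G"
        gp.protected.append((c - 17, c + 6))
    plan = min_plan(codon)
    gp.plants.append(
        PlantedSite(
            editor="PESTOP",
            gene_id=gp.gene_id,
            transcript_id=f"{gp.gene_id}.t1",
            contig="",
            codon_cds_index=slot,
            cds_offset=c,
            codon=codon,
            expected_edit=str(plan),
            decoy=decoy,
        )
    )


def _plant_istop(gp: _GenePlan, slot: int, codon: str, decoy: str | None = None):
    c = 3 * slot
    if decoy == "out_of_frame":
        c += 1  # codon written off-frame; same protospacer geometry
    gp.cds[c : c + 3] = list(codon)
    if codon == "TGG":
        # template-strand protospacer: CCN PAM 5' of the codon places the
        # base pairing the codon's last G at protospacer position 4
        gp.cds[c - 17] = "C"
        gp.cds[c - 16] = "C"
        gp.protected.append((c - 17, c + 6))
    else:
        gp.cds[c + 18] = "G"
        gp.cds[c + 19] = "G"
        gp.protected.append((c - 3, c + 20))
    routes = cbe_stop_routes(codon)
    gp.plants.append(
        PlantedSite(
            editor="ISTOP",
            gene_id=gp.gene_id,
            transcript_id=f"{gp.gene_id}.t1",
            contig="",
            codon_cds_index=c // 3,
            cds_offset=c,
            codon=codon,
            expected_edit=str(routes[0]) if routes else "",
            decoy=decoy,
        )
    )


def _plant_isilence(gp: _GenePlan):
    # A of the start codon at protospacer position 4; PAM at CDS offsets 17-19
    gp.cds[18] = "G"
    gp.cds[19] = "G"
    gp.protected.append((-3, 20))
    gp.plants.append(
        PlantedSite(
            editor="ISILENCE",
            gene_id=gp.gene_id,
            transcript_id=f"{gp.gene_id}.t1",
            contig="",
            codon_cds_index=0,
            cds_offset=0,
            codon="ATG",
            expected_edit=">GTG (A1G)",
            decoy=None,
        )
    )


def _plant_junction_decoy(gp: _GenePlan, slot: int, codon: str):
    _plant_pestop(gp, slot, codon, decoy=None)
    site = gp.plants[-1]
    site.decoy = "junction_span"
    c = 3 * slot
    # every protospacer that could place this codon in the +1..+6 window on
    # the coding-sense NGG side crosses this cut; the codon 5' of the target
    # is sanitized so no CCN PAM offers a junction-free template-side route
    gp.cds[c - 3 : c] = list("TAT")
    gp.forced_cuts.append(c - 8)  # intron inside the protospacer span


def _assemble_gene(
    rng: np.random.Generator, gp: _GenePlan, gc: float
) -> tuple[str, list[tuple[int, int]], list[tuple[int, int]], int]:
    """Return (gene sequence coding sense, exon ivs, CDS ivs, start codon offset),
    all in gene-local coding-sense coordinates."""
    cds = "".join(gp.cds)
    pre = "".join(_random_bases(rng, UTR5_LEN, gc)) + cds + "".join(
        _random_bases(rng, UTR3_LEN, gc)
    )
    cds_lo, cds_hi = UTR5_LEN, UTR5_LEN + len(cds)
    # choose intron cut points (pre-mRNA offsets) outside protected spans
    n_cuts = max(0, gp.n_exons - 1) - len(gp.forced_cuts)
    protected = [(cds_lo + a, cds_lo + b) for a, b in gp.protected]
    cuts = [cds_lo + c for c in gp.forced_cuts]
    candidates = [
        o
        for o in range(cds_lo + 6, cds_hi - 6)
        if not any(a <= o < b for a, b in protected)
        and all(abs(o - c) >= 12 for c in cuts)
    ]
    for _ in range(n_cuts):
        if not candidates:
            break
        o = int(rng.choice(candidates))
        cuts.append(o)
        candidates = [x for x in candidates if abs(x - o) >= 12]
    cuts.sort()
    # splice in introns
    pieces = []
    exon_ivs = []
    pos_map: dict[int, int] = {}
    gpos = 0
    prev = 0
    for cut in cuts + [len(pre)]:
        exon_start = gpos
        for o in range(prev, cut):
            pos_map[o] = gpos
            gpos += 1
        exon_ivs.append((exon_start, gpos))
        pieces.append(pre[prev:cut])
        if cut < len(pre):
            ilen = int(rng.integers(80, 121))
            intron = "GT" + "".join(_random_bases(rng, ilen - 4, gc)) + "AG"
            pieces.append(intron)
            gpos += ilen
        prev = cut
    gene_seq = "".join(pieces)
    # CDS intervals = CDS region intersected with exons, through the map
    cds_ivs = []
    for a, b in zip([0] + cuts, cuts + [len(pre)]):
        lo = max(a, cds_lo)
        hi = min(b, cds_hi)
        if lo < hi:
            cds_ivs.append((pos_map[lo], pos_map[hi - 1] + 1))
    return gene_seq, exon_ivs, cds_ivs, pos_map[cds_lo]


def build_fixture(
    n_genes: int = 6,
    exons_per_gene: int | tuple[int, ...] = (1, 2, 3),
    planted_spec: dict[str, int] | None = None,
    decoys: bool = True,
    n_codons: int = 40,
    seed: int = 0,
    gc: float = 0.45,
    intergenic: tuple[int, int] = (200, 301),
    contig_name: str = "ctgA",
    with_pseudogene: bool = True,
    desert_gene: bool = False,
):
    """Build an in-memory fixture genome with planted sites and ground truth.

    Returns (GenomeAssembly, [TranscriptModel], FixtureTruth).  The same seed
    and arguments reproduce identical sequences and annotations.
    """
    if planted_spec is None:
        planted_spec = {"PESTOP": n_genes}
    rng = np.random.default_rng(seed)
    if isinstance(exons_per_gene, int):
        exon_counts = [exons_per_gene] * n_genes
    else:
        exon_counts = [exons_per_gene[i % len(exons_per_gene)] for i in range(n_genes)]

    plans: list[_GenePlan] = []
    for i in range(n_genes):
        cds = ["A", "T", "G"] + [
            b for codon in _random_sense_codons(rng, n_codons - 2) for b in codon
        ] + ["T", "A", "A"]
        plans.append(
            _GenePlan(
                gene_id=f"gene{i + 1}",
                strand="+" if i % 2 == 0 else "-",
                n_exons=exon_counts[i],
                cds=cds,
                free_slots=list(_SLOTS),
            )
        )

    # distribute planted sites round-robin over genes
    gene_cycle = 0
    rotation = {ed: 0 for ed in planted_spec}
    for editor, count in sorted(planted_spec.items()):
        for _ in range(count):
            for attempt in range(n_genes):
                gp = plans[(gene_cycle + attempt) % n_genes]
                if editor == "ISILENCE":
                    if any(p.editor == "ISILENCE" for p in gp.plants):
                        continue
                    _plant_isilence(gp)
                else:
                    if not gp.free_slots:
                        continue
                    slot = gp.free_slots.pop(0)
                    r = rotation[editor]
                    rotation[editor] += 1
                    if editor == "PESTOP":
                        _plant_pestop(gp, slot, _PESTOP_TARGETS[r % len(_PESTOP_TARGETS)])
                    elif editor == "ISTOP":
                        _plant_istop(gp, slot, _ISTOP_TARGETS[r % len(_ISTOP_TARGETS)])
                    else:
                        raise ValueError(f"unknown editor in planted_spec: {editor}")
                gene_cycle += 1
                break
            else:
                raise ValueError(
                    f"planted_spec infeasible: no remaining slot for a {editor} "
                    f"site across {n_genes} gene(s)"
                )
    if decoys:
        # one decoy of each kind, in the last genes (multi-exon needed for junction)
        for gp in reversed(plans):
            if gp.free_slots and not any(p.decoy == "out_of_window" for s in plans for p in s.plants):
                _plant_pestop(gp, gp.free_slots.pop(0), "CAC", decoy="out_of_window")
                break
        for gp in reversed(plans):
            if gp.free_slots and not any(p.decoy == "out_of_frame" for s in plans for p in s.plants):
                _plant_istop(gp, gp.free_slots.pop(0), "CAG", decoy="out_of_frame")
                break
        for gp in reversed(plans):
            if gp.n_exons >= 2 and gp.free_slots:
                _plant_junction_decoy(gp, gp.free_slots.pop(0), "CGA")
                break

    contig_parts: list[str] = []
    transcripts: list[TranscriptModel] = []
    planted: list[PlantedSite] = []
    extra_features: list[dict] = []
    pos = 0

    def _spacer():
        nonlocal pos
        n = int(rng.integers(*intergenic))
        contig_parts.append("".join(_random_bases(rng, n, gc)))
        pos += n

    for gp in plans:
        _spacer()
        gene_seq, exon_ivs, cds_ivs, start_off = _assemble_gene(rng, gp, gc)
        L = len(gene_seq)
        if gp.strand == "+":
            contig_parts.append(gene_seq)
            exons = [(pos + a, pos + b) for a, b in exon_ivs]
            cds_g = [(pos + a, pos + b) for a, b in cds_ivs]
            start_pos = pos + start_off
        else:
            contig_parts.append(revcomp(gene_seq))
            exons = [(pos + L - b, pos + L - a) for a, b in exon_ivs]
            cds_g = [(pos + L - b, pos + L - a) for a, b in cds_ivs]
            start_pos = pos + L - 1 - start_off
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gp.gene_id}.t1",
                gene_id=gp.gene_id,
                contig=contig_name,
                strand=gp.strand,
                exons=exons,
                cds_intervals=cds_g,
                start_codon_pos=start_pos,
            )
        )
        planted.extend(gp.plants)
        pos += L

    if desert_gene:
        # PAM-desert gene: CDS built from AGT repeats (no GG/CC anywhere) with
        # one GAG codon whose G>T change creates a stop far from any PAM
        _spacer()
        cds = "ATG" + "AGT" * 10 + "GAG" + "AGT" * 10 + "TAA"
        utr5 = "".join("ATA" for _ in range(8))
        utr3 = "".join("TAT" for _ in range(6))
        gene_seq = utr5 + cds + utr3
        contig_parts.append(gene_seq)
        transcripts.append(
            TranscriptModel(
                transcript_id="desert.t1",
                gene_id="desert",
                contig=contig_name,
                strand="+",
                exons=[(pos, pos + len(gene_seq))],
                cds_intervals=[(pos + len(utr5), pos + len(utr5) + len(cds))],
                start_codon_pos=pos + len(utr5),
            )
        )
        extra_features.append({"desert_variant_pos": pos + len(utr5) + 33})
        pos += len(gene_seq)

    if with_pseudogene:
        _spacer()
        pseudo_len = 240
        contig_parts.append("".join(_random_bases(rng, pseudo_len, gc)))
        extra_features.append(
            {
                "pseudogene": ("psi1", pos, pos + pseudo_len),
            }
        )
        pos += pseudo_len
    _spacer()

    genome = GenomeAssembly({contig_name: "".join(contig_parts)})

    # resolve planted sites to genomic coordinates through the CDS maps
    cmap_by_tid = {t.transcript_id: build_cds_map(genome, t) for t in transcripts}
    for site in planted:
        site.contig = contig_name
        cmap = cmap_by_tid[site.transcript_id]
        site.genomic_coords = tuple(
            cmap.genomic_coords[site.cds_offset + j] for j in range(3)
        )

    truth = FixtureTruth(
        planted_sites=planted,
        config={
            "n_genes": n_genes,
            "exons_per_gene": list(exon_counts),
            "planted_spec": planted_spec,
            "decoys": decoys,
            "n_codons": n_codons,
            "seed": seed,
            "gc": gc,
            "contig": contig_name,
            "extra": [
                {k: list(v) if isinstance(v, tuple) else v for k, v in f.items()}
                for f in extra_features
            ],
        },
    )
    truth.coverage_truth = _coverage_truth(genome, transcripts)
    return genome, transcripts, truth


def _coverage_truth(genome, transcripts) -> dict:
    """Per-editor targetable transcript/gene sets from the reference enumerators."""
    out: dict = {}
    for editor, ref in bruteforce.REFERENCE_SCANNERS.items():
        sigs = ref(genome, transcripts)
        tids = {s[0] for s in sigs}
        gids = {t.gene_id for t in transcripts if t.transcript_id in tids}
        out[editor] = {
            "transcripts": sorted(tids),
            "genes": sorted(gids),
            "n_transcripts": len(tids),
            "n_genes": len(gids),
            "total_transcripts": len(transcripts),
            "total_genes": len({t.gene_id for t in transcripts}),
        }
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_fasta(genome: GenomeAssembly, path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n{_wrap(seq)}\n")


def write_gff3(
    transcripts: list[TranscriptModel], path, pseudogenes: list[tuple] = ()
) -> None:
    """Emit gene/mRNA/exon/CDS/start_codon features (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for t in transcripts:
        g_lo = min(s for s, _ in t.exons) + 1
        g_hi = max(e for _, e in t.exons)
        lines.append(
            f"{t.contig}\tsynthetic\tgene\t{g_lo}\t{g_hi}\t.\t{t.strand}\t.\t"
            f"ID={t.gene_id};gene_biotype=protein_coding"
        )
        lines.append(
            f"{t.contig}\tsynthetic\tmRNA\t{g_lo}\t{g_hi}\t.\t{t.strand}\t.\t"
            f"ID={t.transcript_id};Parent={t.gene_id}"
        )
        for j, (s, e) in enumerate(t.exons, 1):
            lines.append(
                f"{t.contig}\tsynthetic\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                f"ID={t.transcript_id}.exon{j};Parent={t.transcript_id}"
            )
        phase = 0
        ivs = t.cds_intervals if t.strand == "+" else list(reversed(t.cds_intervals))
        for j, (s, e) in enumerate(ivs, 1):
            lines.append(
                f"{t.contig}\tsynthetic\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t{phase}\t"
                f"ID={t.transcript_id}.cds{j};Parent={t.transcript_id}"
            )
            phase = (3 - ((e - s) - phase) % 3) % 3
        sc = t.start_codon_pos
        if t.strand == "+":
            lines.append(
                f"{t.contig}\tsynthetic\tstart_codon\t{sc + 1}\t{sc + 3}\t.\t+\t0\t"
                f"ID={t.transcript_id}.start;Parent={t.transcript_id}"
            )
        else:
            lines.append(
                f"{t.contig}\tsynthetic\tstart_codon\t{sc - 1}\t{sc + 1}\t.\t-\t0\t"
                f"ID={t.transcript_id}.start;Parent={t.transcript_id}"
            )
    for name, s, e, contig in pseudogenes:
        lines.append(
            f"{contig}\tsynthetic\tgene\t{s + 1}\t{e}\t.\t+\t.\t"
            f"ID={name};gene_biotype=pseudogene"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def truth_to_frame(truth: FixtureTruth) -> pd.DataFrame:
    rows = []
    for s in truth.planted_sites:
        rows.append(
            {
                "editor": s.editor,
                "gene_id": s.gene_id,
                "transcript_id": s.transcript_id,
                "contig": s.contig,
                "codon_cds_index": s.codon_cds_index,
                "cds_offset": s.cds_offset,
                "codon": s.codon,
                "expected_edit": s.expected_edit,
                "genomic_coords": ",".join(map(str, s.genomic_coords)),
                "status": s.decoy or "planted",
            }
        )
    return pd.DataFrame(rows)


def make_genome(outdir, **kwargs):
    """Generate a fixture genome and write FASTA + GFF3 + truth TSV + manifest.

    Returns (fasta_path, gff_path, FixtureTruth).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, transcripts, truth = build_fixture(**kwargs)
    contig = truth.config["contig"]
    fasta = outdir / "genome.fa"
    gff = outdir / "annotation.gff3"
    write_fasta(genome, fasta)
    pseudo = [
        ("psi1", f["pseudogene"][1], f["pseudogene"][2], contig)
        for f in truth.config["extra"]
        if "pseudogene" in f
    ]
    write_gff3(transcripts, gff, pseudogenes=pseudo)
    truth_to_frame(truth).to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(truth.config, fh, indent=2, sort_keys=True)
    return fasta, gff, truth


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------


def make_variant_table(
    genome: GenomeAssembly,
    transcripts: list[TranscriptModel],
    n_variants: int = 8,
    seed: int = 0,
    ct_ga_fraction: float = 0.6,
    pe_window: tuple[int, int] = (1, 9),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthesize a nonsense-SNV table with known classifications.

    Random CDS positions where a single-base change creates an in-frame stop
    codon become variant rows (base-change classes skewed toward C→T/G→A by
    ``ct_ga_fraction``, echoing real nonsense-variant spectra); a missense
    decoy and a reference-mismatch row are appended.  Returns (variants,
    expected) where expected carries the brute-force classification labels.
    """
    rng = np.random.default_rng(seed)
    candidates_ct = []
    candidates_other = []
    for t in transcripts:
        cmap = build_cds_map(genome, t)
        for k in range(1, cmap.n_codons - 1):
            codon = cmap.codon(k)
            if codon in ("TAA", "TAG", "TGA"):
                continue
            for stop in ("TAA", "TAG", "TGA"):
                diff = [j for j in range(3) if codon[j] != stop[j]]
                if len(diff) != 1:
                    continue
                j = diff[0]
                g = cmap.codon_genomic_coords(k)[j]
                if t.strand == "+":
                    ref, alt = codon[j], stop[j]
                else:
                    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                    ref, alt = comp[codon[j]], comp[stop[j]]
                row = (t.contig, g, ref, alt, t.gene_id)
                if (ref, alt) in (("C", "T"), ("G", "A")):
                    candidates_ct.append(row)
                else:
                    candidates_other.append(row)
    rng.shuffle(candidates_ct)
    rng.shuffle(candidates_other)
    n_ct = min(len(candidates_ct), int(round(n_variants * ct_ga_fraction)))
    chosen = candidates_ct[:n_ct] + candidates_other[: n_variants - n_ct]
    # PAM-desert gene, when present: always include its planted variant
    for t in transcripts:
        if t.gene_id == "desert":
            cmap = build_cds_map(genome, t)
            g = cmap.codon_genomic_coords(11)[0]  # GAG codon; G>T makes TAG
            row = (t.contig, g, "G", "T", t.gene_id)
            if row not in chosen:
                chosen.append(row)
    rows = []
    expected = []
    from .bruteforce import reference_variant_istop, reference_variant_pe

    for contig, g, ref, alt, gene in chosen:
        rows.append(
            {
                "contig": contig,
                "pos": g + 1,
                "ref": ref,
                "alt": alt,
                "gene": gene,
                "consequence": "nonsense",
            }
        )
        pe = reference_variant_pe(genome[contig], g, pe_window)
        istop = reference_variant_istop(genome[contig], g, ref, alt)
        expected.append(
            "PE_and_iSTOP" if pe and istop
            else "PE_only" if pe
            else "ISTOP_only" if istop
            else "neither"
        )
    # decoys: a missense record and a reference-mismatch record
    if chosen:
        contig, g, ref, alt, gene = chosen[0]
        seq = genome[contig]
        m = g + 40
        alt_m = "A" if seq[m] != "A" else "G"
        rows.append(
            {
                "contig": contig,
                "pos": m + 1,
                "ref": seq[m],
                "alt": alt_m,
                "gene": gene,
                "consequence": "missense",
            }
        )
        expected.append("filtered")
        m2 = g + 50
        wrong = "C" if seq[m2] != "C" else "G"
        rows.append(
            {
                "contig": contig,
                "pos": m2 + 1,
                "ref": wrong,
                "alt": "T" if wrong == "C" else "A",
                "gene": gene,
                "consequence": "nonsense",
            }
        )
        expected.append("ref_mismatch")
    variants = pd.DataFrame(rows)
    truth = variants.copy()
    truth["expected"] = expected
    return variants, truth


def mirror_fixture(
    genome: GenomeAssembly, transcripts: list[TranscriptModel]
) -> tuple[GenomeAssembly, list[TranscriptModel]]:
    """Reverse-complement every contig and mirror the annotation accordingly.

    Scanning the mirrored fixture must yield the coordinate-mirrored hit set.
    """
    contigs = {name: revcomp(seq) for name, seq in genome.contigs.items()}
    mirrored = []
    for t in transcripts:
        L = len(genome[t.contig])
        flip = lambda iv: (L - iv[1], L - iv[0])  # noqa: E731
        mirrored.append(
            TranscriptModel(
                transcript_id=t.transcript_id,
                gene_id=t.gene_id,
                contig=t.contig,
                strand="-" if t.strand == "+" else "+",
                exons=[flip(iv) for iv in t.exons],
                cds_intervals=[flip(iv) for iv in t.cds_intervals],
                start_codon_pos=L - 1 - t.start_codon_pos,
            )
        )
    return GenomeAssembly(contigs), mirrored
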