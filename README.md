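# pestop

Design toolkit for installing premature stop codons by **prime editing**
(PE-STOP), with side-by-side support for the CBE-based **iSTOP** and
ABE-based **i-Silence** base-editing strategies.

## The problem

Knocking a gene out without a double-strand break means rewriting a sense
codon into TAA/TAG/TGA (or silencing the start codon). A cytosine base
editor can only do this for codons of three amino acids (Gln, Arg, Trp),
because its chemistry is restricted to C·G → T·A within a narrow protospacer
window. A prime editor — an nCas9(H840A)–reverse-transcriptase fusion
programmed by a pegRNA — writes arbitrary templated substitutions downstream
of its nick, so *every* sense codon of all 20 amino acids is at most three
substitutions away from a stop codon. `pestop` implements the full design
calculus:

- **Genetic-code calculus** — which substitutions turn a codon into which
  stop, under unrestricted (PE) or strand-pure C→T / G→A (CBE) chemistry.
- **Target-site scanners** — PE-STOP sites are in-frame sense codons lying
  wholly within the +1..+6 window downstream of the nick of an NGG
  protospacer (the nick sits 3 nt upstream of the PAM, between protospacer
  positions 17 and 18); iSTOP sites are in-frame CAG/CAA/CGA (coding strand)
  or TGG (template strand) codons with the editable C at protospacer
  positions 4–8; i-Silence sites are annotated start codons in the first
  exon with an editable adenine at positions 4–8. Hits whose
  protospacer+PAM span or target codon crosses an exon junction are
  excluded.
- **Reagent design** — pegRNA assembly with a 13-nt PBS, an RTT extending
  14 nt past the last encoded edit (grown while the scaffold-adjacent base
  would be C), optional 1×/2×/3× adjacent stop codons on a shared
  spacer/PBS, a PE3 nicking sgRNA 50–90 bp away on the opposite strand, and
  golden-gate cloning oligos with fixed vector overhangs.
- **Precise reversion** — when the installed edits spare the PAM GG (nick
  offsets +5/+6), the same protospacer location reverts the stop codon back
  to wild type; otherwise an alternative PAM on the edited allele is
  searched. iSTOP-installed stops are classified for ABE rescue
  (precise vs bystander-prone) and PE rescue.
- **Coverage statistics** — targetable/total counts per gene, transcript,
  exon, early exon (exons 1..⌈E/5⌉, exon 1 holding the start codon) and
  predicted ORF; classification of nonsense-SNV tables (ClinVar-style) as
  PE- and/or iSTOP-installable under the +1..+9 window.
- **Synthetic fixtures** — deterministic genome generators that plant sites
  with known ground truth, so everything is testable offline.

## Worked example

```python
from pestop import (build_fixture, scan_pestop, scan_istop, coverage_report,
                    design_for_hit, build_cds_map)
from pestop.reversion import design_reversion

genome, transcripts, truth = build_fixture(
    n_genes=4, planted_spec={"PESTOP": 2, "ISTOP": 1}, seed=42)
hits = scan_pestop(genome, transcripts)          # window +1..+6, NGG PAM
print(f"{len(hits)} PE-STOP sites across {len(transcripts)} transcripts")

h = next(h for h in hits if h.codon == "CGA")    # arginine, one C>T from TGA
cmap = build_cds_map(genome, next(t for t in transcripts
                                  if t.transcript_id == h.transcript_id))
design = design_for_hit(genome, h, cds_map=cmap)
print("PBS:", design.pegrna.pbs, "| RTT:", design.pegrna.rtt)
print("nick sgRNA distance:", design.nick_sgrna.distance, "bp")

rev = design_reversion(genome, design)
print("same PAM:", rev.same_pam, "| restored:", rev.restores_reference(genome))
```

prints

```
81 PE-STOP sites across 4 transcripts
PBS: CAATGTGGGCCCC | RTT: TCACAACGCCCCATCA
nick sgRNA distance: 71 bp
same PAM: True | restored: True
```

The CGA (Arg) codon is converted to TGA by a single C→T substitution; the
13-nt PBS is the reverse complement of the 13 nt 5′ of the nick, the RTT
(here 16 nt: the edit at +1 plus the 14-nt extension, grown by one base to
avoid a scaffold-adjacent C) templates the edited strand, and because the
edit spares the PAM GG the very same protospacer location supports the
precise T→C reversion. Coverage of this small synthetic genome:

```python
rep = coverage_report(hits + scan_istop(genome, transcripts),
                      transcripts, "transcript")
print(rep.to_frame().to_string(index=False))
#      level editor  targetable  total  percent
# transcript  ISTOP           2      4     50.0
# transcript PESTOP           4      4    100.0
```

The same workflows are available from the shell:

```sh
pestop fixture demo --n-genes 4 --seed 42
pestop scan demo/genome.fa demo/annotation.gff3 -o hits.tsv
pestop design demo/genome.fa demo/annotation.gff3 --n-stops 2 -o designs.tsv
pestop coverage demo/genome.fa demo/annotation.gff3 --level transcript
pestop revert demo/genome.fa demo/annotation.gff3 -o reversions.tsv
```

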