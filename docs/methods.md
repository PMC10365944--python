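# Methods

## Editing model

`pestop` models three DSB-free gene-inactivation chemistries around the
S. pyogenes NGG PAM.

**Prime editing (PE-STOP).** The nCas9(H840A)–RT fusion nicks the
PAM-bearing strand 3 nt upstream of the NGG, between protospacer positions
17 and 18. Edits are referred to by their `+n` offset: `+1` is the first
base 3′ of the nick on the PAM strand, so `+1..+6` covers protospacer
positions 18–20 plus the PAM triplet itself (PE tolerates PAM disruption; an
edit at +5/+6 destroys the GG). A codon is a PE-STOP target when it is an
in-frame sense codon lying *wholly* inside the window of some protospacer on
either strand. Whole-codon containment mirrors the fixed-width motifs the
window definition implies; a relaxed mode (only the substituted bases must
be in-window, `whole_codon=False`) is available. The default window is the
conservative `+1..+6`, where PE efficiency is highest; fixed-location
queries (variant tables) use `+1..+9`.

**iSTOP (CBE).** Cytosine deamination is modelled as strand-pure: a single
editor exposure converts C→T on one strand only, so a codon's routes to a
stop are all-C→T (coding strand: CAG→TAG, CAA→TAA, CGA→TGA) or all-G→A
(coding strand, i.e. C→T on the template strand: TGG→TAG/TGA/TAA). The
activity window is protospacer positions 4–8. Coding-strand hits place the
codon's C there; TGG hits place the template-strand base pairing the codon's
final G there (the CCA complement starting at positions 4–8). An in-frame
filter applies to the target codon in both orientations.

**i-Silence (ABE).** Only the annotated start codon, and only when it lies
in the transcript's first exon, as start-codon disruption relies on the
absence of efficient downstream re-initiation. Both editable adenines are
accepted: the coding-strand A of ATG (→GTG) and the template-strand A
opposite its T (→ACG); either must fall at protospacer positions 4–8 of a
suitably oriented protospacer. The template-adenine route can be disabled
(`accept_template_adenine=False`).

**Exon-junction exclusion.** All scanners work on the genomic sequence, but
a target motif that exists only in the spliced transcript is not a physical
editing site. A hit is therefore discarded when its protospacer+PAM genomic
span overlaps any intron of the transcript, or when the target codon itself
is split across a junction.

## Stop-codon choice

The paper-scale calculus fixes no preference among TAA/TAG/TGA, so the
designer uses a deterministic policy: fewest substitutions first, ties
broken TAA < TAG < TGA. `min_plan(codon, forced_stop=...)` overrides the
policy for a specific product. For a fixed stop codon the substitution set
is unique (exactly the differing positions), so a codon has at most three
plans.

## pegRNA assembly

- **Spacer**: the 20-nt protospacer, with a G prepended when position 1 is
  not G (U6 transcription convention; `g_prepend=False` disables).
- **PBS**: exactly 13 nt, the reverse complement of the 13 bases
  immediately 5′ of the nick on the PAM strand. The fixed length trades a
  small efficiency loss at extreme-GC sites for design determinism.
- **RTT**: reverse complement of the edited PAM-strand segment running from
  the nick through the most 3′ encoded edit plus a 14-nt extension. The RTT
  is grown one base at a time while its 5′-most (scaffold-adjacent) base
  would be C, which impairs reverse transcription initiation.
- **Multi-stop (1×/2×/3×)**: adjacent in-frame codons taken moving away
  from the nick along the PAM strand (the only direction a single RTT can
  encode) each receive their minimal stop plan; spacer and PBS are shared
  across the series, only the RTT differs. Enlarged edits help evade
  MMR-mediated rejection of small mismatches.
- **Nicking sgRNA (PE3)**: the opposite-strand NGG protospacer whose nick
  lies 50–90 bp from the pegRNA nick, preferring the candidate closest to
  70 bp (midpoint of the stated range; ties toward the smaller distance).
- **Cloning oligos**: spacer duplex `ACCG`+spacer+`GTTTC` (top) /
  `CTCTGAAAC`+revcomp (bottom); 3′-extension duplex with `GTGC` / `GACA`
  5′ overhangs. Annealing reconstructs spacer and extension exactly.
- **Scaffold / 3′ appendix**: the canonical sgRNA scaffold ships as a named
  constant; the exoribonuclease-resistant 3′ motif is construct-specific,
  so the bundled `xrRNA` entry is a synthetic placeholder that exercises
  the assembly only and should be overridden with a validated sequence.

All RNA segments are emitted in the DNA alphabet (T not U), matching
oligo-ordering practice. `validate_pegrna` applies the pegRNA in silico —
splicing the reverse complement of the RTT over the nick — and checks that
the Hamming distance to the reference equals the planned substitution count,
that the PBS matches, and (given a CDS map) that stops appear exactly at the
planned codon indices.

## Reversion and rescue classes

A PE-installed stop is precisely revertible by a second pegRNA. When the
forward edits spare the PAM GG (+5/+6), the reverse pegRNA reuses the same
protospacer location with its spacer read from the *edited* allele and the
RTT templating the reference bases, making the two pegRNAs allele-selective;
the forward nicking sgRNA is reused when its site is untouched and still
50–90 bp away. Otherwise the edited allele is searched for an alternative
NGG placing every edited base in-window; failure raises `PEUnreachableError`.
A designed reversion is verified by the involution property: forward then
reverse application restores the reference byte-exactly.

CBE-installed stops are classified for rescue: **ABE_precise** when some
protospacer holds the edited adenine(s) at positions 4–8 of the edited
allele with no other adenine in that window on the protospacer strand;
**ABE_bystander** when every in-window protospacer carries extra window
adenines (reversal would co-mutate them); **PE_precise** when a prime editor
can place the reverse edits in-window; **PE_unreachable** otherwise. The
operational bystander rule (any additional window adenine on the chosen
protospacer's strand) is this package's concretisation of the qualitative
bystander concept; transcript-level summaries take the best class under the
order PE_precise > ABE_precise > ABE_bystander > PE_unreachable.

## Coverage and variant queries

Coverage counts a record as targetable when ≥1 hit falls in its CDS portion.
Levels: gene, transcript, exon (per coding exon, numbered with the
start-codon exon as exon 1), early exon (one record per transcript,
restricted to exons 1..⌈E/5⌉ with E the exon count), and ORF
(transcript-level over single-exon models derived from the six-frame ORF
finder). Duplicate hits on one codon from different PAMs are kept as hits
but deduplicated per record.

Variant tables need `contig, pos, ref, alt, gene, consequence` columns (an
adapter maps ClinVar `variant_summary` columns onto this schema). Records
are filtered to single-nucleotide nonsense changes, checked against the
reference base, and deduplicated by gene location; survivors are classified
by enumerating protospacers in the ±100 bp flank: PE-targetable when the
variant base falls at +1..+9 of some nick, iSTOP-targetable when the change
is C→T (or G→A) with the base at protospacer positions 4–8. Because the two
windows sit on different protospacers, an `ISTOP_only` outcome is possible
alongside `PE_and_iSTOP`, `PE_only` and `neither`.

## Genome model

Coordinates are 0-based half-open internally; GFF3 is converted on load and
written output uses 1-based positions. Only protein-coding genes are kept
(`gene_biotype`/`biotype` equal to `protein_coding`, or absent); pseudogenes
and noncoding biotypes are dropped. A CDS whose length is not a multiple of
3 is trimmed at the 3′ end with a warning; transcripts lacking a
`start_codon` feature anchor the frame at the first CDS base and are flagged
low-confidence. The ORF finder scans all six frames for ATG-initiated ORFs
ending at the first in-frame stop (the stop is required — open-ended ORFs at
sequence edges are dropped), default minimum length 75 nt, nested ORFs
sharing a stop reporting the longest only; all of these are configurable,
75 nt being a common ORF-finder default.

## Synthetic fixtures

The generator assembles genes on their coding sense (30-nt 5′ UTR, CDS of
random sense codons between ATG and TAA, 20-nt 3′ UTR; GT..AG introns of
80–120 nt inserted at cut points that avoid planted spans), places them on a
contig on alternating strands with ≥200 bp intergenic spacing at GC 0.45 —
enough for incidental PAMs at realistic density — and plants sites by
inverse motif synthesis at codon slots spaced so planted spans never
collide. Decoys plant near-miss geometry: a codon at +7..+9 (out of window),
an off-frame CAG, and a protospacer split by an intron; their neighbourhoods
are sanitized so no incidental PAM legitimises them. A PAM-desert gene built
from AGT repeats supports untargetable-variant tests, and a pseudogene
exercises the biotype filter. Everything regenerates byte-identically from
the same seed. Ground-truth coverage and variant classifications come from
the deliberately naive base-by-base enumerators in `pestop.bruteforce`,
which share no code with the optimized scanners and also serve as the
oracle in the test suite.

What the fixtures do *not* emulate: real gene-length and exon-count
distributions, sequence composition biases, repeats, alternative isoforms,
and annotation noise beyond frame-trim cases. Passing tests therefore
demonstrate geometric and combinatorial correctness of the design rules,
not editing-efficiency predictions on real genomes.

## Problem sizes and numerical choices

Tests run on synthetic genomes of ~3–10 kb with 3–6 genes of ~40 codons:
large enough for multi-exon splicing, both strands and incidental sites,
small enough that the exhaustive oracle enumerations stay exact and fast.
Scanner/oracle equivalence is checked exactly (set equality) on 20 seeded
genomes; the pegRNA round-trip and reversion-involution properties are
checked on >100 randomly sampled designs. Genome-scale coverage percentages
on real assemblies depend on the annotation release and are supported as an
ordinary large-input run of the same scanners, not asserted by the tests.

## Known limitations

- NGG PAM only; no PAM-relaxed Cas9 variants.
- No efficiency scoring of pegRNAs (PBS/RTT melting, secondary structure);
  the fixed 13/14-nt sizing rule is a screening default, not an optimum.
- No off-target search; nicking-sgRNA selection considers geometry only.
- Standard genetic code only; selenocysteine recoding and non-standard
  codes are out of scope.
- Stop-codon *insertion* edits are not modelled — only substitutions, which
  keep the nucleotide count unchanged and remain comparable to base-editor
  strategies.
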