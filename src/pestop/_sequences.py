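"""Named reagent sequence constants (DNA alphabet; override as needed).

``SPCAS9_SCAFFOLD`` is the canonical S. pyogenes single-guide scaffold used
in guide/pegRNA expression constructs.

``XRRNA_SYNTHETIC`` is a synthetic stand-in for the ~80-nt
exoribonuclease-resistant 3' stabilisation motif appended to pegRNAs: the
validated motif sequence is construct-specific and should be supplied by the
user (``appendices`` argument / config); this placeholder only exercises the
assembly plumbing and is NOT a functional xrRNA.
"""

SPCAS9_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
)

# synthetic placeholder (not a biological xrRNA); 80 nt
XRRNA_SYNTHETIC = (
    "GGCAGTGCAACTAGCGGTTCAGGTCTCGAAAGGTTAGTGGATCCGCTTAACCGAATGGAGTCCTAGGACTTCAAGCAACG"
)

APPENDICES = {"xrRNA": XRRNA_SYNTHETIC}
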