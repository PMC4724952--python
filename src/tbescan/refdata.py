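"""Published reference features of the four *Oxytricha trifallax* TBE families.

TBE (telomere-bearing element) transposons are Tc1/*mariner*-class DNA
transposons of stichotrich ciliates.  Each complete element carries a pair of
terminal inverted repeats (TIRs) that begin with telomeric repeat sequence,
and three ORFs — a 42kD transposase, a 22kD ORF and a 57kD ORF — with the
22kD ORF in reverse orientation relative to the other two.

This module holds the published per-family TIR consensus sequences and the
associated summary statistics (TIR length, modal TIR-to-ORF distances and the
fraction of copies at the mode) for the four families TBE1, TBE2.1, TBE2.2
(which has two TIR types) and TBE3.  These serve both as reference data for
analyses of real assemblies and as the default TIR templates of the synthetic
genome generator.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Canonical Oxytricha telomeric repeat found at the start of every TBE TIR.
TELOMERIC_CANONICAL = "CAAAACCCCAAAACCCC"  # C A4 C4 A4 C4, 17 nt
#: 16-nt variant (C A4 C4 A4 C3) carried by the TBE2.1 TIR.
TELOMERIC_VARIANT = "CAAAACCCCAAAACCC"

FAMILIES = ("TBE1", "TBE2.1", "TBE2.2", "TBE3")
ORF_ROLES = ("42kD", "22kD", "57kD")

#: Published lengths of the trimmed protein alignments, per ORF (residues).
ORF_LENGTHS = {"42kD": 352, "22kD": 192, "57kD": 471}


@dataclass(frozen=True)
class TIRReference:
    """Published TIR consensus of one family (or TIR type)."""

    family: str
    sequence: str            # 5' TIR consensus, element-forward orientation
    published_length: int    # length as published (bp)
    tsd: str                 # published target-site duplication motif
    dist_to_42kD: int        # modal distance TIR end -> 42kD start (bp)
    dist_from_57kD: int      # modal distance 57kD end -> TIR start (bp)
    pct_at_mode_42kD: float  # % of copies at the modal TIR/42kD distance
    pct_at_mode_57kD: float


# TIR consensus sequences transcribed from the published family table.  The
# transcription source renders each consensus one nucleotide longer than its
# published length (a formatting artifact at the underlined telomeric motif);
# the published lengths are kept alongside and are authoritative for
# length-based comparisons.
TIR_REFERENCES = {
    "TBE1": TIRReference(
        family="TBE1",
        sequence=(
            "CAAAACCCCAAAACCCCTTAATGAGGTTTAA"
            "TAAGTGCTTTGATTTGTAGGGAATTTGTTA"
            "GGGGTTGGGGTTATTAAT"
        ),
        published_length=78,
        tsd="NT",
        dist_to_42kD=3,
        dist_from_57kD=41,
        pct_at_mode_42kD=97.7,
        pct_at_mode_57kD=86.5,
    ),
    "TBE2.1": TIRReference(
        family="TBE2.1",
        sequence=(
            "CAAAACCCCAAAACCCTTTCAGTAGTTTGAA"
            "TTGAGTTTTTGATTGATAAAAGTAGACTAT"
            "TAGTGCATACTTTATTAGGGTTTTAATAGGGTTTATGTAGGGGTTTAATGTTTAAATATTAGTAATTTAAGTGAGTAT"
        ),
        published_length=138,
        tsd="NT",
        dist_to_42kD=0,
        dist_from_57kD=23,
        pct_at_mode_42kD=99.1,
        pct_at_mode_57kD=82.3,
    ),
    "TBE2.2": TIRReference(  # TIR type 1: a 21 bp shorter version of the TBE2.1 TIR
        family="TBE2.2",
        sequence=(
            "CAAAACCCCAAAACCCTTTCAGTAGTTTGAA"
            "TTGAGTTTTTGATTGATAAAAGTAGACTAT"
            "TAGTGCATACTTTATTAGGGTTTTAATAGGGTTTATGTAGGGGTTTAATGTTTAAAT"
        ),
        published_length=117,
        tsd="NT",
        dist_to_42kD=21,
        dist_from_57kD=44,
        pct_at_mode_42kD=96.4,
        pct_at_mode_57kD=86.0,
    ),
    "TBE2.2b": TIRReference(  # TIR type 2 of the TBE2.2 subfamily
        family="TBE2.2",
        sequence=(
            "CAAAACCCCAAAACCCCTGAAGTTGTTTGAA"
            "TTGAGTTTTTGATTGATGAAAGTAGACTAT"
            "TAACGCATGCTTTATTAGGGTTTTAATAGGGTTTATGTAGGGGTTTAGGGTT"
        ),
        published_length=112,
        tsd="NT",
        dist_to_42kD=26,
        dist_from_57kD=49,
        pct_at_mode_42kD=97.6,
        pct_at_mode_57kD=92.1,
    ),
    "TBE3": TIRReference(
        family="TBE3",
        sequence=(
            "CAAAACCCCAAAACCCCTTAGTGAGGTTTAA"
            "TAAGTGCTTTGATTTGTAGGGTATAGTTGG"
            "GGTCTTATTGGGGTTAGTAGAGAAA"
        ),
        published_length=85,
        tsd="NT",
        dist_to_42kD=17,
        dist_from_57kD=54,
        pct_at_mode_42kD=93.3,
        pct_at_mode_57kD=84.6,
    ),
}
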