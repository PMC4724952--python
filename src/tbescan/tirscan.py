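"""Terminal inverted repeats, target-site duplications and the telomeric motif.

TIRs are detected by locally aligning the sequence at the left end of an
element against the reverse complement of its right end — the in-package
equivalent of aligning the two ends of a transposon with BLASTN.  Percent
similarity is therefore always the identity of the best local alignment:
matches divided by alignment columns (including gap columns).  Target-site
duplications are called as the largest exact flanking repeat; the telomeric
motif scan distinguishes the canonical C A4 C4 A4 C4 repeat from the 16-nt
C A4 C4 A4 C3 variant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from Bio import Align

from . import refdata
from .annotate import TBEElement
from .seqcore import GenomeAssembly, Interval, reverse_complement


def _nuc_aligner(mode: str = "local") -> Align.PairwiseAligner:
    """BLASTN-default nucleotide scoring: match 2, mismatch -3, gap 5 + 2k."""
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = 2
    al.mismatch_score = -3
    al.open_gap_score = -7
    al.extend_gap_score = -2
    return al


def _identity_stats(aln) -> tuple[int, int]:
    """(matches, alignment columns) of a Bio.Align alignment."""
    a, b = aln[0], aln[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches, len(a)


def tir_similarity(a: str, b: str) -> float:
    """Percent similarity of two TIR sequences.

    The best local alignment is computed under BLASTN-default scoring and the
    percentage is matches over alignment columns (gap columns included).
    Identical sequences give 100.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _nuc_aligner("local").align(a, b)[0]
    matches, cols = _identity_stats(aln)
    return 100.0 * matches / cols


@dataclass
class TIRPair:
    left: Interval
    right: Interval
    left_seq: str
    right_seq: str
    percent_similarity: float
    alignment_length: int


@dataclass
class TSDCall:
    motif: str
    left_copy: Interval
    right_copy: Interval


@dataclass
class DistanceStats:
    distances: list[int]
    mode: int | None
    fraction_at_mode: float

    @classmethod
    def from_distances(cls, distances: list[int]) -> "DistanceStats":
        if not distances:
            return cls([], None, 0.0)
        counts = Counter(distances)
        top = max(counts.values())
        mode = min(d for d, c in counts.items() if c == top)  # ties -> smaller
        return cls(sorted(distances), mode, top / len(distances))


def _snap_to_motif(window: str, aligned_start: int, slack: int = 25) -> int:
    """Outer terminus of a TIR within its window: the telomeric-motif
    occurrence nearest the alignment start (within ``slack`` bp), else the
    alignment start itself."""
    best = None
    for motif in (refdata.TELOMERIC_CANONICAL, refdata.TELOMERIC_VARIANT):
        i = window.find(motif, max(0, aligned_start - slack))
        if i >= 0 and abs(i - aligned_start) <= slack:
            if best is None or abs(i - aligned_start) < abs(best - aligned_start):
                best = i
    return best if best is not None else aligned_start


def detect_tir(
    element: TBEElement,
    genome: GenomeAssembly,
    window_bp: int = 400,
    inside_bp: int = 100,
    min_len: int = 20,
    min_similarity: float = 70.0,
) -> TIRPair | None:
    """Detect the TIR pair of one element by end self-alignment.

    The 5' window (window_bp outside to inside_bp inside the ORF envelope) is
    locally aligned against the reverse complement of the 3' window.  On
    success the element span is extended to the TIR termini and ``n_tirs`` is
    set to 2; otherwise each window is scanned for the telomeric motif and
    ``n_tirs`` counts the sides carrying it.
    """
    contig_seq = genome[element.contig]
    env = element.orf_envelope()
    lw_start = max(0, env.start - window_bp)
    lw_end = min(len(contig_seq), env.start + inside_bp)
    rw_start = max(0, env.end - inside_bp)
    rw_end = min(len(contig_seq), env.end + window_bp)
    left_w = contig_seq[lw_start:lw_end]
    right_w = contig_seq[rw_start:rw_end]

    pair = None
    if len(left_w) >= min_len and len(right_w) >= min_len:
        rc_right = reverse_complement(right_w)
        aln = _nuc_aligner("local").align(left_w, rc_right)[0]
        matches, cols = _identity_stats(aln)
        if cols >= min_len and 100.0 * matches / cols >= min_similarity:
            (la, lb) = (aln.aligned[0][0][0], aln.aligned[0][-1][1])
            (ra, rb) = (aln.aligned[1][0][0], aln.aligned[1][-1][1])
            # TBE TIRs begin with telomeric repeat sequence; when the motif is
            # visible in a window, snap the outer TIR terminus to it (local
            # alignment alone trims diverged terminal bases, which would shift
            # the element boundary off the true insertion site).
            la = _snap_to_motif(left_w, la)
            ra = _snap_to_motif(rc_right, ra)
            left_iv = Interval(element.contig, lw_start + la, lw_start + lb, element.element_strand)
            right_iv = Interval(element.contig, rw_end - rb, rw_end - ra, element.element_strand)
            if right_iv.start >= left_iv.end:
                pair = TIRPair(
                    left=left_iv,
                    right=right_iv,
                    left_seq=contig_seq[left_iv.start : left_iv.end],
                    right_seq=contig_seq[right_iv.start : right_iv.end],
                    percent_similarity=100.0 * matches / cols,
                    alignment_length=cols,
                )

    if pair is not None:
        element.tir_left = pair.left
        element.tir_right = pair.right
        element.tir_similarity = pair.percent_similarity
        element.n_tirs = 2
        element.span = Interval(
            element.contig,
            min(element.span.start, pair.left.start),
            max(element.span.end, pair.right.end),
            element.element_strand,
        )
        return pair

    # fall back: count sides showing the telomeric motif
    n = 0
    for motif in (refdata.TELOMERIC_CANONICAL, refdata.TELOMERIC_VARIANT):
        if motif in left_w:
            n += 1
            break
    rc = reverse_complement(right_w)
    for motif in (refdata.TELOMERIC_CANONICAL, refdata.TELOMERIC_VARIANT):
        if motif in rc:
            n += 1
            break
    element.n_tirs = n
    return None


def call_tsd(
    element: TBEElement, genome: GenomeAssembly, k_min: int = 2, k_max: int = 10
) -> TSDCall | None:
    """Largest exact repeat shared by the two element flanks.

    Compares the k-mer ending at the element (TIR-extended) start with the
    k-mer starting at the element end, for k from k_max down to k_min; the
    first exact match wins.  Returns None when no k matches.
    """
    seq = genome[element.contig]
    s, e = element.span.start, element.span.end
    for k in range(k_max, k_min - 1, -1):
        if s - k < 0 or e + k > len(seq):
            continue
        if seq[s - k : s] == seq[e : e + k]:
            call = TSDCall(
                motif=seq[s - k : s],
                left_copy=Interval(element.contig, s - k, s),
                right_copy=Interval(element.contig, e, e + k),
            )
            element.tsd = call.motif
            return call
    return None


def five_prime_tir_seq(element: TBEElement, genome: GenomeAssembly) -> str | None:
    """Element-forward sequence of the 5' TIR (starts with telomeric repeat)."""
    if element.element_strand == "+":
        if element.tir_left is None:
            return None
        return genome[element.contig][element.tir_left.start : element.tir_left.end]
    if element.tir_right is None:
        return None
    return reverse_complement(
        genome[element.contig][element.tir_right.start : element.tir_right.end]
    )


def _orf_interval(e: TBEElement, role: str) -> Interval | None:
    """ORF interval, preferring integrity-refined CDS coordinates."""
    if e.cds and role in e.cds:
        return e.cds[role].interval
    if role in e.orf_hits:
        return e.orf_hits[role].interval
    return None


def _with_stop(iv: Interval, genome: GenomeAssembly | None) -> Interval:
    """Extend a CDS interval over its terminal stop codon when present, so
    ORF-to-TIR distances treat the stop as part of the ORF."""
    if genome is None:
        return iv
    seq = genome[iv.contig]
    if iv.strand == "+":
        if seq[iv.end : iv.end + 3] == "TGA":
            return Interval(iv.contig, iv.start, iv.end + 3, "+")
    else:
        if iv.start >= 3 and reverse_complement(seq[iv.start - 3 : iv.start]) == "TGA":
            return Interval(iv.contig, iv.start - 3, iv.end, "-")
    return iv


def distance_stats(
    elements: list[TBEElement], genome: GenomeAssembly | None = None
) -> tuple[DistanceStats, DistanceStats]:
    """Distances between the 5' TIR inner end and the 42kD start, and between
    the 57kD end (terminal stop included when the genome is supplied) and the
    3' TIR inner start, element-forward, in bp."""
    d5: list[int] = []
    d3: list[int] = []
    for e in elements:
        if e.tir_left is None or e.tir_right is None:
            continue
        iv42 = _orf_interval(e, "42kD")
        iv57 = _orf_interval(e, "57kD")
        if iv57 is not None:
            iv57 = _with_stop(iv57, genome)
        if e.element_strand == "+":
            if iv42 is not None:
                d5.append(iv42.start - e.tir_left.end)
            if iv57 is not None:
                d3.append(e.tir_right.start - iv57.end)
        else:
            if iv42 is not None:
                d5.append(e.tir_right.start - iv42.end)
            if iv57 is not None:
                d3.append(iv57.start - e.tir_left.end)
    return DistanceStats.from_distances(d5), DistanceStats.from_distances(d3)


# ---------------------------------------------------------------------------
# Consensus building (greedy centroid clustering, UCLUST-style)
# ---------------------------------------------------------------------------

def _edlib_identity(a: str, b: str) -> float:
    res = edlib.align(a, b, task="path")
    cigar = res["cigar"]
    cols = eq = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch == "=":
                eq += n
    return eq / cols if cols else 0.0


def tir_consensus(
    seqs: list[str], identity_threshold: float = 0.9
) -> list[tuple[str, int]]:
    """Greedy centroid clustering with majority-rule consensus.

    Sequences are taken longest-first as centroids; each sequence joins the
    first centroid with identity >= the threshold.  The consensus is the
    per-centroid-column majority over centroid-anchored pairwise alignments
    (majority deletion removes the column; insertions relative to the
    centroid are ignored).
    """
    if not seqs:
        raise ValueError("no sequences")
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), i))
    centroids: list[int] = []
    members: dict[int, list[int]] = {}
    for i in order:
        for c in centroids:
            if _edlib_identity(seqs[i], seqs[c]) >= identity_threshold:
                members[c].append(i)
                break
        else:
            centroids.append(i)
            members[i] = [i]

    out = []
    for c in centroids:
        cent = seqs[c]
        votes: list[Counter] = [Counter() for _ in cent]
        for i in members[c]:
            res = edlib.align(seqs[i], cent, task="path")
            qpos = cpos = 0
            num = ""
            for ch in res["cigar"]:
                if ch.isdigit():
                    num += ch
                    continue
                n = int(num)
                num = ""
                if ch in "=X":
                    for t in range(n):
                        votes[cpos + t][seqs[i][qpos + t]] += 1
                    qpos += n
                    cpos += n
                elif ch == "I":  # insertion relative to centroid
                    qpos += n
                else:  # deletion: query lacks these centroid columns
                    for t in range(n):
                        votes[cpos + t]["-"] += 1
                    cpos += n
        cons = "".join(
            v.most_common(1)[0][0] for v in votes if v and v.most_common(1)[0][0] != "-"
        )
        out.append((cons, len(members[c])))
    return out


def scan_telomeric(tir: str) -> tuple[str, int]:
    """Locate the telomeric repeat in a TIR: ('canonical'|'variant'|'absent',
    offset).  The canonical 17-nt motif is checked before the 16-nt variant."""
    i = tir.find(refdata.TELOMERIC_CANONICAL)
    if i >= 0:
        return ("canonical", i)
    i = tir.find(refdata.TELOMERIC_VARIANT)
    if i >= 0:
        return ("variant", i)
    return ("absent", -1)


def tir_table(elements: list[TBEElement], genome: GenomeAssembly) -> pd.DataFrame:
    """Per-family TIR/TSD summary in the shape of the published family table:
    TIR consensus, telomeric-motif class, most common TSD, modal distances."""
    rows = []
    by_family: dict[str, list[TBEElement]] = {}
    for e in elements:
        by_family.setdefault(e.family or "unclassified", []).append(e)
    for fam in sorted(by_family):
        group = by_family[fam]
        tirs = [s for s in (five_prime_tir_seq(e, genome) for e in group) if s]
        consensus = tir_consensus(tirs)[0][0] if tirs else ""
        motif_class = scan_telomeric(consensus)[0] if consensus else "absent"
        tsds = Counter(e.tsd for e in group if e.tsd)
        sims = [e.tir_similarity for e in group if e.tir_similarity is not None]
        d5, d3 = distance_stats(group, genome)
        rows.append(
            {
                "family": fam,
                "n": len(group),
                "tir_consensus": consensus,
                "tir_length": len(consensus),
                "telomeric_motif": motif_class,
                "tir_similarity_mean": float(np.mean(sims)) if sims else np.nan,
                "tir_similarity_sd": float(np.std(sims, ddof=1)) if len(sims) > 1 else np.nan,
                "tsd": tsds.most_common(1)[0][0] if tsds else "",
                "dist_tir_42kD_mode": d5.mode,
                "dist_tir_42kD_pct_mode": 100.0 * d5.fraction_at_mode,
                "dist_57kD_tir_mode": d3.mode,
                "dist_57kD_tir_pct_mode": 100.0 * d3.fraction_at_mode,
            }
        )
    return pd.DataFrame(rows)
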