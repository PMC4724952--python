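"""Protein-guided CDS extraction tolerant of frameshifts and premature stops.

A frameshift-aware local dynamic program aligns an ORF protein query to a
genomic region, allowing codon advances (scored on the ciliate-code
translation), in-frame stop codons (fixed penalty, recorded), 1-nt
frameshifts (the DNA advances 2 or 4 nt for one query residue, fixed
penalty, recorded) and affine codon gaps.  The best local path on either
strand is kept.  Extracted coding sequences can then be repaired — frameshift
indels undone and stop codons masked to NNN — for downstream substitution
rate estimation, and per-residue stop-codon profiles expose positional
hotspots like the published residue-70 stop enrichment in TBE3 transposases.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import _align
from .seqcore import CILIATE_CODE, GeneticCode, GenomeAssembly, Interval, reverse_complement


@dataclass
class P2DPenalties:
    """Scoring for protein-to-DNA alignment (BLOSUM62 scale).

    The frameshift penalty is chosen so that one frameshift is preferred over
    abandoning an alignment of more than a few residues; the stop penalty
    lets alignments pass through isolated in-frame TGA codons.
    """

    gap_open: int = 11
    gap_extend: int = 1
    frameshift: int = -15
    stop: int = -10


@dataclass
class CDSAlignment:
    """Protein-guided extraction of one coding region."""

    role: str
    query: str
    interval: Interval            # genomic CDS span (terminal stop excluded)
    strand: str
    score: int
    query_start: int              # aa, 0-based half-open coverage of the query
    query_end: int
    frameshift_ops: list[tuple[int, int]]   # (query codon index 0-based, +1|-1)
    stop_positions: list[int]               # query residue indices with in-frame TGA
    aligned_protein: str          # translation in query coordinates ('-' = gap)
    ops: np.ndarray = field(repr=False)     # raw op codes for repair
    region_seq: str = field(repr=False)     # oriented region the ops refer to
    region_target_start: int = field(repr=False)  # nt offset of ops within region_seq

    @property
    def query_coverage(self) -> float:
        return (self.query_end - self.query_start) / len(self.query)


@dataclass
class IntegrityCall:
    role: str
    has_premature_stop: bool
    has_frameshift: bool
    n_stops: int
    n_frameshifts: int


@dataclass
class StopCodonProfile:
    family: str
    role: str
    n_copies: int
    fractions: np.ndarray         # per-residue fraction of covering copies with a stop
    coverage: np.ndarray          # copies covering each residue
    hotspots: list[tuple[int, float]]  # (residue 0-based, fraction), descending


def align_protein_to_dna(
    query: str,
    region: str,
    penalties: P2DPenalties | None = None,
    code: GeneticCode = CILIATE_CODE,
    role: str = "",
    contig: str = "",
    region_start: int = 0,
    try_both_strands: bool = True,
) -> CDSAlignment:
    """Best frameshift-aware local alignment of ``query`` against ``region``
    (both strands unless disabled).

    ``region_start``/``contig`` georeference the region so the returned
    interval is genomic; with the defaults the interval is region-local.
    """
    pen = penalties or P2DPenalties()
    if len(region) < 30:
        raise ValueError("region shorter than 30 nt")
    qidx = _align.encode_protein(query)
    aa_of, is_stop = _align.codon_tables(code)
    best = None
    for strand, seq in (("+", region), ("-", reverse_complement(region))):
        tidx = _align.encode_nucleotides(seq)
        res = _align.p2d_align(
            qidx, tidx, _align.BLOSUM62, aa_of, is_stop,
            pen.gap_open, pen.gap_extend, pen.frameshift, pen.stop,
        )
        if best is None or res[0] > best[0]:
            best = res
            best_strand, best_seq = strand, seq
        if not try_both_strands:
            break
    score, qs, qe, ts, te, ops = best
    strand, seq = best_strand, best_seq
    qs, qe, ts, te, ops = _trim_weak_ends(ops, qs, ts, qidx, seq, aa_of, is_stop)

    # interpret the ops
    frameshifts: list[tuple[int, int]] = []
    stops: list[int] = []
    aligned = ["-"] * len(query)
    qpos, tpos = qs, ts
    for op in ops:
        if op == _align.P2D_MATCH:
            codon = seq[tpos : tpos + 3]
            aa = code.amino_acid(codon)
            if code.is_stop(codon):
                stops.append(qpos)
                aligned[qpos] = "*"
            else:
                aligned[qpos] = aa
            qpos += 1
            tpos += 3
        elif op == _align.P2D_FS2:
            frameshifts.append((qpos, -1))
            aligned[qpos] = "X"
            qpos += 1
            tpos += 2
        elif op == _align.P2D_FS4:
            frameshifts.append((qpos, +1))
            aligned[qpos] = "X"
            qpos += 1
            tpos += 4
        elif op == _align.P2D_DEL:
            qpos += 1
        else:  # P2D_INS
            tpos += 3

    if not contig:
        contig = "region"
        glen = len(region)
    else:
        glen = None
    if strand == "+":
        iv = Interval(contig, region_start + ts, region_start + te, "+")
    else:
        iv = Interval(contig, region_start + len(region) - te, region_start + len(region) - ts, "-")
    return CDSAlignment(
        role=role,
        query=query,
        interval=iv,
        strand=strand,
        score=int(score),
        query_start=qs,
        query_end=qe,
        frameshift_ops=frameshifts,
        stop_positions=stops,
        aligned_protein="".join(aligned),
        ops=ops,
        region_seq=seq,
        region_target_start=ts,
    )


def _trim_weak_ends(ops, qs, ts, qidx, seq, aa_of, is_stop, min_segment_score: int = 30):
    """Peel weakly supported terminal segments that hang beyond a frameshift
    or gap operation.

    Local alignment can extend past the true coding region into flanking
    sequence shared by related copies, bridging to a few chance matches with
    a frameshift or gap; such phantom terminal segments are separated from
    the alignment body by a non-match op and carry little substitution score.
    A terminal segment (run of codon ops outside the outermost frameshift or
    gap op) is removed when its summed substitution score is below
    ``min_segment_score``; genuinely diverged terminal sequence without an
    intervening frameshift is never touched.
    """
    nt_index = {"A": 0, "C": 1, "G": 2, "T": 3}

    def match_score(qpos: int, tpos: int) -> int:
        codon = seq[tpos : tpos + 3]
        if any(c not in nt_index for c in codon):
            return -1
        k = 16 * nt_index[codon[0]] + 4 * nt_index[codon[1]] + nt_index[codon[2]]
        if is_stop[k]:
            return -10
        return int(_align.BLOSUM62[qidx[qpos], aa_of[k]])

    def walk(ops_list, qpos, tpos):
        pos = []
        for op in ops_list:
            pos.append((qpos, tpos))
            if op == _align.P2D_MATCH:
                qpos, tpos = qpos + 1, tpos + 3
            elif op == _align.P2D_FS2:
                qpos, tpos = qpos + 1, tpos + 2
            elif op == _align.P2D_FS4:
                qpos, tpos = qpos + 1, tpos + 4
            elif op == _align.P2D_DEL:
                qpos += 1
            else:
                tpos += 3
        return pos, qpos, tpos

    changed = True
    while changed and len(ops):
        changed = False
        pos, qe, te = walk(ops, qs, ts)
        n = len(ops)
        nonmatch = [i for i in range(n) if ops[i] != _align.P2D_MATCH]
        if not nonmatch:
            break
        # prefix segment before the first non-match op
        first = nonmatch[0]
        prefix_score = sum(match_score(*pos[i]) for i in range(first))
        if prefix_score < min_segment_score and first < n - 1:
            qs, ts = pos[first + 1]
            ops = ops[first + 1 :]
            changed = True
            continue
        # suffix segment after the last non-match op
        last = nonmatch[-1]
        suffix_score = sum(match_score(*pos[i]) for i in range(last + 1, n))
        if suffix_score < min_segment_score and last > 0:
            ops = ops[:last]
            changed = True
    pos, qe, te = walk(ops, qs, ts)
    return qs, qe, ts, te, ops


def call_integrity(cds: CDSAlignment) -> IntegrityCall:
    """Premature stop = any in-frame stop strictly before the last aligned
    residue; a stop at the final aligned residue is terminal."""
    last = cds.query_end - 1
    premature = [p for p in cds.stop_positions if p < last]
    return IntegrityCall(
        role=cds.role,
        has_premature_stop=bool(premature),
        has_frameshift=bool(cds.frameshift_ops),
        n_stops=len(premature),
        n_frameshifts=len(cds.frameshift_ops),
    )


def repair_sequence(cds: CDSAlignment) -> tuple[list[str], int]:
    """Undo frameshifts and mask stops, returning (codons, query_start).

    Codon i of the output corresponds to query residue ``query_start + i``.
    Frameshift codons keep their recoverable nucleotides (an inserted
    nucleotide is dropped, a deleted one restored as N); stop codons and
    codons deleted from the DNA become NNN.  Requires >= 50% query coverage.
    """
    if cds.query_coverage < 0.5:
        raise ValueError(
            f"alignment covers only {cds.query_coverage:.0%} of the query; "
            "copy excluded from rate analysis"
        )
    codons: list[str] = []
    seq = cds.region_seq
    tpos = cds.region_target_start
    for op in cds.ops:
        if op == _align.P2D_MATCH:
            codon = seq[tpos : tpos + 3]
            codons.append("NNN" if CILIATE_CODE.is_stop(codon) else codon)
            tpos += 3
        elif op == _align.P2D_FS2:
            codons.append(seq[tpos : tpos + 2] + "N")
            tpos += 2
        elif op == _align.P2D_FS4:
            codons.append(seq[tpos : tpos + 3])
            tpos += 4
        elif op == _align.P2D_DEL:
            codons.append("NNN")
        else:  # P2D_INS: extra DNA codon, dropped
            tpos += 3
    return codons, cds.query_start


def consensus_protein(alignments: list[CDSAlignment], query_length: int) -> str:
    """Column-majority consensus over query-coordinate aligned proteins.

    Used as the per-family extraction query in the refinement pass; columns
    with no information fall back to X (never matches).
    """
    cols = []
    for i in range(query_length):
        votes = Counter()
        for a in alignments:
            ch = a.aligned_protein[i]
            if ch not in ("-", "*", "X"):
                votes[ch] += 1
        cols.append(votes.most_common(1)[0][0] if votes else "X")
    return "".join(cols)


def stop_profile(
    group: list[CDSAlignment],
    family: str = "",
    role: str = "",
    hotspot_threshold: float = 0.10,
) -> StopCodonProfile:
    """Per-residue stop-codon fractions for one family x role group.

    The denominator at each residue is the number of copies whose alignment
    covers that residue.
    """
    if not group:
        raise ValueError("empty group")
    n_res = len(group[0].query)
    stops = np.zeros(n_res)
    cover = np.zeros(n_res)
    for a in group:
        cover[a.query_start : a.query_end] += 1
        for p in a.stop_positions:
            stops[p] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(cover > 0, stops / np.maximum(cover, 1), 0.0)
    hotspots = sorted(
        ((int(i), float(frac[i])) for i in np.flatnonzero(frac >= hotspot_threshold)),
        key=lambda t: -t[1],
    )
    return StopCodonProfile(
        family=family,
        role=role,
        n_copies=len(group),
        fractions=frac,
        coverage=cover,
        hotspots=hotspots,
    )
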