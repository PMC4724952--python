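"""Six-frame translated local-alignment search of ORF proteins against a genome.

Every frame of every contig is translated under the ciliate code and scanned
with an exact Smith-Waterman (BLOSUM62, affine gaps); no heuristic seeding is
used, so reported scores are optimal local-alignment scores.  E-values use the
Karlin-Altschul approximation E = K*m*n*exp(-lambda*S) with fixed constants
for BLOSUM62 with gap penalties 11/1; the statistics are therefore approximate
relative to NCBI BLAST, but the default E <= 1e-7 cutoff plays the same role.

For efficiency the genome scan proceeds in two passes: a linear-memory scoring
sweep records the best local score ending in every target column, and full
alignments with traceback are recomputed only inside windows around columns
that beat the score threshold.  Windows expand adaptively if an alignment
touches a window edge, so the reported hit set above threshold is that of the
unwindowed search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _align
from .seqcore import CILIATE_CODE, GeneticCode, GenomeAssembly, Interval, reverse_complement, translate


@dataclass
class ScoringScheme:
    """Scoring parameters for translated search.

    A gap of length k costs ``gap_open + k * gap_extend`` (NCBI convention).
    ``karlin_lambda`` and ``karlin_k`` are the E-value constants; the defaults
    are the standard gapped BLOSUM62 (11/1) values.
    """

    matrix: np.ndarray = field(default_factory=lambda: _align.BLOSUM62)
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    evalue_threshold: float = 1e-7

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.evalue_threshold <= 0:
            raise ValueError("E-value threshold must be positive")

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.karlin_k * m * n * math.exp(-self.karlin_lambda * score)

    def bitscore(self, score: float) -> float:
        return (self.karlin_lambda * score - math.log(self.karlin_k)) / math.log(2)

    def min_score(self, m: int, n: int) -> int:
        """Smallest integer raw score whose E-value is <= the threshold."""
        s = math.log(self.karlin_k * m * n / self.evalue_threshold) / self.karlin_lambda
        return max(1, math.ceil(s))


@dataclass
class Frame:
    """One translated reading frame of a contig with its coordinate map."""

    contig: str
    contig_length: int
    frame: int  # +1..+3, -1..-3
    protein: str
    offset: int  # nt offset of the frame's first codon on its own strand

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    def codon_interval(self, p: int) -> Interval:
        """Genomic interval of the codon encoding protein position ``p``."""
        return self.span_interval(p, p + 1)

    def span_interval(self, pstart: int, pend: int) -> Interval:
        """Genomic interval covered by protein columns [pstart, pend)."""
        a = self.offset + 3 * pstart
        b = self.offset + 3 * pend
        if self.frame > 0:
            return Interval(self.contig, a, b, "+")
        L = self.contig_length
        return Interval(self.contig, L - b, L - a, "-")

    def protein_position(self, iv: Interval) -> int:
        """Inverse of codon_interval (round trip for codon-aligned intervals)."""
        if self.frame > 0:
            return (iv.start - self.offset) // 3
        return (self.contig_length - iv.end - self.offset) // 3


def six_frame_translate(
    contig_name: str, seq: str, code: GeneticCode = CILIATE_CODE
) -> list[Frame]:
    """Translate all six frames of a contig; short frames are simply shorter."""
    frames = []
    rc = reverse_complement(seq)
    for f in (1, 2, 3):
        for strand_seq, sign in ((seq, 1), (rc, -1)):
            off = f - 1
            sub = strand_seq[off : off + 3 * ((len(strand_seq) - off) // 3)]
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                prot = translate(sub, code)
            frames.append(Frame(contig_name, len(seq), sign * f, prot, off))
    frames.sort(key=lambda fr: (0 if fr.frame > 0 else 1, abs(fr.frame)))
    return frames


@dataclass
class TranslatedHit:
    """One local alignment of a protein query against a translated frame."""

    query_name: str
    role: str
    interval: Interval
    frame: int
    score: int
    bitscore: float
    evalue: float
    percent_identity: float
    percent_similarity: float
    query_coverage: float
    query_start: int  # aa, 0-based half-open on the query
    query_end: int

    @property
    def strand(self) -> str:
        return self.interval.strand


def _alignment_stats(ops, q, tprot, qs, ts, matrix):
    matches = positives = 0
    qi, ti = qs, ts
    cols = len(ops)
    for op in ops:
        if op == 0:
            if q[qi] == tprot[ti]:
                matches += 1
            if matrix[q[qi], tprot[ti]] > 0:
                positives += 1
            qi += 1
            ti += 1
        elif op == 1:
            qi += 1
        else:
            ti += 1
    return matches, positives, cols


def _hits_in_frame(qidx, frame: Frame, scheme: ScoringScheme, s_min: int, margin: int):
    """All non-overlapping local alignments with score >= s_min in one frame,
    found greedily by descending score via windowed rescoring."""
    tidx = _align.encode_protein(frame.protein)
    n = len(tidx)
    if n == 0 or len(qidx) == 0:
        return []
    colmax, best = _align.sw_column_max(qidx, tidx, scheme.matrix, scheme.gap_open, scheme.gap_extend)
    if best < s_min:
        return []
    hot = np.flatnonzero(colmax >= s_min)
    # merge hot columns into windows
    windows = []
    lo = hi = int(hot[0])
    for j in hot[1:]:
        if j - hi <= margin:
            hi = int(j)
        else:
            windows.append((lo, hi))
            lo = hi = int(j)
    windows.append((lo, hi))

    results = []

    def align_segment(a: int, b: int) -> None:
        """Greedy best-first extraction of alignments within t[a:b)."""
        if b - a < 1:
            return
        score, qs, qe, ts, te, ops = _align.sw_traceback(
            qidx, tidx[a:b], scheme.matrix, scheme.gap_open, scheme.gap_extend
        )
        if score < s_min:
            return
        results.append((score, qs, qe, a + ts, a + te, ops))
        align_segment(a, a + ts)
        align_segment(a + te, b)

    covered_to = -1
    for lo, hi in windows:
        for attempt in range(6):
            w0 = max(covered_to + 1, lo - margin * (attempt + 1))
            w1 = min(n, hi + 1 + margin * (attempt + 1))
            score, qs, qe, ts, te, ops = _align.sw_traceback(
                qidx, tidx[w0:w1], scheme.matrix, scheme.gap_open, scheme.gap_extend
            )
            touches = (w0 > covered_to + 1 and ts == 0) or (w1 < n and te == w1 - w0)
            if not touches:
                break
        align_segment(w0, w1)
        covered_to = w1 - 1
    return results


def search_protein(
    query: str,
    genome: GenomeAssembly,
    scheme: ScoringScheme | None = None,
    query_name: str = "query",
    role: str = "",
    code: GeneticCode = CILIATE_CODE,
    min_query_length: int = 10,
) -> list[TranslatedHit]:
    """Search one protein query against all six frames of every contig.

    Returns hits with E-value <= the scheme threshold, sorted by contig then
    genomic start.  Hits are trimmed to codon boundaries by construction.
    """
    scheme = scheme or ScoringScheme()
    if "*" in query:
        raise ValueError("query contains a stop codon '*'; queries must be stop-free proteins")
    if len(query) < min_query_length:
        raise ValueError(f"query shorter than {min_query_length} aa")
    qidx = _align.encode_protein(query)
    m = len(query)
    n_total = sum(
        (len(seq) - off) // 3
        for seq in genome.contigs.values()
        for off in (0, 1, 2)
    ) * 2
    s_min = scheme.min_score(m, n_total)
    margin = 2 * m + 50
    hits: list[TranslatedHit] = []
    for name, seq in genome.contigs.items():
        for frame in six_frame_translate(name, seq, code):
            tprot = _align.encode_protein(frame.protein)
            for score, qs, qe, ts, te, ops in _hits_in_frame(qidx, frame, scheme, s_min, margin):
                matches, positives, cols = _alignment_stats(ops, qidx, tprot, qs, ts, scheme.matrix)
                ev = scheme.evalue(score, m, n_total)
                if ev > scheme.evalue_threshold:
                    continue
                hits.append(
                    TranslatedHit(
                        query_name=query_name,
                        role=role or query_name,
                        interval=frame.span_interval(ts, te),
                        frame=frame.frame,
                        score=int(score),
                        bitscore=scheme.bitscore(score),
                        evalue=ev,
                        percent_identity=100.0 * matches / cols,
                        percent_similarity=100.0 * positives / cols,
                        query_coverage=(qe - qs) / m,
                        query_start=qs,
                        query_end=qe,
                    )
                )
    hits.sort(key=lambda h: (h.interval.contig, h.interval.start, h.interval.end))
    return hits


def search_queries(
    queries: dict[str, str],
    genome: GenomeAssembly,
    scheme: ScoringScheme | None = None,
    code: GeneticCode = CILIATE_CODE,
) -> list[TranslatedHit]:
    """Search several role-labeled queries (e.g. the three TBE ORF proteins)."""
    hits: list[TranslatedHit] = []
    for role, seq in queries.items():
        hits.extend(search_protein(seq, genome, scheme, query_name=role, role=role, code=code))
    hits.sort(key=lambda h: (h.interval.contig, h.interval.start, h.interval.end))
    return hits


HIT_COLUMNS = [
    "query", "role", "contig", "start", "end", "strand", "frame",
    "score", "bitscore", "evalue", "pident", "psim", "qcov", "qstart", "qend",
]


def hits_to_frame(hits: list[TranslatedHit]) -> pd.DataFrame:
    rows = [
        (
            h.query_name, h.role, h.interval.contig, h.interval.start, h.interval.end,
            h.strand, h.frame, h.score, round(h.bitscore, 2), h.evalue,
            round(h.percent_identity, 2), round(h.percent_similarity, 2),
            round(h.query_coverage, 4), h.query_start, h.query_end,
        )
        for h in hits
    ]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def frame_to_hits(df: pd.DataFrame) -> list[TranslatedHit]:
    hits = []
    for r in df.itertuples(index=False):
        hits.append(
            TranslatedHit(
                query_name=r.query, role=r.role,
                interval=Interval(r.contig, int(r.start), int(r.end), r.strand),
                frame=int(r.frame), score=int(r.score), bitscore=float(r.bitscore),
                evalue=float(r.evalue), percent_identity=float(r.pident),
                percent_similarity=float(r.psim), query_coverage=float(r.qcov),
                query_start=int(r.qstart), query_end=int(r.qend),
            )
        )
    return hits
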