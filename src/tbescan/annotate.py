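"""Assemble translated hits into complete/partial TBE elements.

A complete element carries all three ORFs within 1 kb of each other and in
the canonical orientation: the 42kD transposase and the 57kD ORF on one
strand, the 22kD ORF between them on the other, reading 42kD-22kD-57kD along
the element strand.  Chains of hits violating the orientation pattern are
split into partial elements; hits of the same role and strand separated by
less than a merge window (frameshift fragments of one ORF) are merged before
assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .search import TranslatedHit
from .seqcore import GenomeAssembly, GFF3Feature, Interval

ROLE_ORDER = ("42kD", "22kD", "57kD")


@dataclass
class AnnotateConfig:
    max_gap_bp: int = 1000
    contig_end_window_bp: int = 500
    min_role_coverage: float = 0.3
    merge_gap_bp: int = 100

    def __post_init__(self) -> None:
        if min(self.max_gap_bp, self.contig_end_window_bp, self.merge_gap_bp) < 0:
            raise ValueError("window sizes must be non-negative")
        if not 0 <= self.min_role_coverage <= 1:
            raise ValueError("min_role_coverage must be in [0, 1]")


@dataclass
class MergedHit:
    """One ORF candidate: one or more same-role, same-strand hits merged."""

    role: str
    interval: Interval
    strand: str
    hits: list[TranslatedHit]

    @property
    def bitscore(self) -> float:
        return sum(h.bitscore for h in self.hits)

    @property
    def query_coverage(self) -> float:
        covered = sorted((h.query_start, h.query_end) for h in self.hits)
        total = 0
        cur_s, cur_e = covered[0]
        for s, e in covered[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
        return total / self._query_length()

    def _query_length(self) -> int:
        h = self.hits[0]
        return max(1, round((h.query_end - h.query_start) / h.query_coverage))

    @property
    def percent_similarity(self) -> float:
        w = sum(h.query_end - h.query_start for h in self.hits)
        return sum(h.percent_similarity * (h.query_end - h.query_start) for h in self.hits) / max(1, w)


@dataclass
class TBEElement:
    """An annotated transposon copy."""

    id: str
    contig: str
    span: Interval                      # ORF envelope; extended to TIRs downstream
    completeness: str                   # complete | partial
    orf_hits: dict[str, MergedHit]
    element_strand: str
    n_tirs: int = 0
    tir_left: Interval | None = None
    tir_right: Interval | None = None
    tir_similarity: float | None = None
    tsd: str | None = None
    family: str | None = None
    near_contig_end: bool = False
    near_mds: bool | None = None
    #: role -> CDSAlignment, set by the integrity stage (refined coordinates)
    cds: dict | None = None

    @property
    def orf_similarity(self) -> dict[str, float]:
        return {r: mh.percent_similarity for r, mh in self.orf_hits.items()}

    def orf_envelope(self) -> Interval:
        starts = [mh.interval.start for mh in self.orf_hits.values()]
        ends = [mh.interval.end for mh in self.orf_hits.values()]
        return Interval(self.contig, min(starts), max(ends), self.element_strand)


def _merge_fragments(hits: list[TranslatedHit], cfg: AnnotateConfig) -> list[MergedHit]:
    """Merge same-role, same-strand hits separated by < merge_gap_bp
    (frameshifted ORFs appear as adjacent hits in different frames)."""
    merged: list[MergedHit] = []
    by_key: dict[tuple[str, str], list[TranslatedHit]] = {}
    for h in sorted(hits, key=lambda h: h.interval.start):
        by_key.setdefault((h.role, h.strand), []).append(h)
    for (role, strand), group in by_key.items():
        cur = [group[0]]
        for h in group[1:]:
            if h.interval.start - cur[-1].interval.end < cfg.merge_gap_bp:
                cur.append(h)
            else:
                merged.append(_mk_merged(role, strand, cur))
                cur = [h]
        merged.append(_mk_merged(role, strand, cur))
    merged.sort(key=lambda m: m.interval.start)
    return merged


def _mk_merged(role: str, strand: str, hits: list[TranslatedHit]) -> MergedHit:
    iv = Interval(
        hits[0].interval.contig,
        min(h.interval.start for h in hits),
        max(h.interval.end for h in hits),
        strand,
    )
    return MergedHit(role=role, interval=iv, strand=strand, hits=hits)


# orientation pattern of (role, relative strand) along the contig, for each
# element strand: on "+" the element reads 42kD(+) 22kD(-) 57kD(+); on "-"
# the mirror image.
_PATTERNS = {
    "+": [("42kD", "+"), ("22kD", "-"), ("57kD", "+")],
    "-": [("57kD", "-"), ("22kD", "+"), ("42kD", "-")],
}


def _pattern_slot(role: str, strand: str, element_strand: str) -> int | None:
    pat = _PATTERNS[element_strand]
    for i, (r, s) in enumerate(pat):
        if (r, s) == (role, strand):
            return i
    return None


def assemble_elements(
    hits: list[TranslatedHit], cfg: AnnotateConfig | None = None
) -> list[TBEElement]:
    """Group hits into elements by proximity and orientation.

    Every input hit is assigned to exactly one element.  Within a proximity
    chain, hits are walked left to right and greedily fitted to the canonical
    orientation pattern on either strand; a hit that cannot extend the current
    pattern closes the element and opens a new one, so orientation-violating
    chains become several partials.  When two candidate hits compete for one
    role slot the higher summed bitscore wins (ties: leftmost) and the loser
    seeds its own partial element.
    """
    cfg = cfg or AnnotateConfig()
    elements: list[TBEElement] = []
    by_contig: dict[str, list[TranslatedHit]] = {}
    for h in hits:
        by_contig.setdefault(h.interval.contig, []).append(h)

    serial = 0
    for contig in sorted(by_contig):
        merged = _merge_fragments(by_contig[contig], cfg)
        # chains by proximity
        chains: list[list[MergedHit]] = []
        cur = [merged[0]]
        for mh in merged[1:]:
            if mh.interval.start - max(x.interval.end for x in cur) <= cfg.max_gap_bp:
                cur.append(mh)
            else:
                chains.append(cur)
                cur = [mh]
        chains.append(cur)

        for chain in chains:
            groups: list[list[MergedHit]] = []
            leftovers: list[MergedHit] = []
            group: list[MergedHit] = []
            gstrand: str | None = None
            gslot = -1
            for mh in chain:
                placed = False
                if not group:
                    for es in ("+", "-"):
                        slot = _pattern_slot(mh.role, mh.strand, es)
                        if slot is not None:
                            group, gstrand, gslot = [mh], es, slot
                            placed = True
                            break
                    if not placed:
                        leftovers.append(mh)
                    continue
                slot = _pattern_slot(mh.role, mh.strand, gstrand)
                if slot is not None and slot > gslot:
                    group.append(mh)
                    gslot = slot
                    placed = True
                elif slot is not None and slot == gslot and mh.role == group[-1].role:
                    # two candidates for one slot: higher bitscore wins
                    if mh.bitscore > group[-1].bitscore:
                        leftovers.append(group[-1])
                        group[-1] = mh
                    else:
                        leftovers.append(mh)
                    placed = True
                if not placed:
                    groups.append(group)
                    group, gstrand, gslot = [], None, -1
                    for es in ("+", "-"):
                        slot = _pattern_slot(mh.role, mh.strand, es)
                        if slot is not None:
                            group, gstrand, gslot = [mh], es, slot
                            break
                    if not group:
                        leftovers.append(mh)
            if group:
                groups.append(group)
            for lo in leftovers:
                groups.append([lo])

            for g in groups:
                serial += 1
                roles = {mh.role: mh for mh in g}
                es = _infer_strand(g)
                covered = all(
                    r in roles and roles[r].query_coverage >= cfg.min_role_coverage
                    for r in ROLE_ORDER
                )
                gaps_ok = all(
                    g[i + 1].interval.start - g[i].interval.end <= cfg.max_gap_bp
                    for i in range(len(g) - 1)
                )
                completeness = "complete" if (covered and gaps_ok and len(roles) == 3) else "partial"
                span = Interval(
                    contig,
                    min(mh.interval.start for mh in g),
                    max(mh.interval.end for mh in g),
                    es,
                )
                elements.append(
                    TBEElement(
                        id=f"TBE_{serial:05d}",
                        contig=contig,
                        span=span,
                        completeness=completeness,
                        orf_hits=roles,
                        element_strand=es,
                    )
                )
    elements.sort(key=lambda e: (e.contig, e.span.start))
    return elements


def _infer_strand(group: list[MergedHit]) -> str:
    votes = {"+": 0.0, "-": 0.0}
    for mh in group:
        es = mh.strand if mh.role in ("42kD", "57kD") else ("-" if mh.strand == "+" else "+")
        votes[es] += mh.bitscore
    return "+" if votes["+"] >= votes["-"] else "-"


def flag_context(
    elements: list[TBEElement], genome: GenomeAssembly, cfg: AnnotateConfig | None = None
) -> list[TBEElement]:
    """Set near_contig_end on each element (span within the window of either
    contig end)."""
    cfg = cfg or AnnotateConfig()
    for e in elements:
        clen = len(genome[e.contig])
        e.near_contig_end = (
            e.span.start <= cfg.contig_end_window_bp
            or clen - e.span.end <= cfg.contig_end_window_bp
        )
    return elements


def element_table(elements: list[TBEElement]) -> pd.DataFrame:
    """Per-family summary table: counts, length, % by length, TIR counts and
    near-MDS counts, with unlabeled elements reported as 'unclassified'."""
    cols = [
        "family", "n_complete", "n_partial", "total_length_bp", "pct_by_length",
        "tir_2", "tir_1", "tir_0", "near_mds", "near_contig_end",
    ]
    if not elements:
        return pd.DataFrame(columns=cols)
    rows = {}
    total_len = sum(e.span.length for e in elements)
    for e in elements:
        fam = e.family or "unclassified"
        r = rows.setdefault(
            fam,
            {c: 0 for c in cols[1:]} | {"family": fam},
        )
        r["n_complete" if e.completeness == "complete" else "n_partial"] += 1
        r["total_length_bp"] += e.span.length
        r[f"tir_{min(e.n_tirs, 2)}"] += 1
        if e.near_mds:
            r["near_mds"] += 1
        if e.near_contig_end:
            r["near_contig_end"] += 1
    df = pd.DataFrame(list(rows.values()), columns=cols)
    df["pct_by_length"] = 100.0 * df["total_length_bp"] / max(1, total_len)
    return df.sort_values("family").reset_index(drop=True)


def elements_to_gff3(elements: list[TBEElement]) -> list[GFF3Feature]:
    feats = []
    for e in elements:
        attrs = {"ID": e.id, "completeness": e.completeness}
        if e.family:
            attrs["family"] = e.family
        if e.tsd:
            attrs["tsd"] = e.tsd
        feats.append(GFF3Feature(interval=e.span, feature_type="mobile_genetic_element", attributes=attrs))
        for role, mh in e.orf_hits.items():
            feats.append(
                GFF3Feature(interval=mh.interval, feature_type="CDS", attributes={"Parent": e.id, "role": role})
            )
        for tir in (e.tir_left, e.tir_right):
            if tir is not None:
                feats.append(
                    GFF3Feature(interval=tir, feature_type="inverted_repeat", attributes={"Parent": e.id})
                )
    return feats
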