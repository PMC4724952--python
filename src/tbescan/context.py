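"""Genomic context: distances to annotation tracks and placement enrichment.

Elements are compared against strandless merged interval tracks (MDS
segments, satellite repeats).  Enrichment of element placement near a track
is tested with a 1-dof chi-squared comparing the observed near/not-near split
against the track's genome-space fraction — the literal published framing
(18.3% of elements within 500 bp of MDSs versus the 11.1% of the genome MDSs
occupy), which is conservative because the expected fraction ignores the
extra reach of the 500 bp window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annotate import TBEElement
from .seqcore import GenomeAssembly, Interval

#: sentinel distance for elements on contigs without track intervals
NO_TRACK = float("inf")


@dataclass
class AnnotationTrack:
    label: str
    intervals: list[Interval]

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)

    def by_contig(self) -> dict[str, np.ndarray]:
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.contig, []).append((iv.start, iv.end))
        return {c: np.array(v, dtype=np.int64) for c, v in out.items()}


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Sort and merge overlapping/abutting intervals, dropping strand."""
    out: list[Interval] = []
    for iv in sorted(intervals, key=lambda x: (x.contig, x.start, x.end)):
        if out and out[-1].contig == iv.contig and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = Interval(iv.contig, out[-1].start, iv.end)
        else:
            out.append(Interval(iv.contig, iv.start, iv.end))
    return out


def nearest_distance(element: TBEElement | Interval, track: AnnotationTrack) -> float:
    """Gap in bp between the element span and the nearest track interval on
    the same contig; 0 when overlapping, inf when the contig has none."""
    span = element.span if isinstance(element, TBEElement) else element
    ivs = [t for t in track.intervals if t.contig == span.contig]
    if not ivs:
        return NO_TRACK
    best = NO_TRACK
    for t in ivs:
        gap = max(t.start - span.end, span.start - t.end, 0)
        best = min(best, gap)
    return best


def genome_fraction(track: AnnotationTrack, genome: GenomeAssembly) -> float:
    """Fraction of genome bp covered by the (merged) track."""
    covered = sum(iv.length for iv in track.intervals)
    return covered / genome.total_length


@dataclass
class EnrichmentResult:
    n_elements: int
    n_near: int
    observed_fraction: float
    expected_fraction: float
    window_bp: int
    chi2: float
    dof: int
    p_value: float


def enrichment_test(
    elements: list[TBEElement] | list[Interval],
    track: AnnotationTrack,
    window_bp: int = 500,
    expected: float | None = None,
    genome: GenomeAssembly | None = None,
    continuity_correction: bool = False,
) -> EnrichmentResult:
    """Chi-squared (1 dof) of near-track element counts vs the expected
    genome fraction.

    ``expected`` defaults to the track's genome fraction (requires
    ``genome``).  Distances of inf (contigs without track) count as not near.
    """
    if not elements:
        raise ValueError("no elements")
    if expected is None:
        if genome is None:
            raise ValueError("need either expected fraction or genome")
        expected = genome_fraction(track, genome)
    if not 0.0 < expected < 1.0:
        raise ValueError(f"expected fraction must be in (0, 1), got {expected}")
    n = len(elements)
    n_near = sum(1 for e in elements if nearest_distance(e, track) <= window_bp)
    exp_counts = np.array([n * expected, n * (1.0 - expected)])
    obs_counts = np.array([n_near, n - n_near], dtype=float)
    if continuity_correction:
        obs_counts = obs_counts + np.clip(exp_counts - obs_counts, -0.5, 0.5)
    chi2 = float(((obs_counts - exp_counts) ** 2 / exp_counts).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return EnrichmentResult(
        n_elements=n,
        n_near=n_near,
        observed_fraction=n_near / n,
        expected_fraction=expected,
        window_bp=window_bp,
        chi2=chi2,
        dof=1,
        p_value=p,
    )
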