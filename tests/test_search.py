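"""Translated-search tests, including the brute-force local-alignment oracle."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from tbescan.seqcore import GenomeAssembly, reverse_complement, translate
from tbescan.search import Frame, ScoringScheme, search_protein, six_frame_translate

_B62 = substitution_matrices.load("BLOSUM62")

PERMISSIVE = dict(scheme=ScoringScheme(evalue_threshold=1e9), min_query_length=1)


def oracle_best_score(query: str, genome: str, gap_open=11, gap_extend=1) -> int:
    """Independent brute-force Smith-Waterman over all six frames.

    Plain affine-gap DP (gap of length k costs open + k*extend) written
    directly against the BLOSUM62 matrix; no sharing with the implementation.
    """
    best = 0
    rc = reverse_complement(genome)
    frames = []
    for off in range(3):
        for s in (genome, rc):
            sub = s[off : off + 3 * ((len(s) - off) // 3)]
            frames.append(translate(sub))
    first = gap_open + gap_extend
    for target in frames:
        m, n = len(query), len(target)
        H = [[0] * (n + 1) for _ in range(m + 1)]
        E = [[-(10**9)] * (n + 1) for _ in range(m + 1)]
        F = [[-(10**9)] * (n + 1) for _ in range(m + 1)]
        for i in range(1, m + 1):
            for j in range(1, n + 1):
                E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
                F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
                s = H[i - 1][j - 1] + _B62[query[i - 1], target[j - 1]]
                H[i][j] = max(0, s, E[i][j], F[i][j])
                best = max(best, H[i][j])
    return int(best)


def test_six_frame_coordinate_round_trip():
    seq = "ATGAAAGTTCCCGGA"
    frames = six_frame_translate("c", seq)
    assert len(frames) == 6
    plus1 = next(f for f in frames if f.frame == 1)
    assert plus1.protein == "MKVPG"
    for p in range(len(plus1.protein)):
        iv = plus1.codon_interval(p)
        assert plus1.protein_position(iv) == p
    minus = next(f for f in frames if f.frame == -1)
    for p in range(len(minus.protein)):
        iv = minus.codon_interval(p)
        assert iv.strand == "-"
        assert minus.protein_position(iv) == p


def test_six_frame_degenerate_short_contig():
    frames = six_frame_translate("c", "ACGT")
    lens = {f.frame: len(f.protein) for f in frames}
    assert lens[1] == 1 and lens[2] == 1 and lens[3] == 0


def test_hand_scored_hit():
    """'MKV' against its exact back-translation scores M=5 + K=5 + V=4 = 14."""
    g = GenomeAssembly({"c1": "TTTTTTTATGAAAGTTTTTTTTT"})
    hits = search_protein("MKV", g, **PERMISSIVE)
    best = max(hits, key=lambda h: h.score)
    assert best.score == 14
    assert best.interval.start == 7 and best.interval.end == 16
    assert best.percent_identity == 100.0
    assert best.query_coverage == 1.0


def test_exact_self_match_full_coverage(rng):
    from tbescan.synth import _random_codons
    from tbescan.seqcore import CILIATE_CODE

    codons = _random_codons(60, rng, CILIATE_CODE)
    cds = "".join(codons)
    flank = "".join(rng.choice(list("ACGT"), 300))
    g = GenomeAssembly({"c": flank + cds + flank})
    query = translate(cds)
    hits = search_protein(query, g, ScoringScheme(evalue_threshold=1e-3))
    best = max(hits, key=lambda h: h.score)
    assert best.percent_identity == 100.0
    assert best.query_coverage == 1.0
    assert (best.interval.start, best.interval.end) == (300, 300 + len(cds))


def test_matches_bruteforce_on_seeded_instances(rng):
    """Optimal local score equals the independent oracle (small spot check;
    the acceptance suite runs 200 instances)."""
    for _ in range(20):
        qlen = int(rng.integers(10, 25))
        glen = int(rng.integers(60, 150))
        query = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), qlen))
        genome = "".join(rng.choice(list("ACGT"), glen))
        hits = search_protein(query, GenomeAssembly({"c": genome}), **PERMISSIVE)
        got = max((h.score for h in hits), default=0)
        assert got == oracle_best_score(query, genome)


def test_strand_symmetry(rng):
    query = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 15))
    genome = "".join(rng.choice(list("ACGT"), 120))
    h1 = search_protein(query, GenomeAssembly({"c": genome}), **PERMISSIVE)
    h2 = search_protein(query, GenomeAssembly({"c": reverse_complement(genome)}), **PERMISSIVE)
    key1 = sorted((h.score, len(genome) - h.interval.end, "-" if h.strand == "+" else "+") for h in h1)
    key2 = sorted((h.score, h.interval.start, h.strand) for h in h2)
    assert [k[0] for k in key1] == [k[0] for k in key2]
    assert key1 == key2


def test_score_monotone_under_genome_extension(rng):
    query = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 12))
    genome = "".join(rng.choice(list("ACGT"), 90))
    def best(g):
        hits = search_protein(query, GenomeAssembly({"c": g}), **PERMISSIVE)
        return max((h.score for h in hits), default=0)
    b0 = best(genome)
    for _ in range(5):
        genome = genome + "".join(rng.choice(list("ACGT"), 30))
        b1 = best(genome)
        assert b1 >= b0
        b0 = b1


def test_query_with_stop_rejected():
    g = GenomeAssembly({"c": "ACGT" * 30})
    with pytest.raises(ValueError, match="stop"):
        search_protein("MKV*LLLLLL", g)


def test_short_query_rejected():
    g = GenomeAssembly({"c": "ACGT" * 30})
    with pytest.raises(ValueError, match="shorter"):
        search_protein("MKV", g)
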