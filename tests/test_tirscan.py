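"""TIR detection, TSD calling, telomeric motif and distance statistics."""

import numpy as np
import pytest

from tbescan import refdata
from tbescan.annotate import assemble_elements
from tbescan.search import TranslatedHit
from tbescan.seqcore import GenomeAssembly, Interval, reverse_complement
from tbescan.tirscan import (
    DistanceStats,
    call_tsd,
    detect_tir,
    distance_stats,
    scan_telomeric,
    tir_consensus,
    tir_similarity,
)

TIR = refdata.TIR_REFERENCES["TBE1"].sequence  # starts with the telomeric repeat


def build_element(rng, tir=TIR, flank=500, core=1200, tsd="TA"):
    """Random contig holding [flank][TSD][TIR][core][rc TIR][TSD][flank]."""
    bases = list("ACGT")
    left = "".join(rng.choice(bases, flank))
    right = "".join(rng.choice(bases, flank))
    core_seq = "".join(rng.choice(bases, core))
    seq = left + tsd + tir + core_seq + reverse_complement(tir) + tsd + right
    start = flank + len(tsd)  # element (TIR) start
    env_start = start + len(tir)
    env_end = env_start + core
    hit = TranslatedHit(
        query_name="42kD", role="42kD",
        interval=Interval("c", env_start, env_start + core, "+"),
        frame=1, score=500, bitscore=250.0, evalue=1e-40,
        percent_identity=95.0, percent_similarity=97.0,
        query_coverage=0.95, query_start=0, query_end=333,
    )
    element = assemble_elements([hit])[0]
    genome = GenomeAssembly({"c": seq})
    truth = dict(tir_left=(start, start + len(tir)),
                 tir_right=(env_end, env_end + len(tir)))
    return element, genome, truth


class TestTirSimilarity:
    def test_identical(self):
        assert tir_similarity(TIR, TIR) == 100.0

    def test_published_tbe22_pair(self):
        a = refdata.TIR_REFERENCES["TBE2.2"].sequence
        b = refdata.TIR_REFERENCES["TBE2.2b"].sequence
        assert tir_similarity(a, b) == pytest.approx(92.5, abs=0.5)

    def test_local_convention_ignores_terminal_mismatch(self):
        # under the local (BLASTN-style) convention a single terminal
        # mismatch is trimmed rather than counted
        assert tir_similarity("AAAA", "AAAT") == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tir_similarity("", "ACGT")


class TestDetectTir:
    def test_perfect_inverted_repeat_found_at_truth(self, rng):
        element, genome, truth = build_element(rng)
        pair = detect_tir(element, genome)
        assert pair is not None
        assert pair.percent_similarity == 100.0
        assert (pair.left.start, pair.left.end) == truth["tir_left"]
        assert (pair.right.start, pair.right.end) == truth["tir_right"]
        assert element.n_tirs == 2
        assert element.span.start == truth["tir_left"][0]
        assert element.span.end == truth["tir_right"][1]

    def test_idempotent_after_span_extension(self, rng):
        element, genome, truth = build_element(rng)
        detect_tir(element, genome)
        span1 = element.span
        detect_tir(element, genome)
        assert element.span == span1 and element.n_tirs == 2

    def test_clipped_window_yields_at_most_one_tir(self, rng):
        element, genome, truth = build_element(rng)
        # cut the contig just after the ORF envelope: right TIR lost
        cut = genome["c"][: element.orf_envelope().end + 5]
        clipped = GenomeAssembly({"c": cut})
        element2, _, _ = build_element(rng)
        element2.span = element.orf_envelope()
        pair = detect_tir(element2, clipped)
        assert pair is None
        assert element2.n_tirs <= 1

    def test_mutated_tirs_similarity_tracks_divergence(self, rng):
        sims = []
        for _ in range(12):
            element, genome, truth = build_element(rng)
            seq = list(genome["c"])
            for (a, b) in (truth["tir_left"], truth["tir_right"]):
                for i in range(a, b):
                    if rng.random() < 0.05:
                        seq[i] = rng.choice([c for c in "ACGT" if c != seq[i]])
            pair = detect_tir(element, GenomeAssembly({"c": "".join(seq)}))
            if pair:
                sims.append(pair.percent_similarity)
        assert 85.0 <= np.mean(sims) <= 95.0


class TestCallTsd:
    def test_constructed_ta(self, rng):
        element, genome, truth = build_element(rng, tsd="TA")
        detect_tir(element, genome)
        call = call_tsd(element, genome)
        assert call is not None and call.motif == "TA"

    def test_no_shared_flank_returns_none(self, rng):
        element, genome, truth = build_element(rng, tsd="TA")
        detect_tir(element, genome)
        seq = list(genome["c"])
        s = element.span.start
        seq[s - 2 : s] = ["G", "G"]  # destroy the left TSD copy
        assert call_tsd(element, GenomeAssembly({"c": "".join(seq)})) is None

    def test_recovers_longer_motif(self, rng):
        element, genome, truth = build_element(rng, tsd="TACGT")
        detect_tir(element, genome)
        call = call_tsd(element, genome)
        assert call is not None and call.motif.endswith("TACGT")


@pytest.mark.parametrize(
    "distances,mode,frac",
    [([3, 3, 3, 41], 3, 0.75), ([0, 0], 0, 1.0), ([1, 2], 1, 0.5)],
)
def test_distance_mode_and_tie_rule(distances, mode, frac):
    stats = DistanceStats.from_distances(distances)
    assert stats.mode == mode
    assert stats.fraction_at_mode == pytest.approx(frac)


def test_distance_stats_empty_group():
    stats = DistanceStats.from_distances([])
    assert stats.mode is None and stats.fraction_at_mode == 0.0


class TestConsensus:
    def test_noisy_copies_recover_original(self, rng):
        base = refdata.TIR_REFERENCES["TBE2.1"].sequence
        seqs = []
        for _ in range(10):
            s = list(base)
            for i in range(len(s)):
                if rng.random() < 0.02:
                    s[i] = rng.choice([c for c in "ACGT" if c != s[i]])
            seqs.append("".join(s))
        cons = tir_consensus(seqs)
        assert len(cons) == 1
        assert cons[0] == (base, 10)

    def test_two_diverged_sets_make_two_clusters(self, rng):
        a = "".join(rng.choice(list("ACGT"), 100))
        b = list(a)
        for i in range(0, 100, 5):  # 20% divergence
            b[i] = "A" if a[i] != "A" else "C"
        clusters = tir_consensus([a, a, "".join(b), "".join(b)], identity_threshold=0.9)
        assert len(clusters) == 2

    def test_single_sequence_is_its_own_consensus(self):
        assert tir_consensus(["ACGTACGT"]) == [("ACGTACGT", 1)]


@pytest.mark.parametrize(
    "seq,expected",
    [
        (refdata.TIR_REFERENCES["TBE1"].sequence, ("canonical", 0)),
        (refdata.TIR_REFERENCES["TBE2.1"].sequence, ("variant", 0)),
        ("GGGGGGGGGGGGGGGGGGGG", ("absent", -1)),
    ],
)
def test_scan_telomeric(seq, expected):
    assert scan_telomeric(seq) == expected
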