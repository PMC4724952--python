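"""Frameshift-aware CDS extraction, repair and stop-codon profiling."""

import numpy as np
import pytest

from tbescan.seqcore import CILIATE_CODE, reverse_complement, translate
from tbescan.synth import _random_codons
from tbescan.integrity import (
    align_protein_to_dna,
    call_integrity,
    consensus_protein,
    repair_sequence,
    stop_profile,
)


@pytest.fixture()
def cds60(rng):
    codons = _random_codons(60, rng, CILIATE_CODE)
    return "".join(codons), translate("".join(codons))


class TestAlignment:
    def test_exact_backtranslation(self, cds60):
        region, query = cds60
        a = align_protein_to_dna(query, region)
        assert a.frameshift_ops == []
        assert a.stop_positions == []
        assert a.query_coverage == 1.0
        assert (a.interval.start, a.interval.end) == (0, len(region))

    def test_single_insertion_detected_at_position(self, cds60):
        region, query = cds60
        mutated = region[:93] + "G" + region[93:]  # insert after codon 30
        a = align_protein_to_dna(query, mutated)
        assert len(a.frameshift_ops) == 1
        pos, kind = a.frameshift_ops[0]
        assert kind == +1 and abs(pos - 31) <= 1
        assert a.query_coverage == 1.0

    def test_single_deletion_detected(self, cds60):
        region, query = cds60
        mutated = region[:94] + region[95:]
        a = align_protein_to_dna(query, mutated)
        assert len(a.frameshift_ops) == 1
        assert a.frameshift_ops[0][1] == -1

    def test_tga_recorded_taa_translates_as_gln(self, cds60):
        region, query = cds60
        mutated = region[:27] + "TGA" + region[30:]  # stop at codon 10 (0-based 9)
        a = align_protein_to_dna(query, mutated)
        assert a.stop_positions == [9]
        # TAA is glutamine under the ciliate code: aligned, not a stop
        mutated2 = region[:27] + "TAA" + region[30:]
        b = align_protein_to_dna(query, mutated2)
        assert b.stop_positions == []
        assert b.aligned_protein[9] == "Q"

    def test_reverse_strand_equivalent(self, cds60):
        region, query = cds60
        a = align_protein_to_dna(query, region)
        b = align_protein_to_dna(query, reverse_complement(region))
        assert b.score == a.score and b.strand == "-"

    def test_true_region_beats_shuffled(self, cds60, rng):
        region, query = cds60
        a = align_protein_to_dna(query, region)
        for _ in range(5):
            shuffled = "".join(rng.permutation(list(region)))
            s = align_protein_to_dna(query, shuffled)
            assert a.score > s.score

    def test_short_region_rejected(self):
        with pytest.raises(ValueError):
            align_protein_to_dna("MKVMKVMKVMKV", "ATG")


class TestIntegrityCall:
    def test_terminal_stop_not_premature(self, cds60, rng):
        region, query = cds60
        # internal stop is premature...
        a = align_protein_to_dna(query, region[:27] + "TGA" + region[30:])
        assert call_integrity(a).has_premature_stop is True
        # ...a stop at the last aligned residue is not
        b = align_protein_to_dna(query, region)
        if b.stop_positions:
            assert max(b.stop_positions) == b.query_end - 1
        assert call_integrity(b).has_premature_stop is False

    def test_frameshift_flag(self, cds60):
        region, query = cds60
        a = align_protein_to_dna(query, region[:93] + "G" + region[93:])
        assert call_integrity(a).has_frameshift is True


class TestRepair:
    def test_intact_unchanged(self, cds60):
        region, query = cds60
        codons, qs = repair_sequence(align_protein_to_dna(query, region))
        assert "".join(codons) == region and qs == 0

    def test_insertion_and_stop(self, cds60):
        region, query = cds60
        mutated = region[:27] + "TGA" + region[30:]
        mutated = mutated[:93] + "G" + mutated[93:]
        codons, qs = repair_sequence(align_protein_to_dna(query, mutated))
        assert len(codons) == 60  # restored to template length
        assert codons.count("NNN") == 1

    def test_repair_then_realign_has_no_frameshifts(self, cds60):
        region, query = cds60
        mutated = region[:93] + "G" + region[93:]
        codons, _ = repair_sequence(align_protein_to_dna(query, mutated))
        again = align_protein_to_dna(query, "".join(codons).replace("N", "A"))
        assert again.frameshift_ops == []

    def test_low_coverage_rejected(self, cds60):
        region, query = cds60
        a = align_protein_to_dna(query, region[:60])  # covers 20 of 60 codons
        with pytest.raises(ValueError, match="exclude"):
            repair_sequence(a)


class TestStopProfile:
    def _aln(self, query, region):
        return align_protein_to_dna(query, region)

    def test_hotspot_fraction(self, cds60):
        region, query = cds60
        group = []
        for i in range(10):
            if i < 8:
                group.append(self._aln(query, region[:27] + "TGA" + region[30:]))
            else:
                group.append(self._aln(query, region))
        prof = stop_profile(group)
        assert prof.fractions[9] == pytest.approx(0.8)
        assert prof.hotspots[0][0] == 9

    def test_profile_is_mean_of_indicators(self, cds60, rng):
        region, query = cds60
        group = []
        indicators = np.zeros((6, 60))
        for i in range(6):
            pos = int(rng.integers(5, 55))
            group.append(self._aln(query, region[: 3 * pos] + "TGA" + region[3 * pos + 3 :]))
            indicators[i, pos] = 1
        prof = stop_profile(group)
        np.testing.assert_allclose(prof.fractions, indicators.mean(axis=0))

    def test_no_stops_no_hotspots(self, cds60):
        region, query = cds60
        prof = stop_profile([self._aln(query, region)])
        assert prof.hotspots == []

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stop_profile([])


def test_consensus_protein_majority(cds60):
    region, query = cds60
    a = align_protein_to_dna(query, region)
    cons = consensus_protein([a, a, a], len(query))
    assert cons == query
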