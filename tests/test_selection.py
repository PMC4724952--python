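"""Nei-Gojobori counting under the ciliate code and the neutrality test."""

import numpy as np
import pytest

from tbescan.seqcore import CILIATE_CODE, translate
from tbescan.synth import _random_codons, mutate_codon_sequence
from tbescan.selection import (
    CodonAlignment,
    SubstCounts,
    jukes_cantor,
    neutrality_test,
    ng86,
    pairwise_codon_align,
    omega_distribution,
    _codon_differences,
    _codon_sites,
)


class TestSites:
    def test_lysine_codon_sites_under_ciliate_code(self):
        """AAA: only AAG (pos 3) is synonymous; TAA is a Gln change (ciliate
        code), counted as nonsynonymous rather than excluded as a stop."""
        s, n = _codon_sites("AAA", 6)
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_stop_adjacent_changes_renormalized(self):
        """TGG: TGA is the sole stop neighbour and is excluded from both
        numerator and denominator, so the codon still contributes 3 sites."""
        s, n = _codon_sites("TGG", 6)
        assert s + n == pytest.approx(3.0)
        assert s == 0.0

    def test_site_conservation_over_random_alignments(self, rng):
        codons = _random_codons(100, rng, CILIATE_CODE)
        aln = CodonAlignment(codons, codons, 100, 0)
        counts, _ = ng86(aln)
        assert counts.S + counts.N == pytest.approx(3 * 100)


class TestDifferences:
    def test_synonymous_single_change(self):
        assert _codon_differences("AAA", "AAG", 6) == (1.0, 0.0)

    def test_pathways_through_stop_excluded(self):
        """TGC -> AGA: the path via TGA (stop) is blocked, so only the
        pathway through AGC contributes."""
        sd, nd = _codon_differences("TGC", "AGA", 6)
        # AGC path: TGC->AGC (C->S, nonsyn), AGC->AGA (S->R, nonsyn)
        assert (sd, nd) == (0.0, 2.0)

    def test_symmetry(self, rng):
        for _ in range(20):
            a = _random_codons(1, rng, CILIATE_CODE)[0]
            b = _random_codons(1, rng, CILIATE_CODE)[0]
            assert _codon_differences(a, b, 6) == _codon_differences(b, a, 6)


class TestRates:
    def test_identical_sequences_invalid_low_ds(self, rng):
        codons = _random_codons(60, rng, CILIATE_CODE)
        _, est = ng86(CodonAlignment(codons, codons, 60, 0))
        assert not est.valid and "below" in est.invalid_reason

    def test_jukes_cantor_undefined_at_saturation(self):
        assert jukes_cantor(0.8) is None
        assert jukes_cantor(0.1) == pytest.approx(-0.75 * np.log(1 - 0.4 / 3))

    def test_ng86_symmetric(self, rng):
        a = _random_codons(80, rng, CILIATE_CODE)
        b = mutate_codon_sequence(a, 0.5, 0.5, rng)
        c1, e1 = ng86(CodonAlignment(a, b, 80, 0))
        c2, e2 = ng86(CodonAlignment(b, a, 80, 0))
        assert (c1.S, c1.N, c1.Sd, c1.Nd) == (c2.S, c2.N, c2.Sd, c2.Nd)


class TestCodonAlign:
    def test_identical(self, rng):
        a = _random_codons(50, rng, CILIATE_CODE)
        aln = pairwise_codon_align(a, list(a))
        assert aln.n_codons == 50 and aln.n_dropped == 0

    def test_masked_codon_dropped(self, rng):
        a = _random_codons(50, rng, CILIATE_CODE)
        b = list(a)
        b[10] = "NNN"
        aln = pairwise_codon_align(a, b)
        assert aln.n_codons == 49 and aln.n_dropped == 1

    def test_protein_gap_drops_columns(self, rng):
        a = _random_codons(60, rng, CILIATE_CODE)
        b = a[:20] + a[22:]  # 2-codon deletion
        aln = pairwise_codon_align(a, b)
        assert aln.n_codons == 58

    def test_too_few_codons_excluded(self, rng):
        a = _random_codons(20, rng, CILIATE_CODE)
        assert pairwise_codon_align(a, list(a)) is None


class TestNeutrality:
    def test_closed_form_binomial(self):
        t = neutrality_test(SubstCounts(S=25, N=75, Sd=10, Nd=0))
        assert t.p_value == pytest.approx(0.25**10)
        assert t.direction == "purifying"

    def test_null_center_not_significant(self):
        t = neutrality_test(SubstCounts(S=25, N=75, Sd=5, Nd=15))
        assert t.p_value > 0.4

    def test_requires_differences(self):
        with pytest.raises(ValueError):
            neutrality_test(SubstCounts(S=25, N=75, Sd=0, Nd=0))


def test_intact_group_has_lower_omega_than_degenerate(rng):
    """Fig-2-style contrast: pairs simulated under strong purifying selection
    show lower dN/dS than pairs under relaxed selection."""
    def medians(omega, n_pairs=15, n_codons=300):
        out = []
        for _ in range(n_pairs):
            anc = _random_codons(n_codons, rng, CILIATE_CODE)
            a = mutate_codon_sequence(anc, omega, 0.25, rng)
            b = mutate_codon_sequence(anc, omega, 0.25, rng)
            _, est = ng86(pairwise_codon_align(a, b))
            if est.valid:
                out.append(est.omega)
        return float(np.median(out))

    assert medians(0.1) < medians(0.3)


def test_omega_distribution_summary_shape():
    import pandas as pd

    df = pd.DataFrame(
        {
            "family": ["TBE1"] * 4,
            "role": ["42kD"] * 4,
            "integrity_class": ["intact", "intact", "degenerate", "degenerate"],
            "omega": [0.1, 0.2, 0.3, np.nan],
            "valid": [True, True, True, False],
            "invalid_reason": [None, None, None, "dS below 0.01"],
        }
    )
    out = omega_distribution(df)
    intact = out[out["integrity_class"] == "intact"].iloc[0]
    assert intact["n"] == 2 and intact["omega_median"] == pytest.approx(0.15)
    degen = out[out["integrity_class"] == "degenerate"].iloc[0]
    assert degen["n_excluded"] == 1
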