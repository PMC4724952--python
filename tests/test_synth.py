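"""Generator tests: templates, codon mutation process, implant truth."""

from collections import Counter

import numpy as np
import pytest

from tbescan import refdata
from tbescan.seqcore import CILIATE_CODE, reverse_complement, translate
from tbescan.synth import (
    SynthConfig,
    _random_codons,
    build_templates,
    mutate_codon_sequence,
    sample_biased_positions,
    simulate_genome,
)


def test_templates_have_telomeric_tirs_and_determinism():
    cfg = SynthConfig()
    t1 = build_templates(cfg)
    t2 = build_templates(cfg)
    assert set(t1) == set(refdata.FAMILIES)
    for fam, tpl in t1.items():
        motif = refdata.TELOMERIC_CANONICAL
        variant = refdata.TELOMERIC_VARIANT
        assert tpl.tir_left.startswith(motif) or tpl.tir_left.startswith(variant)
        assert tpl.tir_right == reverse_complement(tpl.tir_left)
        for role, cds in tpl.orfs.items():
            assert all(not CILIATE_CODE.is_stop(c) for c in cds)
    assert all(t1[f].orfs == t2[f].orfs for f in t1)  # same seed, same templates


def test_templates_zero_between_divergence_gives_identical_orfs():
    cfg = SynthConfig(within_family_divergence=0.0, between_family_divergence=0.0)
    t = build_templates(cfg)
    for role in ("42kD", "22kD", "57kD"):
        seqs = {tuple(t[f].orfs[role]) for f in t}
        assert len(seqs) == 1


def test_incompatible_divergence_targets_rejected():
    with pytest.raises(ValueError, match="divergence"):
        SynthConfig(within_family_divergence=0.4, between_family_divergence=0.3).validate()


def test_template_family_structure():
    """TBE1/TBE2 templates are mutually closer than either is to TBE3, and
    the 57kD ORF is the most diverged between families."""
    t = build_templates(SynthConfig())

    def protein_identity(a, b):
        pa, pb = translate("".join(a)), translate("".join(b))
        return np.mean([x == y for x, y in zip(pa, pb)])

    for role in ("42kD", "22kD", "57kD"):
        d12 = protein_identity(t["TBE1"].orfs[role], t["TBE2.1"].orfs[role])
        d13 = protein_identity(t["TBE1"].orfs[role], t["TBE3"].orfs[role])
        assert d12 > d13
    id_42 = protein_identity(t["TBE1"].orfs["42kD"], t["TBE3"].orfs["42kD"])
    id_57 = protein_identity(t["TBE1"].orfs["57kD"], t["TBE3"].orfs["57kD"])
    assert id_57 < id_42
    # TBE2 subfamilies share 42kD/22kD but differ in 57kD
    assert t["TBE2.1"].orfs["42kD"] == t["TBE2.2"].orfs["42kD"]
    assert t["TBE2.1"].orfs["57kD"] != t["TBE2.2"].orfs["57kD"]


def test_mutate_codon_sequence_invariants(rng):
    codons = _random_codons(200, rng, CILIATE_CODE)
    assert mutate_codon_sequence(codons, omega=1.0, d=0.0, rng=rng) == codons
    out = mutate_codon_sequence(codons, omega=0.0, d=0.5, rng=rng)
    assert translate("".join(out)) == translate("".join(codons))  # only synonymous
    assert out != codons
    out2 = mutate_codon_sequence(codons, omega=0.5, d=0.5, rng=rng)
    assert all(not CILIATE_CODE.is_stop(c) for c in out2)  # never creates stops


class TestSimulatedGenome:
    def test_bookkeeping(self, small_sim):
        cfg = small_sim.config
        assert len(small_sim.truth) == 4 * cfg.copies_per_family
        fams = Counter(t.family for t in small_sim.truth)
        assert all(fams[f] == cfg.copies_per_family for f in refdata.FAMILIES)
        n_partial = sum(t.completeness == "partial" for t in small_sim.truth)
        assert n_partial == round(cfg.partial_copy_fraction * len(small_sim.truth))
        for t in small_sim.truth:
            assert 0 <= t.start < t.end <= len(small_sim.assembly[t.contig])
            if t.completeness == "complete":
                assert t.tir_left is not None and t.tir_right is not None

    def test_same_seed_identical_output(self, small_sim):
        again = simulate_genome(small_sim.config)
        assert again.assembly.contigs == small_sim.assembly.contigs

    def test_tsd_duplicated_on_both_flanks(self, small_sim):
        for t in small_sim.truth:
            seq = small_sim.assembly[t.contig]
            k = len(t.tsd)
            assert seq[t.start - k : t.start] == t.tsd
            assert seq[t.end : t.end + k] == t.tsd

    def test_truth_orfs_translate_cleanly_after_undoing_frameshifts(self, small_sim):
        """Extracted ORFs, with recorded indels undone, contain no internal
        stop except at recorded hotspot positions."""
        for t in small_sim.truth:
            for role, (a, b, strand) in t.orfs.items():
                s = small_sim.assembly[t.contig][a:b]
                if strand == "-":
                    s = reverse_complement(s)
                for _, ci, ntpos, kind in sorted(
                    (f for f in t.frameshifts if f[0] == role), key=lambda f: -f[2]
                ):
                    s = s[:ntpos] + s[ntpos + 1 :] if kind == 1 else s[:ntpos] + "N" + s[ntpos:]
                assert len(s) % 3 == 0
                prot = translate(s)
                recorded = {r for ro, r in t.stops if ro == role}
                assert {i for i, aa in enumerate(prot) if aa == "*"} <= recorded

    def test_mds_fraction_near_target(self, small_sim):
        mds_bp = sum(iv.length for iv in small_sim.mds_track)
        frac = mds_bp / small_sim.assembly.total_length
        assert abs(frac - small_sim.config.mds_genome_fraction) < 0.02

    def test_hotspot_fraction_matches_config(self):
        cfg = SynthConfig(
            seed=11, n_contigs=10, contig_length_bp=50_000, copies_per_family=10,
            stop_hotspots=(("TBE3", "42kD", 70, 0.8),), partial_copy_fraction=0.0,
            satellite_units=(),
        )
        sim = simulate_genome(cfg)
        tbe3 = [t for t in sim.truth if t.family == "TBE3"]
        with_stop = [t for t in tbe3 if ("42kD", 69) in t.stops]
        assert len(with_stop) == round(0.8 * len(tbe3))


def test_fragmentation_bisects_elements():
    cfg = SynthConfig(
        seed=3, n_contigs=6, contig_length_bp=40_000, copies_per_family=2,
        fragmentation=1.0, partial_copy_fraction=0.0, satellite_units=(),
    )
    sim = simulate_genome(cfg)
    bisected = [t for t in sim.truth if t.bisected]
    assert bisected and all(t.completeness == "partial" for t in bisected)
    for t in sim.truth:
        assert t.end <= len(sim.assembly[t.contig])


def test_overdense_placement_raises():
    with pytest.raises(RuntimeError, match="place"):
        sample_biased_positions(
            50, 20_000, [], 1.0, np.random.default_rng(0), min_separation=5_000,
            max_tries=2_000,
        )


def test_biased_positions_prefer_mds(rng):
    mds = [(40_000, 60_000)]
    pos = sample_biased_positions(400, 100_000, mds, 4.0, rng)
    near = sum(1 for p in pos if 39_500 <= p < 60_500)
    assert near / len(pos) > 0.4  # ~0.205 bp fraction, 4x bias -> ~0.51
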