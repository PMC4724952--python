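"""Synthetic germline-genome generator with implanted TBE elements and truth.

The generator emulates the features of a ciliate germline (micronuclear)
assembly that the pipeline consumes: a multi-contig background, four TBE
families built on published TIR consensi, three ORFs per element (42kD
transposase and 57kD ORF forward, 22kD reversed) separated by a ~200 bp
tandem-repeat spacer, target-site duplications flanking each insertion,
codon-level divergence under a configurable dN/dS, lineage-specific stop
hotspots, 1-bp frameshift indels, degenerate partial copies, MDS and
satellite annotation tracks, and optional contig fragmentation.  Every copy
is recorded in an :class:`ImplantTruth`-style ledger so that recall,
precision and parameter recovery can be scored exactly.

Randomness is split into fixed named streams derived from the master seed
(templates / tracks / placement / mutation / degradation), so results are
byte-identical for a given seed and robust to draw-count changes in one
stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import refdata
from .seqcore import (
    CILIATE_CODE,
    GeneticCode,
    GenomeAssembly,
    GFF3Feature,
    Interval,
    reverse_complement,
    translate,
    write_bed,
    write_gff3,
)

_NTS = np.array(list("ACGT"))

ROLES = refdata.ORF_ROLES


@dataclass
class SynthConfig:
    """Study conditions for the synthetic genome.

    Defaults describe a desk-scale analog of the published survey: four
    families of fifteen copies each on a ~3 Mb assembly, 0.08 substitutions
    per site of within-family divergence, dN/dS per ORF in the published
    0.1-0.3 range, frameshift and stop-hotspot rates patterned on the
    published prevalence table, an MDS track covering 11.1% of the genome
    with a 2x insertion bias toward it, and 380 bp / 170 bp satellite
    repeats near their published genome shares.
    """

    seed: int = 42
    n_contigs: int = 40
    contig_length_bp: int = 75_000
    gc_content: float = 0.5
    copies_per_family: int = 15
    within_family_divergence: float = 0.08
    between_family_divergence: float = 0.30
    omega_per_orf: dict[str, float] = field(
        default_factory=lambda: {"42kD": 0.15, "22kD": 0.20, "57kD": 0.25}
    )
    frameshift_prob: dict[str, float] = field(
        default_factory=lambda: {"42kD": 0.70, "22kD": 0.55, "57kD": 0.80}
    )
    #: (family, role, 1-based residue, fraction of eligible copies)
    stop_hotspots: tuple = (("TBE3", "42kD", 70, 0.8),)
    partial_copy_fraction: float = 0.10
    mds_genome_fraction: float = 0.111
    mds_segment_bp: int = 2000
    mds_bias: float = 2.0
    mds_window_bp: int = 500
    satellite_units: tuple = ((380, 110), (170, 210))
    fragmentation: float = 0.0
    tsd_len: int = 2
    protect_telomeric_motif: bool = True

    def validate(self) -> None:
        for name in ("partial_copy_fraction", "mds_genome_fraction", "fragmentation", "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for d in (self.frameshift_prob,):
            for r, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"frameshift_prob[{r}]={v} outside [0, 1]")
        if self.within_family_divergence > self.between_family_divergence:
            raise ValueError(
                "within-family divergence must be below between-family divergence"
            )
        if not 2 <= self.tsd_len <= 10:
            raise ValueError("tsd_len must be in 2..10")
        if self.mds_bias < 1.0:
            raise ValueError("mds_bias must be >= 1")


@dataclass
class TBETemplate:
    """Ancestral (consensus-like) state of one TBE family."""

    family: str
    tir_left: str
    tir_right: str
    orfs: dict[str, list[str]]  # role -> ancestral stop-free codon list
    spacer: str
    gap_42_22: int
    tir_to_42_dist: int
    dist_57_to_tir: int
    tsd_len: int


@dataclass
class ElementTruth:
    """Ground truth for one implanted copy (final genome coordinates)."""

    id: str
    family: str
    contig: str
    start: int
    end: int
    strand: str
    completeness: str  # complete | partial
    tsd: str
    tir_left: tuple[int, int] | None
    tir_right: tuple[int, int] | None
    orfs: dict[str, tuple[int, int, str]]  # role -> (start, end, strand)
    frameshifts: list[tuple[str, int, int, int]]  # (role, codon idx 0-based, nt pos in CDS, +1/-1)
    stops: list[tuple[str, int]]  # (role, residue 0-based)
    bisected: bool = False

    @property
    def interval(self) -> Interval:
        return Interval(self.contig, self.start, self.end, self.strand)

    def orf_interval(self, role: str) -> Interval:
        s, e, st = self.orfs[role]
        return Interval(self.contig, s, e, st)


@dataclass
class SimulatedGenome:
    assembly: GenomeAssembly
    truth: list[ElementTruth]
    mds_track: list[Interval]
    satellite_tracks: dict[str, list[Interval]]
    templates: dict[str, TBETemplate]
    queries: dict[str, str]  # role -> ancestral protein (search queries)
    config: SynthConfig


# ---------------------------------------------------------------------------
# Codon-level mutation process
# ---------------------------------------------------------------------------

def _random_codons(n: int, rng: np.random.Generator, code: GeneticCode) -> list[str]:
    codons = []
    while len(codons) < n:
        c = "".join(_NTS[rng.integers(0, 4, 3)])
        if not code.is_stop(c):
            codons.append(c)
    return codons


def mutate_codon_sequence(
    codons: list[str],
    omega: float,
    d: float,
    rng: np.random.Generator,
    code: GeneticCode = CILIATE_CODE,
) -> list[str]:
    """Evolve a stop-free codon sequence by ``Poisson(d * n)`` accepted
    single-nucleotide substitutions.

    Proposals are uniform over the 9 single-nucleotide neighbours of a random
    codon; synonymous proposals are always accepted, nonsynonymous ones with
    probability ``omega``, and proposals creating a stop codon are re-drawn.
    ``d`` is the expected number of accepted substitutions per codon.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    for c in codons:
        if code.is_stop(c):
            raise ValueError("input contains a stop codon")
    out = list(codons)
    n = len(out)
    if n == 0 or d == 0:
        return out
    target = int(rng.poisson(d * n))
    accepted = 0
    guard = 0
    max_guard = 1000 * (target + 10)
    while accepted < target and guard < max_guard:
        guard += 1
        i = int(rng.integers(0, n))
        pos = int(rng.integers(0, 3))
        old = out[i]
        base = old[pos]
        new_base = str(_NTS[rng.integers(0, 4)])
        if new_base == base:
            continue
        cand = old[:pos] + new_base + old[pos + 1 :]
        if code.is_stop(cand):
            continue
        if code.amino_acid(cand) != code.amino_acid(old):
            if rng.random() >= omega:
                continue
        out[i] = cand
        accepted += 1
    return out


def _mutate_sites(seq: str, rate: float, rng: np.random.Generator, protect: int = 0,
                  protect_tail: int = 0) -> str:
    """Per-site substitutions at the given rate; the first ``protect`` and the
    last ``protect_tail`` positions are left untouched."""
    chars = list(seq)
    n = len(chars)
    hits = np.flatnonzero(rng.random(n) < rate)
    for i in hits:
        if i < protect or i >= n - protect_tail:
            continue
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

_FAMILY_TREE_BRANCHES = {
    # per-family total path length from the root, in units of the configured
    # between-family divergence; TBE1/TBE2 share an internal branch so that
    # they are mutually closer than either is to TBE3.
    "TBE3": 0.5,
    "_TBE12": 0.2,   # shared TBE1/TBE2 ancestor branch
    "TBE1": 0.3,
    "TBE2": 0.3,
}
_ROLE_DIVERGENCE_SCALE = {"42kD": 1.0, "22kD": 1.15, "57kD": 1.9}
#: extra 57kD-only branch separating each TBE2 subfamily from their ancestor
_TBE2_SUBFAMILY_57KD = 0.25


def build_templates(
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    code: GeneticCode = CILIATE_CODE,
    return_ancestor: bool = False,
):
    """Build the four family templates from a common ancestor.

    ORF divergence follows a fixed family tree (TBE1 and TBE2 sister to each
    other, TBE3 the outgroup) scaled by the configured between-family
    divergence, with the 57kD ORF evolving fastest and alone separating the
    TBE2.1 / TBE2.2 subfamilies.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    anc = {role: _random_codons(refdata.ORF_LENGTHS[role], rng, code) for role in ROLES}

    def evolve(codons: list[str], branch: float, role: str) -> list[str]:
        d = 3.0 * cfg.between_family_divergence * _ROLE_DIVERGENCE_SCALE[role] * branch
        return mutate_codon_sequence(codons, omega=1.0, d=d, rng=rng, code=code)

    node12 = {r: evolve(anc[r], _FAMILY_TREE_BRANCHES["_TBE12"], r) for r in ROLES}
    fam_orfs = {
        "TBE3": {r: evolve(anc[r], _FAMILY_TREE_BRANCHES["TBE3"], r) for r in ROLES},
        "TBE1": {r: evolve(node12[r], _FAMILY_TREE_BRANCHES["TBE1"], r) for r in ROLES},
    }
    tbe2 = {r: evolve(node12[r], _FAMILY_TREE_BRANCHES["TBE2"], r) for r in ROLES}
    fam_orfs["TBE2.1"] = {
        "42kD": list(tbe2["42kD"]),
        "22kD": list(tbe2["22kD"]),
        "57kD": evolve(tbe2["57kD"], _TBE2_SUBFAMILY_57KD, "57kD"),
    }
    fam_orfs["TBE2.2"] = {
        "42kD": list(tbe2["42kD"]),
        "22kD": list(tbe2["22kD"]),
        "57kD": evolve(tbe2["57kD"], _TBE2_SUBFAMILY_57KD, "57kD"),
    }

    templates = {}
    for fam in refdata.FAMILIES:
        ref = refdata.TIR_REFERENCES[fam]
        unit = "".join(_NTS[rng.integers(0, 4, 12)])
        spacer = unit * 17
        templates[fam] = TBETemplate(
            family=fam,
            tir_left=ref.sequence,
            tir_right=reverse_complement(ref.sequence),
            orfs=fam_orfs[fam],
            spacer=spacer,
            gap_42_22=int(rng.integers(80, 140)),
            tir_to_42_dist=ref.dist_to_42kD,
            dist_57_to_tir=ref.dist_from_57kD,
            tsd_len=cfg.tsd_len,
        )
    if return_ancestor:
        return templates, {r: translate("".join(anc[r]), code) for r in ROLES}
    return templates


# ---------------------------------------------------------------------------
# Per-copy element construction
# ---------------------------------------------------------------------------

@dataclass
class _BuiltElement:
    seq: str
    tir_left: tuple[int, int]
    tir_right: tuple[int, int]
    orfs: dict[str, tuple[int, int, str]]  # element coords, element-forward strand
    frameshifts: list[tuple[str, int, int, int]]
    stops: list[tuple[str, int]]
    completeness: str


def _motif_protect_lengths(tir: str) -> int:
    for motif in (refdata.TELOMERIC_CANONICAL, refdata.TELOMERIC_VARIANT):
        if tir.startswith(motif):
            return len(motif)
    return 0


def _build_copy(
    template: TBETemplate,
    cfg: SynthConfig,
    rng: np.random.Generator,
    deleted_roles: frozenset[str],
    hotspot_stops: list[tuple[str, int]],  # (role, residue 0-based), pre-assigned
    code: GeneticCode,
) -> _BuiltElement:
    div = cfg.within_family_divergence
    protect = _motif_protect_lengths(template.tir_left) if cfg.protect_telomeric_motif else 0
    tir_l = _mutate_sites(template.tir_left, div, rng, protect=protect)
    tir_r = _mutate_sites(template.tir_right, div, rng, protect_tail=protect)

    frameshifts: list[tuple[str, int, int, int]] = []
    stops: list[tuple[str, int]] = list(hotspot_stops)
    orf_nt: dict[str, str] = {}
    for role in ROLES:
        if role in deleted_roles:
            continue
        codons = mutate_codon_sequence(
            template.orfs[role], omega=cfg.omega_per_orf[role], d=3.0 * div, rng=rng, code=code
        )
        for r, residue in hotspot_stops:
            if r == role:
                codons[residue] = "TGA"
        nt = "".join(codons)
        if rng.random() < cfg.frameshift_prob[role]:
            codon_idx = int(rng.integers(0, len(codons)))
            nt_pos = 3 * codon_idx + int(rng.integers(0, 3))
            if rng.random() < 0.5:  # 1-nt insertion
                nt = nt[:nt_pos] + str(_NTS[rng.integers(0, 4)]) + nt[nt_pos:]
                frameshifts.append((role, codon_idx, nt_pos, +1))
            else:  # 1-nt deletion
                nt = nt[:nt_pos] + nt[nt_pos + 1 :]
                frameshifts.append((role, codon_idx, nt_pos, -1))
        orf_nt[role] = nt

    def pad(n: int) -> str:
        return "".join(_NTS[rng.integers(0, 4, n)]) if n > 0 else ""

    parts: list[str] = []
    orf_coords: dict[str, tuple[int, int, str]] = {}
    pos = 0

    def add(s: str) -> int:
        nonlocal pos
        parts.append(s)
        start = pos
        pos += len(s)
        return start

    tl_start = add(tir_l)
    add(pad(template.tir_to_42_dist))
    if "42kD" in orf_nt:
        s = add(orf_nt["42kD"] + "TGA")
        orf_coords["42kD"] = (s, s + len(orf_nt["42kD"]), "+")
    add(pad(template.gap_42_22))
    if "22kD" in orf_nt:
        s = add(reverse_complement(orf_nt["22kD"] + "TGA"))
        orf_coords["22kD"] = (s + 3, s + 3 + len(orf_nt["22kD"]), "-")
    spacer = _mutate_sites(template.spacer, div, rng)
    add(spacer)
    if "57kD" in orf_nt:
        s = add(orf_nt["57kD"] + "TGA")
        orf_coords["57kD"] = (s, s + len(orf_nt["57kD"]), "+")
    add(pad(template.dist_57_to_tir))
    tr_start = add(tir_r)

    completeness = "complete" if not deleted_roles else "partial"
    return _BuiltElement(
        seq="".join(parts),
        tir_left=(tl_start, tl_start + len(tir_l)),
        tir_right=(tr_start, tr_start + len(tir_r)),
        orfs=orf_coords,
        frameshifts=frameshifts,
        stops=sorted(stops),
        completeness=completeness,
    )


def _flip_built(b: _BuiltElement) -> _BuiltElement:
    """Reverse-complement an element and remap its internal coordinates."""
    L = len(b.seq)

    def flip_iv(t: tuple[int, int]) -> tuple[int, int]:
        return (L - t[1], L - t[0])

    orfs = {
        role: (*flip_iv((s, e)), "-" if st == "+" else "+")
        for role, (s, e, st) in b.orfs.items()
    }
    return _BuiltElement(
        seq=reverse_complement(b.seq),
        tir_left=flip_iv(b.tir_right),
        tir_right=flip_iv(b.tir_left),
        orfs=orfs,
        frameshifts=b.frameshifts,
        stops=b.stops,
        completeness=b.completeness,
    )


# ---------------------------------------------------------------------------
# Track construction and biased placement
# ---------------------------------------------------------------------------

def _random_background(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _place_nonoverlapping(
    contig_len: int, seg_len: int, n_seg: int, rng: np.random.Generator,
    occupied: list[tuple[int, int]] | None = None, tries: int = 2000,
) -> list[tuple[int, int]]:
    placed: list[tuple[int, int]] = list(occupied or [])
    out: list[tuple[int, int]] = []
    for _ in range(n_seg):
        for _ in range(tries):
            s = int(rng.integers(0, max(1, contig_len - seg_len)))
            iv = (s, s + seg_len)
            if all(iv[1] <= a or iv[0] >= b for a, b in placed):
                placed.append(iv)
                out.append(iv)
                break
    return sorted(out)


def _near_any(pos: int, ivs: np.ndarray, window: int) -> bool:
    """Is ``pos`` within ``window`` of any (start, end) row of ``ivs``?"""
    if len(ivs) == 0:
        return False
    return bool(np.any((pos >= ivs[:, 0] - window) & (pos < ivs[:, 1] + window)))


def sample_biased_positions(
    n: int,
    contig_len: int,
    mds: list[tuple[int, int]],
    bias: float,
    rng: np.random.Generator,
    window: int = 500,
    edge_margin: int = 600,
    min_separation: int = 0,
    max_tries: int = 200_000,
) -> list[int]:
    """Sample insertion positions with density ``bias`` : 1 for positions
    within ``window`` bp of an MDS interval versus elsewhere (rejection
    sampling; ``bias`` = 1 is the uniform null)."""
    ivs = np.array(mds, dtype=np.int64).reshape(-1, 2)
    chosen: list[int] = []
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} elements on a {contig_len} bp contig "
                f"(placed {len(chosen)}); density too high"
            )
        p = int(rng.integers(edge_margin, contig_len - edge_margin))
        if bias > 1.0 and not _near_any(p, ivs, window):
            if rng.random() >= 1.0 / bias:
                continue
        if min_separation and any(abs(p - q) < min_separation for q in chosen):
            continue
        chosen.append(p)
    return chosen


# ---------------------------------------------------------------------------
# Whole-genome simulation
# ---------------------------------------------------------------------------

def simulate_genome(cfg: SynthConfig, code: GeneticCode = CILIATE_CODE) -> SimulatedGenome:
    """Generate the assembly, implant truth and annotation tracks."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    (s_templates, s_tracks, s_place, s_mut, s_degrade) = ss.spawn(5)
    rng_t = np.random.default_rng(s_templates)
    rng_tracks = np.random.default_rng(s_tracks)
    rng_place = np.random.default_rng(s_place)
    rng_mut = np.random.default_rng(s_mut)
    rng_deg = np.random.default_rng(s_degrade)

    # queries are the ancestral ORF proteins: a single query per role, roughly
    # equidistant from all four families, mirroring the published use of one
    # protein query per ORF.
    templates, queries = build_templates(cfg, rng=rng_t, code=code, return_ancestor=True)

    families = list(refdata.FAMILIES)
    copy_families = [f for f in families for _ in range(cfg.copies_per_family)]
    n_total = len(copy_families)

    # --- degradation plan -------------------------------------------------
    n_partial = int(round(cfg.partial_copy_fraction * n_total))
    partial_ids = set(rng_deg.choice(n_total, size=n_partial, replace=False).tolist())
    deleted: dict[int, frozenset[str]] = {}
    for i in range(n_total):
        if i in partial_ids:
            k = 1 + int(rng_deg.random() < 0.4)
            roles = rng_deg.choice(len(ROLES), size=k, replace=False)
            deleted[i] = frozenset(ROLES[j] for j in roles)
        else:
            deleted[i] = frozenset()

    # --- stop hotspot plan (among copies retaining the ORF) ---------------
    hotspots: dict[int, list[tuple[str, int]]] = {i: [] for i in range(n_total)}
    for fam, role, residue_1based, frac in cfg.stop_hotspots:
        eligible = [
            i for i in range(n_total)
            if copy_families[i] == fam and role not in deleted[i]
        ]
        k = int(round(frac * len(eligible)))
        for i in rng_deg.choice(len(eligible), size=k, replace=False):
            hotspots[eligible[int(i)]].append((role, residue_1based - 1))

    # --- build copies ------------------------------------------------------
    built: list[_BuiltElement] = []
    for i in range(n_total):
        b = _build_copy(
            templates[copy_families[i]], cfg, rng_mut, deleted[i], hotspots[i], code
        )
        if rng_mut.random() < 0.5:
            b = _flip_built(b)
            strand = "-"
        else:
            strand = "+"
        built.append(b)
        b.strand = strand  # type: ignore[attr-defined]

    total_implant = sum(len(b.seq) for b in built)
    genome_bp = cfg.n_contigs * cfg.contig_length_bp
    if total_implant >= 0.5 * genome_bp:
        raise ValueError(
            f"implants ({total_implant} bp) exceed half the genome ({genome_bp} bp)"
        )

    # --- per-contig tracks and element assignment -------------------------
    contig_names = [f"contig_{i+1:03d}" for i in range(cfg.n_contigs)]
    mds_by_contig: dict[str, list[tuple[int, int]]] = {}
    sat_by_contig: dict[str, list[tuple[int, int, str]]] = {}
    sat_units: dict[str, str] = {}
    for unit_len, _ in cfg.satellite_units:
        sat_units[f"satellite-{unit_len}"] = "".join(_NTS[rng_tracks.integers(0, 4, unit_len)])

    for name in contig_names:
        L = cfg.contig_length_bp
        target = cfg.mds_genome_fraction * L
        n_full = int(target // cfg.mds_segment_bp)
        segs = _place_nonoverlapping(L, cfg.mds_segment_bp, n_full, rng_tracks)
        rem = int(target - n_full * cfg.mds_segment_bp)
        if rem > 100:
            segs += _place_nonoverlapping(L, rem, 1, rng_tracks, occupied=segs)
        mds_by_contig[name] = sorted(segs)
        sat_by_contig[name] = []

    # satellite arrays: tandem runs of ~25 units, placed away from MDS
    for unit_len, copies in cfg.satellite_units:
        label = f"satellite-{unit_len}"
        remaining = copies
        while remaining > 0:
            run = int(min(remaining, rng_tracks.integers(15, 35)))
            name = contig_names[int(rng_tracks.integers(0, cfg.n_contigs))]
            occupied = [(a, b) for a, b in mds_by_contig[name]]
            occupied += [(a, b) for a, b, _ in sat_by_contig[name]]
            placed = _place_nonoverlapping(
                cfg.contig_length_bp, run * unit_len, 1, rng_tracks, occupied=occupied
            )
            if placed:
                a, b = placed[0]
                sat_by_contig[name].append((a, b, label))
                remaining -= run
            else:
                break

    # --- element placement -------------------------------------------------
    order = rng_place.permutation(n_total)
    points_by_contig: dict[str, list[tuple[int, int]]] = {n: [] for n in contig_names}
    max_elem = max(len(b.seq) for b in built)
    for idx in order:
        b = built[int(idx)]
        for _ in range(4000):
            name = contig_names[int(rng_place.integers(0, cfg.n_contigs))]
            L = cfg.contig_length_bp
            p = int(rng_place.integers(600, L - 600))
            ivs = np.array(mds_by_contig[name], dtype=np.int64).reshape(-1, 2)
            if cfg.mds_bias > 1.0 and not _near_any(p, ivs, cfg.mds_window_bp):
                if rng_place.random() >= 1.0 / cfg.mds_bias:
                    continue
            sats = sat_by_contig[name]
            if any(a - 10 <= p < bb + 10 for a, bb, _ in sats):
                continue
            if any(abs(p - q) < max_elem + 1200 for q, _ in points_by_contig[name]):
                continue
            points_by_contig[name].append((p, int(idx)))
            break
        else:
            raise RuntimeError("could not place all elements; genome too dense")

    # --- assemble contigs ---------------------------------------------------
    contigs: dict[str, str] = {}
    truth: list[ElementTruth] = []
    mds_final: list[Interval] = []
    sat_final: dict[str, list[Interval]] = {lab: [] for lab in sat_units}

    for name in contig_names:
        L = cfg.contig_length_bp
        bg = _random_background(L, cfg.gc_content, rng_tracks)
        insertions = sorted(points_by_contig[name])
        k = cfg.tsd_len

        # shift insertion points to the nearest TA dinucleotide and enforce
        # TSD maximality (flanking bases outside the duplication differ)
        adjusted: list[tuple[int, int]] = []
        for p, idx in insertions:
            window = bg[max(0, p - 60) : p + 60]
            ta = np.flatnonzero((window[:-1] == 3) & (window[1:] == 0))  # T then A
            if len(ta):
                off = ta[np.argmin(np.abs(ta - 60))]
                p = max(0, p - 60) + int(off)
            if bg[p - 1] == bg[p + k]:
                choices = [x for x in range(4) if x != bg[p + k]]
                bg[p - 1] = choices[int(rng_tracks.integers(0, 3))]
            adjusted.append((p, idx))
        adjusted.sort()

        bg_str = "".join(_NTS[bg])
        pieces: list[str] = []
        out_len = 0
        cur = 0

        def emit_tracks(chunk_start: int, chunk_end: int, base: int) -> None:
            for a, b in mds_by_contig[name]:
                lo, hi = max(a, chunk_start), min(b, chunk_end)
                if lo < hi:
                    mds_final.append(Interval(name, base + lo - chunk_start, base + hi - chunk_start))
            for a, b, lab in sat_by_contig[name]:
                lo, hi = max(a, chunk_start), min(b, chunk_end)
                if lo < hi:
                    sat_final[lab].append(Interval(name, base + lo - chunk_start, base + hi - chunk_start))

        for p, idx in adjusted:
            b = built[idx]
            chunk = bg_str[cur : p + k]
            emit_tracks(cur, p + k, out_len)
            pieces.append(chunk)
            out_len += len(chunk)
            elem_start = out_len
            pieces.append(b.seq)
            out_len += len(b.seq)
            tsd = bg_str[p : p + k]
            orfs = {
                role: (elem_start + s, elem_start + e, st)
                for role, (s, e, st) in b.orfs.items()
            }
            truth.append(
                ElementTruth(
                    id=f"impl_{idx:04d}",
                    family=copy_families[idx],
                    contig=name,
                    start=elem_start,
                    end=elem_start + len(b.seq),
                    strand=b.strand,  # type: ignore[attr-defined]
                    completeness=b.completeness,
                    tsd=tsd,
                    tir_left=(elem_start + b.tir_left[0], elem_start + b.tir_left[1]),
                    tir_right=(elem_start + b.tir_right[0], elem_start + b.tir_right[1]),
                    orfs=orfs,
                    frameshifts=b.frameshifts,
                    stops=b.stops,
                )
            )
            cur = p
        chunk = bg_str[cur:]
        emit_tracks(cur, L, out_len)
        pieces.append(chunk)
        contigs[name] = "".join(pieces)

    truth.sort(key=lambda t: (t.contig, t.start))

    # --- optional contig fragmentation -------------------------------------
    if cfg.fragmentation > 0:
        contigs, truth, mds_final, sat_final = _fragment(
            cfg, contigs, truth, mds_final, sat_final, rng_place
        )

    assembly = GenomeAssembly(contigs)
    return SimulatedGenome(
        assembly=assembly,
        truth=truth,
        mds_track=sorted(mds_final),
        satellite_tracks={lab: sorted(v) for lab, v in sat_final.items()},
        templates=templates,
        queries=queries,
        config=cfg,
    )


def _fragment(cfg, contigs, truth, mds, sats, rng):
    """Bisect a fraction of elements with a contig break."""
    cut_elements = [t for t in truth if rng.random() < cfg.fragmentation]
    cuts_by_contig: dict[str, list[int]] = {}
    for t in cut_elements:
        cut = int(rng.integers(t.start + 200, t.end - 200))
        cuts_by_contig.setdefault(t.contig, []).append(cut)

    def remap(contig: str, pos: int, cuts: list[int]) -> tuple[str, int]:
        prev = 0
        for i, c in enumerate(sorted(cuts)):
            if pos < c:
                return (f"{contig}.{i+1}", pos - prev)
            prev = c
        return (f"{contig}.{len(cuts)+1}", pos - prev)

    new_contigs: dict[str, str] = {}
    for name, seq in contigs.items():
        cuts = sorted(cuts_by_contig.get(name, []))
        if not cuts:
            new_contigs[name] = seq
            continue
        prev = 0
        for i, c in enumerate(cuts):
            new_contigs[f"{name}.{i+1}"] = seq[prev:c]
            prev = c
        new_contigs[f"{name}.{len(cuts)+1}"] = seq[prev:]

    def remap_iv(iv: Interval) -> list[Interval]:
        cuts = sorted(cuts_by_contig.get(iv.contig, []))
        if not cuts:
            return [iv]
        out = []
        bounds = [0] + cuts + [len(contigs[iv.contig])]
        for i in range(len(bounds) - 1):
            lo, hi = max(iv.start, bounds[i]), min(iv.end, bounds[i + 1])
            if lo < hi:
                nm = f"{iv.contig}.{i+1}"
                out.append(Interval(nm, lo - bounds[i], hi - bounds[i], iv.strand))
        return out

    new_truth: list[ElementTruth] = []
    for t in truth:
        cuts = sorted(cuts_by_contig.get(t.contig, []))
        crossing = [c for c in cuts if t.start < c < t.end]
        if not crossing:
            nm, s = remap(t.contig, t.start, cuts)
            shift = s - t.start
            new_truth.append(
                ElementTruth(
                    id=t.id, family=t.family, contig=nm, start=s, end=t.end + shift,
                    strand=t.strand, completeness=t.completeness, tsd=t.tsd,
                    tir_left=tuple(x + shift for x in t.tir_left) if t.tir_left else None,
                    tir_right=tuple(x + shift for x in t.tir_right) if t.tir_right else None,
                    orfs={r: (a + shift, b + shift, st) for r, (a, b, st) in t.orfs.items()},
                    frameshifts=t.frameshifts, stops=t.stops,
                )
            )
        else:
            for side, piece in enumerate(remap_iv(Interval(t.contig, t.start, t.end, t.strand))):
                orfs = {}
                for r, (a, b, st) in t.orfs.items():
                    for piv in remap_iv(Interval(t.contig, a, b, st)):
                        if piv.contig == piece.contig and piv.length >= 30:
                            orfs[r] = (piv.start, piv.end, st)
                new_truth.append(
                    ElementTruth(
                        id=f"{t.id}.{side}", family=t.family, contig=piece.contig,
                        start=piece.start, end=piece.end, strand=t.strand,
                        completeness="partial", tsd=t.tsd,
                        tir_left=None, tir_right=None, orfs=orfs,
                        frameshifts=t.frameshifts, stops=t.stops, bisected=True,
                    )
                )

    new_mds = [iv for old in mds for iv in remap_iv(old)]
    new_sats = {lab: [iv for old in v for iv in remap_iv(old)] for lab, v in sats.items()}
    return new_contigs, sorted(new_truth, key=lambda t: (t.contig, t.start)), new_mds, new_sats


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_simulation(sim: SimulatedGenome, outdir: str | Path) -> None:
    """Write genome FASTA, truth (GFF3 + JSON), tracks (BED) and queries."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim.assembly.to_fasta(outdir / "genome.fa")
    write_bed(sim.mds_track, outdir / "mds.bed")
    for lab, ivs in sim.satellite_tracks.items():
        write_bed(ivs, outdir / f"{lab}.bed")
    feats = []
    for t in sim.truth:
        feats.append(
            GFF3Feature(
                interval=t.interval,
                feature_type="mobile_genetic_element",
                attributes={"ID": t.id, "family": t.family, "completeness": t.completeness},
            )
        )
        for role in ROLES:
            if role in t.orfs:
                feats.append(
                    GFF3Feature(
                        interval=t.orf_interval(role),
                        feature_type="CDS",
                        attributes={"Parent": t.id, "role": role},
                    )
                )
        for tir in (t.tir_left, t.tir_right):
            if tir:
                feats.append(
                    GFF3Feature(
                        interval=Interval(t.contig, tir[0], tir[1], t.strand),
                        feature_type="inverted_repeat",
                        attributes={"Parent": t.id},
                    )
                )
    write_gff3(feats, outdir / "truth.gff3")
    with open(outdir / "truth.json", "w") as fh:
        json.dump([asdict(t) for t in sim.truth], fh, indent=1)
    with open(outdir / "queries.faa", "w") as fh:
        for role, prot in sim.queries.items():
            fh.write(f">{role}\n{prot}\n")


def load_truth(path: str | Path) -> list[ElementTruth]:
    with open(path) as fh:
        raw = json.load(fh)
    out = []
    for d in raw:
        d["tir_left"] = tuple(d["tir_left"]) if d["tir_left"] else None
        d["tir_right"] = tuple(d["tir_right"]) if d["tir_right"] else None
        d["orfs"] = {r: tuple(v) for r, v in d["orfs"].items()}
        d["frameshifts"] = [tuple(x) for x in d["frameshifts"]]
        d["stops"] = [tuple(x) for x in d["stops"]]
        out.append(ElementTruth(**d))
    return out
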