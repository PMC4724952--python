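"""End-to-end pipeline driver, report tables and truth scoring.

Stages run in the order simulate (optional) -> search -> annotate -> tirscan
-> cluster -> integrity -> selection -> context, producing report tables
shaped like the published summaries: genomic distribution per family,
pairwise protein similarity, TIR/TSD/distance features, and stop/frameshift
prevalence, plus dN/dS distributions stratified by integrity class.  With a
synthetic run the implant ledger allows an exact scorecard (recall/precision
of complete calls, boundary error, family Rand index, TSD accuracy, hotspot
and omega recovery).
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import rand_score

from . import refdata
from .annotate import AnnotateConfig, TBEElement, assemble_elements, elements_to_gff3, element_table, flag_context
from .cluster import (
    ClusterConfig,
    assign_family_labels,
    neighbor_joining,
    pairwise_protein_similarity,
    two_pass_cluster,
)
from .context import AnnotationTrack, EnrichmentResult, enrichment_test, genome_fraction, nearest_distance
from .integrity import (
    CDSAlignment,
    P2DPenalties,
    align_protein_to_dna,
    call_integrity,
    consensus_protein,
    repair_sequence,
    stop_profile,
)
from .search import ScoringScheme, TranslatedHit, hits_to_frame, search_queries
from .seqcore import GenomeAssembly, Interval, read_fasta, read_track, reverse_complement, write_gff3
from .selection import ng86, omega_distribution, pairwise_codon_align, pooled_neutrality_test
from .synth import ROLES, SimulatedGenome, SynthConfig, simulate_genome, write_simulation
from .tirscan import call_tsd, detect_tir, distance_stats, tir_table

logger = logging.getLogger("tbescan")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; file paths or a synthetic config."""

    genome_fasta: str | None = None
    queries_fasta: str | None = None
    mds_track: str | None = None
    satellite_tracks: dict[str, str] = field(default_factory=dict)
    outdir: str | None = None
    seed: int = 42
    synthetic: SynthConfig | None = None
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)
    # shorter anchor words than the classic 50 bp: at the simulated
    # within-family divergence exact 50-mers are rare between copy pairs,
    # while the >= 70% identity edge floor still separates families.
    cluster: ClusterConfig = field(
        default_factory=lambda: ClusterConfig(anchor_word_size=28, cds_anchor_word_size=24)
    )
    penalties: P2DPenalties = field(default_factory=P2DPenalties)
    near_window_bp: int = 500
    max_tree_leaves_per_family: int = 8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("genome_fasta", "queries_fasta", "mds_track", "outdir", "seed", "near_window_bp"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "satellite_tracks" in raw:
            cfg.satellite_tracks = dict(raw["satellite_tracks"])
        if "synthetic" in raw:
            cfg.synthetic = SynthConfig(**(raw["synthetic"] or {}))
        for section, obj in (
            ("scheme", cfg.scheme),
            ("annotate", cfg.annotate),
            ("cluster", cfg.cluster),
            ("penalties", cfg.penalties),
        ):
            for k, v in (raw.get(section) or {}).items():
                setattr(obj, k, v)
        return cfg


@dataclass
class RunReport:
    elements: list[TBEElement]
    table1_distribution: pd.DataFrame
    table2_similarity: pd.DataFrame
    table3_tir: pd.DataFrame
    table4_integrity: pd.DataFrame
    omega_summary: pd.DataFrame
    omega_estimates: pd.DataFrame
    stop_profiles: dict[tuple[str, str], object]
    enrichment: dict[str, EnrichmentResult]
    neutrality: dict[tuple[str, str], object]
    trees_newick: dict[str, str]
    stage_counts: dict[str, int]
    stage_seconds: dict[str, float]
    params: dict
    sim: SimulatedGenome | None = None
    genome: GenomeAssembly | None = None


def _oriented_span_seq(e: TBEElement, genome: GenomeAssembly) -> str:
    s = genome[e.contig][e.span.start : e.span.end]
    return s if e.element_strand == "+" else reverse_complement(s)


def _oriented_orf_seq(e: TBEElement, role: str, genome: GenomeAssembly) -> str:
    iv = e.orf_hits[role].interval
    s = genome[e.contig][iv.start : iv.end]
    return s if iv.strand == "+" else reverse_complement(s)


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    t_all = time.time()
    stage_counts: dict[str, int] = {}
    stage_seconds: dict[str, float] = {}

    def tick(stage: str, t0: float, count: int) -> None:
        stage_seconds[stage] = round(time.time() - t0, 2)
        stage_counts[stage] = count
        logger.info("stage %s: %d records in %.1fs", stage, count, stage_seconds[stage])

    # --- inputs ------------------------------------------------------------
    t0 = time.time()
    sim = None
    if cfg.synthetic is not None:
        sim = simulate_genome(cfg.synthetic)
        genome = sim.assembly
        queries = sim.queries
        mds = AnnotationTrack("MDS", sim.mds_track)
        satellites = {
            lab: AnnotationTrack(lab, ivs) for lab, ivs in sim.satellite_tracks.items()
        }
    else:
        if cfg.genome_fasta is None or cfg.queries_fasta is None:
            raise ValueError("need genome_fasta and queries_fasta (or a synthetic config)")
        for p in (cfg.genome_fasta, cfg.queries_fasta):
            if not Path(p).exists():
                raise FileNotFoundError(f"input not found: {p}")
        from Bio import SeqIO

        genome = read_fasta(cfg.genome_fasta)
        queries = {r.id: str(r.seq) for r in SeqIO.parse(cfg.queries_fasta, "fasta")}
        mds = AnnotationTrack("MDS", read_track(cfg.mds_track)) if cfg.mds_track else None
        satellites = {
            lab: AnnotationTrack(lab, read_track(p)) for lab, p in cfg.satellite_tracks.items()
        }
    tick("input", t0, len(genome))

    # --- search ------------------------------------------------------------
    t0 = time.time()
    hits = search_queries(queries, genome, cfg.scheme)
    tick("search", t0, len(hits))

    # --- annotate ----------------------------------------------------------
    t0 = time.time()
    elements = assemble_elements(hits, cfg.annotate)
    flag_context(elements, genome, cfg.annotate)
    tick("annotate", t0, len(elements))

    # --- tirscan -----------------------------------------------------------
    t0 = time.time()
    for e in elements:
        detect_tir(e, genome)
        call_tsd(e, genome)
    tick("tirscan", t0, sum(e.n_tirs for e in elements))

    # --- cluster -----------------------------------------------------------
    t0 = time.time()
    complete = [e for e in elements if e.completeness == "complete"]
    elem_seqs = {e.id: _oriented_span_seq(e, genome) for e in complete}
    cds57 = {
        e.id: _oriented_orf_seq(e, "57kD", genome)
        for e in complete
        if "57kD" in e.orf_hits
    }
    truth_families = None
    if sim is not None:
        truth_families = {
            e.id: t.family
            for e in elements
            for t in sim.truth
            if _spans_match(e, t)
        }
    if len(elem_seqs) >= 2:
        clusters = two_pass_cluster(elem_seqs, cds57, cfg.cluster)
        labels = assign_family_labels(clusters, truth_families)
        for e in elements:
            e.family = labels.get(e.id)
    else:
        clusters = None
    tick("cluster", t0, len(clusters.clusters) if clusters else 0)

    # --- integrity ---------------------------------------------------------
    t0 = time.time()
    _integrity_stage(elements, genome, queries, cfg)
    integrity_rows = []
    for e in elements:
        for role, cds in (e.cds or {}).items():
            ic = call_integrity(cds)
            integrity_rows.append(
                {
                    "element": e.id,
                    "family": e.family or "unclassified",
                    "role": role,
                    "completeness": e.completeness,
                    "has_stop": ic.has_premature_stop,
                    "has_frameshift": ic.has_frameshift,
                    "n_stops": ic.n_stops,
                    "n_frameshifts": ic.n_frameshifts,
                    "coverage": cds.query_coverage,
                }
            )
    integrity_df = pd.DataFrame(integrity_rows)
    profiles = {}
    if len(integrity_df):
        for (fam, role), grp in integrity_df.groupby(["family", "role"]):
            group_cds = [elements_by_id(elements)[eid].cds[role] for eid in grp["element"]]
            profiles[(fam, role)] = stop_profile(group_cds, family=fam, role=role)
    tick("integrity", t0, len(integrity_rows))

    # --- selection ---------------------------------------------------------
    t0 = time.time()
    omega_df, neutrality = _selection_stage(elements, integrity_df)
    tick("selection", t0, len(omega_df))

    # --- context -----------------------------------------------------------
    t0 = time.time()
    enrichment: dict[str, EnrichmentResult] = {}
    if mds is not None and elements:
        for e in elements:
            e.near_mds = nearest_distance(e, mds) <= cfg.near_window_bp
        enrichment["MDS"] = enrichment_test(
            elements, mds, cfg.near_window_bp, genome=genome
        )
    for lab, track in satellites.items():
        if elements:
            enrichment[lab] = enrichment_test(
                elements, track, cfg.near_window_bp, genome=genome
            )
    tick("context", t0, len(enrichment))

    # --- report ------------------------------------------------------------
    t0 = time.time()
    table1 = element_table(elements)
    table2, trees = _protein_similarity_stage(elements, genome, cfg)
    table3 = tir_table(elements, genome)
    table4 = _integrity_prevalence(integrity_df)
    omega_summary = omega_distribution(omega_df) if len(omega_df) else pd.DataFrame()
    tick("report", t0, len(table1))

    params = {
        "seed": cfg.seed,
        "scheme": {k: v for k, v in asdict_safe(cfg.scheme).items() if k != "matrix"},
        "annotate": asdict_safe(cfg.annotate),
        "cluster": asdict_safe(cfg.cluster),
        "penalties": asdict_safe(cfg.penalties),
        "near_window_bp": cfg.near_window_bp,
        "synthetic": asdict_safe(cfg.synthetic) if cfg.synthetic else None,
        "total_seconds": round(time.time() - t_all, 2),
    }
    report = RunReport(
        elements=elements,
        table1_distribution=table1,
        table2_similarity=table2,
        table3_tir=table3,
        table4_integrity=table4,
        omega_summary=omega_summary,
        omega_estimates=omega_df,
        stop_profiles=profiles,
        enrichment=enrichment,
        neutrality=neutrality,
        trees_newick=trees,
        stage_counts=stage_counts,
        stage_seconds=stage_seconds,
        params=params,
        sim=sim,
        genome=genome,
    )
    if cfg.outdir:
        write_report(report, cfg.outdir)
    return report


def asdict_safe(obj) -> dict:
    try:
        return asdict(obj)
    except TypeError:
        return {k: v for k, v in vars(obj).items() if not k.startswith("_")}


def elements_by_id(elements: list[TBEElement]) -> dict[str, TBEElement]:
    return {e.id: e for e in elements}


def _spans_match(e: TBEElement, t) -> bool:
    if e.contig != t.contig:
        return False
    ov = min(e.span.end, t.end) - max(e.span.start, t.start)
    return ov > 0.5 * min(e.span.length, t.end - t.start)


def _integrity_stage(elements, genome, queries, cfg: PipelineConfig) -> None:
    """Two-pass CDS extraction: global queries first, then per-family
    consensus proteins rebuilt from the first pass."""
    margin = 250
    firsts: dict[tuple[str, str], list[CDSAlignment]] = {}
    for e in elements:
        e.cds = {}
        for role, mh in e.orf_hits.items():
            if role not in queries:
                continue
            iv = mh.interval
            a = max(0, iv.start - margin)
            b = min(len(genome[e.contig]), iv.end + margin)
            region = genome[e.contig][a:b]
            cds = align_protein_to_dna(
                queries[role], region, cfg.penalties, role=role,
                contig=e.contig, region_start=a,
            )
            e.cds[role] = cds
            firsts.setdefault((e.family or "unclassified", role), []).append(cds)
    # refinement pass with family consensus queries
    consensi = {
        key: consensus_protein(alns, len(queries[key[1]]))
        for key, alns in firsts.items()
    }
    for e in elements:
        for role in list(e.cds):
            key = (e.family or "unclassified", role)
            if key not in consensi:
                continue
            iv = e.orf_hits[role].interval
            a = max(0, iv.start - margin)
            b = min(len(genome[e.contig]), iv.end + margin)
            region = genome[e.contig][a:b]
            e.cds[role] = align_protein_to_dna(
                consensi[key], region, cfg.penalties, role=role,
                contig=e.contig, region_start=a,
            )


def _selection_stage(elements, integrity_df):
    """Pairwise dN/dS within family x role over repaired CDSs."""
    rows = []
    neutrality = {}
    if not len(integrity_df):
        return pd.DataFrame(
            columns=["family", "role", "id_a", "id_b", "S", "N", "Sd", "Nd",
                     "dS", "dN", "omega", "valid", "invalid_reason", "integrity_class"]
        ), neutrality
    by_id = elements_by_id(elements)
    flags = {
        (r.element, r.role): (r.has_stop or r.has_frameshift)
        for r in integrity_df.itertuples()
    }
    for (fam, role), grp in integrity_df.groupby(["family", "role"]):
        repaired = {}
        for eid in grp["element"]:
            cds = by_id[eid].cds[role]
            try:
                codons, qs = repair_sequence(cds)
            except ValueError:
                continue
            repaired[eid] = codons
        counts_for_pool = []
        for a, b in itertools.combinations(sorted(repaired), 2):
            aln = pairwise_codon_align(repaired[a], repaired[b])
            if aln is None:
                continue
            counts, est = ng86(aln)
            degenerate_a, degenerate_b = flags[(a, role)], flags[(b, role)]
            cls = (
                "intact" if not (degenerate_a or degenerate_b)
                else "degenerate" if (degenerate_a and degenerate_b)
                else "mixed"
            )
            rows.append(
                {
                    "family": fam, "role": role, "id_a": a, "id_b": b,
                    "S": counts.S, "N": counts.N, "Sd": counts.Sd, "Nd": counts.Nd,
                    "dS": est.dS, "dN": est.dN, "omega": est.omega,
                    "valid": est.valid, "invalid_reason": est.invalid_reason,
                    "integrity_class": cls,
                }
            )
            if est.valid:
                counts_for_pool.append(counts)
        if counts_for_pool:
            neutrality[(fam, role)] = pooled_neutrality_test(counts_for_pool)
    return pd.DataFrame(rows), neutrality


def _protein_similarity_stage(elements, genome, cfg: PipelineConfig):
    """Per-role similarity matrices over family groups and NJ trees."""
    from .seqcore import CILIATE_CODE, translate

    by_role: dict[str, dict[str, list[tuple[str, str]]]] = {}
    for e in elements:
        if e.completeness != "complete" or not e.family:
            continue
        for role, cds in (e.cds or {}).items():
            prot = cds.aligned_protein.replace("-", "").replace("*", "X")
            if len(prot) < 30:
                continue
            by_role.setdefault(role, {}).setdefault(e.family, []).append((e.id, prot))
    rows = []
    trees = {}
    for role, groups in sorted(by_role.items()):
        capped = {
            fam: [p for (_, p) in members[: cfg.max_tree_leaves_per_family]]
            for fam, members in groups.items()
        }
        df = pairwise_protein_similarity(capped)
        df.insert(0, "role", role)
        rows.append(df)
        # NJ tree over the same sampled members
        leaves = [
            (f"{fam}|{eid}", prot)
            for fam, members in groups.items()
            for (eid, prot) in members[: cfg.max_tree_leaves_per_family]
        ]
        if len(leaves) >= 3:
            from .cluster import protein_percent_similarity

            n = len(leaves)
            dm = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d = 1.0 - protein_percent_similarity(leaves[i][1], leaves[j][1]) / 100.0
                    dm[i, j] = dm[j, i] = d
            tree = neighbor_joining([name for name, _ in leaves], dm)
            trees[role] = str(tree).strip()
    table2 = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    return table2, trees


def _integrity_prevalence(integrity_df: pd.DataFrame) -> pd.DataFrame:
    if not len(integrity_df):
        return pd.DataFrame(columns=["family", "role", "n", "pct_stop", "pct_frameshift"])
    rows = []
    for (fam, role), grp in integrity_df.groupby(["family", "role"]):
        rows.append(
            {
                "family": fam,
                "role": role,
                "n": len(grp),
                "pct_stop": 100.0 * grp["has_stop"].mean(),
                "pct_frameshift": 100.0 * grp["has_frameshift"].mean(),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth scoring
# ---------------------------------------------------------------------------

def compare_to_truth(report: RunReport, sim: SimulatedGenome | None = None) -> dict:
    """Scorecard of the pipeline against the implant ledger."""
    sim = sim or report.sim
    if sim is None:
        raise ValueError("no synthetic truth available")
    elements = report.elements
    for e in elements:
        if e.contig not in sim.assembly.contigs:
            raise ValueError(f"element contig {e.contig} absent from truth assembly")
    truth = sim.truth
    matches = {}
    for e in elements:
        for t in truth:
            if _spans_match(e, t):
                matches[e.id] = t
                break
    truth_complete = [t for t in truth if t.completeness == "complete"]
    called_complete = [e for e in elements if e.completeness == "complete"]
    matched_complete = [
        e for e in called_complete
        if e.id in matches and matches[e.id].completeness == "complete"
    ]
    recall = (
        len({matches[e.id].id for e in matched_complete}) / len(truth_complete)
        if truth_complete else float("nan")
    )
    precision = (
        len(matched_complete) / len(called_complete) if called_complete else float("nan")
    )
    boundary_errors = []
    span_errors = []
    for e in matched_complete:
        t = matches[e.id]
        ta = min(v[0] for v in t.orfs.values())
        tb = max(v[1] for v in t.orfs.values())
        env = e.orf_envelope()
        boundary_errors.append(abs(env.start - ta))
        boundary_errors.append(abs(env.end - tb))
        span_errors.append(abs(e.span.start - t.start) + abs(e.span.end - t.end))
    # family recovery (complete, matched elements)
    labeled = [e for e in matched_complete if e.family]
    rand = float("nan")
    if labeled:
        rand = rand_score(
            [matches[e.id].family for e in labeled], [e.family for e in labeled]
        )
    tsd_ok = sum(1 for e in matched_complete if e.tsd == matches[e.id].tsd)
    # hotspot recovery
    hotspots = {}
    if sim.config.stop_hotspots:
        for fam, role, residue, frac in sim.config.stop_hotspots:
            prof = report.stop_profiles.get((fam, role))
            obs = float(prof.fractions[residue - 1]) if prof is not None else float("nan")
            hotspots[f"{fam}:{role}:{residue}"] = {
                "implanted_fraction": frac,
                "observed_fraction": obs,
            }
    # omega recovery per role (valid pairs, within family, intact+degenerate)
    omega_medians = {}
    if len(report.omega_estimates):
        valid = report.omega_estimates[report.omega_estimates["valid"]]
        for role, grp in valid.groupby("role"):
            omega_medians[role] = {
                "median_omega": float(grp["omega"].median()),
                "target_omega": sim.config.omega_per_orf.get(role),
                "n_pairs": len(grp),
            }
    return {
        "n_truth": len(truth),
        "n_truth_complete": len(truth_complete),
        "n_called": len(elements),
        "n_called_complete": len(called_complete),
        "complete_recall": recall,
        "complete_precision": precision,
        "boundary_error_mean_bp": float(np.mean(boundary_errors)) if boundary_errors else float("nan"),
        "boundary_error_max_bp": float(np.max(boundary_errors)) if boundary_errors else float("nan"),
        "span_error_mean_bp": float(np.mean(span_errors)) if span_errors else float("nan"),
        "family_rand_index": rand,
        "n_families_called": len({e.family for e in labeled}),
        "tsd_accuracy": tsd_ok / len(matched_complete) if matched_complete else float("nan"),
        "hotspots": hotspots,
        "omega_recovery": omega_medians,
    }


# ---------------------------------------------------------------------------
# placement-enrichment calibration (MDS bias)
# ---------------------------------------------------------------------------

def placement_calibration(
    n_runs: int = 100,
    n_null: int = 250,
    n_biased: int = 200,
    bias: float = 2.0,
    genome_bp: int = 1_000_000,
    mds_fraction: float = 0.11,
    n_blocks: int = 2,
    window_bp: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error and power of the placement-enrichment test.

    Uniform and bias-weighted placements are simulated on a genome whose MDS
    track consists of a few large blocks (so the window halo is negligible
    against the bp fraction the test uses as its expectation), and the
    fraction of runs rejecting at ``alpha`` is reported for each.
    """
    from .synth import sample_biased_positions

    block = int(mds_fraction * genome_bp / n_blocks)
    starts = np.linspace(0.15 * genome_bp, 0.75 * genome_bp, n_blocks).astype(int)
    mds = [(int(s), int(s) + block) for s in starts]
    track = AnnotationTrack("MDS", [Interval("sim", a, b) for a, b in mds])
    frac = sum(b - a for a, b in mds) / genome_bp
    rej_null = rej_bias = 0
    for child in np.random.SeedSequence(seed).spawn(n_runs):
        rng = np.random.default_rng(child)
        pos = sample_biased_positions(n_null, genome_bp, mds, 1.0, rng, window=window_bp)
        res = enrichment_test(
            [Interval("sim", p, p + 1) for p in pos], track, window_bp, expected=frac
        )
        rej_null += res.p_value < alpha
        posb = sample_biased_positions(n_biased, genome_bp, mds, bias, rng, window=window_bp)
        resb = enrichment_test(
            [Interval("sim", p, p + 1) for p in posb], track, window_bp, expected=frac
        )
        rej_bias += resb.p_value < alpha
    return {
        "n_runs": n_runs,
        "type_i_rate": rej_null / n_runs,
        "power": rej_bias / n_runs,
        "expected_fraction": frac,
        "alpha": alpha,
        "bias": bias,
    }


# ---------------------------------------------------------------------------
# artifact writing
# ---------------------------------------------------------------------------

def write_report(report: RunReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.table1_distribution.to_csv(outdir / "table1_distribution.tsv", sep="\t", index=False)
    report.table2_similarity.to_csv(outdir / "table2_similarity.tsv", sep="\t", index=False)
    report.table3_tir.to_csv(outdir / "table3_tir.tsv", sep="\t", index=False)
    report.table4_integrity.to_csv(outdir / "table4_integrity.tsv", sep="\t", index=False)
    report.omega_estimates.to_csv(outdir / "omega_pairs.tsv", sep="\t", index=False)
    if len(report.omega_summary):
        report.omega_summary.to_csv(outdir / "omega_summary.tsv", sep="\t", index=False)
    write_gff3(elements_to_gff3(report.elements), outdir / "elements.gff3")
    for role, nwk in report.trees_newick.items():
        (outdir / f"tree_{role}.nwk").write_text(nwk + "\n")
    summary = {
        "stage_counts": report.stage_counts,
        "stage_seconds": report.stage_seconds,
        "params": report.params,
        "enrichment": {
            lab: asdict_safe(res) for lab, res in report.enrichment.items()
        },
        "neutrality": {
            f"{fam}:{role}": asdict_safe(t) for (fam, role), t in report.neutrality.items()
        },
    }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=1, default=str))
    if report.sim is not None:
        write_simulation(report.sim, outdir / "simulation")
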