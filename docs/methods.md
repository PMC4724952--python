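# Methods

This note documents the models, conventions and numerical choices behind
`tbescan`, in the package's own terms: what each stage computes, which knobs
matter, what the synthetic generator does and does not emulate, and where
design was genuinely open.

## Coordinates, alphabets, genetic code

All coordinates are 0-based half-open on the contig forward strand;
conversion to 1-based inclusive happens only in the GFF3 writer. Sequences
are uppercase `{A,C,G,T,N}`; `U` maps to `T` on ingestion. Translation uses
the ciliate nuclear code (NCBI table 6): `TAA`/`TAG` encode glutamine and
`TGA` is the sole stop. `N`-containing codons translate to `X`, which never
scores positively in any alignment (conservative treatment of ambiguity).

## Translated search

Each ORF protein query is aligned by exact Smith–Waterman (BLOSUM62, affine
gaps, NCBI convention: a gap of length *k* costs 11 + *k*) against all six
translated frames of every contig. No word-seeding heuristic is used, so
reported scores are optimal local-alignment scores; this is affordable at
desk scale (a 3 Mb genome × three ~350–470 aa queries in about a minute) and
makes the scores verifiable against a brute-force oracle. For efficiency the
scan is two-pass: a linear-memory sweep records the best score ending in
each target column; full tracebacks are recomputed only inside windows
around columns beating the score threshold, and a window expands (up to
six-fold) whenever an alignment touches its edge, so the hit set above
threshold equals that of an unwindowed search. Non-overlapping hits per
frame are extracted greedily by descending score.

E-values use the Karlin–Altschul approximation `E = K·m·n·exp(−λS)` with
fixed constants λ = 0.267, K = 0.041 (gapped BLOSUM62 11/1) and
n = total residues across all six frames of the assembly. These constants
are approximate relative to NCBI BLAST; the default threshold `E ≤ 1e-7`
plays the same screening role. Hits are codon-aligned by construction, so
the coding-sequence handoff is unambiguous.

## Element assembly

Hits of the same role and strand separated by < 100 bp are merged first:
a frameshifted ORF appears as adjacent hits in *different frames*, so the
merge rule deliberately ignores frame. Merged hits are chained by proximity
(nearest-end gap ≤ 1 kb) and each chain is walked left to right against the
canonical orientation pattern (42kD and 57kD co-stranded, 22kD opposite,
order 42–22–57 along the element strand, either genomic orientation). A hit
that cannot extend the current pattern closes the element, so
orientation-violating chains fall apart into partials; when two hits compete
for one role slot the higher summed bitscore wins and the loser seeds its
own partial. An element is *complete* when all three roles are present with
query coverage ≥ 0.3 each and compatible orientation; the coverage floor
keeps degenerate copies visible as partials without inflating the complete
count.

## TIRs, TSDs, distances

TIR detection mirrors end self-alignment with BLASTN: the window 400 bp
outside / 100 bp inside each end of the ORF envelope, the 5′ window aligned
locally against the reverse complement of the 3′ window (match 2, mismatch
−3, gap 5 + 2k), accepted at ≥ 20 aligned columns and ≥ 70% identity.
Because local alignment trims terminal mismatches, the outer TIR terminus is
snapped to the nearest telomeric-motif occurrence (canonical 17-nt
C A₄ C₄ A₄ C₄, else the 16-nt C₃ variant) within 25 bp — TBE TIRs begin with
telomeric sequence, and the snap places the element boundary on the true
insertion site. **All percent TIR similarities are local-alignment
identities: matches / alignment columns, gap columns included.** This is the
committed convention throughout (it reproduces the published 92.5%
similarity of the two TBE2.2 TIR types, which a global end-gap-penalized
alignment does not — that gives 87.3%).

TSDs are called as the largest exact repeat (k from 10 down to 2) shared by
the k-mer ending at the element start and the k-mer starting at the element
end; no fuzzy matching, since a target-site duplication is by definition a
duplication.

TIR→ORF distances are measured element-forward from the TIR inner end to
the 42kD CDS start, and from the 57kD CDS end to the 3′ TIR start, using
integrity-refined CDS coordinates when available. When a stop codon
immediately follows the 57kD CDS it is counted as part of the ORF (protein
alignments cannot see the stop, but the published ORF end includes it).
Modes are reported with ties broken toward the smaller distance. The inner
TIR boundary is itself an alignment artifact of self-alignment and jitters
by ±1–2 bp in a minority of copies (a single chance match extends the local
alignment one column in ~25% of insertions), so per-family mode fractions
are lower than they would be with oracle boundaries; the modal value itself
is stable.

## Family clustering

Whole-element sequences (element-forward orientation) are compared all-vs-all;
a pair enters the similarity graph only if it shares an exact anchor word,
and the edge weight is global percent identity (edlib alignment: matches /
alignment columns). Edges below 70% identity are discarded: whole-element
identity that low never reflects family co-membership here — it arises from
residual cross-family TIR homology — and low-inflation MCL would otherwise
chain families together through such edges.

The classic 50 bp anchor word (appropriate for near-identical copies) is
kept as the library default, but the pipeline profile uses 28 bp anchors for
elements and 24 bp for CDS-level passes: at the simulated within-family
divergence (0.08 substitutions/site per copy, hence ~0.16 pairwise) exact
shared 50-mers between two copies are rare because substitutions are spaced
~6 bp apart on a pairwise basis, and the graph disconnects. With anchors in
the 20–30 bp range the within-family graph is dense while the ≥ 70% identity
floor still keeps families apart.

MCL follows the reference recurrence: self-loops at each node's maximum edge
weight, column normalization, then expansion (matrix squaring) alternating
with inflation (entry-wise power 1.2, renormalization, pruning below 1e−8)
until the sup-norm change falls under 1e−6; clusters are read from the limit
matrix by joining nodes that share an attractor. Inflation 1.2 is
deliberately coarse — even two dense clusters joined by a single weaker edge
merge at 1.2 (they separate at inflation ≥ 1.5). That coarseness is what
makes the first pass merge the TBE2 subfamilies, whose 42kD/22kD genes are
indistinguishable; a second MCL pass restricted to the 57kD coding sequences
inside each first-pass cluster then splits TBE2.1 from TBE2.2 (their 57kD
genes are ~55% similar, far below the edge floor). A split is accepted only
when its parts (each ≥ 2 members) cover the cluster. Families are named by
majority vote of member truth labels on synthetic runs, generically
otherwise.

Protein similarity is percent positives (BLOSUM62 score > 0) over global
alignment columns, with within-group means over distinct unordered pairs.
Neighbor-joining trees (scikit-bio) are built on 1 − similarity/100 over up
to 8 sampled members per family per ORF; NJ is a deliberately lightweight
stand-in for Bayesian phylogenetics, adequate for topology-level checks.

## Frameshift-aware CDS extraction

A local dynamic program aligns a protein query to a genomic region with five
moves: codon advance (+3 nt, BLOSUM62 on the table-6 translation), in-frame
stop (+3 nt, penalty −10, position recorded), frameshift (+2 or +4 nt for
one query residue, penalty −15, recorded as a ±1 indel), and affine
codon gaps in either sequence (11 + k at codon granularity). Both strands
are tried. The frameshift penalty is set so that one frameshift is preferred
over abandoning ≥ ~4 residues of alignment; the stop penalty lets alignments
pass through isolated TGA codons, which is essential given hotspot stops in
otherwise conserved transposases.

Terminal segments that hang beyond a frameshift or gap op with summed
substitution score < 30 are peeled off. Without this, local alignment
extends past the true CDS into flanking sequence that is *shared among
copies of a family* (spacer tandem repeats), and the phantom residues —
being consistent across copies — would be voted into the family consensus,
which then propagates a phantom frameshift to every copy. The cost is that
a genuine indel within a few codons of a CDS terminus is invisible (~3% of
implanted indels in the default simulation).

Extraction is two-pass: the global ORF queries first, then a per-family
consensus protein (column-majority over the query-coordinate aligned
proteins of the first pass) re-extracts every copy. The consensus pass
removes the family-systematic end-trimming that single ancestral queries
produce and sharpens frameshift placement.

A stop is *premature* iff it falls strictly before the last aligned residue
(no tail exemption). Repair undoes frameshifts (inserted nucleotide dropped,
deleted nucleotide restored as N) and masks stop codons to NNN; repaired
codons sit in query coordinates, and any N-containing codon column is
dropped before rate estimation. Repair requires ≥ 50% query coverage;
copies below it are excluded from rate analysis with a tallied reason.

## dN/dS and the neutrality test

Sites per codon: at each position, the fraction of the three single-nt
changes that is synonymous, with stop-creating changes excluded from both
numerator and denominator (each codon contributes exactly 3 sites; the
exclusion matches a mutation process that redraws stop proposals, which is
also how the generator simulates). Differences per codon pair: equal-weight
average over minimal mutational pathways, pathways through stops excluded;
if every pathway is blocked the differences count as nonsynonymous.
Proportions are Jukes–Cantor corrected; the correction is undefined at
p ≥ 3/4 and such pairs are flagged invalid, as are pairs with corrected
dS < 0.01 (uninformative) or dS > 5 (saturated) — the published filter.

The neutrality test is a one-sided exact binomial test of Nd among Nd + Sd
against p₀ = N/(N+S), per pair, or pooled over summed counts per family ×
ORF with an explicit "pairs non-independent" caveat (pairs share sequences;
the pooled p-value is an index of evidence, not an exact error rate). It
replaces a likelihood-ratio comparison of a free-ω codon model against
ω = 1: same inference target (purifying selection), closed-form and
oracle-checkable. Simulation calibration (50 neutral pairs × 500 codons):
median ω̂ ≈ 1.02, type-I error 2% at α = 0.05; under ω = 0.2, median ω̂ ≈ 0.20.

Estimates are stratified by pair integrity class: *intact* (neither copy has
a premature stop or frameshift in that ORF), *degenerate* (both do), else
*mixed*.

## Placement enrichment

"Near" means the element span is within 500 bp (gap distance) of a merged,
strandless track interval; contigs without track intervals count as not
near. The χ² test (1 dof, continuity correction off by default) compares
the near/not-near split against the track's genome bp fraction. Using the
bp fraction as the expectation is a *literal* reading of the published
18.3%-near vs 11.1%-of-genome framing and is conservative in the enrichment
direction, because the true null probability of landing within 500 bp of a
track exceeds the bp fraction by a halo term proportional to the number of
track intervals. The calibration experiment is therefore designed with the
11% MDS in two large blocks on 1 Mb (halo ≈ 0.2% absolute): exact achieved
level 4.6% at α = 0.05 with n = 250 uniform placements, exact power 0.96
against a 2× placement bias at n = 200. Observed over 100 seeded runs:
3% null rejections, 94% detection.

## The synthetic germline generator

Defaults describe the study conditions end to end: 40 contigs × 75 kb
(~3 Mb), i.i.d. uniform background at GC 0.5; four families × 15 copies;
TIR templates are the published per-family TIR consensi (right TIR = exact
reverse complement); ancestral ORFs of 352/192/471 codons evolve down a
fixed family tree (TBE1 and TBE2 sisters, TBE3 outgroup; 57kD fastest at
1.9× the 42kD rate; only the 57kD separates the TBE2 subfamilies) scaled by
a between-family divergence of 0.30 subs/site; each copy then diverges from
its family template by 0.08 subs/site — per-site substitutions in noncoding
sequence and TIRs, and a codon process in ORFs that proposes uniform
single-nt changes, redraws stop proposals, and accepts nonsynonymous
proposals with probability ω (defaults 0.15/0.20/0.25 for 42kD/22kD/57kD,
the published 0.1–0.3 range; d counts *accepted* substitutions, so coding
and noncoding divergence match). Layout per element: TIR — published modal
spacer — 42kD(+) — gap — 22kD(−) — ~200 bp tandem-repeat spacer — 57kD(+) —
published modal spacer — TIR, ~3.5–3.7 kb total, inserted on either strand.

Degradation mirrors the published prevalence patterns: per-ORF frameshift
probabilities 0.70/0.55/0.80 (one ±1 bp indel, uniform position); a stop
hotspot (TGA) at transposase residue 70 in 80% of TBE3 copies, implanted in
an exact rounded fraction of the copies that retain the ORF so the fraction
is recoverable at small n; 10% of copies degraded to partial by deleting one
or two ORFs; optional contig fragmentation bisecting elements (off by
default). The telomeric motif at each TIR terminus is protected from
mutation (selection maintains it in reality; it is also the boundary
anchor). Insertions occur at native TA dinucleotides with the TSD duplicated
on both flanks, biased 2× toward MDS segments (the track covers 11.1% of the
genome in 2 kb segments), and the single base outside each TSD copy is
resampled if it would extend the exact flank repeat — making the recorded
TSD the unique maximal exact repeat, so ground truth for the largest-k
caller is well defined. Satellite tracks (380 bp and 170 bp units at ~1.4%
and ~1.2% of the genome) are placed as tandem arrays that elements avoid.

What the generator does **not** emulate: insertion-age structure (one
divergence per family, no birth process), nested or overlapping insertions,
composition heterogeneity of real germline DNA, assembly error (the real
motivation for some published stop/frameshift counts), IES/MDS scrambling
biology, and satellite-repeat sequence families. Passing recovery tests
therefore demonstrates correctness of the pipeline's inference machinery
under a faithful generative model of element *structure*, not robustness to
assembly artifacts or deep-time age mixtures.

Randomness is split into named child streams (templates / tracks /
placement / mutation / degradation) of the master seed, so outputs are
byte-identical per seed and stable against draw-count changes in one stage.

## Problem sizes and determinism

The default end-to-end run (3 Mb, 60 copies) takes ~2 minutes on one core;
search dominates (~70 s), CDS extraction ~20 s (numba-compiled kernels).
The test suite runs the full pipeline once and shares it across tests.
Simulation-calibration checks use 50 pairs × 500 codons (rates) and 100
seeded runs (enrichment), sizes at which the target tolerance bands are
several standard errors wide. All pipeline stages are deterministic given
their inputs; the only randomness is the generator's seeded streams.

## Known limitations

* Search E-values are approximate (fixed Karlin constants, no
  composition-based statistics); the threshold semantics differ slightly
  from NCBI BLAST.
* The TIR inner boundary inherits ±1–2 bp self-alignment jitter; distance
  mode *fractions* are accordingly conservative.
* Indels within a few codons of a CDS terminus are not recoverable by the
  frameshift caller (alignment-edge invisibility).
* The pooled neutrality test treats non-independent pairs as independent
  counts; it is reported with that caveat and interpreted as an evidence
  index.
* The clustering edge floor (70% identity) and pipeline anchor words
  (28/24 bp) are tuned to the divergence regime of the generator; highly
  diverged real families may need different settings (both are exposed in
  `ClusterConfig`).
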