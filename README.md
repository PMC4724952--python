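# tbescan

Annotation and molecular-evolution analysis of **telomere-bearing element
(TBE) transposons** in ciliate germline genomes.

TBEs are Tc1/*mariner*-class DNA transposons of stichotrich ciliates such as
*Oxytricha trifallax*. They occupy a large fraction of the germline
(micronuclear) genome, are bounded by terminal inverted repeats (TIRs) that
begin with telomeric repeat sequence (C A₄ C₄ A₄ C₄), and encode three ORFs —
a 42kD DDE transposase, a 22kD ORF and a 57kD ORF — with the 22kD ORF in
reverse orientation. Their transposase has been implicated in programmed
genome rearrangement, and despite tens of thousands of degenerate copies the
three genes evolve under strong purifying selection (dN/dS ≪ 1).

`tbescan` is a desk-scale, fully testable re-implementation of the
genome-wide analysis behind those observations:

* **search** — exact six-frame translated Smith–Waterman of ORF protein
  queries against a genome under the ciliate genetic code (NCBI table 6:
  TAA/TAG = Gln, TGA the sole stop), with Karlin–Altschul E-values
  (default cutoff 10⁻⁷);
* **annotate** — assembly of hits into *complete* elements (all three ORFs
  within 1 kb, correct orientation) and *partial* elements;
* **tirscan** — TIR detection by end self-alignment, target-site-duplication
  (TSD) calling from exact flank repeats, telomeric-motif scanning, TIR
  consensus building, and TIR→ORF distance statistics;
* **cluster** — all-vs-all element similarity and Markov clustering
  (inflation 1.2) into families, with a second 57kD-CDS pass that separates
  subfamilies whose transposase genes are indistinguishable; pairwise
  protein-similarity matrices and neighbor-joining trees;
* **integrity** — frameshift-aware protein-to-DNA alignment, premature-stop
  and frameshift calling, positional stop-codon hotspot profiles, and CDS
  repair (frameshifts corrected, stops masked);
* **selection** — pairwise dN/dS by Nei–Gojobori (1986) counting with
  Jukes–Cantor correction, the published dS ∈ [0.01, 5] validity filter, and
  an exact binomial test of dN/dS < 1;
* **context** — distances to MDS (macronuclear-destined sequence) and
  satellite tracks with a χ² placement-enrichment test;
* **synth** — a synthetic germline-genome generator that implants TBE copies
  with full ground truth (family, coordinates, TSD, frameshifts, stop
  hotspots), so every stage is scored exactly without external data.

## Core statistics

For a pair of aligned coding sequences, NG86 counts synonymous/nonsynonymous
sites per codon (fraction of the three single-nucleotide changes per position
that are synonymous, stop-creating changes excluded from numerator and
denominator) and differences by equal-weight averaging over stop-free minimal
mutational pathways; then

&nbsp;&nbsp;p*ₛ* = S_d/S, p*ₙ* = N_d/N, d = −¾ ln(1 − 4p/3), ω = dN/dS.

Under neutrality (ω = 1) each observed difference is nonsynonymous with
probability N/(N+S); the purifying-selection test is the one-sided exact
binomial test of N_d among N_d + S_d against that null.

## Worked example

Run the whole pipeline on the default synthetic germline genome (~3 Mb,
4 families × 15 copies, seed 42) and score it against the implant truth:

```python
from tbescan import PipelineConfig, SynthConfig, run_pipeline, compare_to_truth

report = run_pipeline(PipelineConfig(synthetic=SynthConfig()))
card = compare_to_truth(report)
print(card["complete_recall"], card["complete_precision"], card["family_rand_index"])
print(card["hotspots"]["TBE3:42kD:70"])
print(card["omega_recovery"]["42kD"])
```

prints (about two minutes on one core):

```
1.0 1.0 1.0
{'implanted_fraction': 0.8, 'observed_fraction': 0.8181818181818182}
{'median_omega': 0.14890912657788694, 'target_omega': 0.15, 'n_pairs': 352}
```

— every implanted complete element is recovered as complete and none is
spuriously called (recall = precision = 1.0), Markov clustering reproduces
the four planted families exactly (Rand index 1.0), the stop-codon hotspot
implanted at transposase residue 70 in 80% of TBE3 copies is profiled back
at 0.818, and the pairwise dN/dS estimates recover the simulated
transposase ω of 0.15. `report` also carries the four publication-shaped
summary tables (family distribution, protein-similarity matrix, TIR/TSD
features, stop/frameshift prevalence) plus per-group dN/dS distributions;
with `outdir` set they are written as TSV/GFF3/newick/JSON.

The same run is available from the shell:

```bash
tbescan score --seed 42 --out scorecard.json
tbescan run --synthetic --seed 42 --out results/
```

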