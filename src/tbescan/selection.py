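"""Pairwise dN/dS by Nei-Gojobori counting under the ciliate genetic code.

Synonymous and nonsynonymous *sites* are counted per codon position as the
fraction of single-nucleotide changes that are synonymous, with changes to
stop codons excluded from both numerator and denominator (so every codon
still contributes three sites, and the site counts match a substitution
process that redraws proposals hitting a stop).  *Differences* between codon
pairs are averaged with equal weight over all minimal mutational pathways,
excluding pathways that pass through a stop codon; a pair whose pathways are
all blocked contributes its differences as nonsynonymous.  Proportions are
Jukes-Cantor corrected, d = -(3/4) ln(1 - 4p/3), and an estimate is valid
only when the corrected synonymous rate lies in [0.01, 5] — the published
filter for uninformative (near-identical) and saturated pairs.

The counting-based exact binomial test of dN/dS < 1 plays the role of a
likelihood-ratio comparison against a neutral (dN/dS = 1) codon model: under
neutrality the fraction of nonsynonymous differences should match the
nonsynonymous site fraction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .seqcore import CILIATE_CODE, GeneticCode

DS_MIN, DS_MAX = 0.01, 5.0


@dataclass
class CodonAlignment:
    codons_a: list[str]
    codons_b: list[str]
    n_codons: int
    n_dropped: int

    def pairs(self):
        return zip(self.codons_a, self.codons_b)


@dataclass
class SubstCounts:
    S: float   # synonymous sites
    N: float   # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences


@dataclass
class RateEstimate:
    pS: float
    pN: float
    dS: float | None
    dN: float | None
    omega: float | None
    valid: bool
    invalid_reason: str | None = None


@dataclass
class NeutralityTest:
    statistic: float   # observed nonsynonymous fraction of differences
    expected: float    # nonsynonymous site fraction N/(N+S)
    p_value: float
    direction: str     # "purifying" when statistic < expected
    pooled: bool = False
    note: str = ""


# ---------------------------------------------------------------------------
# per-codon counting (cached; the genetic code is fixed per cache key)
# ---------------------------------------------------------------------------

_NTS = "ACGT"


@lru_cache(maxsize=None)
def _codon_sites(codon: str, table_id: int) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Per position, the fraction of non-stop single-nucleotide changes that are
    synonymous, summed over the three positions (total always 3).
    """
    code = GeneticCode.from_ncbi(table_id)
    aa = code.amino_acid(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for b in _NTS:
            if b == codon[pos]:
                continue
            cand = codon[:pos] + b + codon[pos + 1 :]
            if code.is_stop(cand):
                continue
            non_stop += 1
            if code.amino_acid(cand) == aa:
                syn += 1
        if non_stop:
            s += syn / non_stop
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _codon_differences(c1: str, c2: str, table_id: int) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    with equal weight over stop-free minimal mutational pathways."""
    code = GeneticCode.from_ncbi(table_id)
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if code.is_stop(nxt):
                blocked = True
                break
            if code.amino_acid(nxt) == code.amino_acid(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:
        # every pathway crosses a stop: count all differences as nonsynonymous
        return 0.0, float(len(diffs))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; undefined (None) for p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86(
    aln: CodonAlignment, code: GeneticCode = CILIATE_CODE
) -> tuple[SubstCounts, RateEstimate]:
    """Nei-Gojobori counts and Jukes-Cantor-corrected rates for one pair."""
    S = N = Sd = Nd = 0.0
    for ca, cb in aln.pairs():
        sa, na = _codon_sites(ca, code.table_id)
        sb, nb = _codon_sites(cb, code.table_id)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = _codon_differences(ca, cb, code.table_id)
        Sd += sd
        Nd += nd
    counts = SubstCounts(S=S, N=N, Sd=Sd, Nd=Nd)
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    reason = None
    omega = None
    if dS is None or dN is None:
        reason = "correction undefined (p >= 3/4)"
    elif dS < DS_MIN:
        reason = f"dS below {DS_MIN}"
    elif dS > DS_MAX:
        reason = f"dS above {DS_MAX}"
    else:
        omega = dN / dS
    return counts, RateEstimate(
        pS=pS, pN=pN, dS=dS, dN=dN, omega=omega, valid=reason is None, invalid_reason=reason
    )


# ---------------------------------------------------------------------------
# codon alignment from repaired CDSs
# ---------------------------------------------------------------------------

_PROT_ALIGNER = Align.PairwiseAligner()
_PROT_ALIGNER.mode = "global"
_PROT_ALIGNER.substitution_matrix = substitution_matrices.load("BLOSUM62")
_PROT_ALIGNER.open_gap_score = -12
_PROT_ALIGNER.extend_gap_score = -1


def _codon_clean(codon: str) -> bool:
    return all(c in "ACGT" for c in codon)


def pairwise_codon_align(
    cds_a: list[str],
    cds_b: list[str],
    code: GeneticCode = CILIATE_CODE,
    min_codons: int = 30,
) -> CodonAlignment | None:
    """Globally align the translations and thread the codons back.

    Columns with a gap, an N-containing codon or a stop in either row are
    dropped.  Returns None (pair excluded) if fewer than ``min_codons``
    columns remain.
    """
    prot_a = "".join(code.amino_acid(c) if _codon_clean(c) else "X" for c in cds_a)
    prot_b = "".join(code.amino_acid(c) if _codon_clean(c) else "X" for c in cds_b)
    if prot_a == prot_b and len(cds_a) == len(cds_b):
        pairs = list(zip(cds_a, cds_b))
    else:
        aln = _PROT_ALIGNER.align(prot_a.replace("*", "X"), prot_b.replace("*", "X"))[0]
        pairs = []
        for (a0, a1), (b0, b1) in zip(aln.aligned[0], aln.aligned[1]):
            for k in range(a1 - a0):
                pairs.append((cds_a[a0 + k], cds_b[b0 + k]))
    kept_a, kept_b, dropped = [], [], 0
    for ca, cb in pairs:
        if (
            _codon_clean(ca) and _codon_clean(cb)
            and not code.is_stop(ca) and not code.is_stop(cb)
        ):
            kept_a.append(ca)
            kept_b.append(cb)
        else:
            dropped += 1
    dropped += max(len(cds_a), len(cds_b)) - len(pairs)
    if len(kept_a) < min_codons:
        return None
    return CodonAlignment(kept_a, kept_b, n_codons=len(kept_a), n_dropped=dropped)


# ---------------------------------------------------------------------------
# neutrality test and group summaries
# ---------------------------------------------------------------------------

def neutrality_test(counts: SubstCounts, pooled: bool = False) -> NeutralityTest:
    """One-sided exact binomial test of purifying selection.

    Under dN/dS = 1 each observed difference is nonsynonymous with
    probability N/(N+S); fewer nonsynonymous differences than that indicates
    purifying selection.  Requires at least one observed difference.
    """
    n_diff = counts.Nd + counts.Sd
    if n_diff < 1:
        raise ValueError("no observed differences (Nd + Sd < 1)")
    p0 = counts.N / (counts.N + counts.S)
    k = int(round(counts.Nd))
    n = int(round(n_diff))
    res = stats.binomtest(k, n, p0, alternative="less")
    return NeutralityTest(
        statistic=counts.Nd / n_diff,
        expected=p0,
        p_value=res.pvalue,
        direction="purifying" if counts.Nd / n_diff < p0 else "not purifying",
        pooled=pooled,
        note="pairs non-independent" if pooled else "",
    )


def pooled_neutrality_test(all_counts: list[SubstCounts]) -> NeutralityTest:
    """Neutrality test on summed counts across pairs (flagged: the pairs
    share sequences and are not independent)."""
    tot = SubstCounts(
        S=sum(c.S for c in all_counts),
        N=sum(c.N for c in all_counts),
        Sd=sum(c.Sd for c in all_counts),
        Nd=sum(c.Nd for c in all_counts),
    )
    return neutrality_test(tot, pooled=True)


def omega_distribution(estimates: pd.DataFrame) -> pd.DataFrame:
    """Box-plot summary (median, quartiles, n) of valid omega estimates per
    (family, role, integrity_class) group, with exclusion tallies."""
    rows = []
    for keys, grp in estimates.groupby(["family", "role", "integrity_class"]):
        valid = grp[grp["valid"]]
        excl = grp[~grp["valid"]]["invalid_reason"].value_counts().to_dict()
        q = valid["omega"].quantile([0.25, 0.5, 0.75]) if len(valid) else None
        rows.append(
            {
                "family": keys[0],
                "role": keys[1],
                "integrity_class": keys[2],
                "n": len(valid),
                "omega_q1": q.loc[0.25] if q is not None else np.nan,
                "omega_median": q.loc[0.5] if q is not None else np.nan,
                "omega_q3": q.loc[0.75] if q is not None else np.nan,
                "n_excluded": int(len(excl) and sum(excl.values())),
                "excluded_reasons": "; ".join(f"{k}: {v}" for k, v in excl.items()),
            }
        )
    return pd.DataFrame(rows)
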