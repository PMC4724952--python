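"""Family clustering: all-vs-all similarity, Markov clustering, protein
similarity matrices and neighbor-joining trees.

Element sequences are compared all-vs-all: two elements get an edge only if
they share an exact common word (default 50-mers, the word-size semantics of
the published all-by-all nucleotide search), weighted by global percent
identity.  Markov clustering (MCL) with a low inflation (default 1.2)
partitions the graph into families.  Because the TBE2.1 and TBE2.2
subfamilies share near-identical 42kD/22kD genes but distinct 57kD genes, a
second MCL pass restricted to the 57kD coding sequences (smaller anchor
words, since CDS fragments are shorter than whole elements) is applied
within each first-pass cluster and splits the TBE2 subfamilies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

import skbio


@dataclass
class ClusterConfig:
    inflation: float = 1.2
    max_iterations: int = 200
    convergence_epsilon: float = 1e-6
    prune_threshold: float = 1e-8
    anchor_word_size: int = 50
    cds_anchor_word_size: int = 24
    #: edges below this percent identity are not entered into the graph;
    #: whole-element identity this low never reflects family co-membership,
    #: only residual homology such as cross-family TIR similarity.
    min_edge_weight: float = 70.0

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")


@dataclass
class SimilarityGraph:
    nodes: list[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)  # weight in (0, 100]

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        self.edges[key] = weight

    def to_matrix(self) -> np.ndarray:
        idx = {n: i for i, n in enumerate(self.nodes)}
        m = np.zeros((len(self.nodes), len(self.nodes)))
        for (a, b), w in self.edges.items():
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = w
        return m


def _edlib_identity(a: str, b: str) -> float:
    res = edlib.align(a, b, task="path")
    cols = eq = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch == "=":
                eq += n
    return 100.0 * eq / cols if cols else 0.0


def all_vs_all_similarity(
    seqs: dict[str, str], cfg: ClusterConfig | None = None, word_size: int | None = None
) -> SimilarityGraph:
    """Similarity graph over sequences sharing at least one exact common word.

    Edge weights are global percent identity (matches over alignment
    columns); pairs without a shared word of ``word_size`` get no edge.
    """
    cfg = cfg or ClusterConfig()
    w = word_size or cfg.anchor_word_size
    if len(seqs) < 2:
        return SimilarityGraph(nodes=list(seqs))
    names = list(seqs)
    kmer_owners: dict[str, set[str]] = {}
    for name in names:
        s = seqs[name]
        seen = set()
        for i in range(0, max(0, len(s) - w + 1)):
            seen.add(s[i : i + w])
        for k in seen:
            kmer_owners.setdefault(k, set()).add(name)
    pairs: set[tuple[str, str]] = set()
    for owners in kmer_owners.values():
        if len(owners) > 1:
            for a, b in itertools.combinations(sorted(owners), 2):
                pairs.add((a, b))
    graph = SimilarityGraph(nodes=names)
    for a, b in sorted(pairs):
        ident = _edlib_identity(seqs[a], seqs[b])
        if ident >= cfg.min_edge_weight:
            graph.add_edge(a, b, ident)
    return graph


@dataclass
class ClusterSet:
    clusters: list[list[str]]
    converged: bool

    def labels(self) -> dict[str, int]:
        return {n: i for i, cl in enumerate(self.clusters) for n in cl}


def mcl(graph: SimilarityGraph, cfg: ClusterConfig | None = None) -> ClusterSet:
    """Markov clustering of a weighted undirected graph.

    Self-loops (weight = the node's maximum edge weight) are added, columns
    normalized to a stochastic matrix, then expansion (matrix squaring) and
    inflation (entry-wise power followed by renormalization and pruning)
    alternate until the matrix change falls below epsilon.  Clusters are read
    from the attractor structure of the limit matrix; every node lands in
    exactly one cluster (ties go to the first attractor by node order).
    """
    cfg = cfg or ClusterConfig()
    n = len(graph.nodes)
    if n == 0:
        raise ValueError("empty graph")
    m = graph.to_matrix()
    loops = np.where(m.max(axis=0) > 0, m.max(axis=0), 1.0)
    np.fill_diagonal(m, loops)
    m = m / m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(cfg.max_iterations):
        expanded = m @ m
        inflated = np.power(expanded, cfg.inflation)
        inflated[inflated < cfg.prune_threshold] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated = inflated / colsum
        if np.abs(inflated - m).max() < cfg.convergence_epsilon:
            m = inflated
            converged = True
            break
        m = inflated
    # read clusters: each column's attractor set is the rows holding its
    # mass; nodes sharing an attractor belong to one cluster (union-find)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for j in range(n):
        for i in np.flatnonzero(m[:, j] > 1e-6):
            union(int(i), j)
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(graph.nodes[i])
    clusters = sorted(groups.values(), key=lambda cl: (-len(cl), cl[0]))
    return ClusterSet(clusters=clusters, converged=converged)


def two_pass_cluster(
    element_seqs: dict[str, str],
    cds57_seqs: dict[str, str],
    cfg: ClusterConfig | None = None,
) -> ClusterSet:
    """Whole-element MCL followed by a 57kD-CDS MCL within each cluster.

    The second pass splits clusters (like TBE2) whose members share the
    42kD/22kD genes but carry distinct 57kD ORFs; splits are accepted only
    when each part keeps at least two members.
    """
    cfg = cfg or ClusterConfig()
    first = mcl(all_vs_all_similarity(element_seqs, cfg), cfg)
    final: list[list[str]] = []
    converged = first.converged
    for cl in first.clusters:
        with_cds = [n for n in cl if n in cds57_seqs]
        if len(with_cds) < 4:
            final.append(cl)
            continue
        sub = mcl(
            all_vs_all_similarity(
                {n: cds57_seqs[n] for n in with_cds}, cfg, word_size=cfg.cds_anchor_word_size
            ),
            cfg,
        )
        converged = converged and sub.converged
        parts = [p for p in sub.clusters if len(p) >= 2]
        if len(parts) >= 2 and sum(len(p) for p in parts) == len(with_cds):
            rest = [n for n in cl if n not in cds57_seqs]
            for i, p in enumerate(sorted(parts, key=lambda p: (-len(p), p[0]))):
                final.append(sorted(p) + (rest if i == 0 else []))
        else:
            final.append(cl)
    final.sort(key=lambda cl: (-len(cl), cl[0]))
    return ClusterSet(clusters=final, converged=converged)


def assign_family_labels(
    clusters: ClusterSet, truth_families: dict[str, str] | None = None
) -> dict[str, str]:
    """Name clusters: by majority vote of member truth families when truth is
    available, else generically family_1, family_2, ... by size."""
    labels: dict[str, str] = {}
    used: set[str] = set()
    for i, cl in enumerate(clusters.clusters):
        if truth_families:
            votes = pd.Series([truth_families.get(n) for n in cl if truth_families.get(n)])
            name = votes.mode().iloc[0] if len(votes) else f"family_{i+1}"
            if name in used:
                name = f"{name}#{i+1}"
        else:
            name = f"family_{i+1}"
        used.add(name)
        for n in cl:
            labels[n] = name
    return labels


# ---------------------------------------------------------------------------
# protein similarity (published pairwise-similarity matrix analog)
# ---------------------------------------------------------------------------

_PROT = Align.PairwiseAligner()
_PROT.mode = "global"
_PROT.substitution_matrix = substitution_matrices.load("BLOSUM62")
_PROT.open_gap_score = -12
_PROT.extend_gap_score = -1


def protein_percent_similarity(a: str, b: str) -> float:
    """Percent positives (substitution score > 0) over alignment columns of a
    global protein alignment."""
    mat = _PROT.substitution_matrix
    aln = _PROT.align(a, b)[0]
    sa, sb = aln[0], aln[1]
    pos = sum(
        1
        for x, y in zip(sa, sb)
        if x != "-" and y != "-" and mat[x, y] > 0
    )
    return 100.0 * pos / len(sa)


def pairwise_protein_similarity(
    groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Mean +/- sd percent similarity within and between groups of proteins.

    Within-group means use distinct unordered pairs only.  Returns a long
    table (group_a, group_b, mean, sd, n_pairs).
    """
    rows = []
    names = sorted(groups)
    for i, ga in enumerate(names):
        for gb in names[i:]:
            if ga == gb:
                pairs = list(itertools.combinations(groups[ga], 2))
            else:
                pairs = list(itertools.product(groups[ga], groups[gb]))
            sims = [protein_percent_similarity(a, b) for a, b in pairs]
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "mean": float(np.mean(sims)) if sims else np.nan,
                    "sd": float(np.std(sims, ddof=1)) if len(sims) > 1 else np.nan,
                    "n_pairs": len(sims),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(labels: list[str], distances: np.ndarray) -> skbio.TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix (n >= 3).

    For additive matrices the tree's patristic distances reproduce the input.
    """
    if len(labels) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    dm = skbio.DistanceMatrix(distances, ids=labels)
    return skbio.tree.nj(dm)


def write_newick(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")
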