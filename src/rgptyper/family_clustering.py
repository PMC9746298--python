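"""Gene-family construction and locus clustering.

Comparative analysis of *rgp* loci proceeds in four steps:

1. all-vs-all local protein alignment (BLOSUM62, affine gaps: open 11,
   extend 1), yielding percent identity (identities / alignment columns)
   and per-sequence coverage (aligned residues / sequence length);
2. a similarity graph whose edges are pairs passing the bidirectional
   50/50 criterion — >=50% identity across >=50% of both amino-acid
   sequences (``coverage_mode="either"`` relaxes this to one sequence);
3. gene families as connected components of that graph (default) or as
   Markov clusters (MCL) of its adjacency matrix;
4. a binary locus x family presence/absence matrix, hierarchically
   clustered with Jaccard distance and average linkage.

Family partitioning is invariant to input order: proteins are sorted
canonically before graph construction and family labels are assigned by
first member id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import InputError

#: residues scoreable under BLOSUM62
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZX*")

_ALIGNER: Align.PairwiseAligner | None = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _ALIGNER = a
    return _ALIGNER


@dataclass(frozen=True)
class SimilarityEdge:
    a: str
    b: str
    identity: float  # percent
    coverage_a: float  # percent of a aligned
    coverage_b: float  # percent of b aligned
    bidirectional_pass: bool


def _validate_protein(seq: str, label: str = "sequence") -> None:
    if not seq:
        raise InputError(f"{label}: empty protein sequence")
    bad = set(seq.upper()) - PROTEIN_ALPHABET
    if bad:
        raise InputError(f"{label}: non-amino-acid characters {sorted(bad)}")


def pairwise_similarity(
    a: str,
    b: str,
    id_a: str = "a",
    id_b: str = "b",
    min_id: float = 50.0,
    min_cov: float = 50.0,
    coverage_mode: str = "both",
) -> SimilarityEdge:
    """Local alignment of two proteins with the 50/50 pass decision.

    Identity is identities over alignment columns (gap columns included);
    coverage of each sequence is its aligned length over its full length.
    """
    _validate_protein(a, id_a)
    _validate_protein(b, id_b)
    if coverage_mode not in ("both", "either"):
        raise InputError(f"coverage_mode must be 'both' or 'either', got {coverage_mode!r}")
    alignments = _aligner().align(a.upper(), b.upper())
    identity = cov_a = cov_b = 0.0
    try:
        aln = alignments[0]
    except IndexError:
        aln = None
    if aln is not None and aln.length > 0:
        counts = aln.counts()
        identity = 100.0 * counts.identities / aln.length
        cov_a = 100.0 * sum(e - s for s, e in aln.aligned[0]) / len(a)
        cov_b = 100.0 * sum(e - s for s, e in aln.aligned[1]) / len(b)
    cov_ok = (
        (cov_a >= min_cov and cov_b >= min_cov)
        if coverage_mode == "both"
        else (cov_a >= min_cov or cov_b >= min_cov)
    )
    return SimilarityEdge(
        a=id_a,
        b=id_b,
        identity=identity,
        coverage_a=cov_a,
        coverage_b=cov_b,
        bidirectional_pass=bool(identity >= min_id and cov_ok),
    )


@dataclass(frozen=True)
class GeneFamilySet:
    """A partition of proteins into families."""

    families: tuple[frozenset[str], ...]
    labels: tuple[str, ...]

    @property
    def member_to_family(self) -> dict[str, str]:
        return {
            member: label
            for label, fam in zip(self.labels, self.families)
            for member in fam
        }

    def __len__(self) -> int:
        return len(self.families)


def _flatten(proteins) -> dict[str, str]:
    """Accept {id: seq} or {locus: {id: seq}}; return a flat id->seq map."""
    flat: dict[str, str] = {}
    for key, value in proteins.items():
        if isinstance(value, str):
            flat[key] = value
        else:
            for pid, seq in value.items():
                if pid in flat:
                    raise InputError(f"duplicate protein id {pid!r} across loci")
                flat[pid] = seq
    return flat


def _kmers(seq: str, k: int = 5) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def similarity_edges(
    proteins: Mapping,
    min_id: float = 50.0,
    min_cov: float = 50.0,
    coverage_mode: str = "both",
    prefilter: bool = True,
) -> list[SimilarityEdge]:
    """All-vs-all edges over the input proteins (unordered pairs, a < b).

    With ``prefilter`` (default) pairs sharing no exact 5-mer are skipped
    without alignment: any pair meeting the 50/50 criterion shares exact
    5-mer words with overwhelming probability, while unrelated proteins
    almost never do.  Disable for exhaustive alignment of every pair.
    """
    flat = _flatten(proteins)
    ids = sorted(flat)
    words = {pid: _kmers(flat[pid].upper()) for pid in ids} if prefilter else None
    edges = []
    for i, pa in enumerate(ids):
        for pb in ids[i + 1 :]:
            la, lb = len(flat[pa]), len(flat[pb])
            # a local alignment cannot cover the longer sequence beyond
            # the length of the shorter one: skip hopeless pairs
            if coverage_mode == "both" and 100.0 * min(la, lb) / max(la, lb) < min_cov:
                continue
            if prefilter and words[pa].isdisjoint(words[pb]):
                continue
            edge = pairwise_similarity(
                flat[pa], flat[pb], pa, pb,
                min_id=min_id, min_cov=min_cov, coverage_mode=coverage_mode,
            )
            edges.append(edge)
    return edges


def _mcl(adjacency: np.ndarray, inflation: float = 2.0, max_iter: int = 200) -> list[list[int]]:
    """Markov clustering on a symmetric adjacency matrix (small graphs)."""
    m = adjacency.astype(float) + np.eye(len(adjacency))  # self-loops
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = m @ m
        inflated = np.power(expanded, inflation)
        inflated /= inflated.sum(axis=0, keepdims=True)
        if np.allclose(inflated, m, atol=1e-8):
            m = inflated
            break
        m = inflated
    # attractors: rows with mass; cluster = columns flowing to the attractor
    clusters: list[set[int]] = []
    for i in range(len(m)):
        members = set(np.flatnonzero(m[i] > 1e-6).tolist())
        if not members:
            continue
        for c in clusters:
            if c & members:
                c |= members
                break
        else:
            clusters.append(members)
    # merge overlaps until disjoint
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i] & clusters[j]:
                    clusters[i] |= clusters.pop(j)
                    merged = True
                    break
            if merged:
                break
    return [sorted(c) for c in clusters]


def build_families(
    proteins: Mapping,
    min_id: float = 50.0,
    min_cov: float = 50.0,
    method: str = "components",
    inflation: float = 2.0,
    coverage_mode: str = "both",
    prefilter: bool = True,
) -> GeneFamilySet:
    """Partition proteins into gene families.

    *proteins* is either ``{protein_id: sequence}`` or per-locus
    ``{locus_id: {protein_id: sequence}}`` (ids must be globally unique).
    """
    flat = _flatten(proteins)
    if not flat:
        raise InputError("no proteins supplied")
    if method not in ("components", "mcl"):
        raise InputError(f"unknown method {method!r}")
    ids = sorted(flat)
    edges = similarity_edges(
        flat, min_id=min_id, min_cov=min_cov,
        coverage_mode=coverage_mode, prefilter=prefilter,
    )
    passing = [(e.a, e.b) for e in edges if e.bidirectional_pass]
    if method == "components":
        graph = nx.Graph()
        graph.add_nodes_from(ids)
        graph.add_edges_from(passing)
        raw = [sorted(c) for c in nx.connected_components(graph)]
    else:
        index = {pid: i for i, pid in enumerate(ids)}
        adj = np.zeros((len(ids), len(ids)))
        for a, b in passing:
            adj[index[a], index[b]] = adj[index[b], index[a]] = 1.0
        raw = [[ids[i] for i in cluster] for cluster in _mcl(adj, inflation=inflation)]
    raw.sort(key=lambda fam: fam[0])
    families = tuple(frozenset(fam) for fam in raw)
    width = max(3, len(str(len(families))))
    labels = tuple(f"fam{str(i + 1).zfill(width)}" for i in range(len(families)))
    return GeneFamilySet(families=families, labels=labels)


def presence_absence(
    fams: GeneFamilySet,
    loci: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Binary locus x family matrix (True = the locus has >=1 member).

    *loci* maps locus id to the protein ids it contributes; every protein
    must belong to exactly one family.
    """
    m2f = fams.member_to_family
    matrix = pd.DataFrame(False, index=list(loci), columns=list(fams.labels))
    for locus, members in loci.items():
        for pid in members:
            try:
                matrix.loc[locus, m2f[pid]] = True
            except KeyError:
                raise InputError(f"protein {pid!r} of locus {locus!r} is in no family") from None
    return matrix


@dataclass
class HclResult:
    linkage: np.ndarray
    labels: tuple[str, ...]
    flat_clusters: dict[str, int]
    newick: str


def _to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def hcl_cluster(
    matrix: pd.DataFrame,
    k: int | None = None,
    height: float | None = None,
) -> HclResult:
    """Hierarchical clustering of loci by family presence/absence.

    Jaccard distance, average linkage; flat clusters are cut at *k* groups
    or at *height* (if both are given, *k* wins; default k = number of rows
    gives singletons).  Deterministic: scipy breaks ties by row order.
    """
    if len(matrix) < 2:
        raise InputError("hierarchical clustering needs at least 2 loci")
    data = matrix.to_numpy(dtype=bool)
    dist = pdist(data, metric="jaccard")
    Z = hierarchy.linkage(dist, method="average")
    if k is not None:
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    elif height is not None:
        flat = hierarchy.fcluster(Z, t=height, criterion="distance")
    else:
        flat = hierarchy.fcluster(Z, t=len(matrix), criterion="maxclust")
    labels = tuple(str(i) for i in matrix.index)
    return HclResult(
        linkage=Z,
        labels=labels,
        flat_clusters=dict(zip(labels, (int(c) for c in flat))),
        newick=_to_newick(Z, labels),
    )


def families_to_tsv(fams: GeneFamilySet) -> str:
    lines = ["family\tsize\tmembers"]
    for label, fam in zip(fams.labels, fams.families):
        lines.append(f"{label}\t{len(fam)}\t{','.join(sorted(fam))}")
    return "\n".join(lines) + "\n"
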