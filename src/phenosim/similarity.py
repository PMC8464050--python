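"""Lin similarity, best-match-average set similarity, and variant clustering.

Term-level similarity is Lin's information-content ratio

    Lin(t1, t2) = 2 IC(MICA(t1, t2)) / (IC(t1) + IC(t2))

where MICA is the most informative common ancestor in the corpus-derived
IC map.  Set similarity is best-match-average: the asymmetric similarity
of S1 to S2 is the mean over terms of S1 of their best Lin match in S2;
symmetrized by averaging the two directions.  Group similarity between two
sets of individuals is the mean symmetric similarity over all cross pairs.

Edge case: when IC(t1) + IC(t2) = 0 (both terms are zero-information, e.g.
the root), Lin is defined as 1 for identical terms and 0 otherwise, which
preserves Lin(t, t) = 1 and the [0, 1] range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cohort import CohortTable
from .ontology import ICMap, OntologyGraph, mica

logger = logging.getLogger(__name__)

__all__ = [
    "lin",
    "asym_sim",
    "sym_sim",
    "group_sim",
    "SimilarityMatrix",
    "variant_similarity_matrix",
    "ClusteringResult",
    "cluster_variants",
    "cluster_summary",
    "system_profile",
]

LINKAGE_METHODS = ("average", "complete", "single")


def _pair_cache(ic: ICMap) -> Dict[Tuple[str, str], float]:
    cache = getattr(ic, "_lin_cache", None)
    if cache is None:
        cache = {}
        ic._lin_cache = cache
    return cache


def lin(graph: OntologyGraph, ic: ICMap, t1: str, t2: str) -> float:
    """Lin similarity between two terms, in [0, 1]."""
    t1, t2 = graph.resolve(t1), graph.resolve(t2)
    key = (t1, t2) if t1 <= t2 else (t2, t1)
    cache = _pair_cache(ic)
    hit = cache.get(key)
    if hit is not None:
        return hit
    denom = ic.ic[t1] + ic.ic[t2]
    if denom <= 0.0:
        value = 1.0 if t1 == t2 else 0.0
    else:
        value = 2.0 * ic.ic[mica(graph, ic, t1, t2)] / denom
        value = min(1.0, max(0.0, value))
    cache[key] = value
    return value


def asym_sim(ic: ICMap, graph: OntologyGraph,
             s1: Iterable[str], s2: Iterable[str]) -> float:
    """Best-match-average similarity of term set *s1* into *s2*."""
    s1, s2 = list(s1), list(s2)
    if not s1 or not s2:
        raise ValueError("asym_sim requires two non-empty term sets")
    return float(np.mean([max(lin(graph, ic, t, u) for u in s2) for t in s1]))


def sym_sim(ic: ICMap, graph: OntologyGraph,
            s1: Iterable[str], s2: Iterable[str]) -> float:
    """Symmetric best-match-average similarity (mean of both directions)."""
    s1, s2 = list(s1), list(s2)
    return 0.5 * (asym_sim(ic, graph, s1, s2) + asym_sim(ic, graph, s2, s1))


def group_sim(ic: ICMap, graph: OntologyGraph,
              g1: Sequence[FrozenSet[str]], g2: Sequence[FrozenSet[str]]) -> float:
    """Mean symmetric similarity over all cross pairs of two individual groups.

    Individuals with empty term sets are skipped with a logged warning;
    a group with no usable individuals is an error.
    """
    u1 = [s for s in g1 if s]
    u2 = [s for s in g2 if s]
    if len(u1) < len(g1) or len(u2) < len(g2):
        logger.warning("group_sim: skipped %d individuals with empty term sets",
                       (len(g1) - len(u1)) + (len(g2) - len(u2)))
    if not u1 or not u2:
        raise ValueError("group_sim: a group has no individuals with terms")
    return float(np.mean([sym_sim(ic, graph, a, b) for a in u1 for b in u2]))


@dataclass
class SimilarityMatrix:
    """Square symmetric matrix of phenotype similarity scores in [0, 1]."""

    labels: List[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix is not symmetric")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("label\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def _variant_groups(cohort: CohortTable, variants: Sequence[str],
                    affected_only: bool = True) -> Dict[str, List[FrozenSet[str]]]:
    groups: Dict[str, List[FrozenSet[str]]] = {}
    for v in variants:
        probands = cohort.carriers(v)
        if affected_only:
            probands = probands.subset(lambda p: p.affected == "affected")
        groups[v] = [p.hpo_terms for p in probands if p.hpo_terms]
    return groups


def variant_similarity_matrix(cohort: CohortTable, ic: ICMap,
                              graph: OntologyGraph,
                              variants: Sequence[str],
                              affected_only: bool = True) -> SimilarityMatrix:
    """Pairwise group similarity between the proband groups of variants."""
    groups = _variant_groups(cohort, variants, affected_only)
    empty = [v for v, g in groups.items() if not g]
    if empty:
        raise ValueError(f"variants without phenotyped probands: {sorted(empty)}")
    n = len(variants)
    m = np.zeros((n, n))
    for i, vi in enumerate(variants):
        for j in range(i, n):
            m[i, j] = m[j, i] = group_sim(ic, graph, groups[vi],
                                          groups[variants[j]])
    return SimilarityMatrix(labels=list(variants), values=m)


@dataclass
class ClusteringResult:
    labels: Dict[str, int]          # variant -> 1-based cluster id
    merges: np.ndarray              # scipy linkage matrix
    method: str

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("label\tcluster\n")
            for lab in sorted(self.labels):
                fh.write(f"{lab}\t{self.labels[lab]}\n")


def cluster_variants(matrix: SimilarityMatrix, n_clusters: int,
                     method: str = "average") -> ClusteringResult:
    """Agglomerative clustering of variants on distance 1 - similarity."""
    if method not in LINKAGE_METHODS:
        raise ValueError(f"linkage method must be one of {LINKAGE_METHODS}")
    n = len(matrix.labels)
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}]")
    dist = 1.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method=method)
    flat = fcluster(z, t=n_clusters, criterion="maxclust")
    return ClusteringResult(labels=dict(zip(matrix.labels, map(int, flat))),
                            merges=z, method=method)


def cluster_summary(cohort: CohortTable, graph: OntologyGraph,
                    cluster: Sequence[str], affected_only: bool = True,
                    exclude: Iterable[str] = (),
                    threshold: float = 0.5) -> Tuple[str, FrozenSet[str]]:
    """Summarize a cluster of variants by its probands' propagated phenotypes.

    Returns ``(most_common_term, most_specific_majority_terms)``: the most
    frequent closure term (excluding the root, any term literally named
    "Phenotypic abnormality", and *exclude*), and the terms present in at
    least *threshold* of probands that have no descendant also above the
    threshold (the leaves of the majority sub-DAG).
    """
    if not cluster:
        raise ValueError("cluster is empty")
    seen: Dict[str, FrozenSet[str]] = {}
    for v in cluster:
        probands = cohort.carriers(v)
        if affected_only:
            probands = probands.subset(lambda p: p.affected == "affected")
        for p in probands:
            if p.hpo_terms:
                seen[p.individual_id] = p.hpo_terms
    if not seen:
        raise ValueError("cluster has no phenotyped probands")
    excluded = {graph.root} | set(exclude)
    excluded |= {t for t, name in graph.names.items()
                 if name == "Phenotypic abnormality"}
    counts: Dict[str, int] = {}
    for terms in seen.values():
        for t in graph.closure(terms):
            if t not in excluded:
                counts[t] = counts.get(t, 0) + 1
    if not counts:
        raise ValueError("cluster probands annotate only excluded terms")
    # ties (a term always co-occurs with its ancestors in closures) are
    # resolved in favor of the most specific term, then lexicographically
    max_count = max(counts.values())
    tied = [t for t, c in counts.items() if c == max_count]
    tied = [t for t in tied
            if not any(t != u and t in graph.ancestors(u) for u in tied)]
    most_common = min(tied)
    n = len(seen)
    majority = {t for t, c in counts.items() if c / n >= threshold}
    specific = frozenset(
        t for t in majority
        if not any(t in graph.ancestors(u) for u in majority if u != t))
    return most_common, specific


def system_profile(cohort: CohortTable, graph: OntologyGraph, variant: str,
                   top_level: Sequence[str] | None = None,
                   affected_only: bool = True) -> Dict[str, float]:
    """Fraction of a variant's probands hitting each top-level system term.

    Top-level terms default to the children of the root (for HPO proper,
    pass the children of "Phenotypic abnormality" explicitly).  Fractions
    need not sum to 1: one proband can involve several systems.
    """
    if top_level is None:
        top_level = sorted(graph.children(graph.root))
    probands = cohort.carriers(variant)
    if affected_only:
        probands = probands.subset(lambda p: p.affected == "affected")
    members = [p for p in probands if p.hpo_terms]
    if not members:
        raise ValueError(f"variant {variant!r} has no phenotyped probands")
    out: Dict[str, float] = {}
    closures = [graph.closure(p.hpo_terms) for p in members]
    for sys_term in top_level:
        t = graph.resolve(sys_term)
        out[t] = sum(t in c for c in closures) / len(members)
    return out
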