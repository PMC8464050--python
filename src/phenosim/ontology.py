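"""Phenotype ontology handling: parsing, closures, and information content.

The ontology is a single-rooted directed acyclic graph of phenotype terms
connected by ``is_a`` edges (e.g. the Human Phenotype Ontology, or the
synthetic ontologies produced by :mod:`phenosim.simulate`).  Individuals are
annotated with *minimal* term sets; whenever frequencies are needed the
annotations are propagated to all ancestors first (the "true-path" rule:
an annotation to a term implies annotation to every ancestor).  With
propagation the root is annotated to every individual, so its corpus
frequency is 1 and its information content ``IC(t) = -ln f(t)`` is 0, and
IC decreases monotonically from leaves towards the root.

The natural logarithm is used for IC.  Lin similarity, the only consumer,
is a ratio of ICs and therefore invariant to the choice of log base.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, Mapping, Set

import networkx as nx
import obonet

__all__ = [
    "OntologyError",
    "OntologyGraph",
    "AnnotationCorpus",
    "ICMap",
    "parse_obo",
    "write_obo",
    "ancestors",
    "minimal_set",
    "term_frequencies",
    "information_content",
    "mica",
]


class OntologyError(ValueError):
    """Structural problem in an ontology file or graph."""


@dataclass(eq=False)
class OntologyGraph:
    """Single-rooted DAG of phenotype terms linked by ``is_a`` edges.

    Parameters
    ----------
    names
        Term identifier -> human-readable label.
    parents
        Term identifier -> frozenset of direct ``is_a`` parents.  Exactly
        one term (the root) has no parents.
    alt_ids
        Alternate (or obsolete-replaced) identifier -> canonical identifier.
    """

    names: Dict[str, str]
    parents: Dict[str, FrozenSet[str]]
    alt_ids: Dict[str, str] = field(default_factory=dict)
    root: str = field(init=False)
    _children: Dict[str, FrozenSet[str]] = field(init=False, repr=False)
    _anc_cache: Dict[str, FrozenSet[str]] = field(init=False, repr=False,
                                                  default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    # -- construction -------------------------------------------------
    def _validate(self) -> None:
        terms = set(self.parents)
        if set(self.names) != terms:
            missing = set(self.names) ^ terms
            raise OntologyError(f"names/parents term mismatch: {sorted(missing)}")
        dangling = {p for ps in self.parents.values() for p in ps} - terms
        if dangling:
            raise OntologyError(
                f"is_a targets missing from the ontology: {sorted(dangling)}")
        collisions = set(self.alt_ids) & terms
        if collisions:
            raise OntologyError(
                f"alt_id identifiers collide with canonical terms: {sorted(collisions)}")
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        g.add_edges_from((t, p) for t, ps in self.parents.items() for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            cycle = sorted({u for u, _ in nx.find_cycle(g)})
            raise OntologyError(f"is_a cycle detected involving terms: {cycle}")
        roots = sorted(t for t, ps in self.parents.items() if not ps)
        if len(roots) != 1:
            raise OntologyError(f"ontology must have exactly one root, found: {roots}")
        self.root = roots[0]
        child: Dict[str, Set[str]] = {t: set() for t in terms}
        for t, ps in self.parents.items():
            for p in ps:
                child[p].add(t)
        self._children = {t: frozenset(c) for t, c in child.items()}

    # -- queries -------------------------------------------------------
    @property
    def terms(self) -> FrozenSet[str]:
        return frozenset(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents or term in self.alt_ids

    def __len__(self) -> int:
        return len(self.parents)

    def resolve(self, term: str) -> str:
        """Map an identifier (canonical or alternate) to its canonical term."""
        if term in self.parents:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise KeyError(f"unknown ontology term: {term!r}")

    def children(self, term: str) -> FrozenSet[str]:
        return self._children[self.resolve(term)]

    def ancestors(self, term: str) -> FrozenSet[str]:
        """Inclusive ancestor closure of *term* (contains the term itself)."""
        term = self.resolve(term)
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        seen = {term}
        queue = deque([term])
        while queue:
            for p in self.parents[queue.popleft()]:
                if p not in seen:
                    seen.add(p)
                    queue.append(p)
        result = frozenset(seen)
        self._anc_cache[term] = result
        return result

    def closure(self, terms: Iterable[str]) -> FrozenSet[str]:
        """Union of inclusive ancestor closures of a term set."""
        out: Set[str] = set()
        for t in terms:
            out |= self.ancestors(t)
        return frozenset(out)


@dataclass
class AnnotationCorpus:
    """Minimal phenotype annotations of a set of individuals."""

    annotations: Dict[str, FrozenSet[str]]

    @property
    def n_individuals(self) -> int:
        return len(self.annotations)


@dataclass
class ICMap:
    """Per-term corpus frequency and information content (nats).

    Terms never observed in the corpus carry the smoothed frequency
    ``1 / (2 * corpus_size)`` so that annotations of new patients outside
    the reference corpus remain comparable.
    """

    ic: Dict[str, float]
    freq: Dict[str, float]
    corpus_size: int

    def __getitem__(self, term: str) -> float:
        return self.ic[term]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("term\tfreq\tic\n")
            for t in sorted(self.ic):
                fh.write(f"{t}\t{self.freq[t]:.10g}\t{self.ic[t]:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, corpus_size: int) -> "ICMap":
        ic: Dict[str, float] = {}
        freq: Dict[str, float] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["term", "freq", "ic"]:
                raise ValueError(f"unexpected IC table header: {header}")
            for line in fh:
                t, f, i = line.rstrip("\n").split("\t")
                freq[t] = float(f)
                ic[t] = float(i)
        return cls(ic=ic, freq=freq, corpus_size=corpus_size)


def parse_obo(path: str | Path) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    Obsolete terms are dropped; their identifiers (and any ``alt_id`` /
    ``replaced_by`` pointers) are registered as alternate identifiers when
    a replacement is given.  Only ``is_a`` relations are kept.
    """
    raw = obonet.read_obo(str(path), ignore_obsolete=False)
    names: Dict[str, str] = {}
    parents: Dict[str, FrozenSet[str]] = {}
    alt_ids: Dict[str, str] = {}
    obsolete: Set[str] = set()
    for term, data in raw.nodes(data=True):
        if data.get("is_obsolete") in ("true", True):
            obsolete.add(term)
            replaced = data.get("replaced_by")
            if replaced:
                alt_ids[term] = replaced[0] if isinstance(replaced, list) else replaced
            continue
        if "name" not in data:
            raise OntologyError(
                f"term {term!r} is referenced by is_a but has no [Term] stanza")
        names[term] = data["name"]
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term
    for term in names:
        isa = {p for p in raw.nodes[term].get("is_a", []) if p not in obsolete}
        missing = isa - set(names)
        if missing:
            raise OntologyError(
                f"term {term!r} has dangling is_a target(s): {sorted(missing)}")
        parents[term] = frozenset(isa)
    # redirect alt ids that point at obsolete terms through replaced_by
    resolved_alt: Dict[str, str] = {}
    for alt, target in alt_ids.items():
        seen = {alt}
        while target in alt_ids and target not in names and target not in seen:
            seen.add(target)
            target = alt_ids[target]
        if target in names:
            resolved_alt[alt] = target
    return OntologyGraph(names=names, parents=parents, alt_ids=resolved_alt)


def write_obo(graph: OntologyGraph, path: str | Path) -> None:
    """Write the graph as a minimal OBO 1.2 flat file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: phenosim-synthetic\n")
        reverse_alt: Dict[str, list] = {}
        for alt, canon in graph.alt_ids.items():
            reverse_alt.setdefault(canon, []).append(alt)
        for term in sorted(graph.parents):
            fh.write(f"\n[Term]\nid: {term}\nname: {graph.names[term]}\n")
            for alt in sorted(reverse_alt.get(term, [])):
                fh.write(f"alt_id: {alt}\n")
            for p in sorted(graph.parents[term]):
                fh.write(f"is_a: {p} ! {graph.names[p]}\n")


def ancestors(graph: OntologyGraph, term: str) -> FrozenSet[str]:
    """Inclusive ``is_a`` ancestor closure of *term*."""
    return graph.ancestors(term)


def minimal_set(graph: OntologyGraph, terms: Iterable[str]) -> FrozenSet[str]:
    """Drop every term that is a strict ancestor of another term in the set.

    Idempotent; the result is the minimal ("non-redundant") representation
    of the same propagated annotation closure.
    """
    resolved = {graph.resolve(t) for t in terms}
    redundant: Set[str] = set()
    for t in resolved:
        redundant |= graph.ancestors(t) - {t}
    return frozenset(resolved - redundant)


def term_frequencies(graph: OntologyGraph,
                     corpus: AnnotationCorpus) -> Dict[str, float]:
    """Fraction of corpus individuals whose propagated closure contains each term.

    Covers every term of the graph; terms absent from all closures get 0.
    """
    if corpus.n_individuals < 1:
        raise ValueError("annotation corpus is empty")
    counts = {t: 0 for t in graph.parents}
    for terms in corpus.annotations.values():
        for t in graph.closure(terms):
            counts[t] += 1
    n = corpus.n_individuals
    return {t: c / n for t, c in counts.items()}


def information_content(freqs: Mapping[str, float], corpus_size: int) -> ICMap:
    """IC(t) = -ln f(t), with zero frequencies smoothed to 1/(2*corpus_size)."""
    if corpus_size < 1:
        raise ValueError("corpus_size must be >= 1")
    smoothed = 1.0 / (2.0 * corpus_size)
    freq: Dict[str, float] = {}
    ic: Dict[str, float] = {}
    for t, f in freqs.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"frequency of {t!r} outside [0, 1]: {f}")
        f = f if f > 0 else smoothed
        freq[t] = f
        ic[t] = -math.log(f) if f < 1.0 else 0.0
    return ICMap(ic=ic, freq=freq, corpus_size=corpus_size)


def mica(graph: OntologyGraph, ic: ICMap, t1: str, t2: str) -> str:
    """Most informative common (inclusive) ancestor of two terms.

    Ties in IC are broken by the lexicographically smallest identifier so
    the result is deterministic (the choice does not affect Lin similarity).
    """
    common = graph.ancestors(t1) & graph.ancestors(t2)
    return min(common, key=lambda t: (-ic.ic[t], t))
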