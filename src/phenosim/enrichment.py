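"""Variant-term enrichment with cross-publication replication.

For a variant and a term, carriers and non-carrier probands are compared
with a one-sided Fisher's exact test (enrichment direction: at least as
many carriers-with-term as observed, given the margins).  Term presence is
evaluated on propagated annotation closures.  A term is declared enriched
for a variant only if the pooled test over the whole cohort is significant
at a stringent threshold AND the within-publication test is significant in
at least two independent publications - the replication requirement guards
against author-specific reporting bias.

Enriched terms are further flagged as *under-recognized* when they are
absent from a user-supplied map of established variant-phenotype
annotations (and are not generalizations of a listed term).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence

from scipy.stats import hypergeom

from .cohort import CohortTable
from .ontology import OntologyGraph

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "fisher_one_sided",
    "variant_term_enrichment",
    "scan_enrichment",
    "flag_under_recognized",
    "read_known_map",
    "write_enrichment_tsv",
]

POOLED_ALPHA = 1e-6
PUB_ALPHA = 0.05


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: carriers/non-carriers x with/without term."""

    a: int  # carriers with term
    b: int  # carriers without term
    c: int  # non-carriers with term
    d: int  # non-carriers without term

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency table entries must be non-negative")


@dataclass
class EnrichmentResult:
    variant: str
    term: str
    pooled_p: float
    carrier_freq: float
    background_freq: float
    per_publication_p: Dict[str, float] = field(default_factory=dict)
    n_significant_publications: int = 0
    enriched: bool = False
    under_recognized: Optional[bool] = None  # None = not assessed


def fisher_one_sided(table: ContingencyTable) -> float:
    """Upper-tail hypergeometric p: P(X >= a) given the table margins."""
    m = table.a + table.b + table.c + table.d
    if m == 0:
        return 1.0
    k = table.a + table.c          # individuals with the term
    n = table.a + table.b          # carriers drawn
    return float(hypergeom.sf(table.a - 1, m, k, n))


def _table(carriers: CohortTable, background: CohortTable, term: str,
           graph: OntologyGraph) -> ContingencyTable:
    term = graph.resolve(term)
    a = sum(term in graph.closure(p.hpo_terms) for p in carriers)
    c = sum(term in graph.closure(p.hpo_terms) for p in background)
    return ContingencyTable(a=a, b=len(carriers) - a,
                            c=c, d=len(background) - c)


def variant_term_enrichment(cohort: CohortTable, graph: OntologyGraph,
                            variant: str, term: str,
                            pooled_alpha: float = POOLED_ALPHA,
                            pub_alpha: float = PUB_ALPHA) -> EnrichmentResult:
    """Pooled + per-publication enrichment of a term in a variant's carriers."""
    term = graph.resolve(term)
    carriers = cohort.carriers(variant)
    background = cohort.non_carriers(variant)
    pooled = _table(carriers, background, term, graph)
    per_pub: Dict[str, float] = {}
    for pub in cohort.publications:
        pc = carriers.subset(lambda p: p.publication_id == pub)
        pb = background.subset(lambda p: p.publication_id == pub)
        if len(pc) == 0:
            continue
        per_pub[pub] = fisher_one_sided(_table(pc, pb, term, graph))
    pooled_p = fisher_one_sided(pooled)
    n_sig = sum(p < pub_alpha for p in per_pub.values())
    return EnrichmentResult(
        variant=variant,
        term=term,
        pooled_p=pooled_p,
        carrier_freq=pooled.a / max(1, pooled.a + pooled.b),
        background_freq=pooled.c / max(1, pooled.c + pooled.d),
        per_publication_p=per_pub,
        n_significant_publications=n_sig,
        enriched=(pooled_p < pooled_alpha and n_sig >= 2),
    )


def scan_enrichment(cohort: CohortTable, graph: OntologyGraph,
                    variants: Sequence[str] | None = None,
                    pooled_alpha: float = POOLED_ALPHA,
                    pub_alpha: float = PUB_ALPHA,
                    exclude: Iterable[str] = ()) -> List[EnrichmentResult]:
    """Test every term in any carrier's closure, for each variant.

    The scanned universe excludes the root, any term named "Phenotypic
    abnormality", and *exclude*.
    """
    if variants is None:
        variants = cohort.variants
    excluded = {graph.root} | {graph.resolve(t) for t in exclude}
    excluded |= {t for t, name in graph.names.items()
                 if name == "Phenotypic abnormality"}
    results: List[EnrichmentResult] = []
    for v in variants:
        universe: set = set()
        for p in cohort.carriers(v):
            universe |= graph.closure(p.hpo_terms)
        for term in sorted(universe - excluded):
            results.append(variant_term_enrichment(
                cohort, graph, v, term, pooled_alpha, pub_alpha))
    return results


def read_known_map(path: str | Path, graph: OntologyGraph
                   ) -> Dict[str, FrozenSet[str]]:
    """Read a variant -> known-term map TSV (columns: variant, term)."""
    out: Dict[str, set] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["variant", "term"]:
            raise ValueError(f"unexpected known-map header: {header}")
        for line in fh:
            variant, term = line.rstrip("\n").split("\t")
            out.setdefault(variant, set()).add(graph.resolve(term))
    return {v: frozenset(ts) for v, ts in out.items()}


def flag_under_recognized(results: Sequence[EnrichmentResult],
                          known_map: Mapping[str, Iterable[str]],
                          graph: OntologyGraph) -> List[EnrichmentResult]:
    """Set the under-recognized flag on enriched results.

    An enriched term is under-recognized iff it is not among the variant's
    known terms and is not an ancestor of any known term (a listed specific
    phenotype implies recognition of its generalizations).  Variants with
    no entry in the map are left not-assessed (None).
    """
    known_closures: Dict[str, FrozenSet[str]] = {}
    for variant, terms in known_map.items():
        resolved = {graph.resolve(t) for t in terms}
        known_closures[variant] = graph.closure(resolved)
    for r in results:
        if not r.enriched:
            r.under_recognized = None
            continue
        if r.variant not in known_closures:
            r.under_recognized = None
            continue
        r.under_recognized = r.term not in known_closures[r.variant]
    return list(results)


def write_enrichment_tsv(results: Sequence[EnrichmentResult],
                         path: str | Path,
                         sidecar: str | Path | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("variant\tterm\tpooled_p\tcarrier_freq\tbackground_freq\t"
                 "n_significant_publications\tenriched\tunder_recognized\n")
        for r in results:
            ur = "NA" if r.under_recognized is None else str(r.under_recognized)
            fh.write(f"{r.variant}\t{r.term}\t{r.pooled_p:.6g}\t"
                     f"{r.carrier_freq:.6g}\t{r.background_freq:.6g}\t"
                     f"{r.n_significant_publications}\t{r.enriched}\t{ur}\n")
    if sidecar is not None:
        payload = {f"{r.variant}|{r.term}": r.per_publication_p for r in results}
        with open(sidecar, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
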