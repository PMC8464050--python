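import pytest

from phenosim.cohort import PatientRecord, CohortTable
from phenosim.ontology import (AnnotationCorpus, OntologyGraph,
                               information_content, term_frequencies)
from phenosim.simulate import toy_ontology


@pytest.fixture(scope="session")
def toy40() -> OntologyGraph:
    return toy_ontology()


@pytest.fixture()
def diamond() -> OntologyGraph:
    """root <- b, c; d below both b and c."""
    names = {t: t for t in ("root", "b", "c", "d")}
    parents = {"root": frozenset(), "b": frozenset(["root"]),
               "c": frozenset(["root"]), "d": frozenset(["b", "c"])}
    return OntologyGraph(names=names, parents=parents)


@pytest.fixture(scope="session")
def small_corpus_ic():
    """5-term graph and an 8-individual corpus with hand-computable ICs.

    b and c under the root; d1, d2 under b.  One individual each annotates
    d1 and d2, six annotate c, so freq(b) = 1/4, freq(d1) = freq(d2) = 1/8
    and Lin(d1, d2) = 2 ln4 / (2 ln8) = 2/3 exactly.
    """
    names = {t: t for t in ("root", "b", "c", "d1", "d2")}
    parents = {"root": frozenset(), "b": frozenset(["root"]),
               "c": frozenset(["root"]), "d1": frozenset(["b"]),
               "d2": frozenset(["b"])}
    graph = OntologyGraph(names=names, parents=parents)
    annotations = {"P1": frozenset(["d1"]), "P2": frozenset(["d2"])}
    annotations.update({f"P{i}": frozenset(["c"]) for i in range(3, 9)})
    corpus = AnnotationCorpus(annotations=annotations)
    ic = information_content(term_frequencies(graph, corpus),
                             corpus.n_individuals)
    return graph, ic


def make_patient(pid, variant="m.3243A>G", terms=frozenset(), pub="PUB000",
                 proband=True, affected="affected", het=(), variants=None):
    from phenosim.cohort import HeteroplasmyMeasurement
    return PatientRecord(
        individual_id=pid, proband_id=pid if proband else f"{pid}_pro",
        family_id=f"F_{pid}", publication_id=pub,
        variants=variants if variants is not None else (variant,),
        affected=affected, is_proband=proband, hpo_terms=frozenset(terms),
        heteroplasmy=tuple(HeteroplasmyMeasurement(t, l) for t, l in het),
    )


@pytest.fixture()
def tiny_cohort(toy40) -> CohortTable:
    """Four probands of two variants plus one relative, on the toy ontology."""
    patients = [
        make_patient("A1", "m.3243A>G", {"T:0104", "T:0301"},
                     het=(("blood", 30.0), ("muscle", 60.0))),
        make_patient("A2", "m.3243A>G", {"T:0104", "T:0302"},
                     het=(("blood", 50.0), ("muscle", 80.0))),
        make_patient("B1", "m.8993T>G", {"T:0103"}, pub="PUB001",
                     het=(("muscle", 90.0),)),
        make_patient("B2", "m.8993T>G", {"T:0103", "T:0105"}, pub="PUB001"),
    ]
    relative = make_patient("A1_rel", "m.3243A>G", {"T:0501"},
                            proband=False, affected="unaffected")
    relative = PatientRecord(**{**relative.__dict__, "proband_id": "A1"})
    return CohortTable(patients + [relative])
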