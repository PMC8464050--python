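"""Relational patient data model for mtDNA variant cohorts.

One row per individual: carried variant(s), minimal HPO term set,
heteroplasmy measurements (up to three tissues), publication / family /
proband structure, affected status and optional muscle histology
percentages.  The unit of analysis downstream is the proband (the first
identified affected individual of a family).

Variant labels follow the rCRS convention ``m.<pos><ref>><alt>`` (or small
indel labels such as ``m.3271_3272del``); positions are 1-based within the
16,569 bp mitochondrial genome.  Labels are treated as opaque keys
everywhere except range validation.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

from .ontology import (AnnotationCorpus, ICMap, OntologyGraph,
                       information_content, minimal_set, term_frequencies)

__all__ = [
    "MT_GENOME_LENGTH",
    "TISSUES",
    "CohortValidationError",
    "VariantRecord",
    "HeteroplasmyMeasurement",
    "PatientRecord",
    "CohortTable",
    "parse_variant_label",
    "read_cohort",
    "write_cohort",
    "annotation_corpus",
    "cohort_information_content",
]

MT_GENOME_LENGTH = 16569
TISSUES = ("blood", "muscle", "urine", "fibroblast", "other")
AFFECTED_STATES = ("affected", "unaffected", "unknown")
SEXES = ("M", "F", "unknown")

_SNV_RE = re.compile(r"^m\.(\d+)([ACGTN]+)>([ACGTN]+)$")
_INDEL_RE = re.compile(r"^m\.(\d+)(?:_(\d+))?(del|ins|dup)[ACGTN]*$")

COHORT_COLUMNS = [
    "individual_id", "proband_id", "family_id", "publication_id",
    "variants", "affected", "is_proband", "sex", "age_at_onset",
    "hpo_terms", "het_tissue1", "het_level1", "het_tissue2", "het_level2",
    "het_tissue3", "het_level3", "cox_deficient_pct", "ragged_red_pct",
]


class CohortValidationError(ValueError):
    """Aggregated row/field validation failures for a cohort table."""

    def __init__(self, problems: List[str]):
        self.problems = list(problems)
        super().__init__("cohort validation failed:\n  " + "\n  ".join(problems))


@dataclass(frozen=True)
class VariantRecord:
    """A parsed mtDNA variant label."""

    label: str
    position: int
    kind: str  # "snv" or "indel"
    gene: Optional[str] = None
    gene_class: Optional[str] = None  # protein_coding | tRNA | rRNA | dloop

    def __post_init__(self):
        if not 1 <= self.position <= MT_GENOME_LENGTH:
            raise ValueError(
                f"variant {self.label!r}: position {self.position} outside "
                f"[1, {MT_GENOME_LENGTH}]")


def parse_variant_label(label: str) -> VariantRecord:
    """Parse and range-validate an ``m.`` variant label."""
    m = _SNV_RE.match(label)
    if m:
        return VariantRecord(label=label, position=int(m.group(1)), kind="snv")
    m = _INDEL_RE.match(label)
    if m:
        return VariantRecord(label=label, position=int(m.group(1)), kind="indel")
    raise ValueError(f"malformed variant label: {label!r}")


@dataclass(frozen=True)
class HeteroplasmyMeasurement:
    tissue: str
    level: float  # percentage

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if not 0.0 <= self.level <= 100.0:
            raise ValueError(
                f"heteroplasmy level {self.level} outside [0, 100] ({self.tissue})")


@dataclass(frozen=True)
class PatientRecord:
    individual_id: str
    proband_id: str
    family_id: str
    publication_id: str
    variants: Tuple[str, ...]
    affected: str = "affected"
    is_proband: bool = False
    sex: str = "unknown"
    age_at_onset: Optional[float] = None
    hpo_terms: FrozenSet[str] = frozenset()
    heteroplasmy: Tuple[HeteroplasmyMeasurement, ...] = ()
    cox_deficient_pct: Optional[float] = None
    ragged_red_pct: Optional[float] = None

    def __post_init__(self):
        if len(self.heteroplasmy) > 3:
            raise ValueError(
                f"{self.individual_id}: more than 3 heteroplasmy measurements")
        tissues = [m.tissue for m in self.heteroplasmy]
        if len(tissues) != len(set(tissues)):
            raise ValueError(f"{self.individual_id}: duplicate tissue measurement")
        if self.is_proband and self.proband_id != self.individual_id:
            raise ValueError(
                f"{self.individual_id}: proband must be its own proband_id")
        if self.affected not in AFFECTED_STATES:
            raise ValueError(f"{self.individual_id}: bad affected state "
                             f"{self.affected!r}")

    def het_level(self, tissue: str) -> Optional[float]:
        for m in self.heteroplasmy:
            if m.tissue == tissue:
                return m.level
        return None

    def carries(self, variant: str) -> bool:
        return variant in self.variants


class CohortTable:
    """An indexed collection of :class:`PatientRecord`."""

    def __init__(self, patients: Iterable[PatientRecord]):
        self.patients: List[PatientRecord] = list(patients)
        by_id: Dict[str, PatientRecord] = {}
        problems: List[str] = []
        for p in self.patients:
            if p.individual_id in by_id:
                problems.append(f"duplicate individual_id: {p.individual_id}")
            by_id[p.individual_id] = p
        for p in self.patients:
            if p.proband_id not in by_id:
                problems.append(
                    f"{p.individual_id}: proband_id {p.proband_id} not in table")
        if problems:
            raise CohortValidationError(problems)
        self._by_id = by_id

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def __getitem__(self, individual_id: str) -> PatientRecord:
        return self._by_id[individual_id]

    @property
    def variants(self) -> List[str]:
        return sorted({v for p in self.patients for v in p.variants})

    @property
    def publications(self) -> List[str]:
        return sorted({p.publication_id for p in self.patients})

    def subset(self, predicate) -> "CohortTable":
        sub = CohortTable.__new__(CohortTable)
        sub.patients = [p for p in self.patients if predicate(p)]
        sub._by_id = {p.individual_id: p for p in sub.patients}
        return sub

    def probands(self, affected_only: bool = False) -> "CohortTable":
        return self.subset(
            lambda p: p.is_proband and
            (not affected_only or p.affected == "affected"))

    def carriers(self, variant: str) -> "CohortTable":
        """Probands carrying *variant* (double-carriers count for each)."""
        if variant not in {v for p in self.patients for v in p.variants}:
            raise KeyError(f"variant {variant!r} not present in cohort")
        return self.probands().subset(lambda p: p.carries(variant))

    def non_carriers(self, variant: str) -> "CohortTable":
        """Proband background for *variant*.

        Excludes carriers of the variant and every double-carrier: an
        individual harboring two pathogenic variants is a carrier of each
        and never part of any comparison background.
        """
        if variant not in {v for p in self.patients for v in p.variants}:
            raise KeyError(f"variant {variant!r} not present in cohort")
        return self.probands().subset(
            lambda p: not p.carries(variant) and len(p.variants) == 1)


def annotation_corpus(cohort: CohortTable, graph: OntologyGraph,
                      affected_only: bool = True,
                      nonempty_only: bool = True) -> AnnotationCorpus:
    """Annotation corpus of the cohort's probands (the IC reference context)."""
    ann: Dict[str, FrozenSet[str]] = {}
    for p in cohort.probands(affected_only=affected_only):
        if nonempty_only and not p.hpo_terms:
            continue
        ann[p.individual_id] = p.hpo_terms
    return AnnotationCorpus(annotations=ann)


def cohort_information_content(cohort: CohortTable, graph: OntologyGraph,
                               affected_only: bool = True) -> ICMap:
    """IC map over the whole ontology from the cohort's proband corpus."""
    corpus = annotation_corpus(cohort, graph, affected_only=affected_only)
    freqs = term_frequencies(graph, corpus)
    return information_content(freqs, corpus.n_individuals)


# ---------------------------------------------------------------------------
# TSV serialization.  Missing values are the explicit sentinel "NA".
# ---------------------------------------------------------------------------

def _fmt_num(x: Optional[float]) -> str:
    if x is None:
        return "NA"
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def _parse_num(s: str, line: int, col: str, problems: List[str],
               lo: float = None, hi: float = None) -> Optional[float]:
    if s == "NA" or s == "":
        return None
    try:
        v = float(s)
    except ValueError:
        problems.append(f"line {line}: {col}: not a number: {s!r}")
        return None
    if lo is not None and not (lo <= v <= (hi if hi is not None else v)):
        problems.append(f"line {line}: {col}: value {v} outside [{lo}, {hi}]")
        return None
    return v


def read_cohort(path: str | Path, graph: OntologyGraph) -> CohortTable:
    """Read and validate a cohort TSV, resolving and minimizing HPO terms.

    All row/field offences are collected and reported together with line
    numbers in a single :class:`CohortValidationError`.
    """
    problems: List[str] = []
    patients: List[PatientRecord] = []
    seen_ids: set = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != COHORT_COLUMNS:
            raise CohortValidationError(
                [f"unexpected columns: {reader.fieldnames}"])
        for lineno, row in enumerate(reader, start=2):
            if row["individual_id"] in seen_ids:
                problems.append(f"line {lineno}: duplicate individual_id: "
                                f"{row['individual_id']}")
            seen_ids.add(row["individual_id"])
            variants: List[str] = []
            for v in filter(None, (row["variants"] or "").split(";")):
                try:
                    parse_variant_label(v)
                    variants.append(v)
                except ValueError as e:
                    problems.append(f"line {lineno}: variants: {e}")
            terms = set()
            for t in filter(None, (row["hpo_terms"] or "").split(";")):
                if t == "NA":
                    continue
                try:
                    terms.add(graph.resolve(t))
                except KeyError:
                    problems.append(f"line {lineno}: hpo_terms: "
                                    f"unresolvable term {t!r}")
            het: List[HeteroplasmyMeasurement] = []
            for i in (1, 2, 3):
                tis = row[f"het_tissue{i}"]
                lev = _parse_num(row[f"het_level{i}"], lineno, f"het_level{i}",
                                 problems, 0.0, 100.0)
                if tis in ("NA", "", None):
                    continue
                if tis not in TISSUES:
                    problems.append(f"line {lineno}: het_tissue{i}: "
                                    f"unknown tissue {tis!r}")
                    continue
                if lev is not None:
                    het.append(HeteroplasmyMeasurement(tissue=tis, level=lev))
            affected = row["affected"]
            if affected not in AFFECTED_STATES:
                problems.append(f"line {lineno}: affected: bad value {affected!r}")
                affected = "unknown"
            sex = row["sex"]
            if sex not in SEXES:
                problems.append(f"line {lineno}: sex: bad value {sex!r}")
                sex = "unknown"
            try:
                patients.append(PatientRecord(
                    individual_id=row["individual_id"],
                    proband_id=row["proband_id"],
                    family_id=row["family_id"],
                    publication_id=row["publication_id"],
                    variants=tuple(variants),
                    affected=affected,
                    is_proband=row["is_proband"] == "1",
                    sex=sex,
                    age_at_onset=_parse_num(row["age_at_onset"], lineno,
                                            "age_at_onset", problems),
                    hpo_terms=minimal_set(graph, terms) if terms else frozenset(),
                    heteroplasmy=tuple(het),
                    cox_deficient_pct=_parse_num(row["cox_deficient_pct"], lineno,
                                                 "cox_deficient_pct", problems,
                                                 0.0, 100.0),
                    ragged_red_pct=_parse_num(row["ragged_red_pct"], lineno,
                                              "ragged_red_pct", problems,
                                              0.0, 100.0),
                ))
            except ValueError as e:
                problems.append(f"line {lineno}: {e}")
    if problems:
        raise CohortValidationError(problems)
    return CohortTable(patients)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write the cohort TSV (lossless round-trip with :func:`read_cohort`)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(COHORT_COLUMNS)
        for p in cohort:
            het = list(p.heteroplasmy) + [None] * (3 - len(p.heteroplasmy))
            row = [
                p.individual_id, p.proband_id, p.family_id, p.publication_id,
                ";".join(p.variants), p.affected,
                "1" if p.is_proband else "0", p.sex,
                _fmt_num(p.age_at_onset),
                ";".join(sorted(p.hpo_terms)) or "NA",
            ]
            for m in het:
                row += ([m.tissue, _fmt_num(m.level)] if m else ["NA", "NA"])
            row += [_fmt_num(p.cox_deficient_pct), _fmt_num(p.ragged_red_pct)]
            w.writerow(row)
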