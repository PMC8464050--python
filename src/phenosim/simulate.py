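"""Seeded synthetic ontologies and case/control cohorts.

The generator produces the structure the analysis modules assume:

* a single-rooted ontology whose non-root terms are organized into
  "system" branches under the root, mimicking the top-level organ-system
  organization of the HPO (terms in different systems share only the
  root, so phenotypes drawn from distinct systems are semantically
  separable);
* per-variant phenotype profiles drawn from a home system, annotated to
  probands with imperfect sensitivity plus Poisson off-profile noise
  (term_sensitivity defaults to 0.85, in the range of inter-rater
  concordance of literature HPO coding; profiles of 6 terms plus noise
  give per-proband term counts comparable to curated mtDNA cohorts);
* multi-publication structure with publications shared across variants,
  so within-publication carrier/non-carrier contrasts exist;
* muscle-dominant tissue heteroplasmy (blood = muscle minus a non-negative
  offset, floored at 0 - mutant load is almost always lower in blood);
* optional logistic dose-response links making designated terms depend on
  heteroplasmy level via presence ~ Bernoulli(expit(a + b * level));
* control patients whose profiles share a configurable fraction of terms
  with a random case profile, the remainder drawn from systems unoccupied
  by any variant (overlap 0 gives fully separable cohorts).

All outputs are pure functions of the configuration seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.special import expit

from .cohort import (CohortTable, HeteroplasmyMeasurement, PatientRecord)
from .ontology import OntologyGraph, minimal_set

__all__ = [
    "HeteroplasmyModel",
    "DoseResponseEffect",
    "ControlSpec",
    "SimulationConfig",
    "toy_ontology",
    "generate_ontology",
    "system_members",
    "variant_labels",
    "variant_profiles",
    "generate_cohort",
    "generate_controls",
    "generate_test_cases",
]


@dataclass(frozen=True)
class HeteroplasmyModel:
    """Muscle-level distribution and the non-negative blood offset (%)."""

    muscle_mean: float = 65.0
    muscle_sd: float = 20.0
    blood_offset_mean: float = 15.0
    blood_offset_sd: float = 8.0


@dataclass(frozen=True)
class DoseResponseEffect:
    """presence(term) ~ Bernoulli(expit(intercept + slope * level(tissue)))."""

    variant: str
    term: str
    tissue: str
    intercept: float  # log-odds at 0% heteroplasmy
    slope: float      # log-odds per heteroplasmy percentage point


@dataclass(frozen=True)
class ControlSpec:
    n_controls: int = 200
    profile_overlap: float = 0.3  # fraction of terms shared with a case profile


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_terms: int = 150
    max_parents: int = 2
    n_systems: Optional[int] = None
    n_variants: int = 10
    profile_size: int = 6
    probands_per_variant: int = 20
    n_publications_per_variant: int = 3
    term_sensitivity: float = 0.85
    noise_rate: float = 1.0
    heteroplasmy: HeteroplasmyModel = field(default_factory=HeteroplasmyModel)
    dose_response: Tuple[DoseResponseEffect, ...] = ()
    controls: ControlSpec = field(default_factory=ControlSpec)

    def __post_init__(self):
        if not 0.0 <= self.term_sensitivity <= 1.0:
            raise ValueError("term_sensitivity must be in [0, 1]")
        if not 0.0 <= self.controls.profile_overlap <= 1.0:
            raise ValueError("profile_overlap must be in [0, 1]")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "heteroplasmy" in d and isinstance(d["heteroplasmy"], dict):
            d["heteroplasmy"] = HeteroplasmyModel(**d["heteroplasmy"])
        if "controls" in d and isinstance(d["controls"], dict):
            d["controls"] = ControlSpec(**d["controls"])
        if "dose_response" in d:
            d["dose_response"] = tuple(
                e if isinstance(e, DoseResponseEffect) else DoseResponseEffect(**e)
                for e in d["dose_response"])
        return cls(**d)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


# ---------------------------------------------------------------------------
# Ontologies
# ---------------------------------------------------------------------------

_TOY_TERMS: List[Tuple[str, str, Tuple[str, ...]]] = [
    ("T:0001", "Phenotypic abnormality", ()),
    ("T:0100", "Abnormality of the nervous system", ("T:0001",)),
    ("T:0101", "Seizure", ("T:0100",)),
    ("T:0102", "Encephalopathy", ("T:0100",)),
    ("T:0103", "Necrotizing encephalopathy", ("T:0102",)),
    ("T:0104", "Stroke-like episode", ("T:0100",)),
    ("T:0105", "Developmental regression", ("T:0100",)),
    ("T:0106", "Peripheral neuropathy", ("T:0100",)),
    ("T:0107", "Polyneuropathy", ("T:0106",)),
    ("T:0108", "Focal seizure", ("T:0101",)),
    ("T:0200", "Abnormality of the musculature", ("T:0001",)),
    ("T:0201", "Myopathy", ("T:0200",)),
    ("T:0202", "Exercise intolerance", ("T:0200",)),
    ("T:0203", "Ptosis", ("T:0200",)),
    ("T:0204", "Ophthalmoplegia", ("T:0200",)),
    ("T:0205", "External ophthalmoplegia", ("T:0204",)),
    ("T:0206", "Ragged-red muscle fibers", ("T:0201",)),
    ("T:0300", "Abnormality of metabolism/homeostasis", ("T:0001",)),
    ("T:0301", "Lactic acidosis", ("T:0300",)),
    ("T:0302", "Diabetes mellitus", ("T:0304",)),
    ("T:0303", "Increased serum lactate", ("T:0301",)),
    ("T:0304", "Abnormal glucose homeostasis", ("T:0300",)),
    ("T:0305", "Hyperglycemia", ("T:0304",)),
    ("T:0400", "Abnormality of the cardiovascular system", ("T:0001",)),
    ("T:0401", "Cardiomyopathy", ("T:0400",)),
    ("T:0402", "Hypertrophic cardiomyopathy", ("T:0401",)),
    ("T:0403", "Arrhythmia", ("T:0400",)),
    ("T:0404", "Cardiac conduction abnormality", ("T:0400",)),
    ("T:0405", "Ventricular preexcitation", ("T:0403", "T:0404")),
    ("T:0500", "Abnormality of the ear", ("T:0001",)),
    ("T:0501", "Hearing impairment", ("T:0500",)),
    ("T:0502", "Sensorineural hearing impairment", ("T:0501",)),
    ("T:0503", "Congenital sensorineural hearing impairment", ("T:0502",)),
    ("T:0504", "Tinnitus", ("T:0500",)),
    ("T:0600", "Abnormality of the eye", ("T:0001",)),
    ("T:0601", "Visual impairment", ("T:0600",)),
    ("T:0602", "Optic atrophy", ("T:0600",)),
    ("T:0603", "Leber optic atrophy", ("T:0602",)),
    ("T:0604", "Retinopathy", ("T:0600",)),
    ("T:0605", "Color vision defect", ("T:0601",)),
]


def toy_ontology() -> OntologyGraph:
    """Fixed 40-term ontology with six named organ-system branches.

    Includes one diamond (ventricular preexcitation under both arrhythmia
    and conduction abnormality) and one alternate id (T:9999 -> hearing
    impairment).
    """
    names = {t: n for t, n, _ in _TOY_TERMS}
    parents = {t: frozenset(p) for t, _, p in _TOY_TERMS}
    return OntologyGraph(names=names, parents=parents,
                         alt_ids={"T:9999": "T:0501"})


def default_n_systems(n_terms: int) -> int:
    return min(max(2, n_terms // 10), n_terms - 1)


def generate_ontology(n_terms: int, max_parents: int = 2, seed: int = 0,
                      n_systems: Optional[int] = None) -> OntologyGraph:
    """Random single-rooted DAG organized in system branches.

    The first *n_systems* non-root terms are children of the root; each
    later term joins a system (round-robin) and draws 1..max_parents
    parents among that system's earlier terms, so branches only meet at
    the root.
    """
    if n_terms < 3:
        raise ValueError("n_terms must be >= 3")
    if n_systems is None:
        n_systems = default_n_systems(n_terms)
    rng = np.random.default_rng([int(seed), 1])
    ids = [f"T:{i:04d}" for i in range(n_terms)]
    root = ids[0]
    names = {root: "Synthetic phenotype root"}
    parents: Dict[str, FrozenSet[str]] = {root: frozenset()}
    members: List[List[str]] = []
    for s in range(n_systems):
        head = ids[1 + s]
        names[head] = f"Abnormality of system {s}"
        parents[head] = frozenset([root])
        members.append([head])
    for i in range(1 + n_systems, n_terms):
        term = ids[i]
        s = (i - 1 - n_systems) % n_systems
        pool = members[s]
        k = int(rng.integers(1, max_parents + 1))
        k = min(k, len(pool))
        chosen = rng.choice(len(pool), size=k, replace=False)
        names[term] = f"Synthetic term {i} (system {s})"
        parents[term] = frozenset(pool[j] for j in chosen)
        members[s].append(term)
    return OntologyGraph(names=names, parents=parents)


def system_members(graph: OntologyGraph) -> Dict[str, List[str]]:
    """Map each child of the root (system head) to its member terms.

    Members include the head itself; a term belongs to every system whose
    head is among its ancestors.
    """
    heads = sorted(graph.children(graph.root))
    out: Dict[str, List[str]] = {h: [] for h in heads}
    for t in sorted(graph.parents):
        if t == graph.root:
            continue
        anc = graph.ancestors(t)
        for h in heads:
            if h in anc:
                out[h].append(t)
    return out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def variant_labels(config: SimulationConfig) -> List[str]:
    """Deterministic rCRS-style SNV labels for the configured variants."""
    rng = _rng(config.seed, 2)
    positions = rng.choice(16569, size=config.n_variants, replace=False) + 1
    labels = []
    for pos in positions:
        ref, alt = rng.choice(4, size=2, replace=False)
        labels.append(f"m.{int(pos)}{_BASES[ref]}>{_BASES[alt]}")
    return labels


def variant_profiles(config: SimulationConfig, graph: OntologyGraph
                     ) -> Dict[str, FrozenSet[str]]:
    """Per-variant phenotype profiles, each drawn from the variant's home system."""
    rng = _rng(config.seed, 3)
    labels = variant_labels(config)
    systems = system_members(graph)
    heads = sorted(systems)
    profiles: Dict[str, FrozenSet[str]] = {}
    for i, label in enumerate(labels):
        head = heads[i % len(heads)]
        pool = sorted(set(systems[head]) - {head}) or [head]
        if config.profile_size > len(pool):
            raise ValueError(
                f"profile_size {config.profile_size} exceeds the "
                f"{len(pool)} available terms of system {head}")
        chosen = rng.choice(len(pool), size=config.profile_size, replace=False)
        profiles[label] = frozenset(pool[j] for j in chosen)
    return profiles


def occupied_systems(config: SimulationConfig, graph: OntologyGraph) -> List[str]:
    heads = sorted(system_members(graph))
    return [heads[i % len(heads)] for i in range(config.n_variants)]


def _annotate(rng: np.random.Generator, graph: OntologyGraph,
              profile: FrozenSet[str], sensitivity: float,
              noise_rate: float) -> Set[str]:
    terms = {t for t in sorted(profile) if rng.random() < sensitivity}
    n_noise = int(rng.poisson(noise_rate)) if noise_rate > 0 else 0
    if n_noise:
        pool = sorted(graph.terms - profile - {graph.root})
        n_noise = min(n_noise, len(pool))
        chosen = rng.choice(len(pool), size=n_noise, replace=False)
        terms |= {pool[j] for j in chosen}
    return terms


def _heteroplasmy(rng: np.random.Generator, model: HeteroplasmyModel
                  ) -> Tuple[float, float]:
    muscle = float(np.clip(rng.normal(model.muscle_mean, model.muscle_sd),
                           0.0, 100.0))
    offset = max(0.0, float(rng.normal(model.blood_offset_mean,
                                       model.blood_offset_sd)))
    blood = float(np.clip(muscle - offset, 0.0, 100.0))
    return muscle, blood


def generate_cohort(config: SimulationConfig, graph: OntologyGraph
                    ) -> CohortTable:
    """Synthetic proband cohort with the configured statistical structure."""
    rng = _rng(config.seed, 4)
    labels = variant_labels(config)
    profiles = variant_profiles(config, graph)
    n_pubs = max(config.n_variants, config.n_publications_per_variant)
    pubs = [f"PUB{j:03d}" for j in range(n_pubs)]
    patients: List[PatientRecord] = []
    for i, label in enumerate(labels):
        variant_pubs = [pubs[(i + j) % n_pubs]
                        for j in range(config.n_publications_per_variant)]
        effects = [e for e in config.dose_response if e.variant == label]
        for j in range(config.probands_per_variant):
            pid = f"V{i:02d}_P{j:03d}"
            muscle, blood = _heteroplasmy(rng, config.heteroplasmy)
            terms = _annotate(rng, graph, profiles[label],
                              config.term_sensitivity, config.noise_rate)
            levels = {"muscle": muscle, "blood": blood}
            for e in effects:
                term = graph.resolve(e.term)
                p = float(expit(e.intercept + e.slope * levels[e.tissue]))
                if rng.random() < p:
                    terms.add(term)
                else:
                    terms.discard(term)
            patients.append(PatientRecord(
                individual_id=pid,
                proband_id=pid,
                family_id=f"FAM_{pid}",
                publication_id=variant_pubs[j % len(variant_pubs)],
                variants=(label,),
                affected="affected",
                is_proband=True,
                sex="M" if rng.random() < 0.5 else "F",
                age_at_onset=float(np.clip(rng.normal(25, 15), 0, 90)),
                hpo_terms=minimal_set(graph, terms) if terms else frozenset(),
                heteroplasmy=(
                    HeteroplasmyMeasurement("blood", blood),
                    HeteroplasmyMeasurement("muscle", muscle),
                ),
            ))
    return CohortTable(patients)


def _control_pool(config: SimulationConfig, graph: OntologyGraph,
                  profiles: Dict[str, FrozenSet[str]]) -> List[str]:
    case_terms = set().union(*profiles.values())
    systems = system_members(graph)
    occupied = set(occupied_systems(config, graph))
    free: Set[str] = set()
    for head, members in systems.items():
        if head not in occupied:
            free |= set(members)
    pool = sorted((free or (graph.terms - {graph.root})) - case_terms)
    return pool


def generate_controls(config: SimulationConfig, graph: OntologyGraph
                      ) -> List[Tuple[str, FrozenSet[str]]]:
    """Control patients with configurable profile overlap with case profiles.

    Each control profile shares ``round(profile_overlap * profile_size)``
    terms with a randomly chosen case profile; the remainder comes from
    terms outside every case profile, preferentially from systems with no
    case variant.  At overlap 0 (and no noise) control annotations never
    intersect case profiles.
    """
    rng = _rng(config.seed, 5)
    profiles = variant_profiles(config, graph)
    labels = sorted(profiles)
    pool = _control_pool(config, graph, profiles)
    n_overlap = int(round(config.controls.profile_overlap * config.profile_size))
    n_other = config.profile_size - n_overlap
    if n_other > len(pool):
        raise ValueError(
            f"control profiles need {n_other} off-case terms but only "
            f"{len(pool)} are available")
    out: List[Tuple[str, FrozenSet[str]]] = []
    for j in range(config.controls.n_controls):
        case = sorted(profiles[labels[rng.integers(len(labels))]])
        chosen = rng.choice(len(case), size=n_overlap, replace=False)
        profile = {case[x] for x in chosen}
        chosen = rng.choice(len(pool), size=n_other, replace=False)
        profile |= {pool[x] for x in chosen}
        terms = _annotate(rng, graph, frozenset(profile),
                          config.term_sensitivity, config.noise_rate)
        terms = minimal_set(graph, terms) if terms else frozenset()
        out.append((f"CTRL_{j:04d}", terms))
    return out


def generate_test_cases(config: SimulationConfig, graph: OntologyGraph,
                        n_cases: int, stream: int = 6
                        ) -> List[Tuple[str, FrozenSet[str], str]]:
    """Fresh case patients drawn from the variant profiles (held out of the
    reference cohort); returns (patient_id, terms, source variant)."""
    rng = _rng(config.seed, stream)
    profiles = variant_profiles(config, graph)
    labels = variant_labels(config)
    out: List[Tuple[str, FrozenSet[str], str]] = []
    for j in range(n_cases):
        label = labels[j % len(labels)]
        terms = _annotate(rng, graph, profiles[label],
                          config.term_sensitivity, config.noise_rate)
        terms = minimal_set(graph, terms) if terms else frozenset()
        out.append((f"CASE_{j:04d}", terms, label))
    return out


def write_controls_tsv(controls: Sequence[Tuple[str, FrozenSet[str]]],
                       path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient_id\thpo_terms\n")
        for pid, terms in controls:
            fh.write(f"{pid}\t{';'.join(sorted(terms)) or 'NA'}\n")
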