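"""Similarity-score classification of test patients against a reference cohort.

A test patient's term set is compared with each reference variant: the
per-variant score is the mean of the k best asymmetric best-match-average
similarities between the patient and the variant's phenotyped probands
(default k = 5; variants with fewer than k such probands are excluded from
scoring).  Averaging over the k most similar probands tolerates the
within-variant phenotypic heterogeneity typical of mtDNA disease.  The
patient's overall score is the maximum per-variant score.

The asymmetric direction matches the patient's terms into each proband's
terms, i.e. it rewards the patient's features being explained by a
reference proband and is robust to richly annotated references; the
opposite direction is available via ``direction="proband_to_patient"``.

Classifier performance is summarized by a bootstrap FDR-versus-sensitivity
curve on case/control score mixtures (default: samples of 200 with 10%
true cases).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .cohort import CohortTable
from .ontology import ICMap, OntologyGraph
from .similarity import asym_sim

__all__ = [
    "ClassificationScore",
    "FDRCurve",
    "score_patient",
    "score_patients",
    "fdr_sensitivity_curve",
    "read_test_patients",
    "write_scores_tsv",
]

DEFAULT_K = 5


@dataclass
class ClassificationScore:
    patient_id: str
    per_variant_score: Dict[str, float]
    best_variant: str
    score: float
    k: int

    @property
    def n_variants_scored(self) -> int:
        return len(self.per_variant_score)


@dataclass
class FDRCurve:
    sensitivities: np.ndarray
    fdr: np.ndarray         # mean FDR over bootstrap replicates
    thresholds: np.ndarray  # mean score threshold over replicates
    n_boot: int
    sample_size: int
    case_fraction: float
    seed: int

    def at(self, sensitivity: float) -> float:
        i = int(np.argmin(np.abs(self.sensitivities - sensitivity)))
        return float(self.fdr[i])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("sensitivity\tmean_threshold\tmean_fdr\n")
            for s, th, f in zip(self.sensitivities, self.thresholds, self.fdr):
                fh.write(f"{s:.10g}\t{th:.10g}\t{f:.10g}\n")


def _reference_groups(cohort: CohortTable, k: int
                      ) -> Dict[str, List[Tuple[str, FrozenSet[str]]]]:
    groups: Dict[str, List[Tuple[str, FrozenSet[str]]]] = {}
    for v in cohort.variants:
        probands = [(p.individual_id, p.hpo_terms)
                    for p in cohort.carriers(v)
                    if p.affected == "affected" and p.hpo_terms]
        if len(probands) >= k:
            groups[v] = probands
    return groups


def score_patient(patient_terms: Iterable[str], cohort: CohortTable,
                  ic: ICMap, graph: OntologyGraph, k: int = DEFAULT_K,
                  patient_id: str = "patient",
                  direction: str = "patient_to_proband") -> ClassificationScore:
    """Best-match similarity score of one patient against the reference.

    Ties at the k-th similarity are resolved by a deterministic sort on
    (similarity descending, proband id ascending).
    """
    patient_terms = frozenset(graph.resolve(t) for t in patient_terms)
    if not patient_terms:
        raise ValueError("patient term set is empty")
    if direction not in ("patient_to_proband", "proband_to_patient"):
        raise ValueError(f"unknown direction {direction!r}")
    groups = _reference_groups(cohort, k)
    if not groups:
        raise ValueError(
            f"no reference variant has >= {k} phenotyped probands; "
            f"consider a smaller k")
    per_variant: Dict[str, float] = {}
    for v, probands in groups.items():
        sims = []
        for pid, terms in probands:
            if direction == "patient_to_proband":
                s = asym_sim(ic, graph, patient_terms, terms)
            else:
                s = asym_sim(ic, graph, terms, patient_terms)
            sims.append((s, pid))
        sims.sort(key=lambda t: (-t[0], t[1]))
        per_variant[v] = float(np.mean([s for s, _ in sims[:k]]))
    best = min(per_variant, key=lambda v: (-per_variant[v], v))
    return ClassificationScore(patient_id=patient_id,
                               per_variant_score=per_variant,
                               best_variant=best,
                               score=per_variant[best], k=k)


def score_patients(patients: Mapping[str, Iterable[str]], cohort: CohortTable,
                   ic: ICMap, graph: OntologyGraph, k: int = DEFAULT_K,
                   direction: str = "patient_to_proband"
                   ) -> List[ClassificationScore]:
    return [score_patient(terms, cohort, ic, graph, k=k, patient_id=pid,
                          direction=direction)
            for pid, terms in patients.items()]


def fdr_sensitivity_curve(case_scores: Sequence[float],
                          control_scores: Sequence[float],
                          sample_size: int = 200,
                          case_fraction: float = 0.10,
                          sensitivities: Sequence[float] | None = None,
                          n_boot: int = 200,
                          seed: int = 0) -> FDRCurve:
    """Bootstrap FDR as a function of target sensitivity.

    Each replicate draws (with replacement) a mixture of
    ``sample_size * case_fraction`` case scores and the complement of
    control scores.  For a target sensitivity s the threshold is the
    replicate's empirical (1 - s) case-score quantile (lower order
    statistic, so the achieved sensitivity is at least s), and
    FDR = FP / (FP + TP) with TP = cases >= threshold,
    FP = controls >= threshold.  Reported values are means over replicates.
    """
    case_scores = np.asarray(case_scores, dtype=float)
    control_scores = np.asarray(control_scores, dtype=float)
    if case_scores.size == 0 or control_scores.size == 0:
        raise ValueError("both score lists must be non-empty")
    if sensitivities is None:
        sensitivities = np.round(np.arange(0.05, 1.0001, 0.05), 10)
    sens = np.asarray(sensitivities, dtype=float)
    if np.any(sens <= 0.0) or np.any(sens > 1.0) or np.any(np.diff(sens) <= 0):
        raise ValueError("sensitivities must be a strictly increasing grid "
                         "in (0, 1]")
    n_cases = int(round(sample_size * case_fraction))
    n_controls = sample_size - n_cases
    if n_cases < 1:
        raise ValueError("sample_size * case_fraction must be >= 1")
    rng = np.random.default_rng(seed)
    fdrs = np.zeros((n_boot, sens.size))
    thresholds = np.zeros((n_boot, sens.size))
    idx = np.floor((1.0 - sens) * n_cases).astype(int)
    idx = np.clip(idx, 0, n_cases - 1)
    for b in range(n_boot):
        cases = np.sort(rng.choice(case_scores, size=n_cases, replace=True))
        controls = rng.choice(control_scores, size=n_controls, replace=True)
        th = cases[idx]
        tp = (cases[:, None] >= th[None, :]).sum(axis=0)
        fp = (controls[:, None] >= th[None, :]).sum(axis=0)
        fdrs[b] = fp / np.maximum(1, fp + tp)
        thresholds[b] = th
    return FDRCurve(sensitivities=sens, fdr=fdrs.mean(axis=0),
                    thresholds=thresholds.mean(axis=0), n_boot=n_boot,
                    sample_size=sample_size, case_fraction=case_fraction,
                    seed=seed)


def read_test_patients(path: str | Path, graph: OntologyGraph
                       ) -> Dict[str, FrozenSet[str]]:
    """Read a test-patient TSV (columns: patient_id, hpo_terms ;-separated)."""
    out: Dict[str, FrozenSet[str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["patient_id", "hpo_terms"]:
            raise ValueError(f"unexpected test-patient header: {header}")
        for line in fh:
            pid, terms = line.rstrip("\n").split("\t")
            out[pid] = frozenset(graph.resolve(t)
                                 for t in terms.split(";") if t and t != "NA")
    return out


def write_scores_tsv(scores: Sequence[ClassificationScore], path: str | Path,
                     sidecar: str | Path | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient_id\tbest_variant\tscore\tn_variants_scored\n")
        for s in scores:
            fh.write(f"{s.patient_id}\t{s.best_variant}\t{s.score:.10g}\t"
                     f"{s.n_variants_scored}\n")
    if sidecar is not None:
        payload = {s.patient_id: s.per_variant_score for s in scores}
        with open(sidecar, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
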