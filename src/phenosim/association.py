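"""Heteroplasmy-phenotype dose-response and permutation FDR.

For a (variant, term, tissue) triple, a logistic regression models the
presence of the term in a proband's propagated annotation closure as a
function of the proband's heteroplasmy percentage in that tissue.  The
reported p-value is a likelihood-ratio test of slope = 0, which behaves
better than the Wald test at the small per-variant sample sizes typical of
literature-curated cohorts.

The family-wide false discovery rate at a p-value threshold t is the
expected number of sub-threshold p-values under the null - obtained by
permuting heteroplasmy levels among probands within each (variant, tissue)
stratum - divided by the observed number of sub-threshold p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import warnings

import numpy as np
from scipy.stats import chi2, spearmanr
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (ConvergenceWarning,
                                             PerfectSeparationError,
                                             PerfectSeparationWarning)

from .cohort import CohortTable, TISSUES
from .ontology import OntologyGraph

__all__ = [
    "AssociationResult",
    "PermutationFDR",
    "fit_term_heteroplasmy",
    "permutation_fdr",
    "permutation_pvalues",
    "blood_muscle_correlation",
    "write_association_tsv",
]

# minimum total n and per-class counts for a fit to be attempted
MIN_N = 10
MIN_PER_CLASS = 3


@dataclass
class AssociationResult:
    variant: str
    term: str
    tissue: str
    n: int
    intercept: Optional[float] = None   # log-odds at 0% heteroplasmy
    slope: Optional[float] = None       # log-odds per heteroplasmy %
    p_value: Optional[float] = None     # LRT of slope = 0; present iff ok
    status: str = "ok"                  # ok | separated | skipped_small_n


@dataclass
class PermutationFDR:
    threshold_t: float
    expected_null_discoveries: float
    observed_discoveries: int
    fdr: Optional[float]                # expected / observed; None if observed 0
    n_permutations: int
    seed: int


def _response_and_levels(cohort: CohortTable, variant: str, term: str,
                         tissue: str, graph: OntologyGraph
                         ) -> Tuple[np.ndarray, np.ndarray]:
    if tissue not in TISSUES:
        raise ValueError(f"unknown tissue {tissue!r}")
    term = graph.resolve(term)
    ys, xs = [], []
    # canonical proband order: results invariant to table row order
    for p in sorted(cohort.carriers(variant), key=lambda p: p.individual_id):
        level = p.het_level(tissue)
        if level is None:
            continue
        ys.append(1.0 if term in graph.closure(p.hpo_terms) else 0.0)
        xs.append(level)
    return np.asarray(ys), np.asarray(xs)


def _lrt_logit(y: np.ndarray, x: np.ndarray
               ) -> Tuple[Optional[float], Optional[float], Optional[float], str]:
    """Fit logit(P(y=1)) = a + b x; return (a, b, LRT p, status)."""
    n = y.size
    k = y.sum()
    if np.ptp(x) == 0.0:
        return None, None, None, "separated"
    exog = np.column_stack([np.ones(n), x])
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(y, exog).fit(disp=0, method="newton", maxiter=100)
    except (PerfectSeparationError, PerfectSeparationWarning,
            np.linalg.LinAlgError):
        return None, None, None, "separated"
    a, b = fit.params
    if (not np.all(np.isfinite(fit.params)) or abs(b) > 1e3
            or not fit.mle_retvals.get("converged", True)):
        return None, None, None, "separated"
    # intercept-only log-likelihood in closed form
    p0 = k / n
    ll0 = k * np.log(p0) + (n - k) * np.log1p(-p0)
    stat = max(0.0, 2.0 * (fit.llf - ll0))
    return float(a), float(b), float(chi2.sf(stat, df=1)), "ok"


def fit_term_heteroplasmy(cohort: CohortTable, variant: str, term: str,
                          tissue: str, graph: OntologyGraph,
                          min_n: int = MIN_N,
                          min_per_class: int = MIN_PER_CLASS
                          ) -> AssociationResult:
    """Logistic regression of term presence on heteroplasmy level.

    Probands carrying the variant with a measurement in the tissue enter
    the fit; presence is evaluated on the propagated (true-path) closure.
    Fits with fewer than *min_n* probands or fewer than *min_per_class*
    cases or non-cases are skipped; complete separation and degenerate
    predictors are flagged, with no p-value reported.
    """
    y, x = _response_and_levels(cohort, variant, term, tissue, graph)
    n = int(y.size)
    res = AssociationResult(variant=variant, term=graph.resolve(term),
                            tissue=tissue, n=n)
    if n < min_n or y.sum() < min_per_class or (n - y.sum()) < min_per_class:
        res.status = "skipped_small_n"
        return res
    a, b, p, status = _lrt_logit(y, x)
    res.intercept, res.slope, res.p_value, res.status = a, b, p, status
    return res


def eligible_tests(cohort: CohortTable, graph: OntologyGraph,
                   candidates: Sequence[Tuple[str, str, str]],
                   min_n: int = MIN_N,
                   min_per_class: int = MIN_PER_CLASS
                   ) -> List[Tuple[str, str, str]]:
    """Filter (variant, term, tissue) triples to those meeting the size rule."""
    keep = []
    for variant, term, tissue in candidates:
        y, _ = _response_and_levels(cohort, variant, term, tissue, graph)
        if (y.size >= min_n and y.sum() >= min_per_class
                and y.size - y.sum() >= min_per_class):
            keep.append((variant, term, tissue))
    return keep


def permutation_fdr(cohort: CohortTable, graph: OntologyGraph,
                    tests: Sequence[Tuple[str, str, str]],
                    t: float = 0.05, n_perm: int = 100,
                    seed: int = 0) -> PermutationFDR:
    """Permutation estimate of the FDR at p-value threshold *t*.

    Heteroplasmy levels are shuffled among probands within each
    (variant, tissue) stratum; all tests are refitted per permutation and
    sub-threshold p-values counted.  FDR = mean null count / observed
    count; undefined (None) when nothing is observed below *t*.
    Invariant to the ordering of tests and patients, and reproducible
    from *seed*.
    """
    observed_p, null_p = permutation_pvalues(cohort, graph, tests,
                                             n_perm=n_perm, seed=seed)
    observed = int(np.sum(observed_p < t))
    expected = float(np.mean([np.sum(p < t) for p in null_p]))
    return PermutationFDR(
        threshold_t=t,
        expected_null_discoveries=expected,
        observed_discoveries=observed,
        fdr=(expected / observed) if observed > 0 else None,
        n_permutations=n_perm,
        seed=seed,
    )


def permutation_pvalues(cohort: CohortTable, graph: OntologyGraph,
                        tests: Sequence[Tuple[str, str, str]],
                        n_perm: int = 100, seed: int = 0
                        ) -> Tuple[np.ndarray, List[np.ndarray]]:
    """Observed and within-stratum-permuted p-values for a family of tests.

    Returns the observed p-value array (fits that are skipped or separated
    yield p = 1, so they never count as discoveries) and one array per
    permutation.  Shared backend of :func:`permutation_fdr`; useful when
    the FDR is wanted at several thresholds without refitting.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    # group tests by (variant, tissue) stratum so one shuffle of the
    # heteroplasmy levels serves every term tested in the stratum
    strata: Dict[Tuple[str, str], Dict[str, np.ndarray]] = {}
    xs: Dict[Tuple[str, str], np.ndarray] = {}
    for variant, term, tissue in tests:
        y, x = _response_and_levels(cohort, variant, term, tissue, graph)
        key = (variant, tissue)
        strata.setdefault(key, {})[graph.resolve(term)] = y
        xs[key] = x
    ordered = sorted(strata)

    def pvalues(level_map: Dict[Tuple[str, str], np.ndarray]) -> np.ndarray:
        out = []
        for key in ordered:
            x = level_map[key]
            for term in sorted(strata[key]):
                _, _, p, status = _lrt_logit(strata[key][term], x)
                out.append(p if status == "ok" else 1.0)
        return np.asarray(out)

    observed_p = pvalues(xs)
    rng = np.random.default_rng(seed)
    null_p = []
    for _ in range(n_perm):
        permuted = {key: xs[key][rng.permutation(xs[key].size)]
                    for key in ordered}
        null_p.append(pvalues(permuted))
    return observed_p, null_p


def blood_muscle_correlation(cohort: CohortTable, variant: str
                             ) -> Tuple[Optional[float], int]:
    """Spearman rank correlation between blood and muscle heteroplasmy.

    Computed over the variant's probands with measurements in both
    tissues; returns ``(None, n)`` when fewer than three are available.
    """
    pairs = [(p.het_level("blood"), p.het_level("muscle"))
             for p in cohort.carriers(variant)]
    pairs = [(b, m) for b, m in pairs if b is not None and m is not None]
    n = len(pairs)
    if n < 3:
        return None, n
    blood, muscle = zip(*pairs)
    rho = spearmanr(blood, muscle).statistic
    return float(rho), n


def write_association_tsv(results: Sequence[AssociationResult],
                          path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("variant\tterm\ttissue\tn\tintercept\tslope\tp_value\tstatus\n")
        for r in results:
            fmt = lambda v: "NA" if v is None else f"{v:.10g}"
            fh.write(f"{r.variant}\t{r.term}\t{r.tissue}\t{r.n}\t"
                     f"{fmt(r.intercept)}\t{fmt(r.slope)}\t{fmt(r.p_value)}\t"
                     f"{r.status}\n")
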