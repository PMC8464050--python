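"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: closures are computed
by naive fixed-point iteration, Lin similarity by explicit ancestor-set
intersection and an argmax over IC, Fisher p-values by exact enumeration
of all tables with the observed margins, and logistic likelihood-ratio
p-values by generic numerical optimization of a hand-written likelihood.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Dict, FrozenSet, Set

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from phenosim.ontology import ICMap, OntologyGraph


def naive_closure(parents: Dict[str, FrozenSet[str]], term: str) -> Set[str]:
    """Inclusive ancestor closure by fixed-point iteration over the edge list."""
    closure = {term}
    changed = True
    while changed:
        changed = False
        for t in list(closure):
            for p in parents[t]:
                if p not in closure:
                    closure.add(p)
                    changed = True
    return closure


def random_entangled_dag(rng: np.random.Generator, n_terms: int
                         ) -> OntologyGraph:
    """Random single-rooted DAG with unrestricted cross-branch parents."""
    ids = [f"T:{i:04d}" for i in range(n_terms)]
    names = {t: f"term {t}" for t in ids}
    parents = {ids[0]: frozenset()}
    for i in range(1, n_terms):
        k = min(int(rng.integers(1, 4)), i)
        chosen = rng.choice(i, size=k, replace=False)
        parents[ids[i]] = frozenset(ids[j] for j in chosen)
    return OntologyGraph(names=names, parents=parents)


def brute_mica_ic(graph: OntologyGraph, ic: ICMap, t1: str, t2: str) -> float:
    common = (naive_closure(graph.parents, t1)
              & naive_closure(graph.parents, t2))
    return max(ic.ic[t] for t in common)


def brute_lin(graph: OntologyGraph, ic: ICMap, t1: str, t2: str) -> float:
    denom = ic.ic[t1] + ic.ic[t2]
    if denom <= 0:
        return 1.0 if t1 == t2 else 0.0
    return 2.0 * brute_mica_ic(graph, ic, t1, t2) / denom


def fisher_upper_tail_exact(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) by exact enumeration over tables with the same margins."""
    n1, k, m = a + b, a + c, a + b + c + d
    total = Fraction(0)
    for j in range(a, min(n1, k) + 1):
        if k - j > m - n1:
            continue
        total += Fraction(math.comb(n1, j) * math.comb(m - n1, k - j),
                          math.comb(m, k))
    return float(total)


def _nll(params: np.ndarray, y: np.ndarray, x: np.ndarray) -> float:
    eta = params[0] + params[1] * x
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


def lrt_pvalue_by_optimizer(y: np.ndarray, x: np.ndarray) -> float:
    """LRT p-value of slope = 0 from generic numerical optimization."""
    full = minimize(_nll, x0=np.zeros(2), args=(y, x), method="BFGS",
                    options={"gtol": 1e-10, "maxiter": 500})
    p0 = y.mean()
    ll0 = -(y.sum() * math.log(p0) + (y.size - y.sum()) * math.log1p(-p0))
    stat = max(0.0, 2.0 * (ll0 - full.fun))
    return float(chi2.sf(stat, df=1))
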