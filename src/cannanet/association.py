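"""Likelihood-ratio association testing and relationship direction classes.

Candidate pairs are scored with the Dunning log-likelihood ratio for
collocations: compare binomial likelihoods of entity ``a`` occurring at the
same rate in paragraphs with and without entity ``g`` (null) versus separate
rates (alternative).  Under independence the statistic is asymptotically
chi-square with 1 degree of freedom, which supplies the significance cutoff.

Direction classes operationalize "p(a) ≈ p(a,g)" — nearly every paragraph
containing *a* also contains *g* — as a conditional-probability ratio
threshold ``tau``: with r_a = k11/c(a) and r_g = k11/c(g), both ratios above
``tau`` is *bidirectional*, exactly one gives the corresponding unidirectional
class, neither gives *undirected*.  The graph itself stays undirected; the
class is carried as an edge attribute only.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import xlogy
from scipy.stats import chi2

from .cooccurrence import (
    ContingencyTable,
    CooccurrenceCounts,
    Entity,
    contingency,
    relation_for,
)

__all__ = [
    "AssociationResult",
    "llr_score",
    "llr_from_cells",
    "chi2_critical",
    "is_significant",
    "direction",
    "decide_edges",
]

DIRECTIONS = ("bidirectional", "a_to_g", "g_to_a", "undirected")


def llr_from_cells(k11, k12, k21, k22):
    """Vectorized Dunning log-likelihood ratio from 2x2 cell counts.

    With n1 = k11+k21 (paragraphs containing g), n2 = k12+k22, x1 = k11,
    x2 = k12, the statistic is twice the log-likelihood difference between
    separate binomial rates p1 = x1/n1, p2 = x2/n2 and the pooled rate
    p = (x1+x2)/(n1+n2), under the convention 0·ln 0 = 0.  Clamped at 0
    against rounding.
    """
    k11 = np.asarray(k11, dtype=float)
    k12 = np.asarray(k12, dtype=float)
    k21 = np.asarray(k21, dtype=float)
    k22 = np.asarray(k22, dtype=float)
    x1, x2 = k11, k12
    n1, n2 = k11 + k21, k12 + k22
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise ValueError("LLR undefined: a marginal of the contingency table is zero")
    p1 = x1 / n1
    p2 = x2 / n2
    p = (x1 + x2) / (n1 + n2)

    def ll(x, n, q):
        return xlogy(x, q) + xlogy(n - x, 1.0 - q)

    stat = 2.0 * (ll(x1, n1, p1) + ll(x2, n2, p2) - ll(x1, n1, p) - ll(x2, n2, p))
    # clamp rounding noise so exact-independence tables score exactly 0
    return np.where(stat < 1e-12, 0.0, stat)


def llr_score(t: ContingencyTable) -> float:
    """Dunning LLR of one contingency table; exactly 0 under independence."""
    if t.c_a < 1 or t.c_g < 1:
        raise ValueError("LLR undefined: both entities need at least one occurrence")
    return float(llr_from_cells(t.k11, t.k12, t.k21, t.k22))


@lru_cache(maxsize=64)
def chi2_critical(alpha: float) -> float:
    """Chi-square (df=1) critical value at significance level alpha."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return float(chi2.ppf(1.0 - alpha, df=1))


def is_significant(llr: float, alpha: float = 0.05) -> bool:
    """True iff the LLR reaches the chi-square(1) critical value at alpha."""
    return llr >= chi2_critical(alpha)


def direction(t: ContingencyTable, tau: float = 0.8) -> str:
    """Classify relationship direction from conditional co-occurrence ratios."""
    if not (0.0 < tau <= 1.0):
        raise ValueError("tau must lie in (0, 1]")
    if t.c_a < 1 or t.c_g < 1:
        raise ValueError("direction undefined: both entities need at least one occurrence")
    r_a = t.k11 / t.c_a
    r_g = t.k11 / t.c_g
    if r_a >= tau and r_g >= tau:
        return "bidirectional"
    if r_a >= tau:
        return "a_to_g"
    if r_g >= tau:
        return "g_to_a"
    return "undirected"


@dataclass(frozen=True)
class AssociationResult:
    """Scored candidate edge for one admissible entity pair."""

    entity_a: Entity
    entity_g: Entity
    relation: str
    table: ContingencyTable
    llr: float
    significant: bool
    alpha: float
    direction: str
    tau: float
    weight: int

    @property
    def pair(self) -> tuple[Entity, Entity]:
        return (self.entity_a, self.entity_g)


def decide_edges(
    counts: CooccurrenceCounts,
    alpha: float = 0.05,
    tau: float = 0.8,
    min_pair_count: int = 1,
    bonferroni: bool = False,
) -> list[AssociationResult]:
    """Score every admissible pair with pair_occ >= min_pair_count.

    Pairs below ``min_pair_count`` are excluded entirely.  With
    ``bonferroni`` the significance level is divided by the number of
    scored pairs (off by default: no multiple-testing correction).
    Whether non-significant pairs become edges is the graph builder's
    mode decision; here every scored pair gets a result.
    """
    chi2_critical(alpha)  # validate alpha eagerly
    scored = [
        key for key in counts.pairs() if counts.pair_occ[key] >= min_pair_count
    ]
    eff_alpha = alpha / len(scored) if (bonferroni and scored) else alpha
    results: list[AssociationResult] = []
    for e1, e2 in scored:
        t = contingency(counts, e1, e2)
        llr = llr_score(t)
        rel = relation_for(e1[1], e2[1])
        assert rel is not None  # guaranteed by accumulate's admissibility rule
        results.append(
            AssociationResult(
                entity_a=e1,
                entity_g=e2,
                relation=rel,
                table=t,
                llr=llr,
                significant=is_significant(llr, eff_alpha),
                alpha=eff_alpha,
                direction=direction(t, tau),
                tau=tau,
                weight=counts.pair_weight[(e1, e2)],
            )
        )
    return results


def write_association_report(results, path) -> None:
    """TSV report: one scored pair per row with cells, LLR, flags, weight."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            [
                "entity_a", "etype_a", "entity_g", "etype_g", "relation",
                "k11", "k12", "k21", "k22", "llr", "significant", "direction", "weight",
            ]
        )
        for r in results:
            w.writerow(
                [
                    r.entity_a[0], r.entity_a[1], r.entity_g[0], r.entity_g[1], r.relation,
                    r.table.k11, r.table.k12, r.table.k21, r.table.k22,
                    f"{r.llr:.6g}", int(r.significant), r.direction, r.weight,
                ]
            )
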