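"""Over-representation analysis (ORA) of switching-gene sets.

A query gene set (genes with at least one filtered isoform switch) is
tested against each annotated gene set with the hypergeometric upper
tail, Benjamini-Hochberg corrected across tested sets. Defaults follow
the pathway-enrichment settings of the analysis this package implements:
p <= 0.05, q (BH-adjusted) <= 0.2 (0.5 in disease-ontology mode), top 10
terms reported. The universe defaults to the union of all collection
members and is overridable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from math import comb
from typing import Iterable, Mapping, Sequence

from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection
from .switch_detection import SwitchEvent

__all__ = [
    "OraResult",
    "genes_with_switches",
    "intersect_gene_sets",
    "hypergeom_upper",
    "bh_adjust",
    "run_ora",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OraResult:
    set_id: str
    description: str
    k: int      # overlap of query and set
    K: int      # set size (within universe)
    n: int      # query size (within universe)
    N: int      # universe size
    p: float
    p_adj: float

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("overlap exceeds set or query size")


def genes_with_switches(events: Iterable[SwitchEvent]) -> set[str]:
    """Unique genes over switch events (a gene with several switching
    isoform pairs counts once)."""
    return {e.gene_id for e in events}


def intersect_gene_sets(
    named_sets: Mapping[str, Iterable[str]]
) -> dict[tuple[str, ...], set[str]]:
    """Venn partition of >= 2 named gene sets.

    Returns every non-trivial region keyed by the sorted tuple of set
    names containing it (members exclusive to that region); region sizes
    sum to the union size.
    """
    sets = {name: set(members) for name, members in named_sets.items()}
    if len(sets) < 2:
        raise ValueError("need at least 2 sets to intersect")
    names = sorted(sets)
    regions: dict[tuple[str, ...], set[str]] = {}
    for mask in product((False, True), repeat=len(names)):
        inside = tuple(n for n, bit in zip(names, mask) if bit)
        if not inside:
            continue
        members = set.intersection(*(sets[n] for n in inside))
        for n in names:
            if n not in inside:
                members = members - sets[n]
        regions[inside] = members
    return regions


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) for a draw of n
    from a universe of N containing K marked items, by exact integer
    summation."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    numerator = sum(comb(K, i) * comb(N - K, n - i)
                    for i in range(k, min(K, n) + 1))
    return numerator / comb(N, n)


def bh_adjust(pvalues: Sequence[float], method: str = "fdr_bh") -> list[float]:
    """Benjamini-Hochberg step-up adjustment (input order preserved,
    monotone, capped at 1). ``method='bonferroni'`` gives the family-wise
    alternative."""
    ps = list(pvalues)
    if any(p < 0 or p > 1 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    if not ps:
        return []
    return list(multipletests(ps, method=method)[1])


def run_ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    p_max: float = 0.05,
    q_max: float = 0.2,
    top: int = 10,
    universe: Iterable[str] | None = None,
    adjust_method: str = "fdr_bh",
) -> list[OraResult]:
    """Hypergeometric over-representation of a query gene set against a
    GMT collection.

    Only sets overlapping the query are tested (and enter the BH
    denominator); results passing both the raw-p and adjusted-q cutoffs
    are ranked by adjusted then raw p, at most ``top`` returned. Query
    genes outside the universe are dropped with a logged count. For
    disease-ontology-style collections pass ``q_max=0.5``.
    """
    uni = set(universe) if universe is not None else set(collection.default_universe())
    if not uni:
        raise ValueError("empty universe")
    query_set = set(query)
    dropped = query_set - uni
    if dropped:
        logger.warning("dropping %d query genes outside the universe", len(dropped))
    query_set &= uni
    n, N = len(query_set), len(uni)

    tested: list[OraResult] = []
    for s in collection.sets:
        members = set(s.members) & uni
        k = len(query_set & members)
        if k < 1:
            continue
        p = hypergeom_upper(k, len(members), n, N)
        tested.append(OraResult(s.set_id, s.description, k, len(members),
                                n, N, p, p_adj=1.0))
    if not tested:
        return []
    adjusted = bh_adjust([r.p for r in tested], method=adjust_method)
    tested = [
        OraResult(r.set_id, r.description, r.k, r.K, r.n, r.N, r.p, float(q))
        for r, q in zip(tested, adjusted)
    ]
    passing = [r for r in tested if r.p <= p_max and r.p_adj <= q_max]
    passing.sort(key=lambda r: (r.p_adj, r.p, r.set_id))
    return passing[:top]
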