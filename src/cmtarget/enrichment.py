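"""Over-representation analysis of target sets against gene-set collections.

Each gene set is tested with the hypergeometric upper tail: drawing the
query's m genes from a universe of N that contains K set members, the
p-value is P(X >= k) for the observed overlap k.  Benjamini–Hochberg
adjustment controls the FDR across the tested sets, and significant pathways
can be annotated with which of their overlapping members are direct versus
indirect targets of the compound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_FDR_THRESHOLD = 0.05
DEFAULT_MIN_SET_SIZE = 5
DEFAULT_MAX_SET_SIZE = 2000


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe they are drawn from."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = {g for members in self.sets.values() for g in members}
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name} is empty")


@dataclass
class EnrichmentResult:
    """ORA outcome for one gene set."""

    pathway_id: str
    description: str
    k: int  # overlap
    m: int  # query size (within universe)
    K: int  # set size (within universe)
    N: int  # universe size
    p: float
    fdr: float
    members: list[str] = field(default_factory=list)
    direct_members: list[str] = field(default_factory=list)
    indirect_members: list[str] = field(default_factory=list)


def hypergeom_p(N: int, K: int, m: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Drawing m items without replacement from N of which K are successes.
    """
    if not (0 <= k <= min(m, K) <= N) or m > N or K > N:
        raise ValueError("inconsistent hypergeometric counts")
    return float(hypergeom.sf(k - 1, N, K, m))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(
    query: set[str],
    collection: GeneSetCollection,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    max_set_size: int = DEFAULT_MAX_SET_SIZE,
) -> list[EnrichmentResult]:
    """Hypergeometric ORA of a query set against every eligible gene set.

    Query genes outside the universe are dropped (logged); gene sets are
    filtered to the universe and skipped when their effective size falls
    outside [min_set_size, max_set_size].  FDR is adjusted across all tested
    sets; only sets with overlap k >= 1 are returned, sorted by p ascending.
    ``fdr_threshold`` is carried as the conventional reporting cutoff; no
    rows are removed by it.
    """
    universe = collection.universe
    q = query & universe
    dropped = len(query) - len(q)
    if dropped:
        logger.info("dropped %d query genes absent from the universe", dropped)
    if not q:
        raise ValueError("query has no overlap with the universe")
    N, m = len(universe), len(q)
    tested: list[tuple[str, list[str], float]] = []
    for name, members in collection.sets.items():
        eff = [g for g in members if g in universe]
        if not (min_set_size <= len(eff) <= max_set_size):
            continue
        overlap = sorted(q.intersection(eff))
        p = hypergeom_p(N, len(eff), m, len(overlap))
        tested.append((name, overlap, p))
    if not tested:
        return []
    fdrs = bh_fdr([t[2] for t in tested])
    results = []
    for (name, overlap, p), q_fdr in zip(tested, fdrs):
        if len(overlap) < 1:
            continue
        eff_K = len([g for g in collection.sets[name] if g in universe])
        results.append(
            EnrichmentResult(
                pathway_id=name,
                description=collection.descriptions.get(name, ""),
                k=len(overlap),
                m=m,
                K=eff_K,
                N=N,
                p=p,
                fdr=float(q_fdr),
                members=overlap,
            )
        )
    results.sort(key=lambda r: (r.p, r.pathway_id))
    return results


def annotate_pathway(
    result: EnrichmentResult, direct: set[str], indirect: set[str]
) -> EnrichmentResult:
    """Split a pathway's overlapping members into direct/indirect targets.

    Members in neither set stay unlabeled; the test statistics are untouched.
    """
    return replace(
        result,
        direct_members=[g for g in result.members if g in direct],
        indirect_members=[g for g in result.members if g in indirect],
    )
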