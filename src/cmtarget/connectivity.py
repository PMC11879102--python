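"""Connectivity scoring of ranked queries against target gene signatures.

The statistic follows the connectivity-map family: for a query gene list L
ranked descending by a differential metric and a target signature (t_up,
t_down), two Kolmogorov–Smirnov-style running-sum enrichment scores ES_up and
ES_down are combined into an effect target score

    ETS = (ES_up − ES_down) / 2,

set to zero when ES_up and ES_down share a sign (a coherent signature must
enrich its up and down sets at opposite ends of the list).  Significance is
assessed by permuting the query's gene labels: the nominal p-value uses only
the same-sign portion of the permutation null, ETS is normalized by the mean
of that portion to give a size-comparable NETS, and the false discovery rate
for each NETS is the ratio A/B of its exceedance frequency in the pooled null
(all signatures x all permutations) to its exceedance frequency among the
actual scores.

The running sum is unweighted (rank-only) by default — each hit adds 1/|hits|
and each miss subtracts 1/(G − |hits|) — with an optional metric-weighted
variant behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .signatures import TargetGeneSignature

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000

#: warn when fewer than this fraction of a signature side is found in the query
LOW_COVERAGE_FRACTION = 0.5


@dataclass
class RankedQuery:
    """A gene list ordered descending by a per-gene differential metric."""

    label: str
    gene_ids: list[str]
    metrics: np.ndarray

    def __post_init__(self) -> None:
        self.metrics = np.asarray(self.metrics, dtype=float)
        if len(self.gene_ids) != len(self.metrics):
            raise ValueError("gene_ids and metrics length mismatch")
        if len(self.gene_ids) < 2:
            raise ValueError("query needs at least 2 genes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate genes in query")
        if np.any(np.diff(self.metrics) > 0):
            raise ValueError("metrics must be non-increasing; use from_values()")
        self._pos = {g: i for i, g in enumerate(self.gene_ids)}

    @classmethod
    def from_values(
        cls, label: str, gene_ids: Sequence[str], values: Sequence[float]
    ) -> "RankedQuery":
        """Build a query from unordered values, sorting descending (stable)."""
        values = np.asarray(values, dtype=float)
        order = np.argsort(-values, kind="stable")
        return cls(label, [gene_ids[i] for i in order], values[order])

    def positions(self, genes: Sequence[str]) -> np.ndarray:
        """Sorted 0-based ranks of the given genes that occur in the query."""
        pos = [self._pos[g] for g in genes if g in self._pos]
        return np.sort(np.asarray(pos, dtype=np.int64))

    def negated(self) -> "RankedQuery":
        """The sign-flipped (reversal) query."""
        return RankedQuery(
            f"{self.label}-negated", list(self.gene_ids[::-1]), -self.metrics[::-1]
        )


@dataclass
class ConnectivityResult:
    """Scores for one (query, target-signature) pair."""

    target_id: str
    ets: float
    p: float
    nets: float
    fdr: float
    n_genes_matched_up: int
    n_genes_matched_down: int


def _es_from_positions(pos: np.ndarray, n_total: int) -> float:
    """Running-sum enrichment score from sorted hit ranks.

    The sum starts at 0, gains 1/h at each of the h hits and loses
    1/(G−h) at each miss, ending at 0; the score is the signed extremum of
    largest magnitude.  Maxima occur immediately after a hit and minima
    immediately before one, so only 2h prefix values need inspection.
    """
    h = len(pos)
    if h == 0:
        return 0.0
    if h == n_total:
        return 1.0
    miss_w = 1.0 / (n_total - h)
    i = np.arange(1, h + 1, dtype=float)
    misses_before = pos - (i - 1)  # misses preceding each hit
    after = i / h - misses_before * miss_w
    before = (i - 1) / h - misses_before * miss_w
    return _pick_extremum(float(after.max()), float(before.min()))


def _pick_extremum(es_pos: float, es_neg: float) -> float:
    """Signed extremum of larger magnitude; exact ties resolve positive.

    The tolerance absorbs float rounding so that symmetric hit patterns
    (where the two extrema are equal in exact arithmetic) compare as ties.
    """
    if es_pos >= -es_neg - 1e-12:
        return es_pos
    return es_neg


def _es_weighted(pos: np.ndarray, n_total: int, metrics: np.ndarray) -> float:
    """Metric-weighted (exponent 1) running-sum variant."""
    h = len(pos)
    if h == 0:
        return 0.0
    w = np.abs(metrics[pos])
    if w.sum() == 0:
        w = np.ones(h)
    hit_steps = w / w.sum()
    if h == n_total:
        return 1.0
    miss_w = 1.0 / (n_total - h)
    i = np.arange(1, h + 1, dtype=float)
    misses_before = pos - (i - 1)
    cum_hits = np.cumsum(hit_steps)
    after = cum_hits - misses_before * miss_w
    before = cum_hits - hit_steps - misses_before * miss_w
    return _pick_extremum(float(after.max()), float(before.min()))


def enrichment_score(
    L: RankedQuery, S: Sequence[str], weighted: bool = False
) -> float:
    """KS-style enrichment of gene set S along the ranked list L in [−1, 1].

    Returns 0 (with a logged warning) when S and L do not overlap.
    """
    pos = L.positions(S)
    if len(pos) == 0:
        logger.warning("gene set has no overlap with query %s; ES set to 0", L.label)
        return 0.0
    if weighted:
        return _es_weighted(pos, len(L.gene_ids), L.metrics)
    return _es_from_positions(pos, len(L.gene_ids))


def _combine(es_up: float, es_down: float) -> float:
    """The zero rule: a same-sign (ES_up, ES_down) pair scores 0."""
    if (es_up > 0 and es_down > 0) or (es_up < 0 and es_down < 0):
        return 0.0
    return (es_up - es_down) / 2.0


def ets(L: RankedQuery, sig: TargetGeneSignature, weighted: bool = False) -> float:
    """Effect target score of signature ``sig`` for query ``L``, in [−1, 1].

    A side with no genes in the query contributes ES = 0 (logged as
    low-coverage); the zero rule applies when both one-sided scores are
    strictly positive or strictly negative.
    """
    up_pos = L.positions(sig.t_up)
    dn_pos = L.positions(sig.t_down)
    _coverage_check(L, sig, len(up_pos), len(dn_pos))
    G = len(L.gene_ids)
    if weighted:
        es_up = _es_weighted(up_pos, G, L.metrics) if len(up_pos) else 0.0
        es_dn = _es_weighted(dn_pos, G, L.metrics) if len(dn_pos) else 0.0
    else:
        es_up = _es_from_positions(up_pos, G)
        es_dn = _es_from_positions(dn_pos, G)
    return _combine(es_up, es_dn)


def _coverage_check(
    L: RankedQuery, sig: TargetGeneSignature, n_up: int, n_dn: int
) -> None:
    for side, matched in (("up", n_up), ("down", n_dn)):
        if matched < LOW_COVERAGE_FRACTION * sig.n:
            logger.warning(
                "target %s: %s-side coverage %d/%d in query %s",
                sig.target_id, side, matched, sig.n, L.label,
            )


def permutation_null(
    L: RankedQuery,
    sig: TargetGeneSignature,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null ETS distribution from random permutations of the query's genes.

    Permuting gene labels of L is equivalent to placing the signature's
    matched genes at uniformly random distinct ranks, which is how the null
    is drawn here (the up and down sides never collide since their genes are
    distinct).  Passing a Generator lets a caller share one permutation
    stream across targets for single-seed reproducibility.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h_up = len(L.positions(sig.t_up))
    h_dn = len(L.positions(sig.t_down))
    G = len(L.gene_ids)
    null = np.empty(n_perm)
    if h_up + h_dn == 0:
        null.fill(0.0)
        return null
    for k in range(n_perm):
        # shuffle=True so the split into up/down positions is itself random
        pos = rng.choice(G, size=h_up + h_dn, replace=False, shuffle=True)
        es_up = _es_from_positions(np.sort(pos[:h_up]), G) if h_up else 0.0
        es_dn = _es_from_positions(np.sort(pos[h_up:]), G) if h_dn else 0.0
        null[k] = _combine(es_up, es_dn)
    return null


def p_value(actual: float, null: Sequence[float]) -> float:
    """Sign-split permutation p-value in (0, 1].

    Compares the actual score only against the strictly same-sign portion of
    the null (zero null scores carry no direction, from the zero rule, and
    belong to neither portion); floored at 1/(same-sign count) so finite
    permutations never yield p = 0.  An actual score of 0 — or an empty
    same-sign portion — gets the conventional p = 1.  Restricting to the
    strict portions keeps p uniform under a random query for every target
    with a nonzero score.
    """
    null = np.asarray(null, dtype=float)
    if len(null) == 0:
        raise ValueError("empty null distribution")
    if actual == 0:
        return 1.0
    if actual > 0:
        denom = int(np.sum(null > 0))
        num = int(np.sum(null >= actual))
    else:
        denom = int(np.sum(null < 0))
        num = int(np.sum(null < actual))
    if denom == 0:
        return 1.0
    return max(num, 1) / denom


def nets(actual: float, null: Sequence[float]) -> float:
    """ETS normalized by the same-sign null mean, preserving sign.

    NETS = actual / |mean(same-sign nulls)|; 0 when the actual score is 0 or
    the same-sign portion is empty/degenerate.  Normalization makes scores
    comparable across signature sizes and queries.
    """
    null = np.asarray(null, dtype=float)
    if len(null) == 0:
        raise ValueError("empty null distribution")
    if actual == 0:
        return 0.0
    portion = null[null > 0] if actual > 0 else null[null < 0]
    if len(portion) == 0:
        logger.warning("no same-sign null values; NETS set to 0")
        return 0.0
    denom = abs(float(portion.mean()))
    if denom == 0:
        logger.warning("same-sign null mean is 0; NETS set to 0")
        return 0.0
    return actual / denom


def _null_to_nets(null: np.ndarray) -> np.ndarray:
    """Normalize a null ETS sample by its own sign-portion means."""
    out = np.zeros_like(null)
    pos = null > 0
    neg = null < 0
    if pos.any():
        out[pos] = null[pos] / null[pos].mean()
    if neg.any():
        out[neg] = null[neg] / abs(null[neg].mean())
    return out


@dataclass
class NullStore:
    """Pooled permutation-null and actual NETS values for one query run."""

    null_ets: dict[str, np.ndarray]
    actual_nets: np.ndarray = field(default=None)  # type: ignore[assignment]
    pooled_null_nets: np.ndarray = field(default=None)  # type: ignore[assignment]

    @classmethod
    def from_run(
        cls, null_ets: dict[str, np.ndarray], actual_nets: Sequence[float]
    ) -> "NullStore":
        pooled = (
            np.concatenate([_null_to_nets(v) for v in null_ets.values()])
            if null_ets
            else np.array([])
        )
        return cls(
            null_ets=null_ets,
            actual_nets=np.sort(np.asarray(actual_nets, dtype=float)),
            pooled_null_nets=np.sort(pooled),
        )


def _count_ge(sorted_arr: np.ndarray, x: float) -> int:
    return len(sorted_arr) - int(np.searchsorted(sorted_arr, x, side="left"))


def _count_le(sorted_arr: np.ndarray, x: float) -> int:
    return int(np.searchsorted(sorted_arr, x, side="right"))


def _raw_fdr(store: NullStore, nets_i: float) -> float:
    """A/B tail-frequency ratio at one threshold, clipped to [0, 1]."""
    null, actual = store.pooled_null_nets, store.actual_nets
    if nets_i > 0:
        a_den = _count_ge(null, 0.0)
        a_num = _count_ge(null, nets_i)
        b_den = _count_ge(actual, 0.0)
        b_num = _count_ge(actual, nets_i)
    else:
        a_den = _count_le(null, 0.0)
        a_num = _count_le(null, nets_i)
        b_den = _count_le(actual, 0.0)
        b_num = _count_le(actual, nets_i)
    if a_den == 0 or b_den == 0 or b_num == 0:
        return 1.0
    return min((a_num / a_den) / (b_num / b_den), 1.0)


def fdr(store: NullStore, nets_i: float) -> float:
    """Pooled-null false discovery rate for one NETS value, in [0, 1].

    The raw estimate at threshold t is A/B, where A is the tail frequency of
    t in the pooled null NETS (all signatures x all permutations) and B its
    tail frequency among the actual NETS, each within the matching sign.
    The reported value is the q-value-style minimum of A/B over all same-sign
    thresholds of magnitude up to |nets_i| (every such threshold calls this
    score), which makes FDR non-increasing in |NETS|.  A NETS of exactly 0
    carries no direction and gets FDR 1 by convention.
    """
    if len(store.pooled_null_nets) == 0 or len(store.actual_nets) == 0:
        raise ValueError("empty null store")
    if nets_i == 0:
        logger.warning("NETS of 0 has no direction; FDR set to 1")
        return 1.0
    actual = store.actual_nets
    if nets_i > 0:
        thresholds = actual[(actual > 0) & (actual <= nets_i)]
    else:
        thresholds = actual[(actual < 0) & (actual >= nets_i)]
    best = _raw_fdr(store, nets_i)
    for t in thresholds:
        best = min(best, _raw_fdr(store, float(t)))
    return best


def score_query(
    L: RankedQuery,
    library: Sequence[TargetGeneSignature],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    weighted: bool = False,
) -> list[ConnectivityResult]:
    """Score a query against a signature library: ETS, p, NETS, pooled FDR.

    One permutation stream (from ``seed``) is shared across targets, advanced
    per target, so a single seed reproduces the whole result table.  Results
    are sorted by NETS descending (ties by target id).
    """
    if len(library) == 0:
        raise ValueError("empty signature library")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    null_by_target: dict[str, np.ndarray] = {}
    any_overlap = False
    for sig in library:
        up_pos = L.positions(sig.t_up)
        dn_pos = L.positions(sig.t_down)
        G = len(L.gene_ids)
        es_up = _es_from_positions(up_pos, G) if not weighted else (
            _es_weighted(up_pos, G, L.metrics) if len(up_pos) else 0.0
        )
        es_dn = _es_from_positions(dn_pos, G) if not weighted else (
            _es_weighted(dn_pos, G, L.metrics) if len(dn_pos) else 0.0
        )
        if len(up_pos) + len(dn_pos) > 0:
            any_overlap = True
        actual = _combine(es_up, es_dn)
        null = permutation_null(L, sig, n_perm=n_perm, seed=rng)
        null_by_target[sig.target_id] = null
        rows.append(
            {
                "target_id": sig.target_id,
                "ets": actual,
                "p": p_value(actual, null),
                "nets": nets(actual, null),
                "n_up": len(up_pos),
                "n_down": len(dn_pos),
            }
        )
    if not any_overlap:
        raise ValueError("no signature in the library overlaps the query")
    store = NullStore.from_run(null_by_target, [r["nets"] for r in rows])
    results = [
        ConnectivityResult(
            target_id=r["target_id"],
            ets=r["ets"],
            p=r["p"],
            nets=r["nets"],
            fdr=fdr(store, r["nets"]),
            n_genes_matched_up=r["n_up"],
            n_genes_matched_down=r["n_down"],
        )
        for r in rows
    ]
    results.sort(key=lambda r: (-r.nets, r.target_id))
    return results
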