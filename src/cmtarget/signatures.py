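"""Per-target consensus profiles and fixed-size up/down gene signatures.

A target's reference signature is built in two steps: replicate perturbation
profiles (shRNA, CRISPR, over-expression or compound treatments annotated to
the same target) are collapsed into a single consensus profile by a
correlation-weighted average, and the top/bottom ``n`` genes of that profile
become the paired gene sets ``t_up`` / ``t_down`` used for connectivity
scoring.  The weighting follows the LINCS consensus-signature convention:
each replicate's weight is the sum of its pairwise Spearman correlations with
the other replicates (clipped below to avoid negative or zero weights),
normalized to sum to one, so that outlier replicates contribute less.

The signature size ``n`` can be chosen from the data: the mean absolute
connectivity score shrinks as ``n`` grows, and the first size at which its
relative decrease rate (DR) falls below a threshold (default 0.01) is taken.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

#: clip floor for pairwise Spearman correlations in the consensus weights
RHO_CLIP = 0.01

#: default signature size used at full library scale
DEFAULT_SIGNATURE_SIZE = 350

#: default size grid for the DR-based size selection
DEFAULT_SIZE_GRID = tuple(range(100, 1001, 50))


@dataclass
class ExpressionSignature:
    """A single replicate differential-expression profile.

    ``values`` are unitless z-like differential metrics, one per gene.
    """

    signature_id: str
    gene_ids: list[str]
    values: np.ndarray
    perturbagen_id: str = ""
    target_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.gene_ids) != len(self.values):
            raise ValueError("gene_ids and values length mismatch")
        if len(self.gene_ids) < 2:
            raise ValueError("signature needs at least 2 genes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids in signature")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in signature")


@dataclass
class ConsensusProfile:
    """Weighted-average profile of one target over the common gene universe."""

    target_id: str
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.gene_ids) != len(self.values):
            raise ValueError("gene_ids and values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in consensus profile")


@dataclass
class TargetGeneSignature:
    """Paired up/down gene sets of size ``n`` for one target.

    ``t_up`` holds the ``n`` most up-regulated genes (descending), ``t_down``
    the ``n`` most down-regulated ones (most negative first).
    """

    target_id: str
    t_up: list[str]
    t_down: list[str]
    n: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n == 0:
            self.n = len(self.t_up)
        if len(self.t_up) != self.n or len(self.t_down) != self.n:
            raise ValueError("t_up and t_down must both have size n")
        if set(self.t_up) & set(self.t_down):
            raise ValueError("t_up and t_down must be disjoint")


def _common_genes(signatures: Sequence[ExpressionSignature]) -> list[str]:
    """Intersection of gene sets, ordered as in the first signature."""
    common = set(signatures[0].gene_ids)
    for sig in signatures[1:]:
        common &= set(sig.gene_ids)
    ordered = [g for g in signatures[0].gene_ids if g in common]
    dropped = len(signatures[0].gene_ids) - len(ordered)
    if dropped:
        logger.info("dropped %d genes absent from at least one replicate", dropped)
    return ordered


def _values_on(sig: ExpressionSignature, genes: list[str]) -> np.ndarray:
    """Signature values reindexed onto the common gene order."""
    if sig.gene_ids == genes:
        return sig.values
    lookup = dict(zip(sig.gene_ids, sig.values))
    return np.array([lookup[g] for g in genes])


def consensus_weights(
    signatures: Sequence[ExpressionSignature], clip: float = RHO_CLIP
) -> np.ndarray:
    """Nonnegative replicate weights from the pairwise Spearman matrix.

    weight_i ∝ Σ_{j≠i} max(ρ_ij, clip), normalized to sum to 1.  A single
    replicate gets weight 1; two replicates always get 0.5 each (the Spearman
    matrix is symmetric so both off-diagonal sums are equal).

    Raises
    ------
    ValueError
        If no signatures are given, or the replicates share fewer than three
        common genes (rank correlation is meaningless below that).
    """
    if len(signatures) == 0:
        raise ValueError("no signatures")
    if len(signatures) == 1:
        return np.array([1.0])
    genes = _common_genes(signatures)
    if len(genes) < 3:
        raise ValueError("insufficient overlap: fewer than 3 common genes")
    if len(signatures) == 2:
        # symmetric 2x2 correlation matrix: both row-sums are equal
        return np.array([0.5, 0.5])
    mat = np.column_stack([_values_on(sig, genes) for sig in signatures])
    rho = np.asarray(spearmanr(mat).statistic, dtype=float)
    # constant columns yield NaN correlations; treat them as uninformative
    rho = np.nan_to_num(rho, nan=0.0)
    rho = np.clip(rho, clip, None)
    np.fill_diagonal(rho, 0.0)
    raw = rho.sum(axis=1)
    return raw / raw.sum()


def build_consensus(
    signatures: Sequence[ExpressionSignature], clip: float = RHO_CLIP
) -> ConsensusProfile:
    """Correlation-weighted average of replicate signatures for one target.

    Genes missing in any replicate are dropped (intersection rule); the
    resulting profile lives on the shared gene universe in the first
    replicate's order.
    """
    weights = consensus_weights(signatures, clip=clip)
    if len(signatures) == 1:
        sig = signatures[0]
        return ConsensusProfile(sig.target_id, list(sig.gene_ids), sig.values.copy())
    genes = _common_genes(signatures)
    acc = np.zeros(len(genes))
    for w, sig in zip(weights, signatures):
        acc += w * _values_on(sig, genes)
    return ConsensusProfile(signatures[0].target_id, genes, acc)


def extract_signature(profile: ConsensusProfile, n: int) -> TargetGeneSignature:
    """Top-``n`` and bottom-``n`` genes of a consensus profile.

    Ties are broken by input gene order (stable sort), so the result is
    deterministic for any profile.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if 2 * n > len(profile.gene_ids):
        raise ValueError("signature size exceeds universe")
    order = np.argsort(-profile.values, kind="stable")
    t_up = [profile.gene_ids[i] for i in order[:n]]
    t_down = [profile.gene_ids[i] for i in order[::-1][:n]]
    return TargetGeneSignature(profile.target_id, t_up, t_down, n)


def decrease_rate(
    mean_abs_ets_by_size: Mapping[int, float]
) -> dict[int, float]:
    """Relative shrinkage of mean |ETS| between consecutive signature sizes.

    DR at size s_i is |m_{i+1} − m_i| / m_i where m is the mean absolute
    connectivity score; it is defined for every size but the last.  The
    absolute value is used so that a shrinking sequence yields a positive
    rate.
    """
    sizes = list(mean_abs_ets_by_size.keys())
    if len(sizes) < 2:
        raise ValueError("need at least 2 sizes to compute a decrease rate")
    steps = np.diff(sizes)
    if np.any(steps <= 0) or len(set(steps.tolist())) > 1:
        raise ValueError("sizes must be strictly increasing with constant step")
    values = np.asarray([mean_abs_ets_by_size[s] for s in sizes], dtype=float)
    if np.any(values <= 0):
        raise ValueError("mean |ETS| values must be positive")
    dr = np.abs(np.diff(values)) / values[:-1]
    return {s: float(d) for s, d in zip(sizes[:-1], dr)}


def choose_size(dr_by_size: Mapping[int, float], threshold: float = 0.01) -> int:
    """Smallest size whose DR is at or below ``threshold``.

    Falls back to the largest evaluated size (with a warning) when no size
    qualifies.
    """
    if not dr_by_size:
        raise ValueError("empty DR mapping")
    for size in sorted(dr_by_size):
        if dr_by_size[size] <= threshold:
            return size
    largest = max(dr_by_size)
    warnings.warn(
        f"no size reached DR <= {threshold}; falling back to largest evaluated "
        f"size {largest}",
        stacklevel=2,
    )
    return largest


def mean_abs_ets_grid(
    profiles: Sequence[ConsensusProfile],
    sizes: Sequence[int] = DEFAULT_SIZE_GRID,
) -> dict[int, float]:
    """Mean |ETS| of every profile-as-query against every signature, per size.

    Each consensus profile, ranked descending, serves as a query against the
    signatures extracted from all profiles at the given size; the mean of the
    absolute connectivity scores summarizes how score magnitude shrinks with
    signature size.  Feeds :func:`decrease_rate` / :func:`choose_size`.
    """
    from .connectivity import RankedQuery, ets  # deferred: avoids module cycle

    queries = [
        RankedQuery.from_values(p.target_id, p.gene_ids, p.values) for p in profiles
    ]
    out: dict[int, float] = {}
    for size in sizes:
        usable = [p for p in profiles if 2 * size <= len(p.gene_ids)]
        if not usable:
            raise ValueError(f"size {size} exceeds every profile's gene universe")
        sigs = [extract_signature(p, size) for p in usable]
        scores = [abs(ets(q, s)) for q in queries for s in sigs]
        out[size] = float(np.mean(scores))
    return out
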