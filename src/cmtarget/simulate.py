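"""Seeded synthetic data with planted ground truth for the whole pipeline.

The generator emulates the statistical structure the connectivity method
assumes: each target owns an up-regulated and a down-regulated gene block;
replicate perturbation profiles place a mean shift of ``effect_size`` (in
noise-SD units) on the block genes plus Gaussian noise everywhere; query
profiles activate or reverse chosen targets by summing signed block effects
plus noise.  Binding data are random SMILES-like strings from a small
fragment grammar and random amino-acid sequences, with the positive label
planted as "compound carries fragment motif F AND protein carries sequence
motif P".  Gene-set collections contain sets enriched for planted blocks at a
controlled overlap fraction next to fully random sets.

All randomness flows from one master seed through named substreams
(library / query / binding / genesets), so each piece can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .binding import BindingPair
from .connectivity import RankedQuery
from .enrichment import GeneSetCollection
from .signatures import ExpressionSignature

_STREAMS = {"library": 0, "query": 1, "binding": 2, "genesets": 3}


def substream(seed: int, name: str, extra: int = 0) -> np.random.Generator:
    """Named, independent random stream derived from the master seed."""
    return np.random.default_rng([seed, _STREAMS[name], extra])


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults describe a desk-scale experiment: 2000 genes, 50 targets with
    disjoint planted blocks of 20 genes per direction, 5 replicates per
    target, an effect of 3 noise-SDs, and 1000 permutations for scoring.
    """

    n_genes: int = 2000
    n_targets: int = 50
    replicates_per_target: int = 5
    signature_size: int = 20
    effect_size: float = 3.0
    noise_sd: float = 1.0
    n_perm: int = 1000
    seed: int = 0
    # binding branch
    n_compounds: int = 100
    n_proteins: int = 100
    motif_length: int = 5
    positive_rate: float = 0.5
    n_pairs: int = 2000

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "n_targets", "replicates_per_target", "signature_size",
            "n_perm", "n_compounds", "n_proteins", "motif_length", "n_pairs",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.positive_rate < 1:
            raise ValueError("positive_rate must be in (0, 1)")
        if 2 * self.signature_size > self.n_genes:
            raise ValueError("2 * signature_size must not exceed n_genes")


@dataclass
class GroundTruth:
    """Planted block assignment for every simulated target."""

    genes: list[str]
    up_blocks: dict[str, list[str]]
    down_blocks: dict[str, list[str]]
    effect_size: float
    noise_sd: float

    @property
    def target_ids(self) -> list[str]:
        return sorted(self.up_blocks)


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _target_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"T{i:0{width}d}" for i in range(1, n + 1)]


def generate_signature_library(
    config: SimulationConfig, disjoint: bool = True
) -> tuple[list[ExpressionSignature], GroundTruth]:
    """Replicate perturbation profiles with planted up/down blocks per target.

    In disjoint mode every target's blocks are carved from one global
    permutation (clean ground truth); otherwise blocks are sampled
    independently per target and may overlap, which stresses the pooled-FDR
    machinery downstream.
    """
    rng = substream(config.seed, "library")
    genes = _gene_names(config.n_genes)
    targets = _target_names(config.n_targets)
    n = config.signature_size
    up_blocks: dict[str, list[str]] = {}
    down_blocks: dict[str, list[str]] = {}
    if disjoint:
        if 2 * n * config.n_targets > config.n_genes:
            raise ValueError(
                "disjoint blocks need 2 * signature_size * n_targets <= n_genes"
            )
        perm = rng.permutation(config.n_genes)
        cursor = 0
        for t in targets:
            up_blocks[t] = [genes[i] for i in perm[cursor:cursor + n]]
            down_blocks[t] = [genes[i] for i in perm[cursor + n:cursor + 2 * n]]
            cursor += 2 * n
    else:
        for t in targets:
            pick = rng.choice(config.n_genes, size=2 * n, replace=False)
            up_blocks[t] = [genes[i] for i in pick[:n]]
            down_blocks[t] = [genes[i] for i in pick[n:]]
    gene_index = {g: i for i, g in enumerate(genes)}
    signatures: list[ExpressionSignature] = []
    for t in targets:
        base = np.zeros(config.n_genes)
        base[[gene_index[g] for g in up_blocks[t]]] = config.effect_size
        base[[gene_index[g] for g in down_blocks[t]]] = -config.effect_size
        for r in range(config.replicates_per_target):
            values = base + rng.normal(0.0, config.noise_sd, config.n_genes)
            signatures.append(
                ExpressionSignature(
                    signature_id=f"{t}_rep{r + 1}",
                    gene_ids=genes,
                    values=values,
                    perturbagen_id=f"pert_{t}_{r + 1}",
                    target_id=t,
                )
            )
    truth = GroundTruth(
        genes=genes,
        up_blocks=up_blocks,
        down_blocks=down_blocks,
        effect_size=config.effect_size,
        noise_sd=config.noise_sd,
    )
    return signatures, truth


def generate_query(
    ground_truth: GroundTruth,
    active_targets: Sequence[tuple[str, int]],
    noise_sd: float | None = None,
    seed: int = 0,
    label: str = "query",
) -> RankedQuery:
    """Expression query activating (+1) or reversing (−1) chosen targets.

    The per-gene metric is the sum of signed block effects over the active
    targets plus Gaussian noise; the result is ranked descending.  With no
    active targets the query is pure noise (null calibration input).  The
    paired reversal query for drug-vs-disease tests is ``query.negated()``.
    """
    if noise_sd is None:
        noise_sd = ground_truth.noise_sd
    for t, direction in active_targets:
        if t not in ground_truth.up_blocks:
            raise ValueError(f"unknown target {t}")
        if direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
    rng = substream(seed, "query")
    gene_index = {g: i for i, g in enumerate(ground_truth.genes)}
    metric = rng.normal(0.0, noise_sd, len(ground_truth.genes))
    for t, direction in active_targets:
        up = [gene_index[g] for g in ground_truth.up_blocks[t]]
        dn = [gene_index[g] for g in ground_truth.down_blocks[t]]
        metric[up] += direction * ground_truth.effect_size
        metric[dn] -= direction * ground_truth.effect_size
    return RankedQuery.from_values(label, ground_truth.genes, metric)


#: small fragment grammar for tokenizer-compatible SMILES-like strings
_FRAGMENTS = [
    "C", "CC", "O", "N", "c1ccccc1", "C(=O)O", "CN", "CO", "S",
    "Cl", "F", "C=C", "CCN", "C(C)C", "OC", "NC",
]
#: planted compound motif (amide-like fragment, absent from the grammar)
_COMPOUND_MOTIF = "C(=O)NCC"

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class BindingTruth:
    """Planted rule of the synthetic binding dataset."""

    compound_motif: str
    protein_motif: str
    compounds: dict[str, str]
    proteins: dict[str, str]
    motif_compounds: set[str] = field(default_factory=set)
    motif_proteins: set[str] = field(default_factory=set)


def _random_smiles(rng: np.random.Generator, with_motif: bool) -> str:
    n_frag = int(rng.integers(3, 9))
    parts = [_FRAGMENTS[i] for i in rng.integers(0, len(_FRAGMENTS), n_frag)]
    if with_motif:
        parts.insert(int(rng.integers(0, len(parts) + 1)), _COMPOUND_MOTIF)
    return "".join(parts)


def _random_protein(
    rng: np.random.Generator, motif: str | None, length_range=(50, 200)
) -> str:
    length = int(rng.integers(*length_range))
    seq = "".join(_AA[i] for i in rng.integers(0, len(_AA), length))
    if motif is not None:
        pos = int(rng.integers(0, length - len(motif) + 1))
        seq = seq[:pos] + motif + seq[pos + len(motif):]
    return seq


def generate_binding_dataset(
    config: SimulationConfig, label_noise: float = 0.01
) -> tuple[list[BindingPair], BindingTruth]:
    """Labelled compound-protein pairs governed by a planted motif rule.

    label = 1 iff the compound carries the fragment motif AND the protein
    carries the sequence motif, with a small label-flip noise (default 1%).
    Half the compounds and half the proteins carry their motif, and pairs are
    drawn so the positive fraction sits near ``config.positive_rate``.
    """
    rng = substream(config.seed, "binding")
    protein_motif = "".join(_AA[i] for i in rng.integers(0, len(_AA), config.motif_length))
    compounds: dict[str, str] = {}
    motif_compounds: set[str] = set()
    cw = len(str(config.n_compounds))
    for i in range(config.n_compounds):
        cid = f"com{i + 1:0{cw}d}"
        with_motif = i < config.n_compounds // 2
        smiles = _random_smiles(rng, with_motif)
        if not with_motif and _COMPOUND_MOTIF in smiles:
            with_motif = True  # rare accidental motif from concatenation
        compounds[cid] = smiles
        if with_motif:
            motif_compounds.add(cid)
    proteins: dict[str, str] = {}
    motif_proteins: set[str] = set()
    pw = len(str(config.n_proteins))
    for i in range(config.n_proteins):
        pid = f"prot{i + 1:0{pw}d}"
        with_motif = i < config.n_proteins // 2
        proteins[pid] = _random_protein(rng, protein_motif if with_motif else None)
        if with_motif:
            motif_proteins.add(pid)
    plain_compounds = sorted(set(compounds) - motif_compounds)
    plain_proteins = sorted(set(proteins) - motif_proteins)
    motif_c, motif_p = sorted(motif_compounds), sorted(motif_proteins)
    pairs: list[BindingPair] = []
    for _ in range(config.n_pairs):
        positive = rng.random() < config.positive_rate
        if positive:
            cid = motif_c[rng.integers(len(motif_c))]
            pid = motif_p[rng.integers(len(motif_p))]
        else:
            # a negative pair lacks at least one of the two motifs
            mode = int(rng.integers(3))
            cid = (plain_compounds if mode != 1 else motif_c)[
                rng.integers(len(plain_compounds if mode != 1 else motif_c))
            ]
            pid = (plain_proteins if mode != 0 else motif_p)[
                rng.integers(len(plain_proteins if mode != 0 else motif_p))
            ]
        label = int(cid in motif_compounds and pid in motif_proteins)
        if rng.random() < label_noise:
            label = 1 - label
        pairs.append(BindingPair(cid, compounds[cid], pid, proteins[pid], label))
    truth = BindingTruth(
        compound_motif=_COMPOUND_MOTIF,
        protein_motif=protein_motif,
        compounds=compounds,
        proteins=proteins,
        motif_compounds=motif_compounds,
        motif_proteins=motif_proteins,
    )
    return pairs, truth


def generate_genesets(
    ground_truth: GroundTruth,
    n_sets: int = 20,
    overlap_fraction: float = 0.8,
    set_size: int = 30,
    seed: int = 0,
) -> tuple[GeneSetCollection, dict[str, str]]:
    """Gene sets either enriched for a target's planted block or random.

    The first half of the sets draw ``overlap_fraction`` of their members
    from one target's up+down block (cycling through targets) and the rest
    uniformly; the second half are fully random.  Returns the collection and
    a map set_name -> planted target id ("" for random sets).
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = substream(seed, "genesets")
    genes = ground_truth.genes
    targets = ground_truth.target_ids
    sets: dict[str, list[str]] = {}
    planted_for: dict[str, str] = {}
    for i in range(n_sets):
        name = f"set{i + 1:03d}"
        members: list[str] = []
        if i < n_sets // 2:
            t = targets[i % len(targets)]
            block = ground_truth.up_blocks[t] + ground_truth.down_blocks[t]
            n_planted = min(int(round(overlap_fraction * set_size)), len(block))
            pick = rng.choice(len(block), size=n_planted, replace=False)
            members.extend(block[j] for j in pick)
            planted_for[name] = t
        else:
            planted_for[name] = ""
        pool = sorted(set(genes) - set(members))
        n_fill = set_size - len(members)
        if n_fill > 0:
            fill = rng.choice(len(pool), size=n_fill, replace=False)
            members.extend(pool[j] for j in fill)
        sets[name] = members
    collection = GeneSetCollection(
        sets=sets,
        descriptions={name: f"synthetic set {name}" for name in sets},
        universe=set(genes),
    )
    return collection, planted_for


def generate_target_genesets(
    ground_truth: GroundTruth,
    active_targets: Sequence[str] = (),
    n_sets: int = 10,
    set_size: int = 8,
    seed: int = 0,
) -> GeneSetCollection:
    """Pathway sets over the *target* universe for pathway-mapping runs.

    On real data the scored targets are themselves genes, so ordinary GMT
    collections cover them; the simulation keeps synthetic target labels
    distinct from its gene universe, so pathway mapping needs sets drawn from
    the target identifiers.  The first half of the sets are seeded with the
    given active targets (when any), the rest are random.
    """
    rng = substream(seed, "genesets", extra=1)
    targets = ground_truth.target_ids
    size = min(set_size, len(targets))
    sets: dict[str, list[str]] = {}
    active = [t for t in active_targets if t in targets]
    for i in range(n_sets):
        members: list[str] = []
        if active and i < n_sets // 2:
            members.extend(active[: size // 2])
        pool = [t for t in targets if t not in members]
        fill = rng.choice(len(pool), size=size - len(members), replace=False)
        members.extend(pool[j] for j in fill)
        sets[f"tset{i + 1:03d}"] = members
    return GeneSetCollection(
        sets=sets,
        descriptions={name: f"synthetic target set {name}" for name in sets},
        universe=set(targets),
    )
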