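"""Target algebra: effect, reversal, direct/indirect and the compound network.

Effect targets are signatures whose connectivity with the query is
significant (FDR at or below a threshold).  A reversal (therapeutic) target
is significant for both a drug and a disease query with strictly opposite
NETS signs — the drug pushes the target's program the opposite way the
disease does.  Direct targets are effect targets the compound also binds
(intersection with the binding calls); the remaining effect targets are
indirect.  The compound—direct-target bipartite network supports ranking
herbal components by degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .connectivity import ConnectivityResult

DEFAULT_FDR_THRESHOLD = 0.05
DEFAULT_ABS_NETS_THRESHOLD = 4.0
DEFAULT_TOP_K = 100


@dataclass
class TargetCall:
    """Role assignment for one target across the drug/disease comparison."""

    target_id: str
    effect: bool = False
    binding: bool = False
    direct: bool = False
    indirect: bool = False
    therapeutic: bool = False
    nets_drug: float = float("nan")
    nets_disease: float = float("nan")
    fdr_drug: float = float("nan")
    fdr_disease: float = float("nan")

    def __post_init__(self) -> None:
        if self.direct and not (self.effect and self.binding):
            raise ValueError("direct implies effect and binding")
        if self.indirect and (not self.effect or self.direct):
            raise ValueError("indirect implies effect and not direct")


@dataclass
class ComponentTargetNetwork:
    """Bipartite compound—direct-target graph with node degrees."""

    edges: list[tuple[str, str]]
    graph: nx.Graph = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        g = nx.Graph()
        for compound, target in self.edges:
            g.add_node(compound, bipartite="compound")
            g.add_node(target, bipartite="target")
            g.add_edge(compound, target)
        self.graph = g

    def degree(self, node: str) -> int:
        return self.graph.degree(node) if node in self.graph else 0

    @property
    def compounds(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["bipartite"] == "compound"
        )


def call_effect_targets(
    results: Sequence[ConnectivityResult],
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> set[str]:
    """Targets whose connectivity FDR is at or below the threshold."""
    return {r.target_id for r in results if r.fdr <= fdr_threshold}


def reversal_targets(
    drug: Sequence[ConnectivityResult],
    disease: Sequence[ConnectivityResult],
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> set[str]:
    """Targets significant in both runs with strictly opposite NETS signs.

    A NETS of exactly 0 on either side excludes the target (zero carries no
    direction).  Symmetric in its two arguments.
    """
    drug_by_id = {r.target_id: r for r in drug}
    disease_by_id = {r.target_id: r for r in disease}
    shared = drug_by_id.keys() & disease_by_id.keys()
    if not shared:
        raise ValueError("drug and disease results share no targets")
    out = set()
    for t in shared:
        a, b = drug_by_id[t], disease_by_id[t]
        if a.fdr <= fdr_threshold and b.fdr <= fdr_threshold:
            if a.nets * b.nets < 0:
                out.add(t)
    return out


def classify_targets(effect: set[str], binding: set[str]) -> tuple[set[str], set[str]]:
    """Partition effect targets into direct (also bound) and indirect."""
    direct = effect & binding
    indirect = effect - binding
    return direct, indirect


def compare_queries(
    nets_a: Mapping[str, float],
    nets_b: Mapping[str, float],
    restrict: set[str] | None = None,
) -> float:
    """Pearson correlation of two NETS profiles over their shared targets."""
    shared = sorted(nets_a.keys() & nets_b.keys())
    if restrict is not None:
        shared = [t for t in shared if t in restrict]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared targets")
    a = np.array([nets_a[t] for t in shared])
    b = np.array([nets_b[t] for t in shared])
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def build_component_network(
    binding_calls: Iterable[tuple[str, str]], direct: set[str]
) -> ComponentTargetNetwork:
    """Bipartite network of binding calls restricted to direct targets."""
    edges = sorted({(c, t) for c, t in binding_calls if t in direct})
    return ComponentTargetNetwork(edges)


def top_components(
    network: ComponentTargetNetwork, k: int = DEFAULT_TOP_K
) -> list[str]:
    """Compounds ranked by network degree descending (ties by identifier)."""
    return sorted(network.compounds, key=lambda c: (-network.degree(c), c))[:k]


def top_targets(
    results: Sequence[ConnectivityResult],
    abs_nets_threshold: float = DEFAULT_ABS_NETS_THRESHOLD,
) -> set[str]:
    """Targets whose |NETS| meets the magnitude threshold (inclusive)."""
    return {r.target_id for r in results if abs(r.nets) >= abs_nets_threshold}


def make_calls(
    drug: Sequence[ConnectivityResult],
    disease: Sequence[ConnectivityResult] | None,
    binding: set[str],
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> list[TargetCall]:
    """Full role table for the drug run (therapeutic needs a disease run)."""
    effect = call_effect_targets(drug, fdr_threshold)
    direct, indirect = classify_targets(effect, binding)
    therapeutic = (
        reversal_targets(drug, disease, fdr_threshold) if disease is not None else set()
    )
    disease_by_id = {r.target_id: r for r in disease} if disease else {}
    calls = []
    for r in drug:
        d = disease_by_id.get(r.target_id)
        calls.append(
            TargetCall(
                target_id=r.target_id,
                effect=r.target_id in effect,
                binding=r.target_id in binding,
                direct=r.target_id in direct,
                indirect=r.target_id in indirect,
                therapeutic=r.target_id in therapeutic,
                nets_drug=r.nets,
                nets_disease=d.nets if d else float("nan"),
                fdr_drug=r.fdr,
                fdr_disease=d.fdr if d else float("nan"),
            )
        )
    return calls
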