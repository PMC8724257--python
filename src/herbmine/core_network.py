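"""Core-material extraction and the weighted co-prescription network.

The "core" of a prescription survey is the set of materials that appear in
frequent multi-material combinations. The network has one node per core
material (weighted by its citation count FC, colored by its TCM property)
and one edge per frequent pair (weighted by the number of prescriptions
containing both endpoints).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .errors import ValidationError
from .io_model import MaterialRecord, TransactionSet
from .itemset_mining import ItemsetSupport, brute_force_support

GRAPH_FORMATS = ("graphml", "edgelist", "dot")


@dataclass(frozen=True)
class CoreNetwork:
    #: (material_id, FC, property_bucket or "")
    nodes: tuple[tuple[str, int, str], ...]
    #: (material_a, material_b, pair_count) with a < b
    edges: tuple[tuple[str, str, int], ...]

    def __post_init__(self) -> None:
        ids = {n[0] for n in self.nodes}
        fc = {n[0]: n[1] for n in self.nodes}
        for a, b, w in self.edges:
            if a == b:
                raise ValidationError(f"self-loop on {a}")
            if a not in ids or b not in ids:
                raise ValidationError(f"edge ({a}, {b}) references a non-node")
            if w > min(fc[a], fc[b]):
                raise ValidationError(
                    f"edge ({a}, {b}) weight {w} exceeds an endpoint FC"
                )


def extract_core(frequent: Sequence[ItemsetSupport]) -> frozenset[str]:
    """Union of items over all frequent itemsets of size >= 2.

    Materials that only pass the support threshold alone are not "core":
    the core is defined by participation in frequent combinations.
    """
    core: set[str] = set()
    for s in frequent:
        if len(s.items) >= 2:
            core.update(s.items)
    return frozenset(core)


def build_core_network(
    ts: TransactionSet,
    core: Iterable[str],
    catalog: Sequence[MaterialRecord],
    edge_policy: str = "frequent",
    min_support: float = 0.50,
    support_inclusive: bool = True,
) -> CoreNetwork:
    """Weighted co-prescription graph over the core materials.

    ``edge_policy="frequent"`` (default) keeps a pair only when its
    pair_count passes the mining support threshold — the edges then
    coincide with the frequent two-material combinations. ``"all_pairs"``
    emits every core pair regardless of count.
    """
    if edge_policy not in ("frequent", "all_pairs"):
        raise ValueError(f"unknown edge_policy {edge_policy!r}")
    core_ids = sorted(core)
    by_id = {m.material_id: m for m in catalog}
    missing = [c for c in core_ids if c not in by_id]
    if missing:
        raise ValidationError(f"core material(s) missing from catalog: {missing}")

    fc = {c: brute_force_support(ts, [c]) for c in core_ids}
    nodes = tuple(
        (c, fc[c], by_id[c].property_bucket or "") for c in core_ids
    )
    threshold = min_support * ts.N
    edges = []
    for a, b in combinations(core_ids, 2):
        w = brute_force_support(ts, [a, b])
        keep = (
            edge_policy == "all_pairs"
            or (w >= threshold if support_inclusive else w > threshold)
        )
        if keep and w > 0:
            edges.append((a, b, w))
    return CoreNetwork(nodes=nodes, edges=tuple(edges))


def to_networkx(network: CoreNetwork) -> nx.Graph:
    g = nx.Graph()
    for mid, fc, bucket in network.nodes:
        g.add_node(mid, FC=fc, property_bucket=bucket)
    for a, b, w in network.edges:
        g.add_edge(a, b, weight=w)
    return g


def export_graph(network: CoreNetwork, format: str, path: str | Path) -> Path:
    """Write the network as GraphML, a 3-column edge list, or DOT.

    Node insertion follows the sorted node order, so output bytes are
    stable across runs for identical input.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(to_networkx(network), path)
    elif format == "edgelist":
        lines = ["source,target,weight"]
        lines += [f"{a},{b},{w}" for a, b, w in network.edges]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "dot":
        lines = ["graph core {"]
        for mid, fc, bucket in network.nodes:
            lines.append(
                f'  "{mid}" [FC={fc}, property_bucket="{bucket}"];'
            )
        for a, b, w in network.edges:
            lines.append(f'  "{a}" -- "{b}" [weight={w}];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown graph format {format!r}; use one of {GRAPH_FORMATS}")
    return path
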