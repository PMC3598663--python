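"""Reaction-network enumeration: the DAG reachable from a congener
under a dechlorination rule set.

Every edge removes exactly one chlorine, so the graph is acyclic by
construction and every path from the start congener to a terminal has
length equal to the chlorine-count difference.  Graphs are tiny (the
node set is a subset of the 209 congeners), so enumeration is exhaustive
breadth-first closure.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx

from .congeners import Congener
from .rules import DechlorRule, ProcessRuleSet, applicable_rules, apply_rule


def _node_key(c: Congener) -> tuple[int, str]:
    return (-c.n_chlorines, c.name)


@dataclass
class PathwayGraph:
    """DAG of congeners reachable from ``start`` under one rule set.

    Edges are labeled with the rule applied and the ring index it acted
    on; two distinct rules yielding the same product are kept as two
    parallel edges (their rates add in kinetic simulation).
    """

    graph: nx.MultiDiGraph
    start: Congener
    rule_set: ProcessRuleSet

    @property
    def nodes(self) -> list[Congener]:
        """Nodes ordered by chlorine count descending, then name."""
        return sorted(self.graph.nodes, key=_node_key)

    @property
    def terminals(self) -> set[Congener]:
        """Congeners with no applicable rule (out-degree 0)."""
        return {n for n in self.graph.nodes if self.graph.out_degree(n) == 0}

    def edges(self) -> list[tuple[Congener, Congener, DechlorRule, int]]:
        out = [
            (u, v, d["rule"], d["ring_index"])
            for u, v, d in self.graph.edges(data=True)
        ]
        out.sort(key=lambda e: (_node_key(e[0]), _node_key(e[1]), e[3]))
        return out

    def edge_table(self) -> str:
        """Tab-separated edge list: substrate, product, ring, rule, tag."""
        lines = ["substrate\tproduct\tring_index\trule\ttag"]
        for u, v, rule, ring_index in self.edges():
            lines.append(
                f"{u.name}\t{v.name}\t{ring_index}\t"
                f"{rule.substrate}-{rule.removed_position}\t{rule.tag}"
            )
        return "\n".join(lines)

    def to_dot(self) -> str:
        """GraphViz DOT export for visualization."""
        lines = [f'digraph "{self.start.name} / {self.rule_set.name}" {{']
        lines.append("  rankdir=TB;")
        for n in self.nodes:
            shape = "doubleoctagon" if self.graph.out_degree(n) == 0 else "box"
            lines.append(f'  "{n.name}" [shape={shape}];')
        for u, v, rule, ring_index in self.edges():
            lines.append(
                f'  "{u.name}" -> "{v.name}" '
                f'[label="{rule.substrate}-{rule.removed_position}"];'
            )
        lines.append("}")
        return "\n".join(lines)


def enumerate_pathways(
    start: Congener, rs: ProcessRuleSet, max_depth: int | None = None
) -> PathwayGraph:
    """Breadth-first closure of ``start`` under the rules of ``rs``."""
    g = nx.MultiDiGraph()
    g.add_node(start)
    queue: deque[tuple[Congener, int]] = deque([(start, 0)])
    expanded = {start}
    while queue:
        node, depth = queue.popleft()
        if max_depth is not None and depth >= max_depth:
            continue
        for ring_index, rule in applicable_rules(node, rs):
            product = apply_rule(node, ring_index, rule)
            g.add_edge(node, product, rule=rule, ring_index=ring_index)
            if product not in expanded:
                expanded.add(product)
                queue.append((product, depth + 1))
    return PathwayGraph(graph=g, start=start, rule_set=rs)


@lru_cache(maxsize=4096)
def _closure(start: Congener, rs: ProcessRuleSet) -> frozenset[Congener]:
    """Cached node set of the full pathway graph (rule sets are frozen)."""
    return frozenset(enumerate_pathways(start, rs).graph.nodes)


def terminal_products(start: Congener, rs: ProcessRuleSet) -> set[Congener]:
    """Terminal congeners (no applicable rule) reachable from ``start``."""
    return enumerate_pathways(start, rs).terminals


def reachable(
    src: Congener,
    dst: Congener,
    rs: ProcessRuleSet,
    max_depth: int | None = None,
) -> tuple[bool, list[Congener] | None]:
    """Whether ``dst`` is reachable from ``src`` under ``rs``.

    Returns ``(True, path)`` with one shortest witness path (as a node
    list starting at ``src``), or ``(False, None)``.  The search depth is
    intrinsically capped at the chlorine-count difference.
    """
    if src == dst:
        return True, [src]
    if dst.n_chlorines >= src.n_chlorines:
        return False, None
    if max_depth is None and dst not in _closure(src, rs):
        return False, None
    # shortest path by BFS over single-step products
    parents: dict[Congener, Congener] = {}
    queue: deque[tuple[Congener, int]] = deque([(src, 0)])
    seen = {src}
    while queue:
        node, depth = queue.popleft()
        if max_depth is not None and depth >= max_depth:
            continue
        for ring_index, rule in applicable_rules(node, rs):
            product = apply_rule(node, ring_index, rule)
            if product in seen:
                continue
            seen.add(product)
            parents[product] = node
            if product == dst:
                path = [dst]
                while path[-1] != src:
                    path.append(parents[path[-1]])
                return True, list(reversed(path))
            queue.append((product, depth + 1))
    return False, None
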