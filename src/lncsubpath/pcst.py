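"""Prize-collecting Steiner tree search over weighted pathways.

The target is the connected subgraph minimising

    sum of edge costs over the tree  -  sum of node prizes,

i.e. the classic PCST objective in minimisation form. Two routes are
provided:

* :func:`solve_exact` — exhaustive enumeration of connected induced node
  subsets with an MST over each, feasible up to ~15 nodes; serves as the
  optimality oracle.
* :func:`solve` — per connected component, exact enumeration for small
  components and a deterministic heuristic for larger ones. The heuristic
  combines (a) greedy growth from high-prize seeds with one- and two-step
  lookahead, and (b) optimal subtree pruning ("strong pruning") of the
  component MST, taking the better result.

Tie-breaking everywhere is (smaller objective, fewer nodes, lexicographic
node ids), so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

from .weighting import WeightedPathway

_TOL = 1e-9

__all__ = ["SubgraphSolution", "objective", "solve_exact", "solve", "extract_subpathways"]


@dataclass(frozen=True)
class SubgraphSolution:
    """A connected region: node set, spanning tree edges, objective value."""

    nodes: tuple
    edges: tuple  # tuple of frozenset({u, v})
    objective: float

    def __len__(self) -> int:
        return len(self.nodes)


def objective(nodes, edges, wp: WeightedPathway) -> float:
    """Sum of edge costs minus sum of node prizes; empty -> 0."""
    return sum(wp.edge_cost[frozenset(e)] for e in edges) - sum(
        wp.node_prize.get(v, 0.0) for v in nodes
    )


def _instance(wp: WeightedPathway):
    nodes = sorted(wp.pathway.graph.nodes)
    prize = {v: wp.node_prize.get(v, 0.0) for v in nodes}
    cost = {frozenset((u, v)): wp.edge_cost.get(frozenset((u, v)), 0.0)
            for u, v in wp.pathway.graph.edges}
    adj: dict = {v: [] for v in nodes}
    for e, c in cost.items():
        u, v = tuple(e)
        adj[u].append((v, c))
        adj[v].append((u, c))
    return nodes, prize, cost, adj


def _mst(nodes, adj):
    """Prim MST over the induced subgraph; returns (cost, edges) or None when
    the induced subgraph is disconnected."""
    nodes = set(nodes)
    start = min(nodes)
    seen = {start}
    edges = []
    total = 0.0
    cand = [(c, start, v) for v, c in adj[start] if v in nodes]
    while len(seen) < len(nodes):
        best = None
        for c, u, v in cand:
            if v in seen:
                continue
            if best is None or (c, u, v) < best:
                best = (c, u, v)
        if best is None:
            return None
        c, u, v = best
        seen.add(v)
        total += c
        edges.append(frozenset((u, v)))
        cand.extend((c2, v, w) for w, c2 in adj[v] if w in nodes and w not in seen)
    return total, edges


def _better(a, b):
    """Pick the better of two (objective, nodes, edges) candidates."""
    if b is None:
        return a
    if a is None:
        return b
    ka = (round(a[0], 9), len(a[1]), tuple(sorted(a[1])))
    kb = (round(b[0], 9), len(b[1]), tuple(sorted(b[1])))
    return a if ka <= kb else b


def solve_exact(wp: WeightedPathway, max_nodes: int = 15) -> SubgraphSolution:
    """Brute-force optimum over all non-empty connected induced node subsets.

    Refuses graphs larger than ``max_nodes``.
    """
    nodes, prize, _cost, adj = _instance(wp)
    if len(nodes) > max_nodes:
        raise ValueError(f"graph with {len(nodes)} nodes exceeds max_nodes={max_nodes}")
    if not nodes:
        raise ValueError("empty graph")

    idx = {v: i for i, v in enumerate(nodes)}
    nbit = [0] * len(nodes)
    for v in nodes:
        for u, _c in adj[v]:
            nbit[idx[v]] |= 1 << idx[u]

    best = None
    for mask in range(1, 1 << len(nodes)):
        # connectivity check on the bitmask
        low = mask & -mask
        reach = low
        frontier = low
        while frontier:
            nxt = 0
            m = frontier
            while m:
                b = m & -m
                m ^= b
                nxt |= nbit[b.bit_length() - 1]
            nxt &= mask & ~reach
            reach |= nxt
            frontier = nxt
        if reach != mask:
            continue
        sub = [nodes[i] for i in range(len(nodes)) if mask >> i & 1]
        if len(sub) == 1:
            obj = -prize[sub[0]]
            best = _better(best, (obj, sub, []))
            continue
        mst = _mst(sub, adj)
        obj = mst[0] - sum(prize[v] for v in sub)
        best = _better(best, (obj, sub, mst[1]))
    obj, sub, edges = best
    return SubgraphSolution(nodes=tuple(sorted(sub)), edges=tuple(edges), objective=obj)


def _strong_prune(tree_adj, prize, root):
    """Optimal subtree of a tree containing ``root``: bottom-up net value DP."""
    order = [root]
    parent = {root: None}
    for v in order:
        for u, _c in tree_adj[v]:
            if u not in parent:
                parent[u] = v
                order.append(u)
    net = {}
    keep_children: dict = {v: [] for v in parent}
    for v in reversed(order):
        nv = prize[v]
        for u, c in tree_adj[v]:
            if parent.get(u) is not v:
                continue
            gain = net[u] - c
            if gain > _TOL:
                nv += gain
                keep_children[v].append((u, c))
        net[v] = nv
    # collect the kept subtree
    sub = [root]
    edges = []
    stack = [root]
    while stack:
        v = stack.pop()
        for u, c in keep_children[v]:
            sub.append(u)
            edges.append(frozenset((v, u)))
            stack.append(u)
    return -net[root], sub, edges


def _grow_from(seed, comp, prize, adj):
    """Greedy growth with 1- and 2-step lookahead, then MST + strong prune."""
    comp = set(comp)
    in_t = {seed}
    while True:
        best_gain, best_add = _TOL, None
        # cheapest connection cost from the current tree to each outside node
        conn: dict = {}
        for v in in_t:
            for u, c in adj[v]:
                if u in comp and u not in in_t and c < conn.get(u, float("inf")):
                    conn[u] = c
        for u, c1 in conn.items():
            gain = prize[u] - c1
            if gain > best_gain:
                best_gain, best_add = gain, [u]
            for w, c2 in adj[u]:
                if w in in_t or w not in comp or w == u:
                    continue
                gain2 = prize[u] + prize[w] - c1 - c2
                if gain2 > best_gain:
                    best_gain, best_add = gain2, [u, w]
        if best_add is None:
            break
        in_t.update(best_add)
    mst = _mst(in_t, adj)
    tree_adj: dict = {v: [] for v in in_t}
    for e in mst[1]:
        u, v = tuple(e)
        c = next(c for w, c in adj[u] if w == v)
        tree_adj[u].append((v, c))
        tree_adj[v].append((u, c))
    return _strong_prune(tree_adj, prize, seed)


def _solve_component(comp, prize, adj, n_seeds: int = 8):
    comp = sorted(comp)
    best = None
    # candidate 1: strong pruning of the component MST from every root
    mst = _mst(comp, adj)
    tree_adj: dict = {v: [] for v in comp}
    for e in mst[1]:
        u, v = tuple(e)
        c = next(c for w, c in adj[u] if w == v)
        tree_adj[u].append((v, c))
        tree_adj[v].append((u, c))
    for root in comp:
        best = _better(best, _strong_prune(tree_adj, prize, root))
    # candidate 2: greedy growth from the highest-prize seeds
    seeds = sorted(comp, key=lambda v: (-prize[v], v))[:n_seeds]
    for seed in seeds:
        best = _better(best, _grow_from(seed, comp, prize, adj))
    return best


def solve(wp: WeightedPathway, exact_threshold: int = 4) -> SubgraphSolution | None:
    """Best region across connected components; None when no region with a
    strictly negative objective exists ("no region")."""
    import networkx as nx

    nodes, prize, _cost, adj = _instance(wp)
    if not nodes:
        return None
    best = None
    for comp in nx.connected_components(wp.pathway.graph):
        comp = sorted(comp)
        if len(comp) <= exact_threshold:
            sub_wp = _subgraph_wp(wp, comp)
            sol = solve_exact(sub_wp, max_nodes=exact_threshold)
            cand = (sol.objective, list(sol.nodes), list(sol.edges))
        else:
            cand = _solve_component(comp, prize, adj)
        best = _better(best, cand)
    if best is None or best[0] >= -_TOL:
        return None
    obj, sub, edges = best
    return SubgraphSolution(nodes=tuple(sorted(sub)), edges=tuple(edges), objective=obj)


def _subgraph_wp(wp: WeightedPathway, keep) -> WeightedPathway:
    from .pathway_graphs import PathwayGraph

    keep = set(keep)
    g = wp.pathway.graph.subgraph(keep).copy()
    pg = PathwayGraph(id=wp.pathway.id, name=wp.pathway.name, graph=g, origin=wp.pathway.origin)
    return WeightedPathway(
        pathway=pg,
        node_raw={v: wp.node_raw.get(v, 0.0) for v in keep},
        node_prize={v: wp.node_prize.get(v, 0.0) for v in keep},
        edge_raw={e: w for e, w in wp.edge_raw.items() if e <= keep},
        edge_cost={e: c for e, c in wp.edge_cost.items() if e <= keep},
        node_lncrnas={v: wp.node_lncrnas.get(v, []) for v in keep},
    )


def extract_subpathways(wp: WeightedPathway, max_regions: int = 1,
                        exact_threshold: int = 4) -> list[SubgraphSolution]:
    """Iteratively solve, remove the found region's nodes, and re-solve, up to
    ``max_regions`` or until no profitable region remains. Regions are
    node-disjoint, in discovery order."""
    out: list[SubgraphSolution] = []
    remaining = set(wp.pathway.graph.nodes)
    current = wp
    for _ in range(max_regions):
        sol = solve(current, exact_threshold)
        if sol is None:
            break
        out.append(sol)
        remaining -= set(sol.nodes)
        if not remaining:
            break
        current = _subgraph_wp(wp, remaining)
    return out
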