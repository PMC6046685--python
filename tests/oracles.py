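"""Independent brute-force oracles the implementation is checked against.

Each oracle re-derives a stage's result by the most literal method
available — all-pairs predicate evaluation, iterative select-and-erase,
exhaustive chain search — sharing no code with the production path.
"""

from __future__ import annotations

import networkx as nx

from coastband.adjacency import COAST
from coastband.connectivity import classify_code


def brute_force_adjacency(lulc, coastline, mode="rook", min_shared=0.0):
    """All-pairs geometric predicate evaluation, no spatial index."""
    patches = lulc.active_patches
    g = nx.Graph()
    g.add_node(COAST)
    g.add_nodes_from(p.id for p in patches)
    for i, p in enumerate(patches):
        for q in patches[i + 1:]:
            if not p.geometry.intersects(q.geometry):
                continue
            shared = p.geometry.intersection(q.geometry).length
            if mode == "rook" and shared <= min_shared:
                continue
            g.add_edge(p.id, q.id, shared_len=shared)
        if p.geometry.intersects(coastline.geometry):
            shared = p.geometry.intersection(coastline.geometry).length
            if mode == "queen" or shared > min_shared:
                g.add_edge(p.id, COAST, shared_len=shared)
    return g


def select_and_erase_bands(graph, B):
    """Iterative formulation of band assignment.

    Band 1 = patches touching the coast; band k = patches touching band k-1,
    erased from the candidate pool as they are selected; repeated B times.
    """
    band = {}
    remaining = set(graph.nodes) - {COAST}
    current = {p for p in remaining if graph.has_edge(p, COAST)}
    level = 1
    while current and level <= B:
        for p in current:
            band[p] = level
        remaining -= current
        current = {
            p for p in remaining if any(q in band and band[q] == level for q in graph.neighbors(p))
        }
        level += 1
    return band


def chain_membership(bands, graph, lulc, scheme):
    """Exhaustive search for band-descending natural chains to the coast.

    A natural patch of band b is a member iff some sequence of natural
    patches with bands b, b-1, ..., 1 links it (via adjacency at every
    step) to a coast-adjacent band-1 natural patch.  Memoised DFS over the
    band-descending DAG — exact because chains strictly descend.
    """
    natural = {
        p.id for p in lulc.patches if classify_code(p.clc_code, scheme) == "natural"
    }
    memo: dict[str, bool] = {}

    def reaches_coast(p: str) -> bool:
        if p in memo:
            return memo[p]
        b = bands[p]
        if p not in natural or b < 1:
            result = False
        elif b == 1:
            result = graph.has_edge(p, COAST)
        else:
            result = any(
                bands[q] == b - 1 and reaches_coast(q)
                for q in graph.neighbors(p)
                if q != COAST
            )
        memo[p] = result
        return result

    return {p for p in bands.band if reaches_coast(p)}


def max_ascending_chain(members, bands, graph):
    """TCD oracle: deepest band reachable by strictly band-ascending chains.

    For each member, the maximum over all chains p = q_b, q_{b+1}, ... with
    every q a member, consecutive patches adjacent, and bands increasing by
    exactly one.  Memoised DFS over the band-ascending DAG.
    """
    memo: dict[str, int] = {}

    def deepest(p: str) -> int:
        if p in memo:
            return memo[p]
        b = bands[p]
        up = [
            q for q in graph.neighbors(p)
            if q != COAST and q in members and bands[q] == b + 1
        ]
        result = max((deepest(q) for q in up), default=b)
        memo[p] = result
        return result

    return {p: deepest(p) for p in members}
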