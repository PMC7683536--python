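"""Independent oracles used by the test-suite and the acceptance script.

Everything here is deliberately naive — plain breadth-first search,
exhaustive path enumeration, exhaustive Kuratowski-subdivision search, and a
dense NumPy linear solve — so that it shares no code path with the package
implementations it checks.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


# ---------------------------------------------------------------------------
# shortest paths
# ---------------------------------------------------------------------------


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def all_geodesics_exhaustive(adj: dict, s, t) -> list[list]:
    """All shortest s→t paths by enumerating every simple path."""
    best: list[list] = []
    best_len = [float("inf")]

    def dfs(v, path, seen):
        if len(path) - 1 > best_len[0]:
            return
        if v == t:
            if len(path) - 1 < best_len[0]:
                best_len[0] = len(path) - 1
                best.clear()
            if len(path) - 1 == best_len[0]:
                best.append(list(path))
            return
        for w in sorted(adj[v], key=str):
            if w not in seen:
                path.append(w)
                seen.add(w)
                dfs(w, path, seen)
                seen.remove(w)
                path.pop()

    dfs(s, [s], {s})
    return sorted(best)


# ---------------------------------------------------------------------------
# exhaustive Kuratowski-subdivision search (small graphs)
# ---------------------------------------------------------------------------


def _disjoint_paths(adj: dict, pairs: list, branch: set, interior_pool: set) -> bool:
    """Can all endpoint pairs be joined by internally vertex-disjoint paths?

    Branch vertices are usable only as endpoints; interior vertices come from
    the shared pool and each may serve at most one path.  Backtracking.
    """
    if not pairs:
        return True
    a, b = pairs[0]

    def paths_from(v, used, path):
        if b in adj[v]:
            yield list(path)
        for w in sorted(adj[v] - branch, key=str):
            if w in interior_pool and w not in used:
                used.add(w)
                path.append(w)
                yield from paths_from(w, used, path)
                path.pop()
                used.remove(w)

    for interior in paths_from(a, set(), []):
        remaining = interior_pool - set(interior)
        if _disjoint_paths(adj, pairs[1:], branch, remaining):
            return True
    return False


def has_kuratowski_subdivision(nodes: set, edges: set) -> bool:
    """True iff the graph contains a subdivision of K5 or K3,3 (exhaustive)."""
    adj = {n: set() for n in nodes}
    for e in edges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)
    node_list = sorted(nodes, key=str)
    # K5: five branch vertices of degree >= 4, all ten pairs joined
    for combo in itertools.combinations(node_list, 5):
        if any(len(adj[v]) < 4 for v in combo):
            continue
        branch = set(combo)
        pairs = list(itertools.combinations(combo, 2))
        if _disjoint_paths(adj, pairs, branch, nodes - branch):
            return True
    # K3,3: six branch vertices of degree >= 3, split into two parts of three
    for combo in itertools.combinations(node_list, 6):
        if any(len(adj[v]) < 3 for v in combo):
            continue
        rest = nodes - set(combo)
        first = combo[0]
        others = [v for v in combo if v != first]
        for part in itertools.combinations(others, 2):
            side_a = {first, *part}
            side_b = set(combo) - side_a
            pairs = [(a, b) for a in sorted(side_a, key=str) for b in sorted(side_b, key=str)]
            if _disjoint_paths(adj, pairs, set(combo), rest):
                return True
    return False


def planar_by_subdivision_search(nodes: set, edges: set) -> bool:
    return not has_kuratowski_subdivision(nodes, edges)


# ---------------------------------------------------------------------------
# dense Kirchhoff solve
# ---------------------------------------------------------------------------


def dense_flow_potentials(net, conductances: dict) -> dict:
    """Node potentials via a dense NumPy solve of the grounded Laplacian."""
    order = sorted(net.nodes)
    idx = {nid: i for i, nid in enumerate(order)}
    n = len(order)
    lap = np.zeros((n, n))
    for sid, s in net.segments.items():
        i, j, g = idx[s.u], idx[s.v], conductances[sid]
        lap[i, i] += g
        lap[j, j] += g
        lap[i, j] -= g
        lap[j, i] -= g
    b = np.zeros(n)
    b[idx[net.afferent]] = 1.0
    b[idx[net.efferent]] = -1.0
    ground = idx[net.efferent]
    lap[ground, :] = 0.0
    lap[ground, ground] = 1.0
    b[ground] = 0.0
    phi = np.linalg.solve(lap, b)
    return {nid: float(phi[idx[nid]]) for nid in order}


# ---------------------------------------------------------------------------
# random graph generation (shared by tests and acceptance)
# ---------------------------------------------------------------------------


def random_connected_graph(n: int, p: float, rng) -> tuple[set, set]:
    """Connected G(n, p): edges sampled, then a random spanning tree overlaid."""
    nodes = set(range(n))
    edges = set()
    order = list(range(n))
    rng.shuffle(order)
    for i in range(1, n):
        edges.add(frozenset((order[i], order[rng.randrange(i)])))
    for a, b in itertools.combinations(range(n), 2):
        if rng.random() < p:
            edges.add(frozenset((a, b)))
    return nodes, edges


def random_terminal_network(n: int, p: float, rng):
    """Random connected graph dressed up as a vascular network.

    Two fresh degree-1 terminals are attached to random distinct internal
    nodes; positions are random points in a 40 µm box.
    """
    from glomnet.model import (
        NodeRecord,
        ROLE_AFFERENT,
        ROLE_EFFERENT,
        SegmentRecord,
        VascularNetwork,
    )

    nodes, edges = random_connected_graph(n, p, rng)
    a_attach, e_attach = rng.sample(sorted(nodes), 2)
    recs = [
        NodeRecord(
            id=f"n{i:03d}",
            pos=(rng.uniform(-20, 20), rng.uniform(-20, 20), rng.uniform(-20, 20)),
        )
        for i in sorted(nodes)
    ]
    recs.append(NodeRecord(id="A", pos=(-25.0, 0.0, 25.0), role=ROLE_AFFERENT))
    recs.append(NodeRecord(id="E", pos=(25.0, 0.0, 25.0), role=ROLE_EFFERENT))
    segs = [
        SegmentRecord(id=f"s{k:03d}", u=f"n{min(e):03d}", v=f"n{max(e):03d}")
        for k, e in enumerate(sorted(edges, key=lambda e: sorted(e)))
    ]
    segs.append(SegmentRecord(id="sA", u="A", v=f"n{a_attach:03d}"))
    segs.append(SegmentRecord(id="sE", u="E", v=f"n{e_attach:03d}"))
    return VascularNetwork.from_records(recs, segs)
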