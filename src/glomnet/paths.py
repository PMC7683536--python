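"""Shortest-path analysis by adjacency-matrix powers and derived statistics.

The geodesic length between the arteriole terminals is found by repeatedly
multiplying the boolean adjacency matrix by itself over the OR/AND semiring
until the (afferent, efferent) entry becomes true; all geodesics are then
enumerated by backtracking from the efferent terminal through strictly
descending hop distance.  Hop distances also induce the afferent/efferent
side partition, the no-cross-zone count and the vascular-pole localization
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import InternalError, InvalidValueError, PathExplosionError
from .model import PoleFrame, VascularNetwork

SIDE_AFFERENT = "afferent"
SIDE_EFFERENT = "efferent"
SIDE_BOUNDARY = "boundary"


@dataclass
class DistanceField:
    """Hop distances from the afferent and efferent terminals to every node."""

    d_aff: dict[str, int]
    d_eff: dict[str, int]


@dataclass
class ShortestPathSet:
    """All afferent→efferent geodesics of a network.

    ``length`` counts segments; the interior-node count is ``length - 1``.
    ``edge_set`` holds every segment lying on at least one geodesic.
    """

    length: int
    paths: list[list[str]]
    edge_set: set[str]


@dataclass
class SideAssignment:
    side: dict[str, str]


def shortest_path_length_matrix(net: VascularNetwork) -> int:
    """Geodesic length by boolean adjacency-matrix powers.

    Returns the smallest k for which A^k (over the OR/AND semiring, so
    parallel segments count once and entries cannot overflow) has a nonzero
    (afferent, efferent) entry; equal to the breadth-first-search distance.
    """
    order = net.sorted_node_ids()
    idx = {nid: i for i, nid in enumerate(order)}
    a = net.boolean_adjacency(order)
    i, j = idx[net.afferent], idx[net.efferent]
    reach = a.copy()
    for k in range(1, len(order) + 1):
        if reach[i, j]:
            return k
        # boolean semiring product: integer matmul collapsed back to {0, 1}
        reach = (reach.astype(np.int64) @ a.astype(np.int64)) > 0
    raise InternalError("terminals not connected by any power of the adjacency matrix")


def distance_field(net: VascularNetwork) -> DistanceField:
    """Exact hop distances from both terminals (unweighted breadth-first)."""
    order = net.sorted_node_ids()
    idx = {nid: i for i, nid in enumerate(order)}
    a = csr_matrix(net.boolean_adjacency(order).astype(np.int8))
    d = dijkstra(
        a, unweighted=True, indices=[idx[net.afferent], idx[net.efferent]]
    )
    if not np.all(np.isfinite(d)):
        raise InternalError("distance field undefined: graph not connected")
    d = d.astype(int)
    return DistanceField(
        d_aff={nid: int(d[0, idx[nid]]) for nid in order},
        d_eff={nid: int(d[1, idx[nid]]) for nid in order},
    )


def extract_shortest_paths(
    net: VascularNetwork, field: DistanceField, max_paths: int = 10_000
) -> ShortestPathSet:
    """Enumerate every geodesic by backtracking from the efferent terminal.

    Predecessors of a node are its neighbors one hop-layer closer to the
    afferent terminal; the enumeration is depth-first in lexicographic node-id
    order, so the output order is deterministic.  The geodesic count is
    checked against ``max_paths`` (by dynamic programming) before any path is
    materialized.
    """
    length = field.d_aff[net.efferent]
    adj = net.adjacency()
    neighbors: dict[str, list[str]] = {
        nid: sorted({nb for nb, _ in adj[nid]}) for nid in net.nodes
    }
    # geodesic counts via the DAG of descending d_aff
    count: dict[str, int] = {net.afferent: 1}

    def n_paths_to(v: str) -> int:
        if v not in count:
            count[v] = sum(
                n_paths_to(p)
                for p in neighbors[v]
                if field.d_aff[p] == field.d_aff[v] - 1
            )
        return count[v]

    total = n_paths_to(net.efferent)
    if total > max_paths:
        raise PathExplosionError(
            f"{total} geodesics exceed the cap of {max_paths}; "
            "use the edge_set (on-geodesic segments) instead of full enumeration"
        )

    paths: list[list[str]] = []
    stack = [net.efferent]

    def backtrack(v: str) -> None:
        if v == net.afferent:
            paths.append(list(reversed(stack)))
            return
        for p in neighbors[v]:
            if field.d_aff[p] == field.d_aff[v] - 1:
                stack.append(p)
                backtrack(p)
                stack.pop()

    backtrack(net.efferent)
    paths.sort()
    edge_set = {
        sid
        for sid, s in net.segments.items()
        if through_path_length(net, field, sid) == length
    }
    return ShortestPathSet(length=length, paths=paths, edge_set=edge_set)


def through_path_length(
    net: VascularNetwork, field: DistanceField, segment_id: str
) -> int:
    """Length of the shortest terminal-to-terminal path forced through a segment."""
    s = net.segments[segment_id]
    return min(
        field.d_aff[s.u] + 1 + field.d_eff[s.v],
        field.d_aff[s.v] + 1 + field.d_eff[s.u],
    )


def side_assignment(net: VascularNetwork, field: DistanceField) -> SideAssignment:
    """Partition nodes into afferent side, efferent side, and boundary (ties)."""
    side = {}
    for nid in net.nodes:
        da, de = field.d_aff[nid], field.d_eff[nid]
        if da < de:
            side[nid] = SIDE_AFFERENT
        elif da > de:
            side[nid] = SIDE_EFFERENT
        else:
            side[nid] = SIDE_BOUNDARY
    return SideAssignment(side=side)


def no_cross_zone_score(
    net: VascularNetwork, field: DistanceField, frame: PoleFrame
) -> dict:
    """Count capillaries bridging the two sides within the vascular half.

    A segment crosses when its endpoints carry strictly opposite (non-boundary)
    side labels; it violates the no-cross zone when its midpoint additionally
    lies on the vascular-pole side of the centroid.  A connection there would
    let blood reach the efferent arteriole without traversing the filtering
    tuft.  ``score`` is the violating fraction of all cross segments (0 when
    there are none).
    """
    sides = side_assignment(net, field).side
    n_cross_total = 0
    n_cross_vascular = 0
    for sid, s in net.segments.items():
        pair = {sides[s.u], sides[s.v]}
        if pair == {SIDE_AFFERENT, SIDE_EFFERENT}:
            n_cross_total += 1
            mid = net.segment_midpoint(sid)
            if float(np.dot(mid - frame.centroid, frame.pole_axis)) > 0:
                n_cross_vascular += 1
    score = n_cross_vascular / n_cross_total if n_cross_total else 0.0
    return {
        "n_cross_vascular": n_cross_vascular,
        "n_cross_total": n_cross_total,
        "score": score,
    }


def pole_localization(
    paths: ShortestPathSet, net: VascularNetwork, frame: PoleFrame
) -> float:
    """Fraction of interior geodesic nodes on the vascular-pole side."""
    if not paths.paths:
        raise InvalidValueError("pole_localization requires a nonempty geodesic set")
    interior: set[str] = set()
    for p in paths.paths:
        interior.update(p[1:-1])
    if not interior:
        return 0.0
    above = sum(
        1
        for nid in interior
        if float(np.dot(net.pos(nid) - frame.centroid, frame.pole_axis)) > 0
    )
    return above / len(interior)
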