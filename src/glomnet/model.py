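"""Data model, validation, file I/O and graph simplification for capillary networks.

A glomerular capillary network is a geometric multigraph: nodes are branch
points with 3D positions (µm), segments are capillaries joining them, and two
special degree-1 terminals mark where the afferent arteriole enters and the
efferent arteriole exits the tuft.  Parallel segments between the same pair of
branch points are allowed (longitudinal splitting produces them); self-loops
are not.
"""

from __future__ import annotations

import io
import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeometryError,
    DisconnectedNetworkError,
    DuplicateIdError,
    InvalidValueError,
    NonFiniteCoordinateError,
    SelfLoopError,
    TerminalCountError,
    TerminalDegreeError,
    UnknownNodeError,
)

ROLE_AFFERENT = "afferent_terminal"
ROLE_EFFERENT = "efferent_terminal"
ROLE_INTERNAL = "internal"
ROLES = (ROLE_AFFERENT, ROLE_EFFERENT, ROLE_INTERNAL)

REPORT_SCHEMA = "glomnet-report-1"


@dataclass(frozen=True)
class NodeRecord:
    """A branch point (or arteriole terminal) with a 3D position in µm."""

    id: str
    pos: tuple[float, float, float]
    role: str = ROLE_INTERNAL


@dataclass(frozen=True)
class SegmentRecord:
    """A capillary segment joining nodes ``u`` and ``v``.

    ``radius`` and ``length`` are in µm and optional; a missing length is
    taken as the straight-line distance between the endpoint positions
    (tortuosity ignored).  ``area`` is an optional directly measured
    cross-sectional area (µm²) which, when present, takes precedence over
    ``π·radius²`` in morphometry.
    """

    id: str
    u: str
    v: str
    radius: float | None = None
    length: float | None = None
    area: float | None = None


@dataclass
class PoleFrame:
    """Orientation frame: centroid, vascular-pole axis and cleft normal."""

    centroid: np.ndarray
    pole_axis: np.ndarray
    cleft_normal: np.ndarray


@dataclass
class VascularNetwork:
    """Validated capillary multigraph with designated terminals."""

    nodes: dict[str, NodeRecord]
    segments: dict[str, SegmentRecord]
    afferent: str
    efferent: str

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        nodes: Iterable[NodeRecord],
        segments: Iterable[SegmentRecord],
        validate: bool = True,
    ) -> "VascularNetwork":
        node_map: dict[str, NodeRecord] = {}
        for n in nodes:
            if n.id in node_map:
                raise DuplicateIdError(f"duplicate node id {n.id!r}")
            node_map[n.id] = n
        seg_map: dict[str, SegmentRecord] = {}
        for s in segments:
            if s.id in seg_map:
                raise DuplicateIdError(f"duplicate segment id {s.id!r}")
            seg_map[s.id] = s
        aff = [n.id for n in node_map.values() if n.role == ROLE_AFFERENT]
        eff = [n.id for n in node_map.values() if n.role == ROLE_EFFERENT]
        if len(aff) != 1 or len(eff) != 1:
            raise TerminalCountError(
                f"need exactly one afferent and one efferent terminal, "
                f"found afferent={aff!r} efferent={eff!r}"
            )
        net = cls(node_map, seg_map, aff[0], eff[0])
        if validate:
            net.validate()
        return net

    # -- basic accessors --------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def pos(self, node_id: str) -> np.ndarray:
        return np.asarray(self.nodes[node_id].pos, dtype=float)

    def positions(self) -> np.ndarray:
        """(n, 3) array in sorted-node-id order."""
        return np.array([self.nodes[i].pos for i in self.sorted_node_ids()])

    def sorted_node_ids(self) -> list[str]:
        return sorted(self.nodes)

    def sorted_segment_ids(self) -> list[str]:
        return sorted(self.segments)

    def segment_length(self, seg_id: str) -> float:
        s = self.segments[seg_id]
        if s.length is not None:
            return s.length
        return float(np.linalg.norm(self.pos(s.u) - self.pos(s.v)))

    def segment_midpoint(self, seg_id: str) -> np.ndarray:
        s = self.segments[seg_id]
        return 0.5 * (self.pos(s.u) + self.pos(s.v))

    def adjacency(self) -> dict[str, list[tuple[str, str]]]:
        """node id -> list of (neighbor id, segment id), sorted for determinism."""
        adj: dict[str, list[tuple[str, str]]] = {nid: [] for nid in self.nodes}
        for sid in self.sorted_segment_ids():
            s = self.segments[sid]
            adj[s.u].append((s.v, sid))
            adj[s.v].append((s.u, sid))
        for nid in adj:
            adj[nid].sort()
        return adj

    def degree(self, node_id: str) -> int:
        d = 0
        for s in self.segments.values():
            if s.u == node_id:
                d += 1
            if s.v == node_id:
                d += 1
        return d

    def copy(self) -> "VascularNetwork":
        return VascularNetwork(
            dict(self.nodes), dict(self.segments), self.afferent, self.efferent
        )

    def boolean_adjacency(self, order: list[str] | None = None) -> np.ndarray:
        """Boolean adjacency matrix (parallel segments count once)."""
        order = order or self.sorted_node_ids()
        idx = {nid: i for i, nid in enumerate(order)}
        a = np.zeros((len(order), len(order)), dtype=bool)
        for s in self.segments.values():
            i, j = idx[s.u], idx[s.v]
            a[i, j] = a[j, i] = True
        return a

    # -- validation -------------------------------------------------------

    def validate(self) -> "VascularNetwork":
        """Check every structural invariant; raise a named error otherwise."""
        for n in self.nodes.values():
            if n.role not in ROLES:
                raise InvalidValueError(f"node {n.id!r}: unknown role {n.role!r}")
            if len(n.pos) != 3 or not all(math.isfinite(c) for c in n.pos):
                raise NonFiniteCoordinateError(
                    f"node {n.id!r}: non-finite position {n.pos!r}"
                )
        for s in self.segments.values():
            for endpoint in (s.u, s.v):
                if endpoint not in self.nodes:
                    raise UnknownNodeError(
                        f"segment {s.id!r} references unknown node {endpoint!r}"
                    )
            if s.u == s.v:
                raise SelfLoopError(f"segment {s.id!r} is a self-loop at {s.u!r}")
            if s.radius is not None and not s.radius > 0:
                raise InvalidValueError(
                    f"segment {s.id!r}: radius must be > 0, got {s.radius!r}"
                )
            if s.length is not None and not s.length > 0:
                raise InvalidValueError(
                    f"segment {s.id!r}: length must be > 0, got {s.length!r}"
                )
        aff = [n.id for n in self.nodes.values() if n.role == ROLE_AFFERENT]
        eff = [n.id for n in self.nodes.values() if n.role == ROLE_EFFERENT]
        if len(aff) != 1 or len(eff) != 1 or aff[0] == eff[0]:
            raise TerminalCountError(
                f"need exactly one afferent and one efferent terminal "
                f"(distinct), found afferent={aff!r} efferent={eff!r}"
            )
        if (self.afferent, self.efferent) != (aff[0], eff[0]):
            raise TerminalCountError(
                "terminal designation disagrees with node roles"
            )
        for tid in (self.afferent, self.efferent):
            if self.degree(tid) != 1:
                raise TerminalDegreeError(
                    f"terminal {tid!r} has degree {self.degree(tid)}, must be 1"
                )
        # connectivity by traversal over the adjacency map
        if self.nodes:
            adj = self.adjacency()
            seen = {self.afferent}
            stack = [self.afferent]
            while stack:
                cur = stack.pop()
                for nb, _ in adj[cur]:
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            if len(seen) != len(self.nodes):
                missing = sorted(set(self.nodes) - seen)
                raise DisconnectedNetworkError(
                    f"graph is disconnected; unreachable nodes {missing[:5]!r}"
                    + ("…" if len(missing) > 5 else "")
                )
        return self


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

NODE_COLUMNS = ["id", "x", "y", "z", "role"]
SEGMENT_COLUMNS = ["id", "u", "v", "radius", "length"]


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype={"id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidValueError(
            f"{path}: missing required columns {missing!r} (have {list(df.columns)!r})"
        )
    return df


def read_network(node_table: str | Path, segment_table: str | Path) -> VascularNetwork:
    """Read and validate a network from delimited node and segment tables.

    The node table has header ``id,x,y,z,role`` and the segment table
    ``id,u,v,radius,length`` (an optional ``area`` column is honored);
    radius/length may be blank.  All invariants are checked; a violation
    raises a named :class:`~glomnet.errors.ValidationError` subclass that
    identifies the offending record.
    """
    ndf = _read_table(node_table, NODE_COLUMNS)
    sdf = _read_table(segment_table, SEGMENT_COLUMNS)
    nodes = [
        NodeRecord(
            id=str(r.id),
            pos=(float(r.x), float(r.y), float(r.z)),
            role=str(r.role),
        )
        for r in ndf.itertuples()
    ]

    def _opt(value) -> float | None:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        return float(value)

    segments = [
        SegmentRecord(
            id=str(r.id),
            u=str(r.u),
            v=str(r.v),
            radius=_opt(r.radius),
            length=_opt(r.length),
            area=_opt(getattr(r, "area", None)),
        )
        for r in sdf.itertuples()
    ]
    return VascularNetwork.from_records(nodes, segments)


def write_network(
    net: VascularNetwork, node_table: str | Path, segment_table: str | Path
) -> None:
    """Write node and segment tables; ``read_network`` round-trips losslessly."""
    ndf = pd.DataFrame(
        [
            {
                "id": n.id,
                "x": repr(float(n.pos[0])),
                "y": repr(float(n.pos[1])),
                "z": repr(float(n.pos[2])),
                "role": n.role,
            }
            for n in (net.nodes[i] for i in net.sorted_node_ids())
        ]
    )
    has_area = any(s.area is not None for s in net.segments.values())
    rows = []
    for sid in net.sorted_segment_ids():
        s = net.segments[sid]
        row = {
            "id": s.id,
            "u": s.u,
            "v": s.v,
            "radius": "" if s.radius is None else repr(float(s.radius)),
            "length": "" if s.length is None else repr(float(s.length)),
        }
        if has_area:
            row["area"] = "" if s.area is None else repr(s.area)
        rows.append(row)
    sdf = pd.DataFrame(rows)
    ndf.to_csv(node_table, index=False)
    sdf.to_csv(segment_table, index=False)


# ---------------------------------------------------------------------------
# simplification
# ---------------------------------------------------------------------------


def simplify_topology(
    net_or_graph: "VascularNetwork | tuple[set, set]",
    protected: set[str] | None = None,
) -> tuple[set[str], set[frozenset]]:
    """Reduce a network to a simple graph with the same planarity status.

    Iterates to a fixed point: drop self-loops, collapse parallel edges,
    smooth internal degree-2 vertices (x–y–z becomes x–z) and prune internal
    degree-1 vertices.  The two terminals are never smoothed or pruned.  Each
    operation preserves planarity in both directions, so the verdict of the
    planarity test is unchanged.
    """
    if isinstance(net_or_graph, VascularNetwork):
        nodes = set(net_or_graph.nodes)
        edges = {
            frozenset((s.u, s.v))
            for s in net_or_graph.segments.values()
            if s.u != s.v
        }
        protected = {net_or_graph.afferent, net_or_graph.efferent} | (protected or set())
    else:
        raw_nodes, raw_edges = net_or_graph
        nodes = set(raw_nodes)
        edges = {frozenset(e) for e in raw_edges if len(frozenset(e)) == 2}
        protected = set(protected or ())

    changed = True
    while changed:
        changed = False
        adj: dict[str, set[str]] = {n: set() for n in nodes}
        for e in edges:
            a, b = tuple(e)
            adj[a].add(b)
            adj[b].add(a)
        for n in sorted(nodes):
            if n in protected or n not in adj:
                continue
            nbrs = adj[n]
            if len(nbrs) == 1:
                (x,) = nbrs
                edges.discard(frozenset((n, x)))
                nodes.discard(n)
                adj[x].discard(n)
                del adj[n]
                changed = True
            elif len(nbrs) == 2:
                x, y = sorted(nbrs)
                edges.discard(frozenset((n, x)))
                edges.discard(frozenset((n, y)))
                nodes.discard(n)
                adj[x].discard(n)
                adj[y].discard(n)
                del adj[n]
                if x != y:
                    if frozenset((x, y)) not in edges:
                        edges.add(frozenset((x, y)))
                        adj[x].add(y)
                        adj[y].add(x)
                changed = True
    return nodes, edges


# ---------------------------------------------------------------------------
# orientation frame
# ---------------------------------------------------------------------------


def pole_frame(net: VascularNetwork) -> PoleFrame:
    """Compute the orientation frame of a tuft.

    ``centroid`` is the mean node position; ``pole_axis`` points from the
    centroid toward the midpoint of the two arteriole terminals (the vascular
    pole is where both arterioles attach); ``cleft_normal`` is the
    afferent→efferent direction orthogonalized against ``pole_axis``.
    """
    centroid = net.positions().mean(axis=0)
    p_aff = net.pos(net.afferent)
    p_eff = net.pos(net.efferent)
    mid = 0.5 * (p_aff + p_eff)
    axis = mid - centroid
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise DegenerateGeometryError(
            "terminal midpoint coincides with the network centroid"
        )
    pole_axis = axis / norm
    cleft = p_eff - p_aff
    if np.linalg.norm(cleft) < 1e-9:
        raise DegenerateGeometryError("afferent and efferent terminals coincide")
    cleft = cleft - np.dot(cleft, pole_axis) * pole_axis
    cnorm = np.linalg.norm(cleft)
    if cnorm < 1e-9:
        raise DegenerateGeometryError(
            "afferent–efferent direction is parallel to the pole axis"
        )
    return PoleFrame(centroid=centroid, pole_axis=pole_axis, cleft_normal=cleft / cnorm)


# ---------------------------------------------------------------------------
# report / GraphML export
# ---------------------------------------------------------------------------


def write_report(report: Mapping, path: str | Path) -> None:
    """Write a JSON report stamped with the versioned schema id."""
    payload = {"schema": REPORT_SCHEMA}
    payload.update(report)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def check_report_schema(payload: Mapping) -> bool:
    """Minimal structural check: schema stamp present and keys are strings."""
    return payload.get("schema") == REPORT_SCHEMA and all(
        isinstance(k, str) for k in payload
    )


_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"

# yEd-compatible plain data keys: one <key> element per attribute, attr.name
# set to the column name used in the node/segment tables.
_NODE_KEYS = [("x", "double"), ("y", "double"), ("z", "double"), ("role", "string")]
_EDGE_KEYS = [("radius", "double"), ("length", "double")]


def write_graphml(net: VascularNetwork, path: str | Path) -> None:
    """Export the network as GraphML with positions, roles and radii."""
    ET.register_namespace("", _GRAPHML_NS)
    root = ET.Element(f"{{{_GRAPHML_NS}}}graphml")
    for i, (name, typ) in enumerate(_NODE_KEYS):
        ET.SubElement(
            root,
            f"{{{_GRAPHML_NS}}}key",
            id=f"dn{i}",
            attrib={"for": "node", "attr.name": name, "attr.type": typ},
        )
    for i, (name, typ) in enumerate(_EDGE_KEYS):
        ET.SubElement(
            root,
            f"{{{_GRAPHML_NS}}}key",
            id=f"de{i}",
            attrib={"for": "edge", "attr.name": name, "attr.type": typ},
        )
    graph = ET.SubElement(
        root, f"{{{_GRAPHML_NS}}}graph", id="glomerulus", edgedefault="undirected"
    )
    for nid in net.sorted_node_ids():
        n = net.nodes[nid]
        el = ET.SubElement(graph, f"{{{_GRAPHML_NS}}}node", id=nid)
        values = [repr(n.pos[0]), repr(n.pos[1]), repr(n.pos[2]), n.role]
        for i, val in enumerate(values):
            d = ET.SubElement(el, f"{{{_GRAPHML_NS}}}data", key=f"dn{i}")
            d.text = val
    for sid in net.sorted_segment_ids():
        s = net.segments[sid]
        el = ET.SubElement(
            graph, f"{{{_GRAPHML_NS}}}edge", id=sid, source=s.u, target=s.v
        )
        for i, val in enumerate([s.radius, s.length]):
            if val is not None:
                d = ET.SubElement(el, f"{{{_GRAPHML_NS}}}data", key=f"de{i}")
                d.text = repr(val)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")
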