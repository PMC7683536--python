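"""Shared fixtures: small hand-built networks with known properties."""

from __future__ import annotations

import math

import pytest

from glomnet.model import (
    NodeRecord,
    ROLE_AFFERENT,
    ROLE_EFFERENT,
    SegmentRecord,
    VascularNetwork,
)


def build_network(node_positions: dict, edges: list, afferent="A", efferent="E"):
    """Network from {id: (x,y,z)} and [(u, v)] or [(u, v, radius)]."""
    nodes = []
    for nid, pos in node_positions.items():
        role = (
            ROLE_AFFERENT
            if nid == afferent
            else ROLE_EFFERENT
            if nid == efferent
            else "internal"
        )
        nodes.append(NodeRecord(id=nid, pos=tuple(float(c) for c in pos), role=role))
    segs = []
    for k, e in enumerate(edges):
        u, v = e[0], e[1]
        radius = e[2] if len(e) > 2 else None
        segs.append(SegmentRecord(id=f"s{k:03d}", u=u, v=v, radius=radius))
    return VascularNetwork.from_records(nodes, segs)


@pytest.fixture
def chain_net():
    """A–n1–n2–E series chain."""
    return build_network(
        {"A": (0, 0, 0), "n1": (1, 0, 0), "n2": (2, 0, 0), "E": (3, 0, 0)},
        [("A", "n1"), ("n1", "n2"), ("n2", "E")],
    )


@pytest.fixture
def diamond_net():
    """A–a, then two equal 2-segment arms a–b–d and a–c–d, then d–E."""
    return build_network(
        {
            "A": (0, 0, 0),
            "a": (1, 0, 0),
            "b": (2, 1, 0),
            "c": (2, -1, 0),
            "d": (3, 0, 0),
            "E": (4, 0, 0),
        },
        [("A", "a"), ("a", "b"), ("a", "c"), ("b", "d"), ("c", "d"), ("d", "E")],
    )


@pytest.fixture
def wheatstone_net():
    """Balanced Wheatstone bridge: the bridge segment carries zero current."""
    return build_network(
        {
            "A": (0, 0, 0),
            "L": (1, 0, 0),
            "t": (2, 1, 0),
            "b": (2, -1, 0),
            "R": (3, 0, 0),
            "E": (4, 0, 0),
        },
        [
            ("A", "L"),
            ("L", "t"),
            ("L", "b"),
            ("t", "R"),
            ("b", "R"),
            ("t", "b"),  # bridge
            ("R", "E"),
        ],
    )


def ladder_network(n_rungs: int) -> VascularNetwork:
    """Symmetric ladder: two rails joined at junctions L and R, n interior rungs."""
    positions = {"A": (-2, 0, 0), "L": (-1, 0, 0)}
    edges = [("A", "L")]
    prev_t, prev_b = "L", "L"
    for i in range(n_rungs):
        positions[f"t{i}"] = (i, 1, 0)
        positions[f"b{i}"] = (i, -1, 0)
        edges += [(prev_t, f"t{i}"), (prev_b, f"b{i}"), (f"t{i}", f"b{i}")]
        prev_t, prev_b = f"t{i}", f"b{i}"
    positions["R"] = (n_rungs, 0, 0)
    positions["E"] = (n_rungs + 1, 0, 0)
    edges += [(prev_t, "R"), (prev_b, "R"), ("R", "E")]
    return build_network(positions, edges)


@pytest.fixture
def toy_net():
    """Toy glomerulus: 20 nodes, 28 segments, constructed (not measured data).

    Two concentric octagons in the x–z plane joined by four rungs, plus two
    off-plane nodes on the urinary side; afferent attaches at 135°, efferent
    at 45°, so the vascular pole is +z.
    """
    positions = {}
    edges = []
    for i in range(8):
        a = math.pi * i / 4
        positions[f"O{i}"] = (20 * math.cos(a), 0.0, 20 * math.sin(a))
        positions[f"I{i}"] = (10 * math.cos(a), 0.0, 10 * math.sin(a))
    for i in range(8):
        edges.append((f"O{i}", f"O{(i + 1) % 8}"))
        edges.append((f"I{i}", f"I{(i + 1) % 8}"))
    for i in (0, 2, 4, 6):
        edges.append((f"O{i}", f"I{i}"))
    positions["X"] = (-10.0, 4.0, -14.0)
    positions["Y"] = (8.0, -4.0, -10.0)
    edges += [("X", "O4"), ("X", "I4"), ("X", "O6")]
    edges += [("Y", "I6"), ("Y", "O6"), ("Y", "I0")]
    positions["A"] = (-19.09, 0.0, 19.09)
    positions["E"] = (19.09, 0.0, 19.09)
    edges += [("A", "O3"), ("E", "O1")]
    net = build_network(positions, edges)
    assert net.n_nodes == 20 and net.n_segments == 28
    return net


@pytest.fixture
def toy_tables(toy_net, tmp_path):
    from glomnet.model import write_network

    nodes = tmp_path / "toy.nodes.csv"
    segs = tmp_path / "toy.segments.csv"
    write_network(toy_net, nodes, segs)
    return nodes, segs
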