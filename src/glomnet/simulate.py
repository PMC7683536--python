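"""Generative simulator of glomerular capillary development.

The tuft starts as a single capillary loop between the two arterioles and
grows by three branching mechanisms: longitudinal splitting of a vessel
(intussusception), sprouting from one vessel onto a nearby one
(angiogenesis), and condensation of precursor cells into a bridging vessel
(vasculogenesis).  Growth can be biased toward the urinary pole, and an
optional physical barrier — an idealized mesangial structure spanning the
cleft between afferent and efferent branches on the vascular-pole side —
blocks any event that would bridge that cleft and short-circuit filtration.

Splitting alone provably preserves planarity; sprouting and condensation can
connect distant vessels and make the network nonplanar, which is what makes
the simulated tufts glomerulus-like.

Every simulation is driven by one seeded NumPy Generator (PCG64) with a
documented draw order (event kind, then locations, then jitters), and emits
a replayable :class:`EventLog`: applying the logged structural edits to the
initial loop reconstructs the final network exactly.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .errors import InvalidValueError
from .flow import FlowSolution
from .model import (
    NodeRecord,
    PoleFrame,
    ROLE_AFFERENT,
    ROLE_EFFERENT,
    ROLE_INTERNAL,
    SegmentRecord,
    VascularNetwork,
    pole_frame,
)
from .paths import distance_field, no_cross_zone_score, shortest_path_length_matrix

_JITTER_SD = 0.5  # µm positional jitter on every new branch point


def _t3(p) -> tuple[float, float, float]:
    x, y, z = p
    return (float(x), float(y), float(z))


@dataclass(frozen=True)
class GrowthConfig:
    """Parameters of a simulated growth run.

    Probabilities ``p_split``/``p_sprout``/``p_condense`` must sum to 1.
    ``pole_bias`` (β ≥ 0) sets how strongly events prefer the urinary pole:
    event sites are weighted ∝ exp(β·depth) with depth the distance below the
    centroid along the pole axis, normalized by ``loop_radius`` so β is
    dimensionless.  ``d_max`` is the locality radius for sprout/condense
    partner vessels (default: the loop radius).  Radii follow a Murray-
    type law r = r0·|flow|^γ with multiplicative Gaussian noise.
    """

    n_loop: int = 8
    n_events: int = 60
    p_split: float = 1 / 3
    p_sprout: float = 1 / 3
    p_condense: float = 1 / 3
    barrier: bool = True
    pole_bias: float = 2.0
    d_max: float | None = None
    loop_radius: float = 20.0
    seed: int = 0
    radius_r0: float = 3.0
    murray_exponent: float = 1 / 3
    radius_noise_sd: float = 0.05

    def __post_init__(self):
        if self.n_loop < 4:
            raise InvalidValueError(f"n_loop must be >= 4, got {self.n_loop}")
        if self.n_events < 0:
            raise InvalidValueError("n_events must be >= 0")
        probs = (self.p_split, self.p_sprout, self.p_condense)
        if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1) > 1e-12:
            raise InvalidValueError(
                f"event probabilities must lie in [0,1] and sum to 1, got {probs}"
            )
        if self.loop_radius <= 0 or self.radius_r0 <= 0:
            raise InvalidValueError("loop_radius and radius_r0 must be positive")
        if self.pole_bias < 0 or self.radius_noise_sd < 0:
            raise InvalidValueError("pole_bias and radius_noise_sd must be >= 0")

    @property
    def effective_d_max(self) -> float:
        # default allows sprouts between neighboring arcs of the initial loop
        # (adjacent segment midpoints sit ~0.7·loop_radius apart) while still
        # forbidding tuft-spanning long-range connections
        return self.loop_radius if self.d_max is None else self.d_max

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GrowthConfig":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class LogEntry:
    """One growth event: the structural edit it applied (empty if not applied)."""

    index: int
    kind: str  # split | sprout | condense, with _blocked / _skipped suffixes
    segments: tuple[str, ...] = ()  # pre-existing segments involved
    removed_segments: tuple[str, ...] = ()
    new_nodes: tuple[tuple[str, tuple[float, float, float]], ...] = ()
    new_segments: tuple[tuple[str, str, str], ...] = ()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LogEntry":
        return cls(
            index=d["index"],
            kind=d["kind"],
            segments=tuple(d["segments"]),
            removed_segments=tuple(d["removed_segments"]),
            new_nodes=tuple((nid, tuple(pos)) for nid, pos in d["new_nodes"]),
            new_segments=tuple(tuple(s) for s in d["new_segments"]),
        )


@dataclass
class EventLog:
    config: GrowthConfig
    entries: list[LogEntry] = field(default_factory=list)

    def to_jsonl(self) -> str:
        lines = [json.dumps({"config": asdict(self.config)}, sort_keys=True)]
        lines += [json.dumps(e.to_dict(), sort_keys=True) for e in self.entries]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_jsonl(cls, text: str) -> "EventLog":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        config = GrowthConfig(**json.loads(lines[0])["config"])
        return cls(config, [LogEntry.from_dict(json.loads(ln)) for ln in lines[1:]])


# ---------------------------------------------------------------------------
# initial loop
# ---------------------------------------------------------------------------


def init_loop(config: GrowthConfig) -> VascularNetwork:
    """Single capillary loop with both arterioles attached on the vascular side.

    ``n_loop`` branch points sit on a circle of ``loop_radius`` in the plane
    spanned by the pole axis (0,0,1) and the cleft normal (1,0,0); the
    vascular pole is +z.  The afferent terminal attaches to the loop node
    nearest the (−1,0,+1) direction and the efferent nearest (+1,0,+1).  The
    efferent attachment is additionally chosen (when possible without leaving
    the vascular side) so that an odd number of loop nodes separates the two
    attachments over the apex: the middle one is then equidistant from both
    terminals, i.e. the initial cleft is a hop-distance boundary and the loop
    starts with an intact no-cross zone.
    """
    n, r = config.n_loop, config.loop_radius
    angles = [2 * math.pi * i / n for i in range(n)]
    pos = [(r * math.cos(a), 0.0, r * math.sin(a)) for a in angles]
    dir_a = np.array([-1.0, 0.0, 1.0]) / math.sqrt(2)
    dir_e = np.array([1.0, 0.0, 1.0]) / math.sqrt(2)
    # round so symmetric ties break by index, not by floating-point noise
    dots_a = [round(float(np.dot(p, dir_a)), 9) for p in pos]
    dots_e = [round(float(np.dot(p, dir_e)), 9) for p in pos]
    i_a = max(range(n), key=lambda i: (dots_a[i], -i))
    order_e = sorted((j for j in range(n) if j != i_a), key=lambda j: (-dots_e[j], j))
    i_e = next(
        (j for j in order_e if (i_a - j) % n >= 2 and (i_a - j) % n % 2 == 0 and dots_e[j] > 0),
        order_e[0],
    )

    nodes = [
        NodeRecord(id=f"v{i:04d}", pos=pos[i], role=ROLE_INTERNAL) for i in range(n)
    ]
    p_a = _t3(np.asarray(pos[i_a]) + 0.35 * r * dir_a)
    p_e = _t3(np.asarray(pos[i_e]) + 0.35 * r * dir_e)
    nodes.append(NodeRecord(id="A", pos=p_a, role=ROLE_AFFERENT))
    nodes.append(NodeRecord(id="E", pos=p_e, role=ROLE_EFFERENT))
    segments = [
        SegmentRecord(id=f"s{i:04d}", u=f"v{i:04d}", v=f"v{(i + 1) % n:04d}")
        for i in range(n)
    ]
    segments.append(SegmentRecord(id=f"s{n:04d}", u="A", v=f"v{i_a:04d}"))
    segments.append(SegmentRecord(id=f"s{n + 1:04d}", u="E", v=f"v{i_e:04d}"))
    return VascularNetwork.from_records(nodes, segments)


# ---------------------------------------------------------------------------
# event helpers
# ---------------------------------------------------------------------------

_NUM = re.compile(r"(\d+)$")


def _fresh_ids(net: VascularNetwork, prefix: str, pool: dict, count: int) -> list[str]:
    top = -1
    for key in pool:
        m = _NUM.search(key)
        if m and key.startswith(prefix):
            top = max(top, int(m.group(1)))
    return [f"{prefix}{top + 1 + k:04d}" for k in range(count)]


def _eligible_segments(net: VascularNetwork) -> list[str]:
    """Internal segments: not incident to either arteriole terminal."""
    terms = {net.afferent, net.efferent}
    return sorted(
        sid for sid, s in net.segments.items() if not ({s.u, s.v} & terms)
    )


def _pole_weights(
    net: VascularNetwork, frame: PoleFrame, sids: list[str], config: GrowthConfig
) -> np.ndarray:
    depth = np.array(
        [
            -float(
                np.dot(net.segment_midpoint(sid) - frame.centroid, frame.pole_axis)
            )
            / config.loop_radius
            for sid in sids
        ]
    )
    w = np.exp(config.pole_bias * depth)
    return w / w.sum()


def _jitter(rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, _JITTER_SD, size=3)


def _perpendicular(direction: np.ndarray) -> np.ndarray:
    p = np.cross(direction, np.array([0.0, 1.0, 0.0]))
    if np.linalg.norm(p) < 1e-8:
        p = np.cross(direction, np.array([1.0, 0.0, 0.0]))
    return p / np.linalg.norm(p)


def _apply_entry(net: VascularNetwork, entry: LogEntry) -> VascularNetwork:
    """Apply the structural edit of a log entry (replay primitive)."""
    out = net.copy()
    for sid in entry.removed_segments:
        del out.segments[sid]
    for nid, p in entry.new_nodes:
        out.nodes[nid] = NodeRecord(id=nid, pos=tuple(p), role=ROLE_INTERNAL)
    for sid, u, v in entry.new_segments:
        out.segments[sid] = SegmentRecord(id=sid, u=u, v=v)
    return out


def _cross_segments_exist(net: VascularNetwork) -> bool:
    field = distance_field(net)
    frame = pole_frame(net)
    return no_cross_zone_score(net, field, frame)["n_cross_vascular"] > 0


def _barrier_veto(
    net_before: VascularNetwork, net_after: VascularNetwork, config: GrowthConfig
) -> bool:
    """Barrier rule: reject an event that creates a vascular-half cross segment.

    Only events can be vetoed, so an accepted state never has such a segment
    provided the initial loop has none (guaranteed by the attachment parity
    rule for the default even loop sizes).
    """
    if not config.barrier:
        return False
    return _cross_segments_exist(net_after) and not _cross_segments_exist(net_before)


def _connector_crosses_cleft(
    p1: np.ndarray, p2: np.ndarray, frame: PoleFrame
) -> bool:
    """Does the straight p1–p2 segment pierce the cleft plane in the vascular half?"""
    a = float(np.dot(p1 - frame.centroid, frame.cleft_normal))
    b = float(np.dot(p2 - frame.centroid, frame.cleft_normal))
    if a * b >= 0:
        return False
    crossing = p1 + (a / (a - b)) * (p2 - p1)
    return float(np.dot(crossing - frame.centroid, frame.pole_axis)) > 0


# ---------------------------------------------------------------------------
# the three branching events
# ---------------------------------------------------------------------------


def split_event(
    net: VascularNetwork,
    rng: np.random.Generator,
    config: GrowthConfig,
    index: int = 0,
) -> tuple[VascularNetwork, LogEntry]:
    """Intussusception: replace one vessel by two parallel subdivided copies.

    The chosen segment u–v becomes u–m1–v and u–m2–v with the new branch
    points offset to either side of the midpoint (+2 nodes, +3 segments).
    A subdivided parallel duplicate embeds in a face adjacent to the replaced
    edge, so splitting preserves planarity.
    """
    eligible = _eligible_segments(net)
    if not eligible:
        return net, LogEntry(index=index, kind="split_skipped")
    frame = pole_frame(net)
    sid = str(rng.choice(eligible, p=_pole_weights(net, frame, eligible, config)))
    s = net.segments[sid]
    pu, pv = net.pos(s.u), net.pos(s.v)
    direction = (pv - pu) / np.linalg.norm(pv - pu)
    perp = _perpendicular(direction)
    mid = 0.5 * (pu + pv)
    delta = 0.15 * float(np.linalg.norm(pv - pu))
    m1 = mid + delta * perp + _jitter(rng)
    m2 = mid - delta * perp + _jitter(rng)
    n1, n2 = _fresh_ids(net, "v", net.nodes, 2)
    e1, e2, e3, e4 = _fresh_ids(net, "s", net.segments, 4)
    entry = LogEntry(
        index=index,
        kind="split",
        segments=(sid,),
        removed_segments=(sid,),
        new_nodes=((n1, _t3(m1)), (n2, _t3(m2))),
        new_segments=((e1, s.u, n1), (e2, n1, s.v), (e3, s.u, n2), (e4, n2, s.v)),
    )
    out = _apply_entry(net, entry)
    if _barrier_veto(net, out, config):
        return net, replace(entry, kind="split_blocked", removed_segments=(),
                            new_nodes=(), new_segments=())
    return out, entry


def _pick_segment_pair(
    net: VascularNetwork,
    rng: np.random.Generator,
    config: GrowthConfig,
    frame: PoleFrame,
) -> tuple[str, str] | None:
    """Pole-biased nearby pair of internal vessels (midpoints within d_max)."""
    eligible = _eligible_segments(net)
    if len(eligible) < 2:
        return None
    s1 = str(rng.choice(eligible, p=_pole_weights(net, frame, eligible, config)))
    m1 = net.segment_midpoint(s1)
    candidates = [
        sid
        for sid in eligible
        if sid != s1
        and float(np.linalg.norm(net.segment_midpoint(sid) - m1)) <= config.effective_d_max
    ]
    if not candidates:
        return None
    s2 = str(rng.choice(candidates, p=_pole_weights(net, frame, candidates, config)))
    return s1, s2


def _subdivide_points(
    net: VascularNetwork, rng: np.random.Generator, s1: str, s2: str
) -> tuple[np.ndarray, np.ndarray]:
    pts = []
    for sid in (s1, s2):
        s = net.segments[sid]
        t = rng.uniform(0.25, 0.75)
        pts.append(net.pos(s.u) + t * (net.pos(s.v) - net.pos(s.u)) + _jitter(rng))
    return pts[0], pts[1]


def sprout_event(
    net: VascularNetwork,
    rng: np.random.Generator,
    config: GrowthConfig,
    index: int = 0,
) -> tuple[VascularNetwork, LogEntry]:
    """Angiogenic sprout: bridge two nearby vessels with a new connecting segment.

    Both vessels are subdivided and the subdivision points joined
    (+2 nodes, +3 segments).  Under the barrier, a connector whose straight
    course pierces the cleft plane within the vascular half is blocked, as is
    any outcome that leaves a vascular-half cross segment.
    """
    frame = pole_frame(net)
    pair = _pick_segment_pair(net, rng, config, frame)
    if pair is None:
        return net, LogEntry(index=index, kind="sprout_skipped")
    s1, s2 = pair
    p1, p2 = _subdivide_points(net, rng, s1, s2)
    if config.barrier and _connector_crosses_cleft(p1, p2, frame):
        return net, LogEntry(index=index, kind="sprout_blocked", segments=(s1, s2))
    w1, w2 = _fresh_ids(net, "v", net.nodes, 2)
    e1, e2, e3, e4, e5 = _fresh_ids(net, "s", net.segments, 5)
    r1, r2 = net.segments[s1], net.segments[s2]
    entry = LogEntry(
        index=index,
        kind="sprout",
        segments=(s1, s2),
        removed_segments=(s1, s2),
        new_nodes=((w1, _t3(p1)), (w2, _t3(p2))),
        new_segments=(
            (e1, r1.u, w1),
            (e2, w1, r1.v),
            (e3, r2.u, w2),
            (e4, w2, r2.v),
            (e5, w1, w2),
        ),
    )
    out = _apply_entry(net, entry)
    if _barrier_veto(net, out, config):
        return net, LogEntry(index=index, kind="sprout_blocked", segments=(s1, s2))
    return out, entry


def condense_event(
    net: VascularNetwork,
    rng: np.random.Generator,
    config: GrowthConfig,
    index: int = 0,
) -> tuple[VascularNetwork, LogEntry]:
    """Vasculogenic condensation: a new precursor-derived node bridges two vessels.

    Like a sprout but the bridge runs through a new midpoint node
    (+3 nodes, +4 segments).  Barrier rules apply identically.
    """
    frame = pole_frame(net)
    pair = _pick_segment_pair(net, rng, config, frame)
    if pair is None:
        return net, LogEntry(index=index, kind="condense_skipped")
    s1, s2 = pair
    p1, p2 = _subdivide_points(net, rng, s1, s2)
    center = 0.5 * (p1 + p2) + _jitter(rng)
    if config.barrier and _connector_crosses_cleft(p1, p2, frame):
        return net, LogEntry(index=index, kind="condense_blocked", segments=(s1, s2))
    w1, w2, c0 = _fresh_ids(net, "v", net.nodes, 3)
    e1, e2, e3, e4, e5, e6 = _fresh_ids(net, "s", net.segments, 6)
    r1, r2 = net.segments[s1], net.segments[s2]
    entry = LogEntry(
        index=index,
        kind="condense",
        segments=(s1, s2),
        removed_segments=(s1, s2),
        new_nodes=((w1, _t3(p1)), (w2, _t3(p2)), (c0, _t3(center))),
        new_segments=(
            (e1, r1.u, w1),
            (e2, w1, r1.v),
            (e3, r2.u, w2),
            (e4, w2, r2.v),
            (e5, w1, c0),
            (e6, c0, w2),
        ),
    )
    out = _apply_entry(net, entry)
    if _barrier_veto(net, out, config):
        return net, LogEntry(index=index, kind="condense_blocked", segments=(s1, s2))
    return out, entry


# ---------------------------------------------------------------------------
# full simulation, replay, radii
# ---------------------------------------------------------------------------

_DISPATCH = {0: split_event, 1: sprout_event, 2: condense_event}


def simulate(config: GrowthConfig) -> tuple[VascularNetwork, EventLog]:
    """Grow a tuft: init_loop followed by ``n_events`` seeded event draws.

    Draw order per event: kind first, then locations and jitters, so logs are
    stable.  Deterministic given ``config.seed`` (single PCG64 generator).
    """
    rng = np.random.default_rng(config.seed)
    net = init_loop(config)
    log = EventLog(config=config)
    p = np.array([config.p_split, config.p_sprout, config.p_condense])
    for i in range(config.n_events):
        kind = int(rng.choice(3, p=p))
        net, entry = _DISPATCH[kind](net, rng, config, index=i)
        log.entries.append(entry)
    return net.validate(), log


def replay(log: EventLog) -> VascularNetwork:
    """Reconstruct the final network from the event log alone (no randomness)."""
    net = init_loop(log.config)
    for entry in log.entries:
        net = _apply_entry(net, entry)
    return net.validate()


def trajectory(config: GrowthConfig, every: int = 10) -> list[dict]:
    """Node count and geodesic length along a growth run, sampled every N events."""
    _, log = simulate(config)
    rows = []
    net = init_loop(config)
    for k, entry in enumerate([None] + log.entries):
        if entry is not None:
            net = _apply_entry(net, entry)
        if k % every == 0 or k == len(log.entries):
            rows.append(
                {
                    "event": k,
                    "n_nodes": net.n_nodes,
                    "shortest_path_length": shortest_path_length_matrix(net),
                }
            )
    return rows


def assign_radii(
    net: VascularNetwork,
    flow: FlowSolution,
    config: GrowthConfig,
    rng: np.random.Generator | None = None,
) -> VascularNetwork:
    """Flow-graded radii: r = r0·|I|^γ·(1+ε), floored at 0.1·r0.

    γ = 1/3 (Murray's law) by default; ε is zero-mean Gaussian with sd
    ``radius_noise_sd`` per segment.  Segments are visited in sorted-id order
    so the draw sequence is reproducible.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    out = net.copy()
    for sid in out.sorted_segment_ids():
        s = out.segments[sid]
        eps = rng.normal(0.0, config.radius_noise_sd) if config.radius_noise_sd else 0.0
        r = config.radius_r0 * abs(flow.current[sid]) ** config.murray_exponent * (1 + eps)
        out.segments[sid] = replace(s, radius=max(r, 0.1 * config.radius_r0))
    return out
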