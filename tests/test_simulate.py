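"""Growth simulator: determinism, event arithmetic, barrier, replay."""

import numpy as np
import pytest

from glomnet.errors import InvalidValueError
from glomnet.flow import solve_flow
from glomnet.model import pole_frame, write_network
from glomnet.paths import distance_field, no_cross_zone_score, shortest_path_length_matrix
from glomnet.planarity import is_planar
from glomnet.simulate import (
    EventLog,
    GrowthConfig,
    assign_radii,
    condense_event,
    init_loop,
    replay,
    simulate,
    split_event,
    sprout_event,
    trajectory,
)

from conftest import build_network

SPLIT_ONLY = dict(p_split=1.0, p_sprout=0.0, p_condense=0.0)
SPROUT_ONLY = dict(p_split=0.0, p_sprout=1.0, p_condense=0.0)
CONDENSE_ONLY = dict(p_split=0.0, p_sprout=0.0, p_condense=1.0)


class TestConfig:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(InvalidValueError):
            GrowthConfig(p_split=0.5, p_sprout=0.5, p_condense=0.5)

    def test_loop_size_minimum(self):
        with pytest.raises(InvalidValueError):
            GrowthConfig(n_loop=3)

    def test_json_round_trip(self):
        cfg = GrowthConfig(seed=5, n_events=10, barrier=False)
        assert GrowthConfig.from_json(cfg.to_json()) == cfg


class TestInitLoop:
    def test_minimal_loop_structure(self):
        net = init_loop(GrowthConfig(n_loop=4))
        assert (net.n_nodes, net.n_segments) == (6, 6)
        assert is_planar(net).planar
        # A attaches one node away from E's attachment on the 4-loop
        assert shortest_path_length_matrix(net) == 3

    @pytest.mark.parametrize("n_loop", [4, 5, 6, 8, 12])
    def test_always_valid_and_planar(self, n_loop):
        net = init_loop(GrowthConfig(n_loop=n_loop))
        net.validate()
        assert is_planar(net).planar

    def test_deterministic_tables(self, tmp_path):
        for run in ("one", "two"):
            net = init_loop(GrowthConfig(n_loop=8))
            write_network(net, tmp_path / f"{run}.n.csv", tmp_path / f"{run}.s.csv")
        assert (tmp_path / "one.n.csv").read_bytes() == (tmp_path / "two.n.csv").read_bytes()

    def test_even_loop_starts_with_intact_no_cross_zone(self):
        for n_loop in (6, 8, 10, 16):
            net = init_loop(GrowthConfig(n_loop=n_loop))
            score = no_cross_zone_score(net, distance_field(net), pole_frame(net))
            assert score["n_cross_vascular"] == 0


class TestEventArithmetic:
    def test_split_deltas(self):
        cfg = GrowthConfig(seed=0, barrier=False)
        net = init_loop(cfg)
        rng = np.random.default_rng(0)
        out, entry = split_event(net, rng, cfg)
        assert entry.kind == "split"
        assert (out.n_nodes - net.n_nodes, out.n_segments - net.n_segments) == (2, 3)

    def test_split_makes_parallel_two_segment_arms(self):
        cfg = GrowthConfig(seed=0, barrier=False, pole_bias=0.0)
        net = build_network(
            {"A": (0, 0, 1), "x": (1, 0, 0), "y": (2, 0, 0), "E": (3, 0, 1)},
            [("A", "x"), ("x", "y"), ("y", "E")],
        )
        out, entry = split_event(net, np.random.default_rng(1), cfg)
        assert entry.segments == ("s001",)  # only internal segment x–y
        assert out.n_nodes == 6 and out.n_segments == 6
        # x and y are now joined by two independent 2-segment arms
        assert shortest_path_length_matrix(out) == 4

    def test_sprout_deltas_and_rung(self):
        cfg = GrowthConfig(seed=0, barrier=False, d_max=100.0, pole_bias=0.0)
        positions = {"A": (-1, 0, 1), "E": (5, 0, 1)}
        edges = [("A", "t0"), ("E", "t4")]
        for i in range(4):
            positions[f"t{i}"] = (i, 1, 0)
            positions[f"b{i}"] = (i, -1, 0)
            edges += [(f"t{i}", f"t{i+1}")] if i < 3 else []
            edges += [(f"b{i}", f"b{i+1}")] if i < 3 else []
        positions["t4"] = (4, 1, 0)
        edges += [("t3", "t4"), ("t4", "b3"), ("b0", "t0")]
        net = build_network(positions, edges)
        out, entry = sprout_event(net, np.random.default_rng(3), cfg)
        assert entry.kind == "sprout"
        assert (out.n_nodes - net.n_nodes, out.n_segments - net.n_segments) == (2, 3)
        out.validate()

    def test_condense_deltas(self):
        cfg = GrowthConfig(seed=0, barrier=False, d_max=100.0, pole_bias=0.0)
        net = init_loop(cfg)
        out, entry = condense_event(net, np.random.default_rng(2), cfg)
        assert entry.kind == "condense"
        assert (out.n_nodes - net.n_nodes, out.n_segments - net.n_segments) == (3, 4)

    def test_condense_only_runs_stay_valid(self):
        for seed in range(20):
            net, _ = simulate(
                GrowthConfig(seed=seed, n_events=20, barrier=False, **CONDENSE_ONLY)
            )
            net.validate()  # connected, terminals degree 1


class TestSimulateDeterminism:
    def test_same_seed_identical_output(self):
        cfg = GrowthConfig(seed=123, n_events=30)
        net1, log1 = simulate(cfg)
        net2, log2 = simulate(cfg)
        assert log1.entries == log2.entries
        assert net1.nodes == net2.nodes and net1.segments == net2.segments

    def test_zero_events_is_init_loop(self):
        cfg = GrowthConfig(seed=1, n_events=0)
        net, log = simulate(cfg)
        ref = init_loop(cfg)
        assert net.nodes == ref.nodes and net.segments == ref.segments
        assert log.entries == []

    def test_node_count_matches_log_arithmetic(self):
        cfg = GrowthConfig(seed=7, n_events=60, pole_bias=2.0, barrier=True)
        net, log = simulate(cfg)
        expected = init_loop(cfg).n_nodes + sum(len(e.new_nodes) for e in log.entries)
        assert net.n_nodes == expected

    def test_replay_reconstructs_exactly(self):
        for seed in (0, 5, 9):
            net, log = simulate(GrowthConfig(seed=seed, n_events=40, barrier=False))
            again = replay(log)
            assert again.nodes == net.nodes and again.segments == net.segments

    def test_event_log_jsonl_round_trip(self):
        net, log = simulate(GrowthConfig(seed=3, n_events=25))
        back = EventLog.from_jsonl(log.to_jsonl())
        assert back.config == log.config and back.entries == log.entries
        again = replay(back)
        assert again.segments == net.segments


class TestPaperClaims:
    def test_splitting_only_preserves_planarity(self):
        """Pure intussusception can only build flat (planar) networks."""
        for seed in range(30):
            net, _ = simulate(
                GrowthConfig(seed=seed, n_events=50, barrier=False, **SPLIT_ONLY)
            )
            assert is_planar(net).planar

    def test_sprouting_breaks_planarity_sometimes(self):
        nonplanar = 0
        for seed in range(20):
            net, _ = simulate(
                GrowthConfig(seed=seed, n_events=40, barrier=False, **SPROUT_ONLY)
            )
            nonplanar += not is_planar(net).planar
        assert nonplanar > 0

    def test_barrier_keeps_no_cross_zone_empty(self):
        for seed in range(10):
            net, _ = simulate(GrowthConfig(seed=seed, n_events=50, barrier=True))
            score = no_cross_zone_score(net, distance_field(net), pole_frame(net))
            assert score["n_cross_vascular"] == 0

    def test_barrier_blocks_are_logged(self):
        blocked = 0
        for seed in range(10):
            _, log = simulate(GrowthConfig(seed=seed, n_events=50, barrier=True))
            blocked += sum("_blocked" in e.kind for e in log.entries)
        assert blocked > 0

    def test_shortest_path_stabilizes_under_biased_barrier_growth(self):
        """Nodes keep accumulating while the geodesic length stops growing."""
        for seed in range(5):
            rows = trajectory(
                GrowthConfig(seed=seed, n_events=80, pole_bias=2.0, barrier=True),
                every=10,
            )
            after = [r for r in rows if r["event"] >= 10]
            lengths = [r["shortest_path_length"] for r in after]
            assert all(b <= a for a, b in zip(lengths, lengths[1:]))
            assert rows[-1]["n_nodes"] > rows[0]["n_nodes"]


class TestAssignRadii:
    def test_chain_all_r0_without_noise(self, chain_net):
        cfg = GrowthConfig(radius_noise_sd=0.0)
        out = assign_radii(chain_net, solve_flow(chain_net), cfg)
        for s in out.segments.values():
            assert s.radius == pytest.approx(cfg.radius_r0)

    def test_diamond_arms_follow_murray_law(self, diamond_net):
        cfg = GrowthConfig(radius_noise_sd=0.0)
        out = assign_radii(diamond_net, solve_flow(diamond_net), cfg)
        assert out.segments["s001"].radius == pytest.approx(
            cfg.radius_r0 * 0.5 ** (1 / 3)
        )

    def test_noiseless_radii_monotone_in_current(self):
        net, _ = simulate(GrowthConfig(seed=6, n_events=30))
        flow = solve_flow(net)
        out = assign_radii(net, flow, GrowthConfig(radius_noise_sd=0.0))
        sids = sorted(net.segments, key=lambda sid: abs(flow.current[sid]))
        radii = [out.segments[sid].radius for sid in sids]
        assert all(b >= a - 1e-12 for a, b in zip(radii, radii[1:]))
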