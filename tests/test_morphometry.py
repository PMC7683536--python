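"""Morphometry: area ratio, Spearman concordance, depth profiles, size slope."""

import math
import random

import numpy as np
import pytest
import scipy.stats

from glomnet.errors import MissingRadiusError
from glomnet.flow import solve_flow
from glomnet.model import SegmentRecord
from glomnet.morphometry import (
    analyze,
    flow_diameter_concordance,
    ols_slope,
    radius_depth_profile,
    sp_vs_size_table,
    spearman_rho,
    terminal_area_ratio,
)
from glomnet.paths import distance_field
from glomnet.simulate import GrowthConfig, assign_radii, simulate

from conftest import build_network, ladder_network


def _with_radii(net, radii: dict):
    out = net.copy()
    for sid, r in radii.items():
        s = out.segments[sid]
        out.segments[sid] = SegmentRecord(id=s.id, u=s.u, v=s.v, radius=r)
    return out


class TestTerminalAreaRatio:
    def test_group_mean_areas_give_ratio_2_96(self, chain_net):
        """Mean arteriole lumen areas of 444 and 150 µm² give ratio 2.96."""
        net = _with_radii(
            chain_net,
            {"s000": math.sqrt(444 / math.pi), "s002": math.sqrt(150 / math.pi)},
        )
        aff, eff, ratio = terminal_area_ratio(net)
        assert aff == pytest.approx(444.0)
        assert eff == pytest.approx(150.0)
        assert ratio == pytest.approx(2.96, abs=0.005)

    def test_simple_radii(self, chain_net):
        net = _with_radii(chain_net, {"s000": 2.0, "s002": 1.0})
        aff, eff, ratio = terminal_area_ratio(net)
        assert (aff, eff, ratio) == pytest.approx((4 * math.pi, math.pi, 4.0))

    def test_equal_radii_unit_ratio(self, chain_net):
        net = _with_radii(chain_net, {"s000": 3.0, "s002": 3.0})
        assert terminal_area_ratio(net)[2] == pytest.approx(1.0)

    def test_scale_covariance(self, chain_net):
        net1 = _with_radii(chain_net, {"s000": 2.0, "s002": 1.5})
        net2 = _with_radii(chain_net, {"s000": 6.0, "s002": 4.5})
        a1, e1, r1 = terminal_area_ratio(net1)
        a2, e2, r2 = terminal_area_ratio(net2)
        assert r2 == pytest.approx(r1)
        assert (a2, e2) == pytest.approx((9 * a1, 9 * e1))

    def test_direct_area_takes_precedence(self, chain_net):
        out = chain_net.copy()
        s = out.segments["s000"]
        out.segments["s000"] = SegmentRecord(id=s.id, u=s.u, v=s.v, radius=1.0, area=444.0)
        s = out.segments["s002"]
        out.segments["s002"] = SegmentRecord(id=s.id, u=s.u, v=s.v, radius=1.0, area=150.0)
        assert terminal_area_ratio(out)[2] == pytest.approx(2.96, abs=0.005)

    def test_missing_radius_raises(self, chain_net):
        with pytest.raises(MissingRadiusError):
            terminal_area_ratio(chain_net)


class TestSpearman:
    def test_matches_scipy_with_ties(self):
        """In-repo midrank Spearman equals rank-then-Pearson to 1e-12."""
        import warnings

        rng = random.Random(0)
        for _ in range(1000):
            n = rng.randint(3, 30)
            x = [rng.choice(range(8)) for _ in range(n)]
            y = [rng.choice(range(8)) for _ in range(n)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # constant vectors -> nan
                expected = scipy.stats.spearmanr(x, y).statistic
            got = spearman_rho(x, y)
            if np.isnan(expected):  # constant vector: scipy returns nan, we define 0
                assert got == 0.0
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_monotone_extremes(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_rho(x, [2, 4, 6, 8, 10]) == pytest.approx(1.0)
        assert spearman_rho(x, [10, 8, 6, 4, 2]) == pytest.approx(-1.0)


class TestConcordance:
    def test_strictly_graded_radii_give_rho_one(self):
        net, _ = simulate(GrowthConfig(seed=2, n_events=30))
        flow = solve_flow(net)
        graded = net.copy()
        for sid in graded.segments:
            s = graded.segments[sid]
            graded.segments[sid] = SegmentRecord(
                id=s.id, u=s.u, v=s.v, radius=2.0 * abs(flow.current[sid])
            )
        assert flow_diameter_concordance(graded, flow) == pytest.approx(1.0)

    def test_noiseless_murray_radii_track_current(self):
        """Without noise the radius is a monotone function of |current|.

        Rank correlation is only ~1 because symmetric arms carry currents
        equal up to solver rounding, and those numerical ties can rank-flip
        through the cube root; on distinctly different currents the ordering
        is exact.
        """
        net, _ = simulate(GrowthConfig(seed=2, n_events=30))
        flow = solve_flow(net)
        graded = assign_radii(net, flow, GrowthConfig(radius_noise_sd=0.0))
        assert flow_diameter_concordance(graded, flow) >= 0.99
        sids = sorted(net.segments, key=lambda sid: abs(flow.current[sid]))
        floor = 0.1 * GrowthConfig().radius_r0
        for a, b in zip(sids, sids[1:]):
            ra, rb = graded.segments[a].radius, graded.segments[b].radius
            if abs(flow.current[b]) - abs(flow.current[a]) > 1e-9 and ra > floor:
                assert rb > ra
            else:
                assert rb >= ra - 1e-12

    def test_inverted_radii_give_minus_one(self, chain_net):
        # radii strictly decreasing in |current| on a network with distinct currents
        net, _ = simulate(GrowthConfig(seed=2, n_events=10))
        flow = solve_flow(net)
        inverted = net.copy()
        for sid in inverted.segments:
            s = inverted.segments[sid]
            inverted.segments[sid] = SegmentRecord(
                id=s.id, u=s.u, v=s.v, radius=1.0 / (abs(flow.current[sid]) + 0.01)
            )
        assert flow_diameter_concordance(inverted, flow) == pytest.approx(-1.0)

    def test_noisy_recovery_is_strong(self):
        """5% radius noise still leaves Spearman concordance >= 0.9 on average."""
        rhos = []
        for seed in range(20):
            cfg = GrowthConfig(seed=seed, n_events=60, radius_noise_sd=0.05)
            net, _ = simulate(cfg)
            flow = solve_flow(net)
            graded = assign_radii(net, flow, cfg)
            rhos.append(flow_diameter_concordance(graded, flow))
        assert np.mean(rhos) >= 0.9


class TestDepthProfiles:
    def test_murray_ladder_middle_minimum(self):
        net = ladder_network(9)
        flow = solve_flow(net)
        graded = assign_radii(net, flow, GrowthConfig(radius_noise_sd=0.0))
        profile = radius_depth_profile(graded, distance_field(graded), 3)
        means = profile["mean_radius"].to_numpy()
        assert np.nanargmin(means) == 1

    def test_constant_radii_flat(self, chain_net):
        net = _with_radii(chain_net, {sid: 2.0 for sid in chain_net.segments})
        profile = radius_depth_profile(net, distance_field(net), 2)
        assert np.allclose(profile["mean_radius"].dropna(), 2.0)


class TestSizeSlope:
    def test_ols_matches_polyfit(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.uniform(0, 100, size=12)
            y = 3.0 * x + rng.normal(0, 5, size=12)
            assert ols_slope(x, y) == pytest.approx(np.polyfit(x, y, 1)[0], abs=1e-9)

    def test_biased_barrier_growth_slope_is_flat(self):
        configs = [
            GrowthConfig(seed=seed, n_events=n, pole_bias=2.0, barrier=True)
            for n in (20, 60, 100)
            for seed in range(3)
        ]
        table, slope = sp_vs_size_table(configs)
        assert table["n_nodes"].nunique() > 1
        assert abs(slope) < 0.02

    def test_unbiased_growth_slope_is_larger(self):
        biased = [
            GrowthConfig(seed=s, n_events=n, pole_bias=2.0, barrier=True)
            for n in (20, 60, 100)
            for s in range(3)
        ]
        free = [
            GrowthConfig(seed=s, n_events=n, pole_bias=0.0, barrier=False)
            for n in (20, 60, 100)
            for s in range(3)
        ]
        _, slope_biased = sp_vs_size_table(biased)
        _, slope_free = sp_vs_size_table(free)
        assert abs(slope_free) > abs(slope_biased)


class TestAnalyze:
    def test_chain_report(self, chain_net):
        report = analyze(chain_net)
        assert report.planar is True
        assert report.n_geodesics == 1
        assert report.shortest_path_length == 3
        assert report.area_ratio is None  # no radii present
        assert report.pole_localization is None  # collinear: no pole frame

    def test_report_composes_individual_statistics(self, toy_net):
        from glomnet.model import pole_frame
        from glomnet.paths import (
            extract_shortest_paths,
            no_cross_zone_score,
            pole_localization,
        )
        from glomnet.planarity import is_planar

        report = analyze(toy_net)
        field = distance_field(toy_net)
        paths = extract_shortest_paths(toy_net, field)
        frame = pole_frame(toy_net)
        assert report.shortest_path_length == paths.length
        assert report.n_geodesics == len(paths.paths)
        assert report.planar == is_planar(toy_net).planar
        assert report.pole_localization == pole_localization(paths, toy_net, frame)
        assert (
            report.n_cross_vascular
            == no_cross_zone_score(toy_net, field, frame)["n_cross_vascular"]
        )

    def test_deterministic(self):
        net, _ = simulate(GrowthConfig(seed=8, n_events=30))
        assert analyze(net).to_dict() == analyze(net).to_dict()

    def test_twelve_simulated_glomeruli_summary(self):
        """A 12-tuft batch: every report is complete and self-consistent."""
        for seed in range(12):
            cfg = GrowthConfig(seed=seed, n_events=40)
            net, _ = simulate(cfg)
            net = assign_radii(net, solve_flow(net), cfg)
            report = analyze(net)
            assert report.n_nodes >= 40
            assert report.shortest_path_length >= 3
            assert report.area_ratio == pytest.approx(
                report.afferent_area / report.efferent_area
            )
            assert -1.0 <= report.flow_diameter_rho <= 1.0
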