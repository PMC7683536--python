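"""Per-glomerulus morphometric statistics and the aggregated report.

Covers the arteriole cross-sectional area ratio (afferent arterioles are
wider than efferent ones, reflecting the filtered volume), the concordance
between capillary caliber and simulated blood flow, radius and current depth
profiles, and the batch analysis of geodesic length versus tuft size.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import math

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, InvalidValueError, MissingRadiusError
from .flow import ConductanceModel, current_depth_profile, segment_depths, solve_flow
from .model import VascularNetwork, pole_frame
from .paths import (
    distance_field,
    extract_shortest_paths,
    no_cross_zone_score,
    pole_localization,
    shortest_path_length_matrix,
)
from .planarity import is_planar
from .simulate import GrowthConfig, simulate


def _terminal_segment(net: VascularNetwork, terminal: str):
    for s in net.segments.values():
        if terminal in (s.u, s.v):
            return s
    raise InvalidValueError(f"terminal {terminal!r} has no incident segment")


def terminal_area_ratio(net: VascularNetwork) -> tuple[float, float, float]:
    """Cross-sectional areas (µm²) of the two arterioles and their ratio.

    Uses the directly measured ``area`` of the terminal-incident segment when
    present, else π·radius².  Returns (afferent_area, efferent_area,
    afferent/efferent).
    """
    areas = []
    for terminal in (net.afferent, net.efferent):
        s = _terminal_segment(net, terminal)
        if s.area is not None:
            areas.append(float(s.area))
        elif s.radius is not None:
            areas.append(math.pi * s.radius**2)
        else:
            raise MissingRadiusError(
                f"terminal segment {s.id!r} has neither area nor radius"
            )
    return areas[0], areas[1], areas[0] / areas[1]


def _midranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties averaged."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of midranks."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidValueError("spearman_rho needs two equal-length vectors, n >= 3")
    rx, ry = _midranks(x) - _midranks(x).mean(), _midranks(y) - _midranks(y).mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return 0.0
    return float(rx @ ry) / denom


def flow_diameter_concordance(net: VascularNetwork, flow) -> float:
    """Spearman correlation between |current| and radius over all segments.

    Use currents from the ``unit`` conductance model so radii play no role in
    the flow computation (the Poiseuille model would be circular here).
    """
    sids = net.sorted_segment_ids()
    missing = [sid for sid in sids if net.segments[sid].radius is None]
    if missing:
        raise MissingRadiusError(f"segments without radius: {missing[:5]!r}")
    currents = [abs(flow.current[sid]) for sid in sids]
    radii = [net.segments[sid].radius for sid in sids]
    return spearman_rho(currents, radii)


def radius_depth_profile(
    net: VascularNetwork, field, n_bins: int = 3
) -> pd.DataFrame:
    """Mean capillary radius per normalized hop-depth bin.

    Mirrors the observation that vessels near the urinary pole — the
    mid-depth of the afferent→efferent traversal — are the narrowest.
    """
    if n_bins < 2:
        raise InvalidValueError(f"n_bins must be >= 2, got {n_bins}")
    missing = [sid for sid, s in net.segments.items() if s.radius is None]
    if missing:
        raise MissingRadiusError(f"segments without radius: {sorted(missing)[:5]!r}")
    depths = segment_depths(net, field)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    sids = sorted(net.segments)
    d = np.array([depths[sid] for sid in sids])
    r = np.array([net.segments[sid].radius for sid in sids])
    which = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        rows.append(
            {
                "depth_bin": b,
                "depth_lo": edges[b],
                "depth_hi": edges[b + 1],
                "n_segments": int(mask.sum()),
                "mean_radius": float(r[mask].mean()) if mask.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def ols_slope(x, y) -> float:
    """Ordinary least-squares slope by the closed form Σ(x−x̄)(y−ȳ)/Σ(x−x̄)²."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    dx = x - x.mean()
    denom = float(dx @ dx)
    if denom == 0:
        return 0.0
    return float(dx @ (y - y.mean())) / denom


def sp_vs_size_table(configs: list[GrowthConfig]) -> tuple[pd.DataFrame, float]:
    """Geodesic length versus node count over simulated tufts, with OLS slope.

    A slope near zero reproduces the observation that the shortest path is
    largely independent of glomerulus size.
    """
    if len(configs) < 2:
        raise InvalidValueError("sp_vs_size_table needs at least two configs")
    rows = []
    for cfg in configs:
        net, _ = simulate(cfg)
        rows.append(
            {
                "seed": cfg.seed,
                "n_events": cfg.n_events,
                "n_nodes": net.n_nodes,
                "shortest_path_length": shortest_path_length_matrix(net),
            }
        )
    df = pd.DataFrame(rows)
    slope = ols_slope(df["n_nodes"], df["shortest_path_length"])
    return df, slope


@dataclass
class GlomerulusReport:
    """All per-glomerulus statistics the analysis computes."""

    n_nodes: int
    n_segments: int
    shortest_path_length: int
    shortest_path_interior_nodes: int
    n_geodesics: int
    planar: bool
    current_depth_profile: list[dict]
    # geometric scores are None when the tuft has no usable orientation frame
    pole_localization: float | None = None
    n_cross_vascular: int | None = None
    n_cross_total: int | None = None
    afferent_area: float | None = None
    efferent_area: float | None = None
    area_ratio: float | None = None
    flow_diameter_rho: float | None = None
    radius_depth_profile: list[dict] | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def analyze(net: VascularNetwork, n_bins: int = 3) -> GlomerulusReport:
    """Full single-glomerulus analysis.

    Runs the distance field, geodesic enumeration, planarity test, unit-model
    Kirchhoff flow, localization and no-cross-zone scores; radius-dependent
    morphometrics are included only when every segment carries a radius.
    """
    net.validate()
    field = distance_field(net)
    paths = extract_shortest_paths(net, field)
    flow = solve_flow(net, ConductanceModel("unit"))
    profile = current_depth_profile(net, field, flow, n_bins=n_bins)
    report = GlomerulusReport(
        n_nodes=net.n_nodes,
        n_segments=net.n_segments,
        shortest_path_length=paths.length,
        shortest_path_interior_nodes=paths.length - 1,
        n_geodesics=len(paths.paths),
        planar=is_planar(net).planar,
        current_depth_profile=profile.to_dict(orient="records"),
    )
    try:
        frame = pole_frame(net)
    except DegenerateGeometryError:
        frame = None  # e.g. perfectly collinear toy networks
    if frame is not None:
        cross = no_cross_zone_score(net, field, frame)
        report.pole_localization = pole_localization(paths, net, frame)
        report.n_cross_vascular = cross["n_cross_vascular"]
        report.n_cross_total = cross["n_cross_total"]
    have_radii = all(s.radius is not None for s in net.segments.values())
    if have_radii and net.n_segments >= 3:
        aff_area, eff_area, ratio = terminal_area_ratio(net)
        report.afferent_area = aff_area
        report.efferent_area = eff_area
        report.area_ratio = ratio
        report.flow_diameter_rho = flow_diameter_concordance(net, flow)
        report.radius_depth_profile = radius_depth_profile(
            net, field, n_bins=n_bins
        ).to_dict(orient="records")
    return report
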