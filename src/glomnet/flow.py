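"""Resistor-network blood-flow analogue.

Each capillary segment is a resistor; a unit current is injected at the
afferent terminal and withdrawn at the efferent terminal, which is grounded.
Node potentials solve the weighted graph Laplacian system L·φ = b, and each
segment carries current g·(φ(u) − φ(v)).  Because only relative currents
matter for the topology arguments, conductances are either all 1 (``unit``)
or Poiseuille-scaled g = r⁴/L for radius-weighted analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from .errors import FlowResidualError, InvalidValueError, MissingRadiusError
from .model import VascularNetwork
from .paths import DistanceField

KCL_TOL = 1e-8


@dataclass(frozen=True)
class ConductanceModel:
    """Per-segment conductance rule: ``unit`` (g = 1) or ``poiseuille`` (g = r⁴/L)."""

    kind: str = "unit"

    def conductances(self, net: VascularNetwork) -> dict[str, float]:
        if self.kind == "unit":
            return {sid: 1.0 for sid in net.segments}
        if self.kind == "poiseuille":
            missing = sorted(
                sid for sid, s in net.segments.items() if s.radius is None
            )
            if missing:
                raise MissingRadiusError(
                    f"poiseuille model needs radii on all segments; missing on {missing!r}"
                )
            return {
                sid: net.segments[sid].radius ** 4 / net.segment_length(sid)
                for sid in net.segments
            }
        raise InvalidValueError(f"unknown conductance model {self.kind!r}")


@dataclass
class FlowSolution:
    """Node potentials and signed per-segment currents (u→v positive)."""

    potential: dict[str, float]
    current: dict[str, float]
    kcl_residual: float


def solve_flow(
    net: VascularNetwork, model: ConductanceModel = ConductanceModel("unit")
) -> FlowSolution:
    """Solve the grounded Laplacian system for unit injected current.

    +1 enters at the afferent terminal, −1 leaves at the efferent terminal
    whose potential is fixed at 0; the reduced symmetric system is solved by
    a direct sparse factorization and Kirchhoff's current law is verified
    post hoc at every internal node.
    """
    g = model.conductances(net)
    order = net.sorted_node_ids()
    idx = {nid: i for i, nid in enumerate(order)}
    n = len(order)

    rows, cols, vals = [], [], []
    for sid, s in net.segments.items():
        i, j, w = idx[s.u], idx[s.v], g[sid]
        rows += [i, j, i, j]
        cols += [j, i, i, j]
        vals += [-w, -w, w, w]
    lap = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    b = np.zeros(n)
    b[idx[net.afferent]] = 1.0
    b[idx[net.efferent]] = -1.0

    keep = np.array([i for i in range(n) if i != idx[net.efferent]])
    phi = np.zeros(n)
    phi[keep] = spsolve(lap[np.ix_(keep, keep)].tocsc(), b[keep])

    potential = {nid: float(phi[idx[nid]]) for nid in order}
    current = {
        sid: float(g[sid] * (phi[idx[s.u]] - phi[idx[s.v]]))
        for sid, s in net.segments.items()
    }

    # KCL check: net current at every internal node must vanish
    net_current = {nid: 0.0 for nid in order}
    for sid, s in net.segments.items():
        net_current[s.u] -= current[sid]
        net_current[s.v] += current[sid]
    residual = max(
        abs(net_current[nid])
        for nid in order
        if nid not in (net.afferent, net.efferent)
    ) if n > 2 else 0.0
    if residual > KCL_TOL:
        raise FlowResidualError(
            f"current conservation violated: residual {residual:.3e} > {KCL_TOL:.0e}"
        )
    return FlowSolution(potential=potential, current=current, kcl_residual=residual)


def segment_depths(net: VascularNetwork, field: DistanceField) -> dict[str, float]:
    """Normalized hop depth of each segment: min endpoint d_aff over the maximum."""
    raw = {
        sid: min(field.d_aff[s.u], field.d_aff[s.v])
        for sid, s in net.segments.items()
    }
    dmax = max(raw.values()) or 1
    return {sid: d / dmax for sid, d in raw.items()}


def current_depth_profile(
    net: VascularNetwork,
    field: DistanceField,
    flow: FlowSolution,
    n_bins: int = 3,
) -> pd.DataFrame:
    """Mean |current| per equally spaced normalized-depth bin.

    In an intact tuft the current spreads over many parallel paths mid-way
    between the arterioles, so the middle bins carry the lowest mean current.
    """
    if n_bins < 2:
        raise InvalidValueError(f"n_bins must be >= 2, got {n_bins}")
    depths = segment_depths(net, field)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    sids = sorted(net.segments)
    d = np.array([depths[sid] for sid in sids])
    c = np.array([abs(flow.current[sid]) for sid in sids])
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
                "mean_abs_current": float(c[mask].mean()) if mask.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)
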