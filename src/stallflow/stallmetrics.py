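"""Stall prevalence, cellular composition, and CBF-deficit models.

Prevalence and composition
    :func:`stall_fraction` turns expert-confirmed crowd calls into
    per-stack stalled fractions (confirmed stalls divided by the total
    number of capillary segments in the stack) and per-group summaries.
    :func:`classify_stall_cause` assigns each stalled segment a cellular
    cause from the two-channel labeling logic: a leukocyte is positive
    in both rhodamine (mitochondria) and hoechst (DNA), a platelet in
    rhodamine only, and a red-blood-cell-only stall in neither.

Downstream-occlusion CBF deficit
    Occluding one capillary depresses flow in the vessels downstream of
    it; measured multipliers are 10%, 25% and 50% of baseline for
    vessels 1, 2 and 3–4 branches downstream.  With a fraction ``p`` of
    capillaries occluded and a branching factor of 2, the affected
    fractions per tier are 2p, 4p and 8p (tiers 3–4 pooled), and the
    arithmetic model predicts a total CBF decrease of
    ``100 * [p + sum_k n_k (1 - m_k)]`` — 19.6% at p = 2%.
    :func:`network_deficit` complements this with a simplified linear
    network solver (Poiseuille conductances ~ r^4 / length, flow
    conservation at nodes, fixed inlet/outlet pressures); it is a
    deliberate simplification of full computational fluid dynamics, but
    reproduces the qualitative property that CBF falls
    disproportionately to the occluded fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from ._segments import lumen_mask_from_points

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Stall-cause classification


def _static_patch_location(stack, segment, dark_fraction=0.5, min_patch_voxels=20):
    """Centroid (voxel coords) of the largest static dark patch in the lumen."""
    pts = np.asarray(segment.points_vox, dtype=float)
    lumen = lumen_mask_from_points(
        pts, segment.radius_um / stack.dz, stack.data.shape[2:]
    )
    plasma = stack.channel("plasma")
    level = float(np.percentile(plasma[:, lumen], 80))
    # static = dark in every frame
    dark_all = np.all(plasma < dark_fraction * level, axis=0) & lumen
    lab, nlab = ndimage.label(dark_all, structure=np.ones((3, 3, 3), int))
    if nlab == 0:
        return None
    counts = np.bincount(lab.ravel())[1:]
    best = int(np.argmax(counts)) + 1
    if counts[best - 1] < min_patch_voxels:
        return None
    return np.array(ndimage.center_of_mass(dark_all, lab, best))


def classify_stall_cause(
    stack,
    segment,
    stall_location=None,
    *,
    k: float = 2.0,
    patch_radius_um: float = 3.0,
) -> str:
    """Cellular cause of a stalled segment from the channel logic.

    Channel positivity at the static patch is defined as mean intensity
    greater than ``k`` times the channel's background median over the
    stack.  Returns 'leukocyte' (rhodamine and hoechst positive),
    'platelet' (rhodamine only), 'rbc_only' (neither), or 'ambiguous'
    (hoechst without rhodamine — biologically unexpected; logged).
    """
    if stall_location is None:
        stall_location = _static_patch_location(stack, segment)
        if stall_location is None:
            raise ValueError("no static dark patch found in the segment lumen")
    loc = np.asarray(stall_location, dtype=float)
    shape = stack.data.shape[2:]
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    r = patch_radius_um / stack.dz
    ball = (zz - loc[0]) ** 2 + (yy - loc[1]) ** 2 + (xx - loc[2]) ** 2 <= r**2
    results = {}
    for ch in ("rhodamine", "hoechst"):
        vol = stack.channel(ch)
        background = float(np.median(vol))
        at_patch = float(vol[:, ball].mean())
        results[ch] = at_patch > k * background
    if results["rhodamine"] and results["hoechst"]:
        return "leukocyte"
    if results["rhodamine"]:
        return "platelet"
    if results["hoechst"]:
        logger.warning(
            "segment %s: hoechst-positive but rhodamine-negative patch",
            getattr(segment, "edge", "?"),
        )
        return "ambiguous"
    return "rbc_only"


# --------------------------------------------------------------------------
# Prevalence summaries


@dataclass
class StallSummary:
    stack_id: str
    group: str
    n_segments: int
    n_stalled: int
    composition: dict = field(default_factory=dict)

    @property
    def stall_fraction(self) -> float:
        return self.n_stalled / self.n_segments

    @property
    def composition_percent(self) -> dict:
        total = sum(self.composition.values())
        if total == 0:
            return {k: 0.0 for k in self.composition}
        return {k: 100.0 * v / total for k, v in self.composition.items()}


def stall_fraction(
    calls,
    segments_per_stack: dict,
    groups: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stack stalled fractions and per-group mean ± SD.

    ``calls`` is a finalized (triaged) :class:`StallCallTable`;
    ``segments_per_stack`` maps stack id -> total capillary segments in
    that stack (the denominator); ``groups`` maps stack id -> group
    label (defaults to one group).  The numerator is the number of
    expert-confirmed stalls in the stack.
    """
    df = calls.table
    per_stack = []
    for stack_id, n_seg in segments_per_stack.items():
        if n_seg <= 0:
            raise ValueError(f"stack {stack_id!r} has no segments")
        sel = df[df["stack_id"] == stack_id]
        n_stalled = int((sel["expert_verdict"] == "stalled").sum())
        per_stack.append(
            {
                "stack_id": stack_id,
                "group": (groups or {}).get(stack_id, "all"),
                "n_segments": int(n_seg),
                "n_stalled": n_stalled,
                "stall_fraction": n_stalled / n_seg,
            }
        )
    per_stack = pd.DataFrame(per_stack)
    group = (
        per_stack.groupby("group")["stall_fraction"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return per_stack, group


# --------------------------------------------------------------------------
# Arithmetic downstream-occlusion model

#: (affected-fraction multiple of p, flow multiplier): one branch
#: downstream 2p of vessels at 10% flow, two branches 4p at 25%, and
#: branches 3–4 pooled as 8p at 50%.
DEFAULT_TIERS = ((2.0, 0.10), (4.0, 0.25), (8.0, 0.50))


@dataclass
class DeficitModel:
    """Tiered downstream-occlusion model of the CBF deficit."""

    occluded_fraction: float
    tiers: tuple = DEFAULT_TIERS

    def __post_init__(self):
        p = self.occluded_fraction
        if not (0.0 <= p <= 1.0):
            raise ValueError("occluded fraction must lie in [0, 1]")
        for n_factor, m in self.tiers:
            if not (0.0 <= m <= 1.0):
                raise ValueError(f"flow multiplier {m} outside [0, 1]")
        affected = p + p * sum(nf for nf, _ in self.tiers)
        if affected > 1.0 + 1e-12:
            raise ValueError(
                f"occluded plus affected fractions exceed 1 ({affected:.3f})"
            )


def arithmetic_deficit(model: DeficitModel) -> float:
    """Percent CBF decrease: 100 * [p + sum_k n_k (1 - m_k)].

    The occluded fraction p loses all flow; each downstream tier k holds
    a fraction n_k = p * factor_k of vessels running at m_k of baseline.
    Linear in p, so halving the occluded fraction halves the deficit.
    """
    p = model.occluded_fraction
    deficit = p + sum(p * nf * (1.0 - m) for nf, m in model.tiers)
    return 100.0 * deficit


# --------------------------------------------------------------------------
# Simplified network solver


def network_deficit(
    graph,
    stalled_edges,
    *,
    inlet_kind: str = "surface-arteriole",
    return_flows: bool = False,
):
    """Percent CBF decrease from a linear Poiseuille network solve.

    Edge conductance is r^4 / length (the constant viscosity prefactor
    cancels in the ratio); inlet nodes (``inlet_kind``) are held at unit
    pressure, terminal nodes (no outgoing edges) at zero, and interior
    pressures follow from flow conservation.  Stalled edges get zero
    conductance.  Returns 100 * (1 - Q_stalled / Q_baseline) where Q is
    the total inlet outflow; a fully disconnected inlet reports 100%
    with a warning.
    """
    g = graph.graph if hasattr(graph, "graph") else graph
    stalled = {tuple(e) for e in stalled_edges}
    stalled |= {(v, u) for u, v in stalled}

    nodes = list(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    inlets = [n for n in nodes if g.nodes[n].get("kind") == inlet_kind]
    outlets = [n for n in nodes if g.out_degree(n) == 0]
    if not inlets or not outlets:
        raise ValueError("network needs at least one inlet and one outlet")

    def conductances(exclude):
        c = {}
        for u, v, d in g.edges(data=True):
            gc = d["radius_um"] ** 4 / d["length_um"]
            if (u, v) in exclude:
                gc = 0.0
            c[(u, v)] = gc
        return c

    def solve(cond):
        p = np.zeros(len(nodes))
        fixed = {}
        for n in inlets:
            fixed[idx[n]] = 1.0
        for n in outlets:
            fixed.setdefault(idx[n], 0.0)
        free = [i for i in range(len(nodes)) if i not in fixed]
        fpos = {i: k for k, i in enumerate(free)}
        rows, cols, vals = [], [], []
        b = np.zeros(len(free))
        diag = np.zeros(len(free))
        for (u, v), gc in cond.items():
            if gc == 0:
                continue
            iu, iv = idx[u], idx[v]
            for a, bnode in ((iu, iv), (iv, iu)):
                if a in fpos:
                    diag[fpos[a]] += gc
                    if bnode in fpos:
                        rows.append(fpos[a])
                        cols.append(fpos[bnode])
                        vals.append(-gc)
                    else:
                        b[fpos[a]] += gc * fixed[bnode]
        for k in range(len(free)):
            rows.append(k)
            cols.append(k)
            # tiny shift keeps isolated interior nodes solvable (their
            # pressure is arbitrary; they carry no flow)
            vals.append(diag[k] if diag[k] > 0 else 1.0)
        if free:
            lap = coo_matrix((vals, (rows, cols)), shape=(len(free), len(free))).tocsr()
            p_free = spsolve(lap, b)
            for i, k in fpos.items():
                p[i] = p_free[k]
        for i, val in fixed.items():
            p[i] = val
        # total flow out of the inlets
        q = 0.0
        flows = {}
        for (u, v), gc in cond.items():
            f = gc * (p[idx[u]] - p[idx[v]])
            flows[(u, v)] = f
            if g.nodes[u].get("kind") == inlet_kind and g.nodes[v].get("kind") != inlet_kind:
                q += f
            elif g.nodes[v].get("kind") == inlet_kind and g.nodes[u].get("kind") != inlet_kind:
                q -= f
        return q, p, flows

    q0, p0, flows0 = solve(conductances(set()))
    if q0 <= 0:
        raise ValueError("baseline network carries no flow")
    q1, p1, flows1 = solve(conductances(stalled))
    if q1 <= 1e-15 * q0:
        logger.warning("stalling disconnects all inlets from outlets: 100%% deficit")
        deficit = 100.0
    else:
        deficit = 100.0 * (1.0 - q1 / q0)
    if return_flows:
        return deficit, {"baseline": flows0, "stalled": flows1}
    return deficit


def flow_conservation_residual(graph, flows, inlet_kind="surface-arteriole") -> float:
    """Max |net flow| at interior nodes, as a fraction of total inlet flow."""
    g = graph.graph if hasattr(graph, "graph") else graph
    net = {n: 0.0 for n in g.nodes}
    for (u, v), f in flows.items():
        net[u] -= f
        net[v] += f
    total_in = sum(
        f
        for (u, v), f in flows.items()
        if g.nodes[u].get("kind") == inlet_kind and g.nodes[v].get("kind") != inlet_kind
    )
    interior = [
        n
        for n in g.nodes
        if g.nodes[n].get("kind") != inlet_kind and g.out_degree(n) > 0
    ]
    if not interior or total_in == 0:
        return 0.0
    return max(abs(net[n]) for n in interior) / abs(total_in)
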