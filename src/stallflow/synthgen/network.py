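"""Synthetic cortical microvascular networks with known stall ground truth.

The cortical vasculature is modelled as a layered geometric graph: a
mesh-like chain of surface arterioles feeds penetrating arterioles (PAs)
that plunge into the cortex, and each PA supplies a binary-branching
capillary bed.  Every capillary edge carries a ground-truth flow state:
either flowing, with a log-normal centerline red-blood-cell speed, or
stalled (speed 0) with a cellular cause drawn from a configurable
leukocyte / platelet / RBC-only composition.

Randomness is split across named streams (topology, stall assignment,
cause assignment, speeds) so the stall draw for a given seed can be
reproduced independently of everything else: stalls are assigned by
drawing one uniform per capillary edge, in edge-creation order, from the
``"stalls"`` stream and comparing against the stall rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .._seeds import stream

STALL_CAUSES = ("leukocyte", "platelet", "rbc_only")

#: Physiological capillary radius range, µm.
CAPILLARY_RADIUS_RANGE = (1.5, 4.0)


class SimplexError(ValueError):
    """A probability vector does not lie on the simplex."""


@dataclass
class VesselGraph:
    """A vessel network with per-edge geometry and flow ground truth.

    Nodes carry ``kind`` (``surface-arteriole`` | ``penetrating-arteriole``
    | ``capillary-junction``) and ``pos`` — a (z, y, x) position in µm,
    z increasing with cortical depth.  Edges carry ``kind``
    (``arteriole`` | ``capillary``), ``radius_um``, ``length_um``,
    ``branch_order`` (0 for the PA itself, +1 per branch downstream),
    ``is_stalled``, ``stall_cause`` and ``speed_um_s``.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    # -- convenience views ------------------------------------------------
    def capillary_edges(self) -> list[tuple]:
        return [
            (u, v)
            for u, v, d in self.graph.edges(data=True)
            if d["kind"] == "capillary"
        ]

    def stalled_edges(self) -> list[tuple]:
        return [
            (u, v)
            for u, v, d in self.graph.edges(data=True)
            if d.get("is_stalled", False)
        ]

    def true_stall_fraction(self) -> float:
        caps = self.capillary_edges()
        if not caps:
            return 0.0
        return len(self.stalled_edges()) / len(caps)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) corner of node positions, each (z, y, x) in µm."""
        pos = np.array([d["pos"] for _, d in self.graph.nodes(data=True)])
        return pos.min(axis=0), pos.max(axis=0)

    def validate(self) -> None:
        """Raise if a structural invariant is violated."""
        if not nx.is_weakly_connected(self.graph):
            raise ValueError("vessel graph must be connected")
        lo, hi = CAPILLARY_RADIUS_RANGE
        for u, v, d in self.graph.edges(data=True):
            if d["kind"] == "capillary" and not (lo <= d["radius_um"] <= hi):
                raise ValueError(
                    f"capillary radius {d['radius_um']} outside [{lo}, {hi}] µm"
                )
            if d["is_stalled"]:
                if d["speed_um_s"] != 0:
                    raise ValueError("stalled edge must have centerline speed 0")
                if d["stall_cause"] == "none":
                    raise ValueError("stalled edge must carry a stall cause")
            elif d["stall_cause"] != "none":
                raise ValueError("flowing edge must have stall_cause 'none'")

    # -- I/O ---------------------------------------------------------------
    def to_graphml(self, path) -> None:
        g = nx.DiGraph()
        for n, d in self.graph.nodes(data=True):
            z, y, x = d["pos"]
            g.add_node(n, kind=d["kind"], z_um=float(z), y_um=float(y), x_um=float(x))
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(
                u,
                v,
                kind=d["kind"],
                radius_um=float(d["radius_um"]),
                length_um=float(d["length_um"]),
                branch_order=int(d["branch_order"]),
                is_stalled=bool(d["is_stalled"]),
                stall_cause=str(d["stall_cause"]),
                speed_um_s=float(d["speed_um_s"]),
            )
        nx.write_graphml(g, path)

    @classmethod
    def from_graphml(cls, path) -> "VesselGraph":
        raw = nx.read_graphml(path)
        g = nx.DiGraph()
        for n, d in raw.nodes(data=True):
            g.add_node(n, kind=d["kind"], pos=(d["z_um"], d["y_um"], d["x_um"]))
        for u, v, d in raw.edges(data=True):
            g.add_edge(
                u,
                v,
                kind=d["kind"],
                radius_um=float(d["radius_um"]),
                length_um=float(d["length_um"]),
                branch_order=int(d["branch_order"]),
                is_stalled=bool(d["is_stalled"]),
                stall_cause=str(d["stall_cause"]),
                speed_um_s=float(d["speed_um_s"]),
            )
        return cls(g)


def _check_composition(composition) -> np.ndarray:
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (3,):
        raise SimplexError(
            "composition must have exactly 3 entries "
            "(leukocyte, platelet, rbc_only); got shape "
            f"{comp.shape}"
        )
    if np.any(comp < 0):
        raise SimplexError("composition entries must be non-negative")
    if abs(comp.sum() - 1.0) > 1e-9:
        raise SimplexError(
            f"composition must sum to 1 within 1e-9; got sum {comp.sum()!r}"
        )
    return comp


def stall_uniform_draws(seed: int, n_capillaries: int) -> np.ndarray:
    """The uniforms used to assign stalls, in capillary-creation order.

    Exposed so the stall assignment of :func:`generate_network` can be
    reproduced (or audited) without rebuilding the topology: capillary
    edge ``i`` is stalled iff ``stall_uniform_draws(seed, n)[i] < rate``.
    """
    return stream(seed, "stalls").uniform(size=n_capillaries)


def generate_network(
    n_penetrating: int,
    capillaries_per_pa: int,
    stall_rate: float,
    composition=(0.86, 0.05, 0.09),
    seed: int = 0,
    *,
    speed_median_um_s: float = 1000.0,
    speed_sigma: float = 0.5,
    pa_depth_um: float = 40.0,
    capillary_length_um: tuple[float, float] = (30.0, 60.0),
    pa_spacing_um: float = 150.0,
) -> VesselGraph:
    """Generate a layered synthetic vascular network.

    Parameters
    ----------
    n_penetrating:
        Number of penetrating arterioles fed by the surface network.
    capillaries_per_pa:
        Capillary segments grown downstream of each PA (binary branching).
    stall_rate:
        Per-capillary probability of being stalled, in [0, 0.1].
    composition:
        Probabilities of (leukocyte, platelet, rbc_only) causes for a
        stalled segment; must sum to 1.
    speed_median_um_s, speed_sigma:
        Median and log-SD of the log-normal centerline speed of flowing
        capillaries.
    """
    if n_penetrating < 1:
        raise ValueError("need at least one penetrating arteriole")
    if capillaries_per_pa < 1:
        raise ValueError("need at least one capillary per PA")
    if not (0.0 <= stall_rate <= 0.1):
        raise ValueError(f"stall_rate must lie in [0, 0.1]; got {stall_rate}")
    comp = _check_composition(composition)

    topo = stream(seed, "topology")
    g = nx.DiGraph()
    cap_edges: list[tuple] = []  # creation order, for stall assignment

    # Surface arteriole chain feeding the PA roots.
    prev_surface = None
    for i in range(n_penetrating):
        root = f"sa{i}"
        y = 40.0 + topo.normal(0.0, 5.0)
        x = 40.0 + i * pa_spacing_um
        g.add_node(root, kind="surface-arteriole", pos=(2.0, y, x))
        if prev_surface is not None:
            p0 = np.array(g.nodes[prev_surface]["pos"])
            p1 = np.array(g.nodes[root]["pos"])
            g.add_edge(
                prev_surface,
                root,
                kind="arteriole",
                radius_um=6.0,
                length_um=float(np.linalg.norm(p1 - p0)),
                branch_order=0,
                is_stalled=False,
                stall_cause="none",
                speed_um_s=float(speed_median_um_s * 4),
            )
        prev_surface = root

        # Penetrating arteriole descending from the surface node.
        pa = f"pa{i}"
        z0, y0, x0 = g.nodes[root]["pos"]
        g.add_node(pa, kind="penetrating-arteriole", pos=(z0 + pa_depth_um, y0, x0))
        g.add_edge(
            root,
            pa,
            kind="arteriole",
            radius_um=5.0,
            length_um=pa_depth_um,
            branch_order=0,
            is_stalled=False,
            stall_cause="none",
            speed_um_s=float(speed_median_um_s * 3),
        )

        # Binary-branching capillary bed below the PA.
        frontier = [(pa, np.array([1.0, 0.0, 0.0]), 0)]  # (node, direction, order)
        n_left = capillaries_per_pa
        k = 0
        while n_left > 0:
            parent, pdir, order = frontier.pop(0)
            for _ in range(2):
                if n_left == 0:
                    break
                length = topo.uniform(*capillary_length_um)
                radius = topo.uniform(*CAPILLARY_RADIUS_RANGE)
                # Child direction: parent direction tilted by a random
                # lateral perturbation, renormalised, biased downward.
                tilt = topo.normal(0.0, 0.6, size=3)
                tilt[0] = abs(tilt[0]) * 0.3 + 0.2  # keep descending
                d = pdir + tilt
                d /= np.linalg.norm(d)
                child = f"c{i}_{k}"
                k += 1
                p0 = np.array(g.nodes[parent]["pos"])
                p1 = p0 + d * length
                g.add_node(child, kind="capillary-junction", pos=tuple(p1))
                g.add_edge(
                    parent,
                    child,
                    kind="capillary",
                    radius_um=float(radius),
                    length_um=float(length),
                    branch_order=order + 1,
                    is_stalled=False,  # assigned below
                    stall_cause="none",
                    speed_um_s=0.0,
                )
                cap_edges.append((parent, child))
                frontier.append((child, d, order + 1))
                n_left -= 1

    # Stall assignment: one uniform per capillary edge, creation order.
    n_caps = len(cap_edges)
    u = stall_uniform_draws(seed, n_caps)
    stalled = u < stall_rate

    cause_rng = stream(seed, "causes")
    speed_rng = stream(seed, "speeds")
    speeds = speed_median_um_s * np.exp(speed_sigma * speed_rng.normal(size=n_caps))
    cause_idx = cause_rng.choice(3, size=n_caps, p=comp)

    for j, (uu, vv) in enumerate(cap_edges):
        d = g.edges[uu, vv]
        if stalled[j]:
            d["is_stalled"] = True
            d["stall_cause"] = STALL_CAUSES[cause_idx[j]]
            d["speed_um_s"] = 0.0
        else:
            d["speed_um_s"] = float(speeds[j])

    vg = VesselGraph(g)
    vg.validate()
    return vg
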