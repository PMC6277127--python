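"""Array-backed graph model for splined vascular networks.

A vascular network is a collection of nodes (junctions, inlets, outlets)
and splined segments (tubular connections between junctions).  Each
segment carries a reference orientation tail -> head; signed flows are
positive in that direction.  Geometry lives in micrometres with the pial
surface at z = 0 and cortical depth increasing downward (depth = -z for
slab domains).

The container is column-oriented (NumPy arrays per field) so that the
sparse incidence matrices of the flow problem can be assembled without
per-record Python overhead; record-level views (:class:`Node`,
:class:`Segment`) are provided for convenience.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

#: valid node roles
NODE_ROLES = ("interior", "arterial_inlet", "venous_outlet")

#: anatomical compartments: pial arteries, penetrating arterioles,
#: pre-capillaries, capillaries, post-capillaries, ascending venules,
#: pial veins
COMPARTMENTS = ("PIA", "PEA", "PEC", "CAP", "POC", "AV", "PV")


class SchemaError(ValueError):
    """A record in a network file violates the schema."""


class ValidationError(ValueError):
    """A network violates a structural invariant."""


@dataclass
class Node:
    id: int
    position: np.ndarray  # (3,) um
    role: str = "interior"

    @property
    def depth(self) -> float:
        """Cortical depth in um below the pial surface (z = 0)."""
        return -float(self.position[2])


@dataclass
class Segment:
    id: int
    tail: int
    head: int
    diameter: float  # um
    length: float  # arc length, um
    compartment: str = "CAP"
    control_points: np.ndarray | None = None  # (k, 3) um, Bezier control net

    def chord(self, positions: dict[int, np.ndarray]) -> float:
        return float(np.linalg.norm(positions[self.head] - positions[self.tail]))


@dataclass
class DomainDescriptor:
    """Perfusion-domain geometry.

    ``kind='slab'``: a box with the pial plane at z = 0, lateral extents
    ``lx`` x ``ly`` (um) and cortical depth extent ``depth`` (um).
    ``tissue_volume_convention`` selects between the bounding box and the
    convex hull of the vessel nodes as the tissue-volume denominator used
    by perfusion and surface-to-volume reports.
    """

    kind: str = "slab"
    lx: float = 1000.0
    ly: float = 1000.0
    depth: float = 1000.0
    tissue_volume_convention: str = "box"

    def tissue_volume_mm3(self, net: "VascularNetwork | None" = None) -> float:
        if self.tissue_volume_convention == "convex_hull":
            if net is None or net.n_nodes < 4:
                raise ValidationError("convex hull volume needs a network with >= 4 nodes")
            from scipy.spatial import ConvexHull

            return float(ConvexHull(net.positions).volume) / 1e9
        vol = self.lx * self.ly * self.depth / 1e9
        if vol <= 0:
            raise ValidationError("tissue volume must be positive")
        return vol

    def contains(self, pts: np.ndarray, margin: float = 0.0) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return (
            (pts[:, 0] >= -margin)
            & (pts[:, 0] <= self.lx + margin)
            & (pts[:, 1] >= -margin)
            & (pts[:, 1] <= self.ly + margin)
            & (pts[:, 2] <= margin)
            & (pts[:, 2] >= -self.depth - margin)
        )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "lx_um": self.lx,
            "ly_um": self.ly,
            "depth_um": self.depth,
            "tissue_volume_convention": self.tissue_volume_convention,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DomainDescriptor":
        return cls(
            kind=d.get("kind", "slab"),
            lx=float(d.get("lx_um", 1000.0)),
            ly=float(d.get("ly_um", 1000.0)),
            depth=float(d.get("depth_um", 1000.0)),
            tissue_volume_convention=d.get("tissue_volume_convention", "box"),
        )


@dataclass
class IncidenceMatrices:
    """Connectivity operators of the network flow problem.

    ``C1`` (n_segments x n_nodes) maps nodal pressures to per-segment
    pressure differences (+1 at the tail, -1 at the head).  ``C2``
    (n_interior x n_segments) expresses mass conservation at interior
    nodes.  The hematocrit advection operator C3 depends on the current
    flow field and is assembled by the solver.
    """

    C1: sp.csr_matrix
    C2: sp.csr_matrix
    interior_nodes: np.ndarray  # node indices (positional) of the C2 rows


class VascularNetwork:
    """Nodes + splined segments + perfusion domain."""

    def __init__(
        self,
        node_ids: Sequence[int],
        positions: np.ndarray,
        roles: Sequence[str],
        seg_ids: Sequence[int],
        tails: Sequence[int],
        heads: Sequence[int],
        diameters: Sequence[float],
        lengths: Sequence[float] | None = None,
        compartments: Sequence[str] | None = None,
        control_points: list[np.ndarray | None] | None = None,
        domain: DomainDescriptor | None = None,
    ):
        self.node_ids = np.asarray(node_ids, dtype=np.int64)
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        self.roles = np.asarray(roles, dtype=object)
        self.seg_ids = np.asarray(seg_ids, dtype=np.int64)
        self.tails = np.asarray(tails, dtype=np.int64)
        self.heads = np.asarray(heads, dtype=np.int64)
        self.diameters = np.asarray(diameters, dtype=float)
        self.compartments = (
            np.asarray(compartments, dtype=object)
            if compartments is not None
            else np.full(len(self.seg_ids), "CAP", dtype=object)
        )
        self.control_points = control_points if control_points is not None else [None] * len(self.seg_ids)
        self.domain = domain if domain is not None else DomainDescriptor()

        self._index_of = {int(i): k for k, i in enumerate(self.node_ids)}
        if len(self._index_of) != len(self.node_ids):
            raise SchemaError("duplicate node ids")
        missing = [int(i) for i in np.concatenate([self.tails, self.heads]) if int(i) not in self._index_of]
        if missing:
            raise SchemaError(f"segment references unknown node id(s) {sorted(set(missing))[:5]}")
        self.tail_idx = np.array([self._index_of[int(i)] for i in self.tails], dtype=np.int64)
        self.head_idx = np.array([self._index_of[int(i)] for i in self.heads], dtype=np.int64)
        if lengths is None:
            self.lengths = self.chords().copy()
        else:
            self.lengths = np.asarray(lengths, dtype=float)

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_segments(self) -> int:
        return len(self.seg_ids)

    def node_index(self, node_id: int) -> int:
        return self._index_of[int(node_id)]

    def chords(self) -> np.ndarray:
        """Euclidean tail-head distance per segment, um."""
        return np.linalg.norm(self.positions[self.head_idx] - self.positions[self.tail_idx], axis=1)

    def tortuosity(self) -> np.ndarray:
        chord = self.chords()
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(chord > 0, self.lengths / chord, 1.0)

    def depths(self) -> np.ndarray:
        """Per-node cortical depth, um (>= 0 for in-domain nodes)."""
        return -self.positions[:, 2]

    def segment_mid_depths(self) -> np.ndarray:
        mid = 0.5 * (self.positions[self.tail_idx] + self.positions[self.head_idx])
        return -mid[:, 2]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.tail_idx, 1)
        np.add.at(deg, self.head_idx, 1)
        return deg

    @property
    def inlet_idx(self) -> np.ndarray:
        return np.flatnonzero(self.roles == "arterial_inlet")

    @property
    def outlet_idx(self) -> np.ndarray:
        return np.flatnonzero(self.roles == "venous_outlet")

    def nodes(self) -> Iterable[Node]:
        for k in range(self.n_nodes):
            yield Node(int(self.node_ids[k]), self.positions[k], str(self.roles[k]))

    def segments(self) -> Iterable[Segment]:
        for k in range(self.n_segments):
            yield Segment(
                int(self.seg_ids[k]),
                int(self.tails[k]),
                int(self.heads[k]),
                float(self.diameters[k]),
                float(self.lengths[k]),
                str(self.compartments[k]),
                self.control_points[k],
            )

    # -------------------------------------------------------------- geometry
    def segment_volumes_um3(self) -> np.ndarray:
        return np.pi * self.diameters**2 / 4.0 * self.lengths

    def segment_surfaces_um2(self) -> np.ndarray:
        return np.pi * self.diameters * self.lengths

    # ------------------------------------------------------------- structure
    def to_networkx(self):
        import networkx as nx

        g = nx.MultiGraph()
        g.add_nodes_from(int(i) for i in self.node_ids)
        for k in range(self.n_segments):
            g.add_edge(int(self.tails[k]), int(self.heads[k]), key=int(self.seg_ids[k]))
        return g

    def connected_components(self) -> list[set[int]]:
        import networkx as nx

        return [set(c) for c in nx.connected_components(self.to_networkx())]

    def check(self) -> None:
        """Raise :class:`ValidationError` on any structural defect."""
        if self.n_segments == 0:
            raise ValidationError("network has no segments")
        if np.any(~np.isfinite(self.diameters)) or np.any(self.diameters <= 0):
            raise ValidationError("segment diameters must be finite and > 0")
        if np.any(~np.isfinite(self.lengths)) or np.any(self.lengths <= 0):
            raise ValidationError("segment lengths must be finite and > 0")
        if np.any(self.tail_idx == self.head_idx):
            raise ValidationError("self-loop segment (tail == head)")
        if np.any(self.lengths < self.chords() - 1e-6):
            raise ValidationError("segment arc length shorter than its chord")
        if len(self.inlet_idx) < 1 or len(self.outlet_idx) < 1:
            raise ValidationError("network needs >= 1 arterial inlet and >= 1 venous outlet")
        deg = self.degrees()
        bad = [int(self.node_ids[i]) for i in np.concatenate([self.inlet_idx, self.outlet_idx]) if deg[i] != 1]
        if bad:
            raise ValidationError(f"inlet/outlet nodes must have degree 1: {bad[:5]}")
        comps = self.connected_components()
        if len(comps) > 1:
            sizes = sorted((len(c) for c in comps), reverse=True)
            raise ValidationError(f"network is disconnected: {len(comps)} components of sizes {sizes[:5]}")


# ---------------------------------------------------------------------------
def build_incidence(net: VascularNetwork) -> IncidenceMatrices:
    """Assemble the signed incidence operators C1 and C2.

    C1 rows carry +1 at the segment tail and -1 at the head so that
    ``C1 @ p`` is the tail-to-head pressure drop.  C2 restricts the node
    balance ``C1.T @ Q`` to interior nodes (Dirichlet inlets/outlets are
    excluded).
    """
    ns, nn = net.n_segments, net.n_nodes
    rows = np.repeat(np.arange(ns), 2)
    cols = np.column_stack([net.tail_idx, net.head_idx]).ravel()
    data = np.tile([1.0, -1.0], ns)
    C1 = sp.csr_matrix((data, (rows, cols)), shape=(ns, nn))

    interior = np.flatnonzero(net.roles == "interior")
    # net flow into node = sum_in Q - sum_out Q = -(C1.T Q) restricted
    C2 = (-C1.T).tocsr()[interior]
    return IncidenceMatrices(C1=C1, C2=C2, interior_nodes=interior)


def validate(net: VascularNetwork) -> dict:
    """Report-only structural diagnostics (never raises)."""
    deg = net.degrees()
    interior = net.roles == "interior"
    junction_deg = deg[interior]
    hist = np.bincount(deg)
    try:
        comps = net.connected_components()
        n_comp = len(comps)
    except Exception:
        n_comp = -1
    n_bif = int(np.sum(junction_deg == 3))
    n_multi = int(np.sum(junction_deg >= 4))
    # segments incident to a multifurcation (the paper reports both readings)
    multi_nodes = set(np.flatnonzero(interior & (deg >= 4)))
    seg_multi = int(np.sum([(t in multi_nodes) or (h in multi_nodes) for t, h in zip(net.tail_idx, net.head_idx)]))
    return {
        "n_nodes": net.n_nodes,
        "n_segments": net.n_segments,
        "n_components": n_comp,
        "degree_histogram": hist.tolist(),
        "n_bifurcations": n_bif,
        "n_multifurcations": n_multi,
        "n_segments_at_multifurcations": seg_multi,
        "multifurcation_fraction_of_segments": seg_multi / max(net.n_segments, 1),
        "n_dangling_interior": int(np.sum(junction_deg == 1)),
        "n_inlets": len(net.inlet_idx),
        "n_outlets": len(net.outlet_idx),
    }


def merged_segment_count(net: VascularNetwork) -> int:
    """Number of splined segments after merging degree-2 chains.

    Splines are tubular connections between branching points, so the
    count must be invariant to subdividing a segment with degree-2
    nodes.  Endpoints (inlets/outlets, degree-1 and degree >= 3 nodes)
    delimit splines; pure cycles without any junction count as one.
    """
    deg = net.degrees()
    is_junction = (deg != 2) | (net.roles != "interior")
    adj: dict[int, list[tuple[int, int]]] = {}
    for k in range(net.n_segments):
        adj.setdefault(int(net.tail_idx[k]), []).append((k, int(net.head_idx[k])))
        adj.setdefault(int(net.head_idx[k]), []).append((k, int(net.tail_idx[k])))
    seen = np.zeros(net.n_segments, dtype=bool)
    count = 0
    for start in np.flatnonzero(is_junction):
        for k0, nxt in adj.get(int(start), []):
            if seen[k0]:
                continue
            seen[k0] = True
            node = nxt
            while not is_junction[node]:
                (ka, na), (kb, nb) = adj[node]
                k0, node = (kb, nb) if seen[ka] else (ka, na)
                seen[k0] = True
            count += 1
    # leftover segments belong to junction-free cycles
    for k in range(net.n_segments):
        if not seen[k]:
            count += 1
            node = int(net.tail_idx[k])
            seen[k] = True
            nxt = int(net.head_idx[k])
            while nxt != node:
                (ka, na), (kb, nb) = adj[nxt]
                kk, nxt = (kb, nb) if seen[ka] else (ka, na)
                seen[kk] = True
    return count
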