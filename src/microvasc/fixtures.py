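"""Deterministic miniature networks for testing and demonstration.

Available fixtures:

``single_segment``
    one vessel from an arterial inlet straight down to a venous outlet.
``single_bifurcation``
    a parent splitting into two daughters (configurable daughter
    diameters) that both end in venous outlets.
``y_tree``
    parent + two unequal daughters rejoining nothing: 3 segments,
    4 nodes, 1 bifurcation, 1 inlet, 2 outlets.
``honeycomb_lattice``
    a meshed hexagonal capillary bed (rows x cols cells) spanning inlet
    to outlet; contains flow loops, exercising the non-acyclic
    hematocrit solve.
``two_layer_toy``
    one shallow thin side branch and one deep thick trunk route between
    a single inlet and outlet: the minimal instance of depth-dependent
    hematocrit under plasma skimming.
"""

from __future__ import annotations

import numpy as np

from .network import DomainDescriptor, VascularNetwork

_FIXTURES = ("single_segment", "single_bifurcation", "y_tree", "honeycomb_lattice", "two_layer_toy")


def _net(nodes, segs, domain=None, roles=None):
    nodes = np.asarray(nodes, dtype=float)
    n = len(nodes)
    if roles is None:
        roles = ["interior"] * n
    return VascularNetwork(
        node_ids=np.arange(n),
        positions=nodes,
        roles=roles,
        seg_ids=np.arange(len(segs)),
        tails=[s[0] for s in segs],
        heads=[s[1] for s in segs],
        diameters=[s[2] for s in segs],
        compartments=[s[3] for s in segs],
        domain=domain or DomainDescriptor(lx=1000, ly=1000, depth=1000),
    )


def make_fixture(name: str, **params) -> VascularNetwork:
    """Construct one of the named fixture networks."""
    if name == "single_segment":
        d = params.get("diameter", 10.0)
        nodes = [[100, 100, 0], [100, 100, -500]]
        roles = ["arterial_inlet", "venous_outlet"]
        return _net(nodes, [(0, 1, d, "CAP")], roles=roles)

    if name == "single_bifurcation":
        d1 = params.get("d1", 8.0)
        d2 = params.get("d2", 8.0)
        nodes = [[100, 500, 0], [400, 500, -200], [700, 300, -300], [700, 700, -300]]
        roles = ["arterial_inlet", "interior", "venous_outlet", "venous_outlet"]
        segs = [(0, 1, 10.0, "PEA"), (1, 2, d1, "CAP"), (1, 3, d2, "CAP")]
        return _net(nodes, segs, roles=roles)

    if name == "y_tree":
        return make_fixture("single_bifurcation", d1=params.get("d1", 8.0), d2=params.get("d2", 5.0))

    if name == "honeycomb_lattice":
        return _honeycomb(params.get("rows", 3), params.get("cols", 3))

    if name == "two_layer_toy":
        return _two_layer_toy()

    raise ValueError(f"unknown fixture {name!r}; available: {', '.join(_FIXTURES)}")


def _honeycomb(rows: int, cols: int) -> VascularNetwork:
    """Brick-wall hexagonal lattice of capillaries between one inlet and
    one outlet, laid out in the x-z plane (so rows span cortical depth)."""
    dx, dz = 60.0, 50.0
    idx = {}
    nodes = []

    def node(i, j):
        if (i, j) not in idx:
            x = j * dx + (25.0 if i % 2 else 0.0)
            idx[(i, j)] = len(nodes)
            nodes.append([100.0 + x, 300.0, -80.0 - i * dz])
        return idx[(i, j)]

    segs = []
    for i in range(rows + 1):
        for j in range(cols):
            segs.append((node(i, j), node(i, j + 1), 5.0, "CAP"))  # horizontal rungs
    for i in range(rows):
        for j in range(0, cols + 1, 2):
            jj = j + (1 if i % 2 else 0)
            if jj <= cols:
                segs.append((node(i, jj), node(i + 1, jj), 5.0, "CAP"))  # vertical struts
    inlet = len(nodes)
    nodes.append([40.0, 300.0, -30.0])
    outlet = len(nodes)
    nodes.append([160.0 + cols * dx, 300.0, -30.0 - rows * dz])
    segs.append((inlet, node(0, 0), 8.0, "PEA"))
    segs.append((node(rows, cols), outlet, 8.0, "AV"))
    roles = ["interior"] * len(nodes)
    roles[inlet] = "arterial_inlet"
    roles[outlet] = "venous_outlet"
    return _net(nodes, segs, roles=roles)


def _two_layer_toy() -> VascularNetwork:
    """Shallow thin side branch vs deep thick trunk.

    At the first junction the thick trunk keeps most of the flow, so
    with plasma skimming it is enriched in red cells while the thin
    shallow branch skims plasma: the deep route ends up with higher
    hematocrit despite its greater path length.
    """
    nodes = [
        [100, 500, 0],       # 0 inlet
        [250, 500, -50],     # 1 junction A
        [500, 500, -60],     # 2 shallow route mid (layer I)
        [750, 500, -50],     # 3 junction B
        [350, 500, -500],    # 4 deep route descent
        [550, 500, -800],    # 5 deep route bottom (layer V)
        [750, 500, -400],    # 6 deep route ascent
        [900, 500, 0],       # 7 outlet
    ]
    roles = ["interior"] * 8
    roles[0] = "arterial_inlet"
    roles[7] = "venous_outlet"
    segs = [
        (0, 1, 12.0, "PEA"),
        (1, 2, 4.0, "CAP"),   # shallow, thin
        (2, 3, 4.0, "CAP"),
        (1, 4, 10.0, "PEA"),  # deep, thick
        (4, 5, 9.0, "CAP"),
        (5, 6, 9.0, "POC"),
        (6, 3, 10.0, "AV"),
        (3, 7, 12.0, "AV"),
    ]
    return _net(nodes, segs, roles=roles)
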