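"""Coupled pressure / flow / hematocrit solution on a vascular network.

The unknowns are nodal pressures p (Pa), signed segment flows Q (m^3/s,
positive tail -> head) and per-segment discharge hematocrits h.  They
satisfy three coupled balances: Poiseuille resistance relates Q to the
nodal pressure differences, bulk mass is conserved at every interior
node, and the red-cell phase is advected through junctions with a
plasma-skimming split at diverging nodes.  Because the resistance
depends on h (Fahraeus-Lindqvist viscosity) and the advection operator
depends on the flow directions, the system is nonlinear; it is solved by
Picard alternation with under-relaxation on h, rebuilding the advection
operator whenever flow directions change.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import VascularNetwork, build_incidence
from .rheology import RheologyParams, junction_mix, segment_resistance, skimming_fractions
from .units import PA_PER_MMHG, perfusion_si_to_clinical


class ConvergenceError(RuntimeError):
    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


@dataclass
class BoundaryConditions:
    """Dirichlet pressures at inlets/outlets plus the inlet hematocrit.

    Outlet hematocrit is fully developed (zero gradient): outlet
    segments simply inherit their upstream value.  Closed side/bottom
    boundaries are zero-flux by construction (no boundary segments).
    """

    inlet_pressure_mmhg: float = 120.0
    outlet_pressure_mmhg: float = 5.0
    inlet_hematocrit: float = 0.35

    def __post_init__(self):
        if self.inlet_pressure_mmhg <= self.outlet_pressure_mmhg:
            raise ValueError("inlet pressure must exceed outlet pressure")
        if not (0 < self.inlet_hematocrit < 1):
            raise ValueError("inlet hematocrit must lie in (0, 1)")


@dataclass
class SolverConfig:
    relaxation: float = 0.5  # Picard under-relaxation factor on h
    tolerance: float = 1e-6  # relative L-inf change of h and Q
    max_iterations: int = 200
    zero_flow_threshold: float = 1e-9  # fraction of median |Q|
    rheology: RheologyParams = dc_field(default_factory=RheologyParams)

    def __post_init__(self):
        if not (0 < self.relaxation <= 1):
            raise ValueError("relaxation must lie in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class SolutionField:
    p: np.ndarray  # per-node pressure, Pa
    Q: np.ndarray  # per-segment signed flow, m^3/s (tail -> head positive)
    h: np.ndarray  # per-segment discharge hematocrit
    history: list = dc_field(default_factory=list)  # (dh, dq) per iteration
    zero_flow: np.ndarray | None = None  # flagged stagnant segments

    @property
    def iterations(self) -> int:
        return len(self.history)


# ------------------------------------------------------------ pressure/flow
def solve_pressure_flow(
    net: VascularNetwork,
    h: np.ndarray,
    bc: BoundaryConditions,
    params: RheologyParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-phase Poiseuille solve at fixed hematocrit.

    Eliminates Q to obtain the sparse SPD nodal system
    ``C1^T diag(1/R) C1 p = 0`` on interior nodes with Dirichlet
    pressures at inlets/outlets, then back-substitutes
    ``Q = diag(1/R) C1 p``.
    """
    params = params or RheologyParams()
    R = segment_resistance(net.diameters, net.lengths, h, params)
    g = 1.0 / np.asarray(R)  # segment conductances

    inc = build_incidence(net)
    L = inc.C1.T @ sp.diags(g) @ inc.C1  # weighted graph Laplacian (n_nodes^2)

    p = np.zeros(net.n_nodes)
    p[net.inlet_idx] = bc.inlet_pressure_mmhg * PA_PER_MMHG
    p[net.outlet_idx] = bc.outlet_pressure_mmhg * PA_PER_MMHG
    interior = inc.interior_nodes
    fixed = np.ones(net.n_nodes, dtype=bool)
    fixed[interior] = False

    L = L.tocsr()
    A = L[interior][:, interior].tocsc()
    b = -L[interior][:, np.flatnonzero(fixed)] @ p[fixed]

    # guard against floating components with no Dirichlet (boundary) node
    from scipy.sparse.csgraph import connected_components

    adj = sp.csr_matrix(
        (np.ones(net.n_segments), (net.tail_idx, net.head_idx)), shape=(net.n_nodes, net.n_nodes)
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        anchored = set(labels[fixed])
        orphans = [int(net.node_ids[i]) for i in range(net.n_nodes) if labels[i] not in anchored]
        if orphans:
            raise ValueError(
                f"singular pressure system: component with nodes {orphans[:5]} sees no boundary node"
            )
    try:
        lu = spla.splu(A)
        x = lu.solve(b)
        # one step of iterative refinement keeps nodal balances at ~1e-13
        # relative even on badly scaled capillary/artery conductances
        for _ in range(2):
            r = b - A @ x
            x += lu.solve(r)
        p[interior] = x
    except RuntimeError as e:  # pragma: no cover - factorization failure
        raise ValueError(f"pressure system could not be factorised: {e}") from e

    Q = g * (inc.C1 @ p)
    return p, Q


# --------------------------------------------------------------- hematocrit
def _assemble_advection(net, Q, bc, params, zero_mask):
    """Sparse linear system A h = b of the junction-by-junction advection.

    Every segment's hematocrit is set at its upstream node: inlet-fed
    segments carry the boundary hematocrit, daughters of diverging
    junctions receive skimmed fractions of the mixed inflow, single
    outflows inherit the flux-weighted mix (which also realises the
    fully developed zero-gradient outlet rule).
    """
    ns = net.n_segments
    up_node = np.where(Q >= 0, net.tail_idx, net.head_idx)
    dn_node = np.where(Q >= 0, net.head_idx, net.tail_idx)
    absQ = np.abs(Q)

    active = ~zero_mask
    in_segs: dict[int, list[int]] = {}
    out_segs: dict[int, list[int]] = {}
    for k in np.flatnonzero(active):
        out_segs.setdefault(int(up_node[k]), []).append(k)
        in_segs.setdefault(int(dn_node[k]), []).append(k)

    rows, cols, data, b = [], [], [], np.zeros(ns)
    is_inlet = np.zeros(net.n_nodes, dtype=bool)
    is_inlet[net.inlet_idx] = True

    for node, outs in out_segs.items():
        Qo = absQ[outs]
        phi = skimming_fractions(Qo, params.m) if len(outs) > 1 else np.array([1.0])
        alpha = phi * Qo.sum() / Qo  # h_i = alpha_i * h_mix
        if is_inlet[node]:
            for k, a in zip(outs, alpha):
                rows.append(k)
                cols.append(k)
                data.append(1.0)
                b[k] = a * bc.inlet_hematocrit
            continue
        ins = in_segs.get(node, [])
        Qi = absQ[ins]
        Qi_tot = Qi.sum()
        for k, a in zip(outs, alpha):
            rows.append(k)
            cols.append(k)
            data.append(1.0)
            if Qi_tot > 0:
                for j, qj in zip(ins, Qi):
                    rows.append(k)
                    cols.append(j)
                    data.append(-a * qj / Qi_tot)
            # nodes with outflow but no active inflow: h stays 0 (flagged)
    # stagnant segments: identity row, value filled in afterwards
    for k in np.flatnonzero(zero_mask):
        rows.append(k)
        cols.append(k)
        data.append(1.0)
    A = sp.csr_matrix((data, (rows, cols)), shape=(ns, ns))
    return A, b, up_node, dn_node, in_segs


def solve_hematocrit(
    net: VascularNetwork,
    Q: np.ndarray,
    bc: BoundaryConditions,
    params: RheologyParams | None = None,
    zero_flow_threshold: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear advection solve of the hematocrit field for fixed flows.

    Returns ``(h, zero_flow_mask)``.  The assembled operator is linear
    in h (the skimming coefficients depend only on Q and m), so one
    sparse solve handles meshed beds with flow-directed cycles as well
    as trees.  Stagnant segments (|Q| below a fraction of the median
    flow magnitude) are excluded from junction balances and afterwards
    assigned the mixed hematocrit at their higher-pressure endpoint.
    """
    params = params or RheologyParams()
    absQ = np.abs(Q)
    qref = np.median(absQ[absQ > 0]) if np.any(absQ > 0) else 0.0
    zero_mask = absQ <= zero_flow_threshold * qref

    A, b, up_node, dn_node, in_segs = _assemble_advection(net, Q, bc, params, zero_mask)
    h = spla.spsolve(A.tocsc(), b)
    h = np.clip(h, 0.0, params.h_max)

    if np.any(zero_mask):
        # mixed hematocrit available at each node from active inflows
        node_mix = np.full(net.n_nodes, bc.inlet_hematocrit)
        for node, ins in in_segs.items():
            Qi = absQ[ins]
            if Qi.sum() > 0:
                node_mix[node] = junction_mix(list(zip(Qi, h[ins])))
        for k in np.flatnonzero(zero_mask):
            h[k] = node_mix[up_node[k]]  # upstream = higher-pressure endpoint
    return h, zero_mask


# ------------------------------------------------------------------ coupled
def solve_biphasic(
    net: VascularNetwork,
    bc: BoundaryConditions | None = None,
    config: SolverConfig | None = None,
    h0: np.ndarray | float | None = None,
) -> SolutionField:
    """Fixed-point iteration of the coupled biphasic system.

    Alternates the pressure/flow solve (at the current h) with the
    hematocrit advection solve (at the current Q), under-relaxing h.
    Converges when the relative L-inf changes of both h and Q fall
    below the configured tolerance.
    """
    bc = bc or BoundaryConditions()
    config = config or SolverConfig()
    net.check()
    params = config.rheology

    if h0 is None:
        h = np.full(net.n_segments, bc.inlet_hematocrit)
    else:
        h = np.broadcast_to(np.asarray(h0, float), (net.n_segments,)).copy()
    Q_old = None
    history = []
    zero_mask = np.zeros(net.n_segments, dtype=bool)
    for it in range(config.max_iterations):
        p, Q = solve_pressure_flow(net, h, bc, params)
        h_new, zero_mask = solve_hematocrit(net, Q, bc, params, config.zero_flow_threshold)
        omega = config.relaxation
        dh = float(np.max(np.abs(h_new - h)) / max(np.max(np.abs(h_new)), 1e-300))
        dq = (
            float(np.max(np.abs(Q - Q_old)) / max(np.max(np.abs(Q)), 1e-300))
            if Q_old is not None
            else np.inf
        )
        h = (1.0 - omega) * h + omega * h_new
        Q_old = Q
        history.append((dh, dq))
        if dh < config.tolerance and dq < config.tolerance:
            # final consistent pass: p, Q at the converged hematocrit and
            # h as the exact advection solution for that flow field
            p, Q = solve_pressure_flow(net, h, bc, params)
            h, zero_mask = solve_hematocrit(net, Q, bc, params, config.zero_flow_threshold)
            return SolutionField(p=p, Q=Q, h=h, history=history, zero_flow=zero_mask)
    raise ConvergenceError(
        f"biphasic solve did not converge in {config.max_iterations} iterations "
        f"(last dh={history[-1][0]:.2e}, dq={history[-1][1]:.2e})",
        history,
    )


# ---------------------------------------------------------------- derived
def total_inflow(net: VascularNetwork, field: SolutionField) -> float:
    """Total arterial inflow, m^3/s (signed out of the inlet nodes)."""
    flow = 0.0
    for i in net.inlet_idx:
        out = net.tail_idx == i
        flow += float(np.sum(field.Q[out]))
        flow -= float(np.sum(field.Q[net.head_idx == i]))
    return flow


def compute_perfusion(
    net: VascularNetwork,
    field: SolutionField,
    tissue_density_g_ml: float = 1.0,
) -> dict:
    """Bulk tissue perfusion from the converged solution.

    perfusion = total arterial inflow / (tissue volume x density),
    reported both in ml/100g/min and m^3/kg/s.
    """
    vol_mm3 = net.domain.tissue_volume_mm3(net)
    if vol_mm3 <= 0:
        raise ValueError("tissue volume must be positive")
    inflow = total_inflow(net, field)  # m^3/s
    mass_kg = vol_mm3 * 1e-9 * tissue_density_g_ml * 1000.0  # mm^3 -> m^3 -> kg
    perf_si = inflow / mass_kg
    return {
        "perfusion_ml_100g_min": perfusion_si_to_clinical(perf_si),
        "perfusion_m3_kg_s": perf_si,
        "total_inflow_nl_s": inflow * 1e12,
        "tissue_volume_mm3": vol_mm3,
    }


def rbc_flux(field: SolutionField) -> np.ndarray:
    """Per-segment volumetric RBC flux |Q| h, m^3/s."""
    return np.abs(field.Q) * field.h
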