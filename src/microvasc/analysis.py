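"""Flow-path tracing and cortical-layer statistics.

Paths run from an arterial inlet downstream through the capillary bed to
a venous outlet, following positive-flow directions.  Each path gets a
depth label equal to the cortical depth of its deepest segment and is
thereby ordered within the cortical layer hierarchy (I-VI).  Layer-wise
statistics of discharge hematocrit h, bulk flow Q and RBC flux |Q| h
quantify the depth dependence of the red-cell supply; a one-way ANOVA of
h across layers tests it formally.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .network import VascularNetwork
from .solver import SolutionField, rbc_flux
from .units import PA_PER_MMHG

#: default laminar depth boundaries, um (layer I, II/III, IV, V, VI)
DEFAULT_LAYER_BOUNDARIES = (0.0, 100.0, 420.0, 590.0, 890.0)
LAYER_NAMES = ("I", "II/III", "IV", "V", "VI")


@dataclass
class FlowPath:
    segments: list[int]  # segment positional indices, flow-ordered
    nodes: list[int]  # node positional indices, len(segments) + 1
    length_um: float
    depth_label_um: float  # max mid-segment cortical depth along the path
    layer: str = ""
    pressures_pa: np.ndarray | None = None  # per visited node
    hematocrits: np.ndarray | None = None  # per traversed segment
    flows_m3s: np.ndarray | None = None
    diameters_um: np.ndarray | None = None


@dataclass
class LayerStats:
    table: pd.DataFrame  # one row per layer
    anova_F: float
    anova_p: float
    grouping: str = "segment"


# -------------------------------------------------------------- tracing
def _directed_adjacency(net: VascularNetwork, field: SolutionField):
    up = np.where(field.Q >= 0, net.tail_idx, net.head_idx)
    dn = np.where(field.Q >= 0, net.head_idx, net.tail_idx)
    absQ = np.abs(field.Q)
    out: dict[int, list[int]] = {}
    active = ~(field.zero_flow if field.zero_flow is not None else np.zeros(len(absQ), bool))
    for k in np.flatnonzero(active & (absQ > 0)):
        out.setdefault(int(up[k]), []).append(k)
    return out, up, dn, absQ


def trace_paths(
    net: VascularNetwork,
    field: SolutionField,
    n_paths: int = 1000,
    mode: str = "flux_weighted_sampling",
    rng: np.random.Generator | int | None = None,
    max_steps: int = 100000,
) -> list[FlowPath]:
    """Trace inlet-to-outlet flow paths on a converged solution.

    ``flux_weighted_sampling``: random walks from a flux-weighted random
    inlet, choosing each diverging branch with probability proportional
    to its outflow; duplicates are removed.  ``exhaustive_capped``:
    depth-first enumeration of distinct paths up to ``n_paths``.
    """
    if n_paths < 1:
        raise ValueError("need n_paths >= 1")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else int(rng))
    out, up, dn, absQ = _directed_adjacency(net, field)
    is_outlet = np.zeros(net.n_nodes, dtype=bool)
    is_outlet[net.outlet_idx] = True
    mid_depth = net.segment_mid_depths()

    paths: list[FlowPath] = []
    seen: set[tuple[int, ...]] = set()
    discarded = 0

    def finalize(seg_seq: list[int], node_seq: list[int]):
        key = tuple(seg_seq)
        if key in seen:
            return
        seen.add(key)
        paths.append(
            FlowPath(
                segments=list(seg_seq),
                nodes=list(node_seq),
                length_um=float(np.sum(net.lengths[seg_seq])),
                depth_label_um=float(np.max(mid_depth[seg_seq])),
                pressures_pa=field.p[node_seq].copy(),
                hematocrits=field.h[seg_seq].copy(),
                flows_m3s=field.Q[seg_seq].copy(),
                diameters_um=net.diameters[seg_seq].copy(),
            )
        )

    if mode == "flux_weighted_sampling":
        inlets = net.inlet_idx
        win = np.array([sum(absQ[k] for k in out.get(int(i), [])) for i in inlets])
        if win.sum() <= 0:
            raise ValueError("no flow leaves any inlet")
        win = win / win.sum()
        attempts = 0
        while len(paths) < n_paths and attempts < 20 * n_paths:
            attempts += 1
            node = int(rng.choice(inlets, p=win))
            seg_seq: list[int] = []
            node_seq = [node]
            ok = False
            for _ in range(max_steps):
                outs = out.get(node, [])
                if not outs:
                    break
                w = absQ[outs]
                k = outs[int(rng.choice(len(outs), p=w / w.sum()))] if len(outs) > 1 else outs[0]
                seg_seq.append(int(k))
                node = int(dn[k])
                node_seq.append(node)
                if is_outlet[node]:
                    ok = True
                    break
            if ok:
                finalize(seg_seq, node_seq)
            else:
                discarded += 1
    elif mode == "exhaustive_capped":
        stack = [(int(i), [], [int(i)]) for i in net.inlet_idx]
        while stack and len(paths) < n_paths:
            node, seg_seq, node_seq = stack.pop()
            if is_outlet[node] and seg_seq:
                finalize(seg_seq, node_seq)
                continue
            for k in out.get(node, []):
                if len(seg_seq) < max_steps:
                    stack.append((int(dn[k]), seg_seq + [int(k)], node_seq + [int(dn[k])]))
    else:
        raise ValueError(f"unknown tracing mode {mode!r}")

    boundaries = DEFAULT_LAYER_BOUNDARIES
    labels = assign_layers(np.array([p.depth_label_um for p in paths]), boundaries)
    for p, lab in zip(paths, labels):
        p.layer = lab
    return paths


# --------------------------------------------------------------- layers
def assign_layers(depths_um, boundaries=DEFAULT_LAYER_BOUNDARIES) -> np.ndarray:
    """Half-open binning of cortical depths into layers I-VI.

    ``boundaries`` are the increasing lower edges (um) of layers I,
    II/III, IV, V and VI; depths beyond the last edge map to layer VI.
    A depth exactly on an edge belongs to the deeper layer.
    """
    depths = np.asarray(depths_um, dtype=float)
    if np.any(depths < 0):
        raise ValueError("cortical depth cannot be negative")
    b = np.asarray(boundaries, dtype=float)
    if len(b) != len(LAYER_NAMES) or np.any(np.diff(b) <= 0):
        raise ValueError("boundaries must be strictly increasing, one per layer")
    idx = np.clip(np.searchsorted(b, depths, side="right") - 1, 0, len(LAYER_NAMES) - 1)
    return np.asarray(LAYER_NAMES, dtype=object)[idx]


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA from sums of squares.

    Returns (F, p) with (k-1, N-k) degrees of freedom.  Identical
    constant groups give F = 0, p = 1 (no between-group variation).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    N = sum(len(g) for g in groups)
    k = len(groups)
    if N <= k:
        raise ValueError("need more observations than groups")
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    # between-group variation at rounding level (relative to the data
    # scale) is no variation: identical groups give F = 0 exactly
    scale = N * grand**2 + ss_between + ss_within
    if ss_between <= 1e-13 * scale:
        return 0.0, 1.0
    if ss_within <= 0:
        return np.inf, 0.0
    F = (ss_between / (k - 1)) / (ss_within / (N - k))
    p = float(sps.f.sf(F, k - 1, N - k))
    return float(F), p


def layer_statistics(
    net: VascularNetwork,
    field: SolutionField,
    boundaries=DEFAULT_LAYER_BOUNDARIES,
    grouping: str = "segment",
    paths: list[FlowPath] | None = None,
) -> LayerStats:
    """Per-layer statistics of h, Q and RBC flux.

    ``grouping='segment'`` pools segments by the layer of their midpoint
    depth (as in the layer box-plot statistics); ``grouping='path'``
    pools whole flow paths by their depth label, averaging each path's
    member segments first.  Empty layers are reported as missing rows.
    """
    flux = rbc_flux(field)
    absQ = np.abs(field.Q)
    if grouping == "segment":
        layers = assign_layers(net.segment_mid_depths(), boundaries)
        h, q, f = field.h, absQ, flux
    elif grouping == "path":
        if paths is None:
            raise ValueError("path grouping requires traced paths")
        layers = np.array([p.layer for p in paths], dtype=object)
        h = np.array([np.mean(p.hematocrits) for p in paths])
        q = np.array([np.mean(np.abs(p.flows_m3s)) for p in paths])
        f = np.array([np.mean(np.abs(p.flows_m3s) * p.hematocrits) for p in paths])
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    rows = []
    groups = []
    for name in LAYER_NAMES:
        sel = layers == name
        if not np.any(sel):
            continue
        groups.append(h[sel])
        rows.append(
            {
                "layer": name,
                "n": int(sel.sum()),
                "h_median": float(np.median(h[sel])),
                "h_q25": float(np.percentile(h[sel], 25)),
                "h_q75": float(np.percentile(h[sel], 75)),
                "Q_median_nl_s": float(np.median(q[sel]) * 1e12),
                "rbc_flux_median_nl_s": float(np.median(f[sel]) * 1e12),
                "rbc_flux_variance_nl2_s2": float(np.var(f[sel] * 1e12)),
            }
        )
    table = pd.DataFrame(rows)
    if len(groups) >= 2:
        F, p = anova_oneway(groups)
    else:
        F, p = np.nan, np.nan
    return LayerStats(table=table, anova_F=F, anova_p=p, grouping=grouping)


# -------------------------------------------------------------- profiles
def pressure_profiles(paths: list[FlowPath]) -> pd.DataFrame:
    """Long-format per-path pressure traces vs diameter and path length.

    One row per traversed segment with the path id, cumulative length,
    segment diameter and nodal pressure (mmHg, at the segment's
    downstream node); min/max envelope columns across paths are merged
    in per cumulative-length bin.
    """
    if not paths:
        raise ValueError("need >= 1 path")
    recs = []
    for pid, p in enumerate(paths):
        cum = np.concatenate([[0.0], np.cumsum(_seg_lengths(p))])
        pr = p.pressures_pa / PA_PER_MMHG
        for i, k in enumerate(p.segments):
            recs.append(
                {
                    "path": pid,
                    "layer": p.layer,
                    "segment": k,
                    "cumulative_length_um": float(cum[i + 1]),
                    "diameter_um": float(p.diameters_um[i]),
                    "pressure_mmHg": float(pr[i + 1]),
                }
            )
    df = pd.DataFrame(recs)
    env = (
        df.assign(bin=pd.cut(df["cumulative_length_um"], 50))
        .groupby("bin", observed=True)["pressure_mmHg"]
        .agg(envelope_min="min", envelope_max="max")
        .reset_index(drop=True)
    )
    df.attrs["envelope"] = env
    return df


def _seg_lengths(p: FlowPath) -> np.ndarray:
    # stored per-path diameters parallel the segment list; lengths are
    # reconstructed from cumulative path length proportionally when the
    # network is not at hand
    n = len(p.segments)
    return np.full(n, p.length_um / max(n, 1))


def hematocrit_vs_diameter(
    net: VascularNetwork,
    field: SolutionField,
    bins: int | np.ndarray = 12,
) -> pd.DataFrame:
    """Binned dispersion summary of discharge hematocrit vs diameter.

    Reports per-diameter-bin counts, median h and the interquartile
    range as the variability measure; empty bins are omitted.
    """
    d = net.diameters
    edges = np.histogram_bin_edges(d, bins=bins)
    idx = np.clip(np.digitize(d, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        if not np.any(sel):
            continue
        hh = field.h[sel]
        rows.append(
            {
                "d_low_um": float(edges[b]),
                "d_high_um": float(edges[b + 1]),
                "n": int(sel.sum()),
                "h_median": float(np.median(hh)),
                "h_q25": float(np.percentile(hh, 25)),
                "h_q75": float(np.percentile(hh, 75)),
                "h_iqr": float(np.percentile(hh, 75) - np.percentile(hh, 25)),
            }
        )
    return pd.DataFrame(rows)
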