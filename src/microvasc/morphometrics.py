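"""Topological and geometric summary statistics of vascular networks.

The counting unit is the splined segment: a tubular connection between
branching points.  Degree-2 chains are merged before counting so the
tally is independent of how finely segments are sub-partitioned.
Cumulative metrics (length, intravascular volume, vascular surface
area) integrate over the splines; the blood-brain-barrier ratio divides
the capillary-bed endothelial surface by the domain tissue volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .analysis import anova_oneway
from .network import VascularNetwork, merged_segment_count, validate


@dataclass
class MorphometricSummary:
    n_segments: int  # splined (degree-2-merged) count
    n_raw_segments: int
    segments_per_mm2: float  # per mm^2 of pial coverage area
    n_bifurcations: int
    n_multifurcations: int
    n_segments_at_multifurcations: int
    total_length_m: float
    intravascular_volume_nl: float
    vascular_surface_area_mm2: float
    capillary_surface_area_mm2: float
    pial_coverage_area_mm2: float
    tissue_volume_mm3: float
    bbb_surface_to_volume_mm2_per_mm3: float
    diameter_histogram: pd.DataFrame | None = None
    length_histogram: pd.DataFrame | None = None
    tortuosity_histogram: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if not isinstance(v, pd.DataFrame) and v is not None}
        return d


def pial_coverage_area_mm2(net: VascularNetwork) -> float:
    """Area of the 2D convex hull of pial-segment projections, mm^2."""
    from scipy.spatial import ConvexHull

    pial = np.isin(net.compartments.astype(str), ["PIA", "PV"])
    if np.any(pial):
        nodes = np.union1d(net.tail_idx[np.flatnonzero(pial)], net.head_idx[np.flatnonzero(pial)])
        pts = net.positions[nodes][:, :2]
    else:  # fall back to all near-surface nodes
        pts = net.positions[net.depths() < 100.0][:, :2]
    if len(pts) < 3:
        return net.domain.lx * net.domain.ly / 1e6
    try:
        return float(ConvexHull(pts).volume) / 1e6  # 2D hull "volume" is the area
    except Exception:  # degenerate (collinear) projections
        return net.domain.lx * net.domain.ly / 1e6


def summarize(net: VascularNetwork, histograms: bool = False, bins: int = 30) -> MorphometricSummary:
    """Full morphometric summary of one network."""
    diag = validate(net)
    n_spline = merged_segment_count(net)
    length_um = float(np.sum(net.lengths))
    vol_um3 = float(np.sum(net.segment_volumes_um3()))
    surf_um2 = float(np.sum(net.segment_surfaces_um2()))
    cap = net.compartments.astype(str) == "CAP"
    cap_surf_um2 = float(np.sum(net.segment_surfaces_um2()[cap]))
    area_mm2 = pial_coverage_area_mm2(net)
    tissue_mm3 = net.domain.tissue_volume_mm3(net)

    hists = {}
    if histograms:
        for metric in ("diameter", "length", "tortuosity"):
            hists[metric] = distributions(net, metric, bins)

    return MorphometricSummary(
        n_segments=n_spline,
        n_raw_segments=net.n_segments,
        segments_per_mm2=n_spline / area_mm2,
        n_bifurcations=diag["n_bifurcations"],
        n_multifurcations=diag["n_multifurcations"],
        n_segments_at_multifurcations=diag["n_segments_at_multifurcations"],
        total_length_m=length_um * 1e-6,
        intravascular_volume_nl=vol_um3 * 1e-6,  # 1 nL = 1e6 um^3
        vascular_surface_area_mm2=surf_um2 * 1e-6,
        capillary_surface_area_mm2=cap_surf_um2 * 1e-6,
        pial_coverage_area_mm2=area_mm2,
        tissue_volume_mm3=tissue_mm3,
        bbb_surface_to_volume_mm2_per_mm3=cap_surf_um2 * 1e-6 / tissue_mm3,
        diameter_histogram=hists.get("diameter"),
        length_histogram=hists.get("length"),
        tortuosity_histogram=hists.get("tortuosity"),
    )


def distributions(net: VascularNetwork, metric: str, bins: int | np.ndarray = 30) -> pd.DataFrame:
    """Density-normalised histogram of a per-segment metric."""
    if net.n_segments == 0:
        raise ValueError("empty network has no distributions")
    values = {
        "diameter": net.diameters,
        "length": net.lengths,
        "tortuosity": net.tortuosity(),
    }
    if metric not in values:
        raise ValueError(f"unknown metric {metric!r}")
    x = values[metric]
    dens, edges = np.histogram(x, bins=bins, density=True)
    return pd.DataFrame({"low": edges[:-1], "high": edges[1:], "density": dens})


#: cumulative metrics compared between ensembles
ENSEMBLE_METRICS = (
    "n_segments",
    "total_length_m",
    "vascular_surface_area_mm2",
    "intravascular_volume_nl",
    "segments_per_mm2",
    "bbb_surface_to_volume_mm2_per_mm3",
)


def compare_ensembles(
    a: list[MorphometricSummary],
    b: list[MorphometricSummary],
    metrics=ENSEMBLE_METRICS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-metric one-way ANOVA between two network ensembles.

    Rows report F, p and the statistical-equivalence flag (p > alpha:
    no detectable ensemble difference at that level).
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 summaries per ensemble")
    rows = []
    for m in metrics:
        ga = np.array([getattr(s, m) for s in a], dtype=float)
        gb = np.array([getattr(s, m) for s in b], dtype=float)
        F, p = anova_oneway([ga, gb])
        rows.append({"metric": m, "F": F, "p": p, "equivalent": bool(p > alpha)})
    return pd.DataFrame(rows)
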