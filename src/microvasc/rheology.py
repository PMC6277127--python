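"""Constitutive laws of biphasic microvascular blood flow.

Three ingredients close the network flow problem:

* an empirical relative-viscosity law mu_rel(d, h) capturing the
  Fahraeus-Lindqvist effect (apparent viscosity depends on vessel
  diameter and discharge hematocrit),
* the Poiseuille segment resistance R = 128 mu L / (pi d^4), and
* a kinetic plasma-skimming split rule that partitions the red-cell
  phase at diverging junctions.

The split rule is junction-local and linear in the upstream hematocrits:
daughter i of a diverging junction receives the RBC-flux fraction

    phi_i = Q_i^((m+1)/m) / sum_j Q_j^((m+1)/m)

so its discharge hematocrit is h_i = phi_i * F_in / Q_i with F_in the
mixed inflow RBC flux.  The single coefficient m (default 8) controls
skimming strength: the super-linear flow exponent concentrates red cells
in the stronger daughter branch, and m -> inf recovers the proportional
(no-skimming) split.  The rule handles any number of daughters and never
produces negative or excessive hematocrits (values are clamped to
[0, h_max] with conservative redistribution of the clamped excess).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .units import M_PER_UM


@dataclass
class RheologyParams:
    plasma_viscosity: float = 1.2e-3  # Pa.s
    m: float = 8.0  # skimming coefficient; np.inf disables skimming
    h_max: float = 0.95
    viscosity_law: str = "in_vivo"  # or "in_vitro"

    def __post_init__(self):
        if self.m <= 0:
            raise ValueError("skimming coefficient m must be > 0")
        if not (0 < self.h_max < 1):
            raise ValueError("h_max must lie in (0, 1)")
        if self.viscosity_law not in ("in_vivo", "in_vitro"):
            raise ValueError(f"unknown viscosity law {self.viscosity_law!r}")


# ------------------------------------------------------------- viscosity
def _eta_star_45(d):
    """Relative apparent viscosity at h = 0.45 as a function of diameter (um)."""
    d = np.asarray(d, dtype=float)
    return 6.0 * np.exp(-0.085 * d) + 3.2 - 2.44 * np.exp(-0.06 * d**0.645)


def _shape_exponent(d):
    d = np.asarray(d, dtype=float)
    denom = 1.0 / (1.0 + 1e-11 * d**12)
    return (0.8 + np.exp(-0.075 * d)) * (-1.0 + denom) + denom


def relative_viscosity(d, h, law: str = "in_vivo"):
    """Relative apparent blood viscosity mu_rel(d, h), dimensionless.

    ``d`` is the luminal diameter in um, ``h`` the discharge hematocrit.
    The in-vivo variant multiplies in the (d/(d-1.1))^2 wall-exclusion
    factor of the cell-free layer; blood viscosity is
    ``plasma_viscosity * mu_rel``.
    """
    d = np.asarray(d, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be > 0")
    if np.any((h < 0) | (h >= 1)):
        raise ValueError("hematocrit must lie in [0, 1)")
    eta45 = _eta_star_45(d)
    C = _shape_exponent(d)
    frac = ((1.0 - h) ** C - 1.0) / ((1.0 - 0.45) ** C - 1.0)
    if law == "in_vitro":
        mu = 1.0 + (eta45 - 1.0) * frac
    elif law == "in_vivo":
        wall = (d / (d - 1.1)) ** 2
        mu = (1.0 + (eta45 - 1.0) * frac * wall) * wall
    else:
        raise ValueError(f"unknown viscosity law {law!r}")
    return mu if mu.ndim else float(mu)


def segment_resistance(d_um, L_um, h, params: RheologyParams | None = None):
    """Poiseuille flow resistance of a segment, Pa.s/m^3 (SI)."""
    params = params or RheologyParams()
    d_um = np.asarray(d_um, dtype=float)
    L_um = np.asarray(L_um, dtype=float)
    if np.any(d_um <= 0) or np.any(L_um <= 0):
        raise ValueError("diameter and length must be > 0")
    mu = params.plasma_viscosity * relative_viscosity(d_um, h, params.viscosity_law)
    d = d_um * M_PER_UM
    L = L_um * M_PER_UM
    R = 128.0 * mu * L / (np.pi * d**4)
    return R if R.ndim else float(R)


# ----------------------------------------------------------------- split
def skimming_fractions(outflows: Sequence[float], m: float) -> np.ndarray:
    """RBC-flux fraction phi_i per daughter for outflow magnitudes Q_i."""
    Q = np.asarray(outflows, dtype=float)
    if np.any(Q <= 0):
        raise ValueError("diverging-junction outflows must be > 0")
    if np.isinf(m):
        w = Q
    else:
        e = (m + 1.0) / m
        # normalise before powering for numerical safety at small Q
        w = (Q / Q.max()) ** e
    return w / w.sum()


def kpsm_split(
    outflows: Sequence[tuple[float, float]],
    inflow_rbc_flux: float,
    params: RheologyParams | None = None,
) -> np.ndarray:
    """Daughter discharge hematocrits at a diverging junction.

    ``outflows`` is a list of (Q_i, d_i) pairs (flow magnitude and
    diameter) for every daughter; ``inflow_rbc_flux`` is sum(Q_in h_in).
    Conserves RBC flux exactly; each h_i in [0, h_max].
    """
    params = params or RheologyParams()
    Q = np.asarray([q for q, _ in outflows], dtype=float)
    if len(Q) == 0:
        raise ValueError("junction has no outflow")
    if np.any(Q <= 0) or Q.sum() <= 0:
        raise ValueError("degenerate junction: non-positive outflow")
    phi = skimming_fractions(Q, params.m)
    h = phi * inflow_rbc_flux / Q
    # conservative clamp: move excess RBC flux to unclamped daughters
    for _ in range(len(Q)):
        over = h > params.h_max
        if not np.any(over):
            break
        excess = np.sum((h[over] - params.h_max) * Q[over])
        h[over] = params.h_max
        free = ~over & (h < params.h_max)
        if not np.any(free):
            break  # all clamped: residual flux cannot be carried
        h[free] += excess * (Q[free] / Q[free].sum()) / Q[free]
    return np.clip(h, 0.0, params.h_max)


def junction_mix(inflows: Sequence[tuple[float, float]]) -> float:
    """Flux-weighted mixed hematocrit at a converging node."""
    Q = np.asarray([q for q, _ in inflows], dtype=float)
    h = np.asarray([hh for _, hh in inflows], dtype=float)
    tot = Q.sum()
    if tot <= 0:
        raise ValueError("degenerate junction: zero total inflow")
    return float(np.dot(Q, h) / tot)
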