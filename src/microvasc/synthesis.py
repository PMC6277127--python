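"""Constructive synthesis of cortical vascular networks.

Two layers of machinery live here:

* a constrained-constructive-optimization (CCO) tree grower
  (:class:`GrowthTree`, :func:`grow_tree`): terminals are added one at a
  time, each connected to the existing tree at the bifurcation position
  that minimises total intravascular volume, with diameters recursively
  recomputed so that every bifurcation satisfies the Murray closure
  d_parent^gamma = sum d_child^gamma and all terminals discharge equal
  flows at equal pressure drops;

* a staged cortical-sample generator
  (:func:`synthesize_cortical_sample`, :func:`synthesize_mca_territory`)
  that mirrors the directed growth of the cortical angioarchitecture:
  pial trees on the surface, penetrating arterioles / ascending venules
  descending ~1 mm with side branches, pre-/post-capillary subtrees, and
  a meshed capillary bed pairing arterial and venous terminals.  Its
  internal counts are derived from morphometric surface-density targets;
  vessel calibres follow printed and field-standard values (penetrating
  arterioles ~11 um, capillaries ~4 um, capillary/venule cutoff 6 um).

Tortuosity is imposed afterwards by perturbing each segment into a
quadratic Bezier spline whose arc length realises a sampled
length-to-chord ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import minimize

from .network import DomainDescriptor, VascularNetwork


# ------------------------------------------------------------ distributions
@dataclass
class DistSpec:
    """Small distribution descriptor for synthesis pdfs."""

    kind: str = "point"  # point | normal | lognormal | uniform
    loc: float = 1.0
    scale: float = 0.0
    low: float = -np.inf
    high: float = np.inf

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "point":
            x = np.full(n, self.loc)
        elif self.kind == "normal":
            x = rng.normal(self.loc, self.scale, n)
        elif self.kind == "lognormal":
            x = rng.lognormal(self.loc, self.scale, n)
        elif self.kind == "uniform":
            x = rng.uniform(self.loc, self.scale, n)
        else:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        return np.clip(x, self.low, self.high)


# ------------------------------------------------------------ terminal sites
def sample_terminal_sites(
    domain: DomainDescriptor,
    n: int,
    min_sep: float,
    rng: np.random.Generator,
    margin: float = 0.0,
    surface_only: bool = False,
    max_tries: int = 200,
) -> np.ndarray:
    """Poisson-disc (dart-throwing) site sampling inside the domain.

    Returns ``n`` points with pairwise distance >= ``min_sep``;
    deterministic for a given generator state.  Raises if the packing is
    infeasible after ``max_tries`` rounds per point.
    """
    if n < 1:
        raise ValueError("need n >= 1 sites")
    pts: list[np.ndarray] = []
    for _ in range(n):
        ok = False
        for _ in range(max_tries):
            x = rng.uniform(margin, domain.lx - margin)
            y = rng.uniform(margin, domain.ly - margin)
            z = 0.0 if surface_only else -rng.uniform(margin, domain.depth - margin)
            cand = np.array([x, y, z])
            if not pts or np.min(np.linalg.norm(np.asarray(pts) - cand, axis=1)) >= min_sep:
                pts.append(cand)
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place {n} sites with min_sep={min_sep} um; try a smaller separation"
            )
    return np.asarray(pts)


# ----------------------------------------------------------------- config
@dataclass
class SynthesisConfig:
    domain: DomainDescriptor = dc_field(default_factory=DomainDescriptor)
    n_terminals: int = 100
    root_position: np.ndarray | None = None  # um; default = lateral edge midpoint
    root_diameter: float | None = None  # um; None -> scale to terminal_diameter
    terminal_diameter: float = 11.0  # um, mean terminal calibre when root is free
    murray_exponent: float = 3.0
    min_terminal_separation: float = 25.0  # um
    k_candidates: int = 20  # nearest segments considered per insertion
    n_refine: int = 3  # candidates taken through full bifurcation optimization
    tortuosity_pdf: DistSpec = dc_field(default_factory=lambda: DistSpec("normal", 1.2, 0.08, 1.02, 1.6))
    capillary_diameter_pdf: DistSpec = dc_field(default_factory=lambda: DistSpec("normal", 4.0, 0.35, 3.2, 5.2))
    surface_only: bool = False
    rng_seed: int = 0

    def __post_init__(self):
        if not (2.0 <= self.murray_exponent <= 4.0):
            raise ValueError("Murray exponent must lie in [2, 4]")


# ------------------------------------------------------------- growth tree
class GrowthTree:
    """Rooted binary tree under construction.

    Segments are (tail_node, head_node) index pairs; segment 0 is the
    root segment.  Diameters are maintained by
    :meth:`recompute_diameters` in one of two modes:

    ``balanced`` (default): the classic CCO radius-ratio recursion.  At
    each bifurcation the daughter radius ratio equalises the pressure
    drop to every terminal given equal terminal flows, and the ratios
    are normalised so the Murray closure holds exactly; absolute scale
    comes from the root diameter (or from matching a target mean
    terminal diameter).

    ``murray``: terminal diameters are prescribed and parents follow
    d_p = (sum d_c^gamma)^(1/gamma) leaf-to-root.
    """

    def __init__(self, root_pos, first_terminal, gamma: float = 3.0):
        self.gamma = float(gamma)
        self.node_pos: list[np.ndarray] = [np.asarray(root_pos, float), np.asarray(first_terminal, float)]
        self.seg_tail: list[int] = [0]
        self.seg_head: list[int] = [1]
        self.children: list[list[int]] = [[]]
        self.parent: list[int] = [-1]
        self.diameters = np.array([1.0])

    # -- basic
    @property
    def n_segments(self) -> int:
        return len(self.seg_tail)

    def seg_points(self) -> tuple[np.ndarray, np.ndarray]:
        pos = np.asarray(self.node_pos)
        return pos[self.seg_tail], pos[self.seg_head]

    def lengths(self) -> np.ndarray:
        a, b = self.seg_points()
        return np.linalg.norm(b - a, axis=1)

    def terminal_segments(self) -> list[int]:
        return [j for j, ch in enumerate(self.children) if not ch]

    def _postorder(self) -> list[int]:
        order, stack = [], [0]
        seen = [False] * self.n_segments
        while stack:
            j = stack.pop()
            if seen[j]:
                raise ValueError("cycle detected: diameter recursion is defined on trees only")
            seen[j] = True
            order.append(j)
            stack.extend(self.children[j])
        return order[::-1]

    # -- diameters
    def recompute_diameters(
        self,
        gamma: float | None = None,
        terminal_flow: float = 1.0,
        mode: str = "balanced",
        terminal_diameters: np.ndarray | float = 5.0,
        root_diameter: float | None = None,
        lengths: np.ndarray | None = None,
        viscosity_aware: bool = False,
        h_ref: float = 0.35,
    ) -> np.ndarray:
        gamma = self.gamma if gamma is None else float(gamma)
        L = self.lengths() if lengths is None else lengths
        n = self.n_segments
        order = self._postorder()

        if viscosity_aware:
            # the diameter-dependent apparent viscosity perturbs the
            # equal-pressure-drop balance; re-weight segment resistances
            # with mu_rel(d) and iterate to a self-consistent calibre set
            from .rheology import relative_viscosity

            self.recompute_diameters(
                gamma, terminal_flow, mode, terminal_diameters, root_diameter, L
            )
            for _ in range(6):
                w = relative_viscosity(np.maximum(self.diameters, 2.0), h_ref)
                self.recompute_diameters(
                    gamma, terminal_flow, mode, terminal_diameters, root_diameter, L * w
                )
            return self.diameters

        if mode == "murray":
            d = np.zeros(n)
            terms = self.terminal_segments()
            td = np.broadcast_to(np.asarray(terminal_diameters, float), (len(terms),))
            tmap = dict(zip(terms, td))
            for j in order:
                ch = self.children[j]
                if not ch:
                    d[j] = tmap[j]
                elif len(ch) == 1:
                    d[j] = d[ch[0]]
                else:
                    d[j] = float(np.sum(d[list(ch)] ** gamma)) ** (1.0 / gamma)
            self.diameters = d
            return d

        if mode != "balanced":
            raise ValueError(f"unknown diameter mode {mode!r}")

        # bottom-up: reduced resistance (unit radius) and subtree flows;
        # plain-float arithmetic keeps this hot loop fast
        Ll = [float(x) for x in L]
        Rstar = [0.0] * n
        Qsub = [0.0] * n
        beta = [1.0] * n  # radius ratio to parent
        inv_g = 1.0 / gamma
        children = self.children
        for j in order:
            ch = children[j]
            if not ch:
                Rstar[j] = Ll[j]
                Qsub[j] = terminal_flow
            elif len(ch) == 1:
                c = ch[0]
                beta[c] = 1.0
                Qsub[j] = Qsub[c]
                Rstar[j] = Ll[j] + Rstar[c]
            elif len(ch) == 2:
                c1, c2 = ch
                u1 = (Qsub[c1] * Rstar[c1]) ** 0.25
                u2 = (Qsub[c2] * Rstar[c2]) ** 0.25
                bsum = (u1**gamma + u2**gamma) ** inv_g
                b1, b2 = u1 / bsum, u2 / bsum
                beta[c1], beta[c2] = b1, b2
                Qsub[j] = Qsub[c1] + Qsub[c2]
                Rstar[j] = Ll[j] + 1.0 / (b1**4 / Rstar[c1] + b2**4 / Rstar[c2])
            else:
                u = [(Qsub[c] * Rstar[c]) ** 0.25 for c in ch]
                bsum = sum(ui**gamma for ui in u) ** inv_g
                b = [ui / bsum for ui in u]
                for c, bi in zip(ch, b):
                    beta[c] = bi
                Qsub[j] = sum(Qsub[c] for c in ch)
                Rstar[j] = Ll[j] + 1.0 / sum(bi**4 / Rstar[c] for bi, c in zip(b, ch))

        # top-down radii from the root
        d = [0.0] * n
        d[0] = 1.0
        for j in reversed(order):  # reverse postorder = parents first
            dj = d[j]
            for c in children[j]:
                d[c] = beta[c] * dj
        d = np.asarray(d)
        if root_diameter is not None:
            d *= root_diameter
        else:
            terms = self.terminal_segments()
            mean_term = float(np.mean(d[terms]))
            target = float(np.mean(np.broadcast_to(np.asarray(terminal_diameters, float), (len(terms),))))
            d *= target / mean_term
        self.diameters = d
        return d

    def volume(self, lengths: np.ndarray | None = None) -> float:
        L = self.lengths() if lengths is None else lengths
        return float(np.sum(np.pi * self.diameters**2 / 4.0 * L))

    # -- growth
    def _insert(self, seg: int, x: np.ndarray, terminal: np.ndarray) -> tuple[int, int]:
        """Split ``seg`` at x and attach a new terminal; returns new seg ids."""
        xi = len(self.node_pos)
        self.node_pos.append(np.asarray(x, float))
        ti = len(self.node_pos)
        self.node_pos.append(np.asarray(terminal, float))
        old_head = self.seg_head[seg]
        old_children = self.children[seg]
        # distal half of the split segment
        jd = self.n_segments
        self.seg_tail.append(xi)
        self.seg_head.append(old_head)
        self.children.append(old_children)
        self.parent.append(seg)
        for c in old_children:
            self.parent[c] = jd
        # new terminal segment
        jt = self.n_segments
        self.seg_tail.append(xi)
        self.seg_head.append(ti)
        self.children.append([])
        self.parent.append(seg)
        # proximal half keeps the old id
        self.seg_head[seg] = xi
        self.children[seg] = [jd, jt]
        self.diameters = np.append(self.diameters, [self.diameters[seg]] * 2)
        return jd, jt

    def _undo_insert(self, seg: int, jd: int, jt: int) -> None:
        self.seg_head[seg] = self.seg_head[jd]
        self.children[seg] = self.children[jd]
        for c in self.children[seg]:
            self.parent[c] = seg
        del self.seg_tail[jd:], self.seg_head[jd:], self.children[jd:], self.parent[jd:]
        del self.node_pos[-2:]
        self.diameters = self.diameters[:jd]

    def to_network(
        self,
        domain: DomainDescriptor,
        root_role: str = "arterial_inlet",
        terminal_role: str = "interior",
        compartment: str = "PIA",
        id_offset: int = 0,
    ) -> VascularNetwork:
        pos = np.asarray(self.node_pos)
        roles = np.array(["interior"] * len(pos), dtype=object)
        roles[0] = root_role
        if terminal_role != "interior":
            for j in self.terminal_segments():
                roles[self.seg_head[j]] = terminal_role
        ids = np.arange(len(pos)) + id_offset
        return VascularNetwork(
            node_ids=ids,
            positions=pos,
            roles=roles,
            seg_ids=np.arange(self.n_segments) + id_offset,
            tails=np.asarray(self.seg_tail) + id_offset,
            heads=np.asarray(self.seg_head) + id_offset,
            diameters=self.diameters,
            lengths=self.lengths(),
            compartments=[compartment] * self.n_segments,
            domain=domain,
        )


# ------------------------------------------------- bifurcation optimisation
def _point_segment_distance(p, a, b):
    ab = b - a
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-30), 0, 1)
    proj = a + t[:, None] * ab
    return np.linalg.norm(p - proj, axis=1), proj, t


def optimize_bifurcation(
    tree: GrowthTree,
    candidate_segment: int,
    new_terminal: np.ndarray,
    gamma: float | None = None,
    domain: DomainDescriptor | None = None,
    xatol: float = 0.1,
    maxiter: int = 60,
    diameter_kwargs: dict | None = None,
    surface_only: bool = False,
) -> tuple[np.ndarray, float]:
    """Minimum-volume bifurcation point for attaching ``new_terminal``.

    Temporarily splits ``candidate_segment`` at trial points, recomputes
    the full set of balanced diameters and evaluates total tree volume;
    a derivative-free local search (multi-start from the segment
    midpoint and the terminal's projection point) returns the best
    in-domain point and the associated volume increase.
    """
    gamma = tree.gamma if gamma is None else gamma
    # terminal-calibre normalisation: the root thickens as terminals are
    # added, so attaching a terminal always increases total volume
    dkw = dict(mode="balanced")
    dkw.update(diameter_kwargs or {})
    t = np.asarray(new_terminal, float)
    a = np.asarray(tree.node_pos[tree.seg_tail[candidate_segment]])
    b = np.asarray(tree.node_pos[tree.seg_head[candidate_segment]])

    tree.recompute_diameters(gamma, **dkw)
    vol0 = tree.volume()

    def objective(xy):
        x = np.append(xy, 0.0) if surface_only else np.asarray(xy, float)
        if domain is not None and not domain.contains(x[None, :], margin=1e-9)[0]:
            return vol0 * 10.0  # out-of-domain penalty
        # keep branch points clear of existing nodes: degenerate (near
        # zero-length) segments would dominate the flow-system
        # conditioning and are anatomically meaningless
        if min(np.linalg.norm(x - a), np.linalg.norm(x - b), np.linalg.norm(x - t)) < 2.0:
            return vol0 * 10.0
        jd, jt = tree._insert(candidate_segment, x, t)
        try:
            L = tree.lengths()
            tree.recompute_diameters(gamma, lengths=L, **dkw)
            v = tree.volume(lengths=L)
        finally:
            tree._undo_insert(candidate_segment, jd, jt)
        return v

    _, proj, tt = _point_segment_distance(t[None, :], a[None, :], b[None, :])
    starts = [0.5 * (a + b)]
    if 0.05 < tt[0] < 0.95:  # non-degenerate projection
        starts.append(proj[0])
    best_x, best_v = None, np.inf
    for x0 in starts:
        res = minimize(
            objective,
            x0[:2] if surface_only else x0,
            method="Nelder-Mead",
            options={"xatol": xatol, "fatol": 1e-12, "maxiter": maxiter},
        )
        if res.fun < best_v:
            best_v = float(res.fun)
            best_x = np.append(res.x, 0.0) if surface_only else np.asarray(res.x)
    if best_x is None or not np.isfinite(best_v) or best_v >= vol0 * 9.0:
        best_x = 0.5 * (a + b)  # degenerate geometry fallback
        best_v = objective(best_x[:2] if surface_only else best_x)
    tree.recompute_diameters(gamma, **dkw)  # leave stored diameters consistent
    return best_x, best_v - vol0


def grow_tree(
    config: SynthesisConfig,
    side: str = "arterial",
    rng: np.random.Generator | None = None,
    terminals: np.ndarray | None = None,
) -> GrowthTree:
    """CCO growth of one tree (arterial root = inlet, venous = outlet).

    Terminals are connected sequentially; each insertion evaluates the
    ``k_candidates`` nearest existing segments (pre-ranked by a local
    volume heuristic), runs the full bifurcation optimisation on the
    best few and commits the minimum-volume attachment.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    dom = config.domain
    if terminals is None:
        terminals = sample_terminal_sites(
            dom,
            config.n_terminals,
            config.min_terminal_separation,
            rng,
            margin=min(30.0, 0.05 * dom.lx),
            surface_only=config.surface_only,
        )
    terminals = np.asarray(terminals, float)
    if config.root_position is None:
        root = np.array([0.0, dom.ly / 2.0, 0.0])
    else:
        root = np.asarray(config.root_position, float)

    order = rng.permutation(len(terminals))
    tree = GrowthTree(root, terminals[order[0]], gamma=config.murray_exponent)
    dkw = dict(
        root_diameter=config.root_diameter,
        terminal_diameters=config.terminal_diameter,
    )
    for idx in order[1:]:
        t = terminals[idx]
        a, b = tree.seg_points()
        dist, _, _ = _point_segment_distance(np.broadcast_to(t, a.shape), a, b)
        cand = np.argsort(dist)[: config.k_candidates]
        # cheap pre-rank: added wetted volume of the new branch alone
        heur = dist[cand] * tree.diameters[cand] ** 2
        cand = cand[np.argsort(heur)][: config.n_refine]
        best = (np.inf, None, None)
        for j in cand:
            x, dv = optimize_bifurcation(
                tree, int(j), t, domain=dom, diameter_kwargs=dkw,
                surface_only=config.surface_only,
            )
            if dv < best[0]:
                best = (dv, int(j), x)
        _, j, x = best
        tree._insert(j, x, t)
    # growth ranks candidates with constant-viscosity volumes; the final
    # calibre pass accounts for the diameter-dependent apparent viscosity
    tree.recompute_diameters(config.murray_exponent, mode="balanced", viscosity_aware=True, **dkw)
    return tree


# -------------------------------------------------------------- tortuosity
_ALPHA_GRID = np.linspace(0.0, 2.0, 241)


def _tau_of_alpha(alpha: np.ndarray) -> np.ndarray:
    """Arc-length / chord ratio of a unit-chord quadratic Bezier whose
    middle control point is offset perpendicular by ``alpha``."""
    t = np.linspace(0.0, 1.0, 129)
    integrand = np.sqrt(1.0 + (2.0 * alpha[:, None] * (1.0 - 2.0 * t[None, :])) ** 2)
    return np.trapezoid(integrand, t, axis=1)


_TAU_TABLE = _tau_of_alpha(_ALPHA_GRID)


def apply_tortuosity(
    net: VascularNetwork,
    tortuosity_pdf: DistSpec,
    rng: np.random.Generator,
    skip: np.ndarray | None = None,
) -> VascularNetwork:
    """Impose sampled tortuosity with quadratic Bezier splines (in place).

    Each segment's middle control point is displaced perpendicular to
    the chord so that the spline arc length realises the sampled
    length-to-chord ratio; endpoints are untouched and the segment
    length is updated to the spline arc length.
    """
    tau = tortuosity_pdf.sample(rng, net.n_segments)
    if np.any(tau < 1.0 - 1e-12):
        raise ValueError("tortuosity pdf must have support >= 1")
    tau = np.maximum(tau, 1.0)
    alpha = np.interp(tau, _TAU_TABLE, _ALPHA_GRID)

    a = net.positions[net.tail_idx]
    b = net.positions[net.head_idx]
    chord = np.linalg.norm(b - a, axis=1)
    d = (b - a) / np.maximum(chord, 1e-12)[:, None]
    # prefer a horizontal normal so splines stay inside the slab
    nrm = np.cross(d, np.tile([0.0, 0.0, 1.0], (len(d), 1)))
    small = np.linalg.norm(nrm, axis=1) < 1e-6
    nrm[small] = np.cross(d[small], np.tile([0.0, 1.0, 0.0], (int(small.sum()), 1)))
    nrm /= np.maximum(np.linalg.norm(nrm, axis=1), 1e-12)[:, None]
    sign = rng.choice([-1.0, 1.0], net.n_segments)

    mid = 0.5 * (a + b) + (sign * alpha * chord)[:, None] * nrm
    tau_real = np.interp(alpha, _ALPHA_GRID, _TAU_TABLE)
    for k in range(net.n_segments):
        if skip is not None and skip[k]:
            continue
        if alpha[k] > 1e-9:
            net.control_points[k] = np.vstack([a[k], mid[k], b[k]])
        net.lengths[k] = tau_real[k] * chord[k]
    return net


# ------------------------------------------------------ network assembly
class _Builder:
    """Accumulates nodes and segments before constructing a network."""

    def __init__(self, domain: DomainDescriptor):
        self.domain = domain
        self.pos: list[np.ndarray] = []
        self.role: list[str] = []
        self.tail: list[int] = []
        self.head: list[int] = []
        self.diam: list[float] = []
        self.comp: list[str] = []

    def node(self, p, role="interior") -> int:
        # keep all construction inside the closed slab so no vessel is
        # severed at the tissue boundary
        p = np.asarray(p, float).copy()
        p[0] = np.clip(p[0], 0.0, self.domain.lx)
        p[1] = np.clip(p[1], 0.0, self.domain.ly)
        p[2] = np.clip(p[2], -self.domain.depth, 0.0)
        self.pos.append(p)
        self.role.append(role)
        return len(self.pos) - 1

    def seg(self, t: int, h: int, d: float, comp: str) -> int:
        self.tail.append(t)
        self.head.append(h)
        self.diam.append(float(d))
        self.comp.append(comp)
        return len(self.tail) - 1

    def add_tree(self, tree: GrowthTree, root_role: str, comp: str) -> dict[int, int]:
        """Merge a grown tree; returns tree-node -> builder-node map."""
        nmap = {}
        for i, p in enumerate(tree.node_pos):
            nmap[i] = self.node(p, root_role if i == 0 else "interior")
        for j in range(tree.n_segments):
            self.seg(nmap[tree.seg_tail[j]], nmap[tree.seg_head[j]], tree.diameters[j], comp)
        return nmap

    def build(self) -> VascularNetwork:
        n = len(self.pos)
        return VascularNetwork(
            node_ids=np.arange(n),
            positions=np.asarray(self.pos),
            roles=self.role,
            seg_ids=np.arange(len(self.tail)),
            tails=self.tail,
            heads=self.head,
            diameters=self.diam,
            compartments=self.comp,
            domain=self.domain,
        )


def _unit(v):
    return v / max(np.linalg.norm(v), 1e-12)


def _perp_pair(u):
    """Two unit vectors orthogonal to u (and mostly horizontal)."""
    w1 = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(w1) < 1e-6:
        w1 = np.cross(u, [0.0, 1.0, 0.0])
    w1 = _unit(w1)
    w2 = _unit(np.cross(u, w1))
    return w1, w2


def _capillary_cascade(bld: _Builder, a_node: int, v_node: int, rng, cap_pdf: DistSpec, spread: float = 30.0):
    """Meshed capillary cascade between one arterial and one venous terminal.

    Two binary fan-out levels from the arterial side, two fan-in levels
    into the venous side, and a cyclic double-bridging of the fan leaves
    (each arterial leaf feeds two venous leaves) so every interior node
    is a true junction and the bed contains flow loops, as real
    capillary meshes do.  20 CAP segments per pair.
    """
    a = bld.pos[a_node]
    v = bld.pos[v_node]
    u = v - a
    w1, w2 = _perp_pair(_unit(u) if np.linalg.norm(u) > 1e-9 else np.array([1.0, 0.0, 0.0]))

    def jitter():
        return rng.normal(0.0, 4.5, 3)

    def clampz(p):
        p = np.asarray(p, float)
        p[2] = min(p[2], 0.0)
        return p

    d = cap_pdf.sample(rng, 20)
    di = iter(d)
    # the two fans span ~3.8 steps of the pair separation, leaving ~50 um
    # for the bridges; clipping keeps chords in the realistic 25-110 um
    # range for both close and distant terminal pairs
    unorm = float(np.linalg.norm(u))
    uhat = _unit(u) if unorm > 1e-9 else np.array([1.0, 0.0, 0.0])
    step = float(np.clip((unorm - 50.0) / 3.8, 25.0, 110.0))
    # arterial fan: a -> 2 -> 4
    l1 = [bld.node(clampz(a + step * uhat + s * spread * w1 + jitter())) for s in (-1, 1)]
    for nd in l1:
        bld.seg(a_node, nd, next(di), "CAP")
    l2 = []
    for nd, s1 in zip(l1, (-1, 1)):
        for s2 in (-1, 1):
            c = bld.node(clampz(bld.pos[nd] + 0.9 * step * uhat + s2 * 0.65 * spread * w2 + jitter()))
            bld.seg(nd, c, next(di), "CAP")
            l2.append(c)
    # venous fan (mirrored)
    m1 = [bld.node(clampz(v - step * uhat + s * spread * w1 + jitter())) for s in (-1, 1)]
    for nd in m1:
        bld.seg(nd, v_node, next(di), "CAP")
    m2 = []
    for nd in m1:
        for s2 in (-1, 1):
            c = bld.node(clampz(bld.pos[nd] - 0.9 * step * uhat + s2 * 0.65 * spread * w2 + jitter()))
            bld.seg(c, nd, next(di), "CAP")
            m2.append(c)
    # double bridges: arterial leaf i feeds its aligned venous leaf and
    # the laterally adjacent one, closing capillary loops
    for i, nd in enumerate(l2):
        bld.seg(nd, m2[i], next(di), "CAP")
        bld.seg(nd, m2[i ^ 1], next(di), "CAP")


def _capillary_chain(bld: _Builder, a_node: int, v_node: int, rng, cap_pdf: DistSpec, n_seg: int = 5):
    a, v = bld.pos[a_node], bld.pos[v_node]
    prev = a_node
    for k in range(1, n_seg):
        t = k / n_seg
        p = a + t * (v - a) + rng.normal(0, 8.0, 3)
        p[2] = min(p[2], 0.0)
        nd = bld.node(p)
        bld.seg(prev, nd, float(cap_pdf.sample(rng, 1)[0]), "CAP")
        prev = nd
    bld.seg(prev, v_node, float(cap_pdf.sample(rng, 1)[0]), "CAP")


def close_capillary_bed(
    arterial: VascularNetwork,
    venous: VascularNetwork,
    config: SynthesisConfig,
    rng: np.random.Generator,
    mode: str = "chain",
) -> VascularNetwork:
    """Join two tree fragments through a capillary bed.

    Arterial terminals (degree-1 interior nodes of the arterial
    fragment) are matched to venous terminals by nearest-neighbour
    search with a growing radius; each matched pair is connected either
    by a multi-segment capillary chain (``mode='chain'``) or by a meshed
    cascade (``mode='cascade'``).  Unmatched venous terminals attach to
    their nearest arterial terminal so no dangling nodes remain.
    """
    bld = _Builder(arterial.domain)
    maps = []
    for net in (arterial, venous):
        nmap = {}
        for k in range(net.n_nodes):
            nmap[k] = bld.node(net.positions[k], str(net.roles[k]))
        for j in range(net.n_segments):
            bld.seg(nmap[net.tail_idx[j]], nmap[net.head_idx[j]], net.diameters[j], str(net.compartments[j]))
        maps.append(nmap)

    def fragment_terminals(net, nmap, exclude_roles):
        deg = net.degrees()
        return [
            nmap[k]
            for k in range(net.n_nodes)
            if deg[k] == 1 and str(net.roles[k]) not in exclude_roles and k != 0
        ]

    a_terms = fragment_terminals(arterial, maps[0], {"arterial_inlet", "venous_outlet"})
    v_terms = fragment_terminals(venous, maps[1], {"arterial_inlet", "venous_outlet"})
    if not a_terms or not v_terms:
        raise RuntimeError("fragments expose no free terminals to connect")

    a_pos = np.asarray([bld.pos[i] for i in a_terms])
    v_pos = np.asarray([bld.pos[i] for i in v_terms])
    used_v = np.zeros(len(v_terms), dtype=bool)
    connect = _capillary_chain if mode == "chain" else _capillary_cascade
    for i, an in enumerate(a_terms):
        dists = np.linalg.norm(v_pos - a_pos[i], axis=1)
        free = np.flatnonzero(~used_v)
        j = free[np.argmin(dists[free])] if len(free) else int(np.argmin(dists))
        used_v[j] = True
        connect(bld, an, v_terms[j], rng, config.capillary_diameter_pdf)
    for j in np.flatnonzero(~used_v):
        dists = np.linalg.norm(a_pos - v_pos[j], axis=1)
        connect(bld, a_terms[int(np.argmin(dists))], v_terms[j], rng, config.capillary_diameter_pdf)
    net = bld.build()
    net.check()
    return net


# ----------------------------------------------- cortical sample generator
def _offshoot_subtree(bld, root_node, direction, rng, root_d, gamma, comp, step=64.0):
    """Two-level binary subtree from a trunk junction; returns terminal nodes."""
    terms = []
    w1, w2 = _perp_pair(direction)
    p0 = bld.pos[root_node]
    # root segment of the offshoot
    p1 = p0 + direction * step + rng.normal(0, 6.0, 3)
    p1[2] = min(p1[2], -1.0)
    n1 = bld.node(p1)
    bld.seg(root_node, n1, root_d, comp)
    d1 = root_d / 2.0 ** (1.0 / gamma)
    d2 = d1 / 2.0 ** (1.0 / gamma)
    for s1 in (-1, 1):
        dir1 = _unit(direction + 0.7 * s1 * w1 + rng.normal(0, 0.15, 3))
        p2 = p1 + dir1 * step * 0.9
        p2[2] = min(p2[2], -1.0)
        n2 = bld.node(p2)
        bld.seg(n1, n2, d1, comp)
        for s2 in (-1, 1):
            dir2 = _unit(dir1 + 0.7 * s2 * w2 + rng.normal(0, 0.15, 3))
            p3 = p2 + dir2 * step * 0.85
            p3[2] = min(p3[2], -1.0)
            n3 = bld.node(p3)
            bld.seg(n2, n3, d2, comp)
            terms.append(n3)
    return terms


def _penetrating_tree(bld, start_node: int, site, rng, targets: "CorticalTargets", n_off: int, side: str):
    """One penetrating arteriole (or ascending venule) with side branches.

    The near-vertical trunk descends from the pial junction node with
    ``n_off`` bifurcations; at each one a pre-/post-capillary subtree
    leaves laterally, and the trunk terminates by splitting into two
    subtrees at its deepest junction.  Trunk calibre tapers with depth.
    Returns the microcirculatory terminal node ids.
    """
    if side == "arterial":
        d_top, d_bot = targets.pa_diameter_um, targets.pa_taper_to_um
        comp_trunk, comp_off = "PEA", "PEC"
        off_d = targets.precap_root_diameter_um
    else:
        d_top, d_bot = targets.av_diameter_um, targets.av_taper_to_um
        comp_trunk, comp_off = "AV", "POC"
        off_d = targets.postcap_root_diameter_um

    zmax = rng.uniform(*targets.max_trunk_depth_um)
    zs = np.linspace(60.0, zmax, n_off)
    if n_off > 2:
        zs[1:-1] += rng.normal(0, 0.15 * (zs[1] - zs[0]), n_off - 2)
    prev = start_node
    terms: list[int] = []
    gamma = targets.murray_exponent
    for k, z in enumerate(zs):
        frac = z / targets.depth_um
        dk = d_top + (d_bot - d_top) * frac
        p = np.array([site[0] + rng.normal(0, 10.0), site[1] + rng.normal(0, 10.0), -z])
        nd = bld.node(p)
        bld.seg(prev, nd, dk, comp_trunk)
        phi = rng.uniform(0, 2 * np.pi)
        lateral = _unit(np.array([np.cos(phi), np.sin(phi), -0.25]))
        terms += _offshoot_subtree(bld, nd, lateral, rng, off_d, gamma, comp_off)
        if k == n_off - 1:  # deepest junction: trunk ends in a 2nd subtree
            phi2 = phi + np.pi * rng.uniform(0.6, 1.4)
            lateral2 = _unit(np.array([np.cos(phi2), np.sin(phi2), -0.25]))
            terms += _offshoot_subtree(bld, nd, lateral2, rng, off_d, gamma, comp_off)
        prev = nd
    return terms


@dataclass
class CorticalTargets:
    """Morphometric targets of a ~1 mm^3 cortical sample.

    Segment counts and surface densities follow the experimental
    two-photon morphometry of the murine somatosensory cortex; vessel
    calibres follow the printed penetrating-arteriole diameter (11 um),
    the capillary/venule classification cutoff (6 um) and field-standard
    capillary morphometry (~4 um calibre, ~50 um inter-junction
    spacing).
    """

    n_segments: int = 24679
    segment_density_per_mm2: float = 16710.0
    penetrating_density_per_mm2: float = 13.0
    depth_um: float = 1000.0
    max_trunk_depth_um: tuple[float, float] = (850.0, 930.0)
    # trunk calibres taper linearly with depth; the (top, bottom) pairs
    # are chosen so the depth-average matches the printed mean calibres
    # (penetrating arterioles 11 um, ascending venules 13 um)
    pa_diameter_um: float = 14.0
    pa_taper_to_um: float = 8.0
    av_diameter_um: float = 16.0
    av_taper_to_um: float = 10.0
    precap_root_diameter_um: float = 8.0
    postcap_root_diameter_um: float = 9.0
    murray_exponent: float = 3.0
    cap_diameter_pdf: DistSpec = dc_field(default_factory=lambda: DistSpec("normal", 4.0, 0.35, 3.2, 5.2))
    tortuosity_pdf: DistSpec = dc_field(default_factory=lambda: DistSpec("normal", 1.2, 0.08, 1.02, 1.6))
    hull_factor: float = 0.74  # a-priori pial coverage area / box area
    # (penetrating sites sit >= 4% inside the box and the convex hull of
    #  ~40 scattered pial points covers ~87% of their bounding box)

    @property
    def lateral_um(self) -> float:
        area_mm2 = self.n_segments / self.segment_density_per_mm2
        return math.sqrt(area_mm2) * 1000.0


def _match_terminals(a_pos: np.ndarray, v_pos: np.ndarray) -> list[tuple[int, int]]:
    """One-to-one matching of arterial to venous terminals.

    For equal moderate-sized sets this solves the assignment problem
    exactly (minimum total pairing distance), which keeps capillary
    paths short everywhere; otherwise it falls back to a globally greedy
    shortest-pair-first heap with lazy re-queries.
    """
    import heapq

    from scipy.spatial import cKDTree

    if len(a_pos) == len(v_pos) and len(a_pos) <= 5000:
        from scipy.optimize import linear_sum_assignment

        D = np.linalg.norm(a_pos[:, None, :] - v_pos[None, :, :], axis=2)
        rows, cols = linear_sum_assignment(D)
        return list(zip(rows.tolist(), cols.tolist()))

    kd = cKDTree(v_pos)
    nv = len(v_pos)
    used_v = np.zeros(nv, dtype=bool)

    def nearest_free(i):
        k = 4
        while True:
            d, idx = kd.query(a_pos[i], k=min(k, nv))
            d, idx = np.atleast_1d(d), np.atleast_1d(idx)
            for dd, j in zip(d, idx):
                if not used_v[j]:
                    return float(dd), int(j)
            if k >= nv:
                return None
            k *= 4

    heap = []
    for i in range(len(a_pos)):
        d, j = nearest_free(i)
        heapq.heappush(heap, (d, i, j))
    pairs = []
    while heap:
        d, i, j = heapq.heappop(heap)
        if used_v[j]:
            res = nearest_free(i)
            if res is None:
                j = int(np.argmin(np.linalg.norm(v_pos - a_pos[i], axis=1)))
                pairs.append((i, j))
                continue
            heapq.heappush(heap, (res[0], i, res[1]))
            continue
        used_v[j] = True
        pairs.append((i, j))
    return pairs


def _synthesize_slab(
    targets: "CorticalTargets",
    side_um: float,
    rng: np.random.Generator,
    art_root_diameter: float | None = None,
) -> VascularNetwork:
    """Shared staged construction over a square slab of side ``side_um``.

    Stages: (1) pial arterial and venous CCO trees on the surface whose
    terminals are the penetrating-vessel entry sites, (2) penetrating
    arterioles / ascending venules with laterally branching pre-/post-
    capillary subtrees, (3) a meshed capillary bed pairing arterial and
    venous microcirculatory terminals, (4) Bezier tortuosity.  The
    number of trunk side branches is derived from the segment-density
    target so that the merged-spline density lands on the target over
    the pial coverage area; every junction is a bifurcation.
    """
    from scipy.spatial import cKDTree

    dom = DomainDescriptor(kind="slab", lx=side_um, ly=side_um, depth=targets.depth_um)
    area_mm2 = side_um**2 / 1e6
    n_pen = max(2, round(targets.penetrating_density_per_mm2 * area_mm2))
    # spline budget per arterio-venous penetrating pair: on each side a
    # trunk of n_off splines and (n_off + 1) offshoot subtrees of 7
    # splines, plus 4 (n_off + 1) capillary cascades of 20 splines:
    #   f(n_off) = 2 (n_off + 7 (n_off + 1)) + 80 (n_off + 1) = 96 n_off + 94
    pial_est = 4 * n_pen
    per_pa = (targets.segment_density_per_mm2 * targets.hull_factor * area_mm2 - pial_est) / n_pen
    n_off = max(3, round((per_pa - 94.0) / 96.0))

    margin = 0.04 * side_um
    sites = sample_terminal_sites(
        dom, 2 * n_pen, min_sep=0.45 * side_um / math.sqrt(n_pen), rng=rng,
        margin=margin, surface_only=True,
    )
    a_sites, v_sites = sites[0::2], sites[1::2]

    bld = _Builder(dom)
    gamma = targets.murray_exponent
    pial_art = grow_tree(
        SynthesisConfig(
            domain=dom, murray_exponent=gamma, surface_only=True,
            root_position=np.array([0.0, side_um / 2, 0.0]),
            terminal_diameter=targets.pa_diameter_um,
        ),
        rng=rng, terminals=a_sites,
    )
    if art_root_diameter is not None:
        # reduced-scale territory: pial calibres are intensive and stay
        # as in a full-scale network; only the feeding trunk stub (the
        # MCA M1 entering the patch) carries the printed root calibre
        pial_art.diameters[0] = art_root_diameter
    pial_ven = grow_tree(
        SynthesisConfig(
            domain=dom, murray_exponent=gamma, surface_only=True,
            root_position=np.array([side_um, side_um / 2, 0.0]),
            terminal_diameter=targets.av_diameter_um,
        ),
        rng=rng, terminals=v_sites,
    )
    amap = bld.add_tree(pial_art, "arterial_inlet", "PIA")
    vmap = bld.add_tree(pial_ven, "venous_outlet", "PV")

    a_terms: list[int] = []
    v_terms: list[int] = []
    for tree, nmap, sites_, side, terms_out in (
        (pial_art, amap, a_sites, "arterial", a_terms),
        (pial_ven, vmap, v_sites, "venous", v_terms),
    ):
        term_nodes = {
            tuple(np.round(tree.node_pos[tree.seg_head[j]], 6)): nmap[tree.seg_head[j]]
            for j in tree.terminal_segments()
        }
        for site in sites_:
            pial_node = term_nodes[tuple(np.round(site, 6))]
            terms_out.extend(_penetrating_tree(bld, pial_node, site, rng, targets, n_off, side))

    a_pos = np.asarray([bld.pos[i] for i in a_terms])
    v_pos = np.asarray([bld.pos[i] for i in v_terms])
    used = np.zeros(len(v_terms), dtype=bool)
    for i, j in _match_terminals(a_pos, v_pos):
        used[j] = True
        _capillary_cascade(bld, a_terms[i], v_terms[j], rng, targets.cap_diameter_pdf)
    for j in np.flatnonzero(~used):
        dists = np.linalg.norm(a_pos - v_pos[j], axis=1)
        _capillary_cascade(bld, a_terms[int(np.argmin(dists))], v_terms[j], rng, targets.cap_diameter_pdf)

    net = bld.build()
    apply_tortuosity(net, targets.tortuosity_pdf, rng)
    net.check()
    return net


def synthesize_cortical_sample(
    targets: CorticalTargets | None = None,
    rng: np.random.Generator | int | None = None,
) -> VascularNetwork:
    """Synthesize one ~1 mm^3 cortical microvascular sample.

    The slab's lateral extent follows from the target segment count and
    surface density; cortical depth extent is 1 mm.  See
    :func:`_synthesize_slab` for the staged construction.
    """
    targets = targets or CorticalTargets()
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else int(rng))
    return _synthesize_slab(targets, targets.lateral_um, rng)


#: pial surface area (mm^2) of the full territory implied by the printed
#: segment count and surface density (993,185 segments / 25,144 per mm^2)
FULL_MCA_AREA_MM2 = 39.5
MCA_ROOT_DIAMETER_UM = 142.0


def synthesize_mca_territory(
    targets: CorticalTargets | None = None,
    scale: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> VascularNetwork:
    """Reduced-scale middle-cerebral-artery territory synthesis.

    A pial arterial tree grows from a single root segment of 142 um
    calibre (the M1 trunk) over a surface patch covering ``scale`` x the
    full territory area; penetrating arterioles enter at 13 per mm^2 and
    the microcirculation descends ~1 mm, with a reverse venous side.
    Densities and calibres are intensive, so reduced-scale territories
    preserve them; at scale = 1 the construction targets the full
    ~10^6-segment territory.
    """
    targets = targets or CorticalTargets()
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else int(rng))
    if not (0 < scale <= 1):
        raise ValueError("scale must lie in (0, 1]")
    area = scale * FULL_MCA_AREA_MM2
    if area < 1.0:
        raise ValueError("scaled territory must cover >= 1 mm^2 of pial surface")
    side_um = math.sqrt(area) * 1000.0
    return _synthesize_slab(targets, side_um, rng, art_root_diameter=MCA_ROOT_DIAMETER_UM)
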