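# Methods

This note documents the models implemented in `microvasc`, the
parameter choices behind them, what the synthetic-network generator
does and does not emulate, and the numerical decisions that matter for
reproducing results.

## 1. Network model

A vascular network is a graph of nodes (junctions, arterial inlets,
venous outlets) and *splined segments* — tubular connections between
branching points, each with a calibre `d` (µm), an arc length `L` (µm)
and, after tortuosity imposition, a quadratic Bézier control net.
Coordinates are in µm with the pial surface at `z = 0` and cortical
depth `= −z`.  Inlet/outlet nodes have graph degree 1; segments are
oriented tail→head and signed flows follow that orientation.

Counting is resolution independent: `merged_segment_count` contracts
degree-2 chains before counting, so subdividing a vessel into
sub-segments never changes the splined-segment tally.  Junctions are
classified purely topologically: degree-3 interior nodes are
bifurcations, degree ≥ 4 are multifurcations.

The perfusion domain is a slab (box) with lateral extents and a 1 mm
cortical depth.  Tissue volume defaults to the box volume; a
convex-hull convention is available (`DomainDescriptor
.tissue_volume_convention`).  The box is the denominator of perfusion
and of the blood-brain-barrier (BBB) surface-to-volume ratio.

## 2. Biphasic hemodynamics

Blood is treated as a two-phase suspension: bulk (plasma + cells)
Poiseuille flow plus an advected red-blood-cell (RBC) phase described
by the discharge hematocrit `h` per segment.

**Resistance.**  `R = 128 µ(d, h) L / (π d⁴)` in SI units, with
`µ = µ_plasma · µ_rel(d, h)` and `µ_plasma = 1.2 mPa·s`.  The relative
viscosity implements the standard empirical diameter/hematocrit law

```
µ*₀.₄₅(d) = 6 e^(−0.085 d) + 3.2 − 2.44 e^(−0.06 d^0.645)
C(d)      = (0.8 + e^(−0.075 d)) (−1 + 1/(1+10⁻¹¹ d¹²)) + 1/(1+10⁻¹¹ d¹²)
µ_rel     = 1 + (µ*₀.₄₅ − 1) · ((1−h)^C − 1)/((1−0.45)^C − 1)
```

with an in-vivo variant that multiplies in the wall-exclusion factor
`(d/(d−1.1))²` (default `in_vivo`; `in_vitro` selectable).  The law
captures the Fåhræus–Lindqvist minimum of apparent viscosity at small
calibres; under this functional form the minimum at `h = 0.45` sits at
`d ≈ 44 µm` (dense-grid scan), rising steeply below ~10 µm in vivo.

**Plasma-skimming split.**  At a diverging junction with daughter flows
`Qᵢ` the RBC-flux fractions are

```
φᵢ = Qᵢ^((m+1)/m) / Σⱼ Qⱼ^((m+1)/m),     hᵢ = φᵢ · ΣQ_in h_in / Qᵢ
```

with a single skimming coefficient `m = 8`.  The super-linear exponent
`(m+1)/m > 1` sends disproportionately many red cells into the
stronger daughter; `m → ∞` recovers the proportional (no-skimming)
split, which is the causal control used in tests.  The rule is linear
in the upstream hematocrits (coefficients depend only on `Q` and `m`),
handles any number of daughters, conserves RBC flux exactly, and
clamps to `[0, h_max = 0.95]` with conservative redistribution of
clamped excess.  Converging junctions mix flux-weighted:
`h_mix = Σ Qⱼ hⱼ / Σ Qⱼ`.  The kernel sits behind a single function
(`rheology.kpsm_split`) so a differently parameterized split rule can
be substituted without touching the solver.

**Coupled solve.**  Boundary conditions: Dirichlet pressures at
arterial inlets (120 mmHg) and venous outlets (5 mmHg), inlet
discharge hematocrit 0.35, fully developed (zero-gradient) outlet
hematocrit, closed lateral/deep boundaries (no boundary segments, so
zero flux holds by construction).  The solver alternates:

1. pressure/flow at fixed `h`: eliminate `Q` to get the sparse SPD
   nodal system `C₁ᵀ diag(1/R) C₁ p = 0` on interior nodes (sparse LU
   with two steps of iterative refinement; nodal balances hold to
   ~10⁻¹³ relative), then `Q = diag(1/R) C₁ p`;
2. hematocrit at fixed `Q`: one sparse linear solve of the
   junction-assembled advection operator.  Because the operator is
   linear in `h`, meshed capillary beds with flow-directed loops need
   no special casing.  Segments with `|Q|` below 10⁻⁹ × median are
   excluded from junction balances and afterwards assigned the mixed
   hematocrit of their upstream (higher-pressure) node, flagged in
   `SolutionField.zero_flow`;
3. under-relaxation `h ← (1−ω) h + ω h_new` with `ω = 0.5`, rebuilding
   flow directions each pass.  Convergence: relative L∞ change of both
   `h` and `Q` below 10⁻⁶ (default), typically 25–55 iterations on
   ~20k-segment networks (seconds on one CPU).  The returned field runs
   one final consistent pass so `h` is the exact advection solution of
   the final `Q`.

**Derived quantities.**  Perfusion = total arterial inflow / (tissue
volume × density 1.0 g/ml), reported in ml/100g/min and m³/kg/s
(1 m³/kg/s = 6·10⁶ ml/100g/min).  RBC flux = `|Q| h` per segment.

## 3. CCO tree growth

`grow_tree` adds terminals one at a time.  Each insertion considers the
20 nearest existing segments, pre-ranks them by a cheap added-volume
heuristic (`distance × d²`), and runs a full derivative-free
bifurcation-point optimization (Nelder–Mead, 0.1 µm tolerance,
multi-start from segment midpoint and projection point, out-of-domain
penalty, 2 µm clearance from existing nodes to avoid degenerate
segments) on the best three; the minimum-volume attachment is
committed.  The evaluation objective is the total intravascular volume
with fully rebalanced calibres, so optimality is global-in-tree, not
local-to-junction.

**Calibres.**  Two recursions are provided:

* `murray`: terminal calibres prescribed, parents follow
  `d_p^γ = Σ d_c^γ` leaf-to-root (γ = 3 default, configurable in
  [2, 4]);
* `balanced` (default): the classic CCO radius-ratio recursion — at
  each bifurcation the daughter ratio equalises the pressure drop to
  every terminal for equal terminal flows, normalised so Murray closure
  holds *exactly*; the absolute scale comes from either a fixed root
  calibre or a target mean terminal calibre.  A final viscosity-aware
  pass re-weights segment resistances with `µ_rel(d)` and iterates to
  self-consistency, so that an actual Poiseuille solve on the grown
  tree delivers terminal flows within a few percent of equal (the
  constant-viscosity recursion alone misses by ~2× across the 8–30 µm
  calibre range).

Growth-stage candidate ranking uses the constant-viscosity volumes
(the ranking is insensitive to the re-weighting and this keeps the hot
loop fast).

A note on one intuition that does *not* hold: for a terminal
equidistant from both ends of a segment the optimal bifurcation point
is **not** on the perpendicular bisector — the proximal side carries
the combined flow at larger calibre, pulling the optimum toward the
root.  The optimizer's verified invariants are mirror equivariance,
in-plane optima, positive volume increments, and dominance over random
candidate points.

## 4. Staged cortical-sample generator

`synthesize_cortical_sample` mirrors the developmental hierarchy of
the cortical angioarchitecture in four deterministic-given-seed stages:

1. **Pial networks.**  Arterial and venous CCO trees grown on the
   surface (`z = 0`), rooted at opposite slab edges, whose terminals
   are the penetrating-vessel entry sites (Poisson-disc sampled at
   13 + 13 per mm², ≥ 4% inset from the lateral bounds).
2. **Penetrating vessels.**  From each arterial site a penetrating
   arteriole descends to ~850–930 µm with `n_off` trunk bifurcations;
   at each a pre-capillary subtree (two binary levels, Murray-scaled
   8 → 6.3 → 5 µm) leaves laterally; the deepest junction ends the
   trunk in a second subtree.  Ascending venules mirror this with
   post-capillary subtrees (9 → 7.1 → 5.7 µm).  Trunk calibres taper
   linearly with depth — penetrating arterioles 14 → 8 µm and
   ascending venules 16 → 10 µm, so the depth-averaged calibres equal
   the published means (11 and 13 µm).
3. **Capillary bed.**  Arterial and venous microcirculatory terminals
   are matched one-to-one by solving the assignment problem (minimum
   total pairing distance); each pair is joined by a 20-segment meshed
   cascade: two binary fan-out levels, two fan-in levels, and a double
   bridging of fan leaves that closes capillary loops.  Every interior
   node is a true bifurcation.  Capillary calibres are drawn from
   N(4.0, 0.35) µm clipped to [3.2, 5.2] (all < 6 µm, the
   capillary/venule classification cutoff); fan steps adapt to the
   pair separation so spline chords stay in the realistic 25–110 µm
   range.
4. **Tortuosity.**  Every segment becomes a quadratic Bézier spline
   whose mid control point is offset perpendicular to the chord (with
   a horizontal preference so splines stay inside the slab) to realise
   a length-to-chord ratio sampled from N(1.2, 0.08) clipped to
   [1.02, 1.6]; arc lengths come from a pre-tabulated universal
   quadrature curve (inversion error ≪ 1%).

The only free integer, `n_off` (trunk side branches), is derived from
the morphometric targets: each arterio-venous penetrating pair costs
`96·n_off + 94` splines (trunks, subtrees and 4(n_off+1) cascades), and
the generator solves for `n_off` so the merged-spline density over the
expected pial coverage area (convex hull ≈ 0.74 × box for ~40 inset
pial points) meets the target density.  Slab lateral area = target
segment count / target density (≈ 1.22 × 1.22 mm), depth 1.0 mm.

**What the generator emulates:** published cortical morphometric
statistics — segment density per pial surface, penetrating-vessel
density, mean vessel calibres per compartment, capillary length/calibre
spectra, tortuosity, total length/volume/surface bands, near-absence of
multifurcations — and the hierarchy pial → penetrating → pre-capillary
→ capillary → post-capillary → venule → pial vein.  **What it does
not:** any specific specimen's spatial layout; laminar variations of
capillary density (vessel density is depth-uniform); anastomoses among
pial vessels; dural/subcortical circulation; and the experimental
multifurcation fraction (~7% of segments in imaging-derived data; the
generator produces essentially none, matching the published *synthetic*
column instead).  Passing tests therefore certify statistical, not
anatomical, realism — conclusions transfer to real networks only
insofar as the depth effect is driven by hierarchy + skimming, which is
the model's central claim, not by specimen-specific geometry.

**MCA territory.**  `synthesize_mca_territory(scale)` grows the same
construction over a surface patch of `scale ×` the full territory area
(full ≈ 39.5 mm², from the published segment count over density), with
a single arterial root whose feed stub carries the middle-cerebral-
artery M1 calibre of 142 µm.  All densities and calibres are intensive
and preserved at any scale; within-patch pial calibres stay at their
full-scale values (growing them "balanced" from the 142 µm root over a
handful of sites would inflate them and understate pial resistance).
At `scale = 1` the construction targets the ~10⁶-segment territory;
desk-scale analyses use 5%.  Caveat: a 5% patch shortens pial supply
and drainage paths relative to the full territory, which biases
perfusion upward by roughly a fifth; the scaled territory value
(~60–65 ml/100g/min) should be read with that bias in mind against the
full-territory reference of ~50.

## 5. Layer analysis

Flow paths are traced from flux-weighted random inlets downstream,
choosing each diverging branch with probability proportional to its
outflow, until a venous outlet (duplicates removed, dead ends
discarded and counted); exhaustive capped enumeration is available for
small networks.  Each path's depth label is the cortical depth of its
deepest segment.  Layers use configurable boundaries, default
I [0,100), II/III [100,420), IV [420,590), V [590,890), VI [890,∞) µm —
murine laminar depths are not standardized to the micron, so the
boundaries are parameters, recorded in outputs.  Layer statistics are
segment-based (midpoint depth) by default, path-based optionally; both
groupings are exposed because figure-level conventions differ.
One-way ANOVA is computed from sums of squares with
(k−1, N−k) degrees of freedom; between-group variation at rounding
level returns F = 0 exactly (cross-checked against
`scipy.stats.f_oneway` elsewhere).

## 6. Numerical choices and edge cases

* mmHg ↔ Pa at 133.322 Pa/mmHg; geometry µm, solver SI.
* Zero-flow segments: `h` is advectively undefined; assigned from the
  upstream node mix and flagged, never silently dropped.
* Pressure solve: sparse LU + two refinement steps; singular systems
  (components with no boundary node) are detected up front and named.
* Hematocrit clamping at `h_max = 0.95` redistributes the excess flux
  conservatively among unclamped daughters.
* Tortuosity inversion: 241-point α-grid, 129-point arc quadrature.
* Determinism: every stochastic stage takes a `numpy` Generator or
  integer seed; the CLI expands one seed into independent per-stage
  streams via `SeedSequence`.

## 7. Problem sizes used in the shipped analyses

The default cortical sample is ~18k splines over ~1.5 mm² of pial
surface; ensembles of 3 (solved) and 10 (morphometry only) samples are
used in the acceptance script, and the MCA territory is synthesized at
5% surface area (~25k splines).  These sizes keep a full
synthesize-solve-analyze cycle at ~10–15 s per sample on one CPU while
leaving every density, calibre and boundary condition at its
full-scale value.

## 8. Known limitations

* Steady state only: no pulsatility, no vessel compliance, no
  autoregulation, no oxygen transport.
* The skimming kernel is junction-local with a fixed `m = 8`; no
  diameter-ratio refinement of `m`, and no cell-resolved partitioning.
* The capillary bed is built from paired cascades rather than a
  specimen-matched mesh; loop density is structural, not fitted.
* Perfusion and BBB denominators depend on the box tissue-volume
  convention; convex-hull volumes run ~10–20% smaller and raise both
  numbers accordingly.
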