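# microvasc

Synthesis of cortical microvascular networks and biphasic (red blood
cell + plasma) blood-flow simulation with kinetic plasma skimming.

`microvasc` is for researchers in computational hemodynamics and
neurovascular physiology who want to study **network effects of uneven
red-blood-cell distribution** in the cerebral cortex without access to
full imaging-derived vascular reconstructions.  It provides:

* a **constrained-constructive-optimization (CCO) generator** of
  anatomically realistic cortical angioarchitecture — pial arterial and
  venous networks, penetrating arterioles and ascending venules, and a
  meshed capillary bed — parameterized by published morphometric
  targets (segment density per pial surface, penetrating-vessel density,
  vessel calibres);
* a **biphasic network flow solver** for the coupled nonlinear system

  ```
  R(h, d) Q − C₁ p = 0      (Poiseuille momentum balance)
  C₂ Q = 0                  (bulk mass conservation at junctions)
  C₃(Q, d) h = 0            (red-cell advection with plasma skimming)
  ```

  where `p` are nodal pressures, `Q` signed segment flows and `h`
  segment discharge hematocrits.  Segment resistance uses the empirical
  diameter- and hematocrit-dependent apparent viscosity of blood (the
  Fåhræus–Lindqvist effect); at diverging junctions the red-cell phase
  splits by a kinetic plasma-skimming rule with RBC-flux fractions
  `φᵢ = Qᵢ^((m+1)/m) / Σⱼ Qⱼ^((m+1)/m)` and a single skimming
  coefficient `m = 8` (the stronger daughter branch is enriched; the
  thin side branch skims cell-poor plasma);
* **path and layer analysis**: inlet-to-outlet flow-path tracing, depth
  labels, cortical layer (I–VI) statistics of `h`, `Q` and RBC flux
  `|Q|·h`, one-way ANOVA of the depth dependence, and morphometric
  summaries / ensemble equivalence tests.

The central scientific result this stack reproduces: plasma skimming
acting over thousands of bifurcations produces a **depth-dependent
hematocrit gradient** (deeper cortical layers receive more concentrated
red cells), while bulk flow decreases with depth — so the RBC flux is
far more uniform across layers than the flow itself, a self-regulating
homogenization of oxygen-carrier supply that needs no active feedback.

## Worked example

```python
import microvasc as mv

net = mv.synthesize_cortical_sample(rng=1)   # ~1 mm^3 cortical sample
field = mv.solve_biphasic(net)               # 120 -> 5 mmHg, h_in 0.35, m = 8
perf = mv.compute_perfusion(net, field)
stats = mv.layer_statistics(net, field)
```

prints (via the obvious `print` calls):

```
segments: 18276
iterations: 51
perfusion: 59.1 ml/100g/min
density: 16822 /mm2  BBB: 9.10 mm2/mm3
 layer    n  h_median  Q_median_nl_s  rbc_flux_median_nl_s
     I 1103    0.2921         0.0093                0.0028
II/III 5690    0.3125         0.0066                0.0021
    IV 3027    0.3469         0.0048                0.0017
     V 5582    0.3957         0.0034                0.0013
    VI 2874    0.4366         0.0025                0.0011
ANOVA: F=7351, p=0
```

Reading this: the generator hit the target surface density
(16,822 segments/mm² of pial surface) and capillary surface-to-tissue
ratio (9.1 mm²/mm³); the solver converged in 51 coupled iterations;
tissue perfusion is 59 ml/100 g/min, inside the physiological
40–163 ml/100 g/min range.  Median discharge hematocrit **rises**
monotonically from 0.29 in layer I to 0.44 in layer VI (ANOVA
p ≪ 0.01) while median bulk flow **falls** by ~4× — so the median RBC
flux varies only ~2.5× across layers: the homogenization effect.
Setting `m = inf` (no skimming) collapses the field to the uniform
inlet hematocrit 0.35 and the layer effect vanishes.

The same pipeline is scriptable from a shell:

```sh
microvasc run --outdir out/ --seed 1            # synthesize + solve + analyze
microvasc synthesize --out net.json --seed 2 --mca-scale 0.05
microvasc solve --net net.json --out sol.h5 --skimming-m 8
microvasc analyze --net net.json --solution sol.h5 --out layers.csv
microvasc morphometry --net net.json --out summary.json
microvasc vtk --net net.json --out net.vtp --solution sol.h5
```

## Layout

| module | contents |
| --- | --- |
| `microvasc.network` | graph model, incidence operators, validation, spline counting |
| `microvasc.io` | JSON / CSV-pair network files, VTK PolyData export |
| `microvasc.rheology` | viscosity law, Poiseuille resistance, plasma-skimming split |
| `microvasc.solver` | coupled pressure/flow/hematocrit fixed-point solver, perfusion |
| `microvasc.synthesis` | CCO tree growth, staged cortical/MCA generators, tortuosity |
| `microvasc.analysis` | flow paths, cortical layers, ANOVA, profile tables |
| `microvasc.morphometrics` | summaries, distributions, ensemble equivalence |
| `microvasc.fixtures` | deterministic miniature test networks |
| `microvasc.cli` | `microvasc` command-line tool |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
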