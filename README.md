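# levelkit

A composable level-set segmentation engine for 2D/3D biological images —
built for workloads like segmenting hundreds of cell nuclei in confocal
microscopy stacks, where many active contours must evolve concurrently,
interact, and stay cheap in memory.

An object boundary is the zero level-curve of a scalar field φ (negative
inside).  Its evolution is driven by a generic PDE assembled as a weighted
sum of pluggable terms:

    ∂φ/∂t = Σ_j  α_j · T_j(I, {φ_i})

where the term library covers the two classic model families and their
hybrids:

* **Edge-based** (geodesic active contours):
  advection `A·∇φ` with `A = ∇g`, propagation `P·|∇φ|`, and curvature
  `Z·κ|∇φ|`, with the edge indicator `g = 1/(1+|∇(G_σ∗I)|^p)`.
* **Region-based** (Chan–Vese):
  `δ_ε(φ)[μκ + ν + λ1(I−c1)² − λ2(I−c2)²]` with foreground/background
  means c1, c2 recomputed from the regularized Heaviside partition each
  iteration.
* **Coupling and regularity**: a pairwise overlap penalty
  `γ δ_ε(φ_i) Σ_j H_ε(−φ_j)` that keeps concurrently evolving objects
  disjoint, and a distance-keeping diffusion `div[(1−1/|∇φ|)∇φ]`.

Around that equation system the engine provides

* four grid representations of φ — dense, and the 5-layer (Whitaker),
  2-layer (Shi), and 1-layer (Malcolm) sparse-field narrow bands — behind
  one derivative-query interface with a per-point compute-once cache;
* binary-mask adaptors (Euclidean-distance-transform signed distance, or
  direct layer construction);
* restricted per-level-set domains with a domain map that clusters the
  image into subregions of constant active-id sets (Kd-tree accelerated),
  so memory and work scale with object size, not image size;
* signed-distance reinitialization (Sussman PDE relaxation or a
  fast-marching Eikonal solve) behind a scheduling policy;
* pluggable stopping criteria, per-iteration observer events, a synthetic
  nuclei-scene generator with ground truth, and contour/elevation/layer
  exports.

## Worked example

Segment a noisy synthetic nucleus (foreground 10, background 2, additive
noise σ = 1) with the Chan–Vese equation, starting from a deliberately
offset seed circle:

```python
import levelkit as lk

scene = lk.generate_blobs(n_objects=1, shape=(64, 64), radius_range=(10, 10), seed=42)
center, radius = scene.seeds[0]

phi = lk.binary_to_dense(lk.mask_from_seed((center[0] - 2, center[1] + 2), 8, (64, 64)))
level_sets = lk.LevelSetContainer()
level_sets.add_level_set(1, phi)

equation = lk.TermContainer(1)
for term in lk.chan_vese_term_set(lambda1=1.0, lambda2=1.0, nu=0.0, mu=1.0, level_set_id=1):
    equation.add_term(term)
equations = lk.EquationContainer()
equations.add_equation(1, equation)

system = lk.LevelSetSystem(scene.image, level_sets, equations)
engine = lk.LevelSetEvolution(
    system,
    lk.combine([lk.MaxIterations(120), lk.RmsChangeBelow(5e-4)]),
    reinit=lk.ReinitPolicy(method="sussman", every_k=10),
)
history = engine.evolve()

inside = phi.values < 0
print(f"Dice vs ground truth: {lk.dice(phi.interior_mask(), scene.mask()):.4f}")
print(f"recovered means: c1 = {scene.image[inside].mean():.2f}, c2 = {scene.image[~inside].mean():.2f}")
print(f"energy: {history[0].total_energy:.0f} -> {history[-1].total_energy:.0f}")
```

prints

```
Dice vs ground truth: 1.0000
recovered means: c1 = 9.91, c2 = 1.99
energy: 16841 -> 11399
```

The Dice score compares the recovered interior (φ < 0) with the
generating disk; c1/c2 are the plain means over the segmented partition
and land on the true intensities up to the noise in the sample; the
variational energy decreases monotonically as the contour locks onto the
object.

The same run is available from the shell, along with an edge-based demo
and a ten-object demo with restricted domains and the overlap penalty:

```
levelkit demo --case chanvese-disk --seed 42
levelkit demo --case multiobject
levelkit run --config my_run.yaml      # declarative YAML configuration
levelkit validate-config my_run.yaml
```

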