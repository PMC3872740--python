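# Methods

## Model

A segmentation boundary is carried implicitly as the zero level-curve of
a scalar field φ sampled on the pixel grid, with the **inside-negative**
convention (φ < 0 strictly inside the object).  Each level set evolves by
an explicit-Euler iteration of a generic PDE assembled as a weighted sum
of terms; terms are pure per-pixel functions of the image, the level-set
state, and (for the coupling term) the other level sets in the system.
Terms read level-set quantities (value, one-sided/central gradients,
Hessian, Laplacian, gradient norm, mean curvature) only through a
per-point cache, so the same term runs unchanged on any grid
representation and no stencil is evaluated twice per point however many
terms request it.

Axis order is (row, col) in 2D and (z, y, x) in 3D; indices are 0-based;
regions are half-open boxes `[offset, offset + shape)`.  Optional per-axis
spacing scales the finite differences; curvature uses the general
`(tr(H)|∇φ|² − ∇φᵀH∇φ)/|∇φ|³` form, which equals the familiar 2D formula
and gives the sum of principal curvatures (= (d−1)/R on a sphere) in 3D.

### Sign bookkeeping

All terms return contributions to ∂φ/∂t directly; the engine only sums,
scales by dt, and adds.  Under inside-negative:

* `propagation = P·|∇φ|` with a **positive weight shrinks** the interior
  (grow with a negative weight);
* `advection = Σ A_i D_i φ` is convention-covariant; with `A = ∇g` it
  attracts the contour to edges from either side;
* the Chan–Vese gradient flow becomes
  `δ_ε(φ)[μκ + ν + λ1(I−c1)² − λ2(I−c2)²]`, i.e. the fit terms are
  sign-flipped once relative to the inside-positive textbook form so that
  a pixel whose intensity is closer to c1 is pushed negative (captured);
* the overlap penalty `δ_ε(φ_i)·Σ_{j≠i} H_ε(−φ_j)` is positive where
  another level set claims the pixel, pushing the interior out.

### Discretization choices

* **Upwinding.** The propagation norm uses per-axis one-sided differences
  selected by sign(P) (backward for P > 0, forward for P < 0); advection
  upwinds per component by sign(A_i).  Curvature, Laplacian, and the
  distance-keeping diffusion use central differences.  At region borders
  all stencils fall back to one-sided differences.
* **Degenerate gradients.** Mean curvature returns 0 when |∇φ| < 1e−8;
  the distance-diffusion term floors |∇φ| at 1e−3.
* **Heaviside/Dirac.** The arctan C∞ regularization
  `H_ε(z) = ½(1 + (2/π)atan(z/ε))`, `δ_ε = H_ε′`, default ε = 1.5 px —
  nonzero support everywhere, the standard choice for region terms.  Its
  slow tails mean the *Heaviside-weighted* region means are biased toward
  each other on small images; they are the quantities that drive the
  flow, while reported segmentation statistics are plain means over the
  final φ < 0 partition.
* **Edge function.** `g = 1/(1 + |∇(G_σ∗I)|^p)`, defaults σ = 1 px,
  p = 2; only its limiting behavior (→ 0 at strong edges, 1 in flat
  regions) matters to the model.
* **Time step.** `dt = 0.45 / max|update|`, clamped to `dt_max = 1`; the
  Whitaker band additionally enforces `dt·max|update| ≤ 0.5` so no pixel
  can skip a layer.  Shi/Malcolm moves are sign-driven one-pixel flips
  and ignore dt.

## Grid representations

**Dense** stores φ over the whole region.  **Sparse-field** variants store
values only in thin layers around the zero level-curve, with a signed
label field and per-layer index→value maps kept consistent:

* *Whitaker*: 5 layers −2…+2, layer k values in `[k−0.5, k+0.5)`,
  sentinels ±3 off-band;
* *Shi*: 2 layers (inside boundary −1, outside boundary +1), sentinels ±3;
* *Malcolm*: a single layer 0 on the inside boundary pixels, sentinels ±1.

Adaptors build these from binary masks: the dense signed distance is
`∓(EDT − 0.5)` (zero crossing midway between boundary pixel pairs,
Euclidean metric), and the sparse layers come from 4-/6-connected
adjacency with integer initial values.  Masks touching the region border
are eroded by 1 px with a warning (overridable), since the band cannot be
maintained on the border.

### Whitaker update rule

Per iteration: (1) zero-layer values advance by `dt·u` while keeping
their membership; (2) layers are relaxed in the order +1, −1, +2, −2 —
each pixel takes min(reference-layer neighbors)+1 on the positive side
(max−1 on the negative side), where the reference is layer 0 for ±1 and
layers {0, ±1} for ±2, and is re-binned into whatever band the value
lands in (this is what surfaces fresh zero-layer pixels as the front
moves); pixels with no reference neighbor are demoted outward; (3)
zero-layer values that left `[−0.5, 0.5)` migrate to the ±1 layer; (4)
the band is extended where it borders a sentinel.  Relaxing *before*
migration is essential: it lets a departing zero pixel pull its opposite
neighbor into the zero layer instead of being pulled back itself.
Layer-membership invariants are re-checked by `check_invariants()` in the
tests after every scripted evolution.

Shi keeps two one-pixel-thick lists and switches a boundary pixel to the
other side whenever its PDE update favors capture/release, rebalancing
neighbors from the sentinels; Malcolm moves its single boundary layer one
pixel along the update direction.  Both fire per-pixel notifications so
term parameters (the Chan–Vese sums) stay current mid-iteration via
incremental updates of the Heaviside-weighted sums; a full recomputation
follows each iteration.

## Evolution loop

allocate buffers → compute updates over domain-map subregions (dense:
every pixel of each level set's region; sparse: the interface layers
only; fresh shared cache per pixel) → CFL time step → apply the
representation's update rule → refresh term parameters → RMS change
(whole region for dense; interface pixels for sparse — a comparable
convergence signal) → reinitialization policy → iteration event →
stopping check.  Everything is deterministic: subregions, ids, and layer
pixels are visited in sorted order, and the buffers are pure functions of
the state, so a (configuration, seed) pair reproduces its history
bit-exactly and the result is independent of subregion visitation order.
NaN/Inf in any buffer aborts with the iteration context rather than
clamping.  The Chan–Vese energy
`λ1∫(I−c1)²H + λ2∫(I−c2)²(1−H) + ν·Area + μ·Length` is tracked only when
every term of every equation belongs to the Chan–Vese family; otherwise
it is reported unavailable.

## Reinitialization

Differential front motion steepens/flattens φ; two restorers are
provided behind a policy (`every_k` schedule; `li_term` instead installs
the diffusion term into the equations; sparse variants are skipped with a
log note since their band maintenance is self-reinitializing).

* **Sussman relaxation** iterates
  `φ ← φ − dτ·S(φ0)(|∇φ|_G − 1)` with Peng's smoothed sign
  `S = φ0/√(φ0² + |∇φ0|²h²)` and the Godunov upwind gradient selected by
  sign(φ0); defaults dτ = 0.3 (stability requires ≤ 0.5), 20 inner
  iterations.
* **Fast marching** solves |∇φ| = 1 outward from the interface with the
  standard first-order upwind quadratic update, signs restored from the
  input.

Both take their interface boundary conditions from the same sub-cell
estimate: interface-adjacent pixels get `d = |φ|/|∇φ|` (exact for any
scaled signed-distance input), capped by the grid diagonal, and *kept
as-is* when the local slope is already within 5% of unity.  The pinned
band makes the zero level stationary (measured displacement < 1e−4 px on
circles), makes both operators idempotent to < 1e−3, and — critically for
long curvature-flow runs — removes the systematic inward drift that a
chord-interpolation estimate introduces at curved interfaces.

## Restricted domains

Each level set lives on an axis-aligned sub-box of the image; the default
box for a seed sphere is center ± (radius + margin) with margin = 2·radius.
Per-pixel active-id lists are stamped either by brute force or through a
Kd-tree over region centroids (query radius auto-set to the largest region
half-diagonal, which guarantees the two paths are bit-identical), then
clustered into constant-id-set subdomains in raster first-encounter
order.  Storage and per-iteration work scale with region size, and a
level set evolved in its region matches the full-domain evolution exactly
wherever the border's one-sided stencils cannot reach.

## Synthetic scenes

`generate_blobs` emulates nuclei-like fluorescence data: bright disks or
spheres (foreground 10, background 2 by default) placed by rejection
sampling with pairwise separation `r_i + r_j + min_separation`
(min_separation = 2 px), plus additive Gaussian noise (σ = 1 by default).
The defaults produce exact two-level objects — optional PSF blur
(`blur_sigma`) and per-object intensity jitter are off by default, so the
stated intensities are exactly recoverable and deviations measure the
engine, not the scene.  What the generator does **not** emulate: textured
or graded object interiors, intensity attenuation with depth, anisotropic
PSFs, touching/overlapping objects, and structured (non-Gaussian) noise.
Passing tests therefore demonstrate correct PDE mechanics and coupling,
not robustness to the full variability of real confocal data.

## Validation scenarios (`levelkit.validation`)

Problem sizes are chosen so every scenario runs in seconds on one core:
41×41 grids for the flow laws, a 64×64 noisy disk for region recovery,
100 random 48×48 scenes for the Kd-tree equivalence, and ten objects in
128×128 for the multi-object run (region margin = radius there, so
neighbors' domains overlap without swallowing neighboring objects; 100
iterations with overlap weight 1000, the regime in which coupled runs
settle).  The curve-shortening check uses fast-marching reinitialization
every 5 iterations — curvature flow does not preserve the distance
property, and the measured R(t) tracks √(R0²−2t) to ≈ 2% with it.  The
cross-representation check runs a 10-iteration Chan–Vese flow from a
close initialization, the regime where the dense dt-limited front and
the sign-driven sparse fronts can be compared meaningfully (sparse
schemes deliberately trade sub-pixel accuracy for speed, so agreement is
asserted at the 2 px level).

## Known limitations

* Explicit time stepping only; a single stiff term (e.g. the overlap
  penalty at a contact front) throttles the global CFL step for the whole
  system.
* The sparse variants keep only integer-spaced band values; region
  statistics computed from them treat sentinels as ±3 (±1), a coarse but
  monotone surrogate for the true distances.
* Chan–Vese has no object identity: a level set whose region contains a
  neighboring object will claim it unless the neighbor's level set and
  the overlap penalty push back — region boxes should be sized to the
  object scale.
* Shi/Malcolm fronts move at most one pixel per iteration regardless of
  the speed magnitude; they are order-of-magnitude tools for tracking,
  not sub-pixel segmenters.
* Mesh and analytic (radial-basis/spline) representations of φ are out of
  scope; the term/cache contract is the extension point for them.
* Execution is single-threaded; determinism is guaranteed by sorted
  visitation rather than by a parallel reduction order.
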