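"""Canonical validation scenarios.

Each function builds a scene from scratch, runs the engine, and returns
the measured quantity: structural layer counts, agreement with the
analytic curve-shortening and front-speed laws, reinitialization quality,
Chan–Vese recovery of a noisy disk, the Kd-tree/brute-force and
dense/sparse equivalences, and the multi-object overlap-penalty regime.
The test suite asserts tolerances on these numbers and the acceptance
script reports them.
"""

from __future__ import annotations

import itertools

import numpy as np

from .adaptors import binary_to_dense, binary_to_sparse, mask_from_seed
from .containers import EquationContainer, LevelSetContainer, TermContainer
from .domains import (DomainPartition, default_region_for_seed,
                      populate_id_lists, populate_id_lists_kdtree)
from .evolution import LevelSetEvolution, LevelSetSystem
from .grids import DenseLevelSet, GridRegion, QuantityCache
from .metrics import boundary_hausdorff, dice, interior_mask_of, zero_level_radius
from .reinit import ReinitPolicy, fast_marching_reinit, sussman_reinit
from .sparse import layer_ids
from .stopping import MaxIterations, RmsChangeBelow, combine
from .synthetic import disk_image, generate_blobs
from .terms import (CurvatureTerm, LaplacianTerm, OverlapPenaltyTerm,
                    PropagationTerm, chan_vese_term_set)

__all__ = [
    "layer_cardinality",
    "curve_shortening_error",
    "front_speed",
    "sussman_quality",
    "fast_marching_disk_error",
    "chan_vese_recovery",
    "kdtree_equivalence",
    "cache_soundness",
    "cross_representation_consistency",
    "multi_object_overlap",
    "restricted_domain_equivalence",
]


def _single(image, ls, terms):
    container = LevelSetContainer()
    container.add_level_set(1, ls)
    tc = TermContainer(1)
    for t in terms:
        tc.add_term(t)
    eq = EquationContainer()
    eq.add_equation(1, tc)
    return LevelSetSystem(np.asarray(image, dtype=float), container, eq)


def _circle_sdf(shape, center, radius):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    return DenseLevelSet(GridRegion((0,) * len(shape), shape), r - radius)


def layer_cardinality() -> dict:
    """Non-empty layer counts of the three narrow-band schemes on a disk."""
    mask = mask_from_seed((10, 10), 6, (21, 21))
    out = {}
    for variant in ("whitaker", "shi", "malcolm"):
        ls = binary_to_sparse(mask, variant)
        assert sorted(ls.layers) == sorted(layer_ids(variant))
        out[variant] = sum(1 for k in ls.layers if ls.layers[k])
    return out


def curve_shortening_error(radius: float = 10.0, shape=(41, 41),
                           min_radius: float = 4.0) -> dict:
    """Curvature flow on a circle against ``R(t) = sqrt(R0^2 - 2t)``.

    Returns the maximum relative radius error while the predicted radius
    stays above ``min_radius``.
    """
    center = tuple((s - 1) / 2 for s in shape)
    ls = _circle_sdf(shape, center, radius)
    system = _single(np.zeros(shape), ls, [CurvatureTerm(1.0, weight=1.0)])
    engine = LevelSetEvolution(
        system, MaxIterations(150),
        reinit=ReinitPolicy(method="fast_marching", every_k=5),
    )
    t_acc = 0.0
    errors = []

    def track(event):
        nonlocal t_acc
        t_acc += event.dt
        predicted = np.sqrt(max(radius**2 - 2 * t_acc, 0.0))
        measured = zero_level_radius(ls, center)
        if predicted >= min_radius and np.isfinite(measured):
            errors.append(abs(measured - predicted) / predicted)

    engine.register_observer(track)
    engine.evolve()
    return {"max_rel_error": max(errors), "n_checkpoints": len(errors)}


def front_speed(iterations: int = 40, width: int = 41) -> dict:
    """Planar front under constant unit propagation; returns px per unit time."""
    x = np.arange(float(width))
    ls = DenseLevelSet(GridRegion((0, 0), (9, width)), np.tile(x - 5.0, (9, 1)))
    system = _single(np.zeros((9, width)), ls, [PropagationTerm(1.0, weight=-1.0)])
    engine = LevelSetEvolution(system, MaxIterations(iterations))
    history = engine.evolve()
    total_t = sum(s.dt for s in history)
    row = ls.values[4]
    i = int(np.where(np.diff(np.sign(row)))[0][0])
    crossing = i + row[i] / (row[i] - row[i + 1])
    return {"speed": (crossing - 5.0) / total_t, "elapsed_time": total_t}


def sussman_quality(radius: float = 8.0, shape=(41, 41)) -> dict:
    """Relax a 3x-steepened circle distance; report the median Eikonal
    residual in the band |phi| < 3 and the zero-level displacement."""
    center = tuple((s - 1) / 2 for s in shape)
    sdf = _circle_sdf(shape, center, radius)
    steep = DenseLevelSet(sdf.region, 3.0 * sdf.values)
    out = sussman_reinit(steep, inner_iterations=60)
    g = np.gradient(out.values)
    gnorm = np.sqrt(sum(c**2 for c in g))
    band = np.abs(out.values) < 3
    shift = abs(zero_level_radius(out, center) - zero_level_radius(steep, center))
    return {
        "median_residual": float(np.median(np.abs(gnorm[band] - 1.0))),
        "zero_shift_px": float(shift),
    }


def fast_marching_disk_error(radius: float = 6.0, shape=(31, 31)) -> dict:
    """Fast-marching output vs the analytic disk distance on 31x31."""
    center = tuple((s - 1) / 2 for s in shape)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    steep = DenseLevelSet(GridRegion((0, 0), shape), 2.5 * (r - radius))
    out = fast_marching_reinit(steep)
    return {"max_abs_error_px": float(np.max(np.abs(out.values - (r - radius))))}


def chan_vese_recovery(seed: int = 42, shape=(64, 64), radius: float = 10.0) -> dict:
    """Segment one noisy disk (fg 10, bg 2, noise sigma 1) from an offset
    seed circle; report Dice and the recovered region means."""
    scene = generate_blobs(n_objects=1, shape=shape, radius_range=(radius, radius),
                           seed=seed)
    center, _ = scene.seeds[0]
    offset_center = (center[0] - 2.1, center[1] + 2.1)  # ~3 px offset
    ls = binary_to_dense(mask_from_seed(offset_center, 8, shape))
    system = _single(scene.image, ls, chan_vese_term_set(mu=1.0, level_set_id=1))
    engine = LevelSetEvolution(
        system, combine([MaxIterations(120), RmsChangeBelow(5e-4)]),
        reinit=ReinitPolicy(method="sussman", every_k=10),
    )
    engine.evolve()
    inside = ls.values < 0
    truth = scene.mask()
    n1, n2 = int(truth.sum()), int((~truth).sum())
    return {
        "dice": dice(ls.interior_mask(), truth),
        "c1": float(scene.image[inside].mean()),
        "c2": float(scene.image[~inside].mean()),
        "c1_tolerance": 3.0 * scene.params["noise_sigma"] / np.sqrt(n1),
        "c2_tolerance": 3.0 * scene.params["noise_sigma"] / np.sqrt(n2),
        "n_interior": n1,
    }


def kdtree_equivalence(seed: int = 0, n_scenes: int = 100, domain_size: int = 48) -> dict:
    """Kd-tree vs brute-force id-list images on random rectangle scenes."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_scenes):
        domain = GridRegion((0, 0), (domain_size, domain_size))
        part = DomainPartition(domain)
        for i in range(int(rng.integers(1, 12))):
            shape = tuple(int(rng.integers(3, 16)) for _ in range(2))
            offset = tuple(int(rng.integers(0, domain_size - s)) for s in shape)
            part.add_region(i, GridRegion(offset, shape))
        if not (populate_id_lists_kdtree(part) == populate_id_lists(part)):
            mismatches += 1
    return {"mismatched_scenes": mismatches, "n_scenes": n_scenes}


def cache_soundness(n_pixels: int = 50) -> dict:
    """Max stencil evaluations per quantity per point for an equation whose
    terms repeatedly request the same quantities."""
    ls = _circle_sdf((41, 41), (20, 20), 10.0)
    tc = TermContainer(1)
    for _ in range(3):
        tc.add_term(PropagationTerm(1.0))
        tc.add_term(CurvatureTerm(1.0))
        tc.add_term(LaplacianTerm())
    ls.eval_counts.clear()
    band = [tuple(int(v) for v in p) for p in np.argwhere(np.abs(ls.values) < 2)]
    pixels = band[:n_pixels]
    for idx in pixels:
        tc.evaluate(idx, QuantityCache(ls, idx))
    per_point = {q: c / len(pixels) for q, c in ls.eval_counts.items()}
    return {"max_evals_per_quantity_per_point": max(per_point.values()),
            "n_pixels": len(pixels)}


def cross_representation_consistency(shape=(48, 48), radius: float = 10.0,
                                     iterations: int = 10) -> dict:
    """Dense vs Whitaker vs Shi vs Malcolm zero levels after a short
    Chan-Vese flow toward a crisp disk."""
    center = tuple((s - 1) / 2 for s in shape)
    image, _ = disk_image(shape, center=center, radius=radius)
    masks = {}
    for rep in ("dense", "whitaker", "shi", "malcolm"):
        seed_mask = mask_from_seed((center[0] - 1, center[1] + 1), radius - 1, shape)
        ls = (binary_to_dense(seed_mask) if rep == "dense"
              else binary_to_sparse(seed_mask, rep))
        system = _single(image, ls, chan_vese_term_set(mu=0.5, level_set_id=1))
        LevelSetEvolution(system, MaxIterations(iterations)).evolve()
        masks[rep] = interior_mask_of(ls, shape)
    worst = max(
        boundary_hausdorff(masks[a], masks[b])
        for a, b in itertools.combinations(masks, 2)
    )
    return {"max_pairwise_hausdorff_px": worst, "iterations": iterations}


def multi_object_overlap(seed: int = 3, n_objects: int = 10, shape=(128, 128),
                         iterations: int = 100) -> dict:
    """Packed blobs, one restricted-domain level set per blob, Chan-Vese
    terms plus overlap penalty 1000; report the worst pairwise interior
    overlap and the mean per-object Dice."""
    scene = generate_blobs(n_objects=n_objects, shape=shape, radius_range=(6, 8),
                           min_separation=2.0, seed=seed)
    image_domain = GridRegion((0, 0), shape)
    container = LevelSetContainer()
    equations = EquationContainer()
    partition = DomainPartition(image_domain)
    for i, (center, radius) in enumerate(scene.seeds, start=1):
        region = default_region_for_seed(center, radius, image_domain, margin=radius)
        local_center = tuple(c - o for c, o in zip(center, region.offset))
        ls = binary_to_dense(mask_from_seed(local_center, radius * 0.6, region.shape),
                             region)
        container.add_level_set(i, ls)
        partition.add_region(i, region)
        tc = TermContainer(i)
        for t in chan_vese_term_set(mu=1.0, level_set_id=i):
            tc.add_term(t)
        tc.add_term(OverlapPenaltyTerm(weight=1000.0, level_set_id=i))
        equations.add_equation(i, tc)
    system = LevelSetSystem(scene.image, container, equations, partition)
    interacting = sum(
        1 for _, ids, _ in system.domain_map.iter_subdomains() if len(ids) > 1
    )
    engine = LevelSetEvolution(
        system, MaxIterations(iterations),
        reinit=ReinitPolicy(method="fast_marching", every_k=10),
    )
    engine.evolve()
    masks = {i: interior_mask_of(container.get_level_set(i), shape)
             for i in container.ids()}
    worst = max(
        int((masks[a] & masks[b]).sum())
        for a, b in itertools.combinations(masks, 2)
    )
    per_object = [dice(masks[i], scene.mask(i)) for i in container.ids()]
    return {
        "max_pairwise_overlap_px2": worst,
        "mean_dice": float(np.mean(per_object)),
        "n_level_sets": len(per_object),
        "interacting_subdomains": interacting,
    }


def restricted_domain_equivalence(iterations: int = 5) -> dict:
    """A non-interacting level set evolved in a restricted region matches
    the full-domain evolution inside that region (away from its border)."""
    image = np.zeros((64, 64))

    def evolve_in(region):
        local_center = tuple(16 - o for o in region.offset)
        ls = binary_to_dense(mask_from_seed(local_center, 6, region.shape), region)
        system = _single(image, ls, [PropagationTerm(1.0, weight=-1.0)])
        LevelSetEvolution(system, MaxIterations(iterations)).evolve()
        return ls

    restricted = evolve_in(GridRegion((2, 2), (29, 29)))
    full = evolve_in(GridRegion((0, 0), (64, 64)))
    sub = full.values[2:31, 2:31]
    margin = iterations + 2  # border stencils influence a frame this wide
    inner = np.zeros((29, 29), dtype=bool)
    inner[margin:-margin, margin:-margin] = True
    diff = float(np.max(np.abs(restricted.values - sub)[inner]))
    return {"max_abs_diff": diff, "compared_pixels": int(inner.sum())}
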