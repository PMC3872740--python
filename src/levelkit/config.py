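"""Run configuration: YAML schema validation and system assembly.

A run configuration declares the image source (file or synthetic scene),
the level sets (representation + initialization + optional restricted
region), one equation per level set as a list of named, weighted terms,
the evolution/reinitialization settings, the stopping criteria, and the
outputs.  Unknown keys anywhere are rejected before any computation.

Term names are the operation names of the public API
(``propagation_term``, ``advection_term``, ``curvature_term``,
``laplacian_term``, ``chan_vese_terms``, ``overlap_penalty_term``,
``li_regularization_term``, ``geodesic_active_contour_terms``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import terms as terms_mod
from .adaptors import binary_to_dense, binary_to_sparse, mask_from_seed
from .containers import EquationContainer, LevelSetContainer, TermContainer
from .domains import DomainPartition, default_region_for_seed
from .errors import ConfigurationError
from .evolution import LevelSetEvolution, LevelSetSystem
from .grids import GridRegion
from .io import read_image
from .reinit import ReinitPolicy
from .stopping import (EnergyDeltaBelow, MaxIterations, PointsCaptured,
                       RmsChangeBelow, combine)
from .synthetic import generate_blobs

__all__ = ["load_config", "validate_config", "build_run", "RunAssembly"]

_SCHEMA = {
    "seed": None,
    "image": {"path": None, "synthetic": {
        "n_objects": None, "shape": None, "radius_range": None,
        "fg_intensity": None, "bg_intensity": None, "noise_sigma": None,
        "blur_sigma": None, "intensity_jitter": None, "min_separation": None,
        "border": None,
    }},
    "level_sets": [{
        "id": None, "representation": None,
        "init": {"seed": {"center": None, "radius": None}, "mask": None},
        "region": {"offset": None, "shape": None},
        "seed_margin": None,
    }],
    "equations": [{
        "level_set_id": None,
        "terms": [{"name": None, "weight": None, "parameters": None}],
    }],
    "evolution": {
        "c_cfl": None, "dt_max": None, "hard_cap": None,
        "reinit": {"method": None, "every_k": None, "inner_iterations": None,
                   "dtau": None, "band_width": None},
    },
    "stopping": {"mode": None, "criteria": [{
        "kind": None, "n": None, "threshold": None, "points": None,
        "fraction": None, "tolerance": None,
    }]},
    "outputs": {"directory": None, "log": None, "contours": None,
                "labels": None, "snapshot_every": None},
}

_TERM_PARAM_KEYS = {
    "propagation_term": {"speed"},
    "advection_term": {"velocity"},
    "curvature_term": {"modifier"},
    "laplacian_term": set(),
    "chan_vese_terms": {"lambda1", "lambda2", "nu", "mu", "epsilon"},
    "overlap_penalty_term": {"epsilon"},
    "li_regularization_term": set(),
    "geodesic_active_contour_terms": {"sigma", "p", "alpha", "beta", "gamma"},
}

_CRITERIA = {"max_iterations", "rms_change_below", "energy_delta_below", "points_captured"}
_REPRESENTATIONS = ("dense", "whitaker", "shi", "malcolm")


def _check(node, schema, path):
    if isinstance(schema, dict):
        if not isinstance(node, dict):
            raise ConfigurationError(f"{path or 'config'}: expected a mapping")
        for key, value in node.items():
            if key not in schema:
                raise ConfigurationError(f"unknown config key {path + key!r}")
            if schema[key] is not None and value is not None:
                _check(value, schema[key], path + key + ".")
    elif isinstance(schema, list):
        if not isinstance(node, list):
            raise ConfigurationError(f"{path or 'config'}: expected a list")
        for i, item in enumerate(node):
            _check(item, schema[0], f"{path}{i}.")


def validate_config(cfg: dict) -> dict:
    """Schema-check a configuration mapping; raises ConfigurationError."""
    _check(cfg, _SCHEMA, "")
    if "image" not in cfg:
        raise ConfigurationError("config requires an 'image' section")
    if not cfg.get("level_sets"):
        raise ConfigurationError("config requires at least one level set")
    if not cfg.get("equations"):
        raise ConfigurationError("config requires at least one equation")
    for eq in cfg["equations"]:
        for term in eq.get("terms", []):
            name = term.get("name")
            if name not in _TERM_PARAM_KEYS:
                raise ConfigurationError(f"unknown term name {name!r}")
            params = term.get("parameters") or {}
            bad = set(params) - _TERM_PARAM_KEYS[name]
            if bad:
                raise ConfigurationError(
                    f"unknown parameters {sorted(bad)} for term {name!r}"
                )
    for ls in cfg["level_sets"]:
        rep = ls.get("representation", "dense")
        if rep not in _REPRESENTATIONS:
            raise ConfigurationError(f"unknown representation {rep!r}")
    for crit in (cfg.get("stopping") or {}).get("criteria", []):
        if crit.get("kind") not in _CRITERIA:
            raise ConfigurationError(f"unknown stopping kind {crit.get('kind')!r}")
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return validate_config(cfg)


@dataclass
class RunAssembly:
    """Everything needed to execute and post-process one run."""

    config: dict
    system: LevelSetSystem
    engine: LevelSetEvolution
    scene: object = None  # SyntheticScene when the image is generated


def _build_terms(spec: dict, image, ls_id):
    name = spec["name"]
    weight = float(spec.get("weight", 1.0))
    params = dict(spec.get("parameters") or {})
    if name == "propagation_term":
        return [terms_mod.PropagationTerm(params.get("speed", 1.0), weight, ls_id)]
    if name == "advection_term":
        return [terms_mod.AdvectionTerm(params.get("velocity", 1.0), weight, ls_id)]
    if name == "curvature_term":
        return [terms_mod.CurvatureTerm(params.get("modifier", 1.0), weight, ls_id)]
    if name == "laplacian_term":
        return [terms_mod.LaplacianTerm(weight, ls_id)]
    if name == "li_regularization_term":
        return [terms_mod.LiRegularizationTerm(weight, ls_id)]
    if name == "overlap_penalty_term":
        return [terms_mod.OverlapPenaltyTerm(
            weight, ls_id, epsilon=params.get("epsilon", terms_mod.DEFAULT_EPSILON))]
    if name == "chan_vese_terms":
        made = terms_mod.chan_vese_term_set(
            lambda1=params.get("lambda1", 1.0), lambda2=params.get("lambda2", 1.0),
            nu=params.get("nu", 0.0), mu=params.get("mu", 1.0),
            epsilon=params.get("epsilon", terms_mod.DEFAULT_EPSILON),
            level_set_id=ls_id,
        )
        for t in made:
            t.weight *= weight
        return made
    if name == "geodesic_active_contour_terms":
        ef = terms_mod.EdgeFunctionParams(
            sigma=params.get("sigma", 1.0), p=int(params.get("p", 2))
        )
        made = terms_mod.geodesic_active_contour_terms(
            image, ef, alpha=params.get("alpha", 1.0),
            beta=params.get("beta", 1.0), gamma=params.get("gamma", 1.0),
            level_set_id=ls_id,
        )
        for t in made:
            t.weight *= weight
        return made
    raise ConfigurationError(f"unknown term name {name!r}")


def build_run(cfg: dict, base_dir=".") -> RunAssembly:
    """Assemble image, level sets, equations, and engine from a config."""
    validate_config(cfg)
    base_dir = Path(base_dir)
    seed = int(cfg.get("seed", 0))

    scene = None
    image_cfg = cfg["image"]
    if image_cfg.get("path"):
        image = read_image(base_dir / image_cfg["path"])
    elif image_cfg.get("synthetic") is not None:
        synth = dict(image_cfg["synthetic"])
        synth.setdefault("seed", seed)
        if "radius_range" in synth:
            synth["radius_range"] = tuple(synth["radius_range"])
        if "shape" in synth:
            synth["shape"] = tuple(synth["shape"])
        scene = generate_blobs(**synth)
        image = scene.image
    else:
        raise ConfigurationError("image section needs 'path' or 'synthetic'")
    image_domain = GridRegion((0,) * image.ndim, image.shape)

    level_sets = LevelSetContainer()
    partition = DomainPartition(image_domain)
    for ls_cfg in cfg["level_sets"]:
        ls_id = ls_cfg["id"]
        rep = ls_cfg.get("representation", "dense")
        region_cfg = ls_cfg.get("region")
        init = ls_cfg.get("init") or {}
        if region_cfg:
            region = GridRegion(tuple(region_cfg["offset"]), tuple(region_cfg["shape"]))
        elif "seed" in init:
            region = default_region_for_seed(
                tuple(init["seed"]["center"]), float(init["seed"]["radius"]),
                image_domain, margin=ls_cfg.get("seed_margin"),
            )
        else:
            region = image_domain
        if "seed" in init:
            center = tuple(init["seed"]["center"])
            local_center = tuple(c - o for c, o in zip(center, region.offset))
            mask = mask_from_seed(local_center, float(init["seed"]["radius"]), region.shape)
        elif "mask" in init:
            mask = read_image(base_dir / init["mask"]) > 0
            mask = mask[region.slices()] if mask.shape != tuple(region.shape) else mask
        else:
            raise ConfigurationError(f"level set {ls_id!r} needs a seed or mask init")
        if rep == "dense":
            ls = binary_to_dense(mask, region)
        else:
            ls = binary_to_sparse(mask, rep, region, image_domain=image_domain)
        level_sets.add_level_set(ls_id, ls)
        partition.add_region(ls_id, region)

    equations = EquationContainer()
    for eq_cfg in cfg["equations"]:
        ls_id = eq_cfg["level_set_id"]
        tc = TermContainer(ls_id)
        for term_spec in eq_cfg.get("terms", []):
            for term in _build_terms(term_spec, image, ls_id):
                tc.add_term(term)
        equations.add_equation(ls_id, tc)

    system = LevelSetSystem(image, level_sets, equations, partition)

    evo = cfg.get("evolution") or {}
    reinit_cfg = evo.get("reinit") or {}
    reinit = ReinitPolicy(
        method=reinit_cfg.get("method", "none"),
        every_k=int(reinit_cfg.get("every_k", 1)),
        inner_iterations=int(reinit_cfg.get("inner_iterations", 20)),
        dtau=float(reinit_cfg.get("dtau", 0.3)),
        band_width=float(reinit_cfg.get("band_width", 2.0)),
    )

    stop_cfg = cfg.get("stopping") or {"criteria": [{"kind": "max_iterations", "n": 100}]}
    criteria = []
    for crit in stop_cfg.get("criteria", []):
        kind = crit["kind"]
        if kind == "max_iterations":
            criteria.append(MaxIterations(int(crit["n"])))
        elif kind == "rms_change_below":
            criteria.append(RmsChangeBelow(float(crit["threshold"])))
        elif kind == "energy_delta_below":
            criteria.append(EnergyDeltaBelow(float(crit["threshold"])))
        else:
            criteria.append(PointsCaptured(
                [tuple(p) for p in crit["points"]], float(crit["fraction"]),
                float(crit.get("tolerance", 0.0)),
            ))
    if not criteria:
        criteria = [MaxIterations(100)]
    stopping = combine(criteria, stop_cfg.get("mode", "any"))

    engine = LevelSetEvolution(
        system, stopping, reinit,
        c_cfl=float(evo.get("c_cfl", 0.45)),
        dt_max=float(evo.get("dt_max", 1.0)),
        hard_cap=int(evo.get("hard_cap", 10_000)),
    )
    return RunAssembly(config=cfg, system=system, engine=engine, scene=scene)


def label_image(system) -> np.ndarray:
    """Integer label field: each pixel gets the id of the level set whose
    interior claims it (lowest id wins ties)."""
    labels = np.zeros(system.image.shape, dtype=np.int32)
    for ls_id in reversed(system.level_sets.ids()):
        ls = system.level_sets.get_level_set(ls_id)
        mask = np.zeros(system.image.shape, dtype=bool)
        mask[ls.region.slices()] = ls.interior_mask()
        labels[mask] = int(ls_id) if np.issubdtype(type(ls_id), np.integer) or isinstance(ls_id, int) else hash(ls_id) % 10_000
    return labels
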