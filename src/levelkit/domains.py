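"""Restricted level-set domains and domain-map clustering.

Each level set lives on an axis-aligned sub-region of the image domain;
interactions are limited to level sets whose regions overlap.  The
partition is materialized as a per-pixel list of active level-set ids,
then clustered into subdomains sharing an identical id set, which the
evolution engine iterates instead of testing every pixel against every
level set.  A Kd-tree over region centroids accelerates the id-list
construction for systems with many level sets.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .grids import GridRegion

__all__ = [
    "DomainPartition",
    "IdListImage",
    "DomainMap",
    "populate_id_lists",
    "populate_id_lists_kdtree",
    "build_domain_map",
    "default_region_for_seed",
]


class DomainPartition:
    """id -> region assignment inside one image domain."""

    def __init__(self, image_domain: GridRegion, regions: dict = None):
        self.image_domain = image_domain
        self.regions = {}
        for ls_id, region in (regions or {}).items():
            self.add_region(ls_id, region)

    def add_region(self, ls_id, region: GridRegion):
        if not self.image_domain.contains_region(region):
            raise ConfigurationError(
                f"region {region} for id {ls_id!r} escapes image domain {self.image_domain}"
            )
        self.regions[ls_id] = region

    def remove_region(self, ls_id):
        del self.regions[ls_id]


class IdListImage:
    """Per-pixel ascending tuples of active level-set ids."""

    def __init__(self, image_domain: GridRegion):
        self.image_domain = image_domain
        self.lists = np.empty(image_domain.shape, dtype=object)
        empty = ()
        for local in np.ndindex(*image_domain.shape):
            self.lists[local] = empty
        self.candidate_tests = 0  # instrumentation (Kd-tree path)

    def at(self, idx) -> tuple:
        return self.lists[self.image_domain.to_local(idx)]

    def __eq__(self, other):
        return (
            isinstance(other, IdListImage)
            and self.image_domain == other.image_domain
            and bool(np.all(self.lists == other.lists))
        )


def populate_id_lists(partition: DomainPartition) -> IdListImage:
    """Brute force: stamp each region's pixels with its id."""
    out = IdListImage(partition.image_domain)
    accum = np.empty(partition.image_domain.shape, dtype=object)
    for local in np.ndindex(*partition.image_domain.shape):
        accum[local] = []
    for ls_id in sorted(partition.regions):
        region = partition.regions[ls_id]
        local_slices = tuple(
            slice(o - io, o - io + s)
            for o, s, io in zip(region.offset, region.shape, partition.image_domain.offset)
        )
        for cell in accum[local_slices].flat:
            cell.append(ls_id)
    for local in np.ndindex(*partition.image_domain.shape):
        out.lists[local] = tuple(accum[local])
    return out


def populate_id_lists_kdtree(partition: DomainPartition, query_radius: float = None) -> IdListImage:
    """Kd-tree-accelerated id-list construction.

    Region centroids go into a Kd-tree; each pixel only tests containment
    against regions whose centroid lies within ``query_radius``.  The
    default radius — the largest region half-diagonal — guarantees no
    candidate is missed, so the output is identical to the brute-force
    path.
    """
    out = IdListImage(partition.image_domain)
    if not partition.regions:
        return out
    ids = sorted(partition.regions)
    regions = [partition.regions[i] for i in ids]
    centroids = np.array([r.centroid for r in regions])
    auto_radius = max(r.half_diagonal for r in regions)
    if query_radius is None:
        query_radius = auto_radius
    elif query_radius < auto_radius:
        warnings.warn(
            "query_radius below the largest region half-diagonal; candidates may be missed",
            stacklevel=2,
        )
    tree = cKDTree(centroids)
    domain = partition.image_domain
    coords = np.array(list(np.ndindex(*domain.shape))) + np.array(domain.offset)
    candidate_lists = tree.query_ball_point(coords, query_radius + 1e-9)
    flat = out.lists.reshape(-1)
    tests = 0
    for pix, cands in enumerate(candidate_lists):
        idx = tuple(coords[pix])
        hits = []
        for c in sorted(cands):
            tests += 1
            if regions[c].contains(idx):
                hits.append(ids[c])
        flat[pix] = tuple(hits)
    out.candidate_tests = tests
    return out


class DomainMap:
    """Clustering of the id-list image into constant-id-set subdomains.

    ``label_field`` assigns each pixel the label of its id set; label 0 is
    reserved for the empty set.  ``table`` maps label -> (ids, pixel
    count); ``pixels`` maps label -> array of global indices for
    iteration.
    """

    def __init__(self, image_domain: GridRegion, label_field, table, pixels):
        self.image_domain = image_domain
        self.label_field = label_field
        self.table = table
        self.pixels = pixels

    def iter_subdomains(self):
        """Yield (label, ids, global index array) for non-empty id sets."""
        for label in sorted(self.table):
            ids, _ = self.table[label]
            yield label, ids, self.pixels[label]


def build_domain_map(id_list_image: IdListImage) -> DomainMap:
    """Enumerate distinct id sets in raster first-encounter order."""
    domain = id_list_image.image_domain
    label_field = np.zeros(domain.shape, dtype=np.int32)
    labels = {}
    members = {}
    for local in np.ndindex(*domain.shape):
        ids = id_list_image.lists[local]
        if not ids:
            continue
        if ids not in labels:
            labels[ids] = len(labels) + 1
            members[labels[ids]] = []
        lab = labels[ids]
        label_field[local] = lab
        members[lab].append(domain.to_global(local))
    table = {lab: (ids, len(members[lab])) for ids, lab in labels.items()}
    pixels = {lab: np.array(members[lab], dtype=np.intp) for lab in members}
    return DomainMap(domain, label_field, table, pixels)


def default_region_for_seed(center, radius: float, image_domain: GridRegion,
                            margin: float = None) -> GridRegion:
    """Axis-aligned box ``center +- (radius + margin)`` clipped to the image.

    The default margin of ``2 * radius`` leaves the evolving zero level
    clear of the region border for moderate growth.
    """
    if margin is None:
        margin = 2.0 * radius
    if margin < 0:
        raise ConfigurationError("margin must be >= 0")
    half = int(np.ceil(radius + margin))
    lo = []
    shape = []
    for c, o, s in zip(center, image_domain.offset, image_domain.shape):
        a = max(int(np.floor(c)) - half, o)
        b = min(int(np.ceil(c)) + half, o + s - 1)
        lo.append(a)
        shape.append(b - a + 1)
    return GridRegion(tuple(lo), tuple(shape))
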