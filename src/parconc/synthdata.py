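"""Synthetic parcellation families for end-to-end testing of the pipeline.

Real multi-author atlas sets share one masked volume but disagree in a
structured way: some authors subdivide where others draw a single area
("splitters" vs "lumpers"), and boundaries jitter between observers.  This
module generates families with exactly that structure — a base parcellation
grown by random label filling, nested refinements (each base area split
into connected children), adjacency-respecting coarsenings (neighboring
areas fused), and stochastic boundary perturbation — together with a
cluster map tying every derived area back to its base ancestor and a truth
record for recovery tests.

All connectivity is 6-neighbor.  All randomness flows from one integer
seed per operation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from math import ceil
from typing import Any

import numpy as np

from .volumes import (
    ClusterMap,
    DegeneracyError,
    ParameterError,
    Parcellation,
    VoxelGrid,
)

_NEIGHBOR_OFFSETS = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Parameters of one synthetic atlas family.

    Defaults define the demo family: a 16^3 inscribed ellipsoid mask split
    into 6 base areas, two refinement ("splitter") atlases with 2 children
    per base area, two coarsening ("lumper") atlases fusing pairs of
    neighboring areas, and mild boundary noise on the derived atlases.
    """

    mask_shape: tuple[int, int, int] = (16, 16, 16)
    mask_kind: str = "ellipsoid"  # {box, ellipsoid}
    n_base_areas: int = 6
    n_split_atlases: int = 2
    n_merge_atlases: int = 2
    split_factor: int = 2
    merge_factor: int = 2
    boundary_noise: float = 0.05
    noise_iterations: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.boundary_noise <= 1.0):
            raise ParameterError("boundary_noise must be in [0, 1]")
        if self.n_base_areas < 1:
            raise ParameterError("n_base_areas must be >= 1")
        if self.split_factor < 2 or self.merge_factor < 2:
            raise ParameterError("split_factor and merge_factor must be >= 2")
        if self.n_split_atlases < 0 or self.n_merge_atlases < 0:
            raise ParameterError("atlas counts must be >= 0")


# ---------------------------------------------------------------------------
# Masks and mask topology
# ---------------------------------------------------------------------------

def make_mask(shape: tuple[int, int, int], kind: str = "ellipsoid") -> np.ndarray:
    """Boolean mask volume: the full box, or the ellipsoid inscribed in it.

    The ellipsoid uses semi-axes shape/2 around the box center, so it is
    connected, nonempty, and always contains the center voxel.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 1 for s in shape):
        raise ParameterError(f"mask shape must be >= 1 per axis, got {shape}")
    if kind == "box":
        return np.ones(shape, dtype=bool)
    if kind == "ellipsoid":
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        acc = np.zeros(shape, dtype=float)
        for g, s in zip(grids, shape):
            center = (s - 1) / 2.0
            semi = max(s / 2.0, 0.5)
            acc = acc + ((g - center) / semi) ** 2
        mask = acc <= 1.0
        # numerically degenerate axes can only grow the mask, never empty it
        assert mask.any()
        return mask
    raise ParameterError(f"unknown mask kind {kind!r} (expected 'box' or 'ellipsoid')")


class _MaskTopology:
    """Flat-index view of a boolean mask with per-voxel 6-neighbor lists.

    Built once per mask and reused across many random fills (the null model
    draws hundreds of parcellations of the same mask).
    """

    def __init__(self, mask: np.ndarray):
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim != 3:
            raise ParameterError("mask must be 3D")
        if not mask.any():
            raise ParameterError("mask is empty")
        self.mask = mask
        self.shape = mask.shape
        flat = np.flatnonzero(mask)
        self.n = len(flat)
        local = np.full(mask.size, -1, dtype=np.int64)
        local[flat] = np.arange(self.n)
        coords = np.array(np.unravel_index(flat, mask.shape)).T
        nx, ny, nz = mask.shape
        neighbors: list[tuple[int, ...]] = []
        for (i, j, k) in coords:
            nb = []
            for di, dj, dk in _NEIGHBOR_OFFSETS:
                a, b, c = i + di, j + dj, k + dk
                if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz:
                    li = local[(a * ny + b) * nz + c]
                    if li >= 0:
                        nb.append(int(li))
            neighbors.append(tuple(nb))
        self.neighbors = neighbors
        self.flat_indices = flat

    def labels_to_volume(self, local_labels: np.ndarray) -> np.ndarray:
        vol = np.zeros(self.mask.size, dtype=np.int32)
        vol[self.flat_indices] = local_labels
        return vol.reshape(self.shape)


def _random_fill(topo: _MaskTopology, n_areas: int, seed: int) -> np.ndarray:
    """Partition the mask into ``n_areas`` connected regions by random growth.

    N distinct seed voxels are drawn uniformly without replacement; growth
    proceeds by popping a uniformly random pending claim (voxel, label) —
    the first claim to reach an unassigned voxel wins and enqueues claims
    for its unassigned neighbors.  Every region is 6-connected and nonempty;
    the regions partition the mask.  Deterministic given the seed.
    """
    if not (1 <= n_areas <= topo.n):
        raise ParameterError(
            f"number of areas must be in [1, {topo.n}] for this mask, got {n_areas}"
        )
    rng = random.Random(int(seed))
    labels = np.zeros(topo.n, dtype=np.int32)
    seeds = rng.sample(range(topo.n), n_areas)
    frontier: list[tuple[int, int]] = []
    for lab, v in enumerate(seeds, start=1):
        labels[v] = lab
        for nb in topo.neighbors[v]:
            if labels[nb] == 0:
                frontier.append((nb, lab))
    neighbors = topo.neighbors
    while frontier:
        i = rng.randrange(len(frontier))
        frontier[i], frontier[-1] = frontier[-1], frontier[i]
        v, lab = frontier.pop()
        if labels[v] != 0:
            continue
        labels[v] = lab
        for nb in neighbors[v]:
            if labels[nb] == 0:
                frontier.append((nb, lab))
    return labels


#: world position (mm) of the synthetic volume center: roughly the right
#: thalamus in a standard stereotaxic frame, so coordinate lookup accepts
#: realistic millimeter queries
_SYNTHETIC_CENTER_MM = (13.0, -17.0, -2.0)


def _default_grid(shape: tuple[int, int, int]) -> VoxelGrid:
    # 1 mm isotropic, volume center at the synthetic thalamus position
    affine = np.eye(4)
    affine[:3, 3] = [c - (s - 1) / 2.0 for c, s in zip(_SYNTHETIC_CENTER_MM, shape)]
    return VoxelGrid(shape=shape, affine=affine)


def generate_base_parcellation(
    mask: np.ndarray,
    n_areas: int,
    seed: int,
    name: str = "base",
    grid: VoxelGrid | None = None,
    area_prefix: str = "A",
) -> Parcellation:
    """Random parcellation of ``mask`` into ``n_areas`` connected areas.

    This is the same random-label-filling mechanism used by the null model
    (:func:`parconc.nullmodels.random_parcellation` shares it).
    """
    topo = _MaskTopology(mask)
    labels = _random_fill(topo, n_areas, seed)
    volume = topo.labels_to_volume(labels)
    names = {lab: f"{area_prefix}{lab}" for lab in range(1, n_areas + 1)}
    return Parcellation(
        name=name,
        grid=grid or _default_grid(topo.shape),
        labels=volume,
        area_names=names,
    )


# ---------------------------------------------------------------------------
# Refinement and coarsening
# ---------------------------------------------------------------------------

def split_atlas(
    base: Parcellation,
    split_factor: int,
    seed: int,
    name: str = "split",
) -> tuple[Parcellation, dict[int, int]]:
    """Refine every base area into ``split_factor`` connected children.

    Children are grown by k-seed random filling inside the parent area, so
    nesting is exact: every child lies wholly inside its parent.  Returns
    the refined parcellation and the child -> parent label map.
    """
    if split_factor < 2:
        raise ParameterError("split_factor must be >= 2")
    ss = np.random.SeedSequence(int(seed))
    out = np.zeros_like(base.labels)
    parent_map: dict[int, int] = {}
    names: dict[int, str] = {}
    next_label = 1
    sizes = base.area_sizes()
    for parent in sorted(base.area_names):
        if sizes[parent] < split_factor:
            raise ParameterError(
                f"area {parent} ({base.area_names[parent]!r}) has {sizes[parent]} voxels, "
                f"too small to split into {split_factor}"
            )
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        topo = _MaskTopology(base.labels == parent)
        child_local = _random_fill(topo, split_factor, sub_seed)
        child_vol = topo.labels_to_volume(child_local)
        for c in range(1, split_factor + 1):
            lab = next_label + c - 1
            out[child_vol == c] = lab
            parent_map[lab] = parent
            names[lab] = f"{base.area_names[parent]}.{c}"
        next_label += split_factor
    parc = Parcellation(name=name, grid=base.grid, labels=out, area_names=names)
    return parc, parent_map


def _area_adjacency(parc: Parcellation) -> dict[int, set[int]]:
    """6-neighbor adjacency between distinct nonzero labels."""
    lab = parc.labels
    adj: dict[int, set[int]] = {int(l): set() for l in parc.present_labels()}
    for axis in range(3):
        a = np.moveaxis(lab, axis, 0)[:-1]
        b = np.moveaxis(lab, axis, 0)[1:]
        touching = (a > 0) & (b > 0) & (a != b)
        for x, y in zip(a[touching].ravel(), b[touching].ravel()):
            adj[int(x)].add(int(y))
            adj[int(y)].add(int(x))
    return adj


def merge_atlas(
    base: Parcellation,
    merge_factor: int,
    seed: int,
    name: str = "merge",
) -> tuple[Parcellation, dict[int, list[int]]]:
    """Coarsen the base by fusing groups of ~``merge_factor`` adjacent areas.

    Groups are grown on the area-adjacency graph with a capacity of
    ``merge_factor`` areas; stranded areas then join the smallest adjacent
    group.  The result has ``ceil(n_base / merge_factor)`` connected areas.
    Returns the coarsened parcellation and the merged-label -> constituent
    base labels map.
    """
    if merge_factor < 2:
        raise ParameterError("merge_factor must be >= 2")
    base_labels = sorted(base.area_names)
    n = len(base_labels)
    if n < merge_factor:
        raise ParameterError(f"base has {n} areas, fewer than merge_factor {merge_factor}")
    n_groups = ceil(n / merge_factor)
    rng = random.Random(int(seed))
    adj = _area_adjacency(base)
    group_of: dict[int, int] = {}
    group_members: dict[int, list[int]] = {g: [] for g in range(1, n_groups + 1)}
    seeds = rng.sample(base_labels, n_groups)
    frontier: list[tuple[int, int]] = []
    for g, area in enumerate(seeds, start=1):
        group_of[area] = g
        group_members[g].append(area)
        frontier.extend((nb, g) for nb in adj[area] if nb not in group_of)
    while frontier:
        i = rng.randrange(len(frontier))
        frontier[i], frontier[-1] = frontier[-1], frontier[i]
        area, g = frontier.pop()
        if area in group_of or len(group_members[g]) >= merge_factor:
            continue
        group_of[area] = g
        group_members[g].append(area)
        frontier.extend((nb, g) for nb in adj[area] if nb not in group_of)
    # stranded areas (all neighboring groups at capacity) join the smallest
    # adjacent group; the mask is connected so every area eventually attaches
    unassigned = [a for a in base_labels if a not in group_of]
    while unassigned:
        progressed = False
        rng.shuffle(unassigned)
        remaining = []
        for area in unassigned:
            adjacent_groups = {group_of[nb] for nb in adj[area] if nb in group_of}
            if adjacent_groups:
                g = min(adjacent_groups, key=lambda gg: (len(group_members[gg]), gg))
                group_of[area] = g
                group_members[g].append(area)
                progressed = True
            else:
                remaining.append(area)
        if not progressed and remaining:
            raise DegeneracyError("area adjacency graph is disconnected; cannot merge")
        unassigned = remaining
    out = np.zeros_like(base.labels)
    for area, g in group_of.items():
        out[base.labels == area] = g
    names = {g: "+".join(base.area_names[a] for a in sorted(ms)) for g, ms in group_members.items()}
    parc = Parcellation(name=name, grid=base.grid, labels=out, area_names=names)
    merged_map = {g: sorted(ms) for g, ms in group_members.items()}
    return parc, merged_map


# ---------------------------------------------------------------------------
# Boundary noise
# ---------------------------------------------------------------------------

def perturb_boundaries(
    parc: Parcellation,
    p: float,
    iterations: int,
    seed: int,
    name: str | None = None,
) -> Parcellation:
    """Jitter area boundaries: a stand-in for inter-observer disagreement.

    Per iteration, every voxel with a 6-neighbor of a different (nonzero)
    label is, with probability ``p``, reassigned to the label of one of
    those neighbors chosen uniformly.  Updates are synchronous within an
    iteration.  Mask coverage is unchanged; if any area vanishes a
    DegeneracyError is raised (lower ``p`` or the iteration count).
    """
    if not (0.0 <= p <= 1.0):
        raise ParameterError("noise probability must be in [0, 1]")
    if iterations < 0:
        raise ParameterError("iterations must be >= 0")
    labels = parc.labels.copy()
    if p == 0.0 or iterations == 0:
        return Parcellation(
            name=name or parc.name, grid=parc.grid, labels=labels, area_names=dict(parc.area_names)
        )
    rng = np.random.default_rng(int(seed))
    mask = labels > 0
    flat_mask = np.flatnonzero(mask)
    original_labels = set(parc.area_names)
    for _ in range(iterations):
        nb_labels = np.zeros((6, len(flat_mask)), dtype=np.int32)
        for d, (di, dj, dk) in enumerate(_NEIGHBOR_OFFSETS):
            shifted = np.zeros_like(labels)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            for ax, delta in enumerate((di, dj, dk)):
                if delta == 1:
                    src[ax], dst[ax] = slice(1, None), slice(None, -1)
                elif delta == -1:
                    src[ax], dst[ax] = slice(None, -1), slice(1, None)
            shifted[tuple(dst)] = labels[tuple(src)]
            nb_labels[d] = shifted.ravel()[flat_mask]
        own = labels.ravel()[flat_mask]
        differing = (nb_labels > 0) & (nb_labels != own[None, :])
        counts = differing.sum(axis=0)
        flip = (counts > 0) & (rng.random(len(flat_mask)) < p)
        if flip.any():
            pick = np.floor(rng.random(len(flat_mask)) * counts.clip(min=1)).astype(np.int64)
            order = np.cumsum(differing, axis=0) - 1
            sel = differing & (order == pick[None, :])
            chosen = (nb_labels * sel).sum(axis=0)  # exactly one True per flipped column
            new = own.copy()
            new[flip] = chosen[flip]
            labels.ravel()[flat_mask] = new
    surviving = set(np.unique(labels[labels > 0]).tolist())
    lost = sorted(original_labels - surviving)
    if lost:
        raise DegeneracyError(
            f"boundary noise eliminated areas {lost}; lower p or iterations"
        )
    return Parcellation(
        name=name or parc.name, grid=parc.grid, labels=labels, area_names=dict(parc.area_names)
    )


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------

@dataclass
class FamilyTruth:
    """Ground truth of a generated family, for recovery tests.

    ``family`` maps each atlas name to its role ('base', 'split', 'merge');
    ``split_parents`` maps split-atlas name -> {child label: base label};
    ``merge_groups`` maps merge-atlas name -> {merged label: [base labels]}.
    The boundary-noise model is a synthetic stand-in for inter-observer
    disagreement, not a model fitted to real atlas data.
    """

    spec: dict[str, Any]
    family: dict[str, str] = field(default_factory=dict)
    split_parents: dict[str, dict[int, int]] = field(default_factory=dict)
    merge_groups: dict[str, dict[int, list[int]]] = field(default_factory=dict)
    note: str = (
        "synthetic family; boundary noise is a stand-in for inter-observer disagreement"
    )


def make_family(
    spec: SyntheticFamilySpec,
) -> tuple[list[Parcellation], ClusterMap, FamilyTruth]:
    """Generate base + splitter + lumper atlases with cluster map and truth.

    Clusters correspond to base areas: every derived area is assigned the
    cluster of its base ancestor (for merged areas, the base area with the
    largest overlap).  Derived atlases are perturbed when
    ``spec.boundary_noise > 0``; the base is kept clean as the reference.
    """
    ss = np.random.SeedSequence(int(spec.seed))

    def next_seed() -> int:
        return int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))

    mask = make_mask(spec.mask_shape, spec.mask_kind)
    base = generate_base_parcellation(mask, spec.n_base_areas, next_seed(), name="base")
    parcs = [base]
    truth = FamilyTruth(spec=asdict(spec), family={"base": "base"})
    entries: list[tuple[str, int, int]] = [
        ("base", lab, lab) for lab in sorted(base.area_names)
    ]
    cluster_names = {lab: f"C{lab}" for lab in sorted(base.area_names)}

    def maybe_perturb(parc: Parcellation) -> Parcellation:
        if spec.boundary_noise > 0 and spec.noise_iterations > 0:
            return perturb_boundaries(
                parc, spec.boundary_noise, spec.noise_iterations, next_seed()
            )
        return parc

    for i in range(1, spec.n_split_atlases + 1):
        atlas_name = f"split{i}"
        parc, parent_map = split_atlas(base, spec.split_factor, next_seed(), name=atlas_name)
        parc = maybe_perturb(parc)
        parcs.append(parc)
        truth.family[atlas_name] = "split"
        truth.split_parents[atlas_name] = parent_map
        entries.extend((atlas_name, child, parent) for child, parent in sorted(parent_map.items()))

    for i in range(1, spec.n_merge_atlases + 1):
        atlas_name = f"merge{i}"
        parc, merged_map = merge_atlas(base, spec.merge_factor, next_seed(), name=atlas_name)
        parc = maybe_perturb(parc)
        parcs.append(parc)
        truth.family[atlas_name] = "merge"
        truth.merge_groups[atlas_name] = merged_map
        base_sizes = base.area_sizes()
        for merged_label, constituents in sorted(merged_map.items()):
            ancestor = max(constituents, key=lambda a: (base_sizes[a], -a))
            entries.append((atlas_name, merged_label, ancestor))

    clusters = ClusterMap(entries=entries, cluster_names=cluster_names)
    clusters.validate_against(parcs)
    return parcs, clusters, truth
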