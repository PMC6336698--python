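"""Label volumes, grids, and the tables that describe them.

A *parcellation* is an exhaustive division of a masked 3D volume into
labeled, non-overlapping areas: an integer NIfTI volume (0 = background)
plus a table mapping each label to an area name.  All atlases entering a
concordance analysis must live on one shared voxel grid — this module
validates that and provides the voxel/world coordinate mapping; it never
resamples, because resampling label volumes silently changes overlap
statistics.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

#: Tolerance (mm) for declaring two affines / voxel sizes identical.
GRID_TOLERANCE_MM = 1e-4


class ParcellationError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ParcellationError):
    """Input file does not have the expected format (e.g. non-integer voxels)."""


class ValidationError(ParcellationError):
    """Data violates a structural invariant (e.g. unnamed labels)."""


class GridMismatchError(ParcellationError):
    """Parcellations do not share a common voxel grid."""


class OutOfBoundsError(ParcellationError):
    """A world coordinate maps outside the voxel grid."""


class ParameterError(ParcellationError):
    """An operation parameter is out of its admissible range."""


class DegeneracyError(ParcellationError):
    """An operation produced or encountered a degenerate configuration."""


class UndefinedIndexError(ParcellationError):
    """A concordance index is undefined (zero pair-count denominator)."""


class CalibrationError(ParcellationError):
    """Observed summary and null distribution refer to mismatched region counts."""


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D voxel lattice with its world (mm) coordinate mapping.

    Parameters
    ----------
    shape
        Voxels per axis, all >= 1.
    affine
        4x4 affine mapping 0-based voxel indices to world coordinates in mm
        (the NIfTI convention).  Must be invertible.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValidationError(f"grid shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValidationError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValidationError("affine is not invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths (mm) of one voxel along each axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def voxel_to_world(self, ijk: Sequence[float]) -> np.ndarray:
        """World (mm) coordinate of voxel center ``ijk``."""
        ijk = np.asarray(ijk, dtype=float)
        return self.affine[:3, :3] @ ijk + self.affine[:3, 3]

    def matches(self, other: "VoxelGrid", tol: float = GRID_TOLERANCE_MM) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol, rtol=0.0
        )


@dataclass
class Parcellation:
    """A named integer label volume with its label -> area-name table.

    Invariants (checked on construction): labels are nonnegative integers,
    every nonzero label occurring in the volume has a name, and every named
    label occurs in the volume.  Label 0 is background / unlabeled.
    """

    name: str
    grid: VoxelGrid
    labels: np.ndarray
    area_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValidationError(f"{self.name}: label volume must be 3D")
        if not np.issubdtype(labels.dtype, np.integer):
            raise FormatError(f"{self.name}: label volume must hold integers")
        if tuple(labels.shape) != self.grid.shape:
            raise ValidationError(
                f"{self.name}: volume shape {labels.shape} != grid shape {self.grid.shape}"
            )
        if labels.min(initial=0) < 0:
            raise ValidationError(f"{self.name}: labels must be nonnegative")
        self.labels = labels.astype(np.int32, copy=False)
        present = set(self.present_labels().tolist())
        named = set(int(k) for k in self.area_names)
        missing = sorted(present - named)
        if missing:
            raise ValidationError(
                f"{self.name}: labels present in volume but missing from name table: {missing}"
            )
        unused = sorted(named - present)
        if unused:
            raise ValidationError(
                f"{self.name}: named labels absent from volume: {unused}"
            )
        self.area_names = {int(k): str(v) for k, v in self.area_names.items()}

    def present_labels(self) -> np.ndarray:
        """Sorted array of nonzero labels occurring in the volume."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_areas(self) -> int:
        return len(self.area_names)

    def area_sizes(self) -> dict[int, int]:
        """Voxel count per nonzero label."""
        counts = np.bincount(self.labels.ravel())
        return {int(l): int(counts[l]) for l in self.present_labels()}

    def mask(self) -> np.ndarray:
        """Boolean volume of labeled (nonzero) voxels."""
        return self.labels > 0


@dataclass
class ClusterMap:
    """Assignment of (atlas, label) pairs to named area clusters.

    A label belongs to at most one cluster; clusters group structurally
    related areas across atlases (analogous to grouping thalamic nuclei
    into regions such as MD or VAM).
    """

    entries: list[tuple[str, int, int]]  # (atlas name, label, cluster id)
    cluster_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for atlas, label, _cluster in self.entries:
            key = (atlas, int(label))
            if key in seen:
                raise ValidationError(f"label {label} of atlas {atlas!r} assigned to two clusters")
            seen.add(key)

    def cluster_ids(self) -> list[int]:
        return sorted({c for _, _, c in self.entries})

    def members(self, cluster_id: int) -> dict[str, set[int]]:
        """Map atlas name -> set of member labels for one cluster."""
        out: dict[str, set[int]] = {}
        for atlas, label, cluster in self.entries:
            if cluster == cluster_id:
                out.setdefault(atlas, set()).add(int(label))
        return out

    def validate_against(self, parcs: Sequence[Parcellation]) -> None:
        """Check every referenced label exists in the named atlas."""
        by_name = {p.name: p for p in parcs}
        for atlas, label, _ in self.entries:
            if atlas not in by_name:
                raise ValidationError(f"cluster table references unknown atlas {atlas!r}")
            if int(label) not in by_name[atlas].area_names:
                raise ValidationError(
                    f"cluster table references label {label} absent from atlas {atlas!r}"
                )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_name_table(path: str | Path) -> dict[int, str]:
    """Read a two-column ``label<TAB>name`` TSV into a dict."""
    names: dict[int, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "label":  # optional header
                continue
            if len(row) < 2:
                raise FormatError(f"{path}: malformed name-table row {row!r}")
            names[int(row[0])] = row[1]
    return names


def write_name_table(names: Mapping[int, str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["label", "name"])
        for label in sorted(names):
            w.writerow([label, names[label]])


def read_cluster_table(path: str | Path) -> ClusterMap:
    """Read an ``atlas<TAB>label<TAB>cluster`` TSV (optional 4th column: cluster name)."""
    entries: list[tuple[str, int, int]] = []
    cluster_names: dict[int, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "atlas":
                continue
            if len(row) < 3:
                raise FormatError(f"{path}: malformed cluster-table row {row!r}")
            atlas, label, cluster = row[0], int(row[1]), int(row[2])
            entries.append((atlas, label, cluster))
            if len(row) >= 4 and row[3]:
                cluster_names[cluster] = row[3]
    return ClusterMap(entries=entries, cluster_names=cluster_names)


def write_cluster_table(clusters: ClusterMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["atlas", "label", "cluster", "cluster_name"])
        for atlas, label, cluster in clusters.entries:
            w.writerow([atlas, label, cluster, clusters.cluster_names.get(cluster, "")])


def read_parcellation(volume_path: str | Path, names_path: str | Path, name: str) -> Parcellation:
    """Load a label volume (NIfTI) and its name table into a validated Parcellation.

    Raises
    ------
    FormatError
        If the volume holds non-integer voxel values.
    ValidationError
        If a label in the volume has no entry in the name table (the message
        lists the offending labels), or a named label never occurs.
    """
    img = nib.load(str(volume_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{volume_path}: expected a 3D volume, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise FormatError(f"{volume_path}: voxel values are not integers")
        data = rounded
    data = data.astype(np.int32)
    grid = VoxelGrid(shape=tuple(data.shape), affine=np.asarray(img.affine, dtype=float))
    names = read_name_table(names_path)
    return Parcellation(name=name, grid=grid, labels=data, area_names=names)


def write_parcellation(parc: Parcellation, volume_path: str | Path, names_path: str | Path | None = None) -> None:
    """Write the label volume as int16/int32 NIfTI and (optionally) its name table."""
    dtype = np.int16 if parc.labels.max(initial=0) < 2**15 else np.int32
    img = nib.Nifti1Image(parc.labels.astype(dtype), parc.grid.affine)
    nib.save(img, str(volume_path))
    if names_path is not None:
        write_name_table(parc.area_names, names_path)


def write_scalar_volume(data: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    """Write a float scalar volume (e.g. a concordance map) on ``grid``."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Grid checks and coordinate lookup
# ---------------------------------------------------------------------------

def verify_common_grid(parcs: Sequence[Parcellation]) -> VoxelGrid:
    """Return the grid shared by all parcellations, or raise GridMismatchError.

    Shapes must match exactly and affines within ``GRID_TOLERANCE_MM``.
    """
    if not parcs:
        raise ParameterError("verify_common_grid requires at least one parcellation")
    ref = parcs[0].grid
    for p in parcs[1:]:
        if not ref.matches(p.grid):
            raise GridMismatchError(
                f"atlas {p.name!r} is not on the common grid of {parcs[0].name!r}: "
                f"shape {p.grid.shape} vs {ref.shape}"
            )
    return ref


def world_to_voxel(grid: VoxelGrid, xyz_mm: Sequence[float]) -> tuple[int, int, int]:
    """Map a world (mm) coordinate to the nearest voxel index.

    Uses the inverse affine and nearest-neighbor rounding with half-up
    tie-breaking (floor(x + 0.5)); labels are never interpolated.

    Raises
    ------
    OutOfBoundsError
        If the rounded index falls outside the grid.
    """
    xyz = np.asarray(xyz_mm, dtype=float)
    inv = np.linalg.inv(grid.affine)
    ijk = inv[:3, :3] @ xyz + inv[:3, 3]
    idx = tuple(int(np.floor(c + 0.5)) for c in ijk)
    for c, s in zip(idx, grid.shape):
        if c < 0 or c >= s:
            raise OutOfBoundsError(f"coordinate {tuple(xyz)} mm maps to voxel {idx}, outside grid {grid.shape}")
    return idx
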