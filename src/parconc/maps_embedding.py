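"""Derived views of the concordance results.

Four read-outs sit on top of the Wallace / conditional-probability core:

* block-wise seriation of the area-level P matrix, pulling the overlap
  cloud of every atlas pair toward the block diagonal so subdivision
  structure becomes visible;
* a 2D classical-MDS landscape of atlases from the global W_max / W_asym
  matrices, in which mutually well-predicted, symmetric atlas pairs sit
  close together;
* voxel-wise mean concordance and asymmetry maps over all atlas pairs;
* per-coordinate characterization: the area label each atlas assigns to a
  queried world coordinate plus the local concordance there.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .concordance import ConditionalProbabilityMatrix, contingency, conditional_probability
from .volumes import (
    ParameterError,
    Parcellation,
    ValidationError,
    VoxelGrid,
    verify_common_grid,
    world_to_voxel,
)


# ---------------------------------------------------------------------------
# Block reordering (matrix seriation)
# ---------------------------------------------------------------------------

@dataclass
class BlockReordering:
    """Row/column permutations per block with the seriation objective.

    The objective per block is the mean over nonzero entries of
    ``|i/(rows-1) - j/(cols-1)|`` (normalized index distance from the
    block diagonal, comparable across non-square blocks).  The reordering
    never increases it: when the SVD heuristic would, the identity
    permutation is kept.
    """

    row_perms: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    col_perms: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    objective_before: dict[tuple[str, str], float] = field(default_factory=dict)
    objective_after: dict[tuple[str, str], float] = field(default_factory=dict)

    def reordered_block(self, P: ConditionalProbabilityMatrix, key: tuple[str, str]) -> np.ndarray:
        ra, ca = key
        block = P.P[P.row_blocks[ra], P.col_blocks[ca]]
        return block[np.ix_(self.row_perms[key], self.col_perms[key])]


def diagonal_mass_objective(block: np.ndarray) -> float:
    """Mean normalized distance of nonzero entries from the block diagonal."""
    r, c = block.shape
    i, j = np.nonzero(block)
    if len(i) == 0:
        return 0.0
    ri = i / (r - 1) if r > 1 else np.zeros(len(i))
    cj = j / (c - 1) if c > 1 else np.zeros(len(j))
    return float(np.abs(ri - cj).mean())


def _smoothing_matrix(n: int, w: float = 0.25) -> np.ndarray:
    S = np.eye(n) * (1 - 2 * w)
    for i in range(n - 1):
        S[i, i + 1] = w
        S[i + 1, i] = w
    S[0, 0] += w
    S[-1, -1] += w
    return S


def _svd_ordering(block: np.ndarray, smooth: bool) -> tuple[np.ndarray, np.ndarray]:
    """Row/col orders from the first singular vector pair of the centered block.

    Optional neighbor smoothing breaks the sign/order degeneracy of
    permutation-like blocks (e.g. an exact anti-diagonal, where all
    singular values coincide).  Signs are chosen so the left vector
    correlates positively with the row index; the right vector is flipped
    with it so the pair stays consistent.
    """
    r, c = block.shape
    A = block
    if smooth and r > 1 and c > 1:
        A = _smoothing_matrix(r) @ A @ _smoothing_matrix(c)
    B = A - A.mean(axis=1, keepdims=True) - A.mean(axis=0, keepdims=True) + A.mean()
    U, _s, Vt = np.linalg.svd(B)
    u1, v1 = U[:, 0], Vt[0]
    centered_index = np.arange(r) - (r - 1) / 2
    if float((u1 * centered_index).sum()) < 0:
        u1, v1 = -u1, -v1
    return np.argsort(u1, kind="stable"), np.argsort(v1, kind="stable")


def reorder_block(block: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Seriate one rectangular block toward the diagonal.

    Candidates are the identity and the first-singular-vector orderings of
    the centered block (plain and neighbor-smoothed); the candidate with
    the lowest diagonal-mass objective wins, the identity on ties, so the
    objective never increases.  All-zero blocks keep the identity.

    Returns (row order, col order, objective before, objective after).
    """
    r, c = block.shape
    identity = (np.arange(r), np.arange(c))
    before = diagonal_mass_objective(block)
    if not np.any(block):
        return identity[0], identity[1], before, before
    candidates = [identity]
    for smooth in (False, True):
        try:
            candidates.append(_svd_ordering(block, smooth))
        except np.linalg.LinAlgError:  # pragma: no cover - SVD failure is exotic
            continue
    best = identity
    best_obj = before
    for ro, co in candidates:
        obj = diagonal_mass_objective(block[np.ix_(ro, co)])
        if obj < best_obj - 1e-12:
            best, best_obj = (ro, co), obj
    return best[0], best[1], before, best_obj


def reorder_blocks(P: ConditionalProbabilityMatrix) -> BlockReordering:
    """Seriate every block of a block-structured P matrix independently."""
    if not P.row_blocks or not P.col_blocks:
        raise ParameterError("reorder_blocks requires a block-structured matrix")
    out = BlockReordering()
    for ra in P.row_blocks:
        for ca in P.col_blocks:
            block = P.P[P.row_blocks[ra], P.col_blocks[ca]]
            ro, co, before, after = reorder_block(block)
            key = (ra, ca)
            out.row_perms[key] = ro
            out.col_perms[key] = co
            out.objective_before[key] = before
            out.objective_after[key] = after
    return out


# ---------------------------------------------------------------------------
# MDS atlas landscape
# ---------------------------------------------------------------------------

@dataclass
class AtlasEmbedding:
    """2D classical-MDS coordinates of atlases with the distances used.

    Coordinates are deterministic up to rotation/reflection; compare
    inter-point distances, not raw coordinates.
    """

    atlas_names: list[str]
    coordinates: np.ndarray  # (n_atlases, 2)
    stress: float
    distances: np.ndarray  # (n, n) symmetric, zero diagonal


def concordance_distance(w_max: pd.DataFrame, w_asym: pd.DataFrame) -> np.ndarray:
    """``d(A,B) = sqrt((1 - W_max)^2 + W_asym^2)``.

    Treats shortfall of mutual predictability and asymmetry as orthogonal
    dissimilarity axes: identical atlases are at distance 0, and pairs that
    are both poorly overlapping and strongly asymmetric are farthest.
    """
    if list(w_max.index) != list(w_max.columns) or list(w_asym.index) != list(w_asym.columns):
        raise ValidationError("W matrices must have matching atlas sets on rows and columns")
    if list(w_max.index) != list(w_asym.index):
        raise ValidationError("W_max and W_asym refer to different atlas sets")
    wm = w_max.to_numpy(dtype=float)
    wa = w_asym.to_numpy(dtype=float)
    for name, m in (("W_max", wm), ("W_asym", wa)):
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValidationError(f"{name} matrix is not symmetric")
    d = np.sqrt((1.0 - wm) ** 2 + wa**2)
    np.fill_diagonal(d, 0.0)
    return d


def mds_embed(w_max: pd.DataFrame, w_asym: pd.DataFrame) -> AtlasEmbedding:
    """Classical (Torgerson) MDS of the concordance distances to 2D.

    Double-centers the squared distance matrix and takes the two leading
    nonnegative eigenpairs.  Stress is the relative Frobenius error between
    input distances and embedded distances.
    """
    d = concordance_distance(w_max, w_asym)
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    k = min(2, n)
    lam = np.clip(eigval[:k], 0.0, None)
    coords = eigvec[:, :k] * np.sqrt(lam)[None, :]
    if coords.shape[1] < 2:
        coords = np.hstack([coords, np.zeros((n, 2 - coords.shape[1]))])
    emb_d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    denom = np.sqrt((d**2).sum())
    stress = float(np.sqrt(((d - emb_d) ** 2).sum()) / denom) if denom > 0 else 0.0
    return AtlasEmbedding(
        atlas_names=list(w_max.index),
        coordinates=coords,
        stress=stress,
        distances=d,
    )


# ---------------------------------------------------------------------------
# Voxel-wise maps
# ---------------------------------------------------------------------------

@dataclass
class VoxelConcordanceMap:
    """Per-voxel mean concordance / asymmetry over contributing atlas pairs."""

    grid: VoxelGrid
    mean_concordance: np.ndarray
    mean_asymmetry: np.ndarray
    coverage: np.ndarray  # contributing pair count per voxel


def voxelwise_maps(
    parcs: list[Parcellation],
    statistic: str = "conditional",
) -> VoxelConcordanceMap:
    """Mean local concordance and asymmetry per voxel over all atlas pairs.

    For each unordered atlas pair and each voxel labeled in both, with
    containing areas a (atlas A) and b (atlas B):

    * ``statistic="conditional"`` (default): local concordance is
      ``max(P(a|b), P(b|a))`` and local asymmetry ``|P(a|b) - P(b|a)|``;
    * ``statistic="wallace"``: the same reduction applied to the
      single-area directional Wallace pair of a vs b
      (``n_ab(n_ab-1)/(|a|(|a|-1))`` and its mirror).

    The maps average over contributing pairs; voxels covered by no pair
    are masked out (zero, with coverage 0).
    """
    if len(parcs) < 2:
        raise ParameterError("voxel-wise maps need at least 2 atlases")
    if statistic not in ("conditional", "wallace"):
        raise ParameterError(f"unknown statistic {statistic!r}")
    grid = verify_common_grid(parcs)
    shape = grid.shape
    conc_sum = np.zeros(shape, dtype=float)
    asym_sum = np.zeros(shape, dtype=float)
    coverage = np.zeros(shape, dtype=np.int32)
    for pa, pb in itertools.combinations(parcs, 2):
        table = contingency(pa, pb)
        counts = table.counts.astype(float)
        size_a = table.size_a.astype(float)
        size_b = table.size_b.astype(float)
        if statistic == "conditional":
            p_ab = counts / size_b[None, :]  # P(a|b)
            p_ba = counts / size_a[:, None]  # P(b|a)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                p_ab = np.where(
                    size_b[None, :] > 1,
                    counts * (counts - 1) / (size_b[None, :] * (size_b[None, :] - 1)),
                    0.0,
                )
                p_ba = np.where(
                    size_a[:, None] > 1,
                    counts * (counts - 1) / (size_a[:, None] * (size_a[:, None] - 1)),
                    0.0,
                )
        local_conc = np.maximum(p_ab, p_ba)
        local_asym = np.abs(p_ab - p_ba)
        index_a = np.zeros(int(pa.labels.max()) + 1, dtype=np.int64)
        for i, lab in enumerate(table.labels_a):
            index_a[lab] = i + 1
        index_b = np.zeros(int(pb.labels.max()) + 1, dtype=np.int64)
        for i, lab in enumerate(table.labels_b):
            index_b[lab] = i + 1
        ia = index_a[pa.labels]
        ib = index_b[pb.labels]
        joint = (ia > 0) & (ib > 0)
        conc_sum[joint] += local_conc[ia[joint] - 1, ib[joint] - 1]
        asym_sum[joint] += local_asym[ia[joint] - 1, ib[joint] - 1]
        coverage[joint] += 1
    covered = coverage > 0
    mean_conc = np.zeros(shape, dtype=float)
    mean_asym = np.zeros(shape, dtype=float)
    mean_conc[covered] = conc_sum[covered] / coverage[covered]
    mean_asym[covered] = asym_sum[covered] / coverage[covered]
    return VoxelConcordanceMap(
        grid=grid,
        mean_concordance=mean_conc,
        mean_asymmetry=mean_asym,
        coverage=coverage,
    )


# ---------------------------------------------------------------------------
# Point characterization
# ---------------------------------------------------------------------------

@dataclass
class PointCharacterization:
    """Multi-atlas label lookup at one world coordinate.

    One row per atlas (label + area name, or uncovered), with the voxel's
    mean concordance/asymmetry from the voxel-wise map.
    """

    xyz_mm: tuple[float, float, float]
    voxel: tuple[int, int, int]
    entries: pd.DataFrame  # columns: atlas, label, area_name, covered
    mean_concordance: float
    mean_asymmetry: float
    coverage: int

    def to_table(self) -> pd.DataFrame:
        t = self.entries.copy()
        t["x_mm"], t["y_mm"], t["z_mm"] = self.xyz_mm
        t["mean_concordance"] = self.mean_concordance
        t["mean_asymmetry"] = self.mean_asymmetry
        return t


def characterize_point(
    parcs: list[Parcellation],
    xyz_mm: tuple[float, float, float],
    vmap: VoxelConcordanceMap | None = None,
) -> PointCharacterization:
    """Report each atlas's area at a world coordinate plus local concordance.

    Atlases whose label at the voxel is background are reported uncovered.
    Raises OutOfBoundsError if the coordinate falls outside the grid.
    """
    grid = verify_common_grid(parcs)
    voxel = world_to_voxel(grid, xyz_mm)
    rows = []
    for p in parcs:
        lab = int(p.labels[voxel])
        rows.append(
            {
                "atlas": p.name,
                "label": lab if lab > 0 else 0,
                "area_name": p.area_names.get(lab, "") if lab > 0 else "(uncovered)",
                "covered": lab > 0,
            }
        )
    if vmap is None:
        vmap = voxelwise_maps(parcs)
    return PointCharacterization(
        xyz_mm=tuple(float(v) for v in xyz_mm),
        voxel=voxel,
        entries=pd.DataFrame(rows, columns=["atlas", "label", "area_name", "covered"]),
        mean_concordance=float(vmap.mean_concordance[voxel]),
        mean_asymmetry=float(vmap.mean_asymmetry[voxel]),
        coverage=int(vmap.coverage[voxel]),
    )
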