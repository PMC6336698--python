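"""Directional Wallace indices and conditional-probability overlap.

The spatial agreement of two parcellations A and B of one volume is
quantified at three granularities:

* **area level** — for every pair of areas (a, b), the conditional
  probability ``P(a|b) = |a ∩ b| / |b|`` that a voxel lies in area a of A
  given it lies in area b of B (and symmetrically), assembled into a
  block-structured matrix over all atlases;
* **cluster level** — for a group of related areas in each atlas, the
  directional Wallace index ``W_A→B``: the probability that two voxels
  co-located in one area of group A are also co-located in one area of
  group B.  The pair is summarized by ``W_max = max(W_A→B, W_B→A)`` and
  ``W_asym = |W_A→B − W_B→A|``: large W_max with small W_asym signals
  one-to-one concordance, large W_max with large W_asym a subset
  (subdivision) configuration, and small W_max a lack of concordance;
* **global level** — the same Wallace pair with each group taken as all
  areas of an atlas, giving symmetric W_max / W_asym matrices over atlases.

Raw (unadjusted) directional Wallace values are computed; chance
calibration is delegated to the empirical null model
(:mod:`parconc.nullmodels`).  A Pinto-style analytic chance adjustment is
available as an optional variant.

Denominator convention: the conditioning group's pair counts use the FULL
area sizes, including voxels the other atlas leaves unlabeled; a voxel
pair not jointly covered by a single area of the other group counts as
"not together".  Unordered pairs (n(n−1)/2) throughout.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .volumes import (
    ClusterMap,
    ParameterError,
    Parcellation,
    UndefinedIndexError,
    verify_common_grid,
)


@dataclass
class ContingencyTable:
    """Joint voxel counts between the areas of two parcellations.

    ``counts[k, l]`` is the number of voxels lying in area ``labels_a[k]``
    of atlas A and area ``labels_b[l]`` of atlas B.  ``size_a`` / ``size_b``
    are the FULL area sizes (restricted to the retained subsets but counting
    voxels the other atlas leaves unlabeled); the per-side uncovered counts
    are ``size_a - counts.sum(1)`` and ``size_b - counts.sum(0)``.
    """

    atlas_a: str
    atlas_b: str
    labels_a: list[int]
    labels_b: list[int]
    counts: np.ndarray  # (len(labels_a), len(labels_b)) int64
    size_a: np.ndarray  # full voxel count per retained area of A
    size_b: np.ndarray

    @property
    def domain_size(self) -> int:
        """Total voxels labeled by a retained area in both atlases."""
        return int(self.counts.sum())

    @property
    def marginal_a(self) -> np.ndarray:
        """Row sums: per-area-of-A voxels inside the joint domain."""
        return self.counts.sum(axis=1)

    @property
    def marginal_b(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def uncovered_a(self) -> np.ndarray:
        return self.size_a - self.marginal_a

    @property
    def uncovered_b(self) -> np.ndarray:
        return self.size_b - self.marginal_b

    def transposed(self) -> "ContingencyTable":
        return ContingencyTable(
            atlas_a=self.atlas_b,
            atlas_b=self.atlas_a,
            labels_a=list(self.labels_b),
            labels_b=list(self.labels_a),
            counts=self.counts.T.copy(),
            size_a=self.size_b.copy(),
            size_b=self.size_a.copy(),
        )


@dataclass
class ConditionalProbabilityMatrix:
    """``P[k, l] = P(a_k | b_l)``: rows condition on columns.

    Columns sum to <= 1, with equality exactly when every voxel of the
    column area is labeled by the row atlas.
    """

    P: np.ndarray
    row_atlas: str
    col_atlas: str
    row_labels: list[int]
    col_labels: list[int]
    #: slices of rows/columns per atlas when the matrix is block-structured
    row_blocks: dict[str, slice] = field(default_factory=dict)
    col_blocks: dict[str, slice] = field(default_factory=dict)


@dataclass(frozen=True)
class DirectionalWallace:
    """The two directional Wallace probabilities of one comparison."""

    w_ab: float  # W_A→B
    w_ba: float  # W_B→A

    def __post_init__(self) -> None:
        for v in (self.w_ab, self.w_ba):
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ParameterError(f"Wallace value {v} outside [0, 1]")


@dataclass(frozen=True)
class ConcordanceSummary:
    """W_max / W_asym reduction of a directional Wallace pair."""

    w_max: float
    w_asym: float
    level: str = "global"  # {area-pair, cluster, global}
    id_a: str = ""
    id_b: str = ""

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.w_asym <= self.w_max + 1e-12 <= 1 + 2e-12):
            raise ParameterError(
                f"invalid summary: need 0 <= w_asym <= w_max <= 1, got "
                f"({self.w_max}, {self.w_asym})"
            )


# ---------------------------------------------------------------------------
# Contingency and conditional probability
# ---------------------------------------------------------------------------

def contingency(
    parcA: Parcellation,
    parcB: Parcellation,
    area_subset_a: Iterable[int] | None = None,
    area_subset_b: Iterable[int] | None = None,
) -> ContingencyTable:
    """Tally joint voxel counts between (subsets of) two parcellations.

    Counts cover voxels labeled by a retained area in BOTH atlases; the
    full per-area sizes are kept alongside so directional Wallace
    denominators can include voxels covered on one side only.  An empty
    joint domain yields a zero table with a degeneracy warning.
    """
    verify_common_grid([parcA, parcB])
    labels_a = sorted(area_subset_a) if area_subset_a is not None else sorted(parcA.area_names)
    labels_b = sorted(area_subset_b) if area_subset_b is not None else sorted(parcB.area_names)
    for lab in labels_a:
        if lab not in parcA.area_names:
            raise ParameterError(f"label {lab} not in atlas {parcA.name!r}")
    for lab in labels_b:
        if lab not in parcB.area_names:
            raise ParameterError(f"label {lab} not in atlas {parcB.name!r}")

    a = parcA.labels.ravel()
    b = parcB.labels.ravel()
    max_a = max(labels_a, default=0)
    max_b = max(labels_b, default=0)
    keep_a = np.zeros(max(int(a.max(initial=0)), max_a) + 1, dtype=np.int64)
    keep_b = np.zeros(max(int(b.max(initial=0)), max_b) + 1, dtype=np.int64)
    for i, lab in enumerate(labels_a, start=1):
        keep_a[lab] = i  # 1-based compressed index, 0 = dropped
    for i, lab in enumerate(labels_b, start=1):
        keep_b[lab] = i
    ca = keep_a[a]
    cb = keep_b[b]
    size_a = np.bincount(ca, minlength=len(labels_a) + 1)[1:].astype(np.int64)
    size_b = np.bincount(cb, minlength=len(labels_b) + 1)[1:].astype(np.int64)
    joint = (ca > 0) & (cb > 0)
    ja, jb = ca[joint] - 1, cb[joint] - 1
    counts = np.zeros((len(labels_a), len(labels_b)), dtype=np.int64)
    np.add.at(counts, (ja, jb), 1)
    if counts.sum() == 0:
        warnings.warn(
            f"empty joint domain between {parcA.name!r} and {parcB.name!r}: zero table",
            stacklevel=2,
        )
    return ContingencyTable(
        atlas_a=parcA.name,
        atlas_b=parcB.name,
        labels_a=list(labels_a),
        labels_b=list(labels_b),
        counts=counts,
        size_a=size_a,
        size_b=size_b,
    )


def conditional_probability(table: ContingencyTable) -> ConditionalProbabilityMatrix:
    """``P(a_k | b_l) = n_kl / |b_l|`` with |b_l| the full size of b_l.

    The opposite orientation is obtained from ``table.transposed()``.
    """
    denom = table.size_b.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(denom[None, :] > 0, table.counts / denom[None, :], 0.0)
    return ConditionalProbabilityMatrix(
        P=P,
        row_atlas=table.atlas_a,
        col_atlas=table.atlas_b,
        row_labels=list(table.labels_a),
        col_labels=list(table.labels_b),
    )


# ---------------------------------------------------------------------------
# Wallace indices
# ---------------------------------------------------------------------------

def _pairs(x: np.ndarray) -> np.ndarray:
    """Unordered co-membership pair counts n(n-1)/2, elementwise."""
    x = x.astype(np.float64)
    return x * (x - 1.0) / 2.0


def wallace_from_table(table: ContingencyTable, adjusted: bool = False) -> DirectionalWallace:
    """Directional Wallace pair from a contingency table.

    ``W_A→B = Σ_kl n_kl(n_kl−1) / Σ_k m_k(m_k−1)`` with ``m_k`` the full
    size of area k of A; voxel pairs not jointly inside one area of B
    (including pairs with an uncovered member) count as "not together in
    B".  With ``adjusted=True`` each direction is rescaled against the
    analytic expectation under independent permutation of the other side's
    labels over the joint domain (an adjusted-Wallace variant); the default
    is the raw probability, with chance handled by the empirical null.
    """
    together_both = _pairs(table.counts).sum()
    denom_a = _pairs(table.size_a).sum()
    denom_b = _pairs(table.size_b).sum()
    if denom_a <= 0 or denom_b <= 0:
        side = table.atlas_a if denom_a <= 0 else table.atlas_b
        raise UndefinedIndexError(
            f"all areas of the conditioning group in {side!r} are singletons; "
            "directional Wallace undefined (zero pair-count denominator)"
        )
    w_ab = together_both / denom_a
    w_ba = together_both / denom_b
    if adjusted:
        n = float(table.domain_size)
        if n >= 2:
            tot = n * (n - 1.0) / 2.0
            # expected co-pair count under random alignment of the two
            # marginal partitions over the joint domain
            pa = _pairs(table.marginal_a).sum() / tot
            pb = _pairs(table.marginal_b).sum() / tot
            e_ab = pb * _pairs(table.marginal_a).sum() / denom_a
            e_ba = pa * _pairs(table.marginal_b).sum() / denom_b
            w_ab = (w_ab - e_ab) / (1.0 - e_ab) if e_ab < 1 else 0.0
            w_ba = (w_ba - e_ba) / (1.0 - e_ba) if e_ba < 1 else 0.0
            w_ab = min(max(w_ab, 0.0), 1.0)
            w_ba = min(max(w_ba, 0.0), 1.0)
    return DirectionalWallace(w_ab=float(w_ab), w_ba=float(w_ba))


def wallace_directional(
    parcA: Parcellation,
    parcB: Parcellation,
    groupA: Iterable[int] | None = None,
    groupB: Iterable[int] | None = None,
    adjusted: bool = False,
) -> DirectionalWallace:
    """Directional Wallace pair between area groups of two parcellations."""
    table = contingency(parcA, parcB, groupA, groupB)
    if not table.labels_a or not table.labels_b:
        raise ParameterError("both groups must be nonempty")
    return wallace_from_table(table, adjusted=adjusted)


def wallace_brute_force(
    parcA: Parcellation,
    parcB: Parcellation,
    groupA: Iterable[int] | None = None,
    groupB: Iterable[int] | None = None,
) -> DirectionalWallace:
    """Direct enumeration over all unordered voxel pairs (oracle; O(V^2)).

    Kept deliberately independent of the contingency identity so the two
    routes cross-check each other on small volumes.
    """
    ga = set(groupA) if groupA is not None else set(parcA.area_names)
    gb = set(groupB) if groupB is not None else set(parcB.area_names)
    a = parcA.labels.ravel()
    b = parcB.labels.ravel()
    in_a = np.isin(a, sorted(ga)) & (a > 0)
    in_b = np.isin(b, sorted(gb)) & (b > 0)
    idx = np.flatnonzero(in_a | in_b)
    av, bv = a[idx], b[idx]
    ca, cb = in_a[idx], in_b[idx]
    iu, ju = np.triu_indices(len(idx), k=1)  # every unordered voxel pair once
    ta = ca[iu] & ca[ju] & (av[iu] == av[ju])
    tb = cb[iu] & cb[ju] & (bv[iu] == bv[ju])
    together_a = int(ta.sum())
    together_b = int(tb.sum())
    both = int((ta & tb).sum())
    if together_a == 0 or together_b == 0:
        raise UndefinedIndexError("zero pair-count denominator in brute-force Wallace")
    return DirectionalWallace(w_ab=both / together_a, w_ba=both / together_b)


def summarize(
    dw: DirectionalWallace,
    level: str = "global",
    id_a: str = "",
    id_b: str = "",
) -> ConcordanceSummary:
    """Reduce a directional pair to W_max = max and W_asym = |difference|."""
    return ConcordanceSummary(
        w_max=max(dw.w_ab, dw.w_ba),
        w_asym=abs(dw.w_ab - dw.w_ba),
        level=level,
        id_a=id_a,
        id_b=id_b,
    )


# ---------------------------------------------------------------------------
# Area level: the block-structured P matrix
# ---------------------------------------------------------------------------

def area_level_matrix(parcs: Sequence[Parcellation]) -> ConditionalProbabilityMatrix:
    """Full non-symmetric P matrix over all areas of all atlases.

    Rows and columns are the areas of every atlas grouped in per-atlas
    blocks; entry (i, j) is P(area_i | area_j).  Same-atlas diagonal blocks
    have identity pattern since areas within one atlas are disjoint.
    """
    if len(parcs) < 2:
        raise ParameterError("area-level matrix needs at least 2 atlases")
    verify_common_grid(parcs)
    offsets: dict[str, slice] = {}
    all_labels: list[int] = []
    start = 0
    for p in parcs:
        labs = sorted(p.area_names)
        offsets[p.name] = slice(start, start + len(labs))
        all_labels.extend(labs)
        start += len(labs)
    total = start
    P = np.zeros((total, total), dtype=float)
    for pa in parcs:
        for pb in parcs:
            table = contingency(pa, pb)
            cpm = conditional_probability(table)
            P[offsets[pa.name], offsets[pb.name]] = cpm.P
    return ConditionalProbabilityMatrix(
        P=P,
        row_atlas="|".join(p.name for p in parcs),
        col_atlas="|".join(p.name for p in parcs),
        row_labels=all_labels,
        col_labels=all_labels,
        row_blocks=offsets,
        col_blocks=dict(offsets),
    )


# ---------------------------------------------------------------------------
# Cluster level
# ---------------------------------------------------------------------------

def cluster_level(
    parcs: Sequence[Parcellation],
    clusters: ClusterMap,
    adjusted: bool = False,
) -> pd.DataFrame:
    """Per-cluster concordance across all atlas pairs.

    For each cluster, the Wallace pair is computed between the cluster's
    member-area groups in every unordered pair of atlases having members,
    and summarized by W_max / W_asym; the per-cluster aggregate is the
    arithmetic mean over pairs (per-pair rows are all emitted so any other
    reduction is recomputable).  Clusters with members in fewer than two
    atlases are skipped with a warning; so are pairs whose conditioning
    groups are all singletons.
    """
    clusters.validate_against(parcs)
    by_name = {p.name: p for p in parcs}
    rows: list[dict] = []
    for cid in clusters.cluster_ids():
        members = clusters.members(cid)
        atlases = [n for n in by_name if n in members]
        cname = clusters.cluster_names.get(cid, str(cid))
        if len(atlases) < 2:
            warnings.warn(
                f"cluster {cname!r} has member areas in fewer than 2 atlases; skipped",
                stacklevel=2,
            )
            continue
        pair_wmax: list[float] = []
        pair_wasym: list[float] = []
        for na, nb in itertools.combinations(atlases, 2):
            try:
                dw = wallace_directional(
                    by_name[na], by_name[nb], members[na], members[nb], adjusted=adjusted
                )
            except UndefinedIndexError as err:
                warnings.warn(f"cluster {cname!r}, pair ({na}, {nb}): {err}", stacklevel=2)
                continue
            s = summarize(dw, level="cluster", id_a=na, id_b=nb)
            rows.append(
                {
                    "cluster": cid,
                    "cluster_name": cname,
                    "atlas_a": na,
                    "atlas_b": nb,
                    "w_ab": dw.w_ab,
                    "w_ba": dw.w_ba,
                    "w_max": s.w_max,
                    "w_asym": s.w_asym,
                    "is_aggregate": False,
                }
            )
            pair_wmax.append(s.w_max)
            pair_wasym.append(s.w_asym)
        if pair_wmax:
            rows.append(
                {
                    "cluster": cid,
                    "cluster_name": cname,
                    "atlas_a": "*",
                    "atlas_b": "*",
                    "w_ab": np.nan,
                    "w_ba": np.nan,
                    "w_max": float(np.mean(pair_wmax)),
                    "w_asym": float(np.mean(pair_wasym)),
                    "is_aggregate": True,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster", "cluster_name", "atlas_a", "atlas_b",
            "w_ab", "w_ba", "w_max", "w_asym", "is_aggregate",
        ],
    )


# ---------------------------------------------------------------------------
# Global level
# ---------------------------------------------------------------------------

def global_level(
    parcs: Sequence[Parcellation],
    adjusted: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric W_max and W_asym matrices over atlas pairs.

    Groups are all areas of each atlas.  Diagonals: W_max = 1, W_asym = 0.
    """
    if len(parcs) < 2:
        raise ParameterError("global level needs at least 2 atlases")
    verify_common_grid(parcs)
    names = [p.name for p in parcs]
    wmax = pd.DataFrame(np.eye(len(parcs)), index=names, columns=names)
    wasym = pd.DataFrame(np.zeros((len(parcs), len(parcs))), index=names, columns=names)
    for (i, pa), (j, pb) in itertools.combinations(enumerate(parcs), 2):
        dw = wallace_directional(pa, pb, adjusted=adjusted)
        s = summarize(dw, level="global", id_a=pa.name, id_b=pb.name)
        wmax.iloc[i, j] = wmax.iloc[j, i] = s.w_max
        wasym.iloc[i, j] = wasym.iloc[j, i] = s.w_asym
    return wmax, wasym
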