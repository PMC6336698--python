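"""Empirical chance distributions for Wallace concordance indices.

A measured W_max tells us little without knowing what two *unrelated*
parcellations of the same volume would score: coarse partitions overlap
heavily by geometry alone.  Calibration therefore draws size-matched
random parcellations — grown by the same random label filling used for
synthetic bases — and computes the global Wallace pair for many random
pairs, one parcellation per side.  The empirical 95th percentile of the
resulting W_max (and W_asym) samples is the cutoff below which an observed
value cannot be distinguished from chance.

Reference scale is 50 parcellations per atlas and 1,000 pairs per atlas
comparison; the desk-scale default used in the test fixtures is 10 per
side and 100 pairs on small masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .concordance import ConcordanceSummary, summarize, wallace_directional
from .synthdata import _MaskTopology, _random_fill, _default_grid
from .volumes import (
    CalibrationError,
    ParameterError,
    Parcellation,
    UndefinedIndexError,
    VoxelGrid,
)


@dataclass(frozen=True)
class NullConfig:
    """Monte-Carlo budget of one null distribution.

    ``n_parcellations_per_atlas`` random parcellations are grown per side
    and ``n_pairs`` pairs sampled uniformly without replacement from the
    cross product (or with replacement if ``with_replacement`` is set,
    required when n_pairs exceeds the cross-product size).
    """

    n_parcellations_per_atlas: int = 50
    n_pairs: int = 1000
    percentile: float = 95.0
    seed: int = 0
    with_replacement: bool = False

    def __post_init__(self) -> None:
        if self.n_parcellations_per_atlas < 1 or self.n_pairs < 1:
            raise ParameterError("null config counts must be >= 1")
        if not (0.0 < self.percentile < 100.0):
            raise ParameterError("percentile must be in (0, 100)")
        if (
            not self.with_replacement
            and self.n_pairs > self.n_parcellations_per_atlas**2
        ):
            raise ParameterError(
                f"n_pairs={self.n_pairs} exceeds the {self.n_parcellations_per_atlas}^2 "
                "cross product; set with_replacement=True"
            )


#: desk-scale configuration used by the fixture pipeline
DESK_NULL_CONFIG = NullConfig(n_parcellations_per_atlas=10, n_pairs=100)


@dataclass
class NullDistribution:
    """Monte-Carlo samples of W_max / W_asym for one size-matched comparison."""

    samples_w_max: np.ndarray
    samples_w_asym: np.ndarray
    config: NullConfig
    n_areas_a: int
    n_areas_b: int
    pair_id: str = ""
    n_redraws: int = 0

    def __post_init__(self) -> None:
        self.samples_w_max = np.asarray(self.samples_w_max, dtype=float)
        self.samples_w_asym = np.asarray(self.samples_w_asym, dtype=float)


def random_parcellation(
    mask: np.ndarray,
    n_areas: int,
    seed: int,
    name: str = "random",
    grid: VoxelGrid | None = None,
) -> Parcellation:
    """Size-matched random parcellation: N connected regions by random filling.

    Shares the growth implementation with the synthetic base generator, so
    null parcellations and synthetic bases come from one distribution.
    """
    topo = _MaskTopology(mask)
    labels = _random_fill(topo, n_areas, seed)
    names = {l: f"R{l}" for l in range(1, n_areas + 1)}
    return Parcellation(
        name=name, grid=grid or _default_grid(topo.shape), labels=topo.labels_to_volume(labels),
        area_names=names,
    )


def _fill_pool(topo: _MaskTopology, n_areas: int, count: int, rng: np.random.Generator) -> list[np.ndarray]:
    pool = []
    for _ in range(count):
        s = int(rng.integers(0, 2**31))
        pool.append(_random_fill(topo, n_areas, s))
    return pool


def _global_wallace_local(
    labels_a: np.ndarray, labels_b: np.ndarray, n_a: int, n_b: int
) -> tuple[float, float]:
    """Global Wallace pair for two label vectors over one mask (no gaps)."""
    joint = labels_a.astype(np.int64) * (n_b + 1) + labels_b
    n_kl = np.bincount(joint, minlength=(n_a + 1) * (n_b + 1)).astype(np.float64)
    m_a = np.bincount(labels_a, minlength=n_a + 1).astype(np.float64)
    m_b = np.bincount(labels_b, minlength=n_b + 1).astype(np.float64)
    num = (n_kl * (n_kl - 1.0)).sum()
    den_a = (m_a * (m_a - 1.0)).sum()
    den_b = (m_b * (m_b - 1.0)).sum()
    if den_a <= 0 or den_b <= 0:
        raise UndefinedIndexError("all areas are singletons in a random draw")
    return num / den_a, num / den_b


def null_distribution(
    mask: np.ndarray,
    n_areas_a: int,
    n_areas_b: int,
    config: NullConfig,
    pair_id: str = "",
) -> NullDistribution:
    """Monte-Carlo W_max / W_asym distribution for one atlas-pair comparison.

    Two independent pools of random parcellations are grown (one per side,
    so a pair can never reuse one parcellation on both sides), pairs are
    sampled from the cross product, and the global Wallace pair is computed
    per pair.  Degenerate draws (all-singleton sides) are redrawn with a
    logged count and abort after 10x the pair budget.  Deterministic given
    ``config.seed``.
    """
    if n_areas_a < 2 or n_areas_b < 2:
        raise ParameterError("null model requires at least 2 areas per side")
    topo = _MaskTopology(mask)
    rng = np.random.default_rng(int(config.seed))
    n_pool = config.n_parcellations_per_atlas
    pool_a = _fill_pool(topo, n_areas_a, n_pool, rng)
    pool_b = _fill_pool(topo, n_areas_b, n_pool, rng)
    n_cross = n_pool * n_pool
    if config.with_replacement:
        pair_idx = rng.integers(0, n_cross, size=config.n_pairs)
    else:
        pair_idx = rng.choice(n_cross, size=config.n_pairs, replace=False)
    w_max = np.empty(config.n_pairs)
    w_asym = np.empty(config.n_pairs)
    n_redraws = 0
    budget = 10 * config.n_pairs
    for out_i, flat in enumerate(pair_idx):
        ia, ib = divmod(int(flat), n_pool)
        while True:
            try:
                w_ab, w_ba = _global_wallace_local(pool_a[ia], pool_b[ib], n_areas_a, n_areas_b)
                break
            except UndefinedIndexError:
                n_redraws += 1
                if n_redraws > budget:
                    raise DegeneracyAbort(
                        f"exceeded redraw budget ({budget}) for degenerate random draws"
                    )
                # regrow the degenerate side(s) in place
                pool_a[ia] = _random_fill(topo, n_areas_a, int(rng.integers(0, 2**31)))
                pool_b[ib] = _random_fill(topo, n_areas_b, int(rng.integers(0, 2**31)))
        w_max[out_i] = max(w_ab, w_ba)
        w_asym[out_i] = abs(w_ab - w_ba)
    if n_redraws:
        warnings.warn(f"null model redrew {n_redraws} degenerate parcellations", stacklevel=2)
    return NullDistribution(
        samples_w_max=w_max,
        samples_w_asym=w_asym,
        config=config,
        n_areas_a=n_areas_a,
        n_areas_b=n_areas_b,
        pair_id=pair_id,
        n_redraws=n_redraws,
    )


class DegeneracyAbort(ParameterError):
    """Redraw budget exhausted while avoiding degenerate random draws."""


def calibration_false_positive_rate(
    mask: np.ndarray,
    n_areas: int,
    n_reps: int,
    config: NullConfig,
    seed: int,
) -> float:
    """Fraction of fresh random pairs whose W_max exceeds the null cutoff.

    Each repetition independently redraws the entire procedure: a null
    distribution at ``config``'s budget (with a fresh seed), its percentile
    cutoff, and one fresh random parcellation pair scored against it.  With
    a well-calibrated null the rate approaches ``(100 - percentile)%``;
    small per-side pools leave the cutoff itself noisy, so the rate of any
    single null realization scatters widely and only the average over fully
    independent repetitions is interpretable.
    """
    topo = _MaskTopology(mask)
    rng = np.random.default_rng(int(seed))
    hits = 0
    for _ in range(n_reps):
        cfg = NullConfig(
            n_parcellations_per_atlas=config.n_parcellations_per_atlas,
            n_pairs=config.n_pairs,
            percentile=config.percentile,
            seed=int(rng.integers(0, 2**31)),
            with_replacement=config.with_replacement,
        )
        cutoff, _ = percentile_cutoff(null_distribution(mask, n_areas, n_areas, cfg))
        la = _random_fill(topo, n_areas, int(rng.integers(0, 2**31)))
        lb = _random_fill(topo, n_areas, int(rng.integers(0, 2**31)))
        w_ab, w_ba = _global_wallace_local(la, lb, n_areas, n_areas)
        hits += max(w_ab, w_ba) > cutoff
    return hits / n_reps


def percentile_cutoff(dist: NullDistribution, q: float | None = None) -> tuple[float, float]:
    """Empirical percentile cutoffs (W_max, W_asym), linear interpolation.

    Percentiles interpolate linearly between closest order statistics
    (numpy's ``linear`` method), stated explicitly because percentile
    conventions differ.
    """
    if q is None:
        q = dist.config.percentile
    if len(dist.samples_w_max) == 0:
        raise ParameterError("empty null distribution")
    cut_max = float(np.percentile(dist.samples_w_max, q, method="linear"))
    cut_asym = float(np.percentile(dist.samples_w_asym, q, method="linear"))
    return cut_max, cut_asym


def flag_significant(
    summary: ConcordanceSummary,
    dist: NullDistribution,
    q: float | None = None,
    expected_n: tuple[int, int] | None = None,
) -> dict[str, bool | float]:
    """Flag W_max / W_asym as significant (above cutoff) or chance-level.

    A value exactly at the cutoff is chance-level (<= convention).  The
    two flags are independent.  ``expected_n`` (region counts of the
    observed pair) guards against comparing a summary to a null built for
    different atlas sizes.
    """
    if expected_n is not None:
        got = (dist.n_areas_a, dist.n_areas_b)
        if set(got) != set(expected_n):
            raise CalibrationError(
                f"null distribution matched to region counts {got}, observed pair has {expected_n}"
            )
    cut_max, cut_asym = percentile_cutoff(dist, q)
    return {
        "w_max_significant": bool(summary.w_max > cut_max),
        "w_asym_significant": bool(summary.w_asym > cut_asym),
        "w_max_cutoff": cut_max,
        "w_asym_cutoff": cut_asym,
    }
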