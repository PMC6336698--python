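import numpy as np
import pytest

from parconc import (
    DirectionalWallace,
    ParameterError,
    Parcellation,
    SyntheticFamilySpec,
    UndefinedIndexError,
    VoxelGrid,
    area_level_matrix,
    cluster_level,
    conditional_probability,
    contingency,
    generate_base_parcellation,
    global_level,
    make_family,
    make_mask,
    perturb_boundaries,
    summarize,
    wallace_brute_force,
    wallace_directional,
)
from parconc.volumes import ClusterMap

from conftest import line_parcellation


def random_parc_pair(rng, max_areas=8):
    """Two unconstrained random labelings (with background) of one small grid."""
    shape = tuple(rng.integers(3, 8, size=3))  # <= 7^3 = 343 <= 500 voxels
    grid = VoxelGrid(shape=shape, affine=np.eye(4))

    def one(name):
        n = int(rng.integers(2, max_areas + 1))
        labels = rng.integers(0, n + 1, size=shape).astype(np.int32)
        names = {int(l): f"{name}{l}" for l in np.unique(labels) if l > 0}
        return Parcellation(name=name, grid=grid, labels=labels, area_names=names)

    return one("A"), one("B")


class TestContingency:
    def test_identity_is_diagonal(self, line_pair):
        A, _ = line_pair
        t = contingency(A, A)
        assert np.array_equal(t.counts, np.diag([3, 3]))
        assert t.domain_size == 6

    def test_line_fixture_counts_by_direct_tally(self, line_pair):
        t = contingency(*line_pair)
        assert np.array_equal(t.counts, [[2, 1, 0], [0, 1, 2]])
        assert np.array_equal(t.marginal_a, [3, 3])
        assert np.array_equal(t.size_b, [2, 2, 2])

    def test_disjoint_coverage_warns_with_zero_table(self):
        A = line_parcellation("A", [1, 1, 1, 0, 0, 0], "a")
        B = line_parcellation("B", [0, 0, 0, 2, 2, 2], "b")
        with pytest.warns(UserWarning, match="empty joint domain"):
            t = contingency(A, B)
        assert t.counts.sum() == 0

    def test_partial_coverage_tracked_as_uncovered(self):
        A = line_parcellation("A", [1, 1, 1, 1, 0, 0], "a")
        B = line_parcellation("B", [0, 1, 1, 1, 1, 1], "b")
        t = contingency(A, B)
        assert t.uncovered_a.tolist() == [1] and t.uncovered_b.tolist() == [2]
        assert t.size_a.tolist() == [4] and t.size_b.tolist() == [5]

    def test_subset_restriction(self, line_pair):
        A, B = line_pair
        t = contingency(A, B, area_subset_a=[1], area_subset_b=[1, 2])
        assert t.counts.shape == (1, 2)
        assert np.array_equal(t.counts, [[2, 1]])


class TestConditionalProbability:
    def test_identity_diagonal_one(self, line_pair):
        A, _ = line_pair
        P = conditional_probability(contingency(A, A)).P
        assert np.allclose(P, np.eye(2))

    def test_denominator_is_full_area_size(self):
        # A area of 10 overlapping 5 voxels of a B area of 20 -> P(a|b) = 0.25
        A = line_parcellation("A", [1] * 10 + [0] * 15, "a")
        B = line_parcellation("B", [0] * 5 + [1] * 20, "b")
        # overlap voxels 5..9 -> 5 voxels; |b| = 20
        P = conditional_probability(contingency(A, B)).P
        assert P[0, 0] == pytest.approx(0.25)

    def test_line_fixture_ratio(self, line_pair):
        P = conditional_probability(contingency(*line_pair)).P
        assert P[0, 1] == pytest.approx(0.5)  # P(a=1 | b=2)

    def test_columns_sum_to_at_most_one(self, demo_family):
        parcs, _, _ = demo_family
        P = conditional_probability(contingency(parcs[0], parcs[1])).P
        colsums = P.sum(axis=0)
        assert np.all(colsums <= 1 + 1e-12)


class TestWallace:
    def test_line_fixture_both_routes(self, line_pair):
        dw = wallace_directional(*line_pair)
        bf = wallace_brute_force(*line_pair)
        assert dw.w_ab == pytest.approx(1 / 3, abs=1e-15)
        assert dw.w_ba == pytest.approx(2 / 3, abs=1e-15)
        assert bf.w_ab == pytest.approx(dw.w_ab, abs=1e-12)
        assert bf.w_ba == pytest.approx(dw.w_ba, abs=1e-12)

    def test_identity_is_one(self, line_pair):
        A, _ = line_pair
        dw = wallace_directional(A, A)
        assert dw.w_ab == 1.0 and dw.w_ba == 1.0

    def test_oracle_equivalence_on_random_volumes(self):
        """Contingency-identity Wallace == brute-force pair enumeration."""
        rng = np.random.default_rng(20260923)
        checked = 0
        while checked < 50:
            A, B = random_parc_pair(rng)
            try:
                dw = wallace_directional(A, B)
                bf = wallace_brute_force(A, B)
            except UndefinedIndexError:
                continue
            assert dw.w_ab == pytest.approx(bf.w_ab, abs=1e-12)
            assert dw.w_ba == pytest.approx(bf.w_ba, abs=1e-12)
            checked += 1

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(5)
        A, B = random_parc_pair(rng)
        dw = wallace_directional(A, B)
        # relabel B's areas by a random bijection
        labs = sorted(B.area_names)
        new = dict(zip(labs, rng.permutation(np.arange(1, len(labs) + 1)) * 10))
        relabeled = np.zeros_like(B.labels)
        for old, nw in new.items():
            relabeled[B.labels == old] = nw
        B2 = Parcellation("B2", B.grid, relabeled, {int(new[l]): B.area_names[l] for l in labs})
        dw2 = wallace_directional(A, B2)
        assert dw2.w_ab == pytest.approx(dw.w_ab, abs=1e-14)
        assert dw2.w_ba == pytest.approx(dw.w_ba, abs=1e-14)

    def test_uncovered_voxels_break_togetherness(self):
        # B covers only 2 of A's 4 voxels: the uncovered pairs count
        # against the denominator of W_A->B but not the numerator
        A = line_parcellation("A", [1, 1, 1, 1], "a")
        B = line_parcellation("B", [1, 1, 0, 0], "b")
        dw = wallace_directional(A, B)
        assert dw.w_ab == pytest.approx(1 / 6)  # 1 joint pair / C(4,2)
        assert dw.w_ba == pytest.approx(1.0)

    def test_singleton_conditioning_group_raises(self):
        A = line_parcellation("A", [1, 2, 3], "a")
        B = line_parcellation("B", [1, 1, 1], "b")
        with pytest.raises(UndefinedIndexError):
            wallace_directional(A, B)

    def test_nesting_forces_direction_one(self, clean_family):
        parcs, _, truth = clean_family
        base = parcs[0]
        for p in parcs[1:]:
            if truth.family[p.name] == "split":
                dw = wallace_directional(p, base)
                assert dw.w_ab == 1.0  # child -> parent
            elif truth.family[p.name] == "merge":
                dw = wallace_directional(base, p)
                assert dw.w_ab == 1.0  # fine -> coarse


class TestSummarize:
    def test_worked_example(self):
        s = summarize(DirectionalWallace(0.832, 0.546))
        assert s.w_max == pytest.approx(0.832, abs=1e-12)
        assert s.w_asym == pytest.approx(0.286, abs=1e-12)

    def test_symmetric_pair_has_zero_asymmetry(self):
        for x in (0.0, 0.4, 1.0):
            s = summarize(DirectionalWallace(x, x))
            assert s.w_asym == 0.0 and s.w_max == x

    def test_line_fixture_summary(self, line_pair):
        s = summarize(wallace_directional(*line_pair))
        assert s.w_max == pytest.approx(2 / 3) and s.w_asym == pytest.approx(1 / 3)


class TestAreaLevelMatrix:
    def test_identical_atlases_identity_blocks(self, line_pair):
        A, _ = line_pair
        A2 = Parcellation("A2", A.grid, A.labels.copy(), dict(A.area_names))
        P = area_level_matrix([A, A2])
        off = P.P[P.row_blocks["A"], P.col_blocks["A2"]]
        assert np.allclose(off, np.eye(2))

    def test_base_vs_split_columns_sum_to_one(self, clean_family):
        parcs, _, truth = clean_family
        base = parcs[0]
        split = next(p for p in parcs if truth.family[p.name] == "split")
        P = area_level_matrix([base, split])
        block = P.P[P.row_blocks[split.name], P.col_blocks["base"]]  # P(child | parent)
        assert np.allclose(block.sum(axis=0), 1.0)

    def test_dimensions_are_total_area_count(self, demo_family):
        parcs, _, _ = demo_family
        P = area_level_matrix(parcs)
        total = sum(p.n_areas for p in parcs)
        assert P.P.shape == (total, total)


class TestClusterLevel:
    def test_single_all_area_cluster_reduces_to_global(self, demo_family):
        parcs, _, _ = demo_family
        entries = [(p.name, int(l), 1) for p in parcs for l in p.present_labels()]
        cm = ClusterMap(entries=entries, cluster_names={1: "ALL"})
        table = cluster_level(parcs, cm)
        wmax, wasym = global_level(parcs)
        for _, row in table[~table.is_aggregate].iterrows():
            assert row.w_max == pytest.approx(wmax.loc[row.atlas_a, row.atlas_b])
            assert row.w_asym == pytest.approx(wasym.loc[row.atlas_a, row.atlas_b])

    def test_noise_free_split_cluster_wmax_one(self, clean_family):
        parcs, clusters, _ = clean_family
        table = cluster_level(parcs, clusters)
        pairs = table[~table.is_aggregate & (table.atlas_a == "base")]
        nested = pairs[pairs.atlas_b.str.startswith("split")]
        assert (nested.w_max == 1.0).all()

    def test_cluster_in_single_atlas_skipped_with_warning(self, line_pair):
        A, B = line_pair
        cm = ClusterMap(entries=[("A", 1, 1)], cluster_names={1: "only"})
        with pytest.warns(UserWarning, match="fewer than 2"):
            table = cluster_level([A, B], cm)
        assert table.empty


class TestGlobalLevel:
    def test_identical_atlases(self, line_pair):
        A, _ = line_pair
        A2 = Parcellation("A2", A.grid, A.labels.copy(), dict(A.area_names))
        wmax, wasym = global_level([A, A2])
        assert wmax.loc["A", "A2"] == pytest.approx(1.0)
        assert wasym.loc["A", "A2"] == pytest.approx(0.0)

    def test_line_fixture_pair(self, line_pair):
        wmax, wasym = global_level(list(line_pair))
        assert wmax.loc["A", "B"] == pytest.approx(2 / 3)
        assert wasym.loc["A", "B"] == pytest.approx(1 / 3)

    def test_base_vs_clean_split_subset_signature(self, clean_family):
        parcs, _, truth = clean_family
        base = parcs[0]
        split = next(p for p in parcs if truth.family[p.name] == "split")
        wmax, wasym = global_level([base, split])
        dw = wallace_directional(base, split)
        assert wmax.loc["base", split.name] == pytest.approx(1.0)
        assert wasym.loc["base", split.name] == pytest.approx(1.0 - dw.w_ab)

    def test_matrices_symmetric_with_unit_diagonal(self, demo_family):
        parcs, _, _ = demo_family
        wmax, wasym = global_level(parcs)
        assert np.allclose(wmax, wmax.T) and np.allclose(wasym, wasym.T)
        assert np.allclose(np.diag(wmax), 1.0) and np.allclose(np.diag(wasym), 0.0)
        assert ((wasym.to_numpy() <= wmax.to_numpy() + 1e-12)).all()

    def test_needs_two_atlases(self, line_pair):
        with pytest.raises(ParameterError):
            global_level([line_pair[0]])


class TestMonotoneDegradation:
    def test_wmax_nonincreasing_in_noise(self):
        """Mean W_max between a base and its perturbed copy decreases with p."""
        mask = make_mask((10, 10, 10), "box")
        ps = (0.0, 0.1, 0.3)
        means = []
        for p in ps:
            vals = []
            for seed in range(20):
                base = generate_base_parcellation(mask, 5, seed=seed)
                pert = perturb_boundaries(base, p, 2, seed=1000 + seed, name="pert")
                s = summarize(wallace_directional(base, pert))
                vals.append(s.w_max)
            means.append(np.mean(vals))
        assert means[0] == pytest.approx(1.0)
        assert means[0] >= means[1] >= means[2]
        assert means[2] < means[0]
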