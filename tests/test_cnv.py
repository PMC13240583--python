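"""CNV profile smoothing, Z-score calling, shared/unique partition and
the Ward.D2 lineage tree against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from lesionmap.cnv import (
    CnvCallSet,
    CnvProfile,
    call_cnv,
    cnv_profile,
    cnv_tree,
    partition_shared,
    rf_distance,
)
from lesionmap.io_formats import GeneTable
from lesionmap.markers import NormalizedMatrix


def gene_table(n, chrom="chr1"):
    df = pd.DataFrame(
        {
            "chromosome": chrom,
            "start": np.arange(n) * 100,
            "end": np.arange(n) * 100 + 50,
            "is_mito": False,
            "is_hb": False,
        },
        index=pd.Index([f"G{i:03d}" for i in range(n)], name="gene_id"),
    )
    return GeneTable(df)


class TestProfile:
    def test_hand_computed_moving_average(self):
        # reference cells all zero so centring is the identity; one target
        # cell carries (0,0,10,0,0); window 3 truncated at the ends
        n_ref = 3
        vals = np.zeros((5, n_ref + 1))
        vals[:, -1] = [0, 0, 10, 0, 0]
        nm = NormalizedMatrix(vals, [f"G{i:03d}" for i in range(5)],
                              [f"R{i}" for i in range(n_ref)] + ["T"])
        prof = cnv_profile(nm, gene_table(5), [f"R{i}" for i in range(n_ref)],
                           window=3, recenter_cells=False, min_reference=3)
        np.testing.assert_allclose(prof.values[:, -1], [0, 10 / 3, 10 / 3, 10 / 3, 0])

    def test_constant_matrix_gives_zero_profile(self):
        vals = np.full((8, 25), 3.7)
        nm = NormalizedMatrix(vals, [f"G{i:03d}" for i in range(8)],
                              [f"C{i}" for i in range(25)])
        prof = cnv_profile(nm, gene_table(8), [f"C{i}" for i in range(20)], window=3)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_even_window_rejected(self):
        nm = NormalizedMatrix(np.zeros((4, 25)), [f"G{i:03d}" for i in range(4)],
                              [f"C{i}" for i in range(25)])
        with pytest.raises(ValueError, match="odd"):
            cnv_profile(nm, gene_table(4), [f"C{i}" for i in range(20)], window=4)

    def test_gene_input_order_irrelevant_and_cell_permutation_equivariant(self):
        rng = np.random.default_rng(0)
        n_genes, n_cells = 30, 24
        vals = rng.normal(size=(n_genes, n_cells))
        genes = [f"G{i:03d}" for i in range(n_genes)]
        cells = [f"C{i}" for i in range(n_cells)]
        ann = gene_table(n_genes)
        ref = cells[:20]
        base = cnv_profile(NormalizedMatrix(vals, genes, cells), ann, ref, window=5)
        gperm = rng.permutation(n_genes)
        shuffled = cnv_profile(
            NormalizedMatrix(vals[gperm], [genes[i] for i in gperm], cells), ann, ref,
            window=5,
        )
        assert shuffled.gene_ids == base.gene_ids
        np.testing.assert_allclose(shuffled.values, base.values)
        cperm = rng.permutation(n_cells)
        permuted = cnv_profile(
            NormalizedMatrix(vals[:, cperm], genes, [cells[i] for i in cperm]), ann, ref,
            window=5,
        )
        np.testing.assert_allclose(permuted.values, base.values[:, cperm])

    def test_window_truncates_on_short_chromosome(self):
        vals = np.random.default_rng(1).normal(size=(4, 22))
        nm = NormalizedMatrix(vals, [f"G{i:03d}" for i in range(4)],
                              [f"C{i}" for i in range(22)])
        prof = cnv_profile(nm, gene_table(4), [f"C{i}" for i in range(20)], window=11)
        assert prof.values.shape == (4, 22)


def crafted_profile(z_rows, n_ref=20, sd=1.0, seed=0):
    """Profile whose reference cells are N(0, sd) and target cells sit at
    the requested Z offsets (per gene, per target cell)."""
    rng = np.random.default_rng(seed)
    z_rows = np.asarray(z_rows, dtype=float)
    n_genes, n_tgt = z_rows.shape
    ref = rng.normal(0.0, sd, size=(n_genes, n_ref))
    # build target values directly from the realised reference moments
    mu = ref.mean(axis=1, keepdims=True)
    s = np.maximum(ref.std(axis=1, ddof=1, keepdims=True), 0.01)
    tgt = mu + z_rows * s
    genes = [f"G{i:03d}" for i in range(n_genes)]
    cells = [f"R{i}" for i in range(n_ref)] + [f"T{i}" for i in range(n_tgt)]
    return CnvProfile(np.hstack([ref, tgt]), genes, cells,
                      [f"R{i}" for i in range(n_ref)], 1)


class TestCalling:
    def test_strict_majority_boundary(self):
        # gene 0: 6/10 cells above Z=1 -> amplified; gene 1: exactly 5/10 -> no call
        z = np.zeros((2, 10))
        z[0, :6] = 1.5
        z[1, :5] = 1.5
        prof = crafted_profile(z)
        calls = call_cnv(prof, {"t": [f"T{i}" for i in range(10)]})["t"]
        assert calls.amplified == {"G000"}
        assert calls.deleted == set()

    def test_deletion_called_symmetrically(self):
        z = np.zeros((1, 10))
        z[0, :7] = -1.4
        calls = call_cnv(crafted_profile(z), {"t": [f"T{i}" for i in range(10)]})["t"]
        assert calls.deleted == {"G000"} and calls.amplified == set()

    def test_amplified_and_deleted_disjoint_on_random_profiles(self):
        rng = np.random.default_rng(3)
        z = rng.normal(0, 2.0, size=(50, 15))
        calls = call_cnv(crafted_profile(z), {"t": [f"T{i}" for i in range(15)]})["t"]
        assert not (calls.amplified & calls.deleted)

    def test_empty_group_and_reference_overlap_rejected(self):
        prof = crafted_profile(np.zeros((2, 4)))
        with pytest.raises(ValueError, match="no cells"):
            call_cnv(prof, {"t": []})
        with pytest.raises(ValueError, match="overlaps"):
            call_cnv(prof, {"t": ["R0", "T0"]})


class TestPartition:
    def _cs(self, name, amp=(), dele=()):
        idx = pd.Index([], name="gene")
        return CnvCallSet(name, set(amp), set(dele), pd.Series(dtype=float, index=idx),
                          pd.Series(dtype=float, index=idx))

    def test_same_direction_intersection(self):
        part = partition_shared(self._cs("h", amp={"A", "B"}), self._cs("m", amp={"B", "C"}))
        assert part.shared_amplified == {"B"}
        assert part.unique_to_a == {"A"} and part.unique_to_b == {"C"}
        assert part.discordant == set()

    def test_disjoint_sets_share_nothing(self):
        part = partition_shared(self._cs("h", amp={"A"}), self._cs("m", dele={"B"}))
        assert not part.shared_amplified and not part.shared_deleted
        assert part.unique_to_a == {"A"} and part.unique_to_b == {"B"}

    def test_opposite_directions_flagged_discordant(self):
        part = partition_shared(self._cs("h", amp={"X"}), self._cs("m", dele={"X"}))
        assert part.discordant == {"X"}
        assert "X" in part.unique_to_a and "X" in part.unique_to_b


def ward_d2_oracle(points):
    """Naive O(n^3) Ward.D2 agglomeration via the Lance-Williams update on
    squared Euclidean distances; returns sorted merge heights."""
    points = [np.asarray(p, dtype=float) for p in points]
    n = len(points)
    d2 = {}
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(((points[i] - points[j]) ** 2).sum())
    heights = []
    next_id = n
    while len(active) > 1:
        (a, b), best = min(
            (((i, j), d2[(min(i, j), max(i, j))])
             for k, i in enumerate(active) for j in active[k + 1:]),
            key=lambda kv: kv[1],
        )
        heights.append(np.sqrt(best))
        na, nb = sizes[a], sizes[b]
        for k in active:
            if k in (a, b):
                continue
            nk = sizes[k]
            dak = d2[(min(a, k), max(a, k))]
            dbk = d2[(min(b, k), max(b, k))]
            dab = d2[(min(a, b), max(a, b))]
            d_new = ((na + nk) * dak + (nb + nk) * dbk - nk * dab) / (na + nb + nk)
            d2[(min(next_id, k), max(next_id, k))] = d_new
        sizes[next_id] = na + nb
        active = [k for k in active if k not in (a, b)] + [next_id]
        next_id += 1
    return heights


class TestTree:
    def _profile_from_means(self, means, cells_per=3, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        cols, labels = [], []
        for i, mu in enumerate(means):
            for c in range(cells_per):
                cols.append(np.asarray(mu, float) + rng.normal(0, noise, len(mu)))
                labels.append(f"S{i}")
        vals = np.column_stack(cols)
        cells = [f"C{j}" for j in range(vals.shape[1])]
        return (
            CnvProfile(vals, [f"G{k:03d}" for k in range(vals.shape[0])], cells, [], 1),
            labels,
        )

    def test_identical_pair_merges_first_at_zero_height(self):
        prof, labels = self._profile_from_means([[0, 0], [0, 0], [5, 5]])
        tree = cnv_tree(prof, labels)
        assert tree.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert rf_distance(tree.newick, "((S0,S1),S2);") == 0

    @pytest.mark.parametrize("n_leaves", [4, 5, 6])
    def test_heights_match_lance_williams_oracle(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        means = rng.normal(size=(n_leaves, 7))
        prof, labels = self._profile_from_means(means)
        tree = cnv_tree(prof, labels)
        expected = ward_d2_oracle(means)
        np.testing.assert_allclose(np.sort(tree.linkage[:, 2]), np.sort(expected),
                                   atol=1e-10)

    def test_small_subcluster_pooled_with_warning(self):
        prof, labels = self._profile_from_means([[0, 0], [4, 4], [9, 9]], cells_per=3)
        labels[-1] = "lonely"  # drops S2 to 2 cells and adds a singleton
        with pytest.warns(UserWarning, match="pooled"):
            tree = cnv_tree(prof, labels)
        assert "small" in tree.labels

    def test_leaf_state_composition_metadata(self):
        prof, labels = self._profile_from_means([[0, 0], [5, 5]])
        states = ["x", "x", "y", "y", "y", "y"]
        tree = cnv_tree(prof, labels, state_labels=states)
        assert tree.leaf_metadata.loc["S0", "x"] == pytest.approx(2 / 3)

    def test_planted_topology_recovered_on_desk_fixture(self, desk_run):
        assert desk_run["report"]["stages"]["compare"]["metrics"]["tree_rf_distance"] == 0
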