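"""Binary-marker distances, NJ reconstruction, PCA and W&C84 FST."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix

from mobiscan.popgen import (
    BinaryMatrix,
    fst_wc84,
    mean_difference_distance,
    nj_tree,
    pairwise_fst,
    pca,
    select_informative,
)
from mobiscan.popfreq import locus_frequencies

from tests._oracles import brute_mean_difference, random_tree_distances, wc84_example
from tests.test_filtering import _profile


def structured_cohort(rng, n_loci=150, n_per_group=5):
    """A strongly differentiated four-group cohort of binary markers.

    Each locus gets an independent per-group carrier frequency of either
    0.9 or 0.1, giving every group a distinctive marker profile.
    """
    labels = ["broccoli", "cabbage", "cauliflower", "kohlrabi"]
    accs = [f"{g}_{i}" for g in labels for i in range(n_per_group)]
    groups = {a: a.rsplit("_", 1)[0] for a in accs}
    cells = np.zeros((n_loci, len(accs)), dtype=np.int8)
    for l in range(n_loci):
        for gi, g in enumerate(labels):
            f = 0.9 if rng.random() < 0.5 else 0.1
            for k in range(n_per_group):
                cells[l, gi * n_per_group + k] = rng.random() < f
    bm = BinaryMatrix([f"L{i}" for i in range(n_loci)], accs, cells,
                      np.where(cells > 0, 2, cells).astype(np.int8))
    return groups, bm


def _bm(cells, dosage=None):
    cells = np.asarray(cells, dtype=np.int8)
    if dosage is None:
        dosage = np.where(cells > 0, 2, cells).astype(np.int8)
    ids = [f"L{i}" for i in range(cells.shape[0])]
    accs = [f"a{j}" for j in range(cells.shape[1])]
    return BinaryMatrix(ids, accs, cells, np.asarray(dosage, dtype=np.int8))


class TestSelectInformative:
    def test_inclusive_window_boundaries(self):
        p = _profile(["PPAAAAAAAA",   # 0.2 retained
                      "PPPPPPPPAA",   # 0.8 retained
                      "PPPPPPPPPA",   # 0.9 dropped
                      "PAAAAAAAAA"])  # 0.1 dropped
        freqs = locus_frequencies(p)
        bm = select_informative(freqs, p)
        assert bm.locus_ids == ["L0", "L1"]

    def test_heterozygote_encoded_as_carrier(self):
        p = _profile(["PHAA"])
        bm = select_informative(locus_frequencies(p), p)
        assert bm.cells.tolist() == [[1, 1, 0, 0]]
        assert bm.dosage.tolist() == [[2, 1, 0, 0]]

    def test_retained_count_matches_direct_count(self, e2e_seed1):
        p = e2e_seed1.filtered
        freqs = locus_frequencies(p)
        bm = select_informative(freqs, p)
        expected = sum(1 for f in freqs if 0.2 <= f.freq <= 0.8)
        assert len(bm.locus_ids) == expected

    def test_empty_selection_rejected(self):
        p = _profile(["PPPP"])
        with pytest.raises(ValueError):
            select_informative(locus_frequencies(p), p)


class TestDistance:
    def test_identical_and_complementary_rows(self):
        cells = np.array([[1, 0]] * 10 + [[1, 1]] * 5, dtype=np.int8).reshape(15, 2)
        dm = mean_difference_distance(_bm(cells))
        assert dm["a0", "a1"] == pytest.approx(10 / 15)
        same = _bm(np.ones((8, 2), dtype=np.int8))
        assert mean_difference_distance(same)["a0", "a1"] == 0.0

    def test_missing_handled_like_brute_force(self):
        rng = np.random.default_rng(0)
        cells = rng.choice([1, 0, -1], size=(60, 8), p=[0.45, 0.45, 0.1]).astype(np.int8)
        dm = mean_difference_distance(_bm(cells))
        assert np.allclose(dm.data, brute_mean_difference(cells))

    def test_no_shared_locus_names_pair(self):
        cells = np.array([[1, -1], [-1, 0]], dtype=np.int8)
        with pytest.raises(ValueError, match="a0.*a1"):
            mean_difference_distance(_bm(cells))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], dtype=float),
            ["A", "B", "C"],
        )
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 4.0}

    def test_additive_five_taxon_matrix_recovered_exactly(self):
        # classic additive matrix of ((A,B),(C,D),E) shape
        labels = ["A", "B", "C", "D", "E"]
        D = np.array(
            [
                [0, 5, 9, 9, 8],
                [5, 0, 10, 10, 9],
                [9, 10, 0, 8, 7],
                [9, 10, 8, 0, 3],
                [8, 9, 7, 3, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(DistanceMatrix(D, labels))
        td = tree.tip_tip_distances()
        td = td.filter(labels)
        assert np.allclose(td.data, D)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_additive_matrices_recovered(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        labels, D = random_tree_distances(rng, n)
        tree = nj_tree(DistanceMatrix(D, labels))
        td = tree.tip_tip_distances().filter(labels)
        assert np.allclose(td.data, D), f"n={n}"

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_additive_recovery_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 10))
        labels, D = random_tree_distances(rng, n)
        tree = nj_tree(DistanceMatrix(D, labels))
        td = tree.tip_tip_distances().filter(labels)
        assert np.allclose(td.data, D)

    def test_invalid_inputs_rejected(self):
        # an asymmetric matrix cannot even be constructed as a distance
        # matrix, and fewer than three taxa cannot be joined
        from skbio.stats.distance import DissimilarityMatrixError

        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(DissimilarityMatrixError):
            DistanceMatrix(d, ["a", "b", "c"])
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(np.zeros((2, 2)), ["a", "b"]))

    def test_morphotypes_form_clades_under_strong_differentiation(self):
        groups, bm = structured_cohort(np.random.default_rng(6))
        tree = nj_tree(mean_difference_distance(bm))
        for g in sorted(set(groups.values())):
            tips = [a for a in bm.accessions if groups[a] == g]
            outgroup = next(a for a in bm.accessions if groups[a] != g)
            # monophyly on an unrooted tree: root outside the group first
            work = tree.copy()
            rooted = work.root_at(work.find(outgroup))
            lca = rooted.lowest_common_ancestor(tips)
            assert sorted(t.name for t in lca.tips()) == sorted(tips), g


class TestPCA:
    def test_two_clusters_separate_on_pc1(self):
        cells = np.zeros((30, 10), dtype=np.int8)
        cells[:, 5:] = 1
        cells[::2, :] = 1 - cells[::2, :]  # two complementary locus groups
        res = pca(_bm(cells))
        pc1 = res.coordinates[:, 0]
        assert (pc1[:5] > 0).all() != (pc1[5:] > 0).all()
        assert res.percent_variance[0] == pytest.approx(100.0)
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-9)

    def test_covariance_reconstruction_identity(self):
        rng = np.random.default_rng(1)
        cells = rng.integers(0, 2, size=(80, 12)).astype(np.int8)
        bm = _bm(cells)
        res = pca(bm)
        X = cells.astype(float).T
        p = X.mean(axis=0)
        keep = (p > 0) & (p < 1)
        Xs = (X[:, keep] - p[keep]) / np.sqrt(p[keep] * (1 - p[keep]))
        cov = Xs @ Xs.T / Xs.shape[1]
        approx = res.coordinates @ res.coordinates.T
        assert np.allclose(approx, cov, atol=1e-8)

    def test_percent_variance_sums_to_100(self):
        rng = np.random.default_rng(2)
        cells = rng.integers(0, 2, size=(50, 9)).astype(np.int8)
        res = pca(_bm(cells))
        assert res.percent_variance[res.eigenvalues > 0].sum() == pytest.approx(100.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pca(_bm(np.ones((10, 4), dtype=np.int8)), scale=False)

    def test_groups_recoverable_from_leading_components(self):
        groups, bm = structured_cohort(np.random.default_rng(7))
        res = pca(bm)
        coords = res.coordinates[:, :3]
        labels = sorted(set(groups.values()))
        centroids = {
            g: coords[[i for i, a in enumerate(bm.accessions) if groups[a] == g]].mean(0)
            for g in labels
        }
        wrong = 0
        for i, a in enumerate(bm.accessions):
            nearest = min(
                labels, key=lambda g: np.linalg.norm(coords[i] - centroids[g])
            )
            wrong += nearest != groups[a]
        assert wrong == 0


class TestFst:
    def test_single_locus_hand_computed_components(self):
        ex = wc84_example()
        dosage = np.array([ex["group1"] + ex["group2"]], dtype=np.int8)
        bm = _bm((dosage > 0).astype(np.int8), dosage)
        res = fst_wc84(bm, ["a0", "a1", "a2", "a3"], ["a4", "a5", "a6", "a7"])
        assert res.a[0] == pytest.approx(ex["a"])
        assert res.b[0] == pytest.approx(ex["b"])
        assert res.c[0] == pytest.approx(ex["c"])
        assert res.fst == pytest.approx(ex["fst"])

    def test_fixed_difference_gives_one(self):
        cells = np.tile([1, 1, 1, 0, 0, 0], (20, 1)).astype(np.int8)
        bm = _bm(cells)
        res = fst_wc84(bm, ["a0", "a1", "a2"], ["a3", "a4", "a5"])
        assert res.fst == 1.0

    def test_null_simulation_near_zero(self):
        rng = np.random.default_rng(3)
        n = 200
        cells = (rng.random((300, 2 * n)) < 0.4).astype(np.int8)
        bm = _bm(cells)
        res = fst_wc84(
            bm, [f"a{i}" for i in range(n)], [f"a{i}" for i in range(n, 2 * n)]
        )
        assert abs(res.fst) < 0.02

    def test_monotone_in_frequency_divergence(self):
        rng = np.random.default_rng(4)
        n = 100
        values = []
        for delta in (0.0, 0.1, 0.2, 0.3, 0.4):
            g1 = (rng.random((400, n)) < 0.5 - delta / 2).astype(np.int8)
            g2 = (rng.random((400, n)) < 0.5 + delta / 2).astype(np.int8)
            bm = _bm(np.hstack([g1, g2]))
            values.append(
                fst_wc84(bm, [f"a{i}" for i in range(n)],
                         [f"a{i}" for i in range(n, 2 * n)]).fst
            )
        assert all(b > a for a, b in zip(values, values[1:]))
        assert all(-0.05 <= v <= 1 for v in values)

    def test_monomorphic_set_rejected(self):
        cells = np.ones((5, 6), dtype=np.int8)
        with pytest.raises(ValueError):
            fst_wc84(_bm(cells), ["a0", "a1", "a2"], ["a3", "a4", "a5"])

    def test_pairwise_table_on_structured_cohort(self):
        groups, bm = structured_cohort(np.random.default_rng(8))
        df = pairwise_fst(bm, groups)
        assert len(df) == 6  # 4 morphotypes -> 6 pairs
        assert ((df["fst"] > 0.2) & (df["fst"] <= 1)).all()
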