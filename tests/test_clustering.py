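"""NMI correctness and invariances; embedding and DP-mixture behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from whalecues.clustering import embed_2d, fit_bnp, nmi, scan_clusters


def mi_bruteforce(x, y) -> float:
    """Independent oracle: double sum over the contingency table, base 2."""
    x, y = np.asarray(x), np.asarray(y)
    n = x.size
    mi = 0.0
    for xv in np.unique(x):
        for yv in np.unique(y):
            pxy = np.mean((x == xv) & (y == yv))
            if pxy > 0:
                mi += pxy * np.log2(pxy / (np.mean(x == xv) * np.mean(y == yv)))
    return mi


class TestNMI:
    def test_identical_partitions_score_one(self):
        assert nmi([0, 0, 1, 1], [0, 0, 1, 1]).nmi == pytest.approx(1.0)

    def test_independent_partitions_score_zero(self):
        assert nmi([0, 0, 1, 1], [0, 1, 0, 1]).nmi == pytest.approx(0.0, abs=1e-12)

    def test_hand_enumerated_two_by_two_case(self):
        """X=[0,0,0,1], Y=[0,0,1,1]: I=0.3113, H(X)=0.8113, H(Y)=1, NMI=0.3456."""
        ev = nmi([0, 0, 0, 1], [0, 0, 1, 1])
        assert ev.mi == pytest.approx(0.3113, abs=5e-5)
        assert ev.h_x == pytest.approx(0.8113, abs=5e-5)
        assert ev.h_y == pytest.approx(1.0, abs=1e-12)
        assert ev.nmi == pytest.approx(0.3456, abs=5e-4)

    def test_degenerate_entropies(self):
        assert nmi([7, 7, 7], [1, 1, 1]).nmi == 1.0  # both constant: identical
        assert nmi([7, 7, 7], [0, 1, 2]).nmi == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            nmi([0, 1], [0, 1, 2])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(st.integers(0, 4), min_size=2, max_size=40),
        st.data(),
    )
    def test_random_partition_properties(self, x, data):
        """Symmetry, relabeling invariance, bounds, and the brute-force oracle."""
        y = data.draw(st.lists(st.integers(0, 4), min_size=len(x), max_size=len(x)))
        ev = nmi(x, y)
        assert 0.0 <= ev.nmi <= 1.0
        assert -1e-12 <= ev.mi <= min(ev.h_x, ev.h_y) + 1e-12
        assert ev.mi == pytest.approx(mi_bruteforce(x, y), abs=1e-12)
        assert nmi(y, x).nmi == pytest.approx(ev.nmi, abs=1e-12)
        # relabeling either side changes nothing
        remap = {v: 10 - v for v in set(x)}
        assert nmi([remap[v] for v in x], y).nmi == pytest.approx(ev.nmi, abs=1e-12)

    def test_merging_clusters_never_increases_mi(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 4, 60)
            y = rng.integers(0, 3, 60)
            merged = np.where(x == 3, 2, x)  # merge clusters 3 and 2
            assert nmi(merged, y).mi <= nmi(x, y).mi + 1e-12

    def test_arithmetic_normalization_option(self):
        ev = nmi([0, 0, 0, 1], [0, 0, 1, 1], average="arithmetic")
        assert ev.nmi == pytest.approx(2 * 0.31128 / (0.81128 + 1.0), abs=5e-4)


@pytest.fixture(scope="module")
def blobs():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 200)
    X = rng.normal(size=(200, 13)) + y[:, None] * 10.0
    return X, y


class TestEmbed2d:
    def test_shape_and_determinism(self, blobs):
        X, _ = blobs
        a = embed_2d(X, perplexity=20, seed=1)
        b = embed_2d(X, perplexity=20, seed=1)
        assert a.shape == (200, 2)
        np.testing.assert_array_equal(a, b)

    def test_separated_blobs_stay_separated(self, blobs):
        X, y = blobs
        coords = embed_2d(X, perplexity=20, seed=0)
        # nearest-neighbour label purity
        from scipy.spatial import cKDTree

        _, idx = cKDTree(coords).query(coords, k=2)
        purity = np.mean(y[idx[:, 1]] == y)
        assert purity >= 0.95

    def test_nonfinite_rows_named(self):
        X = np.zeros((100, 5))
        X[3, 2] = np.nan
        with pytest.raises(ValueError, match=r"\[3\]"):
            embed_2d(X, perplexity=10)

    def test_perplexity_precondition(self):
        with pytest.raises(ValueError, match="perplexity"):
            embed_2d(np.zeros((10, 3)), perplexity=5)


class TestFitBnp:
    def test_two_blobs_recovered(self, blobs):
        X, y = blobs
        coords = embed_2d(X, perplexity=20, seed=0)
        labels = fit_bnp(coords, seed=0)
        assert np.unique(labels).size == 2
        # accuracy up to label permutation
        acc = max(np.mean(labels == y), np.mean(labels != y))
        assert acc >= 0.95

    def test_single_blob_single_cluster_at_small_concentration(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(300, 2))
        labels = fit_bnp(coords, concentration=0.1, seed=0)
        assert np.unique(labels).size == 1

    def test_label_contract(self, blobs):
        X, _ = blobs
        coords = embed_2d(X, perplexity=20, seed=0)
        labels = fit_bnp(coords, truncation=10, seed=0)
        assert labels.shape == (200,)
        assert labels.max() < 10

    def test_degenerate_coordinates_single_cluster(self):
        with pytest.warns(UserWarning, match="degenerate"):
            labels = fit_bnp(np.ones((50, 2)))
        assert np.all(labels == 0)


class TestScanClusters:
    def test_returned_best_is_argmax_of_score_table(self, blobs):
        X, y = blobs
        ev, labels, table = scan_clusters(X, y, perplexity=20, n_replicates=2, seed=0)
        assert ev.nmi == pytest.approx(table["nmi"].max())
        assert labels.shape == (200,)
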