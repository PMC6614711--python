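"""Core numerics: relative abundance, Hellinger, Bray-Curtis, Shannon,
PCoA and the Mantel test, each checked against hand values or an
independent implementation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from agsflow.containers import ValidationError
from agsflow.metrics import (bray_curtis, bray_curtis_matrix, hellinger,
                             mantel, pcoa, relative_abundance, shannon)


class TestRelativeAbundance:
    def test_hand_example(self):
        out = relative_abundance(pd.DataFrame([[2, 2, 4]]))
        np.testing.assert_allclose(out.to_numpy(), [[0.25, 0.25, 0.5]])

    def test_single_taxon_and_idempotence(self):
        out = relative_abundance(pd.DataFrame([[7.0]]))
        assert out.iloc[0, 0] == 1.0
        twice = relative_abundance(out)
        pd.testing.assert_frame_equal(out, twice)

    def test_all_zero_sample_named(self):
        frame = pd.DataFrame([[1, 2], [0, 0]], index=["ok", "empty"])
        with pytest.raises(ValidationError, match="empty"):
            relative_abundance(frame)


class TestHellinger:
    def test_hand_square_roots(self):
        out = hellinger(pd.DataFrame([[0.25, 0.25, 0.5]]))
        np.testing.assert_allclose(out.to_numpy(), [[0.5, 0.5, 0.70711]],
                                   atol=5e-6)

    def test_degenerate_vector(self):
        out = hellinger(pd.DataFrame([[1.0, 0.0]]))
        np.testing.assert_allclose(out.to_numpy(), [[1.0, 0.0]])

    @given(arrays(float, (4, 6), elements=st.floats(0.01, 100)))
    @settings(max_examples=30, deadline=None)
    def test_rows_have_unit_sum_of_squares(self, arr):
        out = hellinger(pd.DataFrame(arr))
        np.testing.assert_allclose((out ** 2).sum(axis=1), 1.0, atol=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            hellinger(pd.DataFrame([[-0.1, 1.1]]))


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)
        assert bray_curtis([1, 0, 2], [0, 5, 0]) == pytest.approx(1.0)

    def test_hand_value(self):
        assert bray_curtis([0.5, 0.5, 0], [0, 0.5, 0.5]) == pytest.approx(0.5)

    def test_errors(self):
        with pytest.raises(ValidationError):
            bray_curtis([1, 2], [1, 2, 3])
        with pytest.raises(ValidationError):
            bray_curtis([0, 0], [0, 0])

    def test_matrix_against_naive_loop(self, random_counts):
        dm = bray_curtis_matrix(random_counts)
        arr = random_counts.values.to_numpy(dtype=float)
        n = arr.shape[0]
        for i in range(n):
            for j in range(n):
                if i == j:
                    expected = 0.0
                else:
                    expected = 1 - 2 * np.minimum(arr[i], arr[j]).sum() / (
                        arr[i].sum() + arr[j].sum())
                assert abs(dm.iloc[i, j] - expected) < 1e-12

    def test_matrix_invariants(self, random_counts):
        dm = bray_curtis_matrix(random_counts).to_numpy()
        assert np.allclose(dm, dm.T, atol=1e-12)
        assert np.allclose(np.diag(dm), 0.0)
        assert ((dm >= 0) & (dm <= 1)).all()


class TestShannon:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.25] * 4, np.log(4)),
            ([1.0], 0.0),
            ([0.5, 0.25, 0.25], 1.5 * np.log(2)),
        ],
    )
    def test_hand_values(self, p, expected):
        assert shannon(p) == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_log_richness(self, rng):
        frame = pd.DataFrame(rng.random((10, 8)))
        h = shannon(frame)
        assert ((h >= 0) & (h <= np.log(8) + 1e-12)).all()


class TestPcoa:
    def test_zero_matrix(self):
        res = pcoa(pd.DataFrame(np.zeros((4, 4))), n_axes=2)
        assert res.coordinates.shape[1] == 0 or np.allclose(
            res.coordinates.to_numpy(), 0.0)

    def test_collinear_points(self):
        # points on a line at 0, 1, 3: gaps 1 and 2, end-to-end 3
        d = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], dtype=float)
        with pytest.warns(UserWarning):
            res = pcoa(pd.DataFrame(d), n_axes=2)
        pos = res.eigenvalues[res.eigenvalues > 1e-9]
        assert len(pos) == 1
        x = res.coordinates.iloc[:, 0].to_numpy()
        got = sorted(abs(x[i] - x[j]) for i, j in [(0, 1), (1, 2), (0, 2)])
        np.testing.assert_allclose(got, [1, 2, 3], atol=1e-9)

    def test_euclidean_reconstruction(self, rng):
        pts = rng.normal(size=(12, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(pd.DataFrame(d), n_axes=3)
        c = res.coordinates.to_numpy()
        recon = np.sqrt(((c[:, None] - c[None]) ** 2).sum(-1))
        np.testing.assert_allclose(recon, d, atol=1e-8)

    def test_matches_skbio(self, random_counts):
        skbio = pytest.importorskip("skbio")
        from agsflow.metrics import relative_abundance
        dm = bray_curtis_matrix(relative_abundance(random_counts))
        ours = pcoa(dm, n_axes=2)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.to_numpy(), ids=list(map(str, dm.index)))
        )
        for ax in range(2):
            a = ours.coordinates.iloc[:, ax].to_numpy()
            b = theirs.samples.iloc[:, ax].to_numpy()
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-6

    def test_explained_fraction_sums_below_one(self, random_counts):
        dm = bray_curtis_matrix(relative_abundance(random_counts))
        res = pcoa(dm, n_axes=5)
        assert res.explained_fraction.sum() <= 1 + 1e-12


class TestMantel:
    def _random_dm(self, rng, n=10):
        pts = rng.normal(size=(n, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        return pd.DataFrame(d)

    def test_self_comparison(self, rng):
        a = self._random_dm(rng)
        r, p = mantel(a, a, n_perm=199, seed=0)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(1 / 200)

    def test_affine_invariance(self, rng):
        a = self._random_dm(rng)
        b = 3.0 * a + 0.5
        b.values[np.diag_indices(len(b))] = 0.0
        r, _ = mantel(a, b, n_perm=99, seed=0)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_statistic_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        a, b = self._random_dm(rng), self._random_dm(rng)
        r, _ = mantel(a, b, n_perm=10, seed=0)
        r_sk, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(a.to_numpy()), skbio.DistanceMatrix(b.to_numpy()),
            permutations=0)
        assert r == pytest.approx(r_sk, abs=1e-12)

    def test_label_mismatch(self, rng):
        a = self._random_dm(rng)
        b = self._random_dm(rng)
        b.index = b.columns = [f"x{i}" for i in range(len(b))]
        with pytest.raises(ValidationError):
            mantel(a, b)
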