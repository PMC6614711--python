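"""Taxa-parameter correlations, correlation-profile clustering, and MFA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agsflow.containers import CommunityTable, ValidationError
from agsflow.correlates import (cluster_taxa, match_samples, mfa,
                                taxa_parameter_correlations)


def _community(values, days):
    frame = pd.DataFrame(values)
    frame.index = [f"s{i}" for i in range(len(frame))]
    meta = pd.DataFrame({"reactor": "R1", "day": days}, index=frame.index)
    return CommunityTable(frame, meta)


def _params(days, **cols):
    return pd.DataFrame({"reactor": "R1", "day": days, **cols})


class TestCorrelations:
    def test_proportional_and_antiproportional(self, rng):
        days = np.arange(10) * 7
        x = np.linspace(0.1, 0.9, 10)
        table = _community({"A": x, "B": 1 - x}, days)
        params = _params(days, p_up=np.sqrt(x), p_down=-np.sqrt(x) + 2)
        res = taxa_parameter_correlations(table, params, transform=True)
        # Hellinger(A) = sqrt(x): exactly proportional to p_up
        assert res.correlations.loc["A", "p_up"] == pytest.approx(1.0)
        assert res.correlations.loc["A", "p_down"] == pytest.approx(-1.0)
        assert res.p_values.loc["A", "p_up"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_pearson_three_points(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 1.0, 4.0])
        r = np.corrcoef(x, y)[0, 1]
        assert r == pytest.approx(0.9608, abs=5e-5)
        days = [0, 7, 14]
        table = _community({"A": [1, 2, 3], "B": [9, 8, 7]}, days)
        params = _params(days, q=y)
        res = taxa_parameter_correlations(table, params, transform=False,
                                          min_n=3)
        xa = table.values["A"].to_numpy(dtype=float)
        expected, p_exp = stats.pearsonr(xa, y)
        assert res.correlations.loc["A", "q"] == pytest.approx(expected,
                                                               abs=1e-12)
        assert res.p_values.loc["A", "q"] == pytest.approx(p_exp, abs=1e-12)

    def test_matrix_matches_pairwise_oracle(self, rng, random_counts):
        days = random_counts.meta["day"].to_numpy()
        params = _params(days,
                         u=rng.normal(size=len(days)),
                         v=rng.normal(size=len(days)))
        res = taxa_parameter_correlations(random_counts, params)
        from agsflow.metrics import hellinger
        h = hellinger(random_counts).values
        for taxon in random_counts.taxa[:10]:
            for col in ("u", "v"):
                r, p = stats.pearsonr(h[taxon], params[col])
                assert res.correlations.loc[taxon, col] == pytest.approx(
                    r, abs=1e-12)
                assert res.p_values.loc[taxon, col] == pytest.approx(p, abs=1e-9)

    def test_inverse_transform_applied(self):
        days = np.arange(8) * 7
        x = np.linspace(0.2, 0.8, 8)
        table = _community({"A": x, "B": 1 - x}, days)
        params = _params(days, settling_time=1.0 / np.sqrt(x))
        res = taxa_parameter_correlations(table, params,
                                          inverse_cols=("settling_time",))
        assert res.correlations.loc["A", "settling_time"] == pytest.approx(1.0)

    def test_day_window_matching(self):
        taxa_meta = pd.DataFrame({"reactor": ["R1", "R1"], "day": [10, 100]},
                                 index=["a", "b"])
        params = _params([12, 40], z=[1.0, 2.0])
        matched = match_samples(taxa_meta, params, day_window=7)
        assert list(matched.index) == ["a"]  # sample b is 60 days away


class TestClusterTaxa:
    def _block_profiles(self):
        rows = {}
        for i in range(4):
            rows[f"g{i}"] = [1.0, 0.9, 0.0, 0.0, 0.0, 0.0]
        for i in range(4):
            rows[f"m{i}"] = [0.0, 0.0, 1.0, 0.9, 0.0, 0.0]
        for i in range(4):
            rows[f"p{i}"] = [0.0, 0.0, 0.0, 0.0, 1.0, 0.9]
        cols = ["frac_large", "frac_medium", "frac_small", "svi30",
                "removal_tn", "removal_tp"]
        return pd.DataFrame(rows, index=cols).T

    def test_orthogonal_blocks_recovered(self):
        corr = self._block_profiles()
        labels = cluster_taxa(corr, k=3)
        groups = {labels[f"g{i}"] for i in range(4)}
        assert len(groups) == 1
        assert len({labels[f"m{i}"] for i in range(4)}) == 1
        assert len({labels[f"p{i}"] for i in range(4)}) == 1
        assert set(labels.index) == {f"{c}{i}" for c in "gmp" for i in range(4)}
        # granule-correlated block is numbered cluster 1
        assert labels["g0"] == 1

    def test_identical_profiles_cluster_together(self):
        corr = pd.DataFrame([[0.5, -0.5]] * 2 + [[-0.9, 0.9]],
                            index=["a", "b", "c"], columns=["x", "y"])
        labels = cluster_taxa(corr, k=2, granule_cols=("x",))
        assert labels["a"] == labels["b"] != labels["c"]

    def test_singletons_and_input_order_invariance(self):
        corr = self._block_profiles()
        labels_full = cluster_taxa(corr, k=len(corr))
        assert labels_full.nunique() == len(corr)
        shuffled = corr.sample(frac=1.0, random_state=1)
        a = cluster_taxa(corr, k=3)
        b = cluster_taxa(shuffled, k=3)
        pd.testing.assert_series_equal(a, b)

    def test_k_too_large(self):
        with pytest.raises(ValidationError):
            cluster_taxa(self._block_profiles(), k=99)


class TestMfa:
    def test_single_group_matches_pca(self, rng):
        block = pd.DataFrame(rng.normal(size=(15, 4)))
        res = mfa({"only": block}, n_axes=3)
        z = (block - block.mean()) / block.std(ddof=0)
        u, s, _ = np.linalg.svd(z.to_numpy(), full_matrices=False)
        pcs = u[:, :3] * s[:3]
        for ax in range(3):
            a = res.coordinates.iloc[:, ax].to_numpy()
            b = pcs[:, ax]
            ratio = a @ b / (b @ b)
            np.testing.assert_allclose(a, ratio * b, atol=1e-8)

    def test_duplicated_block_contributes_half(self, rng):
        block = pd.DataFrame(rng.normal(size=(12, 3)))
        res = mfa({"first": block, "second": block.copy()}, n_axes=2)
        np.testing.assert_allclose(
            res.group_contributions.to_numpy(), 0.5, atol=1e-9)

    def test_trace_identity(self, rng):
        groups = {
            "a": pd.DataFrame(rng.normal(size=(10, 3))),
            "b": pd.DataFrame(rng.normal(size=(10, 5))),
        }
        res = mfa(groups, n_axes=2)
        # total inertia = sum over blocks of n_vars / first_singular_value**2
        expected = sum(g.shape[1] * res.group_weights[name] ** 2
                       for name, g in groups.items())
        assert res.eigenvalues.sum() == pytest.approx(expected)

    def test_contributions_sum_to_one(self, rng):
        groups = {
            "a": pd.DataFrame(rng.normal(size=(10, 3))),
            "b": pd.DataFrame(rng.normal(size=(10, 2))),
        }
        res = mfa(groups, n_axes=2)
        np.testing.assert_allclose(res.group_contributions.sum(axis=0), 1.0)
        assert (res.group_contributions.to_numpy() >= 0).all()

    def test_zero_variance_dropped_with_warning(self, rng):
        block = pd.DataFrame(rng.normal(size=(8, 2)))
        block["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            res = mfa({"g": block}, n_axes=1)
        assert "flat" not in res.loadings.index.get_level_values(1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mfa({"g": pd.DataFrame(index=[0, 1])})

    def test_group_separation_on_planted_structure(self, rng):
        # one block carries a two-cluster sample structure, the other is noise:
        # the structured block should dominate axis 1
        labels = np.repeat([0, 1], 8)
        strong = pd.DataFrame(
            rng.normal(size=(16, 4)) + labels[:, None] * 6.0)
        noise = pd.DataFrame(rng.normal(size=(16, 4)))
        res = mfa({"structured": strong, "noise": noise}, n_axes=2)
        contrib = res.group_contributions["axis1"]
        assert contrib["structured"] > contrib["noise"]
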