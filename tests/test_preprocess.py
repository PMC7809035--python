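"""Unit tests for normalization, residualization, and meta-features."""

import numpy as np
import pandas as pd
import pytest

from micronet import preprocess as prep


def em(values, unit="fpkm", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return prep.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), unit=unit)


class TestQuantileNormalize:
    def test_hand_example_two_by_two(self):
        # columns (1,2) and (3,4); rank means are (2, 3)
        out = prep.quantile_normalize(em([[1, 3], [2, 4]]))
        np.testing.assert_allclose(out.values.to_numpy(), [[2, 2], [3, 3]])

    def test_identical_columns_fixed_point(self):
        x = em([[1, 1], [5, 5], [2, 2]])
        out = prep.quantile_normalize(x)
        np.testing.assert_allclose(out.values.to_numpy(), x.values.to_numpy())

    def test_idempotent(self, rng):
        x = em(rng.gamma(2.0, 2.0, (40, 6)))
        once = prep.quantile_normalize(x)
        twice = prep.quantile_normalize(once)
        np.testing.assert_allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12)

    def test_ties_get_mean_of_reference_values(self):
        # col0 sorted = (1,1,5): tied pair takes mean of reference[0:2]
        out = prep.quantile_normalize(em([[1, 4], [1, 5], [5, 6]]))
        reference = np.array([(1 + 4) / 2, (1 + 5) / 2, (5 + 6) / 2])
        expected0 = [reference[:2].mean(), reference[:2].mean(), reference[2]]
        np.testing.assert_allclose(out.values.to_numpy()[:, 0], expected0)

    def test_row_permutation_equivariance(self, rng):
        x = rng.gamma(2.0, 2.0, (30, 4))
        perm = rng.permutation(30)
        out = prep.quantile_normalize(em(x)).values.to_numpy()
        out_perm = prep.quantile_normalize(em(x[perm])).values.to_numpy()
        np.testing.assert_allclose(out[perm], out_perm)

    def test_rejects_single_sample_and_missing(self):
        with pytest.raises(ValueError):
            prep.quantile_normalize(em([[1.0], [2.0]]))
        bad = em([[1, 2], [3, 4]], unit="log2")
        bad.values.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            prep.quantile_normalize(bad)


class TestAdjustBatch:
    def test_constant_shift_removed_exactly(self, rng):
        x = rng.normal(5.0, 1.0, (20, 12))
        shifted = x.copy()
        shifted[:, 6:] += 3.0
        batches = ["a"] * 6 + ["b"] * 6
        out = prep.adjust_batch(em(shifted, unit="log2"), batches).values.to_numpy()
        # batch offset gone: per-gene batch means coincide exactly
        np.testing.assert_allclose(
            out[:, :6].mean(axis=1), out[:, 6:].mean(axis=1), atol=1e-10
        )

    def test_equalizes_per_batch_spread(self, rng):
        x = rng.normal(0.0, 1.0, (15, 20))
        x[:, 10:] *= 2.0
        batches = np.repeat(["a", "b"], 10)
        out = prep.adjust_batch(em(x, unit="log2"), batches).values.to_numpy()
        sd_a = out[:, :10].std(axis=1, ddof=1)
        sd_b = out[:, 10:].std(axis=1, ddof=1)
        np.testing.assert_allclose(sd_a, sd_b, atol=1e-8)

    def test_rejects_single_or_tiny_batches(self, rng):
        x = em(rng.normal(size=(5, 8)), unit="log2")
        with pytest.raises(ValueError):
            prep.adjust_batch(x, ["a"] * 8)
        with pytest.raises(ValueError, match="fewer than 3"):
            prep.adjust_batch(x, ["a"] * 6 + ["b"] * 2)


class TestFilterGenes:
    def test_strict_boundary_and_retention(self):
        x = em([[1.0, 1.0], [0.0, 2.5], [0.5, 1.0]])  # means 1.0, 1.25, 0.75
        out = prep.filter_genes(x)
        assert out.gene_ids.tolist() == ["g1"]

    def test_all_zero_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            out = prep.filter_genes(em(np.zeros((3, 2))))
        assert out.shape[0] == 0

    def test_requires_fpkm_unit(self):
        with pytest.raises(ValueError):
            prep.filter_genes(em([[1, 2]], unit="log2"))


class TestResidualize:
    def test_intercept_only_centers(self, rng):
        x = em(rng.normal(3, 1, (10, 25)), unit="log2")
        covs = pd.DataFrame(index=x.sample_ids)
        out = prep.residualize(x, covs).values.to_numpy()
        expected = x.values.to_numpy() - x.values.to_numpy().mean(axis=1, keepdims=True)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_exact_covariate_multiple_vanishes(self, rng):
        age = rng.normal(85, 5, 30)
        x = em(np.vstack([2 * age]), unit="log2")
        covs = pd.DataFrame({"age": age}, index=x.sample_ids)
        out = prep.residualize(x, covs).values.to_numpy()
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        x = em(rng.normal(size=(20, 50)), unit="log2")
        covs = pd.DataFrame(
            {"a": rng.normal(size=50), "b": rng.integers(0, 2, 50)}, index=x.sample_ids
        )
        out = prep.residualize(x, covs).values.to_numpy()
        for col in covs.columns:
            c = covs[col].to_numpy(dtype=float)
            corr = np.corrcoef(out, c)[:-1, -1]
            assert np.abs(corr).max() < 1e-8

    def test_projection_idempotent(self, rng):
        x = em(rng.normal(size=(15, 40)), unit="log2")
        covs = pd.DataFrame({"a": rng.normal(size=40)}, index=x.sample_ids)
        once = prep.residualize(x, covs)
        twice = prep.residualize(
            prep.ExpressionMatrix(once.values, unit="log2"), covs
        )
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-10
        )

    def test_collinear_design_names_columns(self, rng):
        a = rng.normal(size=30)
        x = em(rng.normal(size=(5, 30)), unit="log2")
        covs = pd.DataFrame({"a": a, "a_copy": a}, index=x.sample_ids)
        with pytest.raises(ValueError, match="a_copy"):
            prep.residualize(x, covs)

    def test_categorical_covariates_expanded(self, rng):
        x = em(rng.normal(size=(5, 30)), unit="log2")
        covs = pd.DataFrame(
            {"batch": np.repeat(["u", "v", "w"], 10)}, index=x.sample_ids
        )
        out = prep.residualize(x, covs).values.to_numpy()
        # residuals centered within every categorical level
        for level in ("u", "v", "w"):
            idx = covs["batch"] == level
            np.testing.assert_allclose(out[:, idx.to_numpy()].mean(axis=1), 0.0, atol=1e-10)


class TestMetaFeature:
    def assignment(self, mapping):
        return prep.ModuleAssignment(pd.Series(mapping))

    def test_single_gene_module_is_zscore(self, rng):
        x = em(rng.normal(size=(3, 8)), unit="log2")
        a = self.assignment({"g0": "mA"})
        score = prep.meta_feature(x, a, "mA")
        vals = x.values.loc["g0"]
        z = (vals - vals.mean()) / vals.std(ddof=1)
        np.testing.assert_allclose(score.to_numpy(), z.to_numpy())

    def test_perfectly_correlated_pair_equals_either_zscore(self, rng):
        base = rng.normal(size=8)
        x = em(np.vstack([base, 3 * base + 7]), unit="log2")
        a = self.assignment({"g0": "mA", "g1": "mA"})
        score = prep.meta_feature(x, a, "mA")
        z = (base - base.mean()) / base.std(ddof=1)
        np.testing.assert_allclose(score.to_numpy(), z, atol=1e-12)

    def test_hand_computed_three_gene_oracle(self):
        vals = np.array(
            [[1.0, 2.0, 3.0, 4.0], [10.0, 10.0, 12.0, 8.0], [0.0, 1.0, 1.0, 0.0]]
        )
        x = em(vals, unit="log2")
        a = self.assignment({"g0": "mA", "g1": "mA", "g2": "mA"})
        # independent arithmetic: z-score each row (ddof=1), average
        z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1, keepdims=True)
        np.testing.assert_allclose(
            prep.meta_feature(x, a, "mA").to_numpy(), z.mean(axis=0), atol=1e-12
        )

    def test_invariant_to_per_gene_affine_rescaling(self, rng):
        vals = rng.normal(size=(4, 10))
        a = self.assignment({f"g{i}": "mA" for i in range(4)})
        scaled = vals * rng.uniform(0.5, 4.0, (4, 1)) + rng.normal(size=(4, 1))
        s1 = prep.meta_feature(em(vals, unit="log2"), a, "mA")
        s2 = prep.meta_feature(em(scaled, unit="log2"), a, "mA")
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-10)

    def test_zero_variance_gene_excluded_with_warning(self, rng):
        vals = np.vstack([rng.normal(size=6), np.full(6, 3.0)])
        a = self.assignment({"g0": "mA", "g1": "mA"})
        with pytest.warns(UserWarning, match="zero-variance"):
            score = prep.meta_feature(em(vals, unit="log2"), a, "mA")
        z = (vals[0] - vals[0].mean()) / vals[0].std(ddof=1)
        np.testing.assert_allclose(score.to_numpy(), z)

    def test_absent_module_raises(self, rng):
        x = em(rng.normal(size=(2, 5)), unit="log2")
        a = self.assignment({"g0": "mA"})
        with pytest.raises(KeyError):
            prep.meta_feature(x, a, "mZ")

    def test_output_mean_zero(self, small_scores):
        scores, _ = small_scores
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-10)
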