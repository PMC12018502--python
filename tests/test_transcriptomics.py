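import numpy as np
import pandas as pd
import pytest

from dfcdtx import transcriptomics as tx
from dfcdtx.dfcd import DFCDMap
from dfcdtx.group_stats import TStatMap
from dfcdtx.imaging_io import AtlasParcellation, SubjectTable
from dfcdtx.synthetic_data import (ExpressionSimConfig, SimConfig,
                                   generate_expression, make_atlas)


def nipals_first_component(X, y, tol=1e-12, max_iter=500):
    """Independent oracle: classic NIPALS iteration for PLS1, column-centred
    inputs, weight vector normalised to unit length."""
    X = X - X.mean(axis=0)
    u = y - y.mean()
    w = np.zeros(X.shape[1])
    for _ in range(max_iter):
        w_new = X.T @ u
        w_new /= np.linalg.norm(w_new)
        t = X @ w_new
        q = (u @ t) / (t @ t)
        u_new = t * q
        if np.linalg.norm(w_new - w) < tol:
            w = w_new
            break
        w, u = w_new, u
    t = X @ w
    return w, t


@pytest.fixture(scope="module")
def atlas():
    return make_atlas(SimConfig())


@pytest.fixture(scope="module")
def planted(atlas):
    rng = np.random.default_rng(5)
    diff = rng.standard_normal(len(atlas.region_ids))
    config = ExpressionSimConfig(n_genes=120, n_linked_pos=6, n_linked_neg=6,
                                 link_strength=0.8, seed=5)
    result = generate_expression(atlas, diff, config)
    y = pd.Series(diff, index=result.matrix.index)
    return y, result


class TestParcelMean:
    def test_piecewise_constant_map_recovers_region_constants(self, atlas):
        mask = atlas.labels != 0
        t_by_region = {int(r): float(r) * 0.5 for r in atlas.region_ids}
        t_vol = np.zeros(atlas.labels.shape)
        for r, v in t_by_region.items():
            t_vol[atlas.labels == r] = v
        tmap = TStatMap(t=t_vol[mask], df=10, mask=mask, affine=atlas.affine,
                        betas=pd.DataFrame(), design=np.zeros((2, 2)),
                        design_columns=["intercept", "group"],
                        response=np.zeros((2, int(mask.sum()))))
        means = tx.parcel_mean(tmap, atlas)
        for r, v in t_by_region.items():
            assert means[r] == pytest.approx(v)

    def test_masked_out_region_excluded(self, atlas):
        mask = (atlas.labels != 0) & (atlas.labels != 3)
        rng = np.random.default_rng(0)
        tmap = TStatMap(t=rng.standard_normal(int(mask.sum())), df=10,
                        mask=mask, affine=atlas.affine, betas=pd.DataFrame(),
                        design=np.zeros((2, 2)),
                        design_columns=["intercept", "group"],
                        response=np.zeros((2, int(mask.sum()))))
        means = tx.parcel_mean(tmap, atlas)
        assert 3 not in means.index
        assert len(means) == len(atlas.region_ids) - 1

    def test_matches_double_loop_oracle(self, atlas, rng):
        mask = atlas.labels != 0
        t_flat = rng.standard_normal(int(mask.sum()))
        tmap = TStatMap(t=t_flat, df=10, mask=mask, affine=atlas.affine,
                        betas=pd.DataFrame(), design=np.zeros((2, 2)),
                        design_columns=["intercept", "group"],
                        response=np.zeros((2, int(mask.sum()))))
        means = tx.parcel_mean(tmap, atlas)
        t_vol = tmap.to_volume()
        for r in atlas.region_ids:
            acc, n = 0.0, 0
            for idx in np.argwhere((atlas.labels == r) & mask):
                acc += t_vol[tuple(idx)]
                n += 1
            assert means[int(r)] == pytest.approx(acc / n)


class TestPLS:
    def test_exact_copy_gene_attains_extreme_weights(self, planted):
        y, result = planted
        X = result.matrix.copy()
        X["COPY"] = y
        X["ANTICOPY"] = -y
        res = tx.pls_association(y, X)
        assert res.weights.idxmax() == "COPY"
        assert res.weights.idxmin() == "ANTICOPY"

    def test_matches_independent_nipals_oracle(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 8)),
                         columns=[f"g{i}" for i in range(8)])
        y = pd.Series(rng.standard_normal(10))
        res = tx.pls_association(y, X, standardize=False)
        w, scores = nipals_first_component(X.to_numpy(), y.to_numpy())
        if np.corrcoef(scores, y - y.mean())[0, 1] < 0:
            w = -w
        np.testing.assert_allclose(res.weights.to_numpy(), w, atol=1e-8)

    def test_region_permutation_invariance(self, planted, rng):
        y, result = planted
        res = tx.pls_association(y, result.matrix)
        perm = rng.permutation(len(y))
        res_p = tx.pls_association(y.iloc[perm], result.matrix.iloc[perm])
        pd.testing.assert_series_equal(res.weights, res_p.weights)

    def test_single_gene_weight_is_sign_of_covariance(self, rng):
        y = pd.Series(rng.standard_normal(15))
        for sign in (+1.0, -1.0):
            X = pd.DataFrame({"g": sign * y + 0.1 * rng.standard_normal(15)})
            res = tx.pls_association(y, X, standardize=False)
            assert np.sign(res.weights["g"]) == sign
            assert abs(abs(res.weights["g"]) - 1.0) < 1e-12

    def test_zero_variance_response_errors(self, planted):
        _, result = planted
        y0 = pd.Series(1.0, index=result.matrix.index)
        with pytest.raises(ValueError, match="zero variance"):
            tx.pls_association(y0, result.matrix)

    def test_planted_recovery_auc(self, planted):
        y, result = planted
        res = tx.pls_association(y, result.matrix)
        auc = tx.recovery_auc(res.weights,
                              set(result.planted_pos + result.planted_neg))
        assert auc >= 0.9


class TestBootstrapAndRanking:
    def test_bootstrap_reproducible_and_separates_planted(self, planted):
        y, result = planted
        z1 = tx.bootstrap_weights(y, result.matrix, n_boot=150, seed=9)
        z2 = tx.bootstrap_weights(y, result.matrix, n_boot=150, seed=9)
        pd.testing.assert_series_equal(z1, z2)
        planted_z = z1[result.planted_pos].abs().min()
        null_q95 = z1.drop(result.planted_pos
                           + result.planted_neg).abs().quantile(0.95)
        assert planted_z > null_q95

    def test_rank_genes_disjoint_and_ordered(self, planted):
        y, result = planted
        res = tx.pls_association(y, result.matrix)
        ranking = tx.rank_genes(res, n_top=20)
        assert not set(ranking.positive) & set(ranking.negative)
        weights = res.weights
        assert weights[ranking.positive[0]] == weights.max()
        assert weights[ranking.negative[0]] == weights.min()

    def test_rank_n_top_one_on_copy_fixture(self, planted):
        y, result = planted
        X = result.matrix.copy()
        X["COPY"] = y
        res = tx.pls_association(y, X)
        ranking = tx.rank_genes(res, n_top=1)
        assert ranking.positive == ["COPY"]

    def test_rank_too_large_errors(self, planted):
        y, result = planted
        res = tx.pls_association(y, result.matrix)
        with pytest.raises(ValueError, match="exceeds"):
            tx.rank_genes(res, n_top=len(res.weights))
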