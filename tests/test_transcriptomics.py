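"""Gene scoring, ensemble enrichment nulls, and PLS component checks."""

import numpy as np
import pandas as pd
import pytest

from crpmap.spatial import surrogate_maps
from crpmap.synthetic import _grf, generate_expression
from crpmap.transcriptomics import (gcea_ensemble, gene_score, normalize_srs,
                                    pls_first_component, pls_permutation_p,
                                    select_top_loadings)


@pytest.fixture(scope="module")
def planted_data(small_atlas):
    expr, cats, pheno = generate_expression(small_atlas, n_genes=200,
                                            seed=11)
    return expr, cats, pheno


class TestGeneScore:
    def test_gene_identical_to_phenotype_scores_one(self, rng):
        pheno = rng.standard_normal(30)
        expr = pd.DataFrame({"g1": pheno, "g2": -pheno})
        s = gene_score(expr, pheno)
        assert s["g1"] == pytest.approx(1.0)
        assert s["g2"] == pytest.approx(-1.0)

    def test_random_gene_scores_zero_on_average(self, rng):
        pheno = rng.standard_normal(40)
        expr = pd.DataFrame(rng.standard_normal((40, 1000)),
                            columns=[f"g{i}" for i in range(1000)])
        assert gene_score(expr, pheno).mean() == pytest.approx(0.0,
                                                               abs=0.02)

    def test_spearman_invariant_to_monotone_transform(self, rng):
        pheno = rng.standard_normal(25)
        g = rng.standard_normal(25)
        a = gene_score(pd.DataFrame({"g": g}), pheno, "spearman")["g"]
        b = gene_score(pd.DataFrame({"g": np.exp(g)}), pheno,
                       "spearman")["g"]
        assert a == pytest.approx(b)


class TestGcea:
    def test_planted_category_attains_minimum_p(self, planted_data,
                                                small_atlas):
        expr, cats, pheno = planted_data
        surr = surrogate_maps(pheno, small_atlas.centroids, 500, seed=1)
        res = gcea_ensemble(expr, pheno, cats, surr)
        assert res.iloc[0]["category_id"] == "planted"
        assert res.iloc[0]["p_ens"] < 0.05
        assert cats["category_id"].nunique() >= 20

    def test_identity_surrogates_give_floor_p_for_perfect_category(
            self, rng):
        """With the surrogate ensemble replaced by copies of the phenotype,
        a category holding a perfectly correlated gene reaches the p floor
        1/(n+1)."""
        pheno = rng.standard_normal(30)
        expr = pd.DataFrame({"hit": pheno,
                             **{f"g{i}": rng.standard_normal(30)
                                for i in range(8)}})
        cats = pd.DataFrame({"category_id": ["c1"] * 5,
                             "gene_id": ["hit", "g0", "g1", "g2", "g3"]})
        surr = np.tile(pheno, (49, 1))
        res = gcea_ensemble(expr, pheno, cats, surr, min_size=5)
        # the category scores exactly its own null -> every null tie counts
        assert res.iloc[0]["p_ens"] == pytest.approx(1.0)
        cats1 = pd.DataFrame({"category_id": ["c1"], "gene_id": ["hit"]})
        res1 = gcea_ensemble(expr, pheno, cats1, surr, min_size=1)
        assert res1.iloc[0]["p_ens"] == pytest.approx(1.0)

    def test_empty_surrogate_ensemble_rejected(self, rng):
        pheno = rng.standard_normal(20)
        expr = pd.DataFrame({"g": rng.standard_normal(20)})
        cats = pd.DataFrame({"category_id": ["c"], "gene_id": ["g"]})
        with pytest.raises(ValueError):
            gcea_ensemble(expr, pheno, cats, np.empty((0, 20)))

    def test_small_categories_skipped(self, rng):
        pheno = rng.standard_normal(20)
        expr = pd.DataFrame(rng.standard_normal((20, 10)),
                            columns=[f"g{i}" for i in range(10)])
        cats = pd.DataFrame({
            "category_id": ["tiny"] * 2 + ["ok"] * 6,
            "gene_id": [f"g{i}" for i in range(8)]})
        surr = rng.standard_normal((20, 20))
        res = gcea_ensemble(expr, pheno, cats, surr, min_size=5)
        assert list(res["category_id"]) == ["ok"]

    def test_null_category_p_roughly_uniform(self, small_atlas):
        """Categories of spatially smooth but unrelated genes get ensemble
        p-values without gross anti-conservatism."""
        ps = []
        for rep in range(15):
            r = np.random.default_rng(900 + rep)
            pheno = _grf(small_atlas.centroids, 1, 30.0, r)[0]
            genes = _grf(small_atlas.centroids, 12, 30.0, r).T
            expr = pd.DataFrame(genes,
                                columns=[f"g{i}" for i in range(12)])
            cats = pd.DataFrame({"category_id": ["c"] * 12,
                                 "gene_id": expr.columns})
            surr = surrogate_maps(pheno, small_atlas.centroids, 99,
                                  seed=rep)
            ps.append(gcea_ensemble(expr, pheno, cats, surr)
                      .iloc[0]["p_ens"])
        assert np.mean(np.array(ps) < 0.05) <= 0.2
        assert np.mean(ps) == pytest.approx(0.5, abs=0.25)


class TestPls:
    def test_first_component_matches_svd_oracle(self, rng):
        """On 10x6 matrices the first PLS weight vector is the leading
        left singular vector of the cross-covariance X'y."""
        X = rng.standard_normal((10, 6))
        y = rng.standard_normal(10)
        expr = pd.DataFrame(X, columns=[f"g{i}" for i in range(6)])
        res = pls_first_component(expr, y)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        ys = y - y.mean()
        w_oracle = Xs.T @ ys
        w_oracle /= np.linalg.norm(w_oracle)
        w = res.loadings.to_numpy()
        w = w / np.linalg.norm(w)
        align = abs(float(w @ w_oracle))
        assert align == pytest.approx(1.0, abs=1e-8)
        scores_oracle = Xs @ w_oracle
        r = abs(np.corrcoef(res.scores, scores_oracle)[0, 1])
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_single_informative_gene_gets_top_loading(self, rng):
        y = rng.standard_normal(40)
        X = rng.standard_normal((40, 20))
        X[:, 7] = y + 0.1 * rng.standard_normal(40)
        expr = pd.DataFrame(X, columns=[f"g{i}" for i in range(20)])
        res = pls_first_component(expr, y)
        assert res.loadings.abs().idxmax() == "g7"
        assert res.r > 0.8

    def test_duplicated_informative_gene_shares_top_loadings(self, rng):
        y = rng.standard_normal(40)
        X = rng.standard_normal((40, 12))
        X[:, 3] = y + 0.1 * rng.standard_normal(40)
        X[:, 9] = X[:, 3]
        expr = pd.DataFrame(X, columns=[f"g{i}" for i in range(12)])
        res = pls_first_component(expr, y)
        top2 = set(res.loadings.abs().nlargest(2).index)
        assert top2 == {"g3", "g9"}

    def test_orthogonal_phenotype_gives_small_r(self, rng):
        X = rng.standard_normal((200, 5))
        y = rng.standard_normal(200)
        expr = pd.DataFrame(X, columns=[f"g{i}" for i in range(5)])
        assert pls_first_component(expr, y).r < 0.3

    def test_permutation_p_detects_planted_signal(self, planted_data,
                                                  small_atlas):
        expr, cats, pheno = planted_data
        surr = surrogate_maps(pheno, small_atlas.centroids, 199, seed=4)
        p, r_null = pls_permutation_p(expr, pheno, surr)
        assert p < 0.05
        p2, _ = pls_permutation_p(expr, pheno, surr)
        assert p == p2  # deterministic given the same ensemble


class TestTopLoadings:
    def test_budget_split_matches_reported_counts(self, rng):
        """A shared floor(0.25*n) budget split by sign: 5013 genes ->
        1253 selected in total."""
        loadings = pd.Series(rng.standard_normal(5013),
                             index=[f"g{i}" for i in range(5013)])
        pos, neg = select_top_loadings(loadings, 0.25)
        assert len(pos) + len(neg) == 1253
        assert not set(pos) & set(neg)

    def test_all_positive_loadings_empty_negative_set(self):
        loadings = pd.Series([0.5, 1.0, 2.0], index=list("abc"))
        pos, neg = select_top_loadings(loadings, 0.25)
        assert neg == []

    def test_fraction_one_selects_everything(self, rng):
        loadings = pd.Series(rng.standard_normal(40),
                             index=[f"g{i}" for i in range(40)])
        pos, neg = select_top_loadings(loadings, 1.0)
        assert len(pos) + len(neg) == 40

    def test_invariant_to_positive_rescaling(self, rng):
        loadings = pd.Series(rng.standard_normal(100),
                             index=[f"g{i}" for i in range(100)])
        a = select_top_loadings(loadings)
        b = select_top_loadings(loadings * 17.3)
        assert a == b


def test_srs_normalization_bounded_and_monotone(rng):
    expr = pd.DataFrame(rng.standard_normal((30, 5)) * 10 + 3,
                        columns=list("abcde"))
    out = normalize_srs(expr)
    assert ((out >= 0) & (out <= 1)).all().all()
    order_in = np.argsort(expr["a"].to_numpy())
    order_out = np.argsort(out["a"].to_numpy())
    np.testing.assert_array_equal(order_in, order_out)
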