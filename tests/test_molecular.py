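"""Molecular association: parcel profiles, gene correlations, hubs,
Spearman receptor association and its permutation null."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from benfc.molecular import (
    gene_map_correlation,
    hub_genes,
    parcel_profile,
    rank_regions_by_expression,
    receptor_permutation_test,
    receptor_spearman,
    select_associated_genes,
)
from benfc.synth import make_map_cohort
from benfc.types import (
    BrainMask,
    ExpressionMatrix,
    ParcelAtlas,
    ParcelProfile,
    ScalarMap,
    VolumeGrid,
)


@pytest.fixture()
def toy_atlas():
    grid = VolumeGrid.isotropic((4, 2, 2), 3.0)
    labels = np.zeros(grid.dims, dtype=np.int32)
    labels[0, 0, 0] = 1
    labels[0, 1, 0] = 1
    labels[3, 0, 0] = 2
    labels[3, 1, 0] = 2
    return ParcelAtlas(grid, labels)


class TestParcelProfile:
    def test_constant_map_gives_constant_profile(self, toy_atlas):
        m = ScalarMap(toy_atlas.grid, np.full(toy_atlas.grid.dims, 3.0), "t")
        prof = parcel_profile(m, toy_atlas)
        assert np.allclose(prof.values, 3.0)

    def test_two_parcel_hand_means(self, toy_atlas):
        v = np.zeros(toy_atlas.grid.dims)
        v[0, 0, 0], v[0, 1, 0] = 1.0, 1.0
        v[3, 0, 0], v[3, 1, 0] = 3.0, 5.0
        prof = parcel_profile(ScalarMap(toy_atlas.grid, v, "t"), toy_atlas)
        assert np.allclose(prof.values, [1.0, 4.0])

    def test_fully_undefined_parcel_is_nan(self, toy_atlas):
        v = np.zeros(toy_atlas.grid.dims)
        v[3, :, 0] = np.nan
        prof = parcel_profile(ScalarMap(toy_atlas.grid, v, "t"), toy_atlas)
        assert np.isnan(prof.values[1]) and np.isfinite(prof.values[0])

    def test_hemisphere_split(self, toy_atlas):
        # RAS+ grid centered at 0: x-index 0 is left, 3 is right
        assert toy_atlas.hemisphere[1] == "left"
        assert toy_atlas.hemisphere[2] == "right"
        m = ScalarMap(toy_atlas.grid, np.ones(toy_atlas.grid.dims), "t")
        assert parcel_profile(m, toy_atlas, "left").parcel_ids == [1]


def profile_of(values):
    return ParcelProfile(list(range(1, len(values) + 1)), np.asarray(values, float))


class TestGeneCorrelation:
    def make_expr(self, cols, symbols=None):
        cols = np.asarray(cols, float)
        symbols = symbols or [f"G{j}" for j in range(cols.shape[1])]
        return ExpressionMatrix(list(range(1, cols.shape[0] + 1)), symbols, cols)

    def test_planted_gene_perfect_correlation(self, rng):
        prof = profile_of(rng.standard_normal(30))
        expr = self.make_expr(
            np.column_stack([prof.values * 2 + 1, rng.standard_normal(30)]),
            ["HIT", "NOISE"],
        )
        out = gene_map_correlation(expr, prof)
        hit = out.set_index("gene").loc["HIT"]
        assert hit.r == pytest.approx(1.0)
        assert hit.q == out.q.min()

    def test_antisymmetric_gene(self, rng):
        prof = profile_of(rng.standard_normal(30))
        expr = self.make_expr(np.column_stack([-prof.values]), ["NEG"])
        out = gene_map_correlation(expr, prof)
        assert out.r.iloc[0] == pytest.approx(-1.0)

    def test_matches_scipy_loop_oracle(self, rng):
        prof = profile_of(rng.standard_normal(40))
        X = rng.standard_normal((40, 25))
        out = gene_map_correlation(self.make_expr(X), prof)
        for j in range(25):
            r_ref, p_ref = sps.pearsonr(X[:, j], prof.values)
            assert out.r.iloc[j] == pytest.approx(r_ref, abs=1e-12)
            assert out.p.iloc[j] == pytest.approx(p_ref, rel=1e-8)

    def test_too_few_parcels_raise(self, rng):
        prof = profile_of(rng.standard_normal(5))
        expr = self.make_expr(rng.standard_normal((5, 3)))
        with pytest.raises(ValueError, match="shared parcels"):
            gene_map_correlation(expr, prof)

    def test_constant_column_excluded_with_warning(self, rng):
        prof = profile_of(rng.standard_normal(20))
        X = rng.standard_normal((20, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            out = gene_map_correlation(self.make_expr(X), prof)
        assert len(out) == 2


class TestGeneSelection:
    def test_boundary_inclusive(self):
        df = pd.DataFrame(
            {"gene": ["a", "b", "c", "d"], "r": [0.3, 0.15, 0.149, -0.2],
             "p": [0.001] * 4, "q": [0.01] * 4}
        )
        assert select_associated_genes(df) == ["a", "b", "d"]

    def test_empty_in_empty_out(self):
        assert select_associated_genes(pd.DataFrame()) == []

    def test_q_requirement_shrinks_list(self):
        df = pd.DataFrame(
            {"gene": ["a", "b"], "r": [0.5, 0.5], "p": [0.001, 0.2],
             "q": [0.01, 0.4]}
        )
        with_q = select_associated_genes(df, require_q=True)
        without = select_associated_genes(df, require_q=False)
        assert set(with_q) <= set(without)
        assert with_q == ["a"]


class TestHubGenes:
    def star_edges(self):
        return pd.DataFrame(
            {"gene_a": ["hub"] * 5,
             "gene_b": [f"leaf{i}" for i in range(5)],
             "confidence": [0.95] * 5}
        )

    def test_star_hand_computation(self):
        deg, hubs = hub_genes(self.star_edges())
        assert dict(zip(deg.gene, deg.degree))["hub"] == 5
        # degrees [5,1,1,1,1,1]: mean 1.667, pop SD 1.491, cutoff 3.158
        assert hubs == ["hub"]

    def test_complete_graph_has_no_hubs(self):
        rows = [(a, b) for i, a in enumerate("abcd") for b in "abcd"[i + 1:]]
        edges = pd.DataFrame(
            {"gene_a": [r[0] for r in rows], "gene_b": [r[1] for r in rows],
             "confidence": [0.95] * len(rows)}
        )
        deg, hubs = hub_genes(edges)
        assert set(deg.degree) == {3}
        assert hubs == []  # SD 0, strict inequality

    def test_all_edges_below_confidence_raise(self):
        e = self.star_edges()
        e["confidence"] = 0.8
        with pytest.raises(ValueError, match="confidence"):
            hub_genes(e)

    def test_isolated_nodes_counted_when_supplied(self):
        deg, _ = hub_genes(self.star_edges(), nodes=["hub", "lonely"])
        assert dict(zip(deg.gene, deg.degree))["lonely"] == 0


class TestRegionRanking:
    def make_expr(self):
        vals = np.array([[1.0], [3.0], [2.0], [3.0]])
        return ExpressionMatrix([10, 20, 30, 40], ["NR3C1"], vals)

    def test_descending_order_with_tie_break(self):
        top = rank_regions_by_expression(self.make_expr(), "NR3C1", k=10)
        assert top.parcel_id.tolist() == [20, 40, 30, 10]  # tie: lower id first

    def test_unknown_gene_raises(self):
        with pytest.raises(KeyError):
            rank_regions_by_expression(self.make_expr(), "NOPE")


class TestReceptorSpearman:
    def test_monotone_transform_is_one(self, rng):
        x = rng.standard_normal(30)
        assert receptor_spearman(x, np.exp(x)) == pytest.approx(1.0)

    def test_reversed_ranks_minus_one(self, rng):
        x = rng.standard_normal(30)
        assert receptor_spearman(x, -x) == pytest.approx(-1.0)

    def test_ties_match_hand_ranked_pearson(self):
        a = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        b = np.array([2.0, 1.0, 4.0, 4.0, 4.0, 6.0, 7.0, 5.0, 9.0, 8.0])
        ra = sps.rankdata(a)
        rb = sps.rankdata(b)
        hand = sps.pearsonr(ra, rb).statistic
        assert receptor_spearman(a, b) == pytest.approx(hand, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            receptor_spearman(np.ones(12), np.arange(12.0))


class TestReceptorPermutation:
    @pytest.fixture()
    def setup(self):
        grid = VolumeGrid.isotropic((8, 8, 8), 3.0)
        mask = BrainMask(grid, np.ones(grid.dims, bool))
        effect = np.zeros(grid.dims)
        effect[2:5, 2:5, 2:5] = 1.0
        eff_map = ScalarMap(grid, effect, "t")
        pre, post = make_map_cohort(mask, n_subjects=12, effect=eff_map,
                                    effect_scale=1.5, seed=11)
        return mask, pre, post

    def test_observed_tmap_as_receptor_attains_lower_bound(self, setup):
        mask, pre, post = setup
        from benfc.stats import paired_t_map

        tmap = paired_t_map(pre, post).t
        res = receptor_permutation_test(
            pre, post, {"self": tmap}, mask=mask, B=200, seed=0
        )[0]
        assert res.observed_rho == pytest.approx(1.0)
        assert res.p_raw == pytest.approx(1.0 / 201.0)

    def test_bit_reproducible_under_seed(self, setup):
        mask, pre, post = setup
        rec = {"a": pre[0], "b": post[0]}
        r1 = receptor_permutation_test(pre, post, rec, mask=mask, B=150, seed=5)
        r2 = receptor_permutation_test(pre, post, rec, mask=mask, B=150, seed=5)
        for a, b in zip(r1, r2):
            assert a.p_raw == b.p_raw
            assert np.array_equal(a.null_rhos, b.null_rhos)

    def test_bonferroni_factor_is_map_count(self, setup):
        mask, pre, post = setup
        rec = {f"m{i}": pre[i] for i in range(3)}
        res = receptor_permutation_test(pre, post, rec, mask=mask, B=120, seed=2)
        for r in res:
            assert r.p_bonferroni == pytest.approx(min(1.0, 3 * r.p_raw))

    def test_unpaired_inputs_raise(self, setup):
        mask, pre, post = setup
        with pytest.raises(ValueError, match="unpaired"):
            receptor_permutation_test(pre, post[:-1], {"a": pre[0]}, mask=mask)
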