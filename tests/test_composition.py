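import itertools

import numpy as np
import pandas as pd
import pytest

from rusfresp import composition
from rusfresp.composition import _pseudo_f
from rusfresp.data_io import TAXONOMIC_RANKS, AsvCountTable, TaxonomyMap
from rusfresp.errors import EmptySampleError, ValidationError

from conftest import keyed_frame


def counts_table(values, columns=None):
    df = keyed_frame(np.asarray(values), columns=columns)
    return AsvCountTable(df.astype(int))


def toy_taxonomy():
    rows = {
        "ASV1": ("P1", "X", "o", "F1", "g1"),
        "ASV2": ("P1", "X", "o", "F1", "g2"),
        "ASV3": ("P2", "Y", "o", "F2", "g3"),
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(TAXONOMIC_RANKS))
    return TaxonomyMap(df)


class TestRelativeAbundance:
    def test_simple_proportions(self):
        table = counts_table([[5, 0, 15]])
        rel = composition.relative_abundance(table)
        assert list(rel.iloc[0]) == [0.25, 0.0, 0.75]

    def test_zero_total_row_names_sample(self):
        table = counts_table([[1, 1], [0, 0]])
        with pytest.raises(EmptySampleError, match="S01"):
            composition.relative_abundance(table)


class TestAggregateTaxa:
    def test_sums_by_class(self):
        table = counts_table([[4, 6, 1]], columns=["ASV1", "ASV2", "ASV3"])
        agg = composition.aggregate_taxa(table, toy_taxonomy(), "class")
        assert agg.data.iloc[0].to_dict() == {"X": 10, "Y": 1}

    def test_unmapped_asvs_pool_under_unassigned(self):
        table = counts_table([[4, 6]], columns=["ASVA", "ASVB"])
        agg = composition.aggregate_taxa(table, toy_taxonomy(), "class")
        assert list(agg.data.columns) == ["unassigned"]
        assert int(agg.data.iloc[0, 0]) == 10

    def test_aggregation_commutes_with_normalization(self):
        rng = np.random.default_rng(0)
        table = counts_table(
            rng.integers(1, 50, size=(6, 3)), columns=["ASV1", "ASV2", "ASV3"]
        )
        tax = toy_taxonomy()
        a = composition.relative_abundance(composition.aggregate_taxa(table, tax, "family"))
        rel = composition.relative_abundance(table)
        b = rel.T.groupby(tax.rank_labels(rel.columns, "family").to_numpy()).sum().T
        b = b[a.columns]
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)


class TestAlphaDiversity:
    @pytest.mark.parametrize(
        "row, richness, simpson",
        [([50, 50], 2, 0.5), ([100, 0], 1, 0.0), ([1, 1, 1, 1], 4, 0.75)],
    )
    def test_known_values(self, row, richness, simpson):
        table = counts_table([row])
        div = composition.alpha_diversity(table)
        assert div["richness"].iloc[0] == richness
        assert div["simpson"].iloc[0] == pytest.approx(simpson)


class TestBrayCurtis:
    def test_known_values(self):
        table = counts_table([[6, 2], [2, 2], [6, 2]])
        d = composition.bray_curtis(table)
        assert d.iloc[0, 1] == pytest.approx(1 / 3)
        assert d.iloc[0, 2] == 0.0

    def test_disjoint_supports_give_one(self):
        d = composition.bray_curtis(counts_table([[2, 0], [0, 2]]))
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_bounds_symmetry_and_composition_invariance(self):
        rng = np.random.default_rng(0)
        table = counts_table(rng.integers(1, 100, size=(8, 10)))
        d = composition.bray_curtis(table)
        arr = d.to_numpy()
        assert (arr >= 0).all() and (arr <= 1).all()
        assert np.allclose(arr, arr.T) and np.allclose(np.diag(arr), 0)
        rel = composition.relative_abundance(table)
        d_rel = composition.bray_curtis(rel)
        d_rel_scaled = composition.bray_curtis(rel * 7.0)
        assert np.allclose(d_rel.to_numpy(), d_rel_scaled.to_numpy(), atol=1e-12)


class TestNmds:
    def test_collinear_points_embed_with_negligible_stress(self):
        from scipy.spatial.distance import pdist, squareform

        pts = np.arange(10.0)[:, None]
        d = pd.DataFrame(squareform(pdist(pts)))
        res = composition.nmds(d, seed=0)
        assert res.stress < 0.01

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(1)
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(rng.normal(size=(12, 4)))))
        a = composition.nmds(d, seed=5)
        b = composition.nmds(d, seed=5)
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)

    def test_stress_non_increasing_on_random_input(self):
        rng = np.random.default_rng(2)
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(rng.normal(size=(20, 6)))))
        res = composition.nmds(d, seed=0)
        assert (np.diff(res.stress_path) <= 1e-12).all()

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValidationError):
            composition.nmds(pd.DataFrame(np.pad(d, ((0, 1), (0, 1)))), seed=0)


class TestPermanova:
    @staticmethod
    def _random_instance(rng, shift):
        from scipy.spatial.distance import pdist, squareform

        X = rng.normal(size=(6, 4))
        X[:3] += shift
        return pd.DataFrame(squareform(pdist(X)))

    def test_perfect_clusters_reach_minimum_p(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(0)
        X = np.r_[np.zeros((8, 2)), np.ones((8, 2)) * 50] + rng.normal(scale=0.1, size=(16, 2))
        d = pd.DataFrame(squareform(pdist(X)))
        res = composition.permanova(d, ["a"] * 8 + ["b"] * 8, n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_matches_exhaustive_enumeration_on_three_vs_three(self):
        rng = np.random.default_rng(0)
        labels = np.array(["a"] * 3 + ["b"] * 3)
        for inst in range(5):
            d = self._random_instance(rng, rng.normal())
            res = composition.permanova(d, labels, n_perm=4999, seed=inst)
            d2 = d.to_numpy() ** 2
            obs = _pseudo_f(d2, np.array([0, 0, 0, 1, 1, 1]), 2)
            fs = []
            for comb in itertools.combinations(range(6), 3):
                codes = np.zeros(6, int)
                codes[list(comb)] = 1
                fs.append(_pseudo_f(d2, codes, 2))
            exact_p = np.mean([f >= obs - 1e-12 for f in fs])
            assert abs(res.p_value - exact_p) <= 0.03

    def test_pseudo_f_matches_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(3)
        X = rng.normal(size=(14, 5))
        X[:7] += 1.0
        d = squareform(pdist(X))
        labels = ["a"] * 7 + ["b"] * 7
        mine = composition.permanova(pd.DataFrame(d), np.array(labels), n_perm=9, seed=0)
        theirs = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(d), labels, permutations=9
        )
        assert mine.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_small_group_rejected(self):
        d = pd.DataFrame(np.zeros((4, 4)))
        with pytest.raises(ValidationError):
            composition.permanova(d, ["a", "b", "b", "b"], n_perm=9, seed=0)


class TestMultilevelComposition:
    def test_single_lineage_blocks_are_constant_100(self):
        tax = TaxonomyMap(
            pd.DataFrame(
                [["P", "C", "O", "F", "G"], ["P", "C", "O", "F", "G"]],
                columns=list(TAXONOMIC_RANKS),
                index=["ASV1", "ASV2"],
            )
        )
        table = counts_table([[3, 7], [5, 5]], columns=["ASV1", "ASV2"])
        multi = composition.multilevel_composition(table, tax)
        assert np.allclose(multi.to_numpy(), 100.0)
        assert list(multi.columns) == ["phylum:P", "class:C", "family:F"]

    def test_block_row_sums_and_column_count(self, cohort):
        counts = cohort.asv.at_timepoint(9)
        multi = composition.multilevel_composition(counts, cohort.taxonomy)
        for rank in ("phylum", "class", "family"):
            block = multi[[c for c in multi.columns if c.startswith(rank + ":")]]
            assert np.allclose(block.sum(axis=1), 100.0)
        n_expected = sum(
            cohort.taxonomy.data[rank].nunique() for rank in ("phylum", "class", "family")
        )
        assert multi.shape[1] == n_expected


class TestCorrelationEdges:
    def test_scaled_copy_and_anticorrelated_features(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        noise = rng.normal(size=100)
        anti = -0.9 * x + np.sqrt(1 - 0.81) * noise
        df = pd.DataFrame({"anchor": x, "double": 2 * x, "anti": anti})
        edges = composition.correlation_edges(df, ["anchor"])
        assert edges.iloc[0]["feature"] == "double"
        assert edges.iloc[0]["r"] == pytest.approx(1.0)
        assert "anti" in set(edges["feature"])
        assert edges.set_index("feature").loc["anti", "r"] < -0.7

    def test_independent_noise_rarely_crosses_threshold(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                rng.normal(size=(100, 6)), columns=[f"f{i}" for i in range(6)]
            )
            edges = composition.correlation_edges(df, ["f0"])
            hits += len(edges) > 0
        assert hits <= 1

    def test_zero_variance_anchor_warns_and_emits_nothing(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        with pytest.warns(UserWarning):
            edges = composition.correlation_edges(df, ["a"])
        assert len(edges) == 0
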