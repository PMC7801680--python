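import math

import numpy as np
import pandas as pd
import pytest

from fgcn.association import (
    HubReport,
    connectivity_vs_proportion,
    covariate_association,
    cross_region_concordance,
    hub_genes,
    hub_turnover,
    hypergeom_tail,
    marker_enrichment,
    module_eigengene,
    module_overlap,
)
from fgcn.deconv import CELL_TYPES, CellTypeMarkers
from fgcn.io import DataError
from fgcn.lmqcm import GeneModule, GeneModuleCollection
from fgcn.network import FrequencyNetwork

from conftest import make_dataset


def comb(n, k):
    return math.comb(n, k)


class TestModuleEigengene:
    def test_rank_one_module(self, rng):
        profile = rng.normal(0, 1, 30)
        values = np.vstack([3 * profile + 1, -2 * profile + 7, 0.5 * profile])
        ds = make_dataset(values, ["disease"] * 15 + ["control"] * 15)
        eig = module_eigengene(ds.gene_ids, ds)
        assert eig.explained_variance == pytest.approx(1.0)
        # orientation: majority of standardized members (2 of 3 positive slope)
        assert np.corrcoef(eig.scores, profile)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_anticorrelated_pair_tie_rule(self, rng):
        profile = rng.normal(0, 1, 20)
        values = np.vstack([profile, -profile])
        ds = make_dataset(values, ["disease"] * 10 + ["control"] * 10)
        eig = module_eigengene(["g0", "g1"], ds)
        assert eig.explained_variance == pytest.approx(1.0)
        # tie broken toward the lexicographically first gene (g0)
        assert np.corrcoef(eig.scores, profile)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_independent_module_explained_variance(self, rng):
        values = rng.normal(0, 1, size=(10, 200))
        ds = make_dataset(values, ["disease"] * 100 + ["control"] * 100)
        eig = module_eigengene(ds.gene_ids, ds)
        assert eig.explained_variance == pytest.approx(1 / 10, abs=0.05)

    def test_gene_order_and_affine_invariance(self, rng):
        values = rng.normal(0, 1, size=(6, 40))
        values += rng.normal(0, 1, 40)  # shared component fixes orientation
        ds = make_dataset(values, ["disease"] * 20 + ["control"] * 20)
        eig_a = module_eigengene(list(ds.gene_ids), ds)
        rescaled = make_dataset(
            values * rng.uniform(0.5, 2, (6, 1)) + rng.uniform(-3, 3, (6, 1)),
            ds.condition, gene_ids=ds.gene_ids,
        )
        eig_b = module_eigengene(list(reversed(ds.gene_ids)), rescaled)
        assert np.corrcoef(eig_a.scores, eig_b.scores)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_constant_gene_rejected(self, rng):
        values = rng.normal(0, 1, size=(3, 10))
        values[2] = 5.0
        ds = make_dataset(values, ["disease"] * 5 + ["control"] * 5)
        with pytest.raises(DataError, match="g2"):
            module_eigengene(ds.gene_ids, ds)


class TestCovariateAssociation:
    def _tables(self, rng, n=30):
        idx = [f"s{i}" for i in range(n)]
        trait = pd.Series(np.linspace(0, 3, n), index=idx)
        return idx, trait

    def test_monotone_transform_spearman_one(self, rng):
        idx, trait = self._tables(rng)
        scores = pd.DataFrame({"m1": np.exp(trait.to_numpy())}, index=idx)
        cov = pd.DataFrame({"cdr": trait}, index=idx)
        table = covariate_association(scores, cov, method="spearman")
        assert table.loc["m1", "cdr_coef"] == pytest.approx(1.0)

    def test_negated_trait_antisymmetry(self, rng):
        idx, trait = self._tables(rng)
        scores = pd.DataFrame({"m1": -trait.to_numpy()}, index=idx)
        cov = pd.DataFrame({"cdr": trait}, index=idx)
        table = covariate_association(scores, cov, method="spearman")
        assert table.loc["m1", "cdr_coef"] == pytest.approx(-1.0)

    def test_bonferroni_family_size(self, rng):
        # 29 rows x 3 covariates -> 0.05 / 87
        idx = [f"s{i}" for i in range(20)]
        scores = pd.DataFrame(
            rng.normal(0, 1, size=(20, 29)), index=idx,
            columns=[f"m{i}" for i in range(29)],
        )
        cov = pd.DataFrame(
            rng.normal(0, 1, size=(20, 3)), index=idx,
            columns=["cdr", "bb_score", "plaque_mean"],
        )
        table = covariate_association(scores, cov, method="spearman")
        assert table.attrs["bonferroni_cutoff"] == pytest.approx(0.05 / 87)
        assert table.attrs["bonferroni_cutoff"] == pytest.approx(5.7e-4, rel=0.01)

    def test_ranking_by_mean_abs_coefficient(self, rng):
        idx = [f"s{i}" for i in range(25)]
        trait = np.linspace(0, 1, 25)
        scores = pd.DataFrame(
            {"strong": trait + rng.normal(0, 0.01, 25),
             "weak": rng.normal(0, 1, 25)},
            index=idx,
        )
        cov = pd.DataFrame({"cdr": trait}, index=idx)
        table = covariate_association(scores, cov, method="pearson")
        assert table.loc["strong", "rank"] == 1
        assert table.index[0] == "strong"

    def test_too_few_shared_samples(self, rng):
        scores = pd.DataFrame({"m1": [1, 2]}, index=["a", "b"])
        cov = pd.DataFrame({"cdr": [1, 2]}, index=["a", "b"])
        with pytest.raises(DataError, match=">= 3"):
            covariate_association(scores, cov)


class TestMarkerEnrichment:
    def _markers(self, universe, per_type=10):
        markers = {}
        for t, ct in enumerate(CELL_TYPES):
            markers[ct] = universe[t * per_type:(t + 1) * per_type]
        return CellTypeMarkers(markers=markers)

    def test_no_overlap_no_assignment(self):
        universe = [f"g{i}" for i in range(200)]
        markers = self._markers(universe)
        module = GeneModule("AD1", members=universe[100:110])
        table = marker_enrichment(module, markers, universe)
        assert (table["p"] == 1.0).all()
        assert table.attrs["assigned_type"] is None

    def test_module_equals_marker_set(self):
        universe = [f"g{i}" for i in range(1000)]
        markers = {ct: universe[t * 50:(t + 1) * 50] for t, ct in enumerate(CELL_TYPES)}
        module = GeneModule("AD1", members=markers["neu"])
        table = marker_enrichment(module, CellTypeMarkers(markers=markers), universe)
        row = table.set_index("cell_type").loc["neu"]
        assert row["p"] == pytest.approx(1 / comb(1000, 50), rel=1e-9)
        assert table.attrs["assigned_type"] == "neu"

    def test_exact_tail_sum(self):
        # module 10, overlap 5 with a 50-marker set, universe 1000
        expected = sum(
            comb(50, k) * comb(950, 10 - k) for k in range(5, 11)
        ) / comb(1000, 10)
        assert hypergeom_tail(5, 10, 50, 1000) == pytest.approx(expected, rel=1e-12)

    def test_exhaustive_small_instances(self):
        # all instances with universe <= 200 per the acceptance contract,
        # sampled on a grid for runtime
        for big_g in (20, 50, 120, 200):
            for big_k in (1, 5, 17, 30):
                if big_k > big_g:
                    continue
                for m in (1, 6, 13, 20):
                    if m > big_g:
                        continue
                    for k in range(0, min(m, big_k) + 1):
                        expected = sum(
                            comb(big_k, j) * comb(big_g - big_k, m - j)
                            for j in range(k, min(m, big_k) + 1)
                        ) / comb(big_g, m)
                        assert hypergeom_tail(k, m, big_k, big_g) == pytest.approx(
                            expected, rel=1e-9
                        ), (big_g, big_k, m, k)

    def test_module_outside_background_rejected(self):
        universe = [f"g{i}" for i in range(100)]
        markers = self._markers(universe)
        module = GeneModule("AD1", members=["alien1", "alien2"])
        with pytest.raises(DataError, match="background"):
            marker_enrichment(module, markers, universe)


class TestModuleOverlap:
    def _coll(self, prefix, member_lists):
        return GeneModuleCollection(
            modules=[GeneModule(f"{prefix}{i+1}", m) for i, m in enumerate(member_lists)]
        )

    def test_identical_modules(self):
        a = self._coll("AD", [["x", "y", "z"]])
        b = self._coll("N", [["x", "y", "z"]])
        assert module_overlap(a, b).iloc[0, 0] == 1.0

    def test_disjoint_modules(self):
        a = self._coll("AD", [["x", "y"]])
        b = self._coll("N", [["p", "q"]])
        assert module_overlap(a, b).iloc[0, 0] == 0.0

    def test_half_overlap(self):
        a = self._coll("AD", [["A", "B", "C"]])
        b = self._coll("N", [["B", "C", "D"]])
        table = module_overlap(a, b)
        assert table.iloc[0, 0] == pytest.approx(0.5)
        assert table.attrs["shared_pairs"] == [("AD1", "N1")]


class TestHubTurnover:
    def _net(self, edges):
        nodes = sorted({g for pair in edges for g in pair})
        return FrequencyNetwork(nodes=nodes, edges=edges, n_datasets=5)

    def test_identical_networks_no_turnover(self):
        net = self._net({("a", "b"): 1.0, ("b", "c"): 0.6})
        report = hub_turnover(net, net)
        assert report.gained == set() and report.lost == set()

    def test_hundred_nodes_five_hubs(self):
        # weighted path v0..v99 with increasing weights plus one closing edge,
        # chosen so all 100 weighted degrees are distinct:
        # d(v0) = 501/1000, d(vi) = (2i+1)/1000 for 1 <= i <= 98, d(v99) = 599/1000
        nodes = [f"v{i:02d}" for i in range(100)]
        edges = {}
        for i in range(99):
            edges[(nodes[i], nodes[i + 1])] = (i + 1) / 1000
        edges[(nodes[0], nodes[99])] = 500 / 1000
        net = FrequencyNetwork(nodes=nodes, edges=edges, n_datasets=1000)
        hubs = hub_genes(net, pct=5)
        assert len(hubs) == 5
        assert hubs == {"v99", "v00", "v98", "v97", "v96"}

    def test_gained_hub_set_algebra(self):
        # x is a hub only in the disease network; node universes match
        net_d = self._net({
            ("a", "b"): 0.2, ("c", "d"): 0.2, ("d", "e"): 0.2,
            ("a", "x"): 1.0, ("b", "x"): 1.0, ("c", "x"): 1.0,
        })
        net_c = self._net({
            ("a", "b"): 1.0, ("c", "d"): 1.0, ("e", "x"): 0.2,
        })
        report = hub_turnover(net_d, net_c, pct=20)
        assert "x" in report.gained
        assert "x" not in report.lost
        assert report.gained & report.lost == set()


class TestConnectivityVsProportion:
    def _setup(self, rng, n=100, n_genes=10, delta=0.0):
        # mutually independent genes so per-gene connectivity signs are
        # close to independent under the null
        genes = [f"g{i}" for i in range(n_genes)]
        props = pd.DataFrame(
            {ct: rng.normal(0, 1, n) for ct in CELL_TYPES},
            index=[f"s{i}" for i in range(n)],
        )
        values = rng.normal(0, 1, size=(n_genes, n))
        if delta:
            # plant a shared component in the low-proportion half only
            order = np.argsort(props["neu"].to_numpy())
            low_half = order[: n // 2]
            boost = rng.normal(0, 1, len(low_half))
            values[:, low_half] += delta * boost
        condition = ["disease"] * (n // 2) + ["control"] * (n - n // 2)
        ds = make_dataset(values, condition, gene_ids=genes)
        return ds, props, genes

    def test_null_split_not_significant_mostly(self):
        pvals = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            ds, props, genes = self._setup(rng)
            table = connectivity_vs_proportion(ds, genes, props, "neu")
            pvals.append(table.attrs["sign_test_p"])
        assert np.mean(np.array(pvals) > 0.05) >= 0.8

    def test_constructed_low_half_signal(self, rng):
        ds, props, genes = self._setup(rng, delta=3.0)
        table = connectivity_vs_proportion(ds, genes, props, "neu")
        assert (table["diff"] < 0).all()
        # all n genes on one side -> p = 2 * (1/2)^n
        assert table.attrs["sign_test_p"] == pytest.approx(2 * 0.5 ** len(genes))

    def test_single_hub_gene_p_one(self, rng):
        ds, props, _ = self._setup(rng)
        table = connectivity_vs_proportion(ds, ["g0"], props, "neu")
        assert table.attrs["sign_test_p"] == 1.0

    def test_too_few_samples_rejected(self, rng):
        ds, props, genes = self._setup(rng, n=6, n_genes=4)
        with pytest.raises(DataError, match=">= 4"):
            connectivity_vs_proportion(ds, genes, props, "neu")


class TestCrossRegionConcordance:
    def test_identical_vectors_cci_one(self, rng):
        v = pd.Series(rng.normal(0, 1, 30), index=[f"subj{i}" for i in range(30)])
        regions = {f"R{k}": v.copy() for k in range(4)}
        assert cross_region_concordance(regions) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self, rng):
        idx = [f"subj{i}" for i in range(5000)]
        regions = {
            f"R{k}": pd.Series(rng.normal(0, 1, 5000), index=idx) for k in range(4)
        }
        assert cross_region_concordance(regions) < 0.05

    def test_two_regions_closed_form(self, rng):
        idx = [f"subj{i}" for i in range(200)]
        a = rng.normal(0, 1, 200)
        b = 0.6 * a + 0.8 * rng.normal(0, 1, 200)
        regions = {"R1": pd.Series(a, index=idx), "R2": pd.Series(b, index=idx)}
        r = np.corrcoef(a, b)[0, 1]
        assert cross_region_concordance(regions) == pytest.approx(abs(r), rel=1e-9)

    def test_unmatched_subjects_listed(self, rng):
        regions = {
            "R1": pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"]),
            "R2": pd.Series([1.0, 2.0, 3.0], index=["a", "b", "d"]),
        }
        with pytest.raises(DataError) as err:
            cross_region_concordance(regions)
        assert "c" in str(err.value) and "d" in str(err.value)


class TestHubReportInvariants:
    def test_gained_lost_disjoint(self):
        report = HubReport(hubs_disease={"a", "b"}, hubs_control={"b", "c"})
        assert report.gained == {"a"}
        assert report.lost == {"c"}
        assert report.gained & report.lost == set()
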