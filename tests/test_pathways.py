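import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chatterjeexi, pearsonr

import spheromap as sp
from spheromap.io import CountMatrix, GeneSetCollection, SpheromapError
from spheromap.pathways import (
    avg_radial_position,
    filter_genesets,
    pathway_fraction_per_cell,
    regress_confounds,
    xi_correlation,
)


def _matrix(counts):
    counts = np.asarray(counts)
    return CountMatrix(
        [f"g{i}" for i in range(counts.shape[0])],
        [f"c{j}" for j in range(counts.shape[1])],
        counts,
    )


class TestPathwayFraction:
    def test_all_genes_sum_to_one(self, rng):
        m = _matrix(rng.poisson(5, size=(6, 10)) + 1)
        frac = pathway_fraction_per_cell(m, m.gene_ids)
        np.testing.assert_allclose(frac, 1.0)

    def test_hand_arithmetic_two_gene_toy(self):
        # 3 + 2 member UMIs out of depth 50 -> 0.1
        counts = np.array([[3], [2], [45]])
        m = _matrix(counts)
        frac = pathway_fraction_per_cell(m, ["g0", "g1"])
        assert frac[0] == pytest.approx(0.1)

    def test_zero_count_set_is_zero_vector(self, rng):
        counts = np.vstack([np.zeros((2, 5), dtype=int),
                            rng.poisson(9, size=(3, 5)) + 1])
        m = _matrix(counts)
        frac = pathway_fraction_per_cell(m, ["g0", "g1"])
        np.testing.assert_array_equal(frac, 0.0)

    def test_disjoint_partition_sums_to_one(self, rng):
        m = _matrix(rng.poisson(4, size=(9, 7)) + 1)
        parts = [m.gene_ids[:3], m.gene_ids[3:5], m.gene_ids[5:]]
        total = sum(pathway_fraction_per_cell(m, p) for p in parts)
        np.testing.assert_allclose(total, 1.0)

    def test_empty_intersection_names_the_set(self, rng):
        m = _matrix(rng.poisson(4, size=(3, 4)) + 1)
        with pytest.raises(SpheromapError, match="mystery"):
            pathway_fraction_per_cell(m, ["nope"], set_name="mystery")


class TestFilterGenesets:
    def test_inclusive_boundary_at_min_genes(self, rng):
        m = _matrix(rng.poisson(3, size=(10, 5)) + 1)
        coll = GeneSetCollection(sets={
            "four": [f"g{i}" for i in range(4)] + ["absent1"],
            "five": [f"g{i}" for i in range(5)],
        })
        kept = filter_genesets(coll, m, min_genes=5)
        assert set(kept.sets) == {"five"}

    def test_kept_sets_match_hand_tally(self, rng):
        m = _matrix(rng.poisson(3, size=(20, 5)) + 1)
        universe = set(m.gene_ids)
        rng2 = np.random.default_rng(5)
        sets = {}
        for k in range(10):
            present = list(rng2.choice(20, size=rng2.integers(2, 9),
                                       replace=False))
            sets[f"S{k}"] = [f"g{i}" for i in present] + [f"x{k}"]
        coll = GeneSetCollection(sets=sets)
        kept = filter_genesets(coll, m, min_genes=5)
        expected = {
            name for name, genes in sets.items()
            if sum(g in universe for g in genes) >= 5
        }
        assert set(kept.sets) == expected


class TestXiCorrelation:
    def test_identity_closed_form(self):
        # no ties: xi(y=x) = 1 - 3/(n+1)
        for n in (5, 10, 50):
            x = np.arange(float(n))
            xi, _ = xi_correlation(x, x, method="asymptotic")
            assert xi == pytest.approx(1 - 3 / (n + 1))

    def test_matches_scipy_reference(self, rng):
        x = rng.normal(size=300)
        y = np.sin(3 * x) + rng.normal(size=300) * 0.2
        xi, p = xi_correlation(x, y, method="asymptotic")
        ref = chatterjeexi(x, y)
        assert xi == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_null_mean_and_variance(self, rng):
        n, reps = 1000, 300
        stats = [
            xi_correlation(rng.normal(size=n), rng.normal(size=n),
                           method="asymptotic")[0]
            for _ in range(reps)
        ]
        stats = np.array(stats)
        assert abs(stats.mean()) <= 3 * np.sqrt(2 / (5 * n) / reps)
        assert stats.var() == pytest.approx(2 / (5 * n), rel=0.25)

    def test_detects_nonmonotone_dependence(self, rng):
        x = rng.uniform(size=1000)
        y = (x - 0.5) ** 2
        xi, p = xi_correlation(x, y)
        assert xi > 0.3 and p < 1e-6
        assert abs(pearsonr(x, y).statistic) < 0.1

    @settings(max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_to_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=120)
        y = x + rng.normal(size=120)
        xi1, _ = xi_correlation(x, y, method="asymptotic", seed=0)
        xi2, _ = xi_correlation(np.exp(x), y**3, method="asymptotic", seed=0)
        assert xi1 == pytest.approx(xi2, abs=1e-12)

    def test_constant_y_degenerate(self):
        xi, p = xi_correlation(np.arange(10.0), np.ones(10))
        assert xi == 0.0 and p == 1.0

    def test_permutation_p_for_small_samples(self, rng):
        x = np.arange(20.0)
        y = x + rng.normal(size=20) * 0.1
        xi, p = xi_correlation(x, y, method="permutation", seed=1)
        assert p < 0.01

    def test_length_mismatch_rejected(self):
        with pytest.raises(SpheromapError):
            xi_correlation([1, 2, 3], [1, 2])


class TestAvgRadialPosition:
    def test_uniform_cells_constant_fraction_centered(self, rng):
        r = rng.uniform(size=5000)
        assert avg_radial_position(np.ones(5000), r) == pytest.approx(0.5,
                                                                      abs=0.02)

    def test_weighted_mean_arithmetic(self):
        r = np.array([0.05] * 10 + [0.95] * 10)
        f = np.array([0.001] * 10 + [0.003] * 10)
        assert avg_radial_position(f, r, n_bins=10) == pytest.approx(0.725)

    def test_top_bin_support(self, rng):
        r = rng.uniform(0.93, 0.99, size=100)
        f = np.ones(100)
        assert avg_radial_position(f, r, 10) == pytest.approx(r.mean())

    def test_all_zero_fractions_error(self):
        with pytest.raises(SpheromapError, match="undefined"):
            avg_radial_position(np.zeros(10), np.linspace(0, 1, 10))


class TestPathwayScan:
    def test_planted_sets_found_with_expected_avgr(self, small_benchmark):
        cells, counts, truth = small_benchmark
        periphery = truth.loc[truth["pattern"] == "periphery", "gene_id"]
        core = truth.loc[truth["pattern"] == "core", "gene_id"]
        null_ids = truth.loc[truth["pattern"] == "flat", "gene_id"].tolist()
        rng = np.random.default_rng(9)
        sets = {
            "planted_periphery": periphery.tolist(),
            "planted_core": core.tolist(),
        }
        for k in range(8):
            sets[f"null_{k}"] = list(rng.choice(null_ids, size=8, replace=False))
        coll = GeneSetCollection(sets=sets)
        table = sp.pathway_spatial_scan(counts, cells, coll, seed=0)
        res = table.set_index("set_name")
        assert res.loc["planted_periphery", "significant"]
        assert res.loc["planted_periphery", "avgR"] > 0.5
        assert res.loc["planted_core", "significant"]
        nulls = table[table["set_name"].str.startswith("null_")]
        assert nulls["significant"].mean() <= 0.25

    def test_shuffled_positions_control_false_positives(self, small_benchmark):
        cells, counts, truth = small_benchmark
        rng = np.random.default_rng(4)
        shuffled_r = rng.permutation([c.radial_position for c in cells])
        cells_shuf = [
            sp.CellProfile(c.cell_id, float(ri), c.depth)
            for c, ri in zip(cells, shuffled_r)
        ]
        null_ids = truth["gene_id"].tolist()
        sets = {
            f"S{k}": list(rng.choice(null_ids, size=10, replace=False))
            for k in range(20)
        }
        table = sp.pathway_spatial_scan(
            counts, cells_shuf, GeneSetCollection(sets=sets), seed=0
        )
        assert table["significant"].sum() <= 0.1 * len(table) + 3

    def test_rerun_identical(self, small_benchmark):
        cells, counts, truth = small_benchmark
        sets = {"A": truth["gene_id"].tolist()[:10],
                "B": truth["gene_id"].tolist()[10:25]}
        coll = GeneSetCollection(sets=sets)
        t1 = sp.pathway_spatial_scan(counts, cells, coll, seed=5)
        t2 = sp.pathway_spatial_scan(counts, cells, coll, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_aggregation_beats_median_single_gene_xi(self, small_benchmark):
        # law of large numbers: pathway fraction is less noisy than genes
        cells, counts, truth = small_benchmark
        r = np.array([c.radial_position for c in cells])
        periphery = truth.loc[truth["pattern"] == "periphery", "gene_id"]
        ids = periphery.tolist()[:10]
        frac = pathway_fraction_per_cell(counts, ids)
        xi_set, _ = xi_correlation(r, frac, method="asymptotic", seed=0)
        per_gene = []
        depths = counts.depths().astype(float)
        for g in ids:
            f1 = counts.counts[counts.gene_index(g)] / depths
            per_gene.append(
                xi_correlation(r, f1, method="asymptotic", seed=0)[0]
            )
        assert xi_set >= np.median(per_gene)


class TestConfoundRegression:
    def _dataset(self, n_cells=800):
        r = sp.sample_radial_positions(n_cells, seed=14)
        N = sp.sample_depths(n_cells, 10_000, 0.3, seed=15).astype(float)
        cells = [sp.CellProfile(f"c{j}", float(ri), int(Ni))
                 for j, (ri, Ni) in enumerate(zip(r, N))]
        return r, N, cells

    def test_space_only_effect_survives_adjustment(self, rng):
        r, N, cells = self._dataset()
        # spatial gene + signature genes independent of r
        spatial = rng.poisson((1e-4 * np.exp(1.2 * r)) * N)
        cc = rng.poisson(1e-3 * N, size=(8, r.size))
        cc_ids = [f"cc{i}" for i in range(8)]
        m = CountMatrix(["sp"] + cc_ids,
                        [f"c{j}" for j in range(r.size)],
                        np.vstack([spatial, cc]))
        table, corr = regress_confounds(m, cells, cc_ids, [])
        row = table.set_index("gene_id").loc["sp"]
        assert row["space_coef_adjusted"] == pytest.approx(
            row["space_coef_raw"], abs=0.3
        )
        assert row["space_coef_raw"] > 0.5

    def test_confounded_gene_is_attenuated(self, rng):
        r, N, cells = self._dataset()
        # latent factor correlated with r drives both the gene and cc genes
        latent = 0.8 * r + 0.2 * rng.uniform(size=r.size)
        gene = rng.poisson(1e-4 * np.exp(2.0 * latent) * N)
        cc = np.vstack([
            rng.poisson(1e-3 * np.exp(2.0 * latent) * N) for _ in range(8)
        ])
        filler = rng.poisson(5e-4 * N, size=(1, r.size))
        cc_ids = [f"cc{i}" for i in range(8)]
        m = CountMatrix(["gene"] + cc_ids + ["filler"],
                        [f"c{j}" for j in range(r.size)],
                        np.vstack([gene, cc, filler]))
        table, _ = regress_confounds(m, cells, cc_ids, [])
        row = table.set_index("gene_id").loc["gene"]
        assert abs(row["space_coef_adjusted"]) < abs(row["space_coef_raw"])

    def test_empty_signatures_identity_with_warning(self, rng):
        r, N, cells = self._dataset(200)
        counts = rng.poisson(2e-4 * N, size=(2, r.size))
        m = CountMatrix(["a", "b"], [f"c{j}" for j in range(r.size)], counts)
        with pytest.warns(UserWarning):
            table, _ = regress_confounds(m, cells, [], [])
        np.testing.assert_allclose(
            table["space_coef_raw"], table["space_coef_adjusted"]
        )
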