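"""Clinal statistics: cpm, down-sampling, DE, concordance, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clinase.clinal import (ase_enrichment, ase_latitude_test,
                            ase_total_correlation, binomial_ci, cpm,
                            cpm_and_filter, downsample_counts,
                            fisher_exact_2x2, format_ci_percent,
                            latitudinal_de_test, major_minor_expression,
                            population_ase_means, power_matched_enrichment,
                            qc_outliers, region_enrichment, sign_concordance,
                            spearman_correlation)
from clinase.grouping import GroupingResult
from clinase.simulate import SimulationConfig, simulate_ase_dataset


# ------------------------------------------------------------------ #
# enumeration oracles (independent of scipy/statsmodels internals)
# ------------------------------------------------------------------ #

def spearman_perm_oracle(x, y):
    """Two-sided permutation p for the rank correlation, full enumeration."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = total = 0
    for perm in itertools.permutations(ry):
        r = abs(np.corrcoef(rx, perm)[0, 1])
        hits += r >= obs - 1e-12
        total += 1
    return hits / total


def fisher_enum_oracle(table):
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(a_):
        return (math.comb(r1, a_) * math.comb(r2, c1 - a_)
                / math.comb(n, c1))

    p_obs = prob(a)
    return sum(prob(a_) for a_ in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(a_) <= p_obs * (1 + 1e-9))


# ------------------------------------------------------------------ #

class TestCpm:
    def test_formula_and_conservation(self):
        m = pd.DataFrame({"s1": [100, 900], "s2": [10, 10]},
                         index=["g1", "g2"])
        c = cpm(m)
        assert c.loc["g1", "s1"] == pytest.approx(1e5)
        assert c.loc["g2", "s1"] == pytest.approx(9e5)
        assert np.allclose(c.sum(axis=0), 1e6)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            cpm(pd.DataFrame({"s1": [0, 0]}))

    def test_filter_boundary_nonstrict(self):
        # gene at exactly 1 cpm in exactly 10 of 12 samples is retained
        cols = [f"s{i}" for i in range(12)]
        row_hit = [1] * 10 + [0, 0]
        filler = [999] * 12
        m = pd.DataFrame([row_hit, filler], index=["g1", "g2"],
                         columns=cols)     # library 1000 -> 1 cpm per count
        filt, _ = cpm_and_filter(m, min_cpm=1, min_samples=10)
        assert "g1" in filt.index

    def test_all_zero_gene_removed(self):
        m = pd.DataFrame({"s%d" % i: [0, 50] for i in range(12)},
                         index=["gz", "g2"])
        filt, _ = cpm_and_filter(m)
        assert "gz" not in filt.index


class TestDownsampling:
    def test_identity_at_library_size(self):
        m = pd.DataFrame({"s1": [5, 10, 0], "s2": [3, 3, 3]})
        out = downsample_counts(m, 9, seed=1)
        assert (out["s2"] == m["s2"]).all()

    def test_column_sums_exact_and_reproducible(self, rng):
        m = pd.DataFrame(rng.integers(0, 500, size=(40, 6)))
        out = downsample_counts(m, 2000, seed=5)
        assert (out.sum(axis=0) == 2000).all()
        assert (out <= m).all().all()
        pd.testing.assert_frame_equal(out, downsample_counts(m, 2000, seed=5))

    def test_proportions_unbiased_over_seeds(self):
        m = pd.DataFrame({"s1": [800, 150, 50]})
        draws = np.stack([downsample_counts(m, 100, seed=s)["s1"].to_numpy()
                          for s in range(100)])
        mean = draws.mean(axis=0)
        se = draws.std(axis=0, ddof=1) / 10
        expected = np.array([80, 15, 5])
        assert np.all(np.abs(mean - expected) < 3 * np.maximum(se, 0.2))

    def test_target_too_large_rejected(self):
        m = pd.DataFrame({"s1": [5, 5]})
        with pytest.raises(ValueError):
            downsample_counts(m, 11)


def de_metadata():
    rows = []
    for cont in ("US", "AUS"):
        for lat in ("temperate", "tropical"):
            for i in range(6):
                rows.append({"sample": f"{cont}_{lat}_{i}",
                             "genotype": f"{cont}_{lat}_g{i}",
                             "replicate": "r1",
                             "population": f"{cont}_{lat}",
                             "continent": cont, "latitude": lat})
    return pd.DataFrame(rows)


class TestLatitudinalDe:
    def test_null_p_uniform(self, rng):
        meta = de_metadata()
        m = pd.DataFrame(rng.poisson(200, size=(300, len(meta))),
                         index=[f"g{i}" for i in range(300)],
                         columns=meta["sample"])
        res = latitudinal_de_test(m, meta, "US")
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_twofold_shift_recovered(self, rng):
        meta = de_metadata()
        lam = np.where(meta["latitude"] == "tropical", 400, 200)
        m = pd.DataFrame(rng.poisson(lam, size=(80, len(meta))),
                         index=[f"g{i}" for i in range(80)],
                         columns=meta["sample"])
        base = pd.DataFrame(rng.poisson(300, size=(200, len(meta))),
                            index=[f"b{i}" for i in range(200)],
                            columns=meta["sample"])
        full = pd.concat([m, base])
        res = latitudinal_de_test(full, meta, "US")
        shifted = res.loc[[f"g{i}" for i in range(80)], "log2_fold"]
        flat = res.loc[[f"b{i}" for i in range(200)], "log2_fold"]
        # cpm normalisation shifts both groups equally; the contrast between
        # planted and flat genes recovers the 2x (1 log2) shift
        assert shifted.mean() - flat.mean() == pytest.approx(1.0, abs=0.1)
        assert shifted.min() > flat.mean()

    def test_missing_latitude_class_rejected(self):
        meta = de_metadata()
        meta = meta[meta["latitude"] == "temperate"]
        m = pd.DataFrame(np.ones((5, len(meta))), columns=meta["sample"])
        with pytest.raises(ValueError):
            latitudinal_de_test(m, meta, "US")


class TestBinomialCi:
    def test_wilson_worked_example(self):
        lo, hi = binomial_ci(53, 59, "wilson")
        assert (lo, hi) == pytest.approx((0.7954, 0.9526), abs=1e-4)
        assert format_ci_percent(lo, hi) == "80-95%"

    def test_clopper_pearson_worked_example(self):
        lo, hi = binomial_ci(159, 192, "clopper_pearson")
        assert (lo, hi) == pytest.approx((0.7672, 0.8786), abs=1e-4)
        assert format_ci_percent(lo, hi) == "77-88%"

    def test_boundary_zero_successes(self):
        lo, hi = binomial_ci(0, 10, "clopper_pearson")
        assert lo == 0.0
        assert 0 < hi < 1

    def test_interval_contains_point_estimate(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 200))
            x = int(rng.integers(0, n + 1))
            for method in ("wilson", "clopper_pearson"):
                lo, hi = binomial_ci(x, n, method)
                assert lo - 1e-12 <= x / n <= hi + 1e-12

    def test_clopper_pearson_coverage(self, rng):
        """Exact interval: coverage >= nominal across a p grid."""
        n = 50
        for p in (0.1, 0.3, 0.5, 0.7, 0.9):
            xs = rng.binomial(n, p, size=2000)
            cover = 0
            for x in np.unique(xs):
                lo, hi = binomial_ci(int(x), n, "clopper_pearson")
                cover += ((lo <= p <= hi) * (xs == x).sum())
            assert cover / len(xs) >= 0.95 - 0.01

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(5, 4)


class TestSignConcordance:
    def frame(self, signs, fdrs):
        return pd.DataFrame({"log2_fold": signs, "fdr": fdrs},
                            index=[f"g{i}" for i in range(len(signs))])

    def test_hand_count(self):
        a = self.frame([1.0, 2.0, -1.0], [0.01] * 3)
        b = self.frame([0.5, -2.0, -0.3], [0.5] * 3)
        out = sign_concordance(a, b)
        assert out["n"] == 3 and out["concordant"] == 2
        assert out["proportion"] == pytest.approx(2 / 3)
        assert out["quadrants"][(1, 1)] == 1
        assert out["quadrants"][(-1, -1)] == 1
        assert out["quadrants"][(1, -1)] == 1

    def test_symmetric_under_continent_swap(self, rng):
        a = self.frame(rng.normal(size=30), rng.random(30) * 0.4)
        b = self.frame(rng.normal(size=30), rng.random(30) * 0.4)
        assert sign_concordance(a, b)["proportion"] == \
            sign_concordance(b, a)["proportion"]

    def test_no_significant_genes_reported_undefined(self):
        a = self.frame([1.0], [0.9])
        b = self.frame([1.0], [0.9])
        out = sign_concordance(a, b)
        assert out["proportion"] is None


class TestSpearman:
    def test_perfect_correlations(self):
        x = [1.0, 2, 3, 4, 5]
        assert spearman_correlation(x, x)[0] == pytest.approx(1.0)
        assert spearman_correlation(x, [-v for v in x])[0] == \
            pytest.approx(-1.0)

    def test_exact_permutation_matches_enumeration(self, rng):
        for _ in range(5):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            _, p = spearman_correlation(x, y, method="exact")
            assert p == pytest.approx(spearman_perm_oracle(x, y), abs=1e-12)

    def test_constant_vector_undefined(self):
        rho, p = spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho)

    def test_length_validation(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 2], [1, 2])


class TestFisher:
    @pytest.mark.parametrize("table", [
        [[3, 1], [1, 3]], [[10, 0], [0, 10]], [[2, 5], [4, 1]],
        [[6, 2], [3, 7]], [[1, 1], [1, 1]],
    ])
    def test_matches_enumeration(self, table):
        _, p = fisher_exact_2x2(table)
        assert p == pytest.approx(fisher_enum_oracle(table), abs=1e-10)

    def test_known_value(self):
        _, p = fisher_exact_2x2([[3, 1], [1, 3]])
        assert p == pytest.approx(0.4857142857, abs=1e-9)

    def test_identical_rows_p_one(self):
        _, p = fisher_exact_2x2([[4, 6], [4, 6]])
        assert p == 1.0

    def test_degenerate_margin(self):
        orat, p = fisher_exact_2x2([[0, 0], [3, 4]])
        assert p == 1.0


class TestEnrichment:
    def test_table_construction_and_direction(self):
        universe = {f"g{i}" for i in range(100)}
        lat = {f"g{i}" for i in range(20)}
        ase = {f"g{i}" for i in range(10)} | {"g50"}
        out = ase_enrichment(lat, ase, universe)
        assert out["table"][0].tolist() == [10, 10]
        assert out["odds_ratio"] > 1
        assert out["ase_fraction_latitudinal"] == pytest.approx(0.5)

    def test_universe_wide_ase_flagged_degenerate(self):
        universe = {"a", "b", "c", "d"}
        out = ase_enrichment({"a"}, universe, universe)
        assert out["degenerate"]

    def test_null_calibration(self, rng):
        universe = [f"g{i}" for i in range(60)]
        ps = []
        for _ in range(30):
            lat = set(rng.choice(universe, 15, replace=False))
            ase = set(rng.choice(universe, 20, replace=False))
            ps.append(ase_enrichment(lat, ase, set(universe))["p"])
        assert np.mean(np.asarray(ps) < 0.05) < 0.2


class TestPowerMatchedEnrichment:
    def test_coverage_confounded_enrichment_disappears(self):
        """Two gene sets with identical true effects but 8x coverage gap:
        raw enrichment of the deep set is a power artefact and must vanish
        once coverage is matched."""
        deep = SimulationConfig(n_genes=30, genotype_sd=0.45,
                                cre_effect_sd=0, depth_mean=400,
                                genotypes_per_population=4, seed=21)
        shallow = SimulationConfig(n_genes=30, genotype_sd=0.45,
                                   cre_effect_sd=0, depth_mean=50,
                                   genotypes_per_population=4, seed=22)
        cd, meta, _ = simulate_ase_dataset(deep)
        cs, _, _ = simulate_ase_dataset(shallow)
        cs = cs.assign(gene="lo_" + cs["gene"])
        cd = cd.assign(gene="hi_" + cd["gene"])
        table = pd.concat([cd, cs], ignore_index=True)
        lat = set(cd["gene"])
        universe = set(table["gene"])
        out = power_matched_enrichment(table, meta, lat, universe, seed=0,
                                       min_replicated_genotypes=None)
        # matched totals should be comparable between the two sets
        mt = (out["matched_table"]
              .assign(tot=lambda d: d.wild_count + d.ref_count)
              .groupby("gene")["tot"].sum())
        hi_med = mt[[g for g in mt.index if g.startswith("hi_")]].median()
        lo_med = mt[[g for g in mt.index if g.startswith("lo_")]].median()
        assert hi_med <= 1.5 * lo_med
        assert out["p"] > 0.01 or out["odds_ratio"] < 2.0

    def test_equal_coverage_is_noop_within_tolerance(self):
        cfg = SimulationConfig(n_genes=20, genotypes_per_population=4,
                               depth_mean=100, seed=23)
        counts, meta, _ = simulate_ase_dataset(cfg)
        lat = {f"gene{i:04d}" for i in range(10)}
        out = power_matched_enrichment(counts, meta, lat,
                                       set(counts["gene"]), seed=1,
                                       min_replicated_genotypes=None)
        before = counts.groupby("gene")[["wild_count", "ref_count"]] \
            .sum().sum(axis=1)
        after = (out["matched_table"]
                 .groupby("gene")[["wild_count", "ref_count"]]
                 .sum().sum(axis=1))
        assert ((before - after) / before).abs().max() < 0.35


def grouping_with_calls(gene, calls, means=(1.0, 0.0)):
    lines = list(calls)
    res = GroupingResult(
        gene=gene, ratios=pd.Series(1.0, index=lines), split_index=1,
        loglik=0.0,
        group_of=pd.Series(["top" if v == "high" else "bottom"
                            for v in calls.values()], index=lines),
        group_means={"top": means[0], "bottom": means[1]})
    res.allele_of = pd.Series(calls)
    return res


class TestMajorMinorExpression:
    def test_single_gene_hand_computation(self):
        calls = {"L1": "high", "L2": "high", "L3": "high", "L4": "low"}
        meta = pd.DataFrame({"sample": [f"{l}_r" for l in calls],
                             "genotype": list(calls)})
        freqs = pd.DataFrame({"maf": [0.25], "major_allele": ["high"]},
                             index=["g"])
        cpm_mat = pd.DataFrame(
            {f"{l}_r": [v] for l, v in zip(calls, [20, 20, 20, 10])},
            index=["g"])
        out = major_minor_expression(freqs, {"g": grouping_with_calls(
            "g", calls)}, cpm_mat, meta, maf_threshold=0.30)
        assert out["n"] == 1
        assert out["log2_ratios"]["g"] == pytest.approx(1.0)

    def test_monomorphic_gene_excluded(self):
        calls = {"L1": "high", "L2": "high"}
        meta = pd.DataFrame({"sample": ["L1_r", "L2_r"],
                             "genotype": ["L1", "L2"]})
        freqs = pd.DataFrame({"maf": [0.0], "major_allele": ["high"]},
                             index=["g"])
        cpm_mat = pd.DataFrame({"L1_r": [5], "L2_r": [9]}, index=["g"])
        out = major_minor_expression(freqs, {"g": grouping_with_calls(
            "g", calls)}, cpm_mat, meta)
        assert out["n"] == 0


class TestRegionEnrichment:
    def test_concentrated_set_flags_its_region(self, rng):
        genes = [f"g{i}" for i in range(80)]
        regions = pd.Series(["2L"] * 20 + ["2R"] * 20 + ["3L"] * 20
                            + ["3R"] * 20, index=genes)
        out = region_enrichment(set(genes[:15]), regions)
        assert out.loc["2L", "p"] == out["p"].min()
        assert out.loc["2L", "fdr"] < 0.05

    def test_uniform_set_rarely_significant(self, rng):
        genes = [f"g{i}" for i in range(80)]
        regions = pd.Series((["2L", "2R", "3L", "3R"] * 20)[:80],
                            index=genes)
        hits = 0
        for _ in range(10):
            s = set(rng.choice(genes, 20, replace=False))
            out = region_enrichment(s, regions)
            hits += (out["fdr"] < 0.2).any()
        assert hits <= 3

    def test_single_region_degenerate(self):
        regions = pd.Series(["2L", "2L"], index=["a", "b"])
        out = region_enrichment({"a"}, regions)
        assert out["degenerate"].all()


class TestAseTotalCorrelation:
    def test_hand_built_two_gene_table(self):
        calls1 = {"L1": "high", "L2": "low"}
        calls2 = {"L1": "low", "L2": "high"}
        groupings = {
            "g1": grouping_with_calls("g1", calls1, means=(2.0, 0.0)),
            "g2": grouping_with_calls("g2", calls2, means=(0.5, 0.0))}
        meta = pd.DataFrame({"sample": ["L1_r", "L2_r"],
                             "genotype": ["L1", "L2"]})
        cpm_mat = pd.DataFrame({"L1_r": [40, 10], "L2_r": [10, 10]},
                               index=["g1", "g2"])
        out = ase_total_correlation(groupings, cpm_mat, meta,
                                    min_group_size=1)
        per = out["per_gene"]
        assert per.loc["g1", "log2_high_low_cpm"] == pytest.approx(2.0)
        assert per.loc["g1", "ase_magnitude"] == pytest.approx(2.0)
        assert per.loc["g2", "log2_high_low_cpm"] == pytest.approx(0.0)


@pytest.fixture(scope="module")
def cline_gene():
    cfg = SimulationConfig(
        n_genes=1, cre_effect_fixed=1.5, genotype_sd=0.2,
        depth_mean=200, seed=31,
        cre_freq_by_population={"US_temperate": 0.1, "US_tropical": 0.9,
                                "AUS_temperate": 0.1,
                                "AUS_tropical": 0.9})
    counts, meta, _ = simulate_ase_dataset(cfg)
    return counts


class TestLatitudeModels:
    def test_population_means_detect_cline(self, cline_gene):
        out = population_ase_means(cline_gene)
        d = out["latitudinal_difference"]
        assert d["US"] > 0.5 and d["AUS"] > 0.5

    def test_latitude_lrt_significant_on_cline(self, cline_gene):
        out = ase_latitude_test(cline_gene)
        assert out["p"] < 0.01

    def test_missing_continent_rejected(self, cline_gene):
        with pytest.raises(ValueError):
            ase_latitude_test(cline_gene[cline_gene["continent"] == "US"])

    def test_symmetric_populations_no_cline(self):
        cfg = SimulationConfig(n_genes=1, cre_effect_sd=0, genotype_sd=0.2,
                               depth_mean=200, seed=33)
        counts, _, _ = simulate_ase_dataset(cfg)
        out = population_ase_means(counts)
        d = out["latitudinal_difference"]
        assert abs(d["US"]) < 0.4 and abs(d["AUS"]) < 0.4


class TestQcOutliers:
    def test_identical_samples_none_flagged(self):
        m = pd.DataFrame({f"s{i}": [10, 20, 30] for i in range(6)})
        assert not qc_outliers(m).any()

    def test_planted_outlier_flagged(self, rng):
        base = rng.poisson(np.tile(rng.lognormal(4, 1, 200), (12, 1)).T)
        m = pd.DataFrame(base, columns=[f"s{i}" for i in range(12)])
        m["s11"] = rng.permutation(m["s11"].to_numpy())
        flags = qc_outliers(m, k_sd=2.5)
        assert flags["s11"]
        assert flags.sum() <= 2

    def test_infinite_threshold_flags_none(self, rng):
        m = pd.DataFrame(rng.poisson(100, size=(50, 5)))
        assert not qc_outliers(m, k_sd=np.inf).any()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            qc_outliers(pd.DataFrame({"s1": [1], "s2": [2]}))
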