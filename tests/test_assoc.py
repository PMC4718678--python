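"""Association core: haplodiploid expectations, exact tests, FDR, cross-tab."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apiscout import assoc
from apiscout.assoc import (
    GenotypeCounts, classify_significance, cross_tab,
    expected_offspring_distribution, fdr_adjust, filter_individuals,
    filter_positions, fisher_exact_2x2, fisher_exact_2x3, genotype_counts,
    run_battery, sister_sharing_probability, trend_test,
)
from conftest import make_matrix


class TestOffspringDistribution:
    @pytest.mark.parametrize("queen,drone,expected", [
        (("R", "N"), "R", {"RR": 0.5, "RN": 0.5}),
        (("N", "N"), "N", {"NN": 1.0}),
        (("R", "N"), "N", {"RN": 0.5, "NN": 0.5}),
        (("R", "R"), "N", {"RN": 1.0}),
    ])
    def test_mendelian_cases(self, queen, drone, expected):
        assert expected_offspring_distribution(queen, drone) == expected

    def test_invalid_allele_rejected(self):
        with pytest.raises(ValueError):
            expected_offspring_distribution(("A", "B"), "R")


class TestSisterSharing:
    def test_closed_form(self):
        assert sister_sharing_probability("haplodiploid") == 0.75
        assert sister_sharing_probability("diploid") == 0.50

    def test_unknown_system_rejected(self):
        with pytest.raises(ValueError):
            sister_sharing_probability("triploid")


class TestFilters:
    def build(self, coverages):
        n = len(coverages)
        ids = [f"b{i}" for i in range(n)]
        calls = {"LG01:10": pd.Series(["RR", "RN"] * (n // 2) + ["RR"] * (n % 2),
                                      index=ids)}
        castes = {i: ("scout" if k < n // 2 else "recruit")
                  for k, i in enumerate(ids)}
        return make_matrix(calls, castes, dict(zip(ids, coverages)))

    def test_low_coverage_individual_removed(self):
        m = self.build([10.0] * 43 + [2.5])
        filtered = filter_individuals(m, min_coverage=3)
        assert filtered.n_individuals == 43

    def test_identity_when_all_covered(self):
        m = self.build([10.0] * 10)
        assert filter_individuals(m).n_individuals == 10
        assert filter_individuals(m, min_coverage=0).n_individuals == 10

    def test_all_removed_raises(self):
        m = self.build([1.0] * 4)
        with pytest.raises(ValueError):
            filter_individuals(m)

    def test_position_classes(self):
        ids = [f"b{i}" for i in range(6)]
        castes = {i: "scout" if k < 3 else "recruit" for k, i in enumerate(ids)}
        calls = {
            "LG01:1": ["NN"] * 6,              # monomorphic non-reference
            "LG01:2": ["RN"] * 6,              # monomorphic heterozygous
            "LG01:3": ["RR"] * 6,              # non-variant
            "LG01:4": ["RR", "RN"] * 3,        # tested
            "LG01:5": [np.nan] * 6,            # no calls at all
            "SCAF9:1": ["RR", "RN"] * 3,       # excluded scaffold
        }
        m = make_matrix({k: pd.Series(v, index=ids, dtype=object)
                         for k, v in calls.items()}, castes)
        tested, tally = filter_positions(m, excluded_scaffolds={"SCAF9"})
        assert list(tested.calls.columns) == ["LG01:4"]
        assert tally == {"tested": 1, "monomorphic-NN": 1, "monomorphic-het": 1,
                         "monomorphic-ref": 1, "all-missing": 1,
                         "excluded-scaffold": 1}


def enumerate_2x2_p(table):
    """Independent oracle: full hypergeometric enumeration of a 2x2 table."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    pmf = [math.comb(c1, x) * math.comb(n - c1, r1 - x) / math.comb(n, r1)
           for x in range(max(0, r1 - (n - c1)), min(r1, c1) + 1)]
    p_obs = math.comb(c1, a) * math.comb(n - c1, r1 - a) / math.comb(n, r1)
    return sum(p for p in pmf if p <= p_obs * (1 + 1e-7))


class TestFisher2x2:
    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == 1.0

    def test_perfect_separation(self):
        expected = 2 / math.comb(20, 10)
        assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(expected)

    def test_symmetry_under_swaps(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            t = rng.integers(0, 12, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            p = fisher_exact_2x2(t)
            assert fisher_exact_2x2(t[::-1]) == pytest.approx(p)
            assert fisher_exact_2x2(t[:, ::-1]) == pytest.approx(p)

    def test_zero_margin_is_na(self):
        assert math.isnan(fisher_exact_2x2([[0, 0], [3, 4]]))
        assert math.isnan(fisher_exact_2x2([[3, 0], [4, 0]]))

    def test_matches_enumeration_oracle_small(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            t = rng.integers(0, 6, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            assert fisher_exact_2x2(t) == pytest.approx(enumerate_2x2_p(t), rel=1e-9)


class TestFisher2x3:
    def test_zero_column_reduces_to_2x2(self):
        expected = 2 / math.comb(20, 10)
        assert fisher_exact_2x3([[10, 0, 0], [0, 10, 0]]) == pytest.approx(expected)

    def test_identical_rows_p_one(self):
        assert fisher_exact_2x3([[4, 3, 2], [4, 3, 2]]) == pytest.approx(1.0)

    def test_two_zero_columns_is_na(self):
        assert math.isnan(fisher_exact_2x3([[5, 0, 0], [7, 0, 0]]))

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            t = rng.integers(0, 8, size=(2, 3))
            if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) > 0).sum() < 2:
                continue
            p = fisher_exact_2x3(t)
            perm = rng.permutation(3)
            assert fisher_exact_2x3(t[:, perm]) == pytest.approx(p)

    def test_matches_permutation_oracle(self):
        """Margin-preserving Monte-Carlo permutation agrees within 3 SE."""
        rng = np.random.default_rng(4)
        tables = [np.array([[8, 3, 10], [2, 9, 11]]),
                  np.array([[5, 5, 5], [1, 8, 4]]),
                  np.array([[12, 1, 2], [3, 6, 6]])]
        for t in tables:
            p = fisher_exact_2x3(t)
            n = t.sum()
            labels = np.repeat([0, 1], t.sum(axis=1))
            cols = np.repeat([0, 1, 2], t.sum(axis=0))
            p_obs = _table_prob(t)
            hits = 0
            n_mc = 4000
            for _ in range(n_mc):
                perm = rng.permutation(labels)
                sim = np.zeros((2, 3), dtype=int)
                np.add.at(sim, (perm, cols), 1)
                if _table_prob(sim) <= p_obs * (1 + 1e-7):
                    hits += 1
            est = hits / n_mc
            se = math.sqrt(max(est * (1 - est), 1e-6) / n_mc)
            assert abs(p - est) < 3 * se


def _table_prob(t):
    """Multivariate hypergeometric probability of a 2x3 table given margins."""
    r1 = t[0].sum()
    n = t.sum()
    num = 1.0
    for j in range(t.shape[1]):
        num *= math.comb(t[:, j].sum(), t[0, j])
    return num / math.comb(n, r1)


class TestTrend:
    def test_perfect_trend(self):
        stat, p = trend_test(GenotypeCounts(scout=(10, 0, 0), recruit=(0, 0, 10)))
        assert stat == pytest.approx(20.0)
        assert p == pytest.approx(7.744e-6, rel=1e-3)

    def test_flat_distribution(self):
        stat, p = trend_test(GenotypeCounts(scout=(5, 5, 5), recruit=(5, 5, 5)))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_symmetry_relabel_and_reverse(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            s = tuple(int(x) for x in rng.integers(0, 10, 3))
            r = tuple(int(x) for x in rng.integers(0, 10, 3))
            stat, _ = trend_test(GenotypeCounts(scout=s, recruit=r))
            mirrored, _ = trend_test(GenotypeCounts(scout=r[::-1], recruit=s[::-1]))
            if math.isnan(stat):
                assert math.isnan(mirrored)
            else:
                assert mirrored == pytest.approx(stat)

    def test_degenerate_cases_na(self):
        assert math.isnan(trend_test(GenotypeCounts((0, 0, 0), (1, 2, 3)))[0])
        assert math.isnan(trend_test(GenotypeCounts((0, 5, 0), (0, 7, 0)))[0])

    def test_matches_correlation_identity(self):
        """Cochran-Armitage chi-square equals N times the squared Pearson
        correlation between caste indicator and genotype score."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            s = tuple(int(x) for x in rng.integers(0, 10, 3))
            r = tuple(int(x) for x in rng.integers(0, 10, 3))
            counts = GenotypeCounts(scout=s, recruit=r)
            stat, _ = trend_test(counts)
            y = np.repeat([1, 1, 1, 0, 0, 0], s + r)
            x = np.repeat([0, 1, 2, 0, 1, 2], s + r)
            if math.isnan(stat) or np.std(x) == 0 or np.std(y) == 0:
                continue
            rho = np.corrcoef(x, y)[0, 1]
            assert stat == pytest.approx(len(x) * rho ** 2)


class TestBattery:
    def test_all_heterozygous_everything_na(self):
        res = run_battery(GenotypeCounts(scout=(0, 21, 0), recruit=(0, 22, 0)))
        assert all(math.isnan(p) for p in res.pvalues().values())
        assert classify_significance(res) == ("NA", "NA", "NA", "NA")

    def test_collapsed_tables_match_hand_collapse(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            s = tuple(int(x) for x in rng.integers(0, 12, 3))
            r = tuple(int(x) for x in rng.integers(0, 12, 3))
            res = run_battery(GenotypeCounts(scout=s, recruit=r))
            dom = fisher_exact_2x2([[s[0] + s[1], s[2]], [r[0] + r[1], r[2]]])
            rec = fisher_exact_2x2([[s[0], s[1] + s[2]], [r[0], r[1] + r[2]]])
            for got, want in ((res.p_dominant, dom), (res.p_recessive, rec)):
                assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(want)

    def test_allele_count_conservation(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            row = tuple(int(x) for x in rng.integers(0, 12, 3))
            r_alleles, n_alleles = assoc.allele_counts(row)
            assert r_alleles + n_alleles == 2 * sum(row)


class TestFdr:
    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2]), [0.2])

    def test_nan_passthrough_excluded_from_m(self):
        out = fdr_adjust([0.01, np.nan, 0.02])
        assert math.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.02])

    def test_monotone_in_raw_rank(self):
        rng = np.random.default_rng(9)
        p = rng.random(50)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestClassification:
    def test_single_significant_genotypic(self):
        res = assoc.AssocResult("x", 5e-5, 0.2, 0.3, 0.4, 0.5)
        assert classify_significance(res) == ("S", "NS", "NS", "NS")

    def test_alpha_boundary_is_strict(self):
        res = assoc.AssocResult("x", 1e-4, 1e-4, 1e-4, 1e-4, 1e-4)
        assert classify_significance(res) == ("NS", "NS", "NS", "NS")

    def test_rn_column_combines_dominant_and_recessive(self):
        res = assoc.AssocResult("x", 0.5, 0.5, 5e-5, 0.9, 0.5)
        assert classify_significance(res)[3] == "S"
        res = assoc.AssocResult("x", 0.5, 0.5, float("nan"), float("nan"), 0.5)
        assert classify_significance(res)[3] == "NA"

    def test_cross_tab_is_a_partition(self):
        rng = np.random.default_rng(10)
        locs = list(assoc.LOCATION_CLASSES)
        patterns, locations, tally = {}, {}, {}
        for i in range(200):
            pat = tuple(rng.choice(["S", "NS", "NA"], size=4))
            loc = locs[rng.integers(len(locs))]
            patterns[f"p{i}"] = pat
            locations[f"p{i}"] = loc
            tally[("/".join(pat), loc)] = tally.get(("/".join(pat), loc), 0) + 1
        table = cross_tab(patterns, locations)
        for (pat, loc), count in tally.items():
            assert table.loc[pat, loc] == count
        body = table.drop(index=["Significant for at least one test",
                                 "Non-significant for any test", "Total"])
        assert body["Total"].sum() == 200
        assert table.loc["Total", "Total"] == 200

    def test_empty_cross_tab(self):
        table = cross_tab({}, {})
        assert table.loc["Total"].sum() == 0


class TestRunAssociation:
    def test_counts_and_patterns_on_hand_built_matrix(self):
        ids = [f"s{i}" for i in range(6)] + [f"r{i}" for i in range(6)]
        castes = {i: ("scout" if i.startswith("s") else "recruit") for i in ids}
        calls = {
            "LG01:100": pd.Series(["RR"] * 6 + ["NN"] * 6, index=ids, dtype=object),
            "LG01:200": pd.Series(["RR", "RN"] * 6, index=ids, dtype=object),
        }
        m = make_matrix(calls, castes)
        counts = genotype_counts(m, "LG01:100")
        assert counts.scout == (6, 0, 0) and counts.recruit == (0, 0, 6)
        results, tally = assoc.run_association(m, alpha=1e-2)
        assert tally["tested"] == 2
        assert bool(results.loc["LG01:100", "significant"])
        assert not bool(results.loc["LG01:200", "significant"])
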