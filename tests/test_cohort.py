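import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cfimmune.cohort import (EXCLUDED, NON_RESPONDER, RESPONDER,
                             cfdna_count_ratio, classify_responders,
                             coefficient_of_variation,
                             fold_change_from_baseline, group_compare,
                             inter_cv_balanced, intra_cv, mad_outlier_mask,
                             roc_auc)


def long_table(rows):
    return pd.DataFrame(rows, columns=["donor_id", "timepoint", "source",
                                       "analyte", "value"])


def make_rows(values_by_donor, analyte="b_cell", source="cfDNA"):
    rows = []
    for donor, vals in values_by_donor.items():
        for t, v in enumerate(vals):
            rows.append((donor, f"T{t}", source, analyte, v))
    return long_table(rows)


class TestCV:
    def test_constant_series(self):
        assert coefficient_of_variation([5, 5, 5]) == 0.0

    def test_hand_computed(self):
        # sd({1,2,3}) = 1 (n-1 denominator), mean = 2
        assert coefficient_of_variation([1, 2, 3]) == pytest.approx(0.5)

    def test_scale_invariance(self):
        vals = [1.0, 2.5, 4.0, 3.5]
        assert coefficient_of_variation([10 * v for v in vals]) == \
            pytest.approx(coefficient_of_variation(vals))

    def test_zero_mean_undefined(self):
        assert math.isnan(coefficient_of_variation([-1.0, 1.0]))

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([1.0])


class TestIntraCV:
    def test_constant_donors(self):
        table = make_rows({"d1": [4, 4, 4], "d2": [7, 7, 7]})
        assert intra_cv(table, "b_cell", "cfDNA") == 0.0

    def test_mean_of_donor_cvs(self):
        # donor CVs hand-set to 0.1 and 0.3 via constructed series
        d1 = [10 * (1 + 0.1), 10 * (1 - 0.1)]  # cv = sd/mean
        cv1 = coefficient_of_variation(d1)
        d2 = [10 * (1 + 0.3), 10 * (1 - 0.3)]
        cv2 = coefficient_of_variation(d2)
        table = make_rows({"d1": d1, "d2": d2})
        assert intra_cv(table, "b_cell", "cfDNA") == \
            pytest.approx((cv1 + cv2) / 2)


class TestInterCVBalanced:
    def test_enumerates_all_5005_subsets(self):
        rng = np.random.default_rng(0)
        table = make_rows({f"d{i:02d}": rng.uniform(1, 5, 6).tolist()
                           for i in range(15)})
        _, n_subsets = inter_cv_balanced(table, "b_cell", "cfDNA",
                                         group_size=6, return_detail=True)
        assert n_subsets == math.comb(15, 6) == 5005

    def test_identical_donors_zero(self):
        table = make_rows({f"d{i}": [3.0, 4.0, 5.0] for i in range(8)})
        assert inter_cv_balanced(table, "b_cell", "cfDNA") == \
            pytest.approx(0.0)

    def test_group_size_equals_n(self):
        rng = np.random.default_rng(1)
        data = {f"d{i}": rng.uniform(1, 5, 4).tolist() for i in range(6)}
        table = make_rows(data)
        got = inter_cv_balanced(table, "b_cell", "cfDNA", group_size=6)
        # single subset: per-timepoint across-donor CV, averaged
        wide = np.array([data[f"d{i}"] for i in range(6)])
        per_tp = wide.std(axis=0, ddof=1) / wide.mean(axis=0)
        assert got == pytest.approx(per_tp.mean())

    def test_brute_force_oracle_small(self):
        rng = np.random.default_rng(2)
        data = {f"d{i}": rng.uniform(1, 5, 3).tolist() for i in range(6)}
        table = make_rows(data)
        got = inter_cv_balanced(table, "b_cell", "cfDNA", group_size=4)
        donors = sorted(data)
        cvs = []
        for combo in itertools.combinations(donors, 4):
            block = np.array([data[d] for d in combo])
            cvs.append(np.mean(block.std(axis=0, ddof=1)
                               / block.mean(axis=0)))
        assert got == pytest.approx(np.mean(cvs))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        data = {f"d{i}": rng.uniform(1, 5, 3).tolist() for i in range(8)}
        table = make_rows(data)
        shuffled = table.sample(frac=1.0, random_state=4)
        assert inter_cv_balanced(table, "b_cell", "cfDNA", group_size=5) == \
            pytest.approx(inter_cv_balanced(shuffled, "b_cell", "cfDNA",
                                            group_size=5))

    def test_group_size_too_large(self):
        table = make_rows({"d1": [1, 2], "d2": [3, 4]})
        with pytest.raises(ValueError):
            inter_cv_balanced(table, "b_cell", "cfDNA", group_size=6)

    def test_sampled_mode_seeded(self):
        rng = np.random.default_rng(5)
        table = make_rows({f"d{i:02d}": rng.uniform(1, 5, 3).tolist()
                           for i in range(12)})
        a = inter_cv_balanced(table, "b_cell", "cfDNA", group_size=6,
                              max_exact=10, n_samples=200, seed=7)
        b = inter_cv_balanced(table, "b_cell", "cfDNA", group_size=6,
                              max_exact=10, n_samples=200, seed=7)
        exact = inter_cv_balanced(table, "b_cell", "cfDNA", group_size=6)
        assert a == b
        assert a == pytest.approx(exact, rel=0.1)


class TestFoldChange:
    def test_basic(self):
        table = long_table([("d1", "D0", "cfDNA", "b_cell", 10),
                            ("d1", "D3", "cfDNA", "b_cell", 20)])
        fc = fold_change_from_baseline(table)
        assert fc.loc[fc["timepoint"] == "D3", "fold_change"].iloc[0] == 2.0

    def test_zero_baseline_excluded(self):
        table = long_table([("d1", "D0", "cfDNA", "b_cell", 0),
                            ("d1", "D3", "cfDNA", "b_cell", 20),
                            ("d2", "D0", "cfDNA", "b_cell", 5),
                            ("d2", "D3", "cfDNA", "b_cell", 5)])
        fc = fold_change_from_baseline(table)
        assert set(fc["donor_id"]) == {"d2"}

    def test_constant_series_all_ones(self):
        table = long_table([("d1", t, "cfDNA", "b_cell", 7)
                            for t in ("D0", "D3", "D7")])
        fc = fold_change_from_baseline(table)
        assert (fc["fold_change"] == 1.0).all()


class TestResponders:
    def titer_frame(self, rows):
        return pd.DataFrame(rows, columns=["donor_id", "strain",
                                           "baseline_titer", "post_titer"])

    def test_seroconversion_responder(self):
        strains = ["H1N1", "H3", "YAMA", "VIC"]
        rows = [("d1", s, 20, p) for s, p in zip(strains, [80, 20, 20, 20])]
        out = classify_responders(self.titer_frame(rows))
        assert out.loc[0, "status"] == RESPONDER

    def test_all_strains_positive_excluded(self):
        strains = ["H1N1", "H3", "YAMA", "VIC"]
        rows = [("d1", s, b, b) for s, b in zip(strains,
                                                [80, 160, 320, 640])]
        out = classify_responders(self.titer_frame(rows))
        assert out.loc[0, "status"] == EXCLUDED

    def test_no_seroconversion(self):
        rows = [("d1", "H1N1", 20, 20), ("d1", "H3", 20, 40)]
        # post exactly 40 is NOT > 40: still non-responder
        out = classify_responders(self.titer_frame(rows))
        assert out.loc[0, "status"] == NON_RESPONDER

    def test_baseline_at_cutoff_not_eligible(self):
        # baseline 40 is not < 40: strain already antibody-positive
        rows = [("d1", "H1N1", 40, 640)]
        out = classify_responders(self.titer_frame(rows))
        assert out.loc[0, "status"] == EXCLUDED

    def test_missing_post_titers_excluded(self):
        rows = [("d1", "H1N1", 20, np.nan)]
        out = classify_responders(self.titer_frame(rows))
        assert out.loc[0, "status"] == EXCLUDED
        assert "post titer" in out.loc[0, "reason"]


class TestROC:
    def test_perfect_separation(self):
        auc, curve = roc_auc([5, 6, 7], [1, 2, 3])
        assert auc == 1.0
        assert {"fpr", "tpr"} <= set(curve.columns)

    def test_all_ties(self):
        auc, _ = roc_auc([1, 1, 1], [1, 1, 1])
        assert auc == 0.5

    def test_mann_whitney_identity(self):
        rng = np.random.default_rng(10)
        cases = rng.normal(1, 1, 25)
        controls = rng.normal(0, 1, 30)
        auc, _ = roc_auc(cases, controls)
        u = sum((c > k) + 0.5 * (c == k) for c in cases for k in controls)
        assert auc == pytest.approx(u / (len(cases) * len(controls)))

    def test_negated_scores_complement(self):
        rng = np.random.default_rng(11)
        cases = rng.normal(1, 1, 10)
        controls = rng.normal(0, 1, 12)
        auc_pos, _ = roc_auc(cases, controls)
        auc_neg, _ = roc_auc(-cases, -controls)
        assert auc_pos + auc_neg == pytest.approx(1.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [1, 2])


class TestGroupCompare:
    def test_identical_samples_u_statistic(self):
        stat, _ = group_compare([[1, 2, 3, 4], [1, 2, 3, 4]], "rank_sum_2")
        assert stat == 4 * 4 / 2

    def test_exact_enumeration_oracle(self):
        # {1,2,3} vs {4,5,6}: all 20 assignments of ranks, one-sided p=1/20
        stat, p = group_compare([[1, 2, 3], [4, 5, 6]], "rank_sum_2",
                                alternative="less")
        # independent enumeration of the U null distribution
        ranks = range(1, 7)
        u_obs = sum(a > b for a in [1, 2, 3] for b in [4, 5, 6])
        n_le = 0
        total = 0
        for combo in itertools.combinations(ranks, 3):
            u = sum(a > b for a in combo
                    for b in set(ranks) - set(combo))
            total += 1
            if u <= u_obs:
                n_le += 1
        assert total == 20
        assert p == pytest.approx(n_le / total)
        assert p == pytest.approx(1 / 20)

    def test_two_tailed_doubles(self):
        _, p1 = group_compare([[1, 2, 3], [4, 5, 6]], "rank_sum_2",
                              alternative="less")
        _, p2 = group_compare([[1, 2, 3], [4, 5, 6]], "rank_sum_2")
        assert p2 == pytest.approx(2 * p1)

    def test_kruskal_three_groups(self):
        stat, p = group_compare([[1, 2, 3], [4, 5, 6], [7, 8, 9]],
                                "kruskal_wallis")
        assert p < 0.05

    def test_pearson_exact_linear(self):
        r, _ = group_compare([[1, 2, 3, 4], [2, 4, 6, 8]], "pearson")
        assert r == pytest.approx(1.0)

    def test_shape_errors(self):
        with pytest.raises(ValueError):
            group_compare([[1, 2]], "rank_sum_2")
        with pytest.raises(ValueError):
            group_compare([[1, 2], [1, 2, 3]], "pearson")
        with pytest.raises(ValueError):
            group_compare([[1], [2]], "bogus")


class TestRatio:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["donor_id", "timepoint", "source",
                                           "analyte", "value"])

    def test_basic_ratio(self):
        t = self.table([("d1", "T0", "cfDNA", "eosinophil", 10),
                        ("d1", "T0", "CBC", "eosinophil", 5)])
        out = cfdna_count_ratio(t)
        assert out["ratio"].iloc[0] == 2.0

    def test_zero_denominator_flagged(self):
        t = self.table([("d1", "T0", "cfDNA", "eosinophil", 10),
                        ("d1", "T0", "CBC", "eosinophil", 0)])
        out = cfdna_count_ratio(t)
        assert math.isnan(out["ratio"].iloc[0])
        assert out["flag"].iloc[0] == "zero_denominator"

    def test_equal_percentages(self):
        t = self.table([("d1", "T0", "cfDNA", "b_cell", 4),
                        ("d1", "T0", "CBC", "b_cell", 4)])
        assert cfdna_count_ratio(t)["ratio"].iloc[0] == 1.0

    def test_no_pairs_errors(self):
        t = self.table([("d1", "T0", "cfDNA", "b_cell", 4)])
        with pytest.raises(ValueError):
            cfdna_count_ratio(t)


class TestOutlierSubstitute:
    def test_flags_far_point(self):
        vals = [10, 11, 9, 10, 12, 300]
        mask = mad_outlier_mask(vals)
        assert mask.tolist() == [False] * 5 + [True]

    def test_constant_values_no_outliers(self):
        assert not mad_outlier_mask([5, 5, 5, 5]).any()
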