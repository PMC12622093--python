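"""SV labeling, filter training, thresholds, Mendelian and cohort QC."""

import math
from fractions import Fraction
from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import roc_auc_score

from locuskit.svfilter import (
    FEATURES,
    PhewasThresholds,
    SVCallFilter,
    SVRecord,
    af_fold_change,
    apply_filter,
    apply_phewas_qc,
    hwe_exact_p,
    label_calls,
    mendelian_consistent,
    mendelian_discordance,
    panel_postfilter,
    select_threshold,
    size_similarity,
    train_filter,
)
from locuskit.synthetic import SvSimSpec, TrioSimSpec, gen_cohort_qc_table, gen_sv_feature_table, gen_trio_genotypes

RNG = np.random.default_rng(31)


def sv_table(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "svtype", "svlen"]).sort_values(
        ["chrom", "pos"], ignore_index=True
    )


class TestLabelCalls:
    def test_identical_call_is_tp(self):
        truth = sv_table([("chr1", 1000, "DEL", -200)])
        cand = sv_table([("chr1", 1000, "DEL", -200)])
        assert list(label_calls(cand, truth)["label"]) == ["TP"]

    def test_distant_call_is_fp(self):
        truth = sv_table([("chr1", 1000, "DEL", -200)])
        cand = sv_table([("chr1", 11_000, "DEL", -200)])
        assert list(label_calls(cand, truth)["label"]) == ["FP"]

    def test_size_similarity_gate(self):
        truth = sv_table([("chr1", 1000, "INS", 100)])
        cand = sv_table([("chr1", 1000, "INS", 60)])  # 0.6 < 0.7
        assert list(label_calls(cand, truth)["label"]) == ["FP"]

    def test_truth_consumed_once(self):
        truth = sv_table([("chr1", 1000, "INS", 100)])
        cand = sv_table([("chr1", 990, "INS", 100), ("chr1", 1005, "INS", 100)])
        labels = label_calls(cand, truth)["label"]
        assert sorted(labels) == ["FP", "TP"]
        # nearest-first: the 1005 candidate (distance 5) wins
        assert list(labels) == ["FP", "TP"]

    def test_unsorted_errors(self):
        cand = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [500, 100], "svtype": "DEL", "svlen": -60}
        )
        with pytest.raises(ValueError):
            label_calls(cand, sv_table([("chr1", 100, "DEL", -60)]))

    def test_greedy_close_to_optimal_matching(self):
        """Greedy nearest-first labels agree with optimal bipartite matching
        (scipy assignment) on >= 99% of calls over randomized 200-call sets."""
        agree = total = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            truth = sv_table(
                [("chr1", int(p), "INS", int(l))
                 for p, l in zip(np.sort(rng.integers(0, 1_000_000, 120)),
                                 rng.integers(50, 500, 120))]
            )
            cand = sv_table(
                [("chr1", int(p), "INS", int(l))
                 for p, l in zip(np.sort(rng.integers(0, 1_000_000, 200)),
                                 rng.integers(50, 500, 200))]
            )
            labeled = label_calls(cand, truth)
            # optimal matching oracle under the same predicate
            cost = np.full((len(cand), len(truth)), 1e9)
            for i in range(len(cand)):
                for j in range(len(truth)):
                    d = abs(cand["pos"][i] - truth["pos"][j])
                    if d <= 500 and size_similarity(cand["svlen"][i], truth["svlen"][j]) >= 0.7:
                        cost[i, j] = d
            ri, ci = linear_sum_assignment(cost)
            optimal_tp = {i for i, j in zip(ri, ci) if cost[i, j] < 1e9}
            greedy_tp = set(np.flatnonzero((labeled["label"] == "TP").to_numpy()))
            agree += len(cand) - len(optimal_tp ^ greedy_tp)
            total += len(cand)
        assert agree / total >= 0.99


class TestFilterModel:
    def test_determinism(self):
        table = gen_sv_feature_table(SvSimSpec(n_calls=2000, seed=8))
        m1 = train_filter(table, seed=5)
        m2 = train_filter(table, seed=5)
        assert np.array_equal(m1.score_samples(table), m2.score_samples(table))
        assert m1.thresholds_ == m2.thresholds_

    def test_single_class_errors(self):
        table = gen_sv_feature_table(SvSimSpec(n_calls=300, seed=1)).copy()
        table["label"] = "TP"
        with pytest.raises(ValueError):
            train_filter(table)

    def test_strong_signal_heldout_auc(self):
        table = gen_sv_feature_table(
            SvSimSpec(n_calls=4000, effect_allele_depth=3, effect_allele_balance=3,
                      effect_length=3, effect_caller_support=3, seed=2)
        )
        train, test = table.iloc[:2000], table.iloc[2000:]
        model = train_filter(train, seed=0)
        auc = roc_auc_score((test["label"] == "TP").astype(int), model.score_samples(test))
        assert auc > 0.95

    def test_sklearn_estimator_contract(self):
        model = SVCallFilter(n_estimators=50)
        params = model.get_params()
        assert params["n_estimators"] == 50
        model.set_params(max_depth=2)
        assert model.get_params()["max_depth"] == 2
        table = gen_sv_feature_table(SvSimSpec(n_calls=500, seed=3))
        model.fit(table[FEATURES], table["label"])
        assert hasattr(model, "model_") and set(model.thresholds_) == {"lenient", "strict"}
        assert model.predict(table[FEATURES]).shape == (500,)

    def test_null_retains_90pct_of_both_classes(self):
        """With zero planted effects a TPR-0.9 threshold chosen on held-out
        scores keeps ~90% of TPs and ~90% of FPs: no free specificity."""
        table = gen_sv_feature_table(
            SvSimSpec(n_calls=10_000, effect_allele_depth=0, effect_allele_balance=0,
                      effect_length=0, effect_caller_support=0, seed=4)
        )
        train, held = table.iloc[:5000], table.iloc[5000:]
        model = train_filter(train, seed=0)
        scores = model.score_samples(held)
        y = (held["label"] == "TP").to_numpy().astype(int)
        thr, tpr, fpr = select_threshold(scores, y, 0.9)
        assert abs(tpr - 0.9) < 0.01
        assert abs(fpr - 0.9) < 0.04


class TestSelectThreshold:
    def test_perfect_separation(self):
        scores = np.array([1.0] * 50 + [0.0] * 50)
        labels = np.array([1] * 50 + [0] * 50)
        thr, tpr, fpr = select_threshold(scores, labels, 0.9)
        assert (tpr, fpr) == (1.0, 0.0) and thr == 1.0

    def test_matches_exhaustive_sweep(self):
        """Selected cut equals a brute-force sweep over all distinct scores."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            scores = rng.random(400)
            labels = (rng.random(400) < 0.5).astype(int)
            for target in (0.7, 0.9):
                thr, tpr, _ = select_threshold(scores, labels, target)
                best = None
                for cut in np.unique(scores):
                    t = (scores[labels == 1] >= cut).mean()
                    if t >= target and (best is None or cut > best):
                        best = cut
                assert thr == best
                assert tpr >= target

    def test_invalid_targets(self):
        with pytest.raises(ValueError):
            select_threshold([0.5], [1], 1.5)
        with pytest.raises(ValueError):
            select_threshold([0.5], [0], 0.9)


class TestApplyFilter:
    def test_threshold_extremes_and_nesting(self):
        table = gen_sv_feature_table(SvSimSpec(n_calls=1000, seed=6))
        model = train_filter(table, seed=0)
        model.thresholds_["lenient"] = 0.0
        assert len(apply_filter(table, model, "lenient")) == 1000
        model.thresholds_["lenient"] = 1.0 + 1e-9
        assert len(apply_filter(table, model, "lenient")) == 0
        model = train_filter(table, seed=0)
        strict = apply_filter(table, model, "strict")
        lenient = apply_filter(table, model, "lenient")
        assert strict.index.isin(lenient.index).all()

    def test_unknown_tier(self):
        table = gen_sv_feature_table(SvSimSpec(n_calls=200, seed=6))
        model = train_filter(table, seed=0)
        with pytest.raises(ValueError):
            apply_filter(table, model, "medium")


class TestMendelian:
    def test_examples(self):
        assert not mendelian_consistent("0/0", "0/0", "0/1")
        for child in ("0/0", "0/1", "1/1"):
            assert mendelian_consistent("0/1", "0/1", child)

    def test_all_27_triplets_match_transmission_enumeration(self):
        gts = ["0/0", "0/1", "1/1"]
        alleles = {"0/0": (0, 0), "0/1": (0, 1), "1/1": (1, 1)}
        for f, m, c in product(gts, repeat=3):
            expected = sorted(alleles[c]) in sorted(
                [sorted((fa, ma)) for fa in alleles[f] for ma in alleles[m]]
            )
            assert mendelian_consistent(f, m, c) == expected

    def test_missing_sites_excluded(self):
        trios = pd.DataFrame(
            {
                "father": ["0/0", "./.", "0/0"],
                "mother": ["0/0", "0/0", "0/0"],
                "child": ["0/1", "0/0", "0/0"],
            }
        )
        assert mendelian_discordance(trios) == 0.5

    def test_zero_complete_sites_errors(self):
        trios = pd.DataFrame({"father": ["./."], "mother": ["0/0"], "child": ["0/0"]})
        with pytest.raises(ValueError):
            mendelian_discordance(trios)

    def test_zero_planted_errors_zero_rate(self):
        trios = gen_trio_genotypes(TrioSimSpec(n_sites=3000, seed=2))
        assert mendelian_discordance(trios) == 0.0


class TestPanelPostfilter:
    def variants(self, rows):
        cols = ["variant_id", "chrom", "pos", "end", "ref", "alt", "is_sv", "ac", "af"]
        return pd.DataFrame(rows, columns=cols).sort_values(
            ["chrom", "pos"], ignore_index=True
        )

    def test_singleton_removed(self):
        table = self.variants(
            [("v1", "chr1", 100, 101, "A", "T", False, 1, 0.01),
             ("v2", "chr1", 200, 201, "C", "G", False, 9, 0.2)]
        )
        kept, log = panel_postfilter(table)
        assert list(kept["variant_id"]) == ["v2"]
        assert log.loc[log["variant_id"] == "v1", "rule"].item() == 1

    def test_cross_callset_duplicate_removes_short_copy(self):
        table = self.variants(
            [("sv1", "chr1", 100, 160, "A", "<DEL>", True, 10, 0.2),
             ("snv1", "chr1", 100, 160, "A", "<DEL>", False, 10, 0.2)]
        )
        kept, log = panel_postfilter(table)
        assert list(kept["variant_id"]) == ["sv1"]
        assert log.loc[log["variant_id"] == "snv1", "rule"].item() == 2

    def test_rare_short_variant_far_from_sv_removed(self):
        table = self.variants(
            [("sv1", "chr1", 1000, 1100, "A", "<DEL>", True, 20, 0.3),
             ("far", "chr1", 31_000, 31_001, "C", "T", False, 2, 0.004),
             ("near", "chr1", 11_000, 11_001, "G", "A", False, 2, 0.004)]
        )
        kept, log = panel_postfilter(table)
        assert sorted(kept["variant_id"]) == ["near", "sv1"]
        assert log.loc[log["variant_id"] == "far", "rule"].item() == 3

    def test_af_at_half_percent_retained(self):
        table = self.variants(
            [("sv1", "chr1", 1000, 1100, "A", "<DEL>", True, 20, 0.3),
             ("v", "chr1", 31_000, 31_001, "C", "T", False, 2, 0.005)]
        )
        kept, _ = panel_postfilter(table)
        assert "v" in set(kept["variant_id"])

    def test_positional_conflict_same_haplotype(self):
        table = self.variants(
            [("a", "chr1", 100, 160, "A", "<DEL>", True, 10, 0.3),
             ("b", "chr1", 130, 190, "C", "<DEL>", True, 5, 0.1)]
        )
        haps = pd.DataFrame([[1, 1, 0], [1, 0, 0]], index=["a", "b"])
        kept, log = panel_postfilter(table, haplotypes=haps)
        assert list(kept["variant_id"]) == ["a"]
        assert log.loc[log["variant_id"] == "b", "rule"].item() == 4
        # same overlap on disjoint haplotypes is not a conflict
        haps2 = pd.DataFrame([[1, 0, 0], [0, 1, 0]], index=["a", "b"])
        kept2, _ = panel_postfilter(table, haplotypes=haps2)
        assert len(kept2) == 2


class TestPhewasQc:
    def passing_row(self, **over):
        row = dict(variant_id="v", mean_gp=0.9, hwe_p=0.5, af_panel=0.2,
                   af_imputed=0.22, carrier_concordance=0.9, n_carriers=50)
        row.update(over)
        return row

    def test_boundaries_inclusive(self):
        table = pd.DataFrame(
            [self.passing_row(mean_gp=0.7, hwe_p=1e-5, af_imputed=0.2 * 1.499,
                              carrier_concordance=0.70, n_carriers=10)]
        )
        kept, counts = apply_phewas_qc(table)
        assert len(kept) == 1 and all(v == 0 for v in counts.values())

    @pytest.mark.parametrize(
        "over,rule",
        [
            ({"mean_gp": 0.69}, "gp"),
            ({"hwe_p": 0.9e-5}, "hwe"),
            ({"af_imputed": 0.2 * 1.6}, "af_fold"),
            ({"carrier_concordance": 0.699}, "concordance"),
            ({"n_carriers": 9}, "min_carriers"),
        ],
    )
    def test_each_rule_removes(self, over, rule):
        table = pd.DataFrame([self.passing_row(**over)])
        kept, counts = apply_phewas_qc(table)
        assert kept.empty and counts[rule] == 1

    def test_zero_af_is_infinite_fold(self):
        assert af_fold_change(0.0, 0.1) == math.inf
        assert af_fold_change(0.0, 0.0) == 1.0
        table = pd.DataFrame([self.passing_row(af_panel=0.0, af_imputed=0.05)])
        kept, counts = apply_phewas_qc(table)
        assert kept.empty and counts["af_fold"] == 1

    def test_planted_violations_removed_exactly(self):
        planted = {"gp": 7, "hwe": 2, "af_fold": 3, "concordance": 4, "min_carriers": 1}
        table = gen_cohort_qc_table(100, planted, seed=9)
        kept, counts = apply_phewas_qc(table)
        removed = set(table["variant_id"]) - set(kept["variant_id"])
        assert removed == set(table.loc[table["viol_any"], "variant_id"])
        for rule, n in planted.items():
            assert counts[rule] == n


class TestHweExact:
    def exact_oracle(self, het, hom_r, hom_a):
        """Direct enumeration with exact rational arithmetic."""
        n = het + hom_r + hom_a
        n_rare = het + 2 * min(hom_r, hom_a)

        def prob(h):
            hr = (n_rare - h) // 2
            hc = n - h - hr
            return Fraction(
                math.factorial(n) * 2**h * math.factorial(n_rare) * math.factorial(2 * n - n_rare),
                math.factorial(h) * math.factorial(hr) * math.factorial(hc) * math.factorial(2 * n),
            )

        valid = [h for h in range(n_rare % 2, n_rare + 1, 2) if n - h - (n_rare - h) // 2 >= 0]
        obs = prob(het)
        return float(sum(prob(h) for h in valid if prob(h) <= obs))

    @pytest.mark.parametrize("het,hom_r,hom_a", [(5, 2, 3), (0, 10, 0), (10, 0, 0), (3, 3, 3), (57, 21, 22)])
    def test_matches_rational_enumeration(self, het, hom_r, hom_a):
        assert hwe_exact_p(het, hom_r, hom_a) == pytest.approx(
            self.exact_oracle(het, hom_r, hom_a), rel=1e-9
        )

    def test_equilibrium_counts_not_rejected(self):
        # 50/25/25 is the modal configuration for 100 samples at AF 0.5
        assert hwe_exact_p(50, 25, 25) > 0.5

    def test_extreme_disequilibrium_rejected(self):
        # all heterozygotes absent despite intermediate AF
        assert hwe_exact_p(0, 50, 50) < 1e-5


def test_svrecord_invariants():
    with pytest.raises(ValueError):
        SVRecord("chr1", 100, 100, "DEL", -50)
    with pytest.raises(ValueError):
        SVRecord("chr1", 100, 150, "INS", 50)
    rec = SVRecord("chr1", 100, 100, "INS", 72)
    assert rec.length == 72
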