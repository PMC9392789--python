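from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bccs.containers import GroupAssignment, ValidationError
from bccs.genomic import (
    adjusted_frequency,
    benjamini_hochberg,
    compare_arm_calls,
    compare_mutations,
    enriched_in_group2,
    fisher_feature_test,
)
from conftest import make_manifest


def hypergeom_fisher_p(k1, n1, k2, n2):
    """Two-sided Fisher p by full enumeration of tables with fixed margins.

    Sums the conditional hypergeometric probabilities of every table whose
    probability does not exceed that of the observed table. Exact rational
    arithmetic via integer binomials avoids rounding ties.
    """
    K = k1 + k2
    N = n1 + n2
    denom = comb(N, K)
    observed = comb(n1, k1) * comb(n2, K - k1)
    total = 0
    for x in range(max(0, K - n2), min(K, n1) + 1):
        prob = comb(n1, x) * comb(n2, K - x)
        if prob <= observed:
            total += prob
    return total / denom


def two_type_manifest(n_per=20):
    rows = []
    for ct, tissue in (("CTA", "TisA"), ("CTB", "TisB"), ("CTC", "TisC")):
        for i in range(n_per):
            rows.append((f"{ct}{i}", "TCGA_TUMOR", tissue, ct, "NONE"))
        rows.append((f"{ct}N", "GTEX", tissue, "", "NONE"))
    return make_manifest(rows)


class TestFisher:
    def test_no_signal_table(self):
        _, p = fisher_feature_test(0, 10, 0, 10)
        assert p == 1.0

    def test_perfect_separation_table(self):
        # p = 2 / C(20, 10) for [[10,0],[0,10]]
        _, p = fisher_feature_test(10, 10, 0, 10)
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_on_random_tables(self, seed):
        local = np.random.default_rng(seed)
        for _ in range(50):
            n1, n2 = local.integers(1, 26, size=2)
            k1 = local.integers(0, n1 + 1)
            k2 = local.integers(0, n2 + 1)
            _, p = fisher_feature_test(k1, n1, k2, n2)
            assert p == pytest.approx(
                hypergeom_fisher_p(k1, n1, k2, n2), rel=1e-9, abs=1e-12
            )

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_scipy_reference(self, seed):
        """Cross-check against the independent scipy implementation."""
        local = np.random.default_rng(seed)
        for _ in range(60):
            n1, n2 = local.integers(1, 40, size=2)
            k1 = local.integers(0, n1 + 1)
            k2 = local.integers(0, n2 + 1)
            odds, p = fisher_feature_test(k1, n1, k2, n2)
            odds_ref, p_ref = stats.fisher_exact(
                [[k1, n1 - k1], [k2, n2 - k2]]
            )
            assert p == pytest.approx(p_ref, rel=1e-10)
            if np.isfinite(odds_ref):
                assert odds == pytest.approx(odds_ref, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            fisher_feature_test(-1, 5, 0, 5)
        with pytest.raises(ValidationError):
            fisher_feature_test(6, 5, 0, 5)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_matches_hand_rolled_step_up(self, rng):
        p = rng.uniform(size=40)
        order = np.argsort(p)
        m = len(p)
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(benjamini_hochberg(p), oracle, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.5, 1.5])


class TestAdjustedFrequency:
    def test_macro_average_ignores_group_sizes(self):
        rows = [(f"A{i}", "TCGA_TUMOR", "T", "CTA", "NONE") for i in range(2)]
        rows += [(f"B{i}", "TCGA_TUMOR", "T", "CTB", "NONE") for i in range(98)]
        manifest = make_manifest(rows)
        # CTA: 0% mutated, CTB: 100% mutated -> macro average 50%
        feature = pd.Series(
            [0, 0] + [1] * 98, index=[r[0] for r in rows], dtype=int
        )
        assert adjusted_frequency(feature, manifest, {"CTA", "CTB"}) == pytest.approx(50.0)

    def test_single_type_equals_plain_frequency(self):
        manifest = two_type_manifest(10)
        ids = [f"CTA{i}" for i in range(10)]
        feature = pd.Series([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], index=ids)
        assert adjusted_frequency(feature, manifest, {"CTA"}) == pytest.approx(30.0)

    def test_matches_two_level_loop(self, rng):
        manifest = two_type_manifest(15)
        ids = list(manifest.frame.loc[manifest.is_tumor, "sample_id"])
        feature = pd.Series(rng.integers(0, 2, len(ids)), index=ids)
        group = {"CTA", "CTB"}
        ct = manifest.cancer_type_of()
        per_type = []
        for c in sorted(group):
            members = [s for s in ids if ct[s] == c]
            per_type.append(sum(feature[s] for s in members) / len(members))
        oracle = 100 * sum(per_type) / len(per_type)
        assert adjusted_frequency(feature, manifest, group) == pytest.approx(oracle)

    def test_invariant_to_duplicating_one_type(self, rng):
        manifest = two_type_manifest(10)
        ids = list(manifest.frame.loc[manifest.is_tumor, "sample_id"])
        feature = pd.Series(rng.integers(0, 2, len(ids)), index=ids)
        base = adjusted_frequency(feature, manifest, {"CTA", "CTB"})
        # duplicate every CTA sample
        extra_rows = [
            (f"dup{i}", "TCGA_TUMOR", "TisA", "CTA", "NONE") for i in range(10)
        ]
        manifest2 = make_manifest(
            list(manifest.frame.itertuples(index=False)) + extra_rows
        )
        feature2 = pd.concat(
            [feature,
             pd.Series(feature[[f"CTA{i}" for i in range(10)]].to_numpy(),
                       index=[f"dup{i}" for i in range(10)])]
        )
        dup = adjusted_frequency(feature2, manifest2, {"CTA", "CTB"})
        assert dup == pytest.approx(base)

    def test_empty_group_rejected(self, rng):
        manifest = two_type_manifest(5)
        ids = list(manifest.frame.loc[manifest.is_tumor, "sample_id"])
        feature = pd.Series(rng.integers(0, 2, len(ids)), index=ids)
        with pytest.raises(ValidationError):
            adjusted_frequency(feature, manifest, set())


class TestCompareMutations:
    @staticmethod
    def _groups():
        return GroupAssignment(frozenset({"CTA"}), frozenset({"CTB"}))

    def test_unmutated_gene_has_p_one(self):
        manifest = two_type_manifest(10)
        ids = list(manifest.frame.loc[manifest.is_tumor, "sample_id"])
        mut = pd.DataFrame(0, index=["G1"], columns=ids)
        result = compare_mutations(mut, manifest, self._groups())
        assert result.loc[0, "p"] == 1.0
        assert result.loc[0, "q"] == 1.0

    def test_planted_enrichment_attains_smallest_q(self):
        local = np.random.default_rng(7)
        n = 300
        rows = [(f"A{i}", "TCGA_TUMOR", "TisA", "CTA", "NONE") for i in range(n)]
        rows += [(f"B{i}", "TCGA_TUMOR", "TisB", "CTB", "NONE") for i in range(n)]
        rows += [("NA0", "GTEX", "TisA", "", "NONE"), ("NB0", "GTEX", "TisB", "", "NONE")]
        manifest = make_manifest(rows)
        ids = [r[0] for r in rows[: 2 * n]]
        genes = [f"G{i}" for i in range(20)]
        mut = pd.DataFrame(
            local.binomial(1, 0.1, size=(20, 2 * n)), index=genes, columns=ids
        )
        # plant ~5x odds in group 2 for G0
        mut.loc["G0", [f"B{i}" for i in range(n)]] = local.binomial(1, 0.36, n)
        result = compare_mutations(mut, manifest, self._groups()).set_index("feature_id")
        assert result["q"].idxmin() == "G0"
        assert result.loc["G0", "q"] < 0.05

    def test_label_permutation_gives_uniform_p(self):
        """Null calibration: permuting group labels yields uniform p."""
        local = np.random.default_rng(3)
        n = 60
        rows = [(f"A{i}", "TCGA_TUMOR", "TisA", "CTA", "NONE") for i in range(n)]
        rows += [(f"B{i}", "TCGA_TUMOR", "TisB", "CTB", "NONE") for i in range(n)]
        rows += [("NA0", "GTEX", "TisA", "", "NONE"), ("NB0", "GTEX", "TisB", "", "NONE")]
        manifest = make_manifest(rows)
        ids = [r[0] for r in rows[: 2 * n]]
        mut = pd.DataFrame(
            local.binomial(1, 0.3, size=(400, 2 * n)),
            index=[f"G{i}" for i in range(400)],
            columns=ids,
        )
        result = compare_mutations(mut, manifest, self._groups())
        # Fisher p-values are discrete and conservative; KS against uniform
        # is run one-sided in the anti-conservative direction
        p = result["p"].to_numpy()
        stat, ks_p = stats.kstest(p, "uniform", alternative="greater")
        assert ks_p > 0.01

    def test_q_below_alpha_rate_controlled_under_null(self):
        local = np.random.default_rng(9)
        n = 50
        rows = [(f"A{i}", "TCGA_TUMOR", "TisA", "CTA", "NONE") for i in range(n)]
        rows += [(f"B{i}", "TCGA_TUMOR", "TisB", "CTB", "NONE") for i in range(n)]
        rows += [("NA0", "GTEX", "TisA", "", "NONE"), ("NB0", "GTEX", "TisB", "", "NONE")]
        manifest = make_manifest(rows)
        ids = [r[0] for r in rows[: 2 * n]]
        mut = pd.DataFrame(
            local.binomial(1, 0.25, size=(300, 2 * n)),
            index=[f"G{i}" for i in range(300)],
            columns=ids,
        )
        result = compare_mutations(mut, manifest, self._groups())
        assert (result["q"] < 0.05).mean() <= 0.05 + 0.02

    def test_cmh_mode_runs_and_agrees_in_direction(self):
        local = np.random.default_rng(5)
        n = 100
        rows = [(f"A{i}", "TCGA_TUMOR", "TisA", "CTA", "NONE") for i in range(n)]
        rows += [(f"B{i}", "TCGA_TUMOR", "TisB", "CTB", "NONE") for i in range(n)]
        rows += [("NA0", "GTEX", "TisA", "", "NONE"), ("NB0", "GTEX", "TisB", "", "NONE")]
        manifest = make_manifest(rows)
        ids = [r[0] for r in rows[: 2 * n]]
        mut = pd.DataFrame(
            np.concatenate([local.binomial(1, 0.1, (1, n)),
                            local.binomial(1, 0.5, (1, n))], axis=1),
            index=["G0"], columns=ids,
        )
        # strata must cut across both groups (e.g. a batch label)
        strata = pd.Series(
            ["batch%d" % (i % 2) for i in range(2 * n)], index=ids
        )
        pooled = compare_mutations(mut, manifest, self._groups(), method="pooled")
        cmh = compare_mutations(
            mut, manifest, self._groups(), method="cmh", strata=strata
        )
        assert pooled.loc[0, "p"] < 0.01
        assert cmh.loc[0, "p"] < 0.01

    def test_cmh_with_degenerate_strata_rejected(self):
        n = 20
        rows = [(f"A{i}", "TCGA_TUMOR", "TisA", "CTA", "NONE") for i in range(n)]
        rows += [(f"B{i}", "TCGA_TUMOR", "TisB", "CTB", "NONE") for i in range(n)]
        rows += [("NA0", "GTEX", "TisA", "", "NONE"), ("NB0", "GTEX", "TisB", "", "NONE")]
        manifest = make_manifest(rows)
        ids = [r[0] for r in rows[: 2 * n]]
        mut = pd.DataFrame(
            np.zeros((1, 2 * n), dtype=int), index=["G0"], columns=ids
        )
        mut.iloc[0, :5] = 1
        strata = manifest.cancer_type_of().loc[ids]  # nested in groups
        with pytest.raises(ValidationError, match="stratum"):
            compare_mutations(mut, manifest, self._groups(), method="cmh",
                              strata=strata)


class TestCompareArmCalls:
    @staticmethod
    def _manifest(n):
        rows = [(f"A{i}", "TCGA_TUMOR", "TisA", "CTA", "NONE") for i in range(n)]
        rows += [(f"B{i}", "TCGA_TUMOR", "TisB", "CTB", "NONE") for i in range(n)]
        rows += [("NA0", "GTEX", "TisA", "", "NONE"), ("NB0", "GTEX", "TisB", "", "NONE")]
        return make_manifest(rows)

    def test_extreme_deletion_table_significant(self):
        n = 20
        manifest = self._manifest(n)
        ids = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
        calls = pd.DataFrame(0, index=["16q"], columns=ids)
        calls.loc["16q", [f"B{i}" for i in range(n)]] = -1
        result = compare_arm_calls(
            calls, manifest, GroupAssignment(frozenset({"CTA"}), frozenset({"CTB"}))
        ).set_index("feature_id")
        assert result.loc["16q_del", "q"] < 0.05
        assert result.loc["16q_amp", "p"] == 1.0

    def test_identical_distributions_nothing_significant(self, rng):
        n = 40
        manifest = self._manifest(n)
        ids = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
        pattern = rng.choice([-1, 0, 1], size=(5, n))
        calls = pd.DataFrame(
            np.hstack([pattern, pattern]),
            index=["1p", "1q", "8p", "16q", "22q"],
            columns=ids,
        )
        result = compare_arm_calls(
            calls, manifest, GroupAssignment(frozenset({"CTA"}), frozenset({"CTB"}))
        )
        assert (result["q"] >= 0.05).all()

    def test_directions_tested_separately_and_filter(self):
        n = 30
        manifest = self._manifest(n)
        ids = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
        calls = pd.DataFrame(0, index=["3q"], columns=ids)
        calls.loc["3q", [f"B{i}" for i in range(n)]] = 1  # pure amplification
        result = compare_arm_calls(
            calls, manifest, GroupAssignment(frozenset({"CTA"}), frozenset({"CTB"}))
        )
        enriched = enriched_in_group2(result)
        assert list(enriched["feature_id"]) == ["3q_amp"]

    def test_invalid_code_rejected(self):
        manifest = self._manifest(3)
        calls = pd.DataFrame([[2, 0, 0, 0, 0, 0]], index=["1p"],
                             columns=[f"A{i}" for i in range(3)] + [f"B{i}" for i in range(3)])
        with pytest.raises(ValidationError):
            compare_arm_calls(calls, manifest, GroupAssignment(frozenset({"CTA"}),
                                                               frozenset({"CTB"})))


def test_planted_arm_enrichment_recovery(small_cohort):
    """The generator's enriched arms are the significant group-2 deletions/
    amplifications."""
    truth = small_cohort.truth
    groups = GroupAssignment(
        frozenset(truth.group1_cancer_types), frozenset(truth.group2_cancer_types)
    )
    result = compare_arm_calls(small_cohort.arm_calls, small_cohort.manifest, groups)
    enriched = set(enriched_in_group2(result)["feature_id"])
    expected = {
        f"{arm}_{'amp' if info['direction'] > 0 else 'del'}"
        for arm, info in truth.arm_rates.items()
        if info["group2"] > info["group1"]
    }
    assert expected <= enriched
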