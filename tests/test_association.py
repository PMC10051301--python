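import numpy as np
import pandas as pd
import pytest

from seroprofile import (
    AntigenRecord,
    ValidationError,
    autoantibody_load,
    compare_load,
    compare_load_multi,
    fisher_exact_p,
    load_age_correlation,
    panel_augmentation,
    prevalence_test,
    select_candidates,
)
from seroprofile.association import PrevalenceResult, benjamini_hochberg

from oracles import fisher_two_sided_oracle, mannwhitney_two_sided_oracle


def series(values, prefix="s"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


class TestLoad:
    def test_row_sums(self):
        df = pd.DataFrame([[1, 0, 1, 1], [0, 0, 0, 0]], index=["a", "b"])
        load = autoantibody_load(df)
        assert load["a"] == 3 and load["b"] == 0

    def test_load_spans_fixture_range(self):
        mat = np.zeros((15, 20), dtype=int)
        for i in range(15):
            mat[i, : i + 1] = 1
        load = autoantibody_load(pd.DataFrame(mat))
        assert load.min() == 1 and load.max() == 15


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        load = series([1, 2, 3, 4, 5, 6])
        labels = series(["x"] * 3 + ["y"] * 3)
        assert compare_load(load, labels).p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one(self):
        load = series([1, 2, 3, 1, 2, 3])
        labels = series(["x"] * 3 + ["y"] * 3)
        assert compare_load(load, labels).p_value == pytest.approx(1.0)

    def test_empty_group_is_error(self):
        load = series([1, 2, 3])
        labels = series(["x", "x", "x"])
        with pytest.raises(ValidationError):
            compare_load(load, labels)

    @pytest.mark.parametrize("n1,n2,seed", [(3, 3, 0), (4, 6, 1), (5, 5, 2), (8, 7, 3), (2, 8, 4)])
    def test_exact_p_matches_enumeration_oracle(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        values = rng.permutation(np.arange(1, n1 + n2 + 1)).astype(float)
        load = series(values)
        labels = series(["x"] * n1 + ["y"] * n2)
        expected = mannwhitney_two_sided_oracle(values[:n1], values[n1:])
        assert compare_load(load, labels).p_value == pytest.approx(expected, abs=1e-12)


class TestKruskalWallis:
    def test_constant_sample_h_zero(self):
        load = series([4, 4, 4, 4, 4, 4])
        labels = series(["a", "a", "b", "b", "c", "c"])
        result = compare_load_multi(load, labels)
        assert result.statistic == 0.0 and result.p_value == 1.0

    def test_matches_rank_formula_hand_computation(self):
        """Groups [1,2],[3,4],[5,6]: H = 12/(6*7) * (3^2+7^2+11^2)/2 - 3*7 = 32/7."""
        from scipy.stats import chi2

        load = series([1, 2, 3, 4, 5, 6])
        labels = series(["a", "a", "b", "b", "c", "c"])
        result = compare_load_multi(load, labels)
        assert result.statistic == pytest.approx(32 / 7, abs=1e-12)
        assert result.p_value == pytest.approx(chi2.sf(32 / 7, 2), abs=1e-12)

    def test_two_groups_rejected(self):
        load = series([1, 2, 3, 4])
        labels = series(["a", "a", "b", "b"])
        with pytest.raises(ValidationError):
            compare_load_multi(load, labels)

    def test_fibrosis_boost_orders_group_medians(self, called_cohort):
        """The generator's load boost puts the lung-fibrosis + high-skin-score
        subgroup at the highest median load (single-feature groups in between)."""
        calls, metadata, _, _, _ = called_cohort
        meta = {r.sample_id: r for r in metadata}
        case_ids = [r.sample_id for r in metadata if r.group == "case"]

        def subgroup(r):
            lf = bool(r.flag("lung_fibrosis"))
            high = r.mrss is not None and r.mrss > 15
            return {(False, False): "neither", (True, False): "lf_only",
                    (False, True): "mrss_only", (True, True): "both"}[(lf, high)]

        labels = pd.Series({s: subgroup(meta[s]) for s in case_ids})
        load = autoantibody_load(calls)[case_ids]
        result = compare_load_multi(load, labels)
        medians = result.group_medians
        assert medians["both"] == max(medians.values())
        assert medians["both"] > medians["neither"]
        assert result.p_value < 0.05


class TestCorrelation:
    def test_monotone_pairs(self):
        load = series([1, 2, 3, 4, 5])
        age = series([10, 20, 30, 40, 50])
        assert load_age_correlation(load, age)[0] == pytest.approx(1.0)
        assert load_age_correlation(load, age[::-1].set_axis(age.index))[0] == pytest.approx(-1.0)

    def test_constant_vector_is_error(self):
        with pytest.raises(ValidationError):
            load_age_correlation(series([1, 1, 1]), series([4, 5, 6]))

    def test_null_correlation_centred_on_zero(self):
        rng = np.random.default_rng(6)
        rs = []
        for _ in range(300):
            load = series(rng.poisson(5, 40).astype(float))
            age = series(rng.integers(20, 80, 40).astype(float))
            rs.append(load_age_correlation(load, age)[0])
        se = 1 / np.sqrt(40 - 1) / np.sqrt(300)
        assert abs(np.mean(rs)) < 3 * se


class TestFisher:
    def test_diagonal_table(self):
        assert fisher_exact_p(3, 0, 0, 3) == pytest.approx(0.1, abs=1e-12)

    def test_balanced_table_p_one(self):
        assert fisher_exact_p(1, 1, 1, 1) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_tables(self):
        for n in range(2, 15):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        if a + b == 0 or c + d == 0:
                            continue
                        assert fisher_exact_p(a, b, c, d) == pytest.approx(
                            fisher_two_sided_oracle(a, b, c, d), abs=1e-12
                        )

    def test_prevalence_test_counts_and_missing_handling(self):
        calls = series([1, 1, 0, 0, 1, 0])
        labels = series(["case", "case", "case", "control", "control", "control"])
        labels.iloc[5] = None
        result = prevalence_test(calls, labels, target_id="t")
        assert (result.a, result.b, result.c, result.d) == (2, 1, 1, 1)
        assert result.n_controls == 2  # missing-label sample dropped

    def test_empty_margin_is_error(self):
        calls = series([1, 0])
        labels = series(["case", "case"])
        with pytest.raises(ValidationError):
            prevalence_test(calls, labels)


class TestSelectionRule:
    @staticmethod
    def result(target, a, b, c, d):
        from seroprofile.association import fisher_exact_p as f

        return PrevalenceResult(target, a, b, c, d, f(a, b, c, d))

    def test_significant_target_selected_regardless_of_flag(self):
        res = self.result("scl70", 18, 37, 4, 48)  # p < 0.05
        (decision,) = select_candidates([res], [AntigenRecord("scl70", "TOP1")])
        assert decision.significant and decision.selected

    def test_fibrosis_flag_rescues_nonsignificant_excess(self):
        res = self.result("ctgf", 4, 51, 1, 51)
        panel = [AntigenRecord("ctgf", "CTGF", fibrosis_related=True)]
        (decision,) = select_candidates([res], panel)
        assert not decision.significant
        assert decision.fibrosis_rescued and decision.selected

    def test_no_excess_never_selected(self):
        res = self.result("flat", 2, 53, 2, 50)
        panel = [AntigenRecord("flat", "FLAT", fibrosis_related=True)]
        (decision,) = select_candidates([res], panel)
        assert not decision.selected

    def test_selected_equals_significant_or_rescued(self):
        rng = np.random.default_rng(13)
        results, panel = [], []
        for i in range(50):
            a, c = int(rng.integers(0, 20)), int(rng.integers(0, 20))
            results.append(self.result(f"t{i}", a, 55 - a, c, 52 - c))
            panel.append(
                AntigenRecord(f"t{i}", f"P{i}", fibrosis_related=bool(rng.random() < 0.5))
            )
        for d in select_candidates(results, panel):
            assert d.selected == (d.significant or d.fibrosis_rescued)

    def test_bh_adjustment_is_monotone_and_conservative(self):
        p = [0.001, 0.01, 0.02, 0.04, 0.5]
        adj = benjamini_hochberg(p)
        assert all(a >= raw for a, raw in zip(adj, p))
        assert list(adj) == sorted(adj)


class TestAugmentation:
    def test_marker_rescues_clinical_negatives(self):
        clinical = [True] * 41 + [False] * 14
        marker = [False] * 41 + [True] * 7 + [False] * 7
        result = panel_augmentation(clinical, marker)
        assert (result.baseline_pct, result.augmented_pct) == (75, 87)
        assert result.n_augmented_positive == 48

    def test_marker_only_among_positives_changes_nothing(self):
        clinical = [True, True, False]
        marker = [True, False, False]
        result = panel_augmentation(clinical, marker)
        assert result.augmented_pct == result.baseline_pct

    def test_all_marker_positive_reaches_100(self):
        result = panel_augmentation([False, True], [True, True])
        assert result.augmented_pct == 100

    def test_augmented_never_below_baseline(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            clinical = rng.random(30) < rng.random()
            marker = rng.random(30) < rng.random()
            result = panel_augmentation(clinical, marker)
            assert result.augmented_pct >= result.baseline_pct
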