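"""CoV baselines, scanner bias, group aggregation, IQM z-scores, edge selection."""

import numpy as np
import pandas as pd
import pytest

from harmony_bench import (
    aggregate_by_group,
    class_cov_profile,
    coefficient_of_variation,
    relative_difference,
    scanner_bias,
    select_top_edges,
    zscore_iqms,
)
from harmony_bench.tables import CategoryMap, ContractError

from conftest import make_study


class TestCoefficientOfVariation:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([5.0, 5.0, 5.0], 0.0),
            ([1.0, 2.0, 3.0], 0.5),  # sd(n-1)=1, mean=2
            ([9.0, 11.0], np.sqrt(2.0) / 10.0),
        ],
    )
    def test_known_values(self, values, expected):
        assert coefficient_of_variation(values) == pytest.approx(expected)

    def test_zero_mean_is_undefined(self):
        assert np.isnan(coefficient_of_variation([1.0, -1.0]))

    def test_single_value_is_undefined(self):
        assert np.isnan(coefficient_of_variation([3.0]))

    def test_population_divisor_option(self):
        # ddof=0: sd([1,2,3]) = sqrt(2/3)
        assert coefficient_of_variation([1, 2, 3], ddof=0) == pytest.approx(
            np.sqrt(2.0 / 3.0) / 2.0
        )

    def test_positive_scaling_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(10, 1, size=20)
        assert coefficient_of_variation(7.3 * v) == pytest.approx(
            coefficient_of_variation(v)
        )


class TestClassCovProfile:
    def test_hand_oracle_on_toy_study(self, toy_study):
        rep = class_cov_profile(toy_study).per_idp
        # within: subject A on s1 has [9, 11] -> sd=sqrt(2), mean=10
        assert rep.loc["idp_0", "cov_within_scanner"] == pytest.approx(
            np.sqrt(2.0) / 10.0
        )
        # between: A has primaries (9, 10) -> CoV = sd/mean; B has (20, 22)
        cov_a = np.std([9, 10], ddof=1) / np.mean([9, 10])
        cov_b = np.std([20, 22], ddof=1) / np.mean([20, 22])
        assert rep.loc["idp_0", "cov_between_scanner"] == pytest.approx(
            (cov_a + cov_b) / 2
        )
        # biological: per scanner across subjects' primaries, then averaged
        cov_s1 = np.std([9, 20], ddof=1) / np.mean([9, 20])
        cov_s2 = np.std([10, 22], ddof=1) / np.mean([10, 22])
        assert rep.loc["idp_0", "cov_biological"] == pytest.approx(
            (cov_s1 + cov_s2) / 2
        )

    def test_identical_values_give_zero_between_cov(self):
        rows = [("A_s1_rep0", "A", "s1", 0), ("A_s2_rep0", "A", "s2", 0)]
        study = make_study(rows, {r[0]: [10.0, 10.0] for r in rows})
        with pytest.warns(UserWarning, match="within-scanner"):
            rep = class_cov_profile(study).per_idp
        assert (rep["cov_between_scanner"] == 0).all()
        assert rep["cov_within_scanner"].isna().all()  # no repeats anywhere

    def test_no_repeats_warns_and_leaves_within_missing(self):
        rows = [("A_s1_rep0", "A", "s1", 0), ("B_s1_rep0", "B", "s1", 0)]
        study = make_study(rows, {"A_s1_rep0": [1.0, 2.0], "B_s1_rep0": [3.0, 4.0]})
        with pytest.warns(UserWarning, match="within-scanner"):
            rep = class_cov_profile(study).per_idp
        assert rep["cov_within_scanner"].isna().all()

    def test_mean_of_repeats_policy(self, toy_study):
        rep = class_cov_profile(toy_study, between_policy="mean-of-repeats").per_idp
        # subject A's scanner-1 entry becomes mean(9, 11) = 10
        cov_a = np.std([10, 10], ddof=1) / 10.0
        cov_b = np.std([20, 22], ddof=1) / np.mean([20, 22])
        assert rep.loc["idp_0", "cov_between_scanner"] == pytest.approx(
            (cov_a + cov_b) / 2
        )

    def test_unknown_policy_raises(self, toy_study):
        with pytest.raises(ContractError):
            class_cov_profile(toy_study, between_policy="bogus")


class TestRelativeDifference:
    @pytest.mark.parametrize(
        "between, within, expected",
        [(0.02, 0.02, 0.0), (0.06, 0.02, 200.0), (0.01, 0.02, -50.0)],
    )
    def test_arithmetic(self, between, within, expected):
        assert relative_difference(between, within) == pytest.approx(expected)

    def test_nonpositive_within_is_missing(self):
        assert np.isnan(relative_difference(0.1, 0.0))
        assert np.isnan(relative_difference(0.1, -0.5))


class TestScannerBias:
    def test_hand_oracle(self, toy_study):
        report = scanner_bias(toy_study)
        # subject A: within mean over s1 sessions = (9+11)/2 = 10;
        # between mean over primaries = (9+10)/2 = 9.5 -> bias = -5%
        assert report.per_subject.loc["A", "idp_0"] == pytest.approx(
            100 * (9.5 - 10.0) / 10.0
        )
        assert report.group["idp_0"] == pytest.approx(-5.0)

    def test_identical_data_gives_zero_bias(self):
        rows = [
            ("A_s1_rep0", "A", "s1", 0),
            ("A_s1_rep1", "A", "s1", 1),
            ("A_s2_rep0", "A", "s2", 0),
        ]
        study = make_study(rows, {r[0]: [7.0, 3.0] for r in rows})
        report = scanner_bias(study)
        np.testing.assert_allclose(report.per_subject.to_numpy(), 0.0)

    def test_vendor_restricted_variant(self):
        rows = [
            ("A_s1_rep0", "A", "s1", "site1", "vendX", 0, 30.0, "M"),
            ("A_s1_rep1", "A", "s1", "site1", "vendX", 1, 30.0, "M"),
            ("A_s2_rep0", "A", "s2", "site2", "vendX", 0, 30.0, "M"),
            ("A_s3_rep0", "A", "s3", "site3", "vendY", 0, 30.0, "M"),
        ]
        values = {
            "A_s1_rep0": [10.0],
            "A_s1_rep1": [10.0],
            "A_s2_rep0": [12.0],
            "A_s3_rep0": [40.0],
        }
        cats = pd.DataFrame(
            {"category": ["c", "c"], "group": ["g", "g"], "modality": ["m", "m"]},
            index=pd.Index(["idp_0", "idp_1"], name="idp_name"),
        )
        for k in values:
            values[k] = values[k] + [1.0]
        study = make_study(rows, values, categories=cats)
        report = scanner_bias(study)
        # all-scanner between mean = (10+12+40)/3; same-vendor = (10+12)/2
        assert report.per_subject.loc["A", "idp_0"] == pytest.approx(
            100 * (62 / 3 - 10) / 10
        )
        assert report.per_subject_same_vendor.loc["A", "idp_0"] == pytest.approx(
            100 * (11 - 10) / 10
        )

    def test_no_repeats_raises(self):
        rows = [("A_s1_rep0", "A", "s1", 0), ("B_s1_rep0", "B", "s1", 0)]
        study = make_study(rows, {r[0]: [1.0, 2.0] for r in rows})
        with pytest.raises(ContractError):
            scanner_bias(study)


class TestAggregateByGroup:
    def _cats(self, mapping):
        return CategoryMap(
            entries=pd.DataFrame(
                {
                    "category": list(mapping.values()),
                    "group": list(mapping.values()),
                    "modality": "m",
                },
                index=pd.Index(mapping.keys(), name="idp_name"),
            )
        )

    def test_mean_and_median(self):
        cats = self._cats({"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        per_idp = pd.DataFrame({"cov": [0.1, 0.3, 1.0, 2.0]}, index=list("abcd"))
        assert aggregate_by_group(per_idp, cats, "mean").loc["g1", "cov"] == pytest.approx(0.2)
        assert aggregate_by_group(per_idp, cats, "median").loc["g2", "cov"] == pytest.approx(1.5)

    def test_all_missing_group_stays_missing(self):
        cats = self._cats({"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        per_idp = pd.DataFrame({"cov": [np.nan, np.nan, 1.0, 3.0]}, index=list("abcd"))
        agg = aggregate_by_group(per_idp, cats, "mean")
        assert np.isnan(agg.loc["g1", "cov"])
        assert agg.loc["g2", "cov"] == pytest.approx(2.0)

    def test_singleton_groups_reproduce_per_idp(self):
        cats = self._cats({"a": "ga", "b": "gb", "c": "ga", "d": "gb"})
        cats.entries["group"] = ["ga", "gb", "gc", "gd"]
        per_idp = pd.DataFrame({"cov": [0.1, 0.2, 0.3, 0.4]}, index=list("abcd"))
        agg = aggregate_by_group(per_idp, cats, "mean")
        np.testing.assert_allclose(agg["cov"].to_numpy(), per_idp["cov"].to_numpy())

    def test_unmapped_idp_raises(self):
        cats = self._cats({"a": "g1", "b": "g1"})
        per_idp = pd.DataFrame({"cov": [0.1]}, index=["zz"])
        with pytest.raises(ContractError):
            aggregate_by_group(per_idp, cats)


def _iqm_study(values_fn, n_sub=3, n_scan=3, with_repeat=True):
    rows, iqms = [], {}
    for i in range(n_sub):
        for j in range(n_scan):
            sid = f"S{i}_sc{j}_rep0"
            rows.append((sid, f"S{i}", f"sc{j}", 0))
            iqms[sid] = values_fn(i, j)
    if with_repeat:
        rows.append(("S0_sc0_rep1", "S0", "sc0", 1))
        iqms["S0_sc0_rep1"] = [999.0, 999.0]  # must be excluded from z-scoring
    values = {r[0]: [1.0, 2.0] for r in rows}
    return make_study(rows, values, iqm_values=iqms)


class TestZscoreIqms:
    def test_identical_values_give_zeros(self):
        study = _iqm_study(lambda i, j: [5.0, 5.0])
        z = zscore_iqms(study, "across_scanners")
        np.testing.assert_array_equal(z.to_numpy(), 0.0)

    def test_repeats_are_excluded(self):
        # the 999-valued repeat session must not perturb the z-scores
        study = _iqm_study(lambda i, j: [5.0, 5.0])
        z = zscore_iqms(study, "across_scanners")
        np.testing.assert_array_equal(z.to_numpy(), 0.0)

    def test_shifted_scanner_is_the_column_maximum(self):
        study = _iqm_study(lambda i, j: [float(i) + (4.0 if j == 1 else 0.0), 1.0])
        z = zscore_iqms(study, "across_scanners")
        assert z["iqm_0"].idxmax() == "sc1"
        assert z["iqm_0"].max() > 0

    def test_across_subjects_axis(self):
        study = _iqm_study(lambda i, j: [10.0 if i == 2 else 0.0, 1.0])
        z = zscore_iqms(study, "across_subjects")
        assert z["iqm_0"].idxmax() == "S2"
        assert set(z.index) == {"S0", "S1", "S2"}

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        draws = {(i, j): list(rng.normal(size=2)) for i in range(3) for j in range(3)}
        s1 = _iqm_study(lambda i, j: draws[(i, j)])
        s2 = _iqm_study(lambda i, j: [3.0 * draws[(i, j)][0] - 7.0, draws[(i, j)][1]])
        pd.testing.assert_frame_equal(
            zscore_iqms(s1, "across_scanners"), zscore_iqms(s2, "across_scanners")
        )

    def test_no_iqms_raises(self, toy_study):
        with pytest.raises(ContractError):
            zscore_iqms(toy_study)


class TestSelectTopEdges:
    def _edge_study(self, means):
        rows = [
            ("A_s1_rep0", "A", "s1", 0),
            ("A_s1_rep1", "A", "s1", 1),
            ("B_s2_rep0", "B", "s2", 0),
        ]
        values = {
            "A_s1_rep0": list(means),
            "A_s1_rep1": list(means),
            "B_s2_rep0": [100.0] * len(means),  # not in any repeat set
        }
        return make_study(rows, values)

    def test_fraction_arithmetic(self):
        study = self._edge_study(np.linspace(1, 10, 10))
        kept = select_top_edges(study, "cat_a", fraction=0.2)
        assert len(kept) == 2

    def test_ranked_by_absolute_mean(self):
        study = self._edge_study([0.9, -0.8, 0.1, 0.2, -0.05])
        kept = select_top_edges(study, "cat_a", k_override=2)
        assert kept == ["idp_0", "idp_1"]

    def test_k_override_identity(self):
        study = self._edge_study([1.0, 2.0, 3.0])
        kept = select_top_edges(study, "cat_a", k_override=3)
        assert sorted(kept) == ["idp_0", "idp_1", "idp_2"]

    def test_k_exceeding_edge_count_raises(self):
        study = self._edge_study([1.0, 2.0])
        with pytest.raises(ContractError):
            select_top_edges(study, "cat_a", k_override=5)

    def test_repeat_set_defines_strength(self):
        # subject B's extreme values must not influence the ranking
        study = self._edge_study([0.1, 0.5, 0.3])
        kept = select_top_edges(study, "cat_a", k_override=1)
        assert kept == ["idp_1"]
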