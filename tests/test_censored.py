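"""Censoring rules, panel totals, class sums and summary statistics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from swallowpfas import datasets
from swallowpfas.censored import (
    anova_log,
    class_sums,
    detection_frequency,
    detection_gate,
    fold_difference,
    geometric_mean_ci,
    pearson_r,
    substitute_half_dl,
    summarize_sites,
    teq,
    total_panel,
)
from swallowpfas.model import ValidationError

pos_floats = st.floats(min_value=1e-6, max_value=1e6)


def diet_record(site, make_sample, region="North"):
    """Published composited diet column as a fully-detected SampleRecord."""
    values = datasets.site_geomean_map(datasets.diet_concentrations(), site)
    return make_sample(
        values, sample_id=site, site=site, region=region, matrix="diet"
    )


class TestDetectionFrequency:
    def test_all_detected_is_100(self, make_sample):
        samples = [
            make_sample({"PFOS": 5.0}, sample_id=f"s{i}") for i in range(47)
        ]
        assert detection_frequency(samples, "PFOS").percent == 100

    def test_none_detected_is_0(self, make_sample):
        samples = [
            make_sample({"PFOS": (None, False)}, sample_id=f"s{i}")
            for i in range(5)
        ]
        assert detection_frequency(samples, "PFOS").percent == 0

    def test_half_detected_fails_strict_gate(self, make_sample):
        samples = [
            make_sample({"PFOS": 5.0}, sample_id=f"d{i}") for i in range(3)
        ] + [
            make_sample({"PFOS": (None, False)}, sample_id=f"n{i}")
            for i in range(3)
        ]
        freq = detection_frequency(samples, "PFOS")
        assert freq.percent == 50
        assert "PFOS" not in detection_gate(samples)

    def test_gate_admits_above_half(self, make_sample):
        samples = [
            make_sample({"PFHxS": 2.0}, sample_id=f"d{i}") for i in range(4)
        ] + [
            make_sample({"PFHxS": (None, False)}, sample_id="n0")
        ]
        assert "PFHxS" in detection_gate(samples)

    def test_absent_analyte_errors(self, make_sample):
        with pytest.raises(ValidationError, match="PFNA"):
            detection_frequency([make_sample({"PFOS": 1.0})], "PFNA")

    def test_invariant_under_reordering(self, make_sample):
        samples = [
            make_sample({"PFOS": (None, False)}, sample_id="a"),
            make_sample({"PFOS": 3.0}, sample_id="b"),
            make_sample({"PFOS": 4.0}, sample_id="c"),
        ]
        forward = detection_frequency(samples, "PFOS")
        assert forward == detection_frequency(samples[::-1], "PFOS")


class TestHalfDlSubstitution:
    def test_nondetect_gets_half_dl(self, make_sample):
        # 7:3 FTCA default DL is 3.0
        rec = make_sample({"7:3 FTCA": (None, False)})
        (out,) = substitute_half_dl([rec], {"7:3 FTCA"})
        assert out.measurements["7:3 FTCA"].value == 1.5
        assert out.measurements["7:3 FTCA"].detected is False

    def test_detect_unchanged(self, make_sample):
        rec = make_sample({"PFOS": 5.0})
        (out,) = substitute_half_dl([rec], {"PFOS"})
        assert out.measurements["PFOS"].value == 5.0

    def test_never_decreases_and_keeps_flags(self, make_sample):
        rec = make_sample({"PFOS": 5.0, "PFHxS": (None, False)})
        (out,) = substitute_half_dl([rec], {"PFOS", "PFHxS"})
        for analyte, before in rec.measurements.items():
            after = out.measurements[analyte]
            assert after.detected == before.detected
            assert after.half_dl_value() >= (before.value or 0.0)


class TestPanelTotals:
    def test_published_diet_totals(self, registry, make_sample):
        martin = diet_record("Martin Road", make_sample)
        assert total_panel(martin, "PFAS40", registry) == pytest.approx(
            92.0, abs=0.05
        )
        assert total_panel(martin, "PFAS13", registry) == pytest.approx(
            47.0, abs=0.06
        )

    def test_all_nondetect_totals_zero(self, registry, make_sample):
        rec = make_sample({
            "PFOS": (None, False), "PFOA": (None, False),
        })
        assert total_panel(rec, "PFAS40", registry) == 0.0

    def test_nondetects_excluded_from_totals(self, registry, make_sample):
        rec = make_sample({"PFOS": 10.0, "PFHxS": (None, False)})
        assert total_panel(rec, "PFAS40", registry) == 10.0

    def test_monotone_in_panel_nesting(self, registry):
        from swallowpfas.synthgen import region_dataset

        records, _ = region_dataset(seed=11, n_per_site=5)
        for rec in records:
            t13 = total_panel(rec, "PFAS13", registry)
            t33 = total_panel(rec, "PFAS33", registry)
            t40 = total_panel(rec, "PFAS40", registry)
            assert t13 <= t33 + 1e-12
            assert t33 <= t40 + 1e-12


class TestClassSums:
    def test_published_nestling_sums(self):
        table = datasets.nestling_site_geomeans()
        carb, sulf = class_sums(
            datasets.site_geomean_map(table, "Rice Lake North")
        )
        assert sulf == pytest.approx(130.19, abs=0.005)
        assert carb == pytest.approx(6.67, abs=0.005)
        carb, sulf = class_sums(
            datasets.site_geomean_map(table, "Boulder Lake")
        )
        assert (carb, sulf) == (pytest.approx(3.03), pytest.approx(1.28))

    def test_published_reference_egg_sums(self):
        table = datasets.egg_site_geomeans()
        carb, sulf = class_sums(
            datasets.site_geomean_map(table, "Boulder Lake")
        )
        assert carb == pytest.approx(4.94, abs=0.005)
        assert sulf == pytest.approx(6.40, abs=0.005)

    def test_all_zero_sample(self):
        assert class_sums({"PFOS": 0.0, "PFOA": 0.0}) == (0.0, 0.0)

    def test_empty_member_list_errors(self):
        with pytest.raises(ValidationError):
            class_sums({"PFOS": 1.0}, carboxylates=(), sulfonates=("PFOS",))


class TestGeometricMean:
    def test_two_point_mean(self):
        gm, _, _ = geometric_mean_ci([1.0, 100.0])
        assert gm == pytest.approx(10.0)

    def test_zero_variance(self):
        gm, lo, hi = geometric_mean_ci([5.0, 5.0, 5.0])
        assert (gm, lo, hi) == (
            pytest.approx(5.0), pytest.approx(5.0), pytest.approx(5.0)
        )

    def test_single_value_has_no_ci(self):
        gm, lo, hi = geometric_mean_ci([7.0])
        assert gm == pytest.approx(7.0) and lo is None and hi is None

    def test_monte_carlo_lognormal_recovery(self, rng):
        draws = rng.lognormal(mean=1.0, sigma=0.5, size=2000)
        gm, lo, hi = geometric_mean_ci(draws)
        assert gm == pytest.approx(math.e, rel=0.02)
        assert lo < gm < hi

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            geometric_mean_ci([1.0, 0.0])

    @given(st.lists(pos_floats, min_size=2, max_size=20))
    def test_am_gm_inequality(self, values):
        gm, _, _ = geometric_mean_ci(values)
        assert gm <= np.mean(values) * (1 + 1e-12)


class TestFoldDifference:
    def test_identity(self):
        assert fold_difference(3.3, 3.3) == 1.0

    def test_published_pfhxs_fold(self):
        # Rice Lake North vs reference nestling PFHxS
        assert fold_difference(8.24, 0.17) == pytest.approx(48.5, abs=0.05)

    @given(a=pos_floats, b=pos_floats)
    def test_reciprocal_symmetry(self, a, b):
        assert fold_difference(a, b) * fold_difference(b, a) == pytest.approx(
            1.0, rel=1e-9
        )


class TestAnova:
    def test_identical_groups_share_letter(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        groups = ["a"] * 3 + ["b"] * 3
        res = anova_log(values, groups)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-10)
        assert set(res.letters["a"]) & set(res.letters["b"])

    def test_separated_groups_get_distinct_letters(self, rng):
        a = 10 ** rng.normal(0.0, 1.0, size=20)
        b = 10 ** rng.normal(3.0, 1.0, size=20)
        res = anova_log(
            np.concatenate([a, b]), ["a"] * 20 + ["b"] * 20
        )
        assert res.p_value < 1e-3
        assert not set(res.letters["a"]) & set(res.letters["b"])

    def test_all_equal_three_groups(self):
        res = anova_log([2.0] * 9, ["a", "b", "c"] * 3)
        assert res.f_statistic == 0.0
        assert len({res.letters[g] for g in "abc"}) == 1

    def test_undersized_group_errors(self):
        with pytest.raises(ValidationError):
            anova_log([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestPearson:
    def test_perfect_positive(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = [1.0, 2.0, 3.0]
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_monte_carlo_bivariate_normal(self, rng):
        cov = [[1.0, 0.8], [0.8, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=5000)
        assert pearson_r(xy[:, 0], xy[:, 1]) == pytest.approx(0.8, abs=0.03)

    def test_zero_variance_errors(self):
        with pytest.raises(ValidationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTeq:
    def test_hand_example(self):
        assert teq({"A": 2.0, "B": 3.0}, {"A": 0.1, "B": 0.01}) == (
            pytest.approx(0.23)
        )

    def test_empty_is_zero(self):
        assert teq({}, {"A": 0.1}) == 0.0

    def test_unit_factors_reduce_to_sum(self):
        concs = {"A": 1.5, "B": 2.5}
        assert teq(concs, {"A": 1.0, "B": 1.0}) == pytest.approx(4.0)

    def test_missing_factor_names_congener(self):
        with pytest.raises(ValidationError, match="B"):
            teq({"A": 1.0, "B": 2.0}, {"A": 0.1})

    @given(scale=pos_floats)
    def test_linearity(self, scale):
        concs = {"A": 2.0, "B": 3.0}
        tefs = {"A": 0.1, "B": 0.01}
        scaled = {k: v * scale for k, v in concs.items()}
        assert teq(scaled, tefs) == pytest.approx(
            scale * teq(concs, tefs), rel=1e-9
        )


class TestSummarizeSites:
    def test_summary_table_shape_and_invariants(self, registry):
        from swallowpfas.synthgen import region_dataset

        records, _ = region_dataset(seed=5, n_per_site=8)
        table = summarize_sites(records, registry)
        assert {"site", "analyte", "geo_mean", "ci_low", "ci_high"} <= set(
            table.columns
        )
        multi = table[table["n"] >= 2].dropna(subset=["ci_low"])
        assert ((multi["ci_low"] <= multi["geo_mean"] + 1e-12)
                & (multi["geo_mean"] <= multi["ci_high"] + 1e-12)).all()
        assert (table["geo_mean"] > 0).all()
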