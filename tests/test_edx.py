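"""Sensitivity-factor quantification, elemental ratios, and cohort summaries."""

import pytest
from hypothesis import given, settings, strategies as st

from pcfkit import edx, reference
from pcfkit.errors import ConfigError, InvalidInputError


def region(counts, sid="r1", strain="GS"):
    return edx.EDXRegionCounts(section_id=sid, strain_label=strain, counts=counts)


class TestRelativeAtomicPercent:
    def test_equal_counts_unit_factors_symmetry(self):
        f = edx.SensitivityFactors(factors={"S": 1.0, "Fe": 1.0, "Ni": 1.0})
        comp = edx.relative_atomic_percent(region({"S": 500, "Fe": 500, "Ni": 500}), f)
        for el in ("S", "Fe", "Ni"):
            assert comp.percents[el] == pytest.approx(100 / 3)

    def test_single_dominant_element(self):
        f = edx.SensitivityFactors(factors={"S": 1.0, "Fe": 1.0})
        comp = edx.relative_atomic_percent(region({"S": 1000, "Fe": 0}), f)
        assert comp.percents["S"] == pytest.approx(100.0)

    def test_all_zero_counts_rejected(self):
        f = edx.SensitivityFactors(factors={"S": 1.0, "Fe": 1.0})
        with pytest.raises(InvalidInputError):
            edx.relative_atomic_percent(region({"S": 0, "Fe": 0}), f)

    def test_missing_factor_is_config_error(self):
        f = edx.SensitivityFactors(factors={"S": 1.0})
        with pytest.raises(ConfigError):
            edx.relative_atomic_percent(region({"S": 10, "Fe": 10}), f)


class TestFitSensitivityFactors:
    def test_unit_row_gives_unit_factors(self):
        comp = edx.Composition(percents={"S": 50.0, "Fe": 50.0})
        f = edx.fit_sensitivity_factors(region({"S": 100, "Fe": 100}), comp)
        assert f.factors["S"] == pytest.approx(1.0)
        assert f.factors["Fe"] == pytest.approx(1.0)

    def test_round_trip_on_published_gs_row(self):
        known = edx.Composition(percents={"S": 13.0, "Fe": 86.3, "Ni": 0.7})
        r = region(reference.EDX_REFERENCE_COUNTS_GS1)
        f = edx.fit_sensitivity_factors(r, known)
        back = edx.relative_atomic_percent(r, f)
        for el in known.percents:
            assert back.percents[el] == pytest.approx(known.percents[el], abs=1e-9)

    def test_round_trip_on_published_rb_row(self):
        known = edx.Composition(percents={"S": 77.2, "Fe": 9.8, "Ni": 13.0})
        r = region(reference.EDX_REFERENCE_COUNTS_RB1, strain="RB")
        f = edx.fit_sensitivity_factors(r, known)
        back = edx.relative_atomic_percent(r, f)
        assert back.percents["S"] == pytest.approx(77.2, abs=0.05)
        assert back.percents["Fe"] == pytest.approx(9.8, abs=0.05)
        assert back.percents["Ni"] == pytest.approx(13.0, abs=0.05)

    def test_factors_scale_invariant_under_count_rescaling(self):
        known = edx.Composition(percents={"S": 30.0, "Fe": 60.0, "Ni": 10.0})
        f1 = edx.fit_sensitivity_factors(region({"S": 11, "Fe": 53, "Ni": 7}), known)
        f2 = edx.fit_sensitivity_factors(region({"S": 110, "Fe": 530, "Ni": 70}), known)
        # factors are reported normalized (first element = 1), so the global
        # count rescale cancels and the normalized factors coincide
        for el in known.percents:
            assert f1.factors[el] == pytest.approx(f2.factors[el], rel=1e-12)

    def test_zero_count_with_nonzero_percent_unsolvable(self):
        known = edx.Composition(percents={"S": 50.0, "Fe": 50.0})
        with pytest.raises(InvalidInputError):
            edx.fit_sensitivity_factors(region({"S": 0, "Fe": 100}), known)

    @given(
        percents=st.lists(st.floats(0.5, 95.0), min_size=3, max_size=3),
        counts=st.lists(st.integers(1, 100000), min_size=3, max_size=3),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_round_trip_identity_on_random_rows(self, percents, counts):
        total = sum(percents)
        norm = {el: 100 * p / total for el, p in zip("ABC", percents)}
        known = edx.Composition(percents=norm)
        r = region(dict(zip("ABC", counts)))
        back = edx.relative_atomic_percent(r, edx.fit_sensitivity_factors(r, known))
        for el in norm:
            assert back.percents[el] == pytest.approx(norm[el], rel=1e-9)
        assert sum(back.percents.values()) == pytest.approx(100.0)

    @pytest.mark.parametrize("row", reference.EDX_REFERENCE_REGIONS, ids=lambda r: r.section_id)
    def test_round_trip_identity_on_every_published_row(self, row):
        counts = {el: 1000.0 + 17 * k for k, el in enumerate(row.percents)}
        known = edx.Composition(percents=row.percents)
        r = region(counts, sid=row.section_id)
        back = edx.relative_atomic_percent(r, edx.fit_sensitivity_factors(r, known))
        # printed rows sum to 100.0-100.1; quantification renormalizes to
        # exactly 100, so the identity holds against the renormalized row
        total = sum(row.percents.values())
        for el in row.percents:
            assert back.percents[el] == pytest.approx(
                100.0 * row.percents[el] / total, rel=1e-9
            )


class TestElementalRatios:
    def test_published_gs_cross_section_2(self):
        comp = edx.Composition(percents={"S": 31.4, "Fe": 64.9, "Ni": 3.8})
        table = edx.elemental_ratios(comp, [("S", "Fe")])
        assert round(table.ratios[("S", "Fe")], 2) == 0.48

    def test_published_gs_cross_section_1(self):
        comp = edx.Composition(percents={"S": 13.0, "Fe": 86.3, "Ni": 0.7})
        table = edx.elemental_ratios(comp, [("S", "Fe")])
        assert round(table.ratios[("S", "Fe")], 2) == 0.15

    def test_equal_percents_give_unit_ratios(self):
        comp = edx.Composition(percents={"S": 100 / 3, "Fe": 100 / 3, "Ni": 100 / 3})
        table = edx.elemental_ratios(comp)
        assert all(r == pytest.approx(1.0) for r in table.ratios.values())

    def test_zero_denominator_flagged_not_raised(self):
        comp = edx.Composition(percents={"S": 100.0, "Fe": 0.0})
        table = edx.elemental_ratios(comp, [("S", "Fe")])
        assert table.ratios[("S", "Fe")] is None

    def test_reciprocal_pairs_multiply_to_one(self):
        comp = edx.Composition(percents={"S": 30.0, "Fe": 70.0})
        table = edx.elemental_ratios(comp, [("S", "Fe"), ("Fe", "S")])
        assert table.ratios[("S", "Fe")] * table.ratios[("Fe", "S")] == pytest.approx(1.0)


class TestSummarizeCompositions:
    def test_gs_means_with_outlier_excluded(self, gs_regions):
        s = edx.summarize_compositions(gs_regions)
        assert round(s.element_mean["S"], 1) == 24.9
        assert round(s.element_std["S"], 1) == 10.3
        assert round(s.element_mean["Fe"], 1) == 72.7
        assert s.excluded_ids == ("GS-4",)
        assert len(s.included_ids) == 3

    def test_rb_means(self, rb_regions):
        s = edx.summarize_compositions(rb_regions)
        assert round(s.element_mean["S"], 1) == 78.6
        assert round(s.element_std["S"], 1) == 3.3
        assert round(s.element_mean["Ni"], 1) == 10.4

    def test_row_ratio_averaging_matches_published_average_row(self, rb_regions):
        s = edx.summarize_compositions(rb_regions, ratio_mode="from_row_ratios")
        assert round(s.ratio_mean[("Fe", "Ni")], 2) == 1.14
        assert round(s.ratio_mean[("S", "Ni")], 2) == 8.26

    def test_ratio_of_mean_percents_differs_from_row_averaging(self, gs_regions):
        rows = edx.summarize_compositions(gs_regions, ratio_mode="from_row_ratios")
        means = edx.summarize_compositions(gs_regions, ratio_mode="from_percents")
        # Fe:Ni is dominated by the near-zero-Ni row under row averaging
        assert rows.ratio_mean[("Fe", "Ni")] > 1.5 * means.ratio_mean[("Fe", "Ni")]

    def test_all_excluded_rejected(self, gs_regions):
        flagged = [
            edx.RegionComposition(r.section_id, r.strain_label, r.percents, r.ratios, outlier=True)
            for r in gs_regions
        ]
        with pytest.raises(InvalidInputError):
            edx.summarize_compositions(flagged)

    def test_unknown_ratio_mode_rejected(self, gs_regions):
        with pytest.raises(ConfigError):
            edx.summarize_compositions(gs_regions, ratio_mode="nonsense")
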