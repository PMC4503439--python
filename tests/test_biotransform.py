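"""Mass-shift rule table, peak matching, fragment evidence, RT polarity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mangopk.biotransform import (
    ParentSpec,
    PeakRecord,
    annotate_peaklist,
    build_rule_table,
    fragment_evidence,
    match_peak,
    rt_consistency,
)
from mangopk.exceptions import DuplicatePeakIdError
from mangopk.simulate import PeakListSpec, simulate_peaklist

EXPECTED_CLASSES = {
    "alpha-MG": "parent",
    "M1": "glucuronidation",
    "M2": "glucuronidation",
    "M3": "glucuronidation",
    "M4": "bis_glucuronidation",
    "M5": "dehydrogenation",
    "M6": "dehydrogenation",
    "M7": "dehydrogenation",
    "M8": "dehydrogenation",
    "M9": "hydrogenation",
    "M10": "oxidation",
    "M11": "oxidation",
    "M12": "oxidation",
    "M13": "oxidation",
    "M14": "oxidation",
    "M15": "methylation",
}


class TestRuleTable:
    def test_rounded_shifts_match_reported_offsets(self, rules):
        shifts = {r.name: round(r.mono_shift, 3) for r in rules}
        assert shifts["methylation"] == 14.016
        assert shifts["oxidation"] == 15.995
        assert shifts["dehydrogenation"] == -2.016
        assert shifts["glucuronidation"] == 176.032

    def test_bis_glucuronidation_is_twice_glucuronidation(self, rules):
        by_name = {r.name: r.mono_shift for r in rules}
        assert by_name["bis_glucuronidation"] == pytest.approx(
            2 * by_name["glucuronidation"], abs=1e-12
        )

    def test_hydrogenation_is_negative_dehydrogenation(self, rules):
        by_name = {r.name: r.mono_shift for r in rules}
        assert by_name["hydrogenation"] == pytest.approx(
            -by_name["dehydrogenation"], abs=1e-12
        )

    def test_only_methylation_elutes_later(self, rules):
        later = [r.name for r in rules if r.rt_direction == "later"]
        assert later == ["methylation"]


class TestMatchPeak:
    def test_glucuronide_shift(self, parent, rules):
        peak = PeakRecord("x", 587.17, 21.4)
        best = match_peak(peak, ParentSpec(parent_mz=411.14), rules)[0]
        assert best.rule == "glucuronidation"
        assert best.nominal_shift == 176

    def test_parent_self_match(self, parent, rules):
        peak = PeakRecord("x", parent.parent_mz, parent.parent_rt)
        best = match_peak(peak, parent, rules)[0]
        assert best.rule == "parent"
        assert best.mass_error == 0.0

    def test_bis_glucuronide_shift(self, rules):
        peak = PeakRecord("x", 763.21, 21.0)
        best = match_peak(peak, ParentSpec(parent_mz=411.14), rules)[0]
        assert best.rule == "bis_glucuronidation"
        assert best.nominal_shift == 352

    def test_unassigned_is_valid_outcome(self, parent, rules):
        peak = PeakRecord("x", 500.0, 10.0)
        best = match_peak(peak, parent, rules)[0]
        assert best.rule == "unassigned"


class TestFragmentEvidence:
    def test_parent_prenyl_cascade(self, parent):
        peak = PeakRecord("p", 411.21, 27.6, fragments=(354.85, 299.19))
        assert fragment_evidence(peak, None, parent) == 2

    def test_empty_fragment_list(self, parent):
        peak = PeakRecord("p", 411.21, 27.6, fragments=())
        assert fragment_evidence(peak, None, parent) == 0

    def test_glucuronide_cascade(self, parent):
        peak = PeakRecord("m2", 587.04, 25.1, fragments=(531.18, 411.05, 354.86))
        assert fragment_evidence(peak, "glucuronidation", parent) == 3

    def test_each_fragment_counted_once(self, parent):
        # two observed ions near the same template still count separately,
        # but one ion never counts twice
        peak = PeakRecord("p", 411.21, 27.6, fragments=(355.0, 355.1))
        assert fragment_evidence(peak, None, parent) == 2


class TestRTConsistency:
    def test_methylation_later_is_consistent(self, parent, rules):
        methyl = next(r for r in rules if r.name == "methylation")
        assert rt_consistency(28.2, parent, methyl)
        assert not rt_consistency(27.0, parent, methyl)

    def test_coelution_allowed_for_earlier_rules(self, parent, rules):
        dehydro = next(r for r in rules if r.name == "dehydrogenation")
        assert rt_consistency(27.6, parent, dehydro)  # boundary co-elution

    def test_later_rt_inconsistent_under_earlier_rule(self, parent, rules):
        gluc = next(r for r in rules if r.name == "glucuronidation")
        assert not rt_consistency(30.0, parent, gluc)


class TestAnnotatePeaklist:
    def test_reference_peaklist_classes(self, reference_peaklist):
        peaks, parent = reference_peaklist
        table = annotate_peaklist(peaks, parent, tolerance_da=0.5)
        assert len(table) == 16
        got = dict(zip(table["peak_id"], table["assignment"]))
        assert got == EXPECTED_CLASSES
        # no cross-class mis-assignment: every |mass error| within tolerance
        errs = table.loc[table["assignment"] != "parent", "mass_error_da"].abs()
        assert errs.max() <= 0.5

    def test_reference_nominal_shifts(self, reference_peaklist):
        peaks, parent = reference_peaklist
        table = annotate_peaklist(peaks, parent).set_index("peak_id")
        assert table.loc["M1", "nominal_shift_da"] == 176
        assert table.loc["M4", "nominal_shift_da"] == 352
        assert table.loc["M15", "nominal_shift_da"] == 14

    def test_deterministic_ordering_by_rt_then_mz(self, reference_peaklist):
        peaks, parent = reference_peaklist
        table = annotate_peaklist(peaks, parent)
        keys = list(zip(table["rt_min"], table["precursor_mz"]))
        assert keys == sorted(keys)

    def test_empty_peak_list(self, parent):
        assert annotate_peaklist([], parent).empty

    def test_duplicate_ids_rejected(self, parent):
        peaks = [PeakRecord("a", 411.2, 27.6), PeakRecord("a", 587.2, 21.0)]
        with pytest.raises(DuplicatePeakIdError):
            annotate_peaklist(peaks, parent)

    def test_round_trip_identity_at_zero_noise(self, parent):
        """Annotating a noise-free synthetic peak list recovers exactly the
        generating reactions with zero false positives."""
        reactions = (
            "glucuronidation",
            "bis_glucuronidation",
            "dehydrogenation",
            "hydrogenation",
            "oxidation",
            "methylation",
        )
        peaks = simulate_peaklist(PeakListSpec(reactions=reactions, mz_noise_sd=0.0))
        table = annotate_peaklist(peaks, parent)
        assigned = set(table["assignment"]) - {"parent"}
        assert assigned == set(reactions)
        assert (table["assignment"] != "unassigned").all()
        assert (table["rt_consistent"].dropna()).all()
        # every metabolite carries its diagnostic fragments
        assert (table.loc[table["assignment"] != "parent", "fragment_evidence"] >= 2).all()

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        tol_small=st.floats(0.01, 0.5),
        factor=st.floats(1.0, 10.0),
        mz=st.floats(430.0, 800.0),  # clear of the parent's own window
    )
    def test_tolerance_monotonicity(self, tol_small, factor, mz, parent, rules):
        """Shrinking the tolerance never adds assignments."""
        peak = PeakRecord("x", mz, 20.0)
        small = match_peak(peak, parent, rules, tolerance_da=tol_small)
        large = match_peak(peak, parent, rules, tolerance_da=tol_small * factor)
        small_rules = {a.rule for a in small} - {"unassigned"}
        large_rules = {a.rule for a in large} - {"unassigned"}
        assert small_rules <= large_rules
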