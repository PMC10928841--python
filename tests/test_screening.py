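"""Fold changes, positivity calls, toxicity flags, call matrices."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from amesbmd.plate_io import Design
from amesbmd.screening import (
    DEFAULT_THRESHOLDS,
    call_arm,
    flag_toxicity,
    fold_changes,
    max_fold_change,
    study_call_matrix,
)
from conftest import make_arm


class TestFoldChanges:
    def test_equal_counts_give_unit_ratios(self):
        arm = make_arm({50.0: (100, 100, 100), 500.0: (100, 100, 100)})
        profile = fold_changes(arm)
        assert all(r == 1.0 for r in profile.ratios().values())

    def test_hand_arithmetic(self):
        arm = make_arm(
            {10.0: (110, 110, 110), 100.0: (200, 200, 200), 1000.0: (430, 430, 430)}
        )
        assert list(fold_changes(arm).ratios().values()) == [1.1, 2.0, 4.3]

    def test_zero_control_mean_is_degenerate(self):
        arm = make_arm({50.0: (10, 10, 10)}, controls=(0, 0, 0, 0, 0, 0))
        with pytest.raises(ZeroDivisionError):
            fold_changes(arm)


class TestCallArm:
    def test_exact_threshold_is_positive(self):
        arm = make_arm({50.0: (200, 200, 200)})  # TA100, ratio exactly 2.0
        call = call_arm(arm)
        assert call.call == "positive"
        assert call.first_positive_dose == 50.0

    def test_three_fold_strain_needs_three(self):
        design = Design("NDMA", "plate_incorporation", "hamster", "dmso", "TA1535")
        arm = make_arm({50.0: (250, 250, 250)}, design=design)
        call = call_arm(arm)
        assert call.threshold == 3.0
        assert call.call == "negative"

    def test_unknown_strain_threshold_errors(self):
        arm = make_arm({50.0: (300, 300, 300)})
        with pytest.raises(ValueError, match="threshold"):
            call_arm(arm, thresholds={"TA98": 2.0})

    def test_toxic_doses_excluded_from_decision(self):
        arm = make_arm(
            {50.0: (150, 150, 150), 5000.0: (400, 400, 400)},
            toxicity_notes={5000.0: {"absent_lawn"}},
        )
        call = call_arm(arm)
        assert call.call == "negative"
        assert call.toxic_doses == frozenset({5000.0})

    def test_all_doses_toxic_is_inconclusive(self):
        arm = make_arm(
            {50.0: (10, 10, 10)}, toxicity_notes={50.0: {"thinning"}}
        )
        assert call_arm(arm).call == "toxic_inconclusive"

    def test_infinite_threshold_never_positive(self):
        arm = make_arm({50.0: (5000, 5000, 5000)})
        thr = {k: float("inf") for k in DEFAULT_THRESHOLDS}
        assert call_arm(arm, thresholds=thr).call == "negative"

    def test_unit_threshold_always_positive(self):
        arm = make_arm({50.0: (101, 101, 101)})
        thr = {k: 1.0 for k in DEFAULT_THRESHOLDS}
        assert call_arm(arm, thresholds=thr).call == "positive"


counts_strategy = st.lists(
    st.integers(min_value=1, max_value=2000), min_size=3, max_size=3
)


@given(
    doses=st.dictionaries(
        st.sampled_from([50.0, 150.0, 500.0, 1500.0, 5000.0]),
        counts_strategy,
        min_size=1,
        max_size=5,
    ),
    factor=st.integers(min_value=2, max_value=7),
)
def test_common_scaling_leaves_ratios_and_calls_invariant(doses, factor):
    arm = make_arm(doses)
    scaled = make_arm(
        {d: tuple(c * factor for c in v) for d, v in doses.items()},
        controls=tuple(c * factor for c in arm.control_counts),
    )
    base, big = fold_changes(arm), fold_changes(scaled)
    assert np.allclose(
        list(base.ratios().values()), list(big.ratios().values())
    )
    assert call_arm(arm).call == call_arm(scaled).call
    assert max_fold_change(arm)[0] == pytest.approx(max_fold_change(scaled)[0])


@given(
    counts=counts_strategy,
    bump=st.integers(min_value=0, max_value=500),
)
def test_raising_treated_counts_never_flips_positive_to_negative(counts, bump):
    arm = make_arm({500.0: counts})
    bumped = make_arm({500.0: tuple(c + bump for c in counts)})
    if call_arm(arm).call == "positive":
        assert call_arm(bumped).call == "positive"


class TestToxicityFlags:
    def test_no_annotations_empty(self):
        arm = make_arm({50.0: (120, 120, 120)})
        assert flag_toxicity(arm).all == frozenset()

    def test_annotated_dose_flagged(self):
        arm = make_arm(
            {50.0: (120, 120, 120), 500.0: (3, 2, 1)},
            toxicity_notes={500.0: {"absent_lawn"}},
        )
        assert flag_toxicity(arm).annotated == frozenset({500.0})

    def test_heuristic_flags_below_half_control_as_advisory(self):
        arm = make_arm(
            {50.0: (40, 40, 40)}, controls=(120, 120, 120, 120, 120, 120)
        )
        flags = flag_toxicity(arm, "annotation_plus_heuristic")
        assert flags.advisory == frozenset({50.0})
        assert flag_toxicity(arm, "annotation_only").all == frozenset()

    def test_unknown_policy_rejected(self):
        arm = make_arm({50.0: (1, 1, 1)})
        with pytest.raises(ValueError):
            flag_toxicity(arm, "guesswork")


class TestMaxFold:
    def test_monotone_profile_peaks_at_top_dose(self):
        arm = make_arm(
            {50.0: (110,) * 3, 500.0: (200,) * 3, 5000.0: (800,) * 3}
        )
        assert max_fold_change(arm) == (8.0, 5000.0)

    def test_interior_peak(self):
        arm = make_arm(
            {50.0: (120,) * 3, 500.0: (310,) * 3, 5000.0: (240,) * 3}
        )
        ratio, dose = max_fold_change(arm)
        assert (ratio, dose) == (3.1, 500.0)

    def test_all_toxic_errors(self):
        arm = make_arm(
            {50.0: (10,) * 3}, toxicity_notes={50.0: {"thinning"}}
        )
        with pytest.raises(ValueError, match="toxic"):
            max_fold_change(arm)


class TestCallMatrix:
    def _arms(self):
        arms = []
        for strain, counts in (
            ("TA98", (150,) * 3),       # 1.5x -> negative
            ("TA100", (260,) * 3),      # 2.6x -> positive
            ("TA1535", (450,) * 3),     # 4.5x -> positive (3x threshold)
        ):
            design = Design("NDMA", "plate_incorporation", "hamster", "dmso", strain)
            arms.append(make_arm({500.0: counts}, design=design))
        return arms

    def test_matrix_cells_and_overall(self):
        matrix = study_call_matrix(self._arms())
        row = ("plate_incorporation", "hamster", "dmso")
        assert matrix.cell(*row, "TA98") == "-"
        assert matrix.cell(*row, "TA100") == "+"
        assert matrix.cell(*row, "TA1535") == "+"
        assert matrix.frame.loc[row, "overall"] == "Positive"

    def test_all_negative_study(self):
        designs = [
            Design("NDMA", "plate_incorporation", "none", "water", s)
            for s in ("TA98", "TA100")
        ]
        arms = [make_arm({500.0: (110,) * 3}, design=d) for d in designs]
        matrix = study_call_matrix(arms)
        assert (matrix.frame["overall"] == "Negative").all()

    def test_toxic_rendered_distinctly(self):
        design = Design("NDEA", "pre_incubation", "hamster", "acetonitrile", "TA98")
        arm = make_arm(
            {500.0: (5,) * 3}, design=design,
            toxicity_notes={500.0: {"thinning"}},
        )
        matrix = study_call_matrix([arm])
        assert matrix.cell("pre_incubation", "hamster", "acetonitrile", "TA98") == "Toxic"

    def test_mixed_compounds_rejected(self):
        arms = self._arms()
        other = make_arm(
            {500.0: (300,) * 3},
            design=Design("NDEA", "plate_incorporation", "hamster", "dmso", "TA100"),
        )
        with pytest.raises(ValueError, match="compound"):
            study_call_matrix(arms + [other])
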