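"""Rubric decision tables: exact bins, boundary membership, monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpdkit import scoring


class TestStandardScore:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (0.0, 0),
            (0.001, 1),
            (0.05, 1),
            (0.10 - 1e-9, 1),
            (0.10, 2),  # "<10%" is score 1, so 10% itself is score 2
            (0.20, 2),
            (0.25, 2),
            (0.25 + 1e-9, 3),
            (0.40, 3),
            (0.50, 3),
            (0.50 + 1e-9, 4),
            (0.51, 4),
            (1.0, 4),
        ],
    )
    def test_bins(self, ratio, expected):
        assert scoring.score_standard(ratio) == expected

    @pytest.mark.parametrize("bad", [-0.1, 1.1, np.nan])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(scoring.ScoringError):
            scoring.score_standard(bad)

    def test_exhaustive_and_monotone_on_dense_grid(self):
        grid = np.linspace(0.0, 1.0, 20001)
        scores = [scoring.score_standard(r) for r in grid]
        assert set(scores) == {0, 1, 2, 3, 4}
        assert all(b >= a for a, b in zip(scores, scores[1:]))


class TestDigitLesionScore:
    @pytest.mark.parametrize(
        "fracs,hematoma,expected",
        [
            ((0.0, 0.0, 0.0), False, 0),
            ((0.0, 0.0, 0.0), True, 1),  # hematoma alone
            ((0.03, 0.0, 0.0), False, 1),  # punctual on one segment
            ((0.03, 0.04, 0.0), False, 1),  # punctual on two
            ((0.03, 0.04, 0.02), False, 2),  # punctual on more than two
            ((0.2, 0.0, 0.0), False, 2),  # one intermediate lesion
            ((0.6, 0.0, 0.0), False, 3),  # one phalanx covered >50%
            ((0.2, 0.3, 0.0), False, 3),  # several intermediate lesions
            ((0.6, 0.7, 0.0), False, 4),  # >one phalanx covered >=50%
            ((1.2, 0.0, 0.0), False, 4),  # larger than the phalanx
            ((0.5, 0.0, 0.0), False, 3),  # boundary: one segment at exactly 50%
            ((0.5, 0.5, 0.0), False, 4),
        ],
    )
    def test_decision_table(self, fracs, hematoma, expected):
        assert scoring.score_digit_lesion(fracs, hematoma) == expected

    def test_rejects_negative_fraction(self):
        with pytest.raises(scoring.ScoringError):
            scoring.score_digit_lesion((-0.1, 0.0, 0.0))

    def test_rejects_empty(self):
        with pytest.raises(scoring.ScoringError):
            scoring.score_digit_lesion(())

    @settings(max_examples=200, deadline=None)
    @given(
        fracs=st.lists(st.floats(0.0, 1.2), min_size=3, max_size=3),
        bumps=st.lists(st.floats(0.0, 0.3), min_size=3, max_size=3),
    )
    def test_monotone_under_pointwise_increase(self, fracs, bumps):
        before = scoring.score_digit_lesion(fracs)
        after = scoring.score_digit_lesion([f + b for f, b in zip(fracs, bumps)])
        assert after >= before


class TestSwellingScore:
    def test_identical_to_reference_is_zero(self):
        assert scoring.score_swelling(1000, 1000) == 0

    def test_default_thresholds(self):
        assert scoring.score_swelling(1200, 1000) == 1  # r = 1.20: slight
        assert scoring.score_swelling(1150, 1000) == 1  # boundary inclusive
        assert scoring.score_swelling(1400, 1000) == 2  # distinct

    def test_zero_reference_rejected(self):
        with pytest.raises(scoring.ScoringError):
            scoring.score_swelling(1000, 0)

    def test_missing_reference_withheld(self):
        with pytest.raises(scoring.NoReferenceError):
            scoring.score_swelling(1000, None)


class TestAssembleRecord:
    def test_intact_foot(self):
        rec = scoring.assemble_record(
            0.0, {d: (0.0, 0.0, 0.0) for d in scoring.DIGITS}
        )
        assert rec.standard_score == 0
        assert all(v == 0 for v in rec.digit_lesion_scores.values())
        assert rec.n_affected_digits == 0
        assert not rec.digit_flag

    def test_single_lesioned_digit_sets_flag(self):
        fr = {2: (0.03, 0.0, 0.0), 3: (0.0,) * 3, 4: (0.0,) * 3}
        rec = scoring.assemble_record(0.0, fr)
        assert rec.digit_lesion_scores[2] == 1
        assert rec.n_affected_digits == 1
        assert rec.digit_flag

    def test_swelling_alone_counts_digit_as_affected(self):
        fr = {d: (0.0,) * 3 for d in scoring.DIGITS}
        rec = scoring.assemble_record(
            0.0, fr,
            digit_areas={2: 1200, 3: 1000, 4: 1000},
            reference_areas={2: 1000, 3: 1000, 4: 1000},
        )
        assert rec.swelling_scores[2] == 1
        assert rec.n_affected_digits == 1
        assert rec.digit_flag

    def test_missing_reference_recorded_as_missing_not_zero(self):
        fr = {d: (0.0,) * 3 for d in scoring.DIGITS}
        rec = scoring.assemble_record(0.0, fr, digit_areas={2: 1200, 3: 1000, 4: 1000})
        assert all(v is None for v in rec.swelling_scores.values())
        assert rec.n_affected_digits == 0
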