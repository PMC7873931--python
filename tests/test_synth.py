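"""Generator invariants: determinism, mask algebra, rubric round-trips, cohorts."""

import numpy as np
import pytest

from fpdkit import morphometry, scoring, synth


class TestFootPair:
    def test_deterministic_given_seed(self):
        p = synth.FootGenParams(met_lesion_frac=0.2, seed=99)
        l1, r1, t1 = synth.generate_foot_pair(p)
        l2, r2, t2 = synth.generate_foot_pair(p)
        assert np.array_equal(l1, l2) and np.array_equal(r1, r2)
        assert np.array_equal(t1.masks.lesion_mask, t2.masks.lesion_mask)

    def test_intact_foot_scores_zero(self, intact_pair):
        _, _, truth = intact_pair
        rec = truth.true_scores
        assert rec.standard_score == 0
        assert all(v == 0 for v in rec.digit_lesion_scores.values())
        assert all(v == 0 for v in rec.swelling_scores.values())
        assert not rec.digit_flag

    def test_met_fraction_exact_to_one_pixel(self):
        p = synth.FootGenParams(met_lesion_frac=0.30, seed=5)
        _, _, truth = synth.generate_foot_pair(p)
        n_pad = truth.true_ratios.px_met
        assert abs(truth.true_ratios.standard - 0.30) <= 1.0 / n_pad
        assert truth.true_scores.standard_score == 3

    def test_mask_conservation(self, default_pair):
        _, _, truth = default_pair
        m = truth.masks
        m.validate()  # disjointness, containment, segment partition
        union = m.metatarsal_mask.copy()
        for dm in m.digit_masks.values():
            union |= dm
        assert not (union & ~m.foot_mask).any()
        assert np.array_equal(union, m.foot_mask)  # pad + digits tile the foot

    def test_true_ratios_recomputable_from_masks(self, default_pair):
        _, _, truth = default_pair
        assert morphometry.measure(truth.masks) == truth.true_ratios

    def test_rubric_round_trip(self, small_cohort):
        for s in small_cohort:
            t = s.truth
            rec = scoring.assemble_record(
                t.true_ratios.standard,
                t.true_segment_fractions,
                t.digit_areas,
                t.reference_digit_areas,
            )
            assert rec == t.true_scores

    def test_reference_foot_unswollen(self, default_pair):
        _, _, truth = default_pair
        # digit 3 was swollen by 1.25: its area exceeds the reference by ~25 %
        ratio = truth.digit_areas[3] / truth.reference_digit_areas[3]
        assert ratio == pytest.approx(1.25, abs=0.03)
        ratio2 = truth.digit_areas[2] / truth.reference_digit_areas[2]
        assert ratio2 == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"met_lesion_frac": 1.5},
            {"swelling_factors": {2: 0.8, 3: 1.0, 4: 1.0}},
            {"image_size": (40, 40)},
            {"n_segments_per_digit": 1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(synth.GenerationError):
            synth.generate_foot_pair(synth.FootGenParams(**kwargs))


class TestCohort:
    def test_exact_level_counts(self, small_cohort):
        levels = [s.level for s in small_cohort]
        for lv in range(5):
            assert levels.count(lv) == 10
        for s in small_cohort:
            assert s.truth.true_scores.standard_score == s.level
            assert 0 <= s.flock < 16

    def test_single_level_cohort(self):
        samples = synth.generate_cohort(
            synth.CohortSpec(n_per_level=2, levels=(0,), seed=1)
        )
        assert len(samples) == 2
        assert all(s.truth.true_scores.standard_score == 0 for s in samples)

    def test_cohort_deterministic(self):
        spec = synth.CohortSpec(n_per_level=2, levels=(0, 2), seed=8)
        a = synth.generate_cohort(spec)
        b = synth.generate_cohort(spec)
        assert all(np.array_equal(x.image, y.image) for x, y in zip(a, b))
        assert [x.flock for x in a] == [y.flock for y in b]

    def test_zero_concordance_decouples_digits_from_level(self):
        # with the level link switched off, digital lesion load is independent
        # of the metatarsal ratio by construction; two cohorts are pooled to
        # keep the sampling noise of r well below the acceptance band
        dp, std = [], []
        for seed in (77, 78):
            samples = synth.generate_cohort(
                synth.CohortSpec(n_per_level=100, digit_concordance=0.0, seed=seed)
            )
            dp += [s.truth.true_ratios.dp_ra1 for s in samples]
            std += [s.truth.true_ratios.standard for s in samples]
        r = np.corrcoef(dp, std)[0, 1]
        assert abs(r) < 0.1

    def test_latent_model_stores_severity(self):
        samples = synth.generate_cohort(
            synth.CohortSpec(n_per_level=2, digit_model="latent", seed=4)
        )
        assert all(s.truth.latent_severity is not None for s in samples)


class TestSimulateRaters:
    def test_zero_error_reproduces_truth(self):
        truth = [0, 1, 2, 3, 4, 2]
        m = synth.simulate_raters(truth, 0.0, n_raters=2, seed=0)
        assert np.array_equal(m, np.tile(truth, (2, 1)))

    def test_reproducible(self):
        truth = np.arange(5) % 5
        a = synth.simulate_raters(truth, 0.2, seed=9)
        b = synth.simulate_raters(truth, 0.2, seed=9)
        assert np.array_equal(a, b)

    def test_error_stays_in_category_range(self):
        truth = [0, 4] * 50
        m = synth.simulate_raters(truth, 0.9, seed=2)
        assert m.min() >= 0 and m.max() <= 4

    def test_bad_error_model_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_raters([1, 2], {-1: 0.3, 0: 0.3, 1: 0.3})

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_raters([], 0.1)


class TestSimulateOrdinalLatent:
    def test_thresholds_control_margins(self):
        th = synth.equiprobable_thresholds(5)
        data = synth.simulate_ordinal_latent(np.eye(2), [th, th], 20000, seed=1)
        counts = np.bincount(data[:, 0], minlength=5) / 20000
        assert np.allclose(counts, 0.2, atol=0.02)

    def test_non_positive_definite_rejected(self):
        bad = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(ValueError):
            synth.simulate_ordinal_latent(bad, [[0.0], [0.0]], 100)

    def test_decreasing_thresholds_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_ordinal_latent(np.eye(2), [[0.5, -0.5], [0.0]], 100)

    def test_reproducible(self):
        th = [np.array([0.0])] * 2
        a = synth.simulate_ordinal_latent(np.eye(2), th, 50, seed=3)
        b = synth.simulate_ordinal_latent(np.eye(2), th, 50, seed=3)
        assert np.array_equal(a, b)
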