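import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from eventshift.boundaries import (
    AnnotationSet,
    BoundaryTimecourse,
    LagEstimate,
    RaterAnnotation,
    annotation_timecourse,
    boundary_strength,
    bootstrap_rater_ci,
    hrf,
    lag_shift,
    optimal_lag,
    quadratic_vertex,
)
from eventshift.hmm import ExpectedEventCurve
from eventshift.synthetic import generate_annotations


class TestHrf:
    def test_zero_at_onset(self):
        assert hrf(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_peaks_between_five_and_six_seconds(self):
        t = np.arange(0, 30, 0.1)
        assert 5.0 <= t[np.argmax(hrf(t))] <= 6.0

    def test_peak_amplitude_is_one(self):
        t = np.arange(0, 30, 0.01)
        assert hrf(t).max() == pytest.approx(1.0, abs=1e-4)

    def test_decays_by_32_seconds(self):
        assert abs(hrf(32.0)) < 0.01


class TestAnnotationTimecourse:
    def test_no_annotations_gives_zeros(self, caplog):
        ann = AnnotationSet([RaterAnnotation("r1", [])], 90.0)
        with caplog.at_level("WARNING"):
            tc = annotation_timecourse(ann, 1.5)
        assert (tc.values == 0).all()
        assert len(tc.values) == 60

    def test_single_impulse_proportional_to_hrf(self):
        t0 = 12.0
        ann = AnnotationSet([RaterAnnotation("r1", [t0])], 90.0)
        tc = annotation_timecourse(ann, 1.5)
        trs = np.arange(60) * 1.5
        active = trs > t0 + 1
        expected = hrf(trs - t0)
        # 1 s binning + linear TR resampling leaves small discretization error
        assert np.corrcoef(tc.values[active], expected[active])[0, 1] > 0.99

    def test_convolution_linearity(self):
        one = AnnotationSet([RaterAnnotation("r1", [30.0])], 90.0)
        two = AnnotationSet(
            [RaterAnnotation("r1", [30.0]), RaterAnnotation("r2", [30.0])], 90.0
        )
        np.testing.assert_allclose(
            annotation_timecourse(two, 1.5).values,
            2 * annotation_timecourse(one, 1.5).values,
            atol=1e-12,
        )


class TestBoundaryStrength:
    def test_constant_curve_all_zeros(self):
        curve = ExpectedEventCurve(np.full(10, 2.0), 1.5, 4)
        assert (boundary_strength(curve).values == 0).all()

    def test_hard_transition_single_spike(self):
        curve = ExpectedEventCurve(np.array([0, 0, 0, 1, 1, 1.0]), 1.5, 2)
        values = boundary_strength(curve).values
        assert values[2] == 1.0
        assert np.count_nonzero(values) == 1

    def test_telescoping_sum(self, rng):
        vals = np.cumsum(rng.random(20))
        curve = ExpectedEventCurve(vals, 1.5, 25)
        assert boundary_strength(curve).values.sum() == pytest.approx(
            vals[-1] - vals[0]
        )


class TestQuadraticVertex:
    def test_symmetric_peak_at_zero(self):
        assert quadratic_vertex(0.5, 0.9, 0.5) == pytest.approx(0.0)

    def test_worked_example(self):
        assert quadratic_vertex(0.2, 0.9, 0.6) == pytest.approx(0.2)

    def test_degenerate_flat_returns_zero(self):
        assert quadratic_vertex(0.5, 0.5, 0.5) == 0.0


class TestOptimalLag:
    def smooth(self, rng, n=200):
        return gaussian_filter1d(rng.standard_normal(n), 2.0)

    def test_sign_convention_brain_leads_gives_negative_lag(self, rng):
        # annotation events happen 2 TRs after the brain's -> brain leads
        x = self.smooth(rng)
        brain = BoundaryTimecourse(x[2:], 1.5, "hmm")
        annot = BoundaryTimecourse(x[:-2], 1.5, "annotation")
        est = optimal_lag(brain, annot, 6)
        assert est.lag_s == pytest.approx(-3.0, abs=0.05)

    def test_integer_shift_recovered_exactly(self, rng):
        # annotation leads the brain by 3 TRs -> shift it later by 3 TRs (4.5 s)
        x = self.smooth(rng)
        est = optimal_lag(
            BoundaryTimecourse(x[:-3], 1.5, "hmm"),
            BoundaryTimecourse(x[3:], 1.5, "annotation"),
            6,
        )
        assert est.lag_s == pytest.approx(4.5, abs=0.05)
        assert not est.at_boundary

    def test_boundary_peak_flagged_and_unrefined(self, rng):
        x = self.smooth(rng)
        est = optimal_lag(
            BoundaryTimecourse(x[:-4], 1.5, "hmm"),
            BoundaryTimecourse(x[4:], 1.5, "annotation"),
            max_lag_trs=4,
        )
        assert est.at_boundary
        assert est.lag_s == pytest.approx(6.0)

    def test_constant_timecourse_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            optimal_lag(
                BoundaryTimecourse(np.ones(30), 1.5, "hmm"),
                BoundaryTimecourse(np.ones(30), 1.5, "annotation"),
                5,
            )


class TestLagShift:
    def test_equal_lags_give_zero(self):
        first = LagEstimate(2.0, 0.9, 1)
        reps = [LagEstimate(2.0, 0.8, v) for v in range(2, 7)]
        assert lag_shift(first, reps) == 0.0

    def test_worked_difference(self):
        first = LagEstimate(2.0, 0.9, 1)
        reps = [LagEstimate(-2.0, 0.8, 2)]
        assert lag_shift(first, reps) == pytest.approx(4.0)

    def test_nan_propagates_with_warning(self, caplog):
        first = LagEstimate(float("nan"), 0.9, 1)
        with caplog.at_level("WARNING"):
            assert np.isnan(lag_shift(first, [LagEstimate(1.0, 0.5, 2)]))


class TestBootstrapRaterCi:
    def _brain_tcs(self, ann, shifts_trs):
        base = annotation_timecourse(ann, 1.5, 60).values
        out = []
        for s in shifts_trs:
            out.append(BoundaryTimecourse(np.roll(base, -s), 1.5, "hmm"))
        return out

    def test_identical_noiseless_raters_zero_width_ci(self):
        ann = generate_annotations([15.0, 40.0, 70.0], 6, 0.0, 0.0, seed=0)
        tcs = self._brain_tcs(ann, [0, 2, 2])
        ci = bootstrap_rater_ci(ann, tcs, max_lag_trs=6, n_boot=20, seed=1)
        lo, hi = ci["first_viewing_ci"]
        assert hi - lo == pytest.approx(0.0, abs=1e-9)
        lo, hi = ci["repeated_viewing_ci"]
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_same_seed_identical_cis(self):
        ann = generate_annotations([15.0, 40.0, 70.0], 6, 1.0, 0.1, seed=2)
        tcs = self._brain_tcs(ann, [0, 1])
        a = bootstrap_rater_ci(ann, tcs, 6, n_boot=15, seed=5)
        b = bootstrap_rater_ci(ann, tcs, 6, n_boot=15, seed=5)
        assert a["first_viewing_ci"] == b["first_viewing_ci"]

    def test_fewer_than_two_raters_rejected(self):
        ann = AnnotationSet([RaterAnnotation("r1", [10.0])], 90.0)
        with pytest.raises(ValueError):
            bootstrap_rater_ci(ann, [BoundaryTimecourse(np.ones(60), 1.5)], 6)
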