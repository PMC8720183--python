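"""Pupil preprocessing: interpolation, smoothing, z-transform, QC,
derivative, downsampling, and trial peaks, each against an independent
brute-force oracle where the operation is nontrivial."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import pupilfmri as pf
from pupilfmri import preprocess as prep


def make_rec(pupil, rate=250.0, blinks=(), saccades=(), gaze=None):
    n = len(pupil)
    t = np.arange(n) / rate
    g = np.zeros(n) if gaze is None else gaze
    return pf.PupilRecording(t=t, pupil=np.asarray(pupil, float), gaze_x=g,
                             gaze_y=np.zeros(n), sample_rate=rate,
                             blinks=tuple(blinks), saccades=tuple(saccades))


class TestInterpolation:
    def test_linear_fill_between_anchors(self):
        """[5, NaN, NaN, 8] with saccades flanking the gap -> [5, 6, 7, 8]."""
        rate = 1.0
        rec = make_rec([5.0, np.nan, np.nan, 8.0], rate=rate,
                       blinks=[(1.0, 3.0)], saccades=[(0.0, 1.0), (3.0, 4.0)])
        out, mask, log = pf.interpolate_blinks(rec)
        assert np.allclose(out.pupil, [5, 6, 7, 8])
        assert mask.tolist() == [False, True, True, False]
        assert log == []

    def test_no_blinks_identity(self, rng):
        rec = make_rec(rng.normal(size=100))
        out, mask, _ = pf.interpolate_blinks(rec)
        assert np.array_equal(out.pupil, rec.pupil)
        assert not mask.any()

    def test_missing_saccade_fallback_and_edges(self):
        """No saccade markers -> nearest valid sample anchors, logged;
        a blink running past the recording end is edge-filled."""
        x = [1.0, 2.0, np.nan, np.nan, 4.0, np.nan, np.nan, np.nan]
        rec = make_rec(x, rate=1.0, blinks=[(2.0, 4.0), (5.0, 8.0)])
        out, mask, log = pf.interpolate_blinks(rec)
        assert np.allclose(out.pupil, [1, 2, 8 / 3, 10 / 3, 4, 4, 4, 4])
        assert mask.sum() == 5
        assert any("anchor" in m for m in log) and any("end" in m for m in log)

    def test_generator_gap_fraction_matches_truth(self, default_pupil, schedule):
        """The interpolation mask recovers exactly the samples the
        generator removed."""
        rec, truth = default_pupil
        _, mask, _ = pf.interpolate_blinks(rec)
        assert np.array_equal(mask, truth["gap_mask"])


class TestSmoothing:
    def test_constant_unchanged(self):
        rec = make_rec(np.full(500, 3.3))
        assert np.allclose(pf.smooth_sliding_mean(rec).pupil, 3.3)

    def test_impulse_plateau(self):
        """A unit impulse at 250 Hz with a 200-ms (50-sample) window
        becomes a plateau of 1/50."""
        x = np.zeros(1000)
        x[500] = 1.0
        out = pf.smooth_sliding_mean(make_rec(x)).pupil
        assert np.isclose(out[500], 1 / 50)
        assert np.isclose(out.sum(), 1.0)
        assert (out[480:520] > 0).all()

    def test_matches_bruteforce_window(self, rng):
        """Random trace equals a per-sample loop over the centered,
        edge-truncated 50-sample window."""
        x = rng.normal(size=400)
        out = pf.smooth_sliding_mean(make_rec(x)).pupil
        expected = np.array([
            np.mean(x[max(0, i - 25):min(len(x), i + 25)]) for i in range(len(x))
        ])
        assert np.allclose(out, expected, atol=1e-12)
        assert out.var() < x.var()


class TestZTransform:
    def test_population_sd(self):
        rec = make_rec([1.0, 2.0, 3.0])
        out = pf.ztransform(rec).pupil
        assert np.allclose(out, [-1.22474487, 0.0, 1.22474487])

    def test_moments_and_affine_invariance(self, rng):
        x = rng.normal(2.0, 5.0, 1000)
        z1 = pf.ztransform(make_rec(x)).pupil
        z2 = pf.ztransform(make_rec(3.0 * x - 7.0)).pupil
        assert abs(z1.mean()) < 1e-10 and abs(z1.std() - 1) < 1e-10
        assert np.allclose(z1, z2)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pf.ztransform(make_rec(np.ones(10)))


class TestDerivativeAndDownsample:
    def test_derivative_identities(self, rng):
        """Constant -> zeros; ramp -> constant slope; cumulative sum of
        the derivative reconstructs the trace."""
        t, d = pf.pupil_change(make_rec(np.full(100, 2.0)))
        assert np.allclose(d, 0) and len(d) == 99
        _, d = pf.pupil_change(make_rec(np.arange(100) * 0.3))
        assert np.allclose(d, 0.3)
        x = rng.normal(size=200)
        _, d = pf.pupil_change(make_rec(x))
        assert np.allclose(x[0] + np.cumsum(d), x[1:])

    def test_per_second_rescale(self):
        _, d = pf.pupil_change(make_rec(np.arange(100) * 0.3), per_second=True)
        assert np.allclose(d, 0.3 * 250)

    def test_downsample_bin_means(self, rng):
        """250 -> 10 Hz bin means of a ramp equal the bin midpoints; a
        constant stays constant; non-divisible rates error."""
        x = np.arange(500, dtype=float)
        t = np.arange(500) / 250.0
        starts, means = pf.downsample(t, x, 10.0, 250.0)
        assert len(means) == 20
        expected = np.array([np.mean(x[i * 25:(i + 1) * 25]) for i in range(20)])
        assert np.allclose(means, expected)
        assert np.allclose(starts, np.arange(20) / 10.0)
        _, const = pf.downsample(t, np.full(500, 5.0), 1.0, 250.0)
        assert np.allclose(const, 5.0)
        with pytest.raises(ValueError):
            pf.downsample(t, x, 7.0, 250.0)


class TestQc:
    def test_cutoff_arithmetic_and_clean_gaze(self, schedule):
        """With the cohort reference SDs the cutoff half-widths are
        3.3 x (105.34, 91.40) = (347.622, 301.62); fixed gaze at the
        center has zero outside fraction and passes."""
        n = int(schedule.span * 250) + 250
        rec = make_rec(np.random.default_rng(0).normal(size=n))
        qc = pf.qc_subject(rec, schedule)
        assert qc.cutoff_half_widths == pytest.approx((347.622, 301.62))
        assert (qc.per_block["gaze_outside_fraction"] == 0).all()
        assert qc.passed

    def test_missing_block_fails_subject(self, schedule):
        """25% interpolated samples inside one block exceed the 20%
        threshold and fail the subject."""
        n = int(schedule.span * 250) + 250
        rec = make_rec(np.zeros(n))
        mask = np.zeros(n, dtype=bool)
        block = schedule.blocks[2]
        i0 = int(block.onset * 250)
        mask[i0:i0 + int(0.25 * 40 * 250)] = True
        qc = pf.qc_subject(rec, schedule, mask=mask)
        assert not qc.passed
        row = qc.per_block.set_index("block_index").loc[2]
        assert row["missing_fraction"] == pytest.approx(0.25)

    def test_qc_matches_generator_gap_fraction(self, default_pupil, schedule):
        """Per-block missing fractions equal the generator's inserted-gap
        fractions (missing == interpolated)."""
        rec, truth = default_pupil
        _, mask, _ = pf.interpolate_blinks(rec)
        qc = pf.qc_subject(rec, schedule, mask=mask)
        for _, row in qc.per_block.iterrows():
            block = schedule.blocks[int(row["block_index"])]
            sel = (rec.t >= block.onset) & (rec.t < block.end)
            assert row["missing_fraction"] == pytest.approx(truth["gap_mask"][sel].mean())


class TestTrialFeatures:
    def test_flat_trace_zero_amplitude(self, schedule):
        n = int(schedule.span * 250) + 250
        rec = make_rec(np.full(n, 1.5))
        feat = pf.extract_trial_peak(rec, schedule.blocks[0].trials[0])
        assert feat["peak_amplitude"] == 0.0

    def test_search_window_excludes_early_max(self, schedule):
        """A larger excursion at 0.9 s is ignored; the peak is taken in
        [1.0, 2.5) s after onset."""
        trial = schedule.blocks[0].trials[0]
        n = int(schedule.span * 250) + 250
        x = np.zeros(n)
        x[int((trial.onset + 0.9) * 250)] = 5.0
        x[int((trial.onset + 1.4) * 250)] = 2.0
        feat = pf.extract_trial_peak(make_rec(x), trial)
        assert feat["peak"] == 2.0

    def test_low_confidence_flag(self, schedule):
        trial = schedule.blocks[0].trials[0]
        n = int(schedule.span * 250) + 250
        rec = make_rec(np.zeros(n))
        mask = np.zeros(n, dtype=bool)
        sel = (rec.t >= trial.onset + 1.0) & (rec.t < trial.onset + 2.5)
        mask[sel] = True
        assert pf.extract_trial_peak(rec, trial, mask=mask)["low_confidence"]
        # partially masked windows keep full confidence
        half = mask.copy()
        half[np.flatnonzero(mask)[::2]] = False
        assert not pf.extract_trial_peak(rec, trial, mask=half)["low_confidence"]


class TestConditionMeans:
    def test_hand_built_block_means(self, schedule):
        """A trace holding value v_b inside block b reproduces v_b as the
        block mean and the two-block average per condition."""
        n = int(schedule.span * 250) + 250
        x = np.zeros(n)
        t = np.arange(n) / 250.0
        for b, block in enumerate(schedule.blocks):
            x[(t >= block.onset) & (t < block.end)] = float(b + 1)
        block_means, cond_means = pf.condition_means(make_rec(x), schedule)
        assert np.allclose(block_means["mean_pupil"], np.arange(1, 9))
        # condition means pair block b with block at the mirrored position
        order = [b.condition.value for b in schedule.blocks]
        for cond in set(order):
            idx = [i for i, c in enumerate(order) if c == cond]
            assert cond_means[cond] == pytest.approx(np.mean([i + 1 for i in idx]))

    def test_generator_tonic_ordering(self, default_pupil, schedule):
        """Condition means preserve the generator's tonic ordering
        fixation < 0-back < 1-back < 2-back."""
        rec, _ = default_pupil
        proc, _, _ = pf.preprocess(rec)
        _, cond_means = pf.condition_means(proc, schedule)
        assert (cond_means["fixation"] < cond_means["0-back"]
                < cond_means["1-back"] < cond_means["2-back"])


class TestProperties:
    """Seeded hypothesis property checks of the signal primitives."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=400),
           st.floats(-50, 50), st.floats(0.1, 20))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_ztransform_affine_invariant(values, shift, scale):
        x = np.asarray(values)
        if np.std(x) < 1e-6:
            return
        a = pf.ztransform(make_rec(x)).pupil
        b = pf.ztransform(make_rec(scale * x + shift)).pupil
        assert np.allclose(a, b, atol=1e-8)
        assert abs(a.mean()) < 1e-9 and abs(a.std() - 1) < 1e-9

    @staticmethod
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=500))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_derivative_telescopes(values):
        x = np.asarray(values)
        _, d = pf.pupil_change(make_rec(x))
        assert np.allclose(x[0] + np.cumsum(d), x[1:], atol=1e-6)

    @staticmethod
    @given(st.integers(1, 25), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_downsample_preserves_total_mass(factor, seed):
        rate = 250.0
        target = rate / factor
        rng_local = np.random.default_rng(seed)
        n = factor * 40
        x = rng_local.normal(size=n)
        t = np.arange(n) / rate
        _, means = pf.downsample(t, x, target, rate)
        # equal-count bins: the mean of bin means equals the overall mean
        assert np.isclose(means.mean(), x.mean(), atol=1e-9)
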