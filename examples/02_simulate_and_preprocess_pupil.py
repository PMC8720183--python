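"""Simulate a pupil recording and run the preprocessing chain.

The generator plants a load-ordered tonic level per condition and
target-evoked phasic dilations; preprocessing interpolates blinks
between saccade anchors, smooths with a 200-ms window, and z-scores the
whole recording.  QC checks per-block missing-data and gaze-excursion
fractions against the 20% thresholds.
"""

import pupilfmri as pf

schedule = pf.build_schedule(seed=1)
rec, truth = pf.simulate_pupil(schedule, pf.PupilGenConfig(seed=7))
print(f"samples: {rec.n_samples} at {rec.sample_rate:.0f} Hz, "
      f"blinks: {len(rec.blinks)} ({100 * truth['gap_fraction']:.1f}% of samples)")

proc, mask, _ = pf.preprocess(rec)
qc = pf.qc_subject(rec, schedule, mask=mask)
print(f"QC pass: {qc.passed}; worst block missing fraction: "
      f"{qc.per_block['missing_fraction'].max():.3f} (threshold 0.20)")

_, cond_means = pf.condition_means(proc, schedule)
print("mean pupil size (z) per condition:")
for cond, value in cond_means.items():
    print(f"  {cond:10s} {value:+.3f}")
print("tonic pupil size tracks working-memory load: fixation < 0-back < 1-back < 2-back.")

features = pf.trial_features(proc, schedule, mask=mask)
peaks = features[features.condition != "fixation"].groupby(
    ["condition", "is_target"])["peak_amplitude"].mean()
print("mean trial peak amplitude, max in 1.0-2.5 s window minus 0-0.5 s baseline:")
print(peaks.to_string())
print("note: these are on the post-z-transform scale (the whole-recording SD "
      "becomes 1), so they sit above the generator's configured amplitudes; "
      "targets dilate more than non-targets and the differential shrinks "
      "with load.")
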