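"""Planted-network recovery on a small synthetic cohort.

The generator couples frontoparietal (FPN) voxels to the pupil-size
modulation, salience voxels to the pupil-change modulation, and default
mode network (DMN) voxels negatively to pupil size.  Group one-sample
maps are thresholded jointly on Cohen's d and the natural-log Bayes
factor (logBF >= 3).
"""

from pupilfmri.recovery import group_recovery

out = group_recovery(n_subjects=12, seed=4)
print(f"cohort: {out['n_subjects']} subjects")
print(f"FPN sensitivity (pupil-size contrast, d>=0.2, logBF>=3): "
      f"{100 * out['fpn_sensitivity']:.1f}%")
print(f"salience sensitivity (pupil-change contrast, d>=0.5, logBF>=3): "
      f"{100 * out['salience_sensitivity']:.1f}%")
print(f"false positives among null voxels: size {100 * out['size_null_fpr']:.2f}%, "
      f"change {100 * out['change_null_fpr']:.2f}%")
print(f"DMN in negative size contrast: {100 * out['dmn_negative_sensitivity']:.1f}%; "
      f"in positive mask: {100 * out['dmn_in_positive_mask']:.2f}%")
print("high sensitivity with near-zero false positives means the two pupil "
      "readouts address their planted networks separately.")
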