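"""Build the parametric-modulation design matrices.

Four task models: blockwise pupil size, pooled 1-s-bin pupil change,
block-mean pupil change, and the demeaned-per-condition control in
which every block's mean change is subtracted bin-wise, removing all
between-block differences.  Modulators are mean-centered and the
modulated column residualized against its unmodulated parent.
"""

import numpy as np

import pupilfmri as pf
from pupilfmri.design import change_bins_per_block

schedule = pf.build_schedule(seed=1)
rec, _ = pf.simulate_pupil(schedule, pf.PupilGenConfig(seed=7))
proc, _, _ = pf.preprocess(rec)

dm_size = pf.build_pupilsize_glm(schedule, proc)
print(f"pupil-size design: {dm_size.matrix.shape[0]} frames x "
      f"{dm_size.matrix.shape[1]} columns -> {list(dm_size.matrix.columns)}")

bins = change_bins_per_block(schedule, proc)
print(f"pupil-change bins: {len(bins)} (= 8 blocks x 40 one-second bins)")

dm_dem = pf.build_pupilchange_glm(schedule, proc, "demeaned_per_condition")
dem = bins["change"] - bins.groupby("block_index")["change"].transform("mean")
print("demeaned variant per-block modulator means, max |.|:",
      float(np.abs(dem.groupby(bins['block_index']).mean()).max()))
print("a zero per-block mean guarantees the regressor carries only "
      "within-block pupil dynamics.")
print("demeaned design modulated columns:", list(dm_dem.modulated_columns))
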