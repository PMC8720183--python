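"""Run the file-based pipeline end to end for a small cohort.

Stages: simulate -> preprocess -> behavior -> design -> fit -> group.
Every stage reads only files written by earlier stages; QC-excluded
subjects are listed, never silently dropped.
"""

import json
import tempfile
from pathlib import Path

from pupilfmri import RunConfig, run_pipeline

out = Path(tempfile.mkdtemp(prefix="pupilfmri_"))
config = RunConfig(seed=1, n_subjects=3)
result = run_pipeline(config, out)

print(f"run dir: {out}")
print(f"exit code: {result.exit_code} (2 would mean QC exclusions)")
qc = json.loads((out / "qc_summary.json").read_text())
print(f"QC included: {qc['included']}, excluded: {qc['excluded']}")

summary = json.loads((out / "group" / "summary.json").read_text())
fpn = summary["size"]["task_block_x_pupil_size"]["pos"]["d>=0.2"]["FPN"]
print(f"group pupil-size contrast: {fpn['n_detected']}/{fpn['n_voxels']} "
      "FPN voxels above (d>=0.2, logBF>=3)")
sal = summary["change_pooled"]["task_bins_x_change"]["pos"]["d>=0.5"]["salience"]
print(f"group pupil-change contrast: {sal['n_detected']}/{sal['n_voxels']} "
      "salience voxels above (d>=0.5, logBF>=3)")
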