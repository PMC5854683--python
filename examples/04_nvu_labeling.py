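"""Neurovascular-uncoupling (NVU) screening: task fMRI vs CVR.

Builds a task t-map and a CVR max-t map on a shared grid, zeroes the
vascular response in part of the expected-function region, and labels the
ROI: voxels with neither response inside the expected region are the
NVU-potential voxels a reader should not interpret as "no activity".
"""

import numpy as np

from presurgmap import nvu_label
from presurgmap.cvr import CVRResult
from presurgmap.volumes import MaskVolume, StatMap, Volume3D

shape = (16, 16, 8)
aff = np.diag([2.0, 2.0, 2.0, 1.0])
aff[:3, 3] = -(np.array(shape) - 1) / 2.0 * 2.0

fmri = np.zeros(shape)
fmri[4:8, 4:8, 3:5] = 6.0          # task response in the motor strip
cvrt = np.full(shape, 5.0)         # healthy vasculature everywhere ...
cvrt[8:12, 4:8, 3:5] = 0.0         # ... except near the lesion

expected = np.zeros(shape, np.uint8)
expected[4:12, 4:8, 3:5] = 1       # where function is expected
roi = np.ones(shape, np.uint8)

cvr = CVRResult(StatMap(cvrt, aff, "cvr_t"),
                Volume3D(np.zeros(shape), aff),
                Volume3D(np.zeros(shape), aff), df=60)
labels = nvu_label(StatMap(fmri, aff, "t", df=100), cvr,
                   fmri_thr=4.04, cvr_thr=2.65,
                   roi=MaskVolume(roi, aff),
                   expected_region=MaskVolume(expected, aff))
print("label counts:", labels.counts)
print(f"NVU-potential voxels: {labels.counts['nvu_potential']} "
      "(expected function, no fMRI response, no CVR)")
print("code 3 = both responses, 2 = CVR only, 1 = fMRI only, 0 = neither; "
      "a silent expected-function area with absent CVR is where a negative "
      "fMRI map cannot be trusted")
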