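"""Breath-hold CVR mapping with per-voxel hemodynamic delay optimization.

Synthesizes the 210-s breath-hold protocol (70 volumes at TR 3 s) with two
responsive regions lagged by 0 s and +6 s, sweeps the RRF regressor over
delays -10..15 s, and reports the recovered delays.
"""

import numpy as np

from presurgmap import DelaySweep, cvr_map
from presurgmap.phantom import generate_session, protocol_fixture

session = generate_session(protocol_fixture("patient1_bh"))
paradigm = session.truth.bh_paradigm
print(f"BH paradigm: {paradigm.total_duration:.0f} s, "
      f"{paradigm.n_volumes} volumes at TR {paradigm.tr:.0f} s")

result = cvr_map(session.bh, paradigm, irf="rrf",
                 sweep=DelaySweep.from_range(-10, 15, 1))
for true_delay in (0.0, 6.0):
    sel = (session.truth.cvr_amplitude.data > 0) \
        & (session.truth.cvr_delay.data == true_delay)
    med = np.median(result.best_delay.data[sel])
    med_t = np.median(result.tmax.data[sel])
    print(f"region injected at {true_delay:+.0f} s: recovered median delay "
          f"{med:+.1f} s, median max-t {med_t:.2f}")
print("max-t selection keeps, per voxel, the delay whose regressor fits "
      "best; recovered delays should match the injected lags within the "
      "1-s sweep step")
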