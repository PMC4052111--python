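"""Evaluate the three-phase ASL kinetic model and invert it.

Prints the difference signal across inversion times for a grey-matter-like
voxel, then recovers the CBF from the plateau value by single subtraction.
"""

import numpy as np

from paslquant import (AcquisitionParams, KineticParams,
                       cbf_single_subtraction, delta_m)

acq = AcquisitionParams()  # TI1/TI2 = 800/1800 ms, alpha 0.95, T1b 1664 ms
kp = KineticParams(cbf=45.0, att=700.0, tau=800.0, m0b=1111.0)

print("t (ms)   dM (signal units)")
for t in (300, 700, 1000, 1500, 1800, 2400):
    print(f"{t:6d}   {delta_m(t, kp, acq):.4f}")

dm_plateau = delta_m(acq.ti2_base, kp, acq)
m0_tissue = kp.m0b * acq.lambda_
cbf = cbf_single_subtraction(dm_plateau, m0_tissue, acq)
print(f"\nplateau dM at TI2={acq.ti2_base:.0f} ms: {dm_plateau:.4f}")
print(f"quantified CBF: {cbf:.2f} mL/100 g/min (truth 45.00)")
# The signal is zero before the 700 ms transit time, ramps while the
# labeled bolus arrives, and decays with blood T1 after the bolus (800 ms,
# matching TI1) is in; quantifying the plateau returns the true perfusion.
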