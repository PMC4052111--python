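"""Simulate a label/control series on the digital phantom and quantify it.

Runs the full pipeline — motion screening, pairwise subtraction, temporal
averaging, per-slice TI2-compensated CBF mapping, tissue masking and ROI
statistics — on 90 simulated pairs with default thermal noise.
"""

from paslquant import (AcquisitionParams, PhantomSpec, build_phantom,
                       quantify_phantom, simulate_series)

acq = AcquisitionParams()
phantom = build_phantom(PhantomSpec(seed=1))
series, trace, m0_pair = simulate_series(phantom, acq, n_pairs=90)

res = quantify_phantom(phantom, series, m0_pair, trace)
s = res.stats
print(f"GM CBF : {s['cbf_gm']:6.2f} mL/100 g/min (truth 45)")
print(f"WM CBF : {s['cbf_wm']:6.2f} mL/100 g/min (truth 27)")
print(f"GM/WM  : {s['gm_wm_ratio']:6.2f}        (truth 1.67)")
print(f"interslice C.V. (GM): {s['interslice_cv_gm']:5.1f} %")
print(f"spatial    C.V. (GM): {s['spatial_cv_gm']:5.1f} %")
print(f"temporal   C.V.     : {s['temporal_cv']:5.1f} %")
print(f"pairs: {res.pair_counts}")
# ROI means land within a few percent of the phantom truth; the C.V. values
# quantify residual thermal-noise variability after averaging 90 pairs.
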