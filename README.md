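# paslquant

Quantification of cerebral blood flow (CBF) from pulsed arterial spin
labeling (PASL) MRI, aimed at perfusion studies of inferior brain regions
such as the cerebellum, where separate grey-matter (GM) and white-matter
(WM) values and careful artifact control matter. The package provides the
full analysis chain a PASL perfusion study needs — kinetic modelling,
label/control preprocessing, multi-inversion-time parameter fitting,
tissue masking, ROI and variability statistics, QC screens — plus a
digital two-tissue phantom so every stage can be run and validated without
scanner data.

## Model

The control-minus-label difference signal follows the three-phase single
blood-compartment model

```
ΔM(t) = 0                                   t < Δt
       = 2 α M0b f (t − Δt) exp(−t/T1b)      Δt ≤ t < Δt + τ
       = 2 α M0b f τ exp(−t/T1b)             t ≥ Δt + τ
```

with `f` the perfusion (internally mL/g/ms; mL/100 g/min at the API),
`Δt` the arterial transit time, `τ` the bolus duration, `α` the labeling
efficiency, `M0b = M0/λ` the arterial-blood equilibrium magnetization and
`T1b` the blood longitudinal relaxation time. With a temporally defined
bolus (width TI1) and acquisition on the plateau at total inversion time
TI2, a single subtraction inverts the model:

```
CBF = λ ΔM / (2 α M0 TI1 exp(−TI2/T1b))
```

Each slice uses its own effective TI2 (base + 30 ms per slice for
ascending EPI readout). Multi-TI2 experiments are fitted by bounded
nonlinear least squares to estimate CBF, Δt and τ per ROI.

## Worked example

```python
from paslquant import (AcquisitionParams, PhantomSpec, build_phantom,
                       quantify_phantom, simulate_series)

acq = AcquisitionParams()                      # TI1/TI2 = 800/1800 ms
phantom = build_phantom(PhantomSpec(seed=1))   # GM 45, WM 27 mL/100 g/min
series, trace, m0_pair = simulate_series(phantom, acq, n_pairs=90)
res = quantify_phantom(phantom, series, m0_pair, trace)
print(res.stats)
```

prints (seed 1):

```
GM CBF : 44.32 mL/100 g/min (truth 45)
WM CBF : 27.59 mL/100 g/min (truth 27)
GM/WM  :  1.61              (truth 1.67)
```

— the ROI means recover the phantom's ground truth within the thermal
noise left after averaging 90 label/control pairs; in the noiseless limit
the recovery is exact to machine precision. The `examples/` directory has
one short script per capability (kinetic model, phantom quantification,
transit-time fitting, group statistics, delay sweep), and the same stages
are available as `paslquant simulate|quantify|fit|roistats|qc|compare`
from the shell.

`paslquant.datasets.cerebellum_cbf_table()` bundles a published
five-subject per-subject CBF table comparing two PASL labeling schemes
(FAIR ASST vs PICORE); `perfusion_report` and `paired_ttest` rebuild all
of its derived rows (means, S.D.s, C.V.s, GM/WM ratios) and the
between-method tests (GM p = 0.135, WM p = 0.278, df = 4).

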