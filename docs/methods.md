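# Methods

## Signal model and quantification

The package models the pulsed-ASL control-minus-label difference signal
with the three-phase single blood-compartment model: zero before the
labeled bolus reaches the voxel (arterial transit time Δt), a linear
inflow ramp damped by blood T1 decay while the bolus enters (duration τ),
and a decaying plateau `2 α M0b f τ exp(−t/T1b)` once the bolus is fully
delivered. The model is continuous at both breakpoints and homogeneous of
degree one in `M0b` and in `f`.

Single-subtraction quantification assumes acquisition on the plateau with
a saturation-defined bolus of width TI1, giving
`CBF = λ ΔM / (2 α M0 TI1 exp(−TI2/T1b))`. Assumptions: the effective
bolus is exactly TI1 (the saturation train truncates a longer bolus), the
whole bolus has arrived (`Δt + TI1 ≤ TI2` in every slice), and no
intravascular label remains. Negative ΔM is preserved with its sign so
subtraction errors remain visible downstream. Voxels with non-positive M0
quantify to NaN and are excluded from ROI statistics.

All times are milliseconds internally; CBF crosses the API in
mL/100 g/min via the factor 6×10⁶ (mL/g/ms → mL/100 g/min) applied only
at boundaries, so no intermediate carries a mixed unit.

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| TI1 | 800 | ms | temporal bolus width (saturation-defined) |
| TI2 (first slice) | 1800 | ms | total inversion time at the first slice |
| slice_dt | 30 | ms | per-slice acquisition increment, ascending order |
| α | 0.95 | — | inversion (labeling) efficiency |
| T1b | 1664 | ms | blood T1 at 3T; not fixed by the study design, so exposed for sensitivity checks |
| λ | 0.9 | mL/g | blood/tissue water partition coefficient |
| TR | 2500 | ms | repetition time (bookkeeping only) |

Slice-timing compensation uses `TI2(k) = TI2_base + k·slice_dt` both in
simulation and quantification; the two must agree for the forward–inverse
identity to be exact, and they do by construction.

## Preprocessing and motion rules

Motion parameters (3 translations mm, 3 rotations deg per volume) are an
input, not estimated here; registration is a solved upstream problem and
its outputs are what the rules consume. Volumes exceeding 1 mm or 1° on
any axis are resampled by the inverse of their recorded transform
(trilinear); volumes exceeding 2 mm or 2° are excluded, and exclusion
always removes the label/control partner too, since an unpaired volume
cannot be subtracted. Decisions are exclusive at the threshold (exactly
1 mm keeps). Subtraction is control − label per surviving pair; the mean
perfusion-weighted image and the mean of the two proton-density images
feed quantification.

## Multi-TI2 kinetic fitting

ROI curves are built from two-sided trimmed means (default 5% per tail,
`floor(frac·n)` values removed per tail so small ROIs are never emptied;
trimming is applied per TI2 point). Grey-matter curves may pool two
adjacent slices (non-overlapping pairs, signal and effective TI2 both
averaged; odd trailing slice kept) to raise SNR at long TI2.

`fit_kinetic` minimizes the residual sum of squares with scipy's bounded
trust-region reflective least squares (ftol/xtol/gtol 1e-12, ≤2000
evaluations — deterministic given data and start). Free parameters: CBF,
Δt, τ, and an additive baseline offset. A free multiplicative amplitude
would be exactly collinear with CBF (both scale the model linearly), so
the calibration amplitude `2 α M0b` is fixed at its measured value and
residual DC leakage from imperfect subtraction is absorbed by the offset
— the identifiable reading of a four-parameter fit of this model.
Initialization: CBF 50 mL/100 g/min, Δt 700 ms, τ max(TI1, 100) ms,
offset 0; bounds CBF [0, 300], Δt [0, 3000] ms, τ [100, 3000] ms. The
breakpoint non-smoothness is handled by finite differences over the
continuous model; in practice noiseless ladders are recovered to ~1e-9
relative. All-zero curves short-circuit to CBF = 0 with a degeneracy
flag; non-convergence is flagged, never raised. Standard errors come from
the Gauss–Newton covariance `(JᵀJ)⁻¹·RSS/dof`.

## Tissue masks

Probability maps are thresholded at 0.75, AND-ed with the anatomical ROI,
and — when interpolation has produced fractional mask values —
conservatively rebinarized at 0.9. If both tissues pass the threshold at
a voxel it goes to the higher probability (tie → GM), keeping the masks
disjoint. The cascade is idempotent and antitone in both thresholds.
Resampling between grids is out of scope; on the phantom all inputs share
the ASL grid.

## ROI statistics

Coefficient of variance is always `100·SD/mean` with the sample (n−1) SD
— the convention the bundled reference table is consistent with.
Interslice variability is the C.V. of per-slice masked means; spatial
variability the C.V. over all masked voxels; temporal variability the
C.V. across time of the mean difference signal in a configurable slice
set (default: the four most inferior slices, the phantom's stand-in for
slices near the transverse sinuses). GM/WM ratios are computed per
subject and then averaged. Report tables round CBF to 2 decimals and
C.V. to 1; full precision is kept internally. Paired method comparisons
use the classical two-tailed paired t-test (df = n−1) via scipy,
cross-checked in the tests against the closed form.

## The phantom and what passing it shows

The phantom is a grey-matter ellipsoidal shell (semi-axes 13×13×5.2
voxels on a 32×32×12 grid, 3×3×6 mm voxels) around a white-matter core
(7.5×7.5×3), with truth values GM: CBF 45 mL/100 g/min, Δt 700 ms, τ
900 ms, M0 1100; WM: CBF 27, Δt 800 ms, τ 1000 ms, M0 1000. Transit
times and bolus durations sit inside the windows multi-TI2 fitting
reports for real cerebellum (≈550–1000 ms and ≈800–1500 ms); WM's
Δt + τ = 1800 ms means both tissues are exactly on the plateau at the
default TI2, so the noiseless pipeline is an exact inverse. GM/WM truth
ratio is 1.67, near the ≈1.6 observed in vivo.

Emulated features: Gaussian thermal noise (σ = 10 signal units on label
and control, i.e. M0 SNR ≈ 100–120, so difference-image SNR is realistic
for 3T EPI); bolus truncation by the saturation train (τ_eff =
min(τ, TI1); off in ladder simulations, where the train is off);
intravascular hyperintensities (6 five-voxel clusters in the three most
inferior slices, amplitude 200 units decaying with post-labeling delay,
time constant 700 ms, extinct at 1000 ms); a partial-volume rim
(outermost shell M0 ×0.65, which puts rim voxels under the 800-unit QC
cut while interiors stay at 1000–1100); probability maps as
Gaussian-smoothed indicators (σ 0.6 voxel), fractional at boundaries;
optional per-volume rigid motion recorded in the ground-truth trace. All
randomness derives from one seed through independent child streams;
identical specs give byte-identical outputs.

Not emulated: physiological noise and its temporal autocorrelation, B0
susceptibility distortion, realistic anatomy, partial-volume mixing of
kinetics (each voxel is purely one tissue), venous inflow physics.
Passing the phantom tests therefore demonstrates correctness of the
numerics and the decision rules under the stated noise model — not
robustness to structured physiological confounds in vivo.

Ladder-curve simulations propagate the voxel noise analytically to the
curve level: σ_curve = σ√2/√(n_pairs·n_voxels) with 30 pairs and 250
voxels, the GM extent of one phantom slice (2952 GM voxels / 12 slices);
the trimmed mean's small variance reduction is neglected, which slightly
overstates the noise.

## Delay-sweep analysis

`delay_sweep_spatial_cv` quantifies each delay's mean difference image to
a CBF map before taking the spatial C.V., so the T1b decay common to all
voxels is compensated and the metric compares delays on one scale. The
C.V. declines with delay while vascular spikes wash out and pre-plateau
transit heterogeneity resolves, reaching its minimum at the 1000 ms
extinction delay; beyond it the C.V. rises slowly again because thermal
noise is amplified by exp(TI2/T1b) while the signal is constant — the
SNR cost of over-long delays. The selection rule this reproduces: choose
the shortest delay at which the map is artifact-free.

## Problem sizes and numerical choices

Default test/validation sizes: 32×32×12 grid; 90 pairs for
quantification runs (4 noiseless); 30 pairs per delay in sweeps; 200
Monte-Carlo ladder fits; 60 in the unit-test variant. Equality checks on
the forward–inverse identity use 1e-8 relative; noiseless fit recovery
1e-6; oracle comparisons 1e-9–1e-12. Reference-table reconstructions are
compared at the table's printed precision, allowing half a printed ULP
plus the table's own evident truncate-vs-round slack (its printed mean
43.78 corresponds to a computed 43.786).

## Known limitations

- Single-compartment model only; no dispersion, no two-compartment
  exchange, no magnetization-transfer modelling.
- The two labeling schemes in the bundled table are compared
  statistically; the simulator does not physically model their pulse
  sequences.
- Rigid-motion correction assumes the recorded trace is exact (true for
  the simulator; an approximation for estimated traces on real data).
- Voxelwise multi-TI fitting maps are out of scope; fitting is per ROI.
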