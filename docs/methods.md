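# Methods

This note documents the models implemented in `ksim`, the defaults and
why they were chosen, the numerical choices that affect results, and the
limits of what the synthetic test conditions can show.

## Forward model

Acquisition is simulated shot by shot. One shot is an ordered list of
k-space locations `k[t_n]` (dimensionless, per-axis in [-0.5, 0.5),
voxel centres at integer offsets from the volume centre) with
echo-centred times `t_n ∈ [-Tobs/2, +Tobs/2]` at a constant dwell. The
forward kernel is `exp(-2iπ k·r)`; the fully sampled Cartesian transform
and its inverse are plain centred FFTs, so the whole package — engines
and reconstruction — shares one k-space convention.

Two engines simulate a shot from the current phantom state:

* **basic** — `y_ℓ[t_n] = F{S_ℓ μ}[k[t_n]]`, one transform per coil;
* **t2s** — the per-tissue sum
  `Σ_i μ_i e^{-t_n/T2*_i} Σ_p c_p[t_n] F{b_p S_ℓ w_i}[k[t_n]]`
  (`n_tis · P · L` transform calls per shot, counted and exposed).
  Times are echo-centred, so the decay factor is exactly 1 at the echo
  and larger than 1 before it; the per-tissue decay index is `T2*_i`
  (the per-tissue reading of the printed decay factor).

Off-resonance enters through a time-segmented separable approximation
`Σ_p c_p(t) b_p(r) ≈ e^{-2iπ Δf(r) t}` with anchors
`b_p = e^{-2iπ Δf τ_p}` at Chebyshev-spaced instants τ_p over the
readout (smaller worst-case residual than uniform spacing) and
coefficients `c_p(t_n)` from a weighted least-squares fit over a
64-bin histogram of the field map. The exact residual
`max_{r,t} |Σ_p c_p b_p - e^{-2iπ Δf t}|` is computed on the true map
and stored; a smooth ±50 Hz map over a 25 ms readout needs P = 8 for a
residual ≲ 1e-3, and P = 1 is exact for constant maps.

### Fourier transforms

No NUFFT library is assumed; off-grid sampling uses a Kaiser–Bessel
gridding transform written for this package: twofold oversampling,
kernel width 8, Beatty-rule shape parameter, apodization by the
quadrature-evaluated kernel transform. Accuracy against the dense DFT is
~1e-7 relative; the adjoint is the literal transpose of the
interpolation, so the dot-product test holds to machine precision
regardless of the gridding error. Exact paths are auto-selected:
on-grid (Cartesian) sample sets use an FFT plus index lookup, and grids
up to 16³ use a cached dense DFT matrix.

## Phantom and contrast

The synthetic phantom is three nested ellipsoidal shells — WM core, GM
shell, CSF rim — on the voxel grid, with fuzzy boundaries from a
1-voxel Gaussian smoothing of the binary shells ("fuzzy segmentation"
is otherwise unquantified). The seed jitters the shell axes by ~2 % so
distinct anatomies can be drawn; fractions satisfy `0 ≤ w_i ≤ 1`,
`Σ_i w_i ≤ 1`. Default 7T-like tissue parameters (all configurable):

| tissue | ρ | T1 (ms) | T2* (ms) |
|--------|------|---------|----------|
| WM | 0.77 | 1330 | 26 |
| GM | 0.86 | 2000 | 33 |
| CSF | 1.00 | 4000 | 100 |

The steady-state spoiled-GRE equation converts these to per-tissue
contrasts at `tref = TE`; the common sequence defaults are
TR_shot = 50 ms, TE = 25 ms, FA = 12° (the Ernst angle regime for GM at
this TR), Tobs = 25 ms. Coil sensitivities come from an analytic ring of
receivers (broad Gaussian magnitudes peaking at L equi-angular
positions, smooth linear phases; L = 1 is the constant map 1): coil
knowledge is treated as oracle throughout. The activation ROI is the
fuzzy GM segmentation thresholded at 0.5 intersected with a
posterior ellipsoid.

## Dynamics

The paradigm is a rest-first block design (20 s off / 20 s on by
default). The normalised response h̃ is the boxcar convolved with a
canonical double-gamma HRF (peak ~6 s, undershoot ~16 s, ratio 1/6),
sampled every TR_shot and rescaled to unit peak. Handlers are pure
functions of (baseline state, shot index, time): every shot's state is
recomputed from the baseline, which is what makes replay and concurrent
shot computation exact. The BOLD handler multiplies the GM
contrast-weighted map inside the ROI by `(1 - TE·ΔR2*·h̃(t))`
(ΔR2* = -1 Hz default; an exact-exponential variant is available behind
a flag). BOLD modulates magnitude only, never phase.

The handler samples h̃ at each shot's echo by default. A **frame-locked**
option freezes h̃ over each volume at its first shot's value. The
distinction matters for noiseless validation: with shot-resolution
modulation a reconstructed volume mixes images from slightly different
times, which leaks small task-correlated signal across kz (the planes
of one volume are measured at different instants), and a GLM on
noiseless data then flags leakage voxels as active however small the
amplitude (t-statistics are scale-free). Frame-locking makes each
volume consistent with a single image — the regime in which the GLM
model is exact — and is what the end-to-end exactness test uses. With
realistic noise the leakage is far below the noise floor and the
default shot-resolution model is the right one.

## Sampling

* **3D EPI**: one fully sampled (kx, ky) plane per shot, raster order
  with alternating line direction, times spanning Tobs so the ky = 0
  line falls at the echo. Union over shots = the exact Cartesian grid.
* **In-out spiral**: Archimedean, outward half from the centre, inward
  half its point reflection, centre crossing exactly at t = 0. Defaults
  (3000 samples, 14 turns, Tobs 30 ms) satisfy Gmax = 40 mT/m,
  Smax = 180 T/m/s at 3 mm / 192 mm FOV with 10 µs dwell (G ≈ 23 mT/m,
  S ≈ 135 T/m/s at the edge).
* **Stack of spirals**: `round(center_frac·nz)` central planes (always
  including kz = 0) acquired every frame; outer planes subsampled by AF
  — a fixed stride subset when static ("scan and repeat"), a per-frame
  seeded uniform draw without replacement when dynamic. The per-frame
  seed is derived from (master seed, frame index), so frames are
  independent but reproducible under parallel generation.
* The hardware audit converts normalised coordinates to physical units
  through the voxel size and reports finite-difference gradient and
  slew magnitudes against the limits.
* Trajectories round-trip losslessly through a small binary container
  (zip of float64 arrays + JSON header) or a plain-text CSV dialect, so
  externally optimised readouts can be imported.

## Noise

Per-sample circular complex Gaussian over the coil array with
covariance `(E/SNR_i)·Σ`, variance split equally between real and
imaginary parts, independent across samples. `E` is defined as the
**mean** squared contrast magnitude over the head support (the printed
definition does not fix the normalisation; the mean makes SNR_i values
comparable across phantom sizes, and the choice is recorded here). Each
shot's noise is drawn from a generator seeded by (master seed, shot
index), so the realisation is independent of execution order. The
RF-off calibration helper estimates the per-sample variance from a
signal-zeroed container and reports `E/var`, which recovers the
prescribed SNR_i.

## Raw-data container

Shots stream into an ISMRMRD-style HDF5 container written by this
package (one acquisition record per shot: complex float32 samples,
float32 per-sample trajectory, scan counter, frame index, plane index,
absolute echo time; the header is a JSON attribute). The writer
disables HDF5 timestamps so identical runs produce byte-identical
payloads. The full 4D image series is never materialised: each shot is
simulated from the baseline-plus-handlers state and appended.

## Reconstruction

* **Adjoint baseline**: fully sampled Cartesian frames invert exactly by
  FFT with conjugate-sensitivity coil combination. Non-Cartesian frames
  use Pipe–Menon density-compensation weights (30 fixed-point iterations
  of the gridding-kernel density) and are normalised by the DC gain of
  the compensated point-spread function, so smooth content reconstructs
  with unit amplitude. On a Nyquist-rate stack of spirals this baseline
  reaches ≈ 29–30 dB PSNR on the 32³ phantom; the quality bound asserted
  in the tests (28 dB) was fixed from this first implementation of the
  compensation rule.
* **CS**: accelerated proximal gradient on the wavelet-ℓ1 objective —
  POGM by default, FISTA as an option — with step 1/L from 20 power
  iterations, soft-thresholding of all wavelet coefficients as the prox,
  stopping on max_iter (default 100) or relative cost change < 1e-5. A
  final plain proximal-gradient step is appended: it can only decrease
  the objective and removes the momentum overshoot of the accelerated
  sequence (visible on perfectly conditioned problems such as fully
  sampled single-coil data, where it lands exactly on the minimiser).
  Divergence (cost above 10× the initial value) aborts with the step
  size in the message.
* **Wavelets**: orthogonal sym-8, periodized, 3 levels by default. With
  periodization the transform stays orthonormal (checked to 1e-10) even
  when the filter is longer than the coarse band, so the level is capped
  by the dyadic size rather than the filter length.
* **SURE weight**: σ is the MAD/0.6745 of the real and imaginary parts
  of the finest detail subband of the density-compensated adjoint image;
  the weight is the soft-threshold minimising the pooled SURE over all
  detail subbands. When an initialisation is available (warm/refined
  passes) the estimate is computed on the adjoint of the **data
  innovation** `y - A x_init`: as the initialisation explains more of
  the measurements the innovation shrinks, so later warm-pass frames are
  regularised less than frame 1 — the committed interpretation of the
  SURE tuning, isolated in one function so it can be swapped. Noiseless
  data yield σ = 0 (the phantom's constant interior dominates the finest
  subband) and hence μ = 0.
* **Strategies**: cold (zero init per frame), warm (previous frame),
  refined (full warm pass, then a second pass over all frames
  initialised with the final warm-pass volume). Diagnostics record the
  initialisation lineage, iteration counts, μ and costs per frame.

## Evaluation

Voxel-wise OLS with the task regressor (paradigm convolved with the same
HRF used in simulation, interpolated at each frame's timestamp — the
echo time of the frame's first shot) plus a constant; drifts are
unnecessary because the simulation has none. The one-sided t-map is
thresholded at the Student quantile (p = 0.001 uncorrected by default).
Voxels whose temporal standard deviation is below 1e-5 of the signal
level (the single-precision quantisation floor of the raw-data
container) carry no temporal information: they get t = 0, a degeneracy
flag, and are excluded from precision/recall curves. The PR curve sweeps
all distinct t values; the AUC is the trapezoid over recall with the
recall = 0 endpoint duplicating the first precision value (PR is used
instead of ROC because active voxels are rare). tSNR is the temporal
mean over temporal standard deviation averaged over the ROI, computed
both on the raw series and after removing the fitted task component
(which definition a study uses is often unstated, so both are
reported). PSNR uses the ideal contrast volume's peak; SSIM uses the
standard constants on magnitude images.

## Scenario scale and runtime

The shipped presets mirror the three study conditions (fully sampled 3D
EPI at 3 mm with one coil and SNR_i = 1000; variable-density stack of
spirals with 8 coils, 10 % centre planes, AF = 4; an imported fully 3D
trajectory with 32 coils and SNR_i = 30). The test suite and the
acceptance script run desk-scale versions of the same conditions — 16³
and 32³ grids, 40–120 s runs, a 5-minute budget only in the timing
arithmetic — chosen so the full suite completes in minutes on one CPU
while exercising every code path at the paper-scale sequence parameters
(TR_shot = 50 ms, TE = 25 ms, FA = 12°, Tobs = 25–30 ms).

## What the synthetic conditions do and do not show

The phantom has smooth ellipsoidal anatomy, oracle coil maps, no
motion, no physiological noise, no susceptibility or B0 scenario content
(the off-resonance interpolator is exercised with synthetic field maps
only), and activation confined to one ROI with a spatially uniform HRF.
Passing tests therefore demonstrate the correctness of the acquisition
model, the calibration of the noise, and the internal consistency of
the reconstruction/analysis chain — upper bounds on what a matched real
experiment could achieve — not performance on real anatomies or in the
presence of the excluded artifact sources. Multi-echo and spin-echo
sequences, GRAPPA/CAIPI parallel-imaging, 4D low-rank+sparse and
learned reconstructions are out of scope.
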