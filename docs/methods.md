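# Methods

`fresco` is a desk-scale re-implementation of a low-latency monitoring
pipeline for real-time phase-contrast MR (PCMR): highly undersampled
variable-density spiral acquisition, deep artifact suppression and
automatic aortic segmentation with two small 2D+time U-Nets, and
beat-to-beat quantification of heart rate (HR), stroke volume (SV) and
cardiac output (CO). Everything is driven by a synthetic pulsatile-flow
phantom with known ground truth; no scanner data are required.

## Acquisition model

### Spiral trajectory

A single interleave follows the pitch ODE

    dr/dtheta = R(r / k_max) / (2 pi FOV),

where the per-arm acceleration `R` (radial gap between successive turns
multiplied by the FOV, i.e. the local undersampling factor relative to
Cartesian Nyquist) is 26 on an inner plateau (rho <= 0.2), 65 on an
outer plateau (rho >= 0.9), and linear in between. The ODE is
integrated with fixed-step RK4 in theta and resampled uniformly in arc
length (default 2048 samples/arm). With FOV 400 mm and 2.1 mm voxels
the arm makes ~2.45 turns; three golden-angle-rotated arms per frame
give per-frame accelerations of 26/3 ~ 8.7 (inner) and 65/3 ~ 21.7
(outer). The golden angle defaults to the full-circle convention
2 pi (1 - 1/phi) ~ 222.49 deg (the ~137.51 deg variant is available);
the schedule is stateless, frame `f` using global arms `3f, 3f+1, 3f+2`.

The audit measures the realized acceleration from the generated
coordinates by intersecting the arm with fixed-azimuth rays and
evaluating the local pitch `2 pi dr/dtheta` at each crossing. With only
~2.45 turns no complete turn-to-turn gap lies inside either plateau, so
the local pitch — the gap the next turn would have at locally constant
pitch — is the well-defined plateau quantity; it converges to the
crossing-to-crossing gap under dense turns.

### NUFFT and density compensation

No NUFFT library is assumed: `fresco.nufft` implements type-1/type-2
gridding transforms with an exponential-of-semicircle kernel (width 8,
2x oversampling, beta = 2.30 w), accurate to ~1e-7 relative against
direct DFT summation, with the adjoint exact by construction (the
spreader is the transpose of the interpolator).

Density compensation is iterative sampling-density estimation
(`w <- w / (P^T P w)`, 10 iterations, kernel width 4). Two details
matter at high undersampling:

* **Estimation grid.** The kernel footprint must span the inter-turn
  gap, otherwise only the dense along-readout direction is sensed and
  the weights come out flat. The grid is chosen so the footprint is
  ~1.5x the largest radial gap measured from the sample cloud
  (azimuthal-sector radial sorting) — coarse for undersampled spirals,
  image-grid-fine for Nyquist-dense ones.
* **Gain calibration.** At 8.7x/21.7x undersampling no per-sample
  weighting represents the sparse central k-space faithfully, and the
  adjoint acquires a large object-dependent brightness gain. The
  weights are therefore rescaled once per trajectory so the
  density-compensated adjoint has unit least-squares gain on a smooth
  reference object pushed through the actual sampling operator.

A spiral samples only the inscribed disk of k-space; corner frequencies
are never acquired. Dense-limit checks therefore compare against the
disk-band-limited reference. At the printed undersampling the
single-frame adjoint is aliasing-dominated (relative L2 ~0.72 on a
Gaussian; tracked as a frozen regression bound, not an accuracy claim);
in the fully sampled regime the same machinery reaches <10%.

### Velocity encoding

One-sided encoding: the compensated readout carries the background
phase `phi0`, the encoded readout adds `pi v / VENC` (VENC 200 cm/s).
Pair combination averages magnitudes and subtracts phases;
`v = VENC angle / pi`, velocities beyond VENC wrap. A low-order
(degree <= 2) polynomial background model stands in for concomitant-
field (Maxwell) correction; the physical field computation is out of
scope.

## Synthetic phantom

A circular vessel (default radius 15 mm at 2.1 mm voxels) with a
parabolic through-plane profile `v(r,t) = 2 v_mean(t) (1 - (r/R)^2)`
pulses over a static background of tissue ellipses. The within-beat
waveform is a systolic half-sinusoid over the first 35% of the cycle on
a 5% diastolic pedestal; its beat average is `v_peak (0.05 + 0.7/pi)`,
from which the per-beat peak velocity is set to hit the target SV
exactly. Physiology defaults echo the study protocol: 40 s rest / 80 s
exercise / 60 s recovery with HR ramping 68 -> 94 bpm and SV ~85 -> 79
mL (piecewise linear), multiplicative lognormal RR jitter
(sigma = 0.03), 4 s respiratory cycle modulating SV (+-10%) and
translating the vessel (2 px peak). Each phantom carries a smooth
random polynomial background phase (up to ~2 rad): real compensated
images are phase-rich, and this is what makes the SSIM loss actually
penalize phase-unfaithful restorations. Complex Gaussian noise
(sd 0.02 relative) is added per coil at k-space simulation time; coil
sensitivities are analytic Gaussian lobes on the FOV perimeter,
RSS-normalized.

Vessel pixels are included by centre-in-circle (no subpixel weighting);
the 5% tolerance on analytic-flow checks budgets for that. Ground-truth
flow is recomputed from the discretized velocity maps and masks, so
truth is self-consistent to machine precision. The phantom does not
model in-plane flow, turbulence, off-resonance, T1/T2 contrast or
anatomically realistic torsos — passing tests demonstrate method
correctness and recovery under the modeled physics, not clinical
performance.

## Training data and networks

Training pairs are built exactly like the acquisition: the truth cine
(optionally augmented first — flips, right-angle rotations, circular
time roll, smooth random 2nd-order phase offsets capped at pi/2, and
sinusoidal translational drift on 50% of cases) is sampled onto the
spiral, density-compensated and gridded back, then cut into 24-frame
centre-cropped blocks. Both members are normalized by the corrupted
member's 99th-percentile magnitude mapped to 0.5 — the headroom keeps
the truth (whose bright vessel is smeared, hence dimmed, in the aliased
member) inside [-1, 1] without clipping.

The artifact suppressor is a 2D+time U-Net (channels = real/imag,
average-pool downsampling by 2 in t, y, x per scale, nearest-neighbour
upsampling, linear 1x1x1 head) trained with the complex SSIM loss

    L = 1 - [SSIM((re y + 1)/2, (re y_hat + 1)/2)
           + SSIM((im y + 1)/2, (im y_hat + 1)/2)] / 2,

SSIM computed per 2D frame with an 11x11 Gaussian window (sigma 1.5,
K1 = 0.01, K2 = 0.03, data range 1, border cropped by the window
radius) and averaged. By default the network predicts a residual added
to its input: at initialization the mapping is the identity, which
preserves the inter-encoding phase difference — without it a small
network first converges to a magnitude-only solution that destroys the
velocity information. The engine is a self-contained numpy layer stack
with explicit backward passes (verified by finite differences) and
Adam; the SSIM gradient is derived analytically through the three
filtered moments.

The segmenter shares the architecture (one sigmoid output channel) and
trains on CLAHE-equalized (clip limit 0.02, 8x8 tiles) combined
phase-contrast blocks with BCE + soft-Dice loss (BCE and Dice alone are
selectable). Its training set mixes clean phase-subtracted truth blocks
with the same blocks restored from their aliased encodings by the
trained suppressor, so inference-domain inputs are in-distribution;
masks threshold the probability at 0.5, with an optional
largest-connected-component filter.

A reduced successive-halving search (keep 1/3 per round, epoch budget
x3 per round) stands in for full-scale hyperparameter optimization.

## Streaming pipeline and latency model

Frames are processed in sliding blocks (window 24, step 18). Mid-stream
blocks keep their central 18 frames; the first and last blocks keep
their edges so the kept ranges partition the stream exactly. Per block:
grid both encodings per coil, coil-combine (maps estimated from the
temporal average of the first 10 frames, Gaussian-smoothed sigma 2 px,
RSS-normalized), centre-crop, normalize, suppress each encoding,
combine, CLAHE + segment, de-normalize, update the flow curve and beat
table. A failing block is flagged and the stream continues.

Flow is `sum_mask v * pixel_area` (cm/s x mm^2 = 0.01 mL/s); in the
pipeline the integration mask is the detected mask dilated by 2 px
(about one point-spread half-width at this undersampling) because the
restored velocity maps approximately conserve through-plane flux but
smear part of it just outside the lumen — a tight-lumen integration
under-measures SV while the capture margin adds little background phase
noise. Reported masks stay undilated. Systolic
peaks are detected with a minimum spacing of 60000/HR_max ms (HR_max
220 bpm) and a prominence threshold of 20% of the median prominence
from a permissive first pass (scale-invariant). Beats run peak-to-peak;
SV is the trapezoidal integral between peaks (beat volumes sum exactly
to the curve integral), HR = 60000/RR, CO = SV HR / 1000. Per-beat
agreement with truth is limited by the 35 ms frame quantization of beat
boundaries (~1 frame on an 800 ms beat, up to ~10% of a beat's volume);
the mean CO is exact to <1%. A 5-beat running median smooths display
curves only.

The latency model reproduces the deployment arithmetic: steady-state
latency of the kept frame at in-block position p is
`(24 - p) * 35 + 16.2 + 151` ms — 622.2 ms for the central kept frame,
902.2 ms for the first. Start-up backlog is a queue drained at one
block-processing time (18 x 16.2 + 151 = 442.6 ms) per 630 ms
acquisition step, so it shrinks monotonically; the exact catch-up
duration depends on queueing details that are modeled only
qualitatively.

An optional temporal-total-variation compressed-sensing reconstruction
(monotone FISTA, temporal-TV prox by vectorized dual ascent,
lambda = 5e-4 on normalized data, step from power iteration) serves as
an internal comparison oracle; it is not in the real-time path.

## Desk-scale study conditions

Tests and the worked example run at a reduced geometry chosen once: a
64 px grid at the unchanged 2.1 mm voxel (FOV scales with the grid so
the per-frame 8.7x/21.7x undersampling severity is preserved), 512
samples/arm, 24 x 64 x 64 blocks, 20 training phantoms (one block
each) with varied HR/SV/vessel geometry, 4 held-out phantoms, a
2-scale/8-filter suppressor (10 epochs) and 2-scale/6-filter segmenter
(6 epochs), and a 20 s rest phantom (75 bpm, SV 80 mL -> CO 6.0 L/min)
for end-to-end monitoring recovery. Under these conditions held-out
magnitude SSIM improves from ~0.41 (aliased) to ~0.55-0.60, held-out
Dice is ~0.9, and pipeline CO is within a few percent of truth.

## Known limitations

* The gridding gain calibration equalizes scales in the least-squares
  sense; residual object-dependent gain of tens of percent remains at
  high undersampling (normalization absorbs it downstream).
* Pipe-Menon-style density estimation cannot represent the sparse
  centre of a 2.45-turn arm exactly; adjoint images at the printed
  acceleration remain aliasing-dominated by design (that is what the
  suppressor is for).
* Beat-table accuracy is bounded by the 35 ms frame duration.
* The numpy engine trains tiny networks in minutes on a CPU; it is not
  a general deep-learning framework (no batching, no GPU).
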