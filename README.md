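# fresco

Low-latency reconstruction, automatic segmentation and beat-to-beat
cardiac-output monitoring for **highly undersampled real-time spiral
phase-contrast MR (PCMR)** — built as a fully testable, desk-scale
pipeline driven by a synthetic pulsatile-flow phantom.

Continuous cardiac-output (CO) monitoring during exercise or other
stressors needs real-time PCMR, which in turn needs aggressive
undersampling (here a variable-density golden-angle spiral, ~8.7x in
the centre of k-space and ~21.7x at the edge per frame) and a
reconstruction fast enough to keep up with acquisition. `fresco`
implements the whole chain:

1. **Trajectory** — variable-density spiral design from the pitch ODE
   `dr/dtheta = R(r/k_max) / (2 pi FOV)` (per-arm acceleration plateaus
   26/65 with a linear ramp), golden-angle scheduling, iterative
   density-compensation weights, and an audit that measures the
   realized acceleration from the generated coordinates.
2. **Encoding** — gridding NUFFT (type 1/2, written in numpy/scipy, no
   external NUFFT dependency), analytic and estimated coil maps,
   one-sided velocity encoding (`phase = pi v / VENC`, VENC 200 cm/s),
   pair combination with polynomial background-phase (Maxwell-style)
   correction, and an optional temporal-TV compressed-sensing oracle.
3. **Phantom** — pulsatile circular vessel with parabolic flow profile,
   rest/exercise/recovery heart-rate ramp (68 -> 94 bpm), RR jitter,
   respiratory stroke-volume modulation and motion, background phase,
   multi-coil noise, and exact ground truth (masks, flow curve, beat
   table).
4. **Networks** — two small 2D+time U-Nets on a self-contained numpy
   engine with exact hand-written backward passes: deep artifact
   suppression trained with the complex SSIM loss
   `L = 1 - [SSIM(re) + SSIM(im)] / 2` (channels mapped to [0,1]), and
   aortic segmentation on CLAHE-equalized combined blocks with a
   BCE + Dice loss.
5. **Streaming** — sliding-window blocks (24 frames, step 18, central
   frames kept), per-block normalization, the latency model of the
   at-scanner deployment (622.2 ms central / 902.2 ms first kept
   frame), and the end-to-end runner producing flow curves and
   beat-to-beat HR/SV/CO tables.
6. **Evaluation** — MAE/PSNR/SSIM, BCE/Dice, and Bland–Altman
   agreement with paired t tests.

## Worked example

Generate a resting phantom and quantify its flow:

```python
from fresco.phantom import PhantomConfig, generate_phantom
from fresco.flowquant import flow_curve, detect_beats, beat_metrics

cfg = PhantomConfig(grid=64, duration_s=20.0, hr_bpm=75.0,
                    hr_ramp=(21.0, 22.0, 75.0),  # stay at rest
                    sv_ml=80.0, sv_peak_ml=80.0, seed=7)
ph = generate_phantom(cfg)
curve = flow_curve(ph.truth.velocity_cm_s, ph.truth.masks,
                   ph.truth.pixel_area_mm2, cfg.frame_ms)
beats = beat_metrics(curve, detect_beats(curve))
print(beats[["peak_time_ms", "rr_ms", "hr_bpm", "sv_ml", "co_l_min"]].head(4).round(2))
print(f"mean CO {beats.co_l_min.mean():.2f} L/min over {len(beats)} beats")
```

```
   peak_time_ms  rr_ms  hr_bpm  sv_ml  co_l_min
0         157.5  770.0   77.92  71.40      5.56
1         927.5  805.0   74.53  86.77      6.47
2        1732.5  805.0   74.53  86.20      6.42
3        2537.5  770.0   77.92  70.15      5.47
mean CO 6.06 L/min over 24 beats
```

Each row is one detected beat: the systolic peak time, the peak-to-peak
RR interval, the heart rate `60000/RR`, the stroke volume (trapezoidal
integral of the flow curve between peaks, in mL) and the cardiac output
`SV x HR / 1000` in L/min. The configured physiology (SV 80 mL at
75 bpm) corresponds to 6.0 L/min; the per-beat scatter comes from the
modeled RR jitter, respiratory stroke-volume modulation and the 35 ms
frame quantization of beat boundaries.

The command line exposes the same operations
(`fresco audit-traj | simulate | train-recon | train-seg | run | eval`),
e.g.

```sh
fresco audit-traj --out audit.json
```

prints the realized acceleration of the printed design
(`per_arm_inner ~ 26`, `per_arm_outer ~ 65`, `per_frame_inner ~ 8.67`,
`per_frame_outer ~ 21.67`, `density_ratio ~ 2.5`).

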