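# rgcspeed

Speed selectivity of retinal ganglion cell (RGC) populations under
stimuli of increasing naturalness — a tested analysis pipeline with a
synthetic LN–Poisson retina as ground truth.

Retinal recordings with drifting gratings and Motion Cloud textures ask a
simple question: when a moving stimulus spreads its spectral energy over a
band of spatial frequencies (as natural scenes do) instead of a single
line (a grating), how does the speed tuning of ganglion cells change, and
what does that do to the population code and to downstream speed read-out?
This package implements the full measurement chain for that question:

* **stimuli** — calibrated drifting gratings, narrow/broad-bandwidth
  Motion Clouds (random-phase textures with a spectral envelope warped
  along the plane of constant speed), and binary white-noise
  checkerboards, over a 6 spatial-frequency × 5 speed grid;
* **synthetic_retina** — populations of ON/OFF cells with elliptical
  receptive fields and biphasic temporal kernels, spiking as LN–Poisson
  processes or with planted skewed-Gaussian speed tuning;
* **receptive_fields** — spike-triggered averages, 2-D Gaussian ellipse
  fits (eccentricity ε = √(1 − (b/a)²), equal-area radius √(ab)),
  difference-of-cascades temporal fits with peak-time and zero-cross
  markers;
* **tuning** — PSTHs, the standardized first harmonic
  zF1 = (F1 − mean(FFT))/SD(FFT), the zF1–rate modulation screen, and
  skewed-Gaussian speed-tuning fits in log₂-speed

  R(v) = A[exp(−(log₂v − log₂V)² / (2(σ_v + ζ(log₂v − log₂V))²)) − e^(−1/ζ²)]

  with speed-responsive classification (χ² < 0.05 at every spatial
  frequency) and bandwidth change Δσ = (σ₁ − σ₂)/(σ₁ + σ₂);
* **population_metrics** — population sparseness
  S_p = [1 − (Σ|Aᵢ|/N)²/(ΣAᵢ²/N)]·(1 − 1/N)⁻¹, population tuning with
  Wilcoxon signed-rank comparisons, flash-response typing;
* **decoding** — linear x–t stimulus reconstruction from spike counts
  (I(x,i) = a + Σ_c ω_c Σ_j r_c[i−j]·RF_c[x,j]), motion-energy filter
  banks of slanted space-time Gabor quadrature pairs, opponent
  subtraction, winner-takes-all speed read-out, error-rate and
  accuracy-cost summaries;
* **pipeline / CLI** — end-to-end orchestration with seeded
  reproducibility (`rgc run`, `stimgen`).

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

Fit the speed tuning of a simulated cell at one spatial frequency:

```python
import numpy as np
from rgcspeed import stimuli as st, synthetic_retina as sr, tuning as tn

speeds = np.array(st.SPEEDS)                     # 0.25 ... 4.0 mm/s
cell = sr.GroundTruthCell(
    0, (0.5, 0.5), 0.05, 0.05, 0.0, -1, (1, 0.5, 4, 7, 5),
    baseline_rate=0.5, gain=30.0,
    tuning_params=(20.0, 1.0, 1.2, 0.1),         # A, V, sigma_v, zeta
)
conds = [{"kind": "grating", "sf0": 1.8, "speed": float(v)} for v in speeds]
data = sr.simulate_tuned_spike_trains([cell], conds, duration=3.0,
                                      n_trials=10, seed=42)
resp = np.array([
    tn.compute_psth(data.trials_of(0, ("grating", 1.8, float(v))), 3.0).mean_rate
    for v in speeds
])
print("responses:", np.round(resp, 2))
fit = tn.fit_speed_tuning(resp, speeds, sf0=1.8, kind="grating")
print(f"A={fit.A:.2f} Hz  V={fit.V:.3f} mm/s  sigma_v={fit.sigma_v:.3f}  "
      f"zeta={fit.zeta:.3f}  chi2={fit.chi2:.4f}")
```

prints

```
responses: [ 3.29 14.5  19.43 15.29  8.11]
A=19.72 Hz  V=0.955 mm/s  sigma_v=1.292  zeta=0.134  chi2=0.0007
```

The mean PSTH rate peaks near the planted preferred speed of 1 mm/s; from
ten 3-s trials the fit recovers the preferred speed within ~5% and the
log₂-speed bandwidth σ_v within ~8%, and χ² = 0.0007 < 0.05 marks the fit
good enough for speed-responsive classification at this spatial
frequency.

The full synthetic experiment (tuning grid, sparseness, receptive fields,
decoding) runs with:

```
rgc run --seed 1 --outdir my_run
```

which writes per-stage CSV tables, `summary.json` and a plain-text report.

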