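# Methods

`rgcspeed` implements the analysis chain used to ask how the spectral
bandwidth of a moving stimulus shapes speed selectivity in retinal ganglion
cells (RGCs), together with a synthetic retina that provides ground truth
for every estimator. This note records the models, the numerical choices,
and what the synthetic benchmarks do and do not establish.

## Stimuli

Three stimulus classes share one calibration (240 px/mm, 60 Hz, 3-s
sequences, luminance affinely rescaled to [0, 1] so Michelson contrast is
1 for every movie):

* **Drifting gratings** `L(x, t) = 1/2 + 1/2 sin(2π(sf₀ x − sf₀ v t) + φ)`
  over a 6 × 5 grid of spatial frequencies
  sf₀ ∈ {0.66, 0.9, 1.26, 1.8, 2.52, 3.6} cycles/mm and speeds
  v ∈ {0.25, 0.5, 1, 2, 4} mm/s. The temporal frequency is sf₀·v.
* **Motion Clouds** — random-phase dynamic textures. The Fourier amplitude
  envelope is a product of (i) a log-Gaussian in spatial-frequency
  magnitude centred at sf₀, divided by f²; the quadratic factor offsets the
  growth of the number of 2-D Fourier modes with radius so the measured
  amplitude-weighted spectral centroid sits at sf₀ for moderate
  bandwidths; (ii) a Gaussian of width `b_v` (Hz) about the constant-speed
  plane f_t = −v·f_x (default `b_v` = 10% of the central temporal
  frequency, floored at 0.05 Hz); (iii) a Gaussian in orientation about
  the motion axis (15° default). The log-domain width is solved in closed
  form so the envelope's linear-frequency standard deviation equals the
  requested `b_sf`. Narrow-bandwidth `b_sf` values are a packaged constant
  table (0.24, 0.36, 0.54, 0.72, 1.08, 1.5 cycles/mm for the six sf₀ —
  chosen so adjacent spectra do not overlap); broad bandwidth means
  `b_sf = sf₀`. Identical parameters + seed give bit-identical movies.
* **Binary white-noise checkerboards** (0.05-mm blocks, 35 × 35, 1200 s)
  for reverse correlation. Analyses run at block resolution
  (`upsample=False`); the per-block pixel pitch is recorded so spatial
  fits still report millimetres.

Two calibration figures circulate for the projector (≈4 µm/px vs the
240:1 px:mm ratio, i.e. 4.167 µm/px); the package treats 240 px/mm as
canonical and exposes it as a parameter everywhere.

Weber-contrast diagnostics (`contrast_profile`) summarize the per-pixel
distribution `(I − Ī)/Ī`; gratings are extreme-heavy (bimodal), clouds
concentrate near zero, which the excess kurtosis captures.

The dominant temporal frequency of a narrowband movie is measured by the
FFT peak refined with the phase slope of the analytic (Hilbert) signal of
one pixel's time course — necessary because the slowest condition
(0.165 Hz) does not complete a cycle within one 3-s sequence; calibration
checks therefore measure on a 30-s rendering.

## Synthetic retina

Cells are parameterized by an elliptical spatial Gaussian (1-s.d.
semi-axes a ≥ b, equivalent radius √(ab), default 0.05 mm), a biphasic
temporal kernel, ON/OFF polarity as a kernel sign flip (default 20% ON,
reflecting the low ON fraction typical of this preparation), a baseline
rate, and a gain. Two generator modes:

* **LN–Poisson**: per frame bin,
  `rate = baseline + gain · max(k·s, 0)` with `k` the unit-L2-norm
  spatiotemporal kernel and `s` the mean-subtracted stimulus history;
  counts are Poisson per bin, trials independent, spikes jittered
  uniformly within their bin. With `poisson=False` the expected counts per
  bin are returned for noiseless-rate experiments.
* **Tuned Poisson**: the mean rate per condition follows the
  skewed-Gaussian speed-tuning curve (below) evaluated at the condition's
  speed, with a preferred speed drifting as `(sf_ref/sf₀)^0.3` so speed
  preference falls with spatial frequency, and per-class multiplicative
  shrinkage of σ_v to emulate bandwidth narrowing
  (defaults 0.8 narrow / 0.55 broad in the pipeline). By default spiking
  is homogeneous within a condition; an optional sinusoidal modulation at
  the condition's temporal frequency (`modulation_depth`, pipeline default
  0.8) provides the stimulus-locked first harmonic that the zF1 screen
  requires — without it the screen would (correctly) discard every cell of
  a homogeneous-Poisson population.

The generators emulate Poisson variability, receptive-field geometry and
tuning-curve shape; they do not model adaptation, surround suppression,
correlated noise, or any mechanistic circuit. Passing the recovery
benchmarks therefore establishes estimator correctness under the model's
assumptions, not biological fidelity of the underlying retina.

## Receptive-field estimation

The STA is the mean mean-luminance-subtracted stimulus over the 18 frames
(0.3 s) preceding each spike. Because RGC kernels are close to
space-time separable, `denoise_sta` takes the best rank-1 approximation of
the (lags × pixels) matrix and hard-thresholds the spatial singular vector
at 3 robust standard deviations; on 1200-s simulated runs this raises the
correlation with the planted kernel from ≈0.6 (raw) to ≈0.98.

The spatial fit is a rotated 2-D Gaussian at the lag of maximum absolute
amplitude (ties → earliest lag), initialized at the argmax pixel with
moment-based widths from the half-max lobe. The 1-s.d. ellipse gives axes
a ≥ b, eccentricity ε = √(1 − (b/a)²), and the equal-area radius √(ab);
fits with ε > 0.9 or degenerate widths are flagged invalid rather than
raised.

The temporal profile is the time course at the maximal-variance pixel,
baseline-zeroed by the mean of the last 3 lags and normalized so the
dominant lobe is +1. It is fitted to a difference of two low-pass filter
cascades with shared order,

    f(t) = p₁ (t/τ₁)ⁿ e^{−n(t/τ₁ − 1)} − p₂ (t/τ₂)ⁿ e^{−n(t/τ₂ − 1)},

each lobe peaking at t = τ with amplitude p (t, τ in frames; τ > 1).
This canonical parameterization was adopted because it is well-posed and
dimensionally consistent; alternative printed forms of the cascade
exponent are ambiguous. Markers: `peak_time` is the first-lobe extremum
of the fitted continuous curve; `zero_cross` is the first sign change
after the peak, refined by Brent root bracketing (absent for monophasic
fits). Marker distributions between cell groups are compared with the
two-sample Kolmogorov–Smirnov test.

## Speed tuning

PSTHs start 200 ms after stimulus onset (onset-transient discard) with
50-ms bins (unstated upstream; config-exposed). The zF1 modulation score
uses a finer 10-ms grid so temporal frequencies up to 14.4 Hz stay below
Nyquist:

    zF1 = (F1 − mean(FFT)) / SD(FFT)

over the amplitude spectrum from 1/T (DC excluded, hence invariance to
adding a constant rate) to Nyquist, F1 at the stimulus temporal
frequency. Cells whose zF1 does not correlate with mean rate across the
30 grating conditions (Pearson, p > 0.05) are discarded.

Mean response (average PSTH rate) versus speed is fitted per spatial
frequency to the skewed Gaussian in log₂-speed

    R(v) = A [exp(−(log₂v − log₂V)² / (2(σ_v + ζ(log₂v − log₂V))²))
           − exp(−1/ζ²)],

peaking at v = V with value A(1 − e^{−1/ζ²}). Fitting uses bounded
least squares (lmfit): V ∈ [min v/2, 2·max v], σ_v ∈ (0.05, 10],
ζ ∈ [−1, 1], A ∈ (0, 10] on peak-normalized responses, multi-started
from every tested speed and ζ₀ ∈ {−0.2, 0, 0.2}; ties resolve to the
smallest σ_v; the width denominator is floored at 10⁻⁹ and a flag records
whether the floor was active at the optimum. χ² is the sum of squared
residuals on the peak-normalized scale (the simplest statistic consistent
with a 0.05 threshold on normalized responses); a cell is *speed
responsive* (SR) if χ² < 0.05 at every one of the six spatial frequencies
and the modulation screen passed. Bandwidth change between stimulus
classes is Δσ = (σ₁ − σ₂)/(σ₁ + σ₂) ∈ (−1, 1).

## Population metrics

Population sparseness `S_p = [1 − (Σ|Aᵢ|/N)²/(ΣAᵢ²/N)] · (1 − 1/N)⁻¹`
(0 = uniform, 1 = one active cell); it is scale- and permutation-
invariant, computed per trial and averaged over trials. Responses are
internally rescaled by their maximum before squaring to guard floating-
point underflow. Condition-wise class comparisons use the two-sided
Wilcoxon signed-rank test, exact for n < 25 pairs, normal approximation
with continuity correction otherwise; all-zero difference vectors return
p = 1 by convention.

Flash typing (Fast/Slow × Transient/Sustained) is a re-implementation
choice, as the upstream index formulas are not public: latency = time to
peak in a 0–400 ms window after flash onset, transience = 1 − (mean rate
in 400–800 ms)/(peak rate), both split at the population median; windows
are config-exposed and flat responses flagged unclassifiable.

## Reconstruction and decoding

The x–t stimulus is reconstructed linearly from spike counts in
Δt = 1/60 s bins:

    I(x, i) = a + Σ_c ω_c Σ_{j=0}^{N−1} r_c[i−j] · RF_c[x, j]

with ω_c = 1 (no weight fitting — a downstream observer has no access to
the true signal) and a = mean luminance. RF_c is the cell's STA collapsed
onto the motion axis by an unweighted row average restricted to the
fitted ellipse's 2-s.d. vertical extent; the unweighted mean preserves
separability and is invariant to orthogonal shifts.

The decoder is a motion-energy cascade: per candidate speed, a space-time
slanted Gabor quadrature pair (carrier sf(x − v t); spatial envelope
s.d. 1/(2·sf) mm; temporal envelope targeting two periods of the
channel's temporal frequency, capped so slow channels fit inside a 3-s
sequence — the cap is what limits discrimination of 0.25 vs 0.5 mm/s at
low spatial frequency). Kernels are zero-mean and unit-energy; squaring
the quadrature outputs and summing over the valid space-time support
gives a phase-invariant energy per direction; opposite directions are
subtracted (net energy, exactly zero for static patterns); the winner is
the channel with the largest |net|, its sign giving direction, so a
time-reversed input selects the same speed with flipped direction. If
every net energy is below 10⁻⁶ of the total energy the decoder reports
no decision (counted as incorrect). A trial is correct only if the
winning channel equals the condition's nominal speed (five-way choice).
Error rate = 1 − correct/trials; accuracy cost = success rate ×
(total spikes / number of cells).

The closed-loop benchmark (simulate → reconstruct → decode) uses a
balanced ON/OFF population (on_fraction 0.5) so the two half-wave
rectified channels complement each other; with the default low ON
fraction the missing bright-phase information leaves a contrast-inverted
residue in the reconstruction that can masquerade as reversed motion.
It decodes 5/5 speeds errorlessly at sf₀ = 1.26 cycles/mm with 120 cells
in noiseless-rate mode, and degrades monotonically as gain falls.

## Problem sizes and orchestration

The pipeline derives independent per-stage child seeds from one global
seed (`numpy.random.SeedSequence.spawn`), so stages re-run in isolation
reproduce exactly. Default benchmark sizes were chosen to keep each
recovery statistic comfortably inside its tolerance while the whole suite
runs on a laptop: 1200-s checkerboards at block resolution for STA
recovery, 200-trial Poisson runs for tuning recovery, 8–15 simulated
cells for classification rates, 120-cell populations for decoding. The
pipeline's reduced defaults (60 cells, 300-s checkerboard) are smoke-run
scale; all sizes are config fields.

## Known limitations

* The Motion-Cloud envelope is this package's formulation of the cited
  open-source family, not a byte-level port; only its measurable contracts
  (centroid, speed-plane slope, bandwidth limit, determinism) are
  guaranteed.
* STA-based kernels assume quasi-linear encoding; strongly nonlinear
  cells would need subunit models out of scope here.
* The χ² statistic is an SSR on normalized responses; other readings
  (reduced χ², test p-values) would shift the 0.05 threshold's meaning.
* Homogeneous-Poisson tuned spiking has no within-trial dynamics beyond
  the optional first harmonic; temporal-code analyses beyond zF1 are not
  supported.
* Biological headline counts (fractions of SR cells, absolute σ_v
  distributions, spikes-per-cell costs) depend on the recorded
  preparation and are not reproduced by the synthetic conditions; the
  synthetic pipeline demonstrates the machinery, with effect directions
  (bandwidth narrowing, sparseness increase) planted by construction.
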