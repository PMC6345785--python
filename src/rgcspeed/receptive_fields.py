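"""Receptive-field estimation and parameterization from checkerboard responses.

The spatiotemporal receptive field (RF) of a ganglion cell is estimated by
reverse correlation against a binary white-noise checkerboard: the
spike-triggered average (STA) is the mean (mean-luminance-subtracted)
stimulus segment preceding each spike. The STA is then condensed into

* a spatial description -- a 2-D Gaussian fitted at the lag of maximum
  amplitude, summarized by its 1-s.d. ellipse (axes ``a >= b``), the
  equal-area equivalent radius ``sqrt(a*b)`` and the ellipse eccentricity
  ``sqrt(1 - (b/a)^2)``; noisy fits with eccentricity > 0.9 are flagged
  invalid;
* a temporal description -- the time course at the maximal-variance pixel,
  fitted to a difference of two low-pass filter cascades, from which the
  peak time and the zero crossing between the two lobes are extracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .stimuli import StimulusMovie

__all__ = [
    "STA",
    "SpatialRFFit",
    "TemporalRFFit",
    "lowpass_cascade",
    "cascade_difference",
    "compute_sta",
    "denoise_sta",
    "fit_spatial_rf",
    "ellipse_eccentricity",
    "fit_temporal_profile",
    "temporal_markers",
    "compare_marker_distributions",
    "ECCENTRICITY_MAX",
    "DEFAULT_N_LAGS",
]

# Discard threshold for noisy elongated ellipse fits.
ECCENTRICITY_MAX = 0.9
# Default STA depth: 18 frames = 0.3 s at 60 Hz.
DEFAULT_N_LAGS = 18


@dataclass
class STA:
    """Spike-triggered average: ``kernel[j]`` is the mean mean-subtracted
    stimulus ``j`` lags (frames) before a spike."""

    kernel: np.ndarray  # (n_lags, height, width), contrast units
    n_lags: int
    frame_dt: float  # s
    n_spikes: int
    px_per_mm: float


@dataclass
class SpatialRFFit:
    center_x: float  # mm
    center_y: float  # mm
    a: float  # major 1-s.d. semi-axis, mm
    b: float  # minor 1-s.d. semi-axis, mm
    angle: float  # radians
    amplitude: float
    polarity: int  # +1 ON, -1 OFF
    equivalent_radius: float  # mm, sqrt(a*b)
    eccentricity: float
    valid: bool
    best_lag: int = 0


@dataclass
class TemporalRFFit:
    p1: float
    p2: float
    tau1: float  # frames
    tau2: float  # frames
    n: float  # shared cascade order
    zero_cross: float | None  # s
    peak_time: float  # s
    fit_residual: float
    frame_dt: float
    sign: int = 1  # sign applied to normalize the dominant lobe positive
    converged: bool = True


def lowpass_cascade(t, p, tau, n):
    """Impulse response of an ``n``-stage low-pass cascade.

    ``f(t) = p * (t/tau)^n * exp(-n*(t/tau - 1))`` for ``t >= 0``; the curve
    peaks at ``t = tau`` with amplitude ``p``. Time and ``tau`` are in
    frames.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    with np.errstate(over="ignore"):
        out[pos] = p * (t[pos] / tau) ** n * np.exp(-n * (t[pos] / tau - 1.0))
    return out


def cascade_difference(t, p1, p2, tau1, tau2, n):
    """Biphasic temporal RF model: difference of two low-pass cascades with
    a shared order ``n``."""
    return lowpass_cascade(t, p1, tau1, n) - lowpass_cascade(t, p2, tau2, n)


def compute_sta(
    spike_times: np.ndarray,
    checkerboard: StimulusMovie,
    n_lags: int = DEFAULT_N_LAGS,
) -> STA:
    """Reverse-correlation RF estimate from checkerboard responses.

    Parameters
    ----------
    spike_times : array of float
        Spike times in seconds within the movie duration (pooled across
        trials of the same frozen stimulus).
    checkerboard : StimulusMovie
    n_lags : int
        Kernel depth in frames.
    """
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    spike_times = np.asarray(spike_times, dtype=float)
    frames = checkerboard.frames
    n_frames = frames.shape[0]
    frame_idx = np.floor(spike_times * checkerboard.frame_rate).astype(int)
    # Keep spikes with a full stimulus history.
    frame_idx = frame_idx[(frame_idx >= n_lags - 1) & (frame_idx < n_frames)]
    n_spikes = frame_idx.size
    if n_spikes == 0:
        raise ValueError("STA undefined: no usable spikes")

    counts = np.bincount(frame_idx, minlength=n_frames).astype(np.float64)
    flat = frames.reshape(n_frames, -1)
    mean_lum = flat.mean()
    kernel = np.empty((n_lags,) + frames.shape[1:], dtype=np.float64)
    for j in range(n_lags):
        # sum over spikes of frame (i - j) = counts[j:] . frames[:T-j]
        w = counts[j:]
        acc = w @ flat[: n_frames - j]
        kernel[j] = acc.reshape(frames.shape[1:]) / n_spikes - mean_lum
    return STA(
        kernel=kernel,
        n_lags=n_lags,
        frame_dt=1.0 / checkerboard.frame_rate,
        n_spikes=int(n_spikes),
        px_per_mm=checkerboard.px_per_mm,
    )


def denoise_sta(sta: STA, spatial_threshold: bool = True) -> STA:
    """Rank-1 (space x time) denoised copy of an STA.

    Ganglion-cell kernels are close to space-time separable, so the best
    rank-1 approximation of the (lags x pixels) STA matrix retains the
    kernel while shedding most estimation noise. With
    ``spatial_threshold=True`` the spatial singular vector is additionally
    hard-thresholded at 3 robust standard deviations (median absolute
    deviation scaled), zeroing pixels outside the receptive field.
    """
    M = sta.kernel.reshape(sta.n_lags, -1)
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    v = Vt[0].copy()
    if spatial_threshold:
        thr = 3.0 * np.median(np.abs(v)) / 0.6745
        v = np.where(np.abs(v) > thr, v, 0.0)
        if not np.any(v):
            v = Vt[0]
    kernel = (S[0] * np.outer(U[:, 0], v)).reshape(sta.kernel.shape)
    return STA(
        kernel=kernel,
        n_lags=sta.n_lags,
        frame_dt=sta.frame_dt,
        n_spikes=sta.n_spikes,
        px_per_mm=sta.px_per_mm,
    )


def ellipse_eccentricity(a: float, b: float) -> float:
    """Eccentricity ``sqrt(1 - (b/a)^2)`` of an ellipse with semi-axes
    ``a >= b``; arguments are swapped with a warning if given in the wrong
    order."""
    if b <= 0:
        raise ValueError(f"semi-axes must be positive, got b={b}")
    if b > a:
        warnings.warn("semi-axes given minor-first; swapping", RuntimeWarning)
        a, b = b, a
    return float(np.sqrt(1.0 - (b / a) ** 2))


def _gauss2d(coords, amp, x0, y0, sx, sy, theta, offset):
    x, y = coords
    ct, st = np.cos(theta), np.sin(theta)
    xr = (x - x0) * ct + (y - y0) * st
    yr = -(x - x0) * st + (y - y0) * ct
    return amp * np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2)) + offset


def fit_spatial_rf(sta: STA) -> SpatialRFFit:
    """2-D Gaussian fit of the STA frame at the lag of maximum amplitude.

    The 1-s.d. ellipse of the fitted Gaussian gives the RF axes; polarity is
    the sign of the fitted amplitude. Degenerate fits (non-positive widths,
    optimizer failure) and elongated fits with eccentricity > 0.9 are
    returned with ``valid=False`` rather than raised.
    """
    amps = np.max(np.abs(sta.kernel.reshape(sta.n_lags, -1)), axis=1)
    best_lag = int(np.argmax(amps))  # ties resolve to the earliest lag
    frame = sta.kernel[best_lag]
    h, w = frame.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    peak_idx = np.unravel_index(np.argmax(np.abs(frame)), frame.shape)
    amp0 = frame[peak_idx]
    # Moment-based width init from the half-max lobe around the peak.
    lobe = np.abs(frame) >= 0.5 * np.abs(amp0)
    mass = np.abs(frame) * lobe
    total = mass.sum()
    mx = (xx * mass).sum() / total
    my = (yy * mass).sum() / total
    sx0 = max(np.sqrt(((xx - mx) ** 2 * mass).sum() / total), 0.5)
    sy0 = max(np.sqrt(((yy - my) ** 2 * mass).sum() / total), 0.5)

    p0 = [amp0, mx, my, sx0, sy0, 0.0, 0.0]
    lo = [-np.inf, -w, -h, 1e-3, 1e-3, -np.pi / 2, -np.inf]
    hi = [np.inf, 2 * w, 2 * h, 4 * w, 4 * h, np.pi / 2, np.inf]
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d,
            (xx.ravel(), yy.ravel()),
            frame.ravel(),
            p0=p0,
            bounds=(lo, hi),
            maxfev=5000,
        )
        converged = True
    except RuntimeError:
        popt, converged = p0, False

    amp, x0, y0, sx, sy, theta, _ = popt
    mm = 1.0 / sta.px_per_mm
    a_px, b_px = (sx, sy) if sx >= sy else (sy, sx)
    if sy > sx:
        theta += np.pi / 2
    a, b = a_px * mm, b_px * mm
    ok = converged and a > 0 and b > 0
    ecc = ellipse_eccentricity(a, b) if ok else 1.0
    return SpatialRFFit(
        center_x=x0 * mm,
        center_y=y0 * mm,
        a=a,
        b=b,
        angle=float(np.mod(theta + np.pi / 2, np.pi) - np.pi / 2),
        amplitude=float(amp),
        polarity=1 if amp >= 0 else -1,
        equivalent_radius=float(np.sqrt(a * b)) if ok else np.nan,
        eccentricity=float(ecc),
        valid=bool(ok and ecc <= ECCENTRICITY_MAX),
        best_lag=best_lag,
    )


def fit_temporal_profile(sta: STA, baseline_lags: int = 3) -> TemporalRFFit:
    """Fit the difference-of-cascades model to the STA time course.

    The time course is taken at the pixel with the largest variance across
    lags, baseline-zeroed by the mean of the last ``baseline_lags`` lags
    (the pre-stimulus tail) and normalized so the dominant lobe has
    amplitude +1. Non-convergence is flagged with an infinite residual.
    """
    if sta.n_lags < 6:
        raise ValueError("need >= 6 lags for a temporal fit")
    flat = sta.kernel.reshape(sta.n_lags, -1)
    pix = int(np.argmax(flat.var(axis=0)))
    y = flat[:, pix].astype(float)
    y = y - y[-baseline_lags:].mean()
    sign = 1 if y[np.argmax(np.abs(y))] >= 0 else -1
    y = sign * y
    y = y / np.abs(y).max()
    t = np.arange(sta.n_lags, dtype=float)

    def resid(params):
        p1, p2, tau1, tau2, n = params
        return cascade_difference(t, p1, p2, tau1, tau2, n) - y

    best = None
    for tau1_0 in (max(np.argmax(y), 2.0), 4.0):
        for n0 in (4.0, 8.0):
            x0 = [1.0, 0.5, float(tau1_0), float(tau1_0) * 1.8, n0]
            try:
                sol = optimize.least_squares(
                    resid,
                    x0,
                    bounds=(
                        [0.0, 0.0, 1.01, 1.01, 1.0],
                        [10.0, 10.0, 3.0 * sta.n_lags, 3.0 * sta.n_lags, 30.0],
                    ),
                    max_nfev=4000,
                )
            except ValueError:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not best.success:
        return TemporalRFFit(
            p1=np.nan, p2=np.nan, tau1=np.nan, tau2=np.nan, n=np.nan,
            zero_cross=None, peak_time=np.nan, fit_residual=np.inf,
            frame_dt=sta.frame_dt, sign=sign, converged=False,
        )

    p1, p2, tau1, tau2, n = best.x
    fit = TemporalRFFit(
        p1=float(p1), p2=float(p2), tau1=float(tau1), tau2=float(tau2),
        n=float(n), zero_cross=None, peak_time=np.nan,
        fit_residual=float(2.0 * best.cost), frame_dt=sta.frame_dt,
        sign=sign, converged=True,
    )
    zc, pk = temporal_markers(fit)
    fit.zero_cross = zc
    fit.peak_time = pk
    return fit


def temporal_markers(
    fit: TemporalRFFit, t_max_frames: float | None = None
) -> tuple[float | None, float]:
    """Extract (zero_cross, peak_time), in seconds, from a converged fit.

    ``peak_time`` is the extremum of the first lobe of the fitted continuous
    curve; ``zero_cross`` is the first sign change after that peak, refined
    by root bracketing. Monophasic fits (no sign change) report
    ``zero_cross = None``.
    """
    if not fit.converged:
        raise ValueError("markers undefined for a non-converged fit")
    if t_max_frames is None:
        t_max_frames = 3.0 * max(fit.tau1, fit.tau2)

    def f(t):
        return cascade_difference(t, fit.p1, fit.p2, fit.tau1, fit.tau2, fit.n)

    grid = np.linspace(1e-6, t_max_frames, 4000)
    vals = f(grid)
    # First lobe extremum: first local extremum of |f| along the grid.
    dv = np.diff(np.abs(vals))
    turning = np.where((dv[:-1] > 0) & (dv[1:] <= 0))[0]
    if turning.size:
        i = turning[0] + 1
        res = optimize.minimize_scalar(
            lambda t: -np.abs(f(np.array([t]))[0]),
            bounds=(grid[max(i - 2, 0)], grid[min(i + 2, grid.size - 1)]),
            method="bounded",
        )
        peak_frames = float(res.x)
    else:
        peak_frames = float(grid[np.argmax(np.abs(vals))])

    zero_cross = None
    after = grid > peak_frames
    sgn = np.sign(vals[after])
    flips = np.where(sgn[:-1] * sgn[1:] < 0)[0]
    if flips.size:
        ga = grid[after]
        lo_t, hi_t = ga[flips[0]], ga[flips[0] + 1]
        root = optimize.brentq(lambda t: f(np.array([t]))[0], lo_t, hi_t)
        zero_cross = float(root) * fit.frame_dt
    return zero_cross, peak_frames * fit.frame_dt


def compare_marker_distributions(
    markers_a: np.ndarray, markers_b: np.ndarray
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of temporal-marker
    distributions (e.g. zero-cross times of two cell groups). Returns
    ``(statistic, p_value)``."""
    res = stats.ks_2samp(markers_a, markers_b)
    return float(res.statistic), float(res.pvalue)
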