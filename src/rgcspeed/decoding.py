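"""Linear stimulus reconstruction and motion-energy speed decoding.

The decoding chain mirrors a simple downstream motion observer:

1. the moving stimulus is linearly reconstructed as a space-time intensity
   map from population spike counts,

   ``I(x, i) = a + sum_c w_c * sum_j r_c[i - j] * RF_c[x, j]``

   with ``r_c`` the per-cell spike counts in bins of ``dt = 1/60 s`` and
   ``RF_c`` the cell's receptive field collapsed onto the motion axis;
2. the reconstruction is filtered with a bank of space-time slanted Gabor
   quadrature pairs (Reichardt-detector-like correlators), one channel per
   candidate speed and direction; squared quadrature outputs are summed
   into a phase-invariant motion energy per channel;
3. opposite-direction energies are subtracted (opponent motion, nulling
   static patterns) and the speed with the highest net energy wins
   (winner-takes-all).

Decoding quality is summarized as an error rate (1 - fraction of trials
with the correct speed) and an accuracy cost (success rate times the mean
number of spikes per cell -- the spike budget of a successful read-out).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .receptive_fields import STA, SpatialRFFit

__all__ = [
    "XTReconstruction",
    "MotionEnergyBank",
    "SpeedDecision",
    "collapse_rf",
    "bin_spike_counts",
    "reconstruct_xt",
    "build_motion_energy_bank",
    "decode_speed",
    "decoding_metrics",
]


@dataclass
class XTReconstruction:
    """Reconstructed space-time intensity map.

    ``intensity[i, x]`` spans time bins (rows) by motion-axis pixels
    (columns)."""

    intensity: np.ndarray  # (n_bins, n_x)
    offset: float
    bin_dt: float  # s
    px_per_mm: float

    @property
    def x_mm(self) -> np.ndarray:
        return np.arange(self.intensity.shape[1]) / self.px_per_mm


@dataclass
class MotionEnergyBank:
    """Quadrature Gabor pairs per candidate speed, both directions.

    ``kernels[speed]`` holds ``(even, odd)`` space-time arrays of shape
    ``(n_t, n_x)`` for the preferred (+x) direction; the opposite direction
    is the x-mirrored kernel. Kernels are zero-mean with unit energy."""

    speeds: tuple
    sf: float  # cycles/mm
    bin_dt: float
    px_per_mm: float
    kernels: dict = field(repr=False, default_factory=dict)


@dataclass
class SpeedDecision:
    net_energy: dict  # speed -> net opponent energy (preferred - opposite)
    chosen_speed: float | None  # None = no decision
    direction: int = 0  # +1 toward +x, -1 toward -x, 0 = no decision
    energies: dict = field(default_factory=dict)  # speed -> (E+, E-)


def collapse_rf(
    sta: STA, spatial_fit: SpatialRFFit | None = None, n_sd: float = 2.0
) -> np.ndarray:
    """Collapse a 3-D STA onto (time, motion axis).

    Rows (the axis orthogonal to motion) are averaged, restricted to those
    intersecting the fitted RF's ``n_sd``-s.d. vertical extent when a
    spatial fit is supplied; the unweighted mean preserves separable
    structure and is invariant to shifts of the RF along the orthogonal
    axis. Returns an ``(n_lags, width)`` array."""
    kernel = sta.kernel
    if spatial_fit is not None:
        cy_px = spatial_fit.center_y * sta.px_per_mm
        half = n_sd * max(spatial_fit.a, spatial_fit.b) * sta.px_per_mm
        lo = max(int(np.floor(cy_px - half)), 0)
        hi = min(int(np.ceil(cy_px + half)) + 1, kernel.shape[1])
        if hi <= lo:
            lo, hi = 0, kernel.shape[1]
        kernel = kernel[:, lo:hi, :]
    return kernel.mean(axis=1)


def bin_spike_counts(
    spike_times: np.ndarray, duration: float, bin_dt: float = 1.0 / 60.0
) -> np.ndarray:
    """Spike counts in consecutive bins of width ``bin_dt`` over
    ``[0, duration)``."""
    n_bins = int(round(duration / bin_dt))
    edges = np.arange(n_bins + 1) * bin_dt
    return np.histogram(np.asarray(spike_times, dtype=float), bins=edges)[0].astype(float)


def reconstruct_xt(
    counts_by_cell: dict,
    kernels_by_cell: dict,
    weights: dict | float = 1.0,
    offset: float = 0.5,
    bin_dt: float = 1.0 / 60.0,
    px_per_mm: float = 240.0,
) -> XTReconstruction:
    """Linear space-time reconstruction from binned spike counts.

    ``counts_by_cell[c]`` is the spike-count vector of cell ``c`` (length =
    number of time bins, all cells equal); ``kernels_by_cell[c]`` the
    collapsed ``(n_lags, n_x)`` receptive field (lag 0 nearest the spike).
    Weights default to 1 for every cell and the offset to the stimulus mean
    luminance; the result is exactly linear in the counts.
    """
    if not counts_by_cell:
        raise ValueError("no cells to reconstruct from")
    missing = set(counts_by_cell) - set(kernels_by_cell)
    if missing:
        raise KeyError(f"cells without a kernel: {sorted(missing)!r}")
    if bin_dt <= 0:
        raise ValueError("bin_dt must be positive")

    first = next(iter(counts_by_cell))
    n_bins = len(counts_by_cell[first])
    n_x = kernels_by_cell[first].shape[1]
    acc = np.zeros((n_bins, n_x))
    for c, r in counts_by_cell.items():
        rf = kernels_by_cell[c]
        if rf.shape[1] != n_x:
            raise ValueError("kernels must share a common spatial grid")
        w = weights if np.isscalar(weights) else weights[c]
        # I[i, x] += w * sum_j r[i-j] rf[j, x]  (causal convolution)
        conv = signal.fftconvolve(
            np.asarray(r, dtype=float)[:, None], rf, axes=0
        )[:n_bins]
        acc += w * conv
    return XTReconstruction(
        intensity=offset + acc,
        offset=offset,
        bin_dt=bin_dt,
        px_per_mm=px_per_mm,
    )


def _gabor_pair(
    speed: float,
    sf: float,
    bin_dt: float,
    px_per_mm: float,
    sigma_x_mm: float,
    sigma_t_s: float,
    n_sigma: float = 2.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Space-time slanted Gabor quadrature pair preferring drift at
    ``speed`` mm/s toward +x. Shape (n_t, n_x); zero-mean, unit energy."""
    half_x = max(int(np.ceil(n_sigma * sigma_x_mm * px_per_mm)), 2)
    half_t = max(int(np.ceil(n_sigma * sigma_t_s / bin_dt)), 2)
    x = np.arange(-half_x, half_x + 1) / px_per_mm  # mm
    t = np.arange(-half_t, half_t + 1) * bin_dt  # s
    X = x[None, :]
    T = t[:, None]
    envelope = np.exp(
        -0.5 * ((X / sigma_x_mm) ** 2 + (T / sigma_t_s) ** 2)
    )
    arg = 2.0 * np.pi * sf * (X - speed * T)
    even = envelope * np.cos(arg)
    odd = envelope * np.sin(arg)
    even -= even.mean()
    odd -= odd.mean()
    even /= np.linalg.norm(even)
    odd /= np.linalg.norm(odd)
    return even, odd


def build_motion_energy_bank(
    speeds,
    sf: float,
    bin_dt: float = 1.0 / 60.0,
    px_per_mm: float = 240.0,
    sigma_x_mm: float | None = None,
    max_t_extent_s: float = 2.9,
    grid_shape: tuple | None = None,
) -> MotionEnergyBank:
    """Motion-energy filter bank over candidate speeds at one spatial
    frequency.

    Spatial envelope s.d. defaults to ``1/(2*sf)`` mm (one half-cycle);
    the temporal envelope targets two periods of the channel's preferred
    temporal frequency ``sf * speed`` but is capped so slow channels stay
    shorter than ``max_t_extent_s``. If ``grid_shape`` (n_t, n_x) is given,
    kernels exceeding the grid raise a size error.
    """
    speeds = tuple(float(s) for s in speeds)
    if len(set(speeds)) != len(speeds) or any(s <= 0 for s in speeds):
        raise ValueError("candidate speeds must be positive and distinct")
    if sigma_x_mm is None:
        sigma_x_mm = 1.0 / (2.0 * sf)
    kernels = {}
    for v in speeds:
        tf = sf * v  # Hz
        sigma_t = min(2.0 / tf / 2.5, max_t_extent_s / 5.0) if tf > 0 else max_t_extent_s / 5.0
        even, odd = _gabor_pair(v, sf, bin_dt, px_per_mm, sigma_x_mm, sigma_t)
        if grid_shape is not None and (
            even.shape[0] > grid_shape[0] or even.shape[1] > grid_shape[1]
        ):
            raise ValueError(
                f"kernel for speed {v} mm/s ({even.shape}) exceeds the "
                f"reconstruction grid {grid_shape}"
            )
        kernels[v] = (even, odd)
    return MotionEnergyBank(
        speeds=speeds, sf=sf, bin_dt=bin_dt, px_per_mm=px_per_mm,
        kernels=kernels,
    )


def decode_speed(
    xt: XTReconstruction | np.ndarray,
    bank: MotionEnergyBank,
    no_decision_tol: float = 1e-6,
) -> SpeedDecision:
    """Winner-takes-all speed read-out of an x-t map.

    Per candidate speed, motion energy in each direction is the space-time
    sum of squared quadrature outputs ('valid' correlation support); the net
    signal is preferred-direction minus opponent-direction energy. The
    winning channel is the net-energy argmax; if every net energy is
    negligible relative to the total energy (as for a static pattern, where
    opponent energies cancel) no decision is made.
    """
    I = xt.intensity if isinstance(xt, XTReconstruction) else np.asarray(xt, float)
    I = I - I.mean()
    net = {}
    energies = {}
    total = 0.0
    for v, (even, odd) in bank.kernels.items():
        if even.shape[0] > I.shape[0] or even.shape[1] > I.shape[1]:
            raise ValueError("bank kernel larger than the x-t map")
        e_pos = 0.0
        e_neg = 0.0
        for kern_even, kern_odd, sign in (
            (even, odd, +1),
            (even[:, ::-1], odd[:, ::-1], -1),
        ):
            re = signal.fftconvolve(I, kern_even[::-1, ::-1], mode="valid")
            ro = signal.fftconvolve(I, kern_odd[::-1, ::-1], mode="valid")
            energy = float(np.sum(re**2) + np.sum(ro**2))
            if sign > 0:
                e_pos = energy
            else:
                e_neg = energy
        net[v] = e_pos - e_neg
        energies[v] = (e_pos, e_neg)
        total += e_pos + e_neg
    if total == 0 or max(abs(n) for n in net.values()) < no_decision_tol * total:
        return SpeedDecision(net_energy=net, chosen_speed=None, energies=energies)
    # Winner by net-energy magnitude; the sign carries the direction, so a
    # time-reversed input keeps the same speed channel with flipped direction.
    chosen = max(net, key=lambda v: abs(net[v]))
    return SpeedDecision(
        net_energy=net,
        chosen_speed=chosen,
        direction=1 if net[chosen] >= 0 else -1,
        energies=energies,
    )


def decoding_metrics(
    decisions: list,
    total_spikes: int,
    n_cells: int,
) -> dict:
    """Error rate and accuracy cost of a set of per-trial decisions.

    ``decisions`` is a list of ``(true_speed, chosen_speed)`` pairs (chosen
    may be None = no decision, counted incorrect). Accuracy cost =
    success_rate * total_spikes / n_cells (spikes per cell spent per unit
    of successful transmission)."""
    if not decisions:
        raise ValueError("no decisions to summarize")
    n_correct = sum(1 for truth, chosen in decisions if chosen == truth)
    n = len(decisions)
    success = n_correct / n
    return {
        "n_trials": n,
        "n_correct": n_correct,
        "error_rate": 1.0 - success,
        "success_rate": success,
        "accuracy_cost": success * total_spikes / n_cells,
    }
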