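"""Population-level summaries: sparseness, population tuning, flash typing.

Population sparseness quantifies how concentrated the response to a
stimulus is on few cells:

``S_p = [1 - (sum|A_i|/N)^2 / (sum A_i^2 / N)] * (1 - 1/N)^(-1)``

where ``A_i`` is the average response of cell ``i``. ``S_p`` is 0 for a
perfectly uniform population response and 1 when a single cell carries the
entire response; it is invariant to rescaling and to permutation of cells.

Class-wise comparisons between stimulus conditions use the two-sided
Wilcoxon signed-rank test on paired per-cell (or per-trial) values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "population_sparseness",
    "wilcoxon_signed_rank",
    "population_tuning",
    "flash_response_classification",
    "FlashClassification",
]


def population_sparseness(responses: np.ndarray) -> float:
    """Population sparseness of a vector of per-cell responses (Hz).

    Uses absolute responses; requires at least two cells and a non-zero
    vector (both make the measure undefined otherwise).
    """
    a = np.abs(np.asarray(responses, dtype=float))
    n = a.size
    if n < 2:
        raise ValueError("population sparseness requires N >= 2 cells")
    if not np.any(a > 0):
        raise ValueError("population sparseness undefined for all-zero responses")
    a = a / a.max()  # scale-invariant; guards underflow of squared terms
    num = (a.sum() / n) ** 2
    den = (a**2).sum() / n
    return float((1.0 - num / den) / (1.0 - 1.0 / n))


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Exact null distribution for n < 25 pairs, normal approximation with
    continuity correction otherwise. All-zero differences cannot reject:
    returns ``(0.0, 1.0)`` by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    d = x - y
    if np.all(d == 0):
        return 0.0, 1.0
    method = "exact" if x.size < 25 else "approx"
    res = stats.wilcoxon(x, y, correction=(method == "approx"), method=method)
    return float(res.statistic), float(res.pvalue)


def population_tuning(
    responses: pd.DataFrame,
    sr_cells: list,
    baseline_kind: str = "grating",
) -> pd.DataFrame:
    """Condition-wise population response of the speed-responsive cells.

    Parameters
    ----------
    responses : DataFrame
        Columns ``cell_id, kind, sf0, speed, response`` with the mean PSTH
        rate (Hz) of each cell per condition.
    sr_cells : list
        Cell ids classified speed-responsive; must be non-empty.
    baseline_kind : str
        Stimulus class against which the others are compared (paired
        Wilcoxon over the same cells at matched ``(sf0, speed)``).

    Returns
    -------
    DataFrame with one row per condition: ``kind, sf0, speed, mean, sd, n,
    wilcoxon_T, wilcoxon_p`` (test columns are NaN for the baseline class).
    """
    if len(sr_cells) == 0:
        raise ValueError("speed-responsive cell set is empty")
    df = responses[responses.cell_id.isin(sr_cells)].copy()
    if df.empty:
        raise ValueError("no responses for the requested cells")

    rows = []
    for (kind, sf0, speed), grp in df.groupby(["kind", "sf0", "speed"]):
        grp = grp.sort_values("cell_id")
        entry = {
            "kind": kind,
            "sf0": sf0,
            "speed": speed,
            "mean": grp.response.mean(),
            "sd": grp.response.std(ddof=1) if len(grp) > 1 else 0.0,
            "n": len(grp),
            "wilcoxon_T": np.nan,
            "wilcoxon_p": np.nan,
        }
        if kind != baseline_kind:
            base = df[
                (df.kind == baseline_kind)
                & (df.sf0 == sf0)
                & (df.speed == speed)
            ].sort_values("cell_id")
            if len(base) != len(grp) or not np.array_equal(
                base.cell_id.values, grp.cell_id.values
            ):
                raise ValueError(
                    f"unmatched cell sets for {(kind, sf0, speed)} vs "
                    f"{baseline_kind}"
                )
            if len(base):
                T, p = wilcoxon_signed_rank(
                    grp.response.values, base.response.values
                )
                entry["wilcoxon_T"], entry["wilcoxon_p"] = T, p
        rows.append(entry)
    return pd.DataFrame(rows)


@dataclass
class FlashClassification:
    cell_id: object
    latency: float | None  # s, time to peak after flash onset
    transience: float | None  # 1 - late rate / peak rate
    speed_label: str | None  # Fast / Slow
    duration_label: str | None  # Transient / Sustained
    classifiable: bool = True


def flash_response_classification(
    flash_psths: dict,
    onset: float = 0.0,
    peak_window: tuple = (0.0, 0.4),
    late_window: tuple = (0.4, 0.8),
) -> list[FlashClassification]:
    """Fast/Slow x Transient/Sustained labels from full-field flash PSTHs.

    Latency is the time to peak rate after flash onset within
    ``peak_window``; the transience index is ``1 - (mean rate in
    late_window) / (peak rate)``. Labels split each index at the population
    median (ties at the median fall in the Fast / Transient half). Flat
    responses are flagged unclassifiable and excluded from the medians.

    ``flash_psths`` maps cell id to a :class:`rgcspeed.tuning.PSTH`.
    """
    raw = []
    for cid, psth in flash_psths.items():
        centers = psth.bin_centers - onset
        rates = psth.rates
        in_peak = (centers >= peak_window[0]) & (centers < peak_window[1])
        in_late = (centers >= late_window[0]) & (centers < late_window[1])
        if not np.any(in_peak) or rates[in_peak].max() <= 0:
            raw.append((cid, None, None))
            continue
        peak_rate = rates[in_peak].max()
        latency = float(centers[in_peak][np.argmax(rates[in_peak])])
        late = rates[in_late].mean() if np.any(in_late) else 0.0
        transience = float(1.0 - late / peak_rate)
        raw.append((cid, latency, transience))

    lat_vals = [l for _, l, _ in raw if l is not None]
    tra_vals = [t for _, _, t in raw if t is not None]
    lat_med = float(np.median(lat_vals)) if lat_vals else np.nan
    tra_med = float(np.median(tra_vals)) if tra_vals else np.nan

    out = []
    for cid, lat, tra in raw:
        if lat is None:
            out.append(
                FlashClassification(cid, None, None, None, None, False)
            )
            continue
        out.append(
            FlashClassification(
                cell_id=cid,
                latency=lat,
                transience=tra,
                speed_label="Fast" if lat <= lat_med else "Slow",
                duration_label="Transient" if tra >= tra_med else "Sustained",
            )
        )
    return out
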