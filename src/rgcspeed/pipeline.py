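"""End-to-end orchestration of the synthetic speed-selectivity experiment.

``run_analysis`` composes the full chain on simulated data: stimulus grid
-> synthetic-retina spike trains -> receptive-field estimation -> zF1
modulation screen -> speed-tuning fits and SR classification -> tuning
bandwidth comparisons -> population sparseness grid -> linear
reconstruction and motion-energy speed decoding. Every stage writes a
delimited table; a machine-readable JSON summary and a human-readable
report are produced at the end. A single global seed fans out into
independent per-stage child seeds so stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decoding as dec
from . import population_metrics as pm
from . import receptive_fields as rf
from . import stimuli as stim
from . import synthetic_retina as retina
from . import tuning

__all__ = ["RunConfig", "run_analysis", "write_report"]


@dataclass
class RunConfig:
    """Serializable configuration of one synthetic experiment run."""

    # Population
    n_cells: int = 60
    on_fraction: float = 0.2
    rf_radius_mean: float = 0.05  # mm
    field_size: float = 1.0  # mm

    # Stimulus grid
    spatial_frequencies: tuple = stim.SPATIAL_FREQUENCIES
    speeds: tuple = stim.SPEEDS
    kinds: tuple = ("grating", "mc_narrow", "mc_broad")
    duration: float = 3.0  # s
    n_trials: int = 10
    frame_rate: float = 60.0

    # Generator conditions emulating bandwidth narrowing
    sigma_scale_narrow: float = 0.8
    sigma_scale_broad: float = 0.55
    modulation_depth: float = 0.8

    # Analysis thresholds
    chi2_max: float = tuning.DEFAULT_CHI2_MAX
    eccentricity_max: float = rf.ECCENTRICITY_MAX
    onset_discard: float = tuning.DEFAULT_ONSET_DISCARD
    psth_bin: float = tuning.DEFAULT_BIN_WIDTH
    zf1_bin: float = 0.01  # finer bins so high temporal frequencies resolve
    n_lags: int = rf.DEFAULT_N_LAGS

    # Receptive-field stage (reverse correlation)
    sta_cells: int = 8
    checkerboard_duration: float = 300.0  # s

    # Decoding stage: a balanced ON/OFF population so the complementary
    # rectified halves reconstruct both stimulus phases.
    decode_sf0: float = 1.26  # cycles/mm
    decode_trials: int = 5
    decode_cells: int = 150
    decode_on_fraction: float = 0.5
    decode_gain: float = 150.0
    decode_px_per_mm: float = 30.0
    decode_size_px: int = 120

    seed: int = 0
    outdir: str = "rgc_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        for k in ("spatial_frequencies", "speeds", "kinds"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def config_hash(self) -> str:
        # outdir is a bookkeeping detail, not part of the experiment identity
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _tuning_stage(cfg: RunConfig, spikes, conditions):
    """PSTHs, zF1 screen, tuning fits, SR classification."""
    resp_rows, fit_rows = [], []
    screen = {}
    grating_conds = [c for c in conditions if c["kind"] == "grating"]
    for cid in spikes.cells:
        zf1s, rates = [], []
        for c in grating_conds:
            cond = (c["kind"], c["sf0"], c["speed"])
            trials = spikes.trials_of(cid, cond)
            fine = tuning.compute_psth(
                trials, cfg.duration, bin_width=cfg.zf1_bin,
                onset_discard=cfg.onset_discard,
            )
            tf = c["sf0"] * c["speed"]
            try:
                score = tuning.zf1_score(fine, tf)
                zf1s.append(score.zf1)
                rates.append(fine.mean_rate)
            except ValueError:
                pass
        if len(zf1s) >= 3:
            screen[cid] = tuning.screen_modulated(np.array(zf1s), np.array(rates))
        else:
            screen[cid] = tuning.ScreenResult(False, np.nan, np.nan, "too few conditions")

    for cid in spikes.cells:
        for c in conditions:
            cond = (c["kind"], c["sf0"], c["speed"])
            psth = tuning.compute_psth(
                spikes.trials_of(cid, cond), cfg.duration,
                bin_width=cfg.psth_bin, onset_discard=cfg.onset_discard,
            )
            resp_rows.append(
                {"cell_id": cid, "kind": c["kind"], "sf0": c["sf0"],
                 "speed": c["speed"], "response": psth.mean_rate}
            )
    responses = pd.DataFrame(resp_rows)

    sr_flags = {}
    for cid in spikes.cells:
        fits_by_sf = {}
        for kind in cfg.kinds:
            for sf0 in cfg.spatial_frequencies:
                sel = responses[
                    (responses.cell_id == cid)
                    & (responses.kind == kind)
                    & (responses.sf0 == sf0)
                ].sort_values("speed")
                if sel.empty or sel.response.max() <= 0:
                    continue
                try:
                    fit = tuning.fit_speed_tuning(
                        sel.response.values, sel.speed.values, sf0=sf0, kind=kind
                    )
                except (ValueError, RuntimeError):
                    continue
                fit_rows.append(
                    {"cell_id": cid, "kind": kind, "sf0": sf0, "A": fit.A,
                     "V": fit.V, "sigma_v": fit.sigma_v, "zeta": fit.zeta,
                     "chi2": fit.chi2}
                )
                if kind == "grating":
                    fits_by_sf[sf0] = fit
        try:
            sr_flags[cid] = tuning.classify_speed_responsive(
                fits_by_sf, screened=screen[cid].keep,
                chi2_max=cfg.chi2_max,
                expected_sf=tuple(cfg.spatial_frequencies),
            )
        except ValueError:
            sr_flags[cid] = False
    fits = pd.DataFrame(fit_rows)
    fits["sr"] = fits.cell_id.map(sr_flags)
    return responses, fits, screen, sr_flags


def _bandwidth_stage(cfg: RunConfig, fits: pd.DataFrame, sr_flags: dict):
    """Per-cell bandwidth change (grating vs clouds) at the preferred sf."""
    rows = []
    sr_cells = [c for c, ok in sr_flags.items() if ok]
    for cid in sr_cells:
        cell = fits[fits.cell_id == cid]
        grat = cell[cell.kind == "grating"]
        if grat.empty:
            continue
        pref = grat.loc[grat.A.idxmax()]
        for kind in cfg.kinds:
            if kind == "grating":
                continue
            other = cell[(cell.kind == kind) & (cell.sf0 == pref.sf0)]
            if other.empty:
                continue
            rows.append(
                {"cell_id": cid, "sf0": pref.sf0, "kind": kind,
                 "sigma_grating": pref.sigma_v,
                 "sigma_other": other.sigma_v.iloc[0],
                 "delta_sigma": tuning.delta_sigma(
                     pref.sigma_v, other.sigma_v.iloc[0])}
            )
    table = pd.DataFrame(rows)
    tests = {}
    if not table.empty:
        for kind, grp in table.groupby("kind"):
            if len(grp) >= 5:
                T, p = pm.wilcoxon_signed_rank(
                    grp.sigma_grating.values, grp.sigma_other.values
                )
                tests[kind] = {"T": T, "p": p, "n": len(grp),
                               "median_delta": float(grp.delta_sigma.median())}
    return table, tests


def _sparseness_stage(cfg: RunConfig, spikes, conditions, sr_flags: dict):
    """Per-trial population sparseness, averaged over trials."""
    sr_cells = [c for c, ok in sr_flags.items() if ok] or list(spikes.cells)
    rows = []
    for c in conditions:
        cond = (c["kind"], c["sf0"], c["speed"])
        per_trial = []
        for t in range(spikes.n_trials):
            a = np.array([
                len(spikes.get(cid, cond, t)) / cfg.duration
                for cid in sr_cells
            ])
            if np.any(a > 0):
                per_trial.append(pm.population_sparseness(a))
        if per_trial:
            rows.append(
                {"kind": c["kind"], "sf0": c["sf0"], "speed": c["speed"],
                 "sparseness_mean": float(np.mean(per_trial)),
                 "sparseness_sd": float(np.std(per_trial, ddof=1))
                 if len(per_trial) > 1 else 0.0,
                 "n_trials": len(per_trial)}
            )
    return pd.DataFrame(rows)


def _rf_stage(cfg: RunConfig, population, seed: int):
    """Checkerboard reverse correlation on a subset of cells."""
    checker = stim.make_checkerboard(
        duration=cfg.checkerboard_duration, frame_rate=cfg.frame_rate,
        seed=seed, upsample=False,
    )
    subset = population[: cfg.sta_cells]
    # Re-centre RFs inside the checkerboard patch so the coarse grid sees them.
    patch_mm = checker.frames.shape[1] / checker.px_per_mm
    rng = np.random.default_rng(seed + 1)
    for cell in subset:
        cell.center_xy = tuple(rng.uniform(0.25, 0.75, 2) * patch_mm)
    data = retina.simulate_ln_responses(
        subset, checker, n_trials=1, n_lags=cfg.n_lags, seed=seed + 2,
    )
    rows = []
    stas = {}
    for cell in subset:
        st = data.get(cell.cell_id, data.conditions[0], 0)
        if st.size < 10:
            continue
        sta = rf.compute_sta(st, checker, n_lags=cfg.n_lags)
        spat = rf.fit_spatial_rf(sta)
        temp = rf.fit_temporal_profile(sta)
        stas[cell.cell_id] = sta
        rows.append(
            {"cell_id": cell.cell_id, "n_spikes": sta.n_spikes,
             "center_x": spat.center_x, "center_y": spat.center_y,
             "a": spat.a, "b": spat.b,
             "equivalent_radius": spat.equivalent_radius,
             "eccentricity": spat.eccentricity,
             "polarity": spat.polarity, "valid": spat.valid,
             "tau1": temp.tau1, "tau2": temp.tau2, "n": temp.n,
             "peak_time": temp.peak_time, "zero_cross": temp.zero_cross,
             "fit_residual": temp.fit_residual}
        )
    return pd.DataFrame(rows), stas, checker


def _decode_stage(cfg: RunConfig, seed: int):
    """Closed-loop decode: LN population on gratings, reconstruct, decode."""
    px_per_mm = cfg.decode_px_per_mm
    size_px = cfg.decode_size_px
    field_mm = size_px / px_per_mm
    pop = retina.make_ground_truth_population(
        n_cells=cfg.decode_cells, on_fraction=cfg.decode_on_fraction,
        rf_radius_mean=cfg.rf_radius_mean, field_size=field_mm,
        baseline_rate=0.0, gain=cfg.decode_gain, seed=seed,
    )
    kernels = {
        c.cell_id: dec.collapse_rf(
            rf.STA(
                kernel=retina.cell_kernel(c, (size_px, size_px), px_per_mm,
                                          cfg.n_lags),
                n_lags=cfg.n_lags, frame_dt=1.0 / cfg.frame_rate,
                n_spikes=1, px_per_mm=px_per_mm,
            )
        )
        for c in pop
    }
    bank = dec.build_motion_energy_bank(
        cfg.speeds, cfg.decode_sf0, bin_dt=1.0 / cfg.frame_rate,
        px_per_mm=px_per_mm,
    )
    decisions = []
    total_spikes = 0
    rows = []
    for i, v in enumerate(cfg.speeds):
        movie = stim.make_drifting_grating(
            cfg.decode_sf0, v, duration=cfg.duration,
            frame_rate=cfg.frame_rate, size_px=size_px, px_per_mm=px_per_mm,
        )
        data = retina.simulate_ln_responses(
            pop, movie, n_trials=cfg.decode_trials, n_lags=cfg.n_lags,
            seed=seed + 10 + i,
        )
        cond = data.conditions[0]
        for t in range(cfg.decode_trials):
            counts = {
                c.cell_id: dec.bin_spike_counts(
                    data.get(c.cell_id, cond, t), cfg.duration,
                    1.0 / cfg.frame_rate)
                for c in pop
            }
            total_spikes += int(sum(cnt.sum() for cnt in counts.values()))
            recon = dec.reconstruct_xt(
                counts, kernels, offset=movie.mean_luminance,
                bin_dt=1.0 / cfg.frame_rate, px_per_mm=px_per_mm,
            )
            decision = dec.decode_speed(recon, bank)
            decisions.append((v, decision.chosen_speed))
            rows.append({"true_speed": v, "trial": t,
                         "chosen_speed": decision.chosen_speed,
                         "correct": decision.chosen_speed == v})
    metrics = dec.decoding_metrics(decisions, total_spikes, len(pop))
    return pd.DataFrame(rows), metrics


def run_analysis(config: RunConfig) -> dict:
    """Run the full synthetic experiment; returns the summary dict and
    writes all stage tables plus ``summary.json`` and ``report.txt`` under
    ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 6)

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)

    conditions = stim.condition_grid(
        kinds=config.kinds,
        spatial_frequencies=config.spatial_frequencies,
        speeds=config.speeds,
    )
    pop = retina.make_ground_truth_population(
        n_cells=config.n_cells, on_fraction=config.on_fraction,
        rf_radius_mean=config.rf_radius_mean, field_size=config.field_size,
        seed=seeds[0],
    )
    retina.assign_tuning_params(pop, seed=seeds[1])
    spikes = retina.simulate_tuned_spike_trains(
        pop, conditions, duration=config.duration, n_trials=config.n_trials,
        seed=seeds[2],
        sigma_scale_by_kind={"mc_narrow": config.sigma_scale_narrow,
                             "mc_broad": config.sigma_scale_broad},
        modulation_depth=config.modulation_depth,
    )

    responses, fits, screen, sr_flags = _tuning_stage(config, spikes, conditions)
    bandwidth, bw_tests = _bandwidth_stage(config, fits, sr_flags)
    sparseness = _sparseness_stage(config, spikes, conditions, sr_flags)
    rf_table, _, _ = _rf_stage(config, pop, seeds[3])
    decode_table, decode_metrics = _decode_stage(config, seeds[4])

    responses.to_csv(out / "responses.csv", index=False)
    fits.to_csv(out / "tuning_fits.csv", index=False)
    bandwidth.to_csv(out / "bandwidth_changes.csv", index=False)
    sparseness.to_csv(out / "sparseness_grid.csv", index=False)
    rf_table.to_csv(out / "receptive_fields.csv", index=False)
    decode_table.to_csv(out / "decoding_trials.csv", index=False)

    n_sr = int(sum(sr_flags.values()))
    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_cells": config.n_cells,
        "n_screened": int(sum(1 for s in screen.values() if s.keep)),
        "n_speed_responsive": n_sr,
        "bandwidth_tests": bw_tests,
        "median_delta_sigma": (
            float(bandwidth.delta_sigma.median()) if not bandwidth.empty else None
        ),
        "sparseness_by_kind": {
            k: float(g.sparseness_mean.mean())
            for k, g in sparseness.groupby("kind")
        } if not sparseness.empty else {},
        "rf_valid_fraction": (
            float(rf_table.valid.mean()) if not rf_table.empty else None
        ),
        "decoding": decode_metrics,
        "thresholds": {
            "chi2_max": config.chi2_max,
            "eccentricity_max": config.eccentricity_max,
            "onset_discard": config.onset_discard,
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    write_report(summary, fits, sparseness, out / "report.txt")
    return summary


def write_report(summary, fits, sparseness, path) -> str:
    """Human-readable run report; every number is recomputable from the
    emitted stage tables."""
    lines = [
        f"rgcspeed run report (config {summary['config_hash']}, "
        f"seed {summary['seed']})",
        "=" * 60,
        f"cells simulated:            {summary['n_cells']}",
        f"passed modulation screen:   {summary['n_screened']}",
        f"speed-responsive (SR):      {summary['n_speed_responsive']}",
    ]
    if summary["n_speed_responsive"] == 0:
        lines.append("NOTE: no speed-responsive cells in this run; "
                     "tuning-grid tables are empty.")
    if summary.get("median_delta_sigma") is not None:
        lines.append(
            f"median delta-sigma (grating vs clouds): "
            f"{summary['median_delta_sigma']:.3f}"
        )
    for kind, t in summary.get("bandwidth_tests", {}).items():
        lines.append(
            f"  sigma_v grating vs {kind}: T={t['T']:.0f}, p={t['p']:.4g} "
            f"(n={t['n']})"
        )
    if summary.get("sparseness_by_kind"):
        lines.append("mean population sparseness by stimulus class:")
        for k, v in summary["sparseness_by_kind"].items():
            lines.append(f"  {k:10s} {v:.3f}")
    if not fits.empty:
        grid = fits[fits.sr].groupby(["kind", "sf0"]).sigma_v.median()
        if not grid.empty:
            lines.append("median sigma_v of SR cells per (class, sf0):")
            for (kind, sf0), v in grid.items():
                lines.append(f"  {kind:10s} sf0={sf0:<5g} {v:.3f}")
    d = summary["decoding"]
    lines.append(
        f"decoding: error rate {d['error_rate']:.3f} over {d['n_trials']} "
        f"trials; accuracy cost {d['accuracy_cost']:.2f} spikes/cell"
    )
    text = "\n".join(lines) + "\n"
    with open(path, "w") as fh:
        fh.write(text)
    return text
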