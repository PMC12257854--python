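"""Measurement and analysis orchestration.

``measure_frames`` runs segmentation -> correction -> reconstruction on one
eye/time frame series; ``measure_dataset`` walks a generated dataset on
disk; ``analyze_region_table`` produces the group summaries, exponential
fits, asymmetry metrics and the repeated-measures ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as sio
from .anova import RepeatedMeasuresAnova
from .errors import SclsettleError
from .kinetics import ExponentialSettling, meridional_asymmetry, reduction_metrics
from .reconstruction import (
    DEFAULT_N_FLUID,
    PolarGrid,
    assemble_polar_map,
    boundaries_to_profile,
)
from .regions import DEFAULT_SCHEME, summarize_regions
from .segmentation import DEFAULT_PARAMS, segment_frame

log = logging.getLogger("sclsettle")


def measure_frames(frames, n_fluid=DEFAULT_N_FLUID, params=DEFAULT_PARAMS,
                   grid=None, scheme=DEFAULT_SCHEME, min_coverage=0.5):
    """Full measurement of one eye/time series of frames.

    Returns ``(region_summary_df, polar_map)``.  Individual frame failures
    propagate as exceptions; callers decide whether to skip the series.
    """
    profiles = []
    for frame in frames:
        pair = segment_frame(frame, params)
        prof = boundaries_to_profile(
            pair,
            axial_pitch_um=frame.axial_pitch_um,
            lateral_pitch_um=frame.lateral_pitch_um,
            frame_width_mm=frame.frame_width_mm,
            n_fluid=n_fluid,
            meridian_angle_deg=frame.meridian_angle_deg,
        )
        profiles.append(prof)
    pmap = assemble_polar_map(profiles, laterality=frames[0].laterality, grid=grid)
    summary = summarize_regions(pmap, scheme, min_coverage)
    return summary, pmap


@dataclass
class MeasureReport:
    """Bookkeeping for a dataset measurement run."""

    n_series: int = 0
    n_failed: int = 0
    failures: list = field(default_factory=list)


def measure_dataset(dataset_dir, n_fluid=DEFAULT_N_FLUID, params=DEFAULT_PARAMS,
                    grid=None, scheme=DEFAULT_SCHEME, maps_dir=None):
    """Measure every eye/time series of a generated dataset directory.

    Returns ``(long_table, MeasureReport)``; series that fail segmentation
    or reconstruction are logged and skipped.  When ``maps_dir`` is given,
    each reconstructed thickness map is saved there as a CSV matrix plus a
    rendered PNG heat map.
    """
    rows = []
    report = MeasureReport()
    for sidecar in sio.list_sidecars(dataset_dir):
        meta, frames = sio.read_eye_time(sidecar)
        report.n_series += 1
        try:
            summary, pmap = measure_frames(frames, n_fluid, params, grid, scheme)
        except SclsettleError as exc:
            report.n_failed += 1
            report.failures.append((meta["eye"], meta["time_min"], str(exc)))
            log.warning("skipping %s t=%s: %s", meta["eye"], meta["time_min"], exc)
            continue
        if maps_dir is not None:
            from .plotting import plot_thickness_map

            maps_dir = sio.ensure_dir(maps_dir)
            stem = f"{meta['eye']}_{meta['time_min']:g}min_map"
            sio.write_map_csv(maps_dir / f"{stem}.csv", pmap)
            plot_thickness_map(
                pmap, maps_dir / f"{stem}.png",
                title=f"{meta['eye']} t={meta['time_min']:g} min",
            )
        summary = summary.assign(
            eye=meta["eye"], group=meta["group"], time_min=meta["time_min"],
        )
        summary["map_coverage"] = pmap.coverage
        rows.append(summary)
    if not rows:
        table = pd.DataFrame(
            columns=["eye", "group", "time_min", "region", "level",
                     "mean_um", "sd_um", "n_cells", "coverage"]
        )
    else:
        table = pd.concat(rows, ignore_index=True)
        table = table.sort_values(["eye", "time_min", "level", "region"],
                                  kind="stable").reset_index(drop=True)
    return table, report


def group_summary(table):
    """Group x region x time mean/sd/sem/n of the measured region means."""
    sub = table[table["level"] == "region"]
    g = sub.groupby(["group", "region", "time_min"])["mean_um"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"].clip(lower=1))
    return out


def settling_fits(table, level="zone"):
    """Per-eye exponential fits of the zonal (or regional) series."""
    sub = table[table["level"] == level]
    rows = []
    for (eye, group, region), d in sub.groupby(["eye", "group", "region"]):
        d = d.sort_values("time_min")
        t = d["time_min"].to_numpy(float)
        y = d["mean_um"].to_numpy(float)
        if t.size < 4 or np.any(~np.isfinite(y)) or np.any(y <= 0):
            continue
        res = ExponentialSettling(t, y).fit()
        obs = res.observed
        rows.append(
            dict(eye=eye, group=group, region=region,
                 T0=res.T0, C=res.C, tau=res.tau, rmse=res.rmse,
                 converged=res.converged,
                 reduction_4h=obs.reduction_4h if obs else np.nan,
                 percent_reduction=obs.percent_reduction if obs else np.nan,
                 fraction_2h=obs.fraction_2h if obs else np.nan)
        )
    return pd.DataFrame(rows)


def per_eye_reduction(table, level="region"):
    """Observed per-eye reduction metrics averaged across regions."""
    sub = table[table["level"] == level]
    rows = []
    for (eye, group), d in sub.groupby(["eye", "group"]):
        reds, pcts, fracs = [], [], []
        for region, dd in d.groupby("region"):
            dd = dd.sort_values("time_min")
            try:
                m = reduction_metrics(dd["time_min"].to_numpy(), dd["mean_um"].to_numpy())
            except SclsettleError:
                continue
            reds.append(m.reduction_4h)
            pcts.append(m.percent_reduction)
            fracs.append(m.fraction_2h)
        if reds:
            rows.append(
                dict(eye=eye, group=group,
                     reduction_4h=float(np.mean(reds)),
                     percent_reduction=float(np.nanmean(pcts)),
                     fraction_2h=float(np.nanmean(fracs)),
                     n_regions=len(reds))
            )
    return pd.DataFrame(rows)


def asymmetry_table(table):
    """Meridional asymmetry per eye per time point."""
    sub = table[table["level"] == "region"]
    rows = []
    for (eye, group, t), d in sub.groupby(["eye", "group", "time_min"]):
        asym = meridional_asymmetry(d)
        rows.append(dict(eye=eye, group=group, time_min=t,
                         vertical_um=asym["vertical"],
                         horizontal_um=asym["horizontal"]))
    return pd.DataFrame(rows)


def analyze_region_table(table, run_anova=True):
    """All analysis products from a measured long-format region table."""
    out = dict(
        group_summary=group_summary(table),
        fits=settling_fits(table),
        per_eye=per_eye_reduction(table),
        asymmetry=asymmetry_table(table),
    )
    if run_anova:
        sub = table[table["level"] == "region"].dropna(subset=["mean_um"])
        n_groups = sub["group"].nunique()
        try:
            res = RepeatedMeasuresAnova(
                sub, dv="mean_um", subject="eye",
                within=["time_min", "region"],
                between="group" if n_groups > 1 else None,
            ).fit()
            out["anova"] = res
        except SclsettleError as exc:
            log.warning("ANOVA skipped: %s", exc)
            out["anova"] = None
    return out
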