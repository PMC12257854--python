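"""Dataset I/O: TIFF/PNG frames, JSON sidecars, CSV tables.

Layout written by :func:`sclsettle.cohort.generate_cohort`::

    <dataset>/
      ground_truth.csv
      {eye}_{t}min.json          # sidecar per eye per time point
      {eye}_{t}min_{i:02d}.tif   # one frame per meridian

Frames are single-channel 16-bit TIFF (fixed intensity scale); sidecars
record meridian angles, pixel pitches, frame width, laterality, group and
time so frames are self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigError
from .render import BScanFrame

INTENSITY_SCALE = 16000.0  # float intensity units -> uint16 counts


def ensure_dir(path):
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ConfigError(f"output directory not writable: {path} ({exc})")
    return path


def _time_tag(t):
    return f"{t:g}min"


def frame_filename(eye, t, index, ext="tif"):
    return f"{eye}_{_time_tag(t)}_{index:02d}.{ext}"


def sidecar_filename(eye, t):
    return f"{eye}_{_time_tag(t)}.json"


def write_frame(path, frame, ext=None):
    """Write one frame as 16-bit TIFF (or 8-bit PNG)."""
    path = Path(path)
    ext = ext or path.suffix.lstrip(".")
    if ext == "tif":
        data = np.clip(frame.pixels * INTENSITY_SCALE, 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, data)
    elif ext == "png":
        data = np.clip(frame.pixels * INTENSITY_SCALE / 256.0, 0, 255).astype(np.uint8)
        iio.imwrite(path, data)
    else:
        raise ConfigError(f"unsupported frame format {ext!r}")


def write_eye_time(out_dir, eye, group, t, frames, ext="tif"):
    """Write all meridian frames of one eye/time plus the sidecar JSON."""
    out_dir = ensure_dir(out_dir)
    names = []
    for i, frame in enumerate(frames):
        name = frame_filename(eye, t, i, ext)
        write_frame(out_dir / name, frame, ext)
        names.append(name)
    f0 = frames[0]
    sidecar = dict(
        eye=eye,
        group=group,
        time_min=float(t),
        laterality=f0.laterality,
        frame_width_mm=f0.frame_width_mm,
        axial_pitch_um=f0.axial_pitch_um,
        lateral_pitch_um=f0.lateral_pitch_um,
        meridian_angles_deg=[float(fr.meridian_angle_deg) for fr in frames],
        frames=names,
    )
    with open(out_dir / sidecar_filename(eye, t), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def list_sidecars(dataset_dir):
    """Sorted sidecar paths in a dataset directory."""
    return sorted(Path(dataset_dir).glob("*.json"))


def read_eye_time(sidecar_path):
    """Load one eye/time series: returns (sidecar dict, list of BScanFrame)."""
    sidecar_path = Path(sidecar_path)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    frames = []
    for name, angle in zip(meta["frames"], meta["meridian_angles_deg"]):
        path = sidecar_path.parent / name
        pixels = np.asarray(
            tifffile.imread(path) if path.suffix == ".tif" else iio.imread(path),
            float,
        ) / (INTENSITY_SCALE if path.suffix == ".tif" else INTENSITY_SCALE / 256.0)
        frames.append(
            BScanFrame(
                pixels=pixels,
                meridian_angle_deg=float(angle),
                axial_pitch_um=meta["axial_pitch_um"],
                lateral_pitch_um=meta["lateral_pitch_um"],
                frame_width_mm=meta["frame_width_mm"],
                time_min=meta["time_min"],
                laterality=meta["laterality"],
            )
        )
    return meta, frames


def write_boundary_csv(path, pair):
    """Per-frame boundary table: column, lens_back_row, cornea_front_row, valid."""
    df = pd.DataFrame(
        dict(
            column=np.arange(pair.lens_back_rows.size),
            lens_back_row=pair.lens_back_rows,
            cornea_front_row=pair.cornea_front_rows,
            valid=pair.valid.astype(int),
        )
    )
    df.to_csv(path, index=False, float_format="%.4f")


def write_map_csv(path, pmap):
    """Thickness map as a CSV matrix: rows = radial grid, cols = angles."""
    g = pmap.grid
    df = pd.DataFrame(
        pmap.thickness_um,
        index=pd.Index(np.round(g.r_centers, 4), name="r_mm"),
        columns=np.round(g.theta_centers, 3),
    )
    df.to_csv(path, float_format="%.3f")


def write_region_table(path, table):
    table.to_csv(path, index=False, float_format="%.4f")


def read_region_table(path):
    return pd.read_csv(path)
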