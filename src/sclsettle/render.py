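"""Synthetic radial B-scan rendering.

A frame shows two bright curvilinear ridges: the lens back surface (anterior,
smaller row) and the corneal epithelial front surface.  Row positions encode
optical path: row(z) = margin + z * n_fluid * 1000 / axial_pitch, so the
axial ridge separation in pixels equals geometric gap (um) * n_fluid /
axial_pitch.  Speckle is multiplicative gamma noise; ``noise_level = 0`` is
exactly noise-free.  Ground-truth sub-pixel ridge rows are returned with
every frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FieldOfViewError
from .reconstruction import DEFAULT_N_FLUID

DEFAULT_TIME_POINTS = (0.0, 30.0, 60.0, 120.0, 240.0)


@dataclass(frozen=True)
class ScanProtocol:
    """Acquisition protocol for one radial scan series.

    32 meridians uniformly spaced over [0, 180) deg, 16-mm-wide frames of
    512 x 512 px, five time points over four hours.  ``axial_pitch_um`` is
    optical path per pixel; ``lateral_pitch_um`` defaults to
    frame_width * 1000 / columns.
    """

    n_meridians: int = 32
    frame_width_mm: float = 16.0
    image_size: tuple[int, int] = (512, 512)
    axial_pitch_um: float = 15.0
    lateral_pitch_um: float | None = None
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS
    noise_level: float = 0.3
    support_mm: float = 6.3  # lateral half-extent with visible boundaries
    margin_px: float = 100.0  # row of the corneal apex plane
    ridge_sigma_px: float = 1.3
    lens_amplitude: float = 0.65  # lens back surface: weaker index contrast
    cornea_amplitude: float = 0.9  # epithelial surface: bright specular ridge
    background: float = 0.08
    n_fluid: float = DEFAULT_N_FLUID
    seed: int = 0

    @property
    def meridian_angles(self):
        return np.arange(self.n_meridians) * 180.0 / self.n_meridians

    @property
    def lateral_pitch(self):
        if self.lateral_pitch_um is not None:
            return self.lateral_pitch_um
        return self.frame_width_mm * 1000.0 / self.image_size[1]


@dataclass
class BScanFrame:
    """One radial B-scan with its acquisition metadata."""

    pixels: np.ndarray
    meridian_angle_deg: float
    axial_pitch_um: float
    lateral_pitch_um: float
    frame_width_mm: float = 16.0
    time_min: float = 0.0
    laterality: str = "OD"
    meta: dict = field(default_factory=dict)


@dataclass
class FrameGroundTruth:
    """Sub-pixel true ridge rows per column (NaN outside rendered support)."""

    lens_back_rows: np.ndarray
    cornea_front_rows: np.ndarray
    thickness_um: np.ndarray  # true geometric gap per column


def anatomical_direction(meridian_angle_deg, laterality):
    """Unit (x, y) anatomical direction of the positive lateral frame axis.

    For OD the scan angle equals the anatomical angle (0 = nasal, 90 =
    superior); for OS angles are mirrored about the vertical meridian.
    """
    if laterality == "OD":
        theta = meridian_angle_deg
    elif laterality == "OS":
        theta = 180.0 - meridian_angle_deg
    else:
        raise ValueError(f"laterality must be OD or OS, got {laterality!r}")
    th = np.deg2rad(theta)
    return np.cos(th), np.sin(th)


def render_bscan(
    cornea,
    thickness_fn,
    meridian_angle_deg,
    protocol,
    time_min=0.0,
    laterality="OD",
    seed=None,
):
    """Render one radial frame and its ground truth.

    ``thickness_fn(x, y)`` returns the true fluid gap (um) at anatomical
    Cartesian mm coordinates, already settled to ``time_min``.  The lens back
    surface is placed at cornea_sag - gap, so rendered geometry and stored
    truth agree exactly.  Raises :class:`FieldOfViewError` when a boundary
    leaves the image rows.
    """
    if not (0.0 <= meridian_angle_deg < 180.0):
        raise ValueError("meridian_angle_deg must be in [0, 180)")
    rows, cols = protocol.image_size
    lateral_pitch = protocol.lateral_pitch
    s = (np.arange(cols) - (cols - 1) / 2.0) * lateral_pitch / 1000.0  # mm
    ux, uy = anatomical_direction(meridian_angle_deg, laterality)
    x, y = s * ux, s * uy
    support = np.abs(s) <= protocol.support_mm

    z_c = np.full(cols, np.nan)
    gap = np.full(cols, np.nan)
    z_c[support] = cornea.sag(x[support], y[support])
    gap[support] = thickness_fn(x[support], y[support])
    z_l = z_c - gap / 1000.0

    scale = protocol.n_fluid * 1000.0 / protocol.axial_pitch_um  # px per mm
    row_l = protocol.margin_px + z_l * scale
    row_c = protocol.margin_px + z_c * scale
    for rr in (row_l, row_c):
        finite = rr[np.isfinite(rr)]
        if finite.size and (finite.min() < 0 or finite.max() > rows - 1):
            raise FieldOfViewError(
                "boundary rows outside image: field of view too small "
                f"(rows span {finite.min():.1f}..{finite.max():.1f})"
            )

    img = np.full((rows, cols), protocol.background)
    sig2 = 2.0 * protocol.ridge_sigma_px**2
    halfwidth = int(np.ceil(6.0 * protocol.ridge_sigma_px))
    offs = np.arange(-halfwidth, halfwidth + 1)[:, None]
    col_idx = np.broadcast_to(np.arange(cols)[None, :], (offs.size, cols))
    for rr, amp in ((row_l, protocol.lens_amplitude),
                    (row_c, protocol.cornea_amplitude)):
        ok = np.isfinite(rr)
        rr_f = np.where(ok, rr, 0.0)
        # rasterize each ridge only inside a +-6 sigma band of rows
        band_rows = np.round(rr_f).astype(int)[None, :] + offs
        vals = amp * np.exp(-((band_rows - rr_f[None, :]) ** 2) / sig2)
        vals[:, ~ok] = 0.0
        inside = (band_rows >= 0) & (band_rows < rows)
        np.add.at(
            img, (band_rows[inside], col_idx[inside]), vals[inside]
        )

    if protocol.noise_level > 0:
        rng = np.random.default_rng(protocol.seed if seed is None else seed)
        shape = 1.0 / protocol.noise_level**2
        img = img * rng.gamma(shape, 1.0 / shape, size=img.shape)

    frame = BScanFrame(
        pixels=img,
        meridian_angle_deg=float(meridian_angle_deg),
        axial_pitch_um=protocol.axial_pitch_um,
        lateral_pitch_um=lateral_pitch,
        frame_width_mm=protocol.frame_width_mm,
        time_min=float(time_min),
        laterality=laterality,
    )
    truth = FrameGroundTruth(row_l, row_c, gap)
    return frame, truth
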