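"""Radial-profile to polar-map reconstruction.

Boundary pairs become geometric thickness profiles (optical path divided by
the fluid refractive index) and 32 radial profiles are assembled into a
polar thickness map over the 12-mm-diameter disc.

Polar map conventions: theta = 0 deg nasal, 90 deg superior, in the
laterality-corrected (anatomical) frame.  The default grid has 120 radial
cells over [0, 6] mm and 64 angular cells of 5.625 deg aligned with the 64
half-meridian rays of a 32-frame radial scan, so the angular assignment of
rays to grid columns is exact (nearest-ray with zero offset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ReconstructionError

DEFAULT_N_FLUID = 1.336  # refractive index of the saline reservoir


@dataclass(frozen=True)
class PolarGrid:
    """Cell-centred polar grid over the 12-mm disc.

    Angular cell centres coincide with the scan ray angles (multiples of
    5.625 deg for the default 32-meridian protocol), so ray-to-cell
    assignment is exact.  Region quadrature splits each cell into two
    angular half-cells so that sector boundaries (odd multiples of
    22.5 deg) fall on sub-cell edges.
    """

    n_r: int = 120
    n_theta: int = 64
    r_max: float = 6.0

    @property
    def dr(self):
        return self.r_max / self.n_r

    @property
    def dtheta(self):
        return 360.0 / self.n_theta

    @property
    def r_centers(self):
        return (np.arange(self.n_r) + 0.5) * self.dr

    @property
    def theta_centers(self):
        return np.arange(self.n_theta) * self.dtheta

    @property
    def cell_weights(self):
        """Area weights (r dr dtheta), shape (n_r, n_theta)."""
        w = self.r_centers * self.dr * np.deg2rad(self.dtheta)
        return np.repeat(w[:, None], self.n_theta, axis=1)


@dataclass
class ThicknessProfile:
    """One meridian's geometric thickness profile.

    ``lateral_position_mm`` is signed along the meridian (0 at the frame
    centre, positive toward the meridian-angle direction); thickness in um.
    """

    lateral_position_mm: np.ndarray
    thickness_um: np.ndarray
    valid: np.ndarray
    meridian_angle_deg: float = 0.0

    def __post_init__(self):
        self.lateral_position_mm = np.asarray(self.lateral_position_mm, float)
        self.thickness_um = np.asarray(self.thickness_um, float)
        self.valid = np.asarray(self.valid, bool)


@dataclass
class PolarThicknessMap:
    """Reconstructed thickness (um) on an (r, theta) grid; NaN = missing."""

    grid: PolarGrid
    thickness_um: np.ndarray  # (n_r, n_theta), NaN where missing
    laterality: str = "OD"
    meta: dict = field(default_factory=dict)

    @property
    def coverage(self):
        return float(np.mean(np.isfinite(self.thickness_um)))


def boundaries_to_profile(
    pair,
    axial_pitch_um,
    lateral_pitch_um=None,
    frame_width_mm=16.0,
    n_cols=None,
    n_fluid=DEFAULT_N_FLUID,
    meridian_angle_deg=0.0,
):
    """Convert a segmented :class:`~sclsettle.segmentation.BoundaryPair` to a
    geometric thickness profile.

    thickness(col) = (cornea_front_row - lens_back_row) * axial_pitch / n_fluid
    lateral_position(col) = (col - center_col) * lateral_pitch, with
    lateral_pitch = frame_width_mm * 1000 / n_cols when not given.
    Columns with non-positive separation are marked invalid and counted in
    the returned profile's ``meta`` attribute.
    """
    lens = np.asarray(pair.lens_back_rows, float)
    cornea = np.asarray(pair.cornea_front_rows, float)
    valid = np.asarray(pair.valid, bool).copy()
    n = lens.size
    if n_cols is None:
        n_cols = n
    if lateral_pitch_um is None:
        lateral_pitch_um = frame_width_mm * 1000.0 / n_cols
    sep = cornea - lens
    # zero separation is a legitimate zero-thickness measurement; negative is not
    neg = valid & (sep < 0)
    valid[neg] = False
    thickness = sep * axial_pitch_um / n_fluid
    thickness[~valid] = np.nan
    center = (n - 1) / 2.0
    lateral = (np.arange(n) - center) * lateral_pitch_um / 1000.0
    prof = ThicknessProfile(lateral, thickness, valid, meridian_angle_deg)
    prof.n_invalid_separation = int(np.count_nonzero(neg))
    return prof


def _ray_values(profile, sign, r_centers):
    """Interpolate one half-meridian (sign=+1/-1) onto the radial grid."""
    s = profile.lateral_position_mm * sign
    keep = profile.valid & (s >= 0)
    if np.count_nonzero(keep) < 2:
        return np.full_like(r_centers, np.nan)
    s_k = s[keep]
    t_k = profile.thickness_um[keep]
    order = np.argsort(s_k)
    s_k, t_k = s_k[order], t_k[order]
    vals = np.interp(r_centers, s_k, t_k, left=np.nan, right=np.nan)
    # do not extrapolate inside gaps larger than ~3 sample spacings
    if s_k.size > 1:
        spacing = np.median(np.diff(s_k))
        gaps = np.diff(s_k) > 3.5 * max(spacing, 1e-9)
        for i in np.nonzero(gaps)[0]:
            vals[(r_centers > s_k[i]) & (r_centers < s_k[i + 1])] = np.nan
    vals[r_centers < s_k[0] - 1e-9] = np.nan
    return vals


def assemble_polar_map(profiles, laterality="OD", grid=None, angle_tol=1e-6,
                       allow_sparse=False):
    """Assemble radial thickness profiles into a :class:`PolarThicknessMap`.

    Each profile contributes two rays (its meridian angle and angle+180).
    Scan meridian angles must be uniformly spaced over [0, 180).  The
    laterality mapping makes theta anatomically correct: for OD the scan
    angle is the anatomical angle; for OS angles are mirrored about the
    vertical axis (theta_anat = 180 - theta_scan), so nasal is at 0 deg for
    both eyes.
    """
    if grid is None:
        grid = PolarGrid()
    profiles = list(profiles)
    n = len(profiles)
    if n == 0:
        raise ReconstructionError("no profiles to assemble")
    angles = np.array([p.meridian_angle_deg for p in profiles], float)
    order = np.argsort(angles)
    angles = angles[order]
    profiles = [profiles[i] for i in order]
    expected = np.arange(n) * 180.0 / n + angles[0]
    if np.max(np.abs(angles - expected)) > max(angle_tol, 1e-6):
        raise ReconstructionError(
            "meridian angles are not uniformly spaced over [0, 180)"
        )
    if grid.n_theta % (2 * n) != 0 or (not allow_sparse and 2 * n != grid.n_theta):
        raise ReconstructionError(
            f"{n} profiles provide {2 * n} rays for {grid.n_theta} angular "
            "cells; expected one ray per cell"
        )
    if laterality not in ("OD", "OS"):
        raise ReconstructionError(f"laterality must be OD or OS, got {laterality!r}")

    # collect the 2n rays in the anatomical frame
    rays = []  # (theta_anat, profile, sign)
    for prof in profiles:
        for sign in (+1, -1):
            theta_scan = prof.meridian_angle_deg % 360.0
            if sign < 0:
                theta_scan = (theta_scan + 180.0) % 360.0
            if laterality == "OD":
                theta_anat = theta_scan
            else:
                theta_anat = (180.0 - theta_scan) % 360.0
            rays.append((theta_anat % 360.0, prof, sign))

    thickness = np.full((grid.n_r, grid.n_theta), np.nan)
    r_centers = grid.r_centers
    ray_angles = np.array([r[0] for r in rays])
    cache = {}
    for j, theta_cell in enumerate(grid.theta_centers):
        d = np.abs((ray_angles - theta_cell + 180.0) % 360.0 - 180.0)
        k = int(np.argmin(d))  # nearest ray in angle
        if k not in cache:
            cache[k] = _ray_values(rays[k][1], rays[k][2], r_centers)
        thickness[:, j] = cache[k]
    return PolarThicknessMap(grid, thickness, laterality)


def map_coverage(pmap):
    """Fraction of grid cells with a non-missing thickness value."""
    return pmap.coverage
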