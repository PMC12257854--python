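"""Parametric eye and lens geometry.

Axial coordinate convention: ``z`` increases posteriorly (into the eye) and is
zero at the corneal apex of the unperturbed conicoid.  All surface heights are
in millimetres; thickness fields are in micrometres.  ``+y`` is superior,
``+x`` is nasal in the anatomically corrected frame.

The cornea is a conicoid (apical radius + asphericity Q) plus optional smooth
perturbations: a Gaussian cone bump for keratoconic eyes and band-limited
random low-order modes for post-keratoplasty eyes.  Perturbations protrude
anteriorly, i.e. they *reduce* the sag and therefore reduce the local fluid
gap under a lens of fixed position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import LensTouchError, UnknownGroupError

GROUP_LABELS = ("myopia", "keratoconus", "post_keratoplasty")

#: default conicoid parameters per morphology group (apical radius mm, Q)
_GROUP_DEFAULTS = {
    "myopia": dict(apical_radius=7.8, asphericity=-0.25),
    "keratoconus": dict(
        apical_radius=6.6,
        asphericity=-0.50,
        cone_amplitude=40.0,
        cone_center=(0.0, -1.0),
        cone_width=1.5,
    ),
    "post_keratoplasty": dict(
        apical_radius=7.6,
        asphericity=-0.20,
        graft_amplitude=25.0,
    ),
}


def conicoid_sag(r, apical_radius, asphericity=0.0):
    """Sag (mm, posterior positive) of a conicoid at chord radius ``r`` mm.

    z(r) = r^2 / (R + sqrt(R^2 - (1+Q) r^2)); for Q = 0 this is the circle
    z = R - sqrt(R^2 - r^2).
    """
    r = np.asarray(r, dtype=float)
    R = float(apical_radius)
    disc = R * R - (1.0 + asphericity) * r * r
    if np.any(disc <= 0):
        raise ValueError(
            "conicoid undefined at requested radius for apical_radius="
            f"{R}, Q={asphericity}"
        )
    return r * r / (R + np.sqrt(disc))


@dataclass(frozen=True)
class CorneaModel:
    """Anterior corneal surface: conicoid plus smooth perturbations.

    Parameters
    ----------
    apical_radius : float
        Apical radius of curvature in mm.
    asphericity : float
        Conic Q value (0 sphere, negative prolate).
    cone_amplitude : float
        Keratoconic cone elevation in um (anterior protrusion).
    cone_center : tuple of float
        Cone centre (x, y) in mm; default inferior-paracentral.
    cone_width : float
        Gaussian sigma of the cone in mm.
    graft_amplitude : float
        RMS amplitude (um) of post-graft band-limited irregularity.
    graft_seed : int
        Seed for the random irregularity modes.
    """

    apical_radius: float = 7.8
    asphericity: float = 0.0
    cone_amplitude: float = 0.0
    cone_center: tuple[float, float] = (0.0, -1.0)
    cone_width: float = 1.5
    graft_amplitude: float = 0.0
    graft_seed: int = 0
    _graft_coeffs: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.graft_amplitude > 0:
            rng = np.random.default_rng(self.graft_seed)
            # low-order smooth modes: (radial power n, angular freq m, phase)
            modes = [(n, m) for n in (2, 3, 4) for m in (0, 1, 2, 3)]
            amps = rng.normal(size=len(modes))
            phases = rng.uniform(0, 2 * np.pi, size=len(modes))
            # normalize so the surface RMS over the 12-mm disc ~ graft_amplitude
            rr = np.linspace(0, 6, 80)
            tt = np.linspace(0, 2 * np.pi, 96, endpoint=False)
            R, T = np.meshgrid(rr, tt, indexing="ij")
            z = np.zeros_like(R)
            for (n, m), a, p in zip(modes, amps, phases):
                z += a * (R / 6.0) ** n * np.cos(m * T + p)
            w = R  # polar area weight
            rms = np.sqrt(np.average(z**2, weights=np.maximum(w, 1e-9)))
            scale = self.graft_amplitude / max(rms, 1e-12)
            coeffs = tuple(
                (n, m, float(a * scale), float(p))
                for (n, m), a, p in zip(modes, amps, phases)
            )
            object.__setattr__(self, "_graft_coeffs", coeffs)

    def perturbation_um(self, x, y):
        """Anterior elevation perturbation (um) at Cartesian mm coordinates."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(np.broadcast(x, y).shape)
        if self.cone_amplitude != 0.0:
            cx, cy = self.cone_center
            d2 = (x - cx) ** 2 + (y - cy) ** 2
            out = out + self.cone_amplitude * np.exp(-d2 / (2.0 * self.cone_width**2))
        if self.graft_amplitude > 0 and self._graft_coeffs:
            r = np.hypot(x, y)
            th = np.arctan2(y, x)
            for n, m, a, p in self._graft_coeffs:
                out = out + a * (r / 6.0) ** n * np.cos(m * th + p)
        return out

    def sag(self, x, y):
        """Corneal surface height z (mm, posterior positive) at (x, y) mm."""
        r = np.hypot(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        z = conicoid_sag(r, self.apical_radius, self.asphericity)
        return z - self.perturbation_um(x, y) / 1000.0


@dataclass(frozen=True)
class LensModel:
    """Scleral lens back surface: spherical optic zone + conic periphery.

    The optic zone is a sphere of radius ``back_optic_zone_radius`` out to
    ``optic_zone_semi_diameter``; beyond it a slope-continuous quadratic
    continuation is scaled so the total sag at the lens semi-diameter equals
    ``sagittal_height``.  Decentration shifts the surface laterally; tilt
    (small-angle, about the horizontal axis unless ``tilt_meridian_deg``
    says otherwise) adds a linear term.
    """

    back_optic_zone_radius: float = 7.6  # mm, default within [6.90, 8.45]
    sagittal_height: float = 4000.0  # um, default within [3800, 4800]
    diameter: float = 15.6  # mm, default in {15.6, 16.3}
    center_thickness: float = 300.0  # um
    optic_zone_semi_diameter: float = 4.0  # mm
    decentration: tuple[float, float] = (0.0, 0.0)  # (dx, dy) mm
    tilt_deg: float = 0.0
    tilt_meridian_deg: float = 0.0  # axis the lens tilts about; 0 = horizontal

    def back_sag(self, x, y):
        """Back-surface height (mm, posterior positive) from the lens apex."""
        x = np.asarray(x, dtype=float) - self.decentration[0]
        y = np.asarray(y, dtype=float) - self.decentration[1]
        r = np.hypot(x, y)
        R = self.back_optic_zone_radius
        r_oz = self.optic_zone_semi_diameter
        semi = self.diameter / 2.0
        z_oz = R - np.sqrt(np.maximum(R * R - np.minimum(r, r_oz) ** 2, 1e-12))
        # slope-continuous quadratic periphery hitting sagittal_height at semi
        z0 = R - np.sqrt(R * R - r_oz * r_oz)
        m = r_oz / np.sqrt(R * R - r_oz * r_oz)
        sag_mm = self.sagittal_height / 1000.0
        c = (sag_mm - z0 - m * (semi - r_oz)) / (semi - r_oz) ** 2
        dr = np.maximum(r - r_oz, 0.0)
        z = np.where(r <= r_oz, z_oz, z0 + m * dr + c * dr * dr)
        if self.tilt_deg != 0.0:
            # tilt about the named meridian: positive tilt lifts the +normal side
            phi = np.deg2rad(self.tilt_meridian_deg)
            lever = -np.sin(phi) * x + np.cos(phi) * y
            z = z + np.tan(np.deg2rad(self.tilt_deg)) * lever
        return z


def make_cornea(group_label, seed=0, **overrides):
    """Build a :class:`CorneaModel` for a morphology group.

    ``group_label`` must be one of ``myopia`` (regular conicoid),
    ``keratoconus`` (inferior-paracentral Gaussian cone) or
    ``post_keratoplasty`` (band-limited random irregularity from ``seed``).
    Keyword overrides replace any default parameter.
    """
    if group_label not in _GROUP_DEFAULTS:
        raise UnknownGroupError(
            f"unknown group label {group_label!r}; expected one of {GROUP_LABELS}"
        )
    params = dict(_GROUP_DEFAULTS[group_label])
    if group_label == "post_keratoplasty":
        params.setdefault("graft_seed", seed)
        params["graft_seed"] = overrides.pop("graft_seed", params["graft_seed"])
    params.update(overrides)
    return CorneaModel(**params)


def baseline_gap(
    cornea,
    lens,
    x,
    y,
    apex_clearance_um=300.0,
    check_touch=True,
):
    """Geometric fluid gap (um) between lens back surface and cornea.

    The lens rests on its scleral landing zone, so its axial position is
    referenced to the *unperturbed* conicoid: the clearance over the
    conicoid apex equals ``apex_clearance_um``.  A corneal perturbation
    (cone, graft irregularity) therefore changes the local gap by its full
    amplitude wherever it sits, including under the lens apex.
    Gap(x, y) = z_cornea - z_lens >= 0; inferior decentration of the lens
    increases the inferior gap.

    Raises :class:`LensTouchError` if the clearance is negative anywhere in
    the evaluated points lying inside the 12-mm disc.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    zc = np.asarray(cornea.sag(x, y))
    zl_rel = np.asarray(lens.back_sag(x, y))
    # conicoid apex sag is 0 by construction, so the offset uses only the
    # lens sag at the corneal apex position
    zl0 = float(lens.back_sag(0.0, 0.0))
    offset = -zl0 - apex_clearance_um / 1000.0
    gap_um = (zc - (zl_rel + offset)) * 1000.0
    if check_touch:
        inside = np.hypot(x, y) <= 6.0
        if np.any(gap_um[inside] < 0):
            raise LensTouchError(
                "lens touch: negative clearance inside the 12-mm disc "
                f"(min {float(np.min(gap_um[inside])):.1f} um)"
            )
    return gap_um
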