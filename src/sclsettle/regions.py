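"""17-region corneal reporting scheme.

A central 4-mm-diameter disc (C), a 3-mm mid-peripheral annulus (2-5 mm
radius, M) and a 1-mm peripheral annulus (5-6 mm radius, P); each annulus is
divided into 8 sectors of 45 deg centred on the principal and oblique
meridians: N (0 deg, nasal), SN (45), S (90, superior), ST (135), T (180),
IT (225), I (270, inferior), IN (315), in the laterality-corrected frame.
Radial intervals are half-open ([0,2), [2,5), [5,6]) and sector boundary
angles belong to the counter-clockwise sector, so the assignment is a
partition of the disc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import RegionSchemeError

SECTORS = ("N", "SN", "S", "ST", "T", "IT", "I", "IN")


@dataclass(frozen=True)
class RegionScheme:
    """Annulus radii (mm) and sector layout of the reporting scheme."""

    central_radius: float = 2.0
    mid_radius: float = 5.0
    outer_radius: float = 6.0
    sectored_annuli: tuple = ("M", "P")  # annuli split into 8 sectors

    @property
    def labels(self):
        out = ["C"] if "C" not in self.sectored_annuli else [
            f"C-{s}" for s in SECTORS
        ]
        for ann in ("M", "P"):
            if ann in self.sectored_annuli:
                out.extend(f"{ann}-{s}" for s in SECTORS)
            else:
                out.append(ann)
        return out


DEFAULT_SCHEME = RegionScheme()


def count_regions(scheme=DEFAULT_SCHEME):
    """Number of distinct region labels in the scheme (default 17)."""
    return len(scheme.labels)


def sector_of(theta_deg):
    """Sector label for an anatomical angle (0 = nasal, 90 = superior)."""
    theta = np.asarray(theta_deg, float) % 360.0
    idx = (np.floor((theta + 22.5) / 45.0).astype(int)) % 8
    return np.asarray(SECTORS, dtype=object)[idx]


def region_of(r_mm, theta_deg, scheme=DEFAULT_SCHEME):
    """Region label(s) for polar coordinates in the anatomical frame.

    Raises :class:`RegionSchemeError` for points outside the outer radius.
    """
    r = np.asarray(r_mm, float)
    th = np.asarray(theta_deg, float)
    scalar = r.ndim == 0 and th.ndim == 0
    r, th = np.atleast_1d(r), np.atleast_1d(th)
    r, th = np.broadcast_arrays(r, th)
    if np.any(r > scheme.outer_radius + 1e-12) or np.any(r < 0):
        raise RegionSchemeError(
            f"radius outside [0, {scheme.outer_radius}] mm"
        )
    annulus = np.where(
        r < scheme.central_radius, "C", np.where(r < scheme.mid_radius, "M", "P")
    ).astype(object)
    sect = sector_of(th)
    out = np.empty(r.shape, dtype=object)
    for ann in ("C", "M", "P"):
        m = annulus == ann
        if not np.any(m):
            continue
        if ann in scheme.sectored_annuli:
            out[m] = np.array([f"{ann}-{s}" for s in sect[m]], dtype=object)
        else:
            out[m] = ann
    if scalar:
        return str(out.ravel()[0])
    return out


def region_index_map(grid, scheme=DEFAULT_SCHEME):
    """Region label per cell of a :class:`~sclsettle.reconstruction.PolarGrid`."""
    r = grid.r_centers[:, None]
    th = grid.theta_centers[None, :]
    rr = np.broadcast_to(r, (grid.n_r, grid.n_theta))
    tt = np.broadcast_to(th, (grid.n_r, grid.n_theta))
    return region_of(rr, tt, scheme)


def quadrature(grid, scheme=DEFAULT_SCHEME):
    """Half-cell angular quadrature of a polar grid.

    The default grid's angular cell centres sit on the scan rays, which
    places sector boundaries through cell centres; splitting each cell into
    two angular halves puts every sector boundary on a sub-cell edge, so
    region integrals nest exactly.  Returns ``(sub_theta, labels, weights)``
    with shapes (2 n_theta,), (n_r, 2 n_theta), (n_r, 2 n_theta); sub-cell
    ``2j`` and ``2j+1`` belong to map cell ``j``.
    """
    n = grid.n_theta
    sub_theta = np.empty(2 * n)
    sub_theta[0::2] = grid.theta_centers - grid.dtheta / 4.0
    sub_theta[1::2] = grid.theta_centers + grid.dtheta / 4.0
    sub_theta %= 360.0
    rr = np.broadcast_to(grid.r_centers[:, None], (grid.n_r, 2 * n))
    tt = np.broadcast_to(sub_theta[None, :], (grid.n_r, 2 * n))
    labels = region_of(rr, tt, scheme)
    w = grid.r_centers[:, None] * grid.dr * np.deg2rad(grid.dtheta / 2.0)
    weights = np.broadcast_to(w, (grid.n_r, 2 * n)).copy()
    return sub_theta, labels, weights


def summarize_regions(pmap, scheme=DEFAULT_SCHEME, min_coverage=0.5):
    """Area-weighted per-region summary of a polar thickness map.

    Region integrals use the half-cell angular quadrature of
    :func:`quadrature` so sector boundaries split boundary cells evenly.
    Returns a DataFrame with one row per region label plus pooled zonal
    aggregates (``level`` column: ``region`` vs ``zone``).  A region whose
    non-missing area fraction is below ``min_coverage`` is reported with a
    missing mean (never imputed).
    """
    _, labels, w = quadrature(pmap.grid, scheme)
    t = np.repeat(pmap.thickness_um, 2, axis=1)
    rows = []

    def _summary(mask, label, level):
        wt = w[mask]
        vals = t[mask]
        ok = np.isfinite(vals)
        cov = float(wt[ok].sum() / wt.sum()) if wt.sum() > 0 else 0.0
        if cov >= min_coverage and ok.any():
            mean = float(np.average(vals[ok], weights=wt[ok]))
            var = float(np.average((vals[ok] - mean) ** 2, weights=wt[ok]))
            sd = float(np.sqrt(var))
        else:
            mean, sd = np.nan, np.nan
        rows.append(
            dict(
                region=label,
                level=level,
                mean_um=mean,
                sd_um=sd,
                n_cells=int(ok.sum() // 2),
                coverage=cov,
            )
        )

    for lab in scheme.labels:
        _summary(labels == lab, lab, "region")
    # pooled zones: C (as-is), M, P pooled over sectors
    zone_of = np.where(
        pmap.grid.r_centers < scheme.central_radius,
        "C",
        np.where(pmap.grid.r_centers < scheme.mid_radius, "M", "P"),
    )
    zone_cells = np.repeat(zone_of[:, None], 2 * pmap.grid.n_theta, axis=1)
    for zone in ("C", "M", "P"):
        _summary(zone_cells == zone, zone, "zone")
    return pd.DataFrame(rows)


def region_areas(grid=None, scheme=DEFAULT_SCHEME):
    """Discrete-quadrature area (mm^2) per region label on the grid."""
    from .reconstruction import PolarGrid

    if grid is None:
        grid = PolarGrid()
    _, labels, w = quadrature(grid, scheme)
    return {lab: float(w[labels == lab].sum()) for lab in scheme.labels}
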