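"""Ground-truthed synthetic cohorts.

A cohort couples group-level corneal/lens geometry with a programmed
regional thickness trajectory.  The true fluid-gap field of a group is the
analytic geometric gap multiplied by a smooth polar control field calibrated
(iterative proportional fitting on the 17-region quadrature) so the field's
region means equal the configured targets exactly.  Settling follows the
single-exponential law per region; per-eye variability is a smooth scalar
trajectory factor drawn per eye and, by default, centred across the cohort
so realized cohort means equal the programmed ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .geometry import CorneaModel, LensModel, baseline_gap, make_cornea
from .reconstruction import PolarGrid
from .regions import DEFAULT_SCHEME
from .render import ScanProtocol, render_bscan
from .settling import plateau_from_endpoints

CONTROL_RADII = (1.0, 3.5, 5.5)
SECTOR_ANGLES = np.arange(8) * 45.0

#: default tempering of the raw geometric gap shape toward its disc mean.
#: Raw conicoid-vs-lens gaps under the default decentration/tilt reach
#: near-touch extremes at the superior periphery that a clinically fitted
#: lens would not show; tempering keeps the smooth shape while bounding the
#: pointwise spread.
SHAPE_TEMPER = 0.5


def tempered_gap_fn(raw_gap_fn, grid=None, temper=SHAPE_TEMPER):
    """Shrink a gap field's deviations about its disc mean by ``temper``."""
    if grid is None:
        grid = PolarGrid()
    r = grid.r_centers[:, None]
    th = np.deg2rad(grid.theta_centers)[None, :]
    g = np.asarray(raw_gap_fn(r * np.cos(th), r * np.sin(th)))
    g0 = float(np.average(g, weights=grid.cell_weights))
    return lambda x, y: g0 + temper * (np.asarray(raw_gap_fn(x, y)) - g0)


class ThicknessField:
    """Continuous true-gap field: analytic gap times a smooth multiplier.

    The multiplier is controlled by a 3 x 8 table (annulus x sector):
    periodic linear interpolation in angle at each control radius, quadratic
    Lagrange interpolation across the control radii (clamped outside).
    """

    def __init__(self, gap_fn, control=None):
        self.gap_fn = gap_fn
        self.control = (
            np.ones((3, 8)) if control is None else np.asarray(control, float)
        )

    def multiplier(self, r_mm, theta_deg):
        r_in = np.asarray(r_mm, float)
        r = np.clip(r_in, CONTROL_RADII[0], CONTROL_RADII[-1])
        th = np.asarray(theta_deg, float) % 360.0
        # periodic linear interpolation over the 8 sector-centre angles
        ext_angles = np.concatenate([SECTOR_ANGLES, [360.0]])
        rows = []
        for k in range(3):
            vals = np.concatenate([self.control[k], self.control[k][:1]])
            rows.append(np.interp(th, ext_angles, vals))
        a0, a1, a2 = rows
        r0, r1, r2 = CONTROL_RADII
        l0 = (r - r1) * (r - r2) / ((r0 - r1) * (r0 - r2))
        l1 = (r - r0) * (r - r2) / ((r1 - r0) * (r1 - r2))
        l2 = (r - r0) * (r - r1) / ((r2 - r0) * (r2 - r1))
        m = l0 * a0 + l1 * a1 + l2 * a2
        # taper angular variation to its mean inside the innermost control
        # radius so the field is continuous at the apex
        inner = r_in < CONTROL_RADII[0]
        if np.any(inner):
            mbar = float(np.mean(self.control[0]))
            w = np.clip(r_in / CONTROL_RADII[0], 0.0, 1.0)
            m = np.where(inner, mbar + w * (m - mbar), m)
        return m

    def __call__(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        r = np.hypot(x, y)
        th = np.degrees(np.arctan2(y, x))
        return np.asarray(self.gap_fn(x, y)) * self.multiplier(r, th)

    def region_means(self, grid=None, scheme=DEFAULT_SCHEME):
        """Quadrature region means (um) on the polar grid (17 + 3 zones)."""
        from .regions import quadrature

        if grid is None:
            grid = PolarGrid()
        sub_theta, labels, w = quadrature(grid, scheme)
        r = grid.r_centers[:, None]
        th = np.deg2rad(sub_theta)[None, :]
        vals = self(r * np.cos(th), r * np.sin(th))
        out = {}
        for lab in scheme.labels:
            m = labels == lab
            out[lab] = float(np.average(vals[m], weights=w[m]))
        for zone, (lo, hi) in {
            "C": (0.0, scheme.central_radius),
            "M": (scheme.central_radius, scheme.mid_radius),
            "P": (scheme.mid_radius, scheme.outer_radius),
        }.items():
            m = (grid.r_centers[:, None] >= lo) & (grid.r_centers[:, None] < hi)
            m = np.repeat(m, 2 * grid.n_theta, axis=1)
            out[zone] = float(np.average(vals[m], weights=w[m]))
        return out


def calibrate_field(gap_fn, targets, grid=None, scheme=DEFAULT_SCHEME,
                    tol_um=1e-3, max_iter=400):
    """Calibrate a :class:`ThicknessField` so its 17 region means match
    ``targets`` (dict region label -> um) on the polar-grid quadrature.

    Iterative proportional fitting on the 3 x 8 control table; raises
    :class:`ConfigError` if the targets cannot be matched.
    """
    if grid is None:
        grid = PolarGrid()
    missing = [lab for lab in scheme.labels if lab not in targets]
    if missing:
        raise ConfigError(f"targets missing regions: {missing}")
    if any(targets[lab] <= 0 for lab in scheme.labels):
        raise ConfigError("all region targets must be positive")
    fld = ThicknessField(gap_fn)
    sector_labels = [[f"M-{s}" for s in _SECTOR_ORDER], [f"P-{s}" for s in _SECTOR_ORDER]]
    for _ in range(max_iter):
        means = fld.region_means(grid, scheme)
        err = max(abs(means[lab] - targets[lab]) for lab in scheme.labels)
        if err < tol_um:
            return fld
        control = fld.control.copy()
        control[0, :] *= targets["C"] / means["C"]
        for row, labs in zip((1, 2), sector_labels):
            for j, lab in enumerate(labs):
                control[row, j] *= targets[lab] / means[lab]
        fld = ThicknessField(gap_fn, control)
    raise ConfigError(
        f"field calibration did not converge (residual {err:.3g} um)"
    )


# sector order matching SECTOR_ANGLES
_SECTOR_ORDER = ("N", "SN", "S", "ST", "T", "IT", "I", "IN")


@dataclass(frozen=True)
class CohortConfig:
    """One synthetic cohort: geometry, programmed trajectory, protocol."""

    name: str = "cohort"
    group_label: str = "myopia"
    n_eyes: int = 10
    baseline_targets: dict | None = None  # region -> um at t = 0
    t240_targets: dict | None = None  # region -> um at t = 240
    tau_min: float = 120.7
    cv_baseline: float = 0.04  # per-eye baseline scale SD
    cv_endpoint: float = 0.04  # per-eye 240-min scale SD
    center_cohort: bool = True  # centre per-eye factors so cohort means are exact
    shape_temper: float = SHAPE_TEMPER
    apex_clearance_um: float = 300.0
    lens: LensModel = field(
        default_factory=lambda: LensModel(decentration=(0.0, -0.3), tilt_deg=0.5)
    )
    cornea_overrides: dict = field(default_factory=dict)
    protocol: ScanProtocol = field(default_factory=ScanProtocol)
    alternate_laterality: bool = True
    seed: int = 0

    @property
    def time_points(self):
        return self.protocol.time_points


@dataclass
class EyeRecord:
    eye_id: str
    group: str
    laterality: str
    cornea: CorneaModel
    a: float  # baseline scale deviation
    b: float  # endpoint scale deviation
    seed: int

    def trajectory_factor(self, t, tau):
        s = (1.0 - np.exp(-t / tau)) / (1.0 - np.exp(-240.0 / tau))
        return 1.0 + self.a + (self.b - self.a) * s


class SyntheticCohort:
    """Realized cohort: group-level calibrated fields + per-eye records.

    ``true_field(eye, t)`` returns a callable (x, y) -> um; ``truth_table``
    is the long-format ground-truth region-mean table.
    """

    def __init__(self, config, grid=None, scheme=DEFAULT_SCHEME):
        self.config = config
        self.scheme = scheme
        self.grid = grid if grid is not None else PolarGrid()
        self._group_cornea = make_cornea(
            config.group_label, seed=config.seed, **config.cornea_overrides
        )
        raw_gap = lambda x, y: baseline_gap(  # noqa: E731
            self._group_cornea, config.lens, x, y,
            apex_clearance_um=config.apex_clearance_um, check_touch=False,
        )
        gap_fn = tempered_gap_fn(raw_gap, self.grid, config.shape_temper)
        self._gap_fn = gap_fn
        if config.baseline_targets is None:
            base = ThicknessField(gap_fn)
            self.baseline_targets = {
                k: v for k, v in base.region_means(self.grid, scheme).items()
                if k in scheme.labels
            }
        else:
            self.baseline_targets = dict(config.baseline_targets)
        if config.t240_targets is None:
            decay = float(np.exp(-240.0 / config.tau_min))
            plateau = 0.55
            self.t240_targets = {
                k: plateau * v + (1 - plateau) * v * decay
                for k, v in self.baseline_targets.items()
            }
        else:
            self.t240_targets = dict(config.t240_targets)
        self._plateaus = {
            k: float(plateau_from_endpoints(
                self.baseline_targets[k], self.t240_targets[k], config.tau_min))
            for k in self.baseline_targets
        }
        if any(v < 0 for v in self._plateaus.values()):
            raise ConfigError("programmed trajectory implies a negative plateau")
        self._fields = {}
        self.eyes = self._draw_eyes()

    def _draw_eyes(self):
        cfg = self.config
        ss = np.random.SeedSequence([cfg.seed, 101])
        rng = np.random.default_rng(ss)
        a = rng.normal(0.0, cfg.cv_baseline, cfg.n_eyes)
        b = rng.normal(0.0, cfg.cv_endpoint, cfg.n_eyes)
        if cfg.center_cohort and cfg.n_eyes > 1:
            a -= a.mean()
            b -= b.mean()
        radius_jit = rng.normal(0.0, 0.10, cfg.n_eyes)
        eyes = []
        for i in range(cfg.n_eyes):
            overrides = dict(cfg.cornea_overrides)
            overrides["apical_radius"] = (
                self._group_cornea.apical_radius + radius_jit[i]
            )
            if cfg.group_label == "post_keratoplasty":
                overrides["graft_seed"] = cfg.seed * 1000 + i
            cornea = make_cornea(cfg.group_label, seed=cfg.seed, **overrides)
            lat = ("OD", "OS")[i % 2] if cfg.alternate_laterality else "OS"
            eyes.append(
                EyeRecord(
                    eye_id=f"{cfg.name}-{i:03d}",
                    group=cfg.group_label,
                    laterality=lat,
                    cornea=cornea,
                    a=float(a[i]),
                    b=float(b[i]),
                    seed=int(
                        np.random.SeedSequence([cfg.seed, 202, i]).generate_state(1)[0]
                        % (2**31)
                    ),
                )
            )
        return eyes

    def region_targets_at(self, t):
        """Programmed group-level region means (um) at time t minutes."""
        tau = self.config.tau_min
        return {
            k: self._plateaus[k]
            + (self.baseline_targets[k] - self._plateaus[k]) * np.exp(-t / tau)
            for k in self.baseline_targets
        }

    def group_field(self, t):
        """Calibrated group-level field at time t (cached per time)."""
        key = round(float(t), 6)
        if key not in self._fields:
            targets = self.region_targets_at(t)
            self._fields[key] = calibrate_field(
                self._gap_fn, targets, self.grid, self.scheme
            )
        return self._fields[key]

    def true_field(self, eye, t):
        f = eye.trajectory_factor(t, self.config.tau_min)
        fld = self.group_field(t)
        return lambda x, y: f * fld(x, y)

    def true_region_means(self, eye, t):
        f = eye.trajectory_factor(t, self.config.tau_min)
        base = self.group_field(t).region_means(self.grid, self.scheme)
        return {k: f * v for k, v in base.items()}

    def truth_table(self, times=None):
        """Long-format ground truth: eye, group, time_min, region, true_mean_um."""
        times = self.config.time_points if times is None else times
        rows = []
        for eye in self.eyes:
            for t in times:
                means = self.true_region_means(eye, t)
                for region, val in means.items():
                    rows.append(
                        dict(
                            eye=eye.eye_id,
                            group=eye.group,
                            time_min=float(t),
                            region=region,
                            true_mean_um=val,
                        )
                    )
        return pd.DataFrame(rows)

    def render_eye_time(self, eye, t):
        """Render all meridian frames for one eye at one time point."""
        cfg = self.config
        fld = self.true_field(eye, t)
        frames, truths = [], []
        for i, ang in enumerate(cfg.protocol.meridian_angles):
            fseed = int(
                np.random.SeedSequence(
                    [cfg.seed, eye.seed, int(round(t * 1000)), i]
                ).generate_state(1)[0]
                % (2**31)
            )
            frame, truth = render_bscan(
                eye.cornea, fld, ang, cfg.protocol,
                time_min=t, laterality=eye.laterality, seed=fseed,
            )
            frames.append(frame)
            truths.append(truth)
        return frames, truths


def generate_cohort(config, out_dir, times=None, writer=None):
    """Write a cohort to disk: TIFF frames, JSON sidecars, ground-truth CSV.

    Returns the :class:`SyntheticCohort`.  Layout: one file per meridian
    frame named ``{eye}_{t}min_{angle_index}.tif`` plus one sidecar JSON per
    eye per time point; ``ground_truth.csv`` is the long-format truth table.
    """
    from . import io as sio

    cohort = SyntheticCohort(config)
    times = config.time_points if times is None else times
    out_dir = sio.ensure_dir(out_dir)
    for eye in cohort.eyes:
        for t in times:
            frames, _ = cohort.render_eye_time(eye, t)
            sio.write_eye_time(out_dir, eye.eye_id, eye.group, t, frames)
    truth = cohort.truth_table(times)
    truth.to_csv(
        out_dir / "ground_truth.csv", index=False, float_format="%.4f"
    )
    return cohort
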