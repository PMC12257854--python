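"""Settling-dynamics statistics.

Observed reduction metrics, the single-exponential-with-plateau fit
T(t) = C + (T0 - C) exp(-t/tau), and meridional asymmetry of the regional
thickness pattern.  The fit is exposed as a small model/results pair:

>>> res = ExponentialSettling(times, thickness).fit()
>>> res.tau, res.fraction_2h
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import SettlingFitError

_REQUIRED_TIMES = (0.0, 120.0, 240.0)


@dataclass
class ReductionMetrics:
    """Observed settling metrics for one thickness series.

    ``reduction_4h`` = T(0) - T(240) um; ``percent_reduction`` =
    100 * reduction / T(0); ``fraction_2h`` = (T(0) - T(120)) / reduction.
    Undefined quantities are NaN with a label in ``errors``.
    """

    reduction_4h: float
    percent_reduction: float
    fraction_2h: float
    errors: tuple = ()


def reduction_metrics(times, values):
    """Observed reduction metrics; requires samples at 0, 120 and 240 min."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    lookup = {}
    for t in _REQUIRED_TIMES:
        hit = np.isclose(times, t)
        if not hit.any():
            raise SettlingFitError(f"series lacks the t = {t:g} min sample")
        lookup[t] = float(values[hit][0])
    t0, t120, t240 = (lookup[t] for t in _REQUIRED_TIMES)
    reduction = t0 - t240
    errors = []
    if t0 == 0:
        percent = np.nan
        errors.append("percent_undefined_zero_baseline")
    else:
        percent = 100.0 * reduction / t0
    if reduction == 0:
        fraction = np.nan
        errors.append("fraction_undefined_no_change")
    else:
        fraction = (t0 - t120) / reduction
    return ReductionMetrics(reduction, percent, fraction, tuple(errors))


def _exp_model(params, t):
    t0, c, tau = params
    return c + (t0 - c) * np.exp(-t / tau)


@dataclass
class ExponentialSettlingResults:
    """Fitted settling curve with parameter uncertainties and diagnostics."""

    T0: float
    C: float
    tau: float
    bse: dict = field(default_factory=dict)
    rmse: float = np.nan
    converged: bool = False
    n_obs: int = 0
    observed: ReductionMetrics = None
    fallback: bool = False

    def predict(self, t):
        if not self.converged:
            raise SettlingFitError("fit did not converge; no fitted curve")
        return _exp_model((self.T0, self.C, self.tau), np.asarray(t, float))

    @property
    def fraction_2h_fitted(self):
        """Closed-form fraction of the 4-h change completed by 2 h: the
        single-exponential identity 1 / (1 + e^(-120/tau))."""
        if not self.converged:
            return np.nan
        return 1.0 / (1.0 + np.exp(-120.0 / self.tau))

    def summary(self):
        lines = [
            "Exponential settling fit: T(t) = C + (T0 - C) exp(-t/tau)",
            f"  n = {self.n_obs} time points, converged = {self.converged}",
        ]
        if self.converged:
            for name, val in (("T0", self.T0), ("C", self.C), ("tau", self.tau)):
                se = self.bse.get(name, np.nan)
                unit = "min" if name == "tau" else "um"
                lines.append(f"  {name:>3} = {val:9.3f} {unit}  (se {se:.3f})")
            lines.append(f"  rmse = {self.rmse:.3f} um")
            lines.append(f"  fraction of 4-h change by 2 h = {self.fraction_2h_fitted:.3f}")
        if self.observed is not None:
            o = self.observed
            lines.append(
                f"  observed: reduction {o.reduction_4h:.1f} um, "
                f"{o.percent_reduction:.1f} %, fraction 2 h {o.fraction_2h:.3f}"
            )
        return "\n".join(lines)


class ExponentialSettling:
    """Model object for a settling series (thickness um vs minutes).

    ``fit()`` performs bounded nonlinear least squares with a grid of tau
    initializations (each solved linearly for T0 and C); on failure it falls
    back to the observed metrics with the fit fields marked unconverged.
    """

    def __init__(self, times, values):
        self.times = np.asarray(times, float)
        self.values = np.asarray(values, float)
        if self.times.size != self.values.size:
            raise SettlingFitError("times and values differ in length")
        if self.times.size < 4:
            raise SettlingFitError(
                f"need >= 4 time points to fit 3 parameters, got {self.times.size}"
            )
        if np.any(self.values <= 0):
            raise SettlingFitError("thickness values must be positive")

    def _observed(self):
        try:
            return reduction_metrics(self.times, self.values)
        except SettlingFitError:
            return None

    def fit(self, tau_grid=(20, 40, 60, 90, 120, 180, 300, 600)):
        t, y = self.times, self.values
        best = None
        for tau0 in tau_grid:
            u = np.exp(-t / tau0)
            A = np.column_stack([1.0 - u, u])  # [C, T0] basis
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            c0 = max(float(coef[0]), 0.0)
            t00 = max(float(coef[1]), c0 + 1e-6)
            sse = float(np.sum((_exp_model((t00, c0, tau0), t) - y) ** 2))
            if best is None or sse < best[0]:
                best = (sse, (t00, c0, tau0))
        x0 = np.array(best[1], float)
        ymax = float(np.max(y))
        try:
            sol = least_squares(
                lambda p: _exp_model(p, t) - y,
                x0,
                bounds=([1e-9, 0.0, 1e-3], [10 * ymax, 10 * ymax, 1e6]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            sol = None
        obs = self._observed()
        if sol is None or not sol.success or sol.x[0] <= sol.x[1]:
            return ExponentialSettlingResults(
                np.nan, np.nan, np.nan, {}, np.nan, False, t.size, obs, True
            )
        t0_hat, c_hat, tau_hat = (float(v) for v in sol.x)
        dof = max(t.size - 3, 1)
        rmse = float(np.sqrt(np.mean(sol.fun**2)))
        s2 = float(np.sum(sol.fun**2)) / dof
        try:
            cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            bse = dict(zip(("T0", "C", "tau"), (float(v) for v in se)))
        except np.linalg.LinAlgError:
            bse = {}
        return ExponentialSettlingResults(
            t0_hat, c_hat, tau_hat, bse, rmse, True, t.size, obs, False
        )


def fit_exponential(times, values):
    """Convenience wrapper: ``ExponentialSettling(times, values).fit()``."""
    return ExponentialSettling(times, values).fit()


def meridional_asymmetry(region_summary, annuli=("M", "P")):
    """Vertical and horizontal asymmetry (um) of a regional summary.

    Sign convention: vertical = inferior - superior, horizontal = nasal -
    temporal (positive vertical = inferior thicker, the typical settled-lens
    pattern).  Computed per annulus from the cardinal sector means and
    pooled (plain mean across annuli).  ``region_summary`` is the DataFrame
    from :func:`sclsettle.regions.summarize_regions` (or any frame with
    ``region`` and ``mean_um`` columns).

    Returns a dict with per-annulus and pooled values; missing cardinal
    sectors are labelled in ``missing``.
    """
    means = dict(zip(region_summary["region"], region_summary["mean_um"]))
    out = {"missing": []}
    vs, hs = [], []
    for ann in annuli:
        need = [f"{ann}-{s}" for s in ("I", "S", "N", "T")]
        if any(k not in means or not np.isfinite(means[k]) for k in need):
            out["missing"].append(ann)
            out[f"vertical_{ann}"] = np.nan
            out[f"horizontal_{ann}"] = np.nan
            continue
        v = means[f"{ann}-I"] - means[f"{ann}-S"]
        h = means[f"{ann}-N"] - means[f"{ann}-T"]
        out[f"vertical_{ann}"] = float(v)
        out[f"horizontal_{ann}"] = float(h)
        vs.append(v)
        hs.append(h)
    out["vertical"] = float(np.mean(vs)) if vs else np.nan
    out["horizontal"] = float(np.mean(hs)) if hs else np.nan
    return out
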