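"""Exponential settling of the fluid reservoir.

The reservoir thins as the lens settles into the conjunctiva following a
single-exponential decay toward a plateau:

    T(t) = C + (T0 - C) * exp(-t / tau)

with ``tau`` in minutes and plateau ``C = plateau_fraction * T0``, optionally
modulated by a smooth spatial scaling field so different regions plateau at
different fractions of their baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SettlingFitError


def settling_fraction(t, tau, horizon=240.0):
    """Fraction of the total 0..horizon change completed by time ``t``.

    For a single-exponential decay this depends only on tau:
    (1 - e^(-t/tau)) / (1 - e^(-horizon/tau)); for t = horizon/2 it equals
    the logistic form 1 / (1 + e^(-t/tau)).
    """
    if tau <= 0:
        raise SettlingFitError(f"tau must be positive, got {tau}")
    t = np.asarray(t, dtype=float)
    return (1.0 - np.exp(-t / tau)) / (1.0 - np.exp(-horizon / tau))


def plateau_from_endpoints(t0_value, t_end_value, tau, horizon=240.0):
    """Plateau C implied by observed endpoints of an exponential decay."""
    decay = np.exp(-horizon / tau)
    return (np.asarray(t_end_value, float) - np.asarray(t0_value, float) * decay) / (
        1.0 - decay
    )


@dataclass(frozen=True)
class SettlingModel:
    """Generator-side settling law applied to a baseline thickness field.

    Parameters
    ----------
    tau : float
        Decay time constant in minutes (> 0).
    plateau_fraction : float
        Plateau as a fraction of the baseline, in (0, 1].
    spatial_scaling : array or None
        Optional dimensionless multiplier field (same shape as the baseline)
        modulating the plateau fraction smoothly across the map.
    """

    tau: float = 120.7
    plateau_fraction: float = 0.55
    spatial_scaling: object = None

    def __post_init__(self):
        if self.tau <= 0:
            raise SettlingFitError(f"tau must be positive, got {self.tau}")
        if not (0.0 < self.plateau_fraction <= 1.0):
            raise SettlingFitError(
                f"plateau_fraction must be in (0, 1], got {self.plateau_fraction}"
            )


def settle_thickness(baseline, t, model):
    """Thickness field (um) after ``t`` minutes of settling.

    T(t) = C + (T0 - C) e^(-t/tau) pointwise, C = plateau_fraction * T0
    (times the optional spatial scaling).  T(0) equals the baseline exactly.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    baseline = np.asarray(baseline, dtype=float)
    frac = model.plateau_fraction
    if model.spatial_scaling is not None:
        frac = np.clip(frac * np.asarray(model.spatial_scaling, float), 0.0, 1.0)
    plateau = frac * baseline
    if t == 0:
        return baseline.copy()
    return plateau + (baseline - plateau) * np.exp(-t / model.tau)
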