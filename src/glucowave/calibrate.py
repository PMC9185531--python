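"""Least-squares energy-vs-concentration calibration and drift diagnostics.

Within a single power-on session the total spectral energy of the beat
signal is close to linear in the glucose concentration, so a degree-1
least-squares fit

    y_hat = k * x + b,
    k = sum((x_i - x_bar)(y_i - y_bar)) / sum((x_i - x_bar)^2),
    b = y_bar - k * x_bar

turns a measured echo energy into an extrapolated concentration
``(E - b) / k``.  Higher-order fits are deliberately not offered: the
mild nonlinearity at the top of the concentration range would invite
overfitting of a five-point calibration.

The catch — and the reason the package carries a learned classifier — is
that the line only holds per power cycle: the radar's gain and offset move
when it is power-cycled, so a line fitted in one session mispredicts
energies measured in another.  :func:`drift_report` quantifies exactly
that failure mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from glucowave.simulate import BeatSignal
from glucowave.spectral import energy_by_class


@dataclass
class LinearFit:
    """Closed-form least-squares line with its sufficient statistics."""

    slope: float
    intercept: float
    x_mean: float
    y_mean: float
    r_squared: float


def linear_fit(xs: Sequence[float], ys: Sequence[float]) -> LinearFit:
    """Degree-1 least-squares fit of energies against concentrations.

    Uses the closed-form normal-equation solution; raises if fewer than two
    distinct abscissae are supplied (the design matrix is then singular).
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xs and ys must be one-dimensional and equally long")
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("need at least two distinct concentrations")
    x_bar = float(x.mean())
    y_bar = float(y.mean())
    sxx = float(np.sum((x - x_bar) ** 2))
    sxy = float(np.sum((x - x_bar) * (y - y_bar)))
    k = sxy / sxx
    b = y_bar - k * x_bar
    ss_res = float(np.sum((y - (k * x + b)) ** 2))
    ss_tot = float(np.sum((y - y_bar) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return LinearFit(slope=k, intercept=b, x_mean=x_bar, y_mean=y_bar, r_squared=r2)


def predict_concentration(energy: float, fit: LinearFit) -> float:
    """Invert the calibration line: concentration = (E - b) / k."""
    if fit.slope == 0:
        raise ZeroDivisionError("calibration line has zero slope")
    return (energy - fit.intercept) / fit.slope


@dataclass
class DriftReport:
    """Comparison of two per-session calibration lines.

    ``cross_session_mae`` is the mean absolute concentration error made by
    applying session A's line to session B's energies; ``within_session_mae``
    is session B's own line applied to the same energies.
    """

    slope_delta: float
    intercept_delta: float
    cross_session_mae: float
    within_session_mae: float


def drift_report(
    fit_a: LinearFit,
    fit_b: LinearFit,
    concentrations_b: Sequence[float],
    energies_b: Sequence[float],
) -> DriftReport:
    """Quantify how badly session A's line predicts session B's data."""
    cs = np.asarray(concentrations_b, dtype=float)
    es = np.asarray(energies_b, dtype=float)
    cross = np.abs([predict_concentration(e, fit_a) for e in es] - cs)
    within = np.abs([predict_concentration(e, fit_b) for e in es] - cs)
    return DriftReport(
        slope_delta=fit_b.slope - fit_a.slope,
        intercept_delta=fit_b.intercept - fit_a.intercept,
        cross_session_mae=float(cross.mean()),
        within_session_mae=float(within.mean()),
    )


class EnergyCalibration:
    """Model object: energy-vs-concentration calibration of one session.

    Built either from raw beat signals (class means of total spectral
    energy are computed internally) or from precomputed (concentration,
    energy) pairs; ``fit()`` returns an
    :class:`EnergyCalibrationResults`.

    Parameters
    ----------
    concentrations, energies
        Calibration abscissae/ordinates.  By default replicate energies
        are averaged per concentration class before fitting; pass
        ``per_class_mean=False`` to fit the raw replicates.
    """

    def __init__(
        self,
        concentrations: Sequence[float],
        energies: Sequence[float],
        per_class_mean: bool = True,
    ) -> None:
        cs = np.asarray(concentrations, dtype=float)
        es = np.asarray(energies, dtype=float)
        if per_class_mean:
            classes = np.unique(cs)
            es = np.array([es[cs == c].mean() for c in classes])
            cs = classes
        self.concentrations = cs
        self.energies = es

    @classmethod
    def from_signals(
        cls, signals: Sequence[BeatSignal], **kwargs
    ) -> "EnergyCalibration":
        """Build from beat signals by running the spectral chain."""
        by_class = energy_by_class(list(signals))
        return cls(list(by_class.keys()), list(by_class.values()), **kwargs)

    def fit(self) -> "EnergyCalibrationResults":
        return EnergyCalibrationResults(self, linear_fit(self.concentrations, self.energies))


@dataclass
class EnergyCalibrationResults:
    """Fitted calibration line with prediction and reporting helpers."""

    model: EnergyCalibration
    params: LinearFit

    @property
    def slope(self) -> float:
        return self.params.slope

    @property
    def intercept(self) -> float:
        return self.params.intercept

    @property
    def r_squared(self) -> float:
        return self.params.r_squared

    def predict_energy(self, concentration: float | np.ndarray) -> np.ndarray:
        return self.params.slope * np.asarray(concentration) + self.params.intercept

    def predict_concentration(self, energy: float) -> float:
        return predict_concentration(energy, self.params)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Energy-vs-concentration calibration (degree-1 least squares)",
            "-" * 60,
            f"  slope k       {p.slope: .6g}  (a.u.^2 per mg/mL)",
            f"  intercept b   {p.intercept: .6g}  (a.u.^2)",
            f"  r-squared     {p.r_squared: .6f}",
            f"  n points      {len(self.model.concentrations)}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter the calibration points with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.plot(m.concentrations, m.energies, "o", label="measured energy")
        grid = np.linspace(m.concentrations.min(), m.concentrations.max(), 50)
        ax.plot(grid, self.predict_energy(grid), "-", label="least-squares line")
        ax.set_xlabel("concentration (mg/mL)")
        ax.set_ylabel("total spectral energy (a.u.$^2$)")
        ax.legend()
        return ax
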