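"""Deterministic validation utilities: logistic growth AUC and qPCR fold
change.

Growth curves from a plate reader are summarized by fitting the logistic

    N(t) = K / (1 + ((K - N0) / N0) * exp(-r t))

and integrating the fitted curve from 0 to ``t_end``; the integral has the
closed form ``(K / r) * log((N0 * (exp(r t) - 1) + K) / K)``, which reduces
to ``N0 * t`` as r -> 0 and approaches ``K * t`` for fast growth.  The area
under the logistic curve is a robust single-number growth phenotype that
folds lag, rate and carrying capacity together.

Reporter qPCR is summarized by the efficiency-corrected ddCt method:
fold change = efficiency ** -ddCt, with the target Ct referenced to a
constitutive normalizer within each sample and then to a calibrator sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .library import ParameterError


class FitError(RuntimeError):
    """The growth-curve fit failed to converge on usable parameters."""


@dataclass
class GrowthCurve:
    """A plate-reader timecourse (hours, OD)."""

    times: np.ndarray
    od: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise ParameterError("times and od must have equal length")
        if len(self.times) < 4:
            raise ParameterError("need at least 4 points to fit")
        if (np.diff(self.times) <= 0).any():
            raise ParameterError("times must be strictly ascending")
        if (self.od < 0).any():
            raise ParameterError("od values must be non-negative")


@dataclass
class QpcrMeasurement:
    """Paired target/reference Ct values for one sample."""

    ct_target: float
    ct_reference: float
    efficiency: float = 2.0

    def __post_init__(self):
        if self.efficiency <= 1:
            raise ParameterError("amplification efficiency must exceed 1")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass
class LogisticFit:
    K: float
    N0: float
    r: float
    auc: float


def logistic(t, K, N0, r):
    """Logistic growth curve N(t)."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))


def logistic_auc(K: float, N0: float, r: float, t_end: float) -> float:
    """Closed-form integral of the logistic curve on [0, t_end]."""
    if t_end < 0:
        raise ParameterError("t_end must be non-negative")
    if r == 0:
        return N0 * t_end
    # (K/r) * log((N0*(exp(r t) - 1) + K)/K), written overflow-safely as
    # (K/r) * (r t + log(N0/K) + log1p(((K - N0)/N0) * exp(-r t)))
    b = (K - N0) / N0
    return (K / r) * (r * t_end + np.log(N0 / K) + np.log1p(b * np.exp(-r * t_end)))


def fit_logistic_auc(curve: GrowthCurve, t_end: float | None = None) -> LogisticFit:
    """Least-squares logistic fit plus the closed-form AUC up to ``t_end``.

    Initialization: K from the curve maximum, N0 from the first positive
    reading, r from the log-linear slope of the early (sub-half-max) points;
    the optimizer is bounded to positive parameters.  Near-constant curves
    are returned as the flat limit (K = N0 = mean, r = 0) rather than fitted.
    Degenerate data that defeat the optimizer raise :class:`FitError`.
    """
    t_end = float(curve.times.max()) if t_end is None else float(t_end)
    if t_end > curve.times.max() + 1e-9:
        raise ParameterError("t_end exceeds the measured time range")

    od = curve.od
    span = od.max() - od.min()
    if span <= 1e-9 * max(od.max(), 1.0):
        c = float(od.mean())
        return LogisticFit(K=c, N0=c, r=0.0, auc=c * t_end)

    k0 = float(od.max())
    n0 = float(od[od > 0][0]) if (od > 0).any() else 1e-6
    early = od < (od.min() + 0.5 * span)
    if early.sum() >= 2 and (od[early] > 0).all():
        slope = np.polyfit(curve.times[early], np.log(od[early]), 1)[0]
        r0 = float(np.clip(slope, 1e-3, 10.0))
    else:
        r0 = 0.5
    try:
        popt, _ = curve_fit(
            logistic,
            curve.times,
            od,
            p0=[k0, max(n0, 1e-6), r0],
            bounds=([1e-9, 1e-9, 1e-6], [np.inf, np.inf, 100.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"logistic fit failed: {exc}") from exc
    K, N0, r = (float(v) for v in popt)
    resid = od - logistic(curve.times, K, N0, r)
    rms = float(np.sqrt(np.mean(resid**2)))
    if not np.isfinite(rms) or rms > max(0.25 * span, 1e-6):
        raise FitError("logistic fit does not describe the data (large residuals)")
    return LogisticFit(K=K, N0=N0, r=r, auc=logistic_auc(K, N0, r, t_end))


def qpcr_relative_expression(sample: QpcrMeasurement, calibrator: QpcrMeasurement) -> float:
    """Fold change of the target in ``sample`` versus ``calibrator``.

    Computed as efficiency ** -ddCt with ddCt the calibrator-referenced
    delta-Ct; swapping sample and calibrator exactly inverts the result.
    """
    if sample.efficiency != calibrator.efficiency:
        raise ParameterError("sample and calibrator must share the amplification efficiency")
    ddct = sample.delta_ct - calibrator.delta_ct
    return float(sample.efficiency ** (-ddct))


def fit_plate_table(df: pd.DataFrame, time_column: str = "time_h", t_end: float | None = None) -> pd.DataFrame:
    """Fit every well column of a plate-reader table; returns one row per well."""
    rows = []
    times = df[time_column].to_numpy(dtype=float)
    for well in [c for c in df.columns if c != time_column]:
        curve = GrowthCurve(times, df[well].to_numpy(dtype=float))
        try:
            fit = fit_logistic_auc(curve, t_end=t_end)
            rows.append(
                {"well": well, "K": fit.K, "N0": fit.N0, "r": fit.r, "auc": fit.auc, "status": "ok"}
            )
        except FitError as exc:
            rows.append(
                {
                    "well": well,
                    "K": np.nan,
                    "N0": np.nan,
                    "r": np.nan,
                    "auc": np.nan,
                    "status": f"failed: {exc}",
                }
            )
    return pd.DataFrame(rows)
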