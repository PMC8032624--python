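"""Concentration-response modelling of AChE inhibition.

Activity (% of solvent control) versus log10 profenofos concentration is
described by a unit-slope log-logistic:

    Y = 100 / (1 + 10**(X - logIC50))

where X = log10(concentration) and IC50 is the concentration halving the
activity.  A free-Hill-slope variant is available behind a flag but off by
default.  Fitting is unweighted least squares on the pooled replicate
points (percent-activity scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .kinetics import FitError


@dataclass(frozen=True)
class InhibitionDataset:
    """AChE activity (% of control) at profenofos concentrations (nM)."""

    label: str  # e.g. "human recombinant" or "rat RBC"
    concentration_nM: np.ndarray
    activity_pct: np.ndarray
    replicate: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration_nM, dtype=float)
        a = np.asarray(self.activity_pct, dtype=float)
        if np.any(c <= 0):
            raise ValueError("concentrations must be > 0")
        if np.any(a < 0) or np.any(a > 130):
            raise ValueError("activities must lie in [0, ~120]% of control")
        if len(c) != len(a):
            raise ValueError("concentration and activity arrays differ in length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "concentration_nM": self.concentration_nM,
                "activity_pct": self.activity_pct,
                "replicate": self.replicate,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str) -> "InhibitionDataset":
        return cls(
            label=label,
            concentration_nM=df["concentration_nM"].to_numpy(dtype=float),
            activity_pct=df["activity_pct"].to_numpy(dtype=float),
            replicate=df["replicate"].to_numpy(),
        )


@dataclass(frozen=True)
class IC50Fit:
    """Fitted logIC50 (log10 nM) with uncertainty and diagnostics."""

    logIC50: float
    logIC50_se: float
    hill_slope: float = 1.0
    residual_ss: float = float("nan")
    n_points: int = 0

    @property
    def IC50(self) -> float:
        """IC50 in the units of the fitted concentrations (nM)."""
        return 10.0 ** self.logIC50

    def to_dict(self) -> dict:
        return {
            "logIC50": self.logIC50,
            "IC50_nM": self.IC50,
            "logIC50_se": self.logIC50_se,
            "hill_slope": self.hill_slope,
            "residual_ss": self.residual_ss,
            "n_points": self.n_points,
        }


def logistic_activity(X, logIC50: float, hill_slope: float = 1.0):
    """Activity (% of control) at X = log10 concentration."""
    X = np.asarray(X, dtype=float)
    out = 100.0 / (1.0 + 10.0 ** (hill_slope * (X - logIC50)))
    return out.item() if out.ndim == 0 else out


def fit_ic50(data: InhibitionDataset, free_slope: bool = False) -> IC50Fit:
    """Least-squares fit of the unit-slope log-logistic to pooled points.

    Requires at least 4 distinct concentrations and an observed transition
    (some activity below 90% and some above 10% of control).
    """
    conc = np.asarray(data.concentration_nM, dtype=float)
    act = np.asarray(data.activity_pct, dtype=float)
    if len(np.unique(conc)) < 4:
        raise FitError("need >= 4 distinct concentrations spanning the transition")
    if act.min() > 90.0 or act.max() < 10.0:
        raise FitError(
            "no transition observed: activities do not span the 10-90% range"
        )
    X = np.log10(conc)
    x0 = float(X[np.argmin(np.abs(act - 50.0))])
    if free_slope:
        popt, pcov = curve_fit(
            lambda x, l, h: 100.0 / (1.0 + 10.0 ** (h * (x - l))),
            X,
            act,
            p0=[x0, 1.0],
            maxfev=20000,
        )
        log_ic50, slope = popt
        se = float(np.sqrt(pcov[0, 0]))
        resid = act - logistic_activity(X, log_ic50, slope)
    else:
        popt, pcov = curve_fit(
            lambda x, l: 100.0 / (1.0 + 10.0 ** (x - l)),
            X,
            act,
            p0=[x0],
            maxfev=20000,
        )
        log_ic50, slope = float(popt[0]), 1.0
        se = float(np.sqrt(pcov[0, 0]))
        resid = act - logistic_activity(X, log_ic50)
    return IC50Fit(
        logIC50=float(log_ic50),
        logIC50_se=se,
        hill_slope=float(slope),
        residual_ss=float(np.sum(resid**2)),
        n_points=len(act),
    )


def inhibition_at(conc_nM, fit: IC50Fit):
    """Percent AChE inhibition (100 - activity) at a concentration in nM."""
    conc_nM = np.asarray(conc_nM, dtype=float)
    if np.any(conc_nM <= 0):
        raise ValueError("concentration must be > 0")
    out = 100.0 - np.asarray(
        logistic_activity(np.log10(conc_nM), fit.logIC50, fit.hill_slope)
    )
    return out.item() if out.ndim == 0 else out
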