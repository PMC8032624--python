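"""Benchmark-dose analysis of predicted dose-response curves.

Continuous-response model families in the EFSA tradition (exponential and
Hill, with background forced to ~0 for predicted inhibition curves) are
fitted by least squares; models are combined by AIC weights and the BMDL
is the 5th percentile of model-averaged BMDs over a parametric (residual
resampling) bootstrap.  This is a minimal model-averaging engine, an
approximation of the full EFSA PROAST suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit

from .dosimetry import DoseResponseCurve
from .kinetics import FitError


def _hill(d, c, k, n):
    return c * d**n / (k**n + d**n)


def _exponential(d, c, k, n):
    return c * (1.0 - np.exp(-((d / k) ** n)))


MODEL_FAMILIES: dict[str, Callable] = {
    "exponential": _exponential,
    "hill": _hill,
}


@dataclass(frozen=True)
class ModelFit:
    """One fitted dose-response family with its AIC and BMD."""

    family: str
    params: tuple
    aic: float
    bmd: float
    residuals: np.ndarray = field(repr=False, default=None)

    def predict(self, d):
        return MODEL_FAMILIES[self.family](np.asarray(d, dtype=float), *self.params)


@dataclass(frozen=True)
class BMDResult:
    """Model-averaged benchmark-dose result."""

    bmr: float
    model_fits: tuple
    weights: dict
    bmd: float  # model-averaged BMD, mg/kg bw
    bmdl: float  # bootstrap lower bound, mg/kg bw
    n_boot: int
    seed: int
    warnings: tuple = ()

    def to_dict(self) -> dict:
        return {
            "bmr": self.bmr,
            "bmd_mg_kg": self.bmd,
            "bmdl_mg_kg": self.bmdl,
            "weights": self.weights,
            "models": [
                {"family": f.family, "params": list(f.params), "aic": f.aic, "bmd": f.bmd}
                for f in self.model_fits
            ],
            "n_boot": self.n_boot,
            "seed": self.seed,
            "warnings": list(self.warnings),
        }


def _fit_family(family: str, dose, resp) -> ModelFit | None:
    func = MODEL_FAMILIES[family]
    c0 = float(min(max(resp.max(), 1e-3), 100.0))
    k0 = float(dose[np.argmin(np.abs(resp - c0 / 2.0))])
    try:
        popt, _ = curve_fit(
            func,
            dose,
            resp,
            p0=[c0, k0, 1.0],
            bounds=([1e-6, 1e-12, 0.1], [120.0, 1e12, 15.0]),
            maxfev=40000,
        )
    except RuntimeError:
        return None
    resid = resp - func(dose, *popt)
    n = len(resp)
    rss = float(np.sum(resid**2))
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * 3
    return ModelFit(family=family, params=tuple(popt), aic=aic, bmd=np.nan, residuals=resid)


def fit_dose_response_models(
    curve: DoseResponseCurve,
    families: Sequence[str] = ("exponential", "hill"),
    bmr: float = 0.10,
) -> list[ModelFit]:
    """Fit each family to the curve and attach its BMD at ``bmr``."""
    dose = np.asarray(curve.dose_mg_kg, dtype=float)
    resp = np.asarray(curve.inhibition_pct, dtype=float)
    if len(dose) < 5:
        raise FitError("need >= 5 dose points for BMD modelling")
    if resp.max() - resp.min() < 100.0 * bmr:
        raise FitError(
            "flat response: observed range does not span the benchmark response"
        )
    fits = []
    for family in families:
        fit = _fit_family(family, dose, resp)
        if fit is not None:
            fit = ModelFit(
                family=fit.family,
                params=fit.params,
                aic=fit.aic,
                bmd=bmd_at_bmr(fit, bmr, dose),
                residuals=fit.residuals,
            )
            fits.append(fit)
    if not fits:
        raise FitError("no dose-response family converged")
    return fits


def bmd_at_bmr(fit: ModelFit, bmr: float, dose_range=None) -> float:
    """Dose at which predicted inhibition equals ``bmr`` x 100 percentage points."""
    if bmr < 0:
        raise ValueError("BMR must be >= 0")
    if bmr == 0:
        return 0.0
    target = 100.0 * bmr
    if dose_range is None:
        hi = fit.params[1] * 1e6
    else:
        hi = float(np.max(dose_range)) * 10.0
    lo = hi * 1e-12
    f = lambda d: fit.predict(d) - target
    if f(hi) < 0:
        raise ValueError(f"BMR {bmr} outside fitted response range")
    while f(lo) > 0:
        lo *= 1e-3
        if lo < 1e-30:
            raise ValueError("BMD search failed at the low-dose end")
    return float(brentq(f, lo, hi, rtol=1e-6))


def model_average_bmdl(
    fits: Sequence[ModelFit],
    curve: DoseResponseCurve,
    bmr: float = 0.10,
    n_boot: int = 200,
    seed: int = 1,
) -> BMDResult:
    """AIC-weighted model averaging with a residual-resampling bootstrap BMDL.

    The model-averaged BMD is the AIC-weighted geometric mean of per-model
    BMDs; the BMDL is the 5th percentile of model-averaged BMDs refitted on
    bootstrap datasets (fitted ensemble prediction + resampled residuals).
    """
    if not fits:
        raise FitError("need at least one converged fit")
    warnings = []
    if n_boot < 50:
        warnings.append(f"n_boot={n_boot} is low; BMDL may be unstable")
    dose = np.asarray(curve.dose_mg_kg, dtype=float)
    resp = np.asarray(curve.inhibition_pct, dtype=float)

    aics = np.array([f.aic for f in fits])
    w = np.exp(-(aics - aics.min()) / 2.0)
    w = w / w.sum()
    weights = {f.family: float(wi) for f, wi in zip(fits, w)}
    bmd_ma = float(np.exp(np.sum(w * np.log([f.bmd for f in fits]))))

    yhat = np.sum([wi * f.predict(dose) for f, wi in zip(fits, w)], axis=0)
    resid = resp - yhat
    rng = np.random.default_rng(seed)
    boot_bmds = []
    families = [f.family for f in fits]
    for _ in range(n_boot):
        y_star = yhat + rng.choice(resid, size=len(resid), replace=True)
        y_star = np.clip(y_star, 0.0, 100.0)
        b_fits = []
        for family in families:
            bf = _fit_family(family, dose, y_star)
            if bf is None:
                continue
            try:
                bmd_b = bmd_at_bmr(bf, bmr, dose)
            except ValueError:
                continue
            b_fits.append((bf.aic, bmd_b))
        if not b_fits:
            continue
        a = np.array([x[0] for x in b_fits])
        wb = np.exp(-(a - a.min()) / 2.0)
        wb = wb / wb.sum()
        boot_bmds.append(float(np.exp(np.sum(wb * np.log([x[1] for x in b_fits])))))
    if boot_bmds:
        bmdl = float(np.percentile(boot_bmds, 5.0))
    else:
        warnings.append("bootstrap produced no usable BMDs; BMDL set to BMD")
        bmdl = bmd_ma
    bmdl = min(bmdl, bmd_ma)
    return BMDResult(
        bmr=bmr,
        model_fits=tuple(fits),
        weights=weights,
        bmd=bmd_ma,
        bmdl=bmdl,
        n_boot=n_boot,
        seed=seed,
        warnings=tuple(warnings),
    )


def bmd_analysis(
    curve: DoseResponseCurve,
    bmr: float = 0.10,
    n_boot: int = 200,
    seed: int = 1,
) -> BMDResult:
    """Convenience wrapper: fit families, average, bootstrap BMDL."""
    fits = fit_dose_response_models(curve, bmr=bmr)
    return model_average_bmdl(fits, curve, bmr=bmr, n_boot=n_boot, seed=seed)
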