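"""Michaelis-Menten fitting of incubation data and in-vitro -> in-vivo scaling.

Metabolite-formation rates measured in liver microsomal, liver cytosolic and
plasma incubations are fitted to V = Vmax*[S]/(Km + [S]); the catalytic
efficiency Vmax/Km (ml/min/mg protein) summarises low-concentration intrinsic
clearance.  Fitted Vmax values (nmol/min/mg protein) are scaled to whole-organ
capacities (umol/h/kg liver or kg blood) with standard protein-content
scaling factors; in vivo Km is the in vitro Km corrected by the fraction
unbound in the incubation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .physiology import SpeciesPhysiology

MATRICES = ("liver_microsomes", "liver_cytosol", "plasma")

#: mg protein (or mg plasma, for the plasma matrix) per g tissue
DEFAULT_SCALING = {
    "liver_microsomes": 35.0,  # mg microsomal protein / g liver
    "liver_cytosol": 80.7,  # mg cytosolic protein / g liver
    "plasma": 550.0,  # mg plasma / g blood
}


class FitError(RuntimeError):
    """Raised when a nonlinear fit cannot be performed or did not converge."""


@dataclass(frozen=True)
class IncubationDataset:
    """Substrate-concentration-dependent metabolite formation rates."""

    matrix: str  # one of MATRICES
    species: str
    concentration_uM: np.ndarray
    rate_nmol_min_mg: np.ndarray
    replicate: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration_uM, dtype=float)
        r = np.asarray(self.rate_nmol_min_mg, dtype=float)
        if np.any(c <= 0):
            raise ValueError("substrate concentrations must be > 0")
        if np.any(r < 0):
            raise ValueError("rates must be >= 0")
        if len(c) != len(r):
            raise ValueError("concentration and rate arrays differ in length")

    @property
    def n_concentrations(self) -> int:
        return len(np.unique(self.concentration_uM))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "concentration_uM": self.concentration_uM,
                "rate_nmol_min_mg": self.rate_nmol_min_mg,
                "replicate": self.replicate,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, matrix: str, species: str) -> "IncubationDataset":
        return cls(
            matrix=matrix,
            species=species,
            concentration_uM=df["concentration_uM"].to_numpy(dtype=float),
            rate_nmol_min_mg=df["rate_nmol_min_mg"].to_numpy(dtype=float),
            replicate=df["replicate"].to_numpy(),
        )


@dataclass(frozen=True)
class MMFit:
    """Fitted Michaelis-Menten parameters with standard errors."""

    Km: float  # uM
    Vmax: float  # nmol/min/mg protein
    Km_se: float
    Vmax_se: float
    converged: bool
    residuals: np.ndarray = field(repr=False)

    @property
    def catalytic_efficiency(self) -> float:
        """Vmax/Km, ml/min/mg protein (uM and nmol/ml cancel)."""
        return self.Vmax / self.Km

    def to_dict(self) -> dict:
        return {
            "Km_uM": self.Km,
            "Vmax_nmol_min_mg": self.Vmax,
            "Km_se": self.Km_se,
            "Vmax_se": self.Vmax_se,
            "catalytic_efficiency_ml_min_mg": self.catalytic_efficiency,
            "converged": self.converged,
        }


@dataclass(frozen=True)
class ScalingFactors:
    """Protein-content scaling factors and incubation unbound fractions."""

    mg_per_g: dict = field(default_factory=lambda: dict(DEFAULT_SCALING))
    fu_incubation: dict = field(
        default_factory=lambda: {m: 1.0 for m in MATRICES}
    )

    def __post_init__(self) -> None:
        for m, v in self.mg_per_g.items():
            if not v > 0:
                raise ValueError(f"scaling factor for {m!r} must be > 0")
        for m, v in self.fu_incubation.items():
            if not (0 < v <= 1):
                raise ValueError(f"fu_incubation for {m!r} must be in (0,1]")


def michaelis_menten_rate(S, Km: float, Vmax: float):
    """Michaelis-Menten rate V = Vmax*S/(Km + S); S in uM, V in rate units."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be >= 0")
    out = Vmax * S / (Km + S)
    return out.item() if out.ndim == 0 else out


def fit_michaelis_menten(data: IncubationDataset) -> MMFit:
    """Unweighted nonlinear least-squares fit on the pooled replicate points.

    Initial values: Vmax0 = max observed rate; Km0 = concentration nearest
    half of Vmax0; both parameters bounded positive.
    """
    if data.n_concentrations < 4:
        raise FitError(
            f"need >= 4 distinct concentrations, got {data.n_concentrations}"
        )
    S = np.asarray(data.concentration_uM, dtype=float)
    V = np.asarray(data.rate_nmol_min_mg, dtype=float)
    vmax0 = float(V.max())
    if vmax0 <= 0:
        raise FitError("all rates are zero: no saturable signal to fit")
    km0 = float(S[np.argmin(np.abs(V - vmax0 / 2.0))])
    try:
        popt, pcov = curve_fit(
            lambda s, km, vm: vm * s / (km + s),
            S,
            V,
            p0=[km0, vmax0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    km, vm = popt
    se = np.sqrt(np.diag(pcov))
    residuals = V - vm * S / (km + S)
    return MMFit(
        Km=float(km),
        Vmax=float(vm),
        Km_se=float(se[0]),
        Vmax_se=float(se[1]),
        converged=True,
        residuals=residuals,
    )


def catalytic_efficiency(fit: MMFit) -> float:
    """Vmax/Km in ml/min/mg protein."""
    if not fit.Km > 0:
        raise ValueError("Km must be > 0")
    return fit.Vmax / fit.Km


def scale_vmax_to_in_vivo(
    fit: "MMFit | float",
    matrix: str,
    sf: ScalingFactors | None = None,
) -> float:
    """Scale an in vitro Vmax to umol/h per kg liver (or kg blood for plasma).

    Accepts an MMFit or a bare Vmax in nmol/min/mg protein.

    nmol/min/mg * (mg/g tissue) * 60 min/h * 1e-3 umol/nmol * 1e3 g/kg
    = vmax * sf * 60  (umol/h/kg).
    """
    if sf is None:
        sf = ScalingFactors()
    if matrix not in MATRICES:
        raise ValueError(f"unknown matrix {matrix!r}; expected one of {MATRICES}")
    vmax = fit.Vmax if isinstance(fit, MMFit) else float(fit)
    return vmax * sf.mg_per_g[matrix] * 60.0


def in_vivo_km(km_uM: float, matrix: str, sf: ScalingFactors | None = None) -> float:
    """In vivo Km = in vitro Km x fraction unbound in the incubation."""
    if sf is None:
        sf = ScalingFactors()
    if matrix not in MATRICES:
        raise ValueError(f"unknown matrix {matrix!r}; expected one of {MATRICES}")
    return km_uM * sf.fu_incubation[matrix]
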