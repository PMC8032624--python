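"""Reverse dosimetry: in vitro concentration-response -> in vivo dose-response.

Each in vitro concentration (nM, nominal ~ unbound) is equated to the in
vivo unbound Cmax of profenofos in blood; the PBK dose->Cmax map is
inverted to find the oral dose producing that Cmax.  The in vitro response
at that concentration is carried over unchanged, turning the in vitro
concentration-response curve into a predicted in vivo dose-response curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ache import IC50Fit, inhibition_at
from .pbk import DoseCmaxMap, PBKModelSpec, dose_to_cmax_map

#: default inversion grid: 40 log-spaced doses, mg/kg bw
DEFAULT_DOSE_GRID = np.logspace(-4, 3, 40)


@dataclass(frozen=True)
class DoseResponseCurve:
    """Predicted in vivo dose-response points with their source concentrations."""

    species: str
    dose_mg_kg: np.ndarray
    inhibition_pct: np.ndarray
    source_conc_nM: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dose_mg_kg, dtype=float)
        i = np.asarray(self.inhibition_pct, dtype=float)
        if np.any(d <= 0):
            raise ValueError("doses must be > 0")
        if np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(np.diff(i) < 0):
            raise ValueError("inhibition must be non-decreasing with dose")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose_mg_kg": self.dose_mg_kg,
                "inhibition_pct": self.inhibition_pct,
                "source_conc_nM": self.source_conc_nM,
            }
        )

    def dose_at_inhibition(self, pct: float) -> float:
        """Interpolated dose at a given % inhibition (log-dose linear interp)."""
        if not (self.inhibition_pct[0] <= pct <= self.inhibition_pct[-1]):
            raise ValueError(f"{pct}% inhibition outside curve range")
        return float(
            np.exp(np.interp(pct, self.inhibition_pct, np.log(self.dose_mg_kg)))
        )


def build_cmax_map(
    model: PBKModelSpec,
    dose_grid=None,
    duration: float = 24.0,
    **sim_kwargs,
) -> DoseCmaxMap:
    grid = DEFAULT_DOSE_GRID if dose_grid is None else np.asarray(dose_grid, float)
    return dose_to_cmax_map(model, grid, duration=duration, **sim_kwargs)


def concentration_to_dose(
    cmax_map: DoseCmaxMap,
    conc_uM_unbound: float,
    rtol: float = 1e-6,
) -> float:
    """Oral dose (mg/kg bw) whose simulated unbound Cmax equals ``conc``.

    Root-finding on the monotone interpolated map; conc 0 maps to dose 0.
    Raises ValueError when the concentration is outside the mapped range.
    """
    if conc_uM_unbound < 0:
        raise ValueError("concentration must be >= 0")
    if conc_uM_unbound == 0.0:
        return 0.0
    # the PCHIP inverse is already exact at the nodes; polish with brentq so
    # the forward map evaluates back to conc within rtol
    d0 = cmax_map.dose(conc_uM_unbound)
    f = lambda logd: cmax_map.cmax(np.exp(logd)) - conc_uM_unbound
    lo, hi = np.log(d0) - 0.7, np.log(d0) + 0.7
    lo = max(lo, np.log(cmax_map.doses[0]))
    hi = min(hi, np.log(cmax_map.doses[-1]))
    try:
        if f(lo) * f(hi) < 0:
            logd = brentq(f, lo, hi, rtol=rtol)
            return float(np.exp(logd))
    except ValueError:
        pass
    return d0


def predict_dose_response(
    model: PBKModelSpec,
    ic50fit: IC50Fit,
    conc_grid_nM=None,
    cmax_map: DoseCmaxMap | None = None,
    species: str | None = None,
    **map_kwargs,
) -> DoseResponseCurve:
    """Translate an in vitro inhibition curve into an in vivo dose-response.

    ``conc_grid_nM`` defaults to 16 log-spaced concentrations spanning
    roughly the 1-99% inhibition range around the fitted IC50.
    """
    if conc_grid_nM is None:
        conc_grid_nM = np.logspace(
            ic50fit.logIC50 - 2.0, ic50fit.logIC50 + 2.0, 16
        )
    conc = np.asarray(conc_grid_nM, dtype=float)
    if cmax_map is None:
        cmax_map = build_cmax_map(model, **map_kwargs)
    # automatic grid extension when a concentration falls outside the map
    for _ in range(4):
        lo_u, hi_u = conc.min() / 1000.0, conc.max() / 1000.0
        if cmax_map.cmax_unbound[0] <= lo_u and hi_u <= cmax_map.cmax_unbound[-1]:
            break
        lo_d = np.log10(cmax_map.doses[0]) - (2.0 if lo_u < cmax_map.cmax_unbound[0] else 0.0)
        hi_d = np.log10(cmax_map.doses[-1]) + (2.0 if hi_u > cmax_map.cmax_unbound[-1] else 0.0)
        n = int(round((hi_d - lo_d) / 7.0 * 40)) + 1
        cmax_map = build_cmax_map(
            model, dose_grid=np.logspace(lo_d, hi_d, max(n, 20)), **map_kwargs
        )
    doses = np.array(
        [concentration_to_dose(cmax_map, c / 1000.0) for c in conc]  # nM -> uM
    )
    inhibition = inhibition_at(conc, ic50fit)
    return DoseResponseCurve(
        species=species or model.physiology.species_name,
        dose_mg_kg=doses,
        inhibition_pct=np.asarray(inhibition, dtype=float),
        source_conc_nM=conc,
    )
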