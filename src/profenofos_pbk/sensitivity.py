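"""Local normalized sensitivity analysis of PBK model outputs.

SC = (C' - C) / (P' - P) * (P / C), with P' = (1 + delta) * P and C the
model output (unbound Cmax in blood) — a one-sided forward difference at
delta = 0.05 by default; central differences are available via option.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

from .pbk import MetabolismTerm, PBKModelSpec, simulate, unbound_cmax
from .partition import PartitionSet

#: parameter paths of the chemical-specific inputs of the profenofos model
CHEMICAL_PARAMETERS = (
    "ka",
    "fup",
    "renal_clearance",
    "kp:gut",
    "kp:liver",
    "kp:fat",
    "met:liver_microsomes:vmax",
    "met:liver_microsomes:km",
    "met:liver_cytosol:vmax",
    "met:liver_cytosol:km",
    "met:plasma:vmax",
    "met:plasma:km",
)


class ParameterError(KeyError):
    """Raised for an unrecognised parameter path."""


def get_parameter(model: PBKModelSpec, path: str) -> float:
    parts = path.split(":")
    if path == "ka":
        return model.ka
    if path == "fup":
        return model.chem.fup
    if path == "renal_clearance":
        return model.renal_clearance
    if parts[0] == "kp" and len(parts) == 2:
        return model.partitions[parts[1]]
    if parts[0] == "met" and len(parts) == 3:
        term = model.metabolism[parts[1]]
        return getattr(term, parts[2])
    raise ParameterError(f"unknown parameter path {path!r}")


def set_parameter(model: PBKModelSpec, path: str, value: float) -> PBKModelSpec:
    """Return a copy of ``model`` with the parameter at ``path`` set to ``value``."""
    parts = path.split(":")
    if path == "ka":
        return model.replace(ka=value)
    if path == "fup":
        return model.replace(chem=dataclasses.replace(model.chem, fup=value))
    if path == "renal_clearance":
        return model.replace(renal_clearance=value)
    if parts[0] == "kp" and len(parts) == 2:
        kp = dict(model.partitions.kp)
        if parts[1] not in kp:
            raise ParameterError(f"unknown tissue {parts[1]!r}")
        kp[parts[1]] = value
        prov = dict(model.partitions.provenance)
        return model.replace(partitions=PartitionSet(kp=kp, provenance=prov))
    if parts[0] == "met" and len(parts) == 3:
        if parts[1] not in model.metabolism:
            raise ParameterError(f"unknown matrix {parts[1]!r}")
        term = model.metabolism[parts[1]]
        new_term = MetabolismTerm(**{**dataclasses.asdict(term), parts[2]: value})
        met = dict(model.metabolism)
        met[parts[1]] = new_term
        return model.replace(metabolism=met)
    raise ParameterError(f"unknown parameter path {path!r}")


def _default_output(model: PBKModelSpec, dose: float) -> float:
    return unbound_cmax(simulate(model, dose))


def sensitivity_coefficient(
    model: PBKModelSpec,
    dose: float,
    parameter: str,
    delta: float = 0.05,
    central: bool = False,
    output: Callable[[PBKModelSpec, float], float] | None = None,
) -> float:
    """Normalized sensitivity coefficient of the output to one parameter."""
    if not delta > 0:
        raise ValueError("delta must be > 0")
    output = output or _default_output
    p = get_parameter(model, parameter)
    if not p > 0:
        raise ValueError(f"parameter {parameter!r} must be positive for a relative perturbation")
    c = output(model, dose)
    if c == 0:
        raise ValueError("model output is zero; normalized SC undefined")
    c_up = output(set_parameter(model, parameter, p * (1.0 + delta)), dose)
    if central:
        c_dn = output(set_parameter(model, parameter, p * (1.0 - delta)), dose)
        return (c_up - c_dn) / (2.0 * delta * c)
    return (c_up - c) / (delta * c)


@dataclass(frozen=True)
class SensitivityResult:
    """SCs of one output at one dose for a set of parameters."""

    output_label: str
    dose: float
    coefficients: dict  # parameter path -> SC
    delta: float

    @property
    def influential(self) -> dict:
        """Parameters with |SC| > 0.1 (the headline set)."""
        return {k: v for k, v in self.coefficients.items() if abs(v) > 0.1}


def sensitivity_profile(
    model: PBKModelSpec,
    dose: float,
    parameters: Sequence[str] = CHEMICAL_PARAMETERS,
    delta: float = 0.05,
    central: bool = False,
    output: Callable[[PBKModelSpec, float], float] | None = None,
    output_label: str = "unbound_cmax",
) -> SensitivityResult:
    """SCs for a list of parameter paths (deduplicated, order-preserving)."""
    seen: dict[str, float] = {}
    for p in parameters:
        if p in seen:
            continue
        seen[p] = sensitivity_coefficient(
            model, dose, p, delta=delta, central=central, output=output
        )
    return SensitivityResult(
        output_label=output_label, dose=dose, coefficients=seen, delta=delta
    )
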