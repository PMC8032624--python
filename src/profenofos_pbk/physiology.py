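"""Species physiology and chemical-property parameter sets.

The kinetic model distinguishes 14 anatomical compartments connected by
blood flows.  Perfused tissues (everything except lung and the two blood
pools) each carry a blood flow; the lung sits in series with the total
cardiac output between the venous and arterial pools.  The liver flow
recorded here is the hepatic *artery* flow only — the portal inflow is the
sum of the gut and spleen effluents and is assembled by the engine.

Units are fixed package-wide: volumes L, flows L/h, amounts umol,
concentrations uM, time h, oral doses mg/kg bw.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

#: the 14 model compartments, in canonical order
COMPARTMENTS: tuple[str, ...] = (
    "liver",
    "gut",
    "fat",
    "muscle",
    "skin",
    "bone",
    "brain",
    "heart",
    "kidney",
    "lung",
    "spleen",
    "venous_blood",
    "arterial_blood",
    "rest",
)

#: compartments that carry an individual blood flow (lung takes cardiac output)
PERFUSED_TISSUES: tuple[str, ...] = tuple(
    c for c in COMPARTMENTS if c not in ("lung", "venous_blood", "arterial_blood")
)

#: tissues whose venous effluent drains into the portal vein (to liver)
PORTAL_TISSUES: tuple[str, ...] = ("gut", "spleen")

SUPPORTED_SPECIES = ("rat", "human")


class ConfigError(ValueError):
    """Raised when a physiology or chemical configuration fails validation."""


@dataclass(frozen=True)
class SpeciesPhysiology:
    """Validated anatomical/physiological parameter set for one species."""

    species_name: str
    body_weight: float  # kg
    tissue_volumes: Mapping[str, float]  # L, keyed by COMPARTMENTS
    blood_flows: Mapping[str, float]  # L/h, keyed by PERFUSED_TISSUES
    cardiac_output: float  # L/h
    renal_clearance: float  # L/h (glomerular filtration of unbound blood)

    def __post_init__(self) -> None:
        if self.species_name not in SUPPORTED_SPECIES:
            raise ConfigError(
                f"unsupported species {self.species_name!r}; "
                f"expected one of {SUPPORTED_SPECIES}"
            )
        missing = [c for c in COMPARTMENTS if c not in self.tissue_volumes]
        if missing:
            raise ConfigError(f"missing tissue volume(s): {', '.join(missing)}")
        unknown = [c for c in self.tissue_volumes if c not in COMPARTMENTS]
        if unknown:
            raise ConfigError(f"unknown tissue(s) in volumes: {', '.join(unknown)}")
        missing_q = [c for c in PERFUSED_TISSUES if c not in self.blood_flows]
        if missing_q:
            raise ConfigError(f"missing blood flow(s): {', '.join(missing_q)}")
        unknown_q = [c for c in self.blood_flows if c not in PERFUSED_TISSUES]
        if unknown_q:
            raise ConfigError(f"unknown tissue(s) in flows: {', '.join(unknown_q)}")
        for name, v in self.tissue_volumes.items():
            if not v > 0:
                raise ConfigError(f"tissue volume for {name!r} must be > 0, got {v}")
        for name, q in self.blood_flows.items():
            if not q > 0:
                raise ConfigError(f"blood flow for {name!r} must be > 0, got {q}")
        for label, value in (
            ("body_weight", self.body_weight),
            ("cardiac_output", self.cardiac_output),
            ("renal_clearance", self.renal_clearance),
        ):
            if not value > 0:
                raise ConfigError(f"{label} must be > 0, got {value}")
        total_q = sum(self.blood_flows.values())
        if abs(total_q - self.cardiac_output) > 0.01 * self.cardiac_output:
            raise ConfigError(
                "flow imbalance: perfused-tissue flows sum to "
                f"{total_q:.4g} L/h but cardiac output is "
                f"{self.cardiac_output:.4g} L/h (> 1% apart)"
            )

    @property
    def blood_volume(self) -> float:
        """Total blood volume (venous + arterial pools), L."""
        return (
            self.tissue_volumes["venous_blood"] + self.tissue_volumes["arterial_blood"]
        )

    @property
    def liver_blood_flow(self) -> float:
        """Total liver effluent flow: hepatic artery + portal inflow, L/h."""
        return self.blood_flows["liver"] + sum(
            self.blood_flows[t] for t in PORTAL_TISSUES
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissue_volumes"] = dict(self.tissue_volumes)
        d["blood_flows"] = dict(self.blood_flows)
        return d


@dataclass(frozen=True)
class ChemicalProperties:
    """Physicochemical descriptors needed for partitioning and binding."""

    name: str
    molecular_weight: float  # g/mol
    logKow: float
    fup: float  # fraction unbound in plasma, (0, 1]
    pKa: float | None = None
    ionization: str = "neutral"  # neutral | acid | base
    blood_plasma_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not self.molecular_weight > 0:
            raise ConfigError(f"molecular_weight must be > 0, got {self.molecular_weight}")
        if not (0 < self.fup <= 1):
            raise ConfigError(f"fup must be in (0, 1], got {self.fup}")
        if self.ionization not in ("neutral", "acid", "base"):
            raise ConfigError(
                f"ionization must be neutral/acid/base, got {self.ionization!r}"
            )
        if self.ionization != "neutral" and self.pKa is None:
            raise ConfigError("pKa required for acid/base ionization class")
        if not self.blood_plasma_ratio > 0:
            raise ConfigError(
                f"blood_plasma_ratio must be > 0, got {self.blood_plasma_ratio}"
            )

    def neutral_fraction(self, pH: float = 7.4) -> float:
        """Henderson-Hasselbalch fraction of the un-ionized species at ``pH``."""
        if self.ionization == "neutral" or self.pKa is None:
            return 1.0
        if self.ionization == "acid":
            return 1.0 / (1.0 + 10.0 ** (pH - self.pKa))
        return 1.0 / (1.0 + 10.0 ** (self.pKa - pH))

    def to_dict(self) -> dict:
        return asdict(self)


def _load_source(source) -> dict:
    """Accept a mapping, a YAML string, or a path to a YAML file."""
    if isinstance(source, Mapping):
        return dict(source)
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        with open(source) as fh:
            return yaml.safe_load(fh)
    if isinstance(source, str):
        return yaml.safe_load(source)
    raise ConfigError(f"cannot interpret config source of type {type(source)!r}")


def load_physiology(source) -> SpeciesPhysiology:
    """Load and validate a species physiology from a config source.

    ``source`` may be a dict, a YAML document, or a path to a YAML file.
    """
    raw = _load_source(source)
    try:
        return SpeciesPhysiology(
            species_name=raw["species_name"],
            body_weight=float(raw["body_weight"]),
            tissue_volumes={k: float(v) for k, v in raw["tissue_volumes"].items()},
            blood_flows={k: float(v) for k, v in raw["blood_flows"].items()},
            cardiac_output=float(raw["cardiac_output"]),
            renal_clearance=float(raw["renal_clearance"]),
        )
    except KeyError as exc:
        raise ConfigError(f"missing config field: {exc.args[0]}") from exc


def load_chemical(source) -> ChemicalProperties:
    """Load and validate chemical properties from a config source."""
    raw = _load_source(source)
    raw.pop("kp_overrides", None)  # consumed by partition.resolve_partitions
    raw.pop("comment", None)
    try:
        return ChemicalProperties(
            name=raw["name"],
            molecular_weight=float(raw["molecular_weight"]),
            logKow=float(raw["logKow"]),
            fup=float(raw["fup"]),
            pKa=None if raw.get("pKa") is None else float(raw["pKa"]),
            ionization=raw.get("ionization", "neutral"),
            blood_plasma_ratio=float(raw.get("blood_plasma_ratio", 1.0)),
        )
    except KeyError as exc:
        raise ConfigError(f"missing config field: {exc.args[0]}") from exc


def save_physiology(phys: SpeciesPhysiology, path) -> None:
    """Write a physiology back to YAML (round-trips through load_physiology)."""
    with open(path, "w") as fh:
        yaml.safe_dump(phys.to_dict(), fh, sort_keys=False)


def _packaged(name: str):
    return importlib.resources.files("profenofos_pbk.data").joinpath(name)


def default_physiology(species: str) -> SpeciesPhysiology:
    """Packaged default physiology for ``rat`` or ``human``."""
    if species not in SUPPORTED_SPECIES:
        raise ConfigError(f"unsupported species {species!r}")
    return load_physiology(yaml.safe_load(_packaged(f"physiology_{species}.yaml").read_text()))


def default_chemical(name: str = "profenofos") -> ChemicalProperties:
    """Packaged default chemical properties (profenofos, bcp, bcp_glucuronide)."""
    return load_chemical(yaml.safe_load(_packaged(f"chemical_{name}.yaml").read_text()))


def default_chemical_config(name: str = "profenofos") -> dict:
    """Raw packaged chemical config (including any Kp overrides)."""
    return yaml.safe_load(_packaged(f"chemical_{name}.yaml").read_text())
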