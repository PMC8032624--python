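"""Tissue:plasma partition coefficient (Kp) estimation.

Kp values are estimated from tissue composition: a chemical distributes
between the aqueous and lipid phases of each tissue according to its
octanol:water partitioning, with ionization at physiological pH handled by
Henderson-Hasselbalch speciation (only the neutral species partitions into
neutral lipid).  Phospholipids behave as a 30:70 lipid:water mixture.  For
adipose the vegetable-oil:water distribution coefficient of the neutral
species is used; for all other tissues the full octanol:water coefficient.
Plasma-protein binding enters through fup, and the tissue unbound fraction
is derived from fup assuming tissue interstitial binding proteins at half
the plasma concentration.

Kp here is a *total tissue*:*total plasma* ratio, used directly by the
flow-limited engine (blood:plasma ratio handled separately).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .physiology import COMPARTMENTS, ChemicalProperties, ConfigError

BLOOD_COMPARTMENTS = ("venous_blood", "arterial_blood")
#: tissues that need a composition row (everything but the blood pools)
COMPOSED_TISSUES = tuple(c for c in COMPARTMENTS if c not in BLOOD_COMPARTMENTS)


@dataclass(frozen=True)
class TissueCompositionTable:
    """Fractional water / neutral-lipid / phospholipid content per tissue."""

    fractions: Mapping[str, tuple[float, float, float]]  # tissue -> (fw, fnl, fph)

    def __post_init__(self) -> None:
        if "plasma" not in self.fractions:
            raise ConfigError("composition table must include a 'plasma' row")
        for tissue, (fw, fnl, fph) in self.fractions.items():
            for label, f in (("water", fw), ("neutral lipid", fnl), ("phospholipid", fph)):
                if not (0 <= f <= 1):
                    raise ConfigError(
                        f"{label} fraction for {tissue!r} must be in [0,1], got {f}"
                    )
            if fw + fnl + fph > 1.0 + 1e-9:
                raise ConfigError(f"fractions for {tissue!r} exceed 1")

    def row(self, tissue: str) -> tuple[float, float, float]:
        try:
            return self.fractions[tissue]
        except KeyError:
            raise ConfigError(f"tissue {tissue!r} missing from composition table") from None


def default_composition_table() -> TissueCompositionTable:
    """The packaged composition table (see data/tissue_composition.csv)."""
    path = importlib.resources.files("profenofos_pbk.data").joinpath(
        "tissue_composition.csv"
    )
    with path.open() as fh:
        df = pd.read_csv(fh, comment="#")
    return TissueCompositionTable(
        fractions={
            r.tissue: (r.f_water, r.f_neutral_lipid, r.f_phospholipid)
            for r in df.itertuples()
        }
    )


@dataclass(frozen=True)
class PartitionSet:
    """Map tissue -> Kp with per-tissue provenance (estimated | user-supplied)."""

    kp: Mapping[str, float]
    provenance: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [c for c in COMPARTMENTS if c not in self.kp]
        if missing:
            raise ConfigError(f"missing Kp for: {', '.join(missing)}")
        for tissue, value in self.kp.items():
            if not value > 0:
                raise ConfigError(f"Kp for {tissue!r} must be > 0, got {value}")

    def __getitem__(self, tissue: str) -> float:
        return self.kp[tissue]


def _tissue_unbound_fraction(fup: float) -> float:
    # interstitial binding proteins assumed at half their plasma concentration
    return 1.0 / (1.0 + 0.5 * (1.0 - fup) / fup)


def estimate_partition_coefficients(
    chem: ChemicalProperties,
    table: TissueCompositionTable | None = None,
    pH: float = 7.4,
) -> PartitionSet:
    """Estimate Kp for every model compartment from tissue composition.

    Deterministic: identical inputs give bit-identical outputs.  The blood
    pools get Kp = blood_plasma_ratio.
    """
    if table is None:
        table = default_composition_table()
    p_ow = 10.0 ** chem.logKow
    fn = chem.neutral_fraction(pH)
    # vegetable-oil:water distribution of the neutral species (adipose phase);
    # standard regression from octanol:water
    log_d_vo = 1.115 * chem.logKow - 1.35
    d_vo = (10.0 ** log_d_vo) * fn
    p_eff = p_ow * fn  # octanol-phase distribution coefficient at pH

    fw_p, fnl_p, fph_p = table.row("plasma")
    fut = _tissue_unbound_fraction(chem.fup)

    kp: dict[str, float] = {}
    prov: dict[str, str] = {}
    for tissue in COMPOSED_TISSUES:
        fw_t, fnl_t, fph_t = table.row(tissue)
        if tissue == "fat":
            num = d_vo * (fnl_t + 0.3 * fph_t) + (fw_t + 0.7 * fph_t)
            den = d_vo * (fnl_p + 0.3 * fph_p) + (fw_p + 0.7 * fph_p)
            kp[tissue] = (num / den) * chem.fup  # adipose unbound fraction ~ 1
        else:
            num = p_eff * (fnl_t + 0.3 * fph_t) + (fw_t + 0.7 * fph_t)
            den = p_eff * (fnl_p + 0.3 * fph_p) + (fw_p + 0.7 * fph_p)
            kp[tissue] = (num / den) * chem.fup / fut
        prov[tissue] = "estimated"
    for blood in BLOOD_COMPARTMENTS:
        kp[blood] = chem.blood_plasma_ratio
        prov[blood] = "estimated"
    return PartitionSet(kp=kp, provenance=prov)


def resolve_partitions(
    config_source: Mapping | None,
    chem: ChemicalProperties,
    table: TissueCompositionTable | None = None,
) -> PartitionSet:
    """Combine user-supplied Kp overrides with composition-based estimates.

    ``config_source`` is a chemical-config mapping whose optional
    ``kp_overrides`` entry maps tissue name -> Kp; supplied values take
    precedence per tissue.
    """
    overrides: Mapping[str, float] = {}
    if config_source:
        overrides = config_source.get("kp_overrides") or {}
    unknown = [t for t in overrides if t not in COMPARTMENTS]
    if unknown:
        raise ConfigError(f"unknown tissue(s) in kp_overrides: {', '.join(unknown)}")
    for tissue, value in overrides.items():
        if not value > 0:
            raise ConfigError(f"supplied Kp for {tissue!r} must be > 0, got {value}")
    estimated = estimate_partition_coefficients(chem, table)
    kp = dict(estimated.kp)
    prov = dict(estimated.provenance)
    for tissue, value in overrides.items():
        kp[tissue] = float(value)
        prov[tissue] = "user-supplied"
    return PartitionSet(kp=kp, provenance=prov)
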