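"""Flow-limited whole-body PBK model for profenofos (rat and human).

The model has 14 perfusion-limited compartments.  Oral dosing enters the
gut lumen as a bolus and is absorbed by a first-order process (ka, default
1 h^-1) routed entirely to the liver via the portal vein.  Elimination:

* liver — microsomal + cytosolic Michaelis-Menten hydrolysis to BCP,
  acting on the unbound concentration in liver venous blood;
* blood — plasma-enzyme Michaelis-Menten hydrolysis acting on the unbound
  blood concentration, split over the venous and arterial pools by volume;
* kidney — passive glomerular filtration of unbound venous blood at the
  fixed species rate.

For model evaluation in rat, an optional sub-model tracks the hydrolysis
product BCP (formed mole-for-mole from all parent metabolism, distributed
over the same compartments with its own partition coefficients, and
glucuronidated in the liver) and the BCP-glucuronide (held in a central
volume and filtered to urine), giving cumulative urinary excretion.

The stiff system is integrated with scipy's LSODA at tight tolerances,
with dense output used to refine the unbound-Cmax estimate.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize_scalar

from .kinetics import ScalingFactors, in_vivo_km, scale_vmax_to_in_vivo
from .partition import PartitionSet, estimate_partition_coefficients, resolve_partitions
from .physiology import (
    COMPARTMENTS,
    PERFUSED_TISSUES,
    PORTAL_TISSUES,
    ChemicalProperties,
    ConfigError,
    SpeciesPhysiology,
    default_chemical,
    default_chemical_config,
    default_physiology,
)

NONPORTAL_TISSUES = tuple(
    t for t in PERFUSED_TISSUES if t not in PORTAL_TISSUES and t != "liver"
)


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails or produces inconsistent output."""


@dataclass(frozen=True)
class MetabolismTerm:
    """One saturable clearance route: Vmax in umol/h/kg tissue, Km in uM."""

    vmax: float
    km: float

    def __post_init__(self) -> None:
        if self.vmax < 0:
            raise ConfigError(f"metabolic Vmax must be >= 0, got {self.vmax}")
        if not self.km > 0:
            raise ConfigError(f"metabolic Km must be > 0, got {self.km}")


@dataclass(frozen=True)
class BCPSubmodel:
    """Parameters of the rat BCP / BCP-glucuronide evaluation sub-model."""

    chem: ChemicalProperties  # BCP properties
    partitions: PartitionSet  # BCP Kp set
    glucuronidation: MetabolismTerm  # liver, umol/h/kg liver on unbound BCP
    glucuronide_fup: float  # fraction unbound of the conjugate
    glucuronide_volume: float  # central distribution volume, L

    def __post_init__(self) -> None:
        if not (0 < self.glucuronide_fup <= 1):
            raise ConfigError("glucuronide_fup must be in (0,1]")
        if not self.glucuronide_volume > 0:
            raise ConfigError("glucuronide_volume must be > 0")


@dataclass(frozen=True)
class PBKModelSpec:
    """Fully parameterized species model, ready to integrate."""

    physiology: SpeciesPhysiology
    chem: ChemicalProperties
    partitions: PartitionSet
    ka: float  # 1/h first-order absorption
    metabolism: Mapping[str, MetabolismTerm]  # liver_microsomes/liver_cytosol/plasma
    renal_clearance: float  # L/h on unbound venous blood
    bcp_submodel: BCPSubmodel | None = None

    def __post_init__(self) -> None:
        if not self.ka > 0:
            raise ConfigError(f"ka must be > 0, got {self.ka}")
        for key in ("liver_microsomes", "liver_cytosol", "plasma"):
            if key not in self.metabolism:
                raise ConfigError(f"metabolism term {key!r} missing")
        missing = [c for c in COMPARTMENTS if c not in self.partitions.kp]
        if missing:
            raise ConfigError(f"compartment(s) lacking Kp: {', '.join(missing)}")

    def replace(self, **kwargs) -> "PBKModelSpec":
        current = {
            "physiology": self.physiology,
            "chem": self.chem,
            "partitions": self.partitions,
            "ka": self.ka,
            "metabolism": self.metabolism,
            "renal_clearance": self.renal_clearance,
            "bcp_submodel": self.bcp_submodel,
        }
        current.update(kwargs)
        return PBKModelSpec(**current)


@dataclass
class SimulationResult:
    """Time courses of amounts/concentrations plus derived dose metrics."""

    time: np.ndarray  # h
    amounts: dict  # name -> umol array (compartments + lumen + sinks)
    concentrations: dict  # compartment -> uM array
    dose_umol: float
    fup: float
    mass_balance: np.ndarray  # (body + lumen + eliminated) / dose
    _dense: object = field(default=None, repr=False)
    _ven_index: int = field(default=0, repr=False)

    def venous_concentration(self, t: float) -> float:
        if self._dense is None:
            raise SimulationError("dense output not available")
        v_ven = self.amounts_volume
        return float(self._dense(t)[self._ven_index]) / v_ven

    amounts_volume: float = 1.0  # venous blood volume, set by simulate

    @property
    def auc_venous(self) -> float:
        """AUC of total venous blood concentration over the horizon, uM*h."""
        return float(np.trapezoid(self.concentrations["venous_blood"], self.time))


def _scaled_metabolism(
    species: str,
    invitro: Mapping[str, Mapping[str, float]],
    sf: ScalingFactors,
) -> dict[str, MetabolismTerm]:
    terms = {}
    for matrix in ("liver_microsomes", "liver_cytosol", "plasma"):
        p = invitro[matrix]
        terms[matrix] = MetabolismTerm(
            vmax=scale_vmax_to_in_vivo(p["Vmax"], matrix, sf),
            km=in_vivo_km(p["Km"], matrix, sf),
        )
    return terms


def _default_invitro() -> dict:
    path = importlib.resources.files("profenofos_pbk.data").joinpath(
        "invitro_kinetics.yaml"
    )
    return yaml.safe_load(path.read_text())


def build_model(
    physiology: SpeciesPhysiology,
    chem: ChemicalProperties,
    partitions: PartitionSet,
    metabolism: Mapping[str, MetabolismTerm],
    ka: float | None = None,
    renal_clearance: float | None = None,
    bcp_submodel: BCPSubmodel | None = None,
) -> PBKModelSpec:
    """Assemble a validated model spec (ka defaults to 1 h^-1)."""
    return PBKModelSpec(
        physiology=physiology,
        chem=chem,
        partitions=partitions,
        ka=1.0 if ka is None else ka,
        metabolism=dict(metabolism),
        renal_clearance=(
            physiology.renal_clearance if renal_clearance is None else renal_clearance
        ),
        bcp_submodel=bcp_submodel,
    )


def default_bcp_submodel(physiology: SpeciesPhysiology) -> BCPSubmodel:
    """BCP/BCP-glucuronide sub-model from packaged defaults."""
    chem_bcp = default_chemical("bcp")
    kp_bcp = resolve_partitions(default_chemical_config("bcp"), chem_bcp)
    chem_glu = default_chemical("bcp_glucuronide")
    kp_glu = estimate_partition_coefficients(chem_glu)
    v_glu = physiology.blood_volume + sum(
        physiology.tissue_volumes[t] * kp_glu[t]
        for t in COMPARTMENTS
        if t not in ("venous_blood", "arterial_blood")
    )
    gluc = _default_invitro()["bcp_glucuronidation"]
    return BCPSubmodel(
        chem=chem_bcp,
        partitions=kp_bcp,
        glucuronidation=MetabolismTerm(
            vmax=scale_vmax_to_in_vivo(gluc["Vmax"], "liver_microsomes"),
            km=gluc["Km"],
        ),
        glucuronide_fup=chem_glu.fup,
        glucuronide_volume=v_glu,
    )


def default_model(
    species: str,
    with_bcp: bool | None = None,
    sf: ScalingFactors | None = None,
) -> PBKModelSpec:
    """Species model from packaged physiology, chemistry and kinetics.

    The BCP evaluation sub-model is attached for rat by default (it exists
    to allow evaluation against in vivo rat excretion data) and omitted
    for human.
    """
    sf = sf or ScalingFactors()
    phys = default_physiology(species)
    chem = default_chemical("profenofos")
    partitions = resolve_partitions(default_chemical_config("profenofos"), chem)
    metabolism = _scaled_metabolism(species, _default_invitro()[species], sf)
    if with_bcp is None:
        with_bcp = species == "rat"
    bcp = default_bcp_submodel(phys) if with_bcp else None
    return build_model(phys, chem, partitions, metabolism, bcp_submodel=bcp)


# ---------------------------------------------------------------------------
# integration

def _rhs_factory(model: PBKModelSpec):
    phys = model.physiology
    vol = np.array([phys.tissue_volumes[c] for c in COMPARTMENTS])
    kp = np.array([model.partitions[c] for c in COMPARTMENTS])
    idx = {c: i for i, c in enumerate(COMPARTMENTS)}
    q = {t: phys.blood_flows[t] for t in PERFUSED_TISSUES}
    qc = phys.cardiac_output
    q_liver_total = phys.liver_blood_flow
    fup = model.chem.fup
    ka = model.ka
    clr = model.renal_clearance

    v_liver_kg = phys.tissue_volumes["liver"]  # density 1 g/ml -> kg
    v_blood_kg = phys.blood_volume
    mic = model.metabolism["liver_microsomes"]
    cyt = model.metabolism["liver_cytosol"]
    pla = model.metabolism["plasma"]
    vmax_mic = mic.vmax * v_liver_kg
    vmax_cyt = cyt.vmax * v_liver_kg
    vmax_blood = pla.vmax * v_blood_kg
    sh_ven = phys.tissue_volumes["venous_blood"] / v_blood_kg
    sh_art = 1.0 - sh_ven

    i_li, i_lu, i_ven, i_art = idx["liver"], idx["lung"], idx["venous_blood"], idx["arterial_blood"]

    bcp = model.bcp_submodel
    if bcp is not None:
        kp_b = np.array([bcp.partitions[c] for c in COMPARTMENTS])
        fup_b = bcp.chem.fup
        vmax_glu = bcp.glucuronidation.vmax * v_liver_kg
        km_glu = bcp.glucuronidation.km

    n_parent = 1 + len(COMPARTMENTS) + 3  # lumen + compartments + urine + 2 met sinks
    n_total = n_parent + (len(COMPARTMENTS) + 2 if bcp is not None else 0)

    def species_fluxes(a, kp_vec):
        """Flow-limited transport fluxes for one chemical species."""
        conc = a / vol
        cv = conc / kp_vec  # venous-equilibrium concentration per tissue
        c_art = conc[i_art]
        dc = np.zeros(len(COMPARTMENTS))
        # plain perfused tissues
        for t in NONPORTAL_TISSUES:
            i = idx[t]
            dc[i] = q[t] * (c_art - cv[i])
        for t in PORTAL_TISSUES:
            i = idx[t]
            dc[i] = q[t] * (c_art - cv[i])
        # liver: hepatic artery + portal effluents in, pooled flow out
        portal_in = sum(q[t] * cv[idx[t]] for t in PORTAL_TISSUES)
        dc[i_li] = q["liver"] * c_art + portal_in - q_liver_total * cv[i_li]
        # venous pool collects everything except portal tissues
        dc[i_ven] = (
            sum(q[t] * cv[idx[t]] for t in NONPORTAL_TISSUES)
            + q_liver_total * cv[i_li]
            - qc * conc[i_ven]
        )
        dc[i_lu] = qc * conc[i_ven] - qc * cv[i_lu]
        dc[i_art] = qc * cv[i_lu] - qc * c_art
        return conc, cv, dc

    def rhs(t, y):
        dy = np.zeros(n_total)
        a_lumen = y[0]
        a = y[1 : 1 + len(COMPARTMENTS)]
        conc, cv, dc = species_fluxes(a, kp)
        # absorption: lumen -> liver
        dy[0] = -ka * a_lumen
        dc[i_li] += ka * a_lumen
        # liver metabolism on unbound liver venous concentration
        cu_li = fup * cv[i_li]
        r_mic = vmax_mic * cu_li / (mic.km + cu_li)
        r_cyt = vmax_cyt * cu_li / (cyt.km + cu_li)
        dc[i_li] -= r_mic + r_cyt
        # blood metabolism on unbound blood concentration, volume-weighted
        cu_ven = fup * conc[i_ven]
        cu_art = fup * conc[i_art]
        r_bl_ven = vmax_blood * sh_ven * cu_ven / (pla.km + cu_ven)
        r_bl_art = vmax_blood * sh_art * cu_art / (pla.km + cu_art)
        dc[i_ven] -= r_bl_ven
        dc[i_art] -= r_bl_art
        # renal filtration of unbound venous blood
        r_renal = clr * fup * conc[i_ven]
        dc[i_ven] -= r_renal
        dy[1 : 1 + len(COMPARTMENTS)] = dc
        dy[1 + len(COMPARTMENTS)] = r_renal  # urine (parent)
        dy[2 + len(COMPARTMENTS)] = r_mic + r_cyt  # liver-metabolized sink
        dy[3 + len(COMPARTMENTS)] = r_bl_ven + r_bl_art  # blood-metabolized sink
        if bcp is not None:
            ab = y[n_parent : n_parent + len(COMPARTMENTS)]
            conc_b, cv_b, dcb = species_fluxes(ab, kp_b)
            # formation mole-for-mole where parent is metabolized
            dcb[i_li] += r_mic + r_cyt
            dcb[i_ven] += r_bl_ven
            dcb[i_art] += r_bl_art
            # hepatic glucuronidation, the only BCP elimination route
            cu_b = fup_b * cv_b[i_li]
            r_glu = vmax_glu * cu_b / (km_glu + cu_b)
            dcb[i_li] -= r_glu
            dy[n_parent : n_parent + len(COMPARTMENTS)] = dcb
            # conjugate: central volume, filtered to urine
            a_glu = y[n_parent + len(COMPARTMENTS)]
            c_glu = a_glu / bcp.glucuronide_volume
            r_glu_renal = clr * bcp.glucuronide_fup * c_glu
            dy[n_parent + len(COMPARTMENTS)] = r_glu - r_glu_renal
            dy[n_parent + len(COMPARTMENTS) + 1] = r_glu_renal
        return dy

    return rhs, n_parent, n_total


def dose_to_umol(model: PBKModelSpec, oral_dose_mg_per_kg: float) -> float:
    """Convert an oral dose in mg/kg bw to umol for this species."""
    dose_mg = oral_dose_mg_per_kg * model.physiology.body_weight
    return dose_mg / model.chem.molecular_weight * 1000.0


def simulate(
    model: PBKModelSpec,
    oral_dose: float,
    duration: float = 24.0,
    n_points: int = 481,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the model for a single oral bolus dose (mg/kg bw)."""
    if oral_dose < 0:
        raise ValueError("dose must be >= 0")
    if not duration > 0:
        raise ValueError("duration must be > 0")
    rhs, n_parent, n_total = _rhs_factory(model)
    dose_umol = dose_to_umol(model, oral_dose)
    y0 = np.zeros(n_total)
    y0[0] = dose_umol
    t_eval = np.linspace(0.0, duration, n_points)
    sol = solve_ivp(
        rhs,
        (0.0, duration),
        y0,
        method=method,
        t_eval=t_eval,
        dense_output=True,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(
            f"solver failed: {sol.message}; final state norm "
            f"{np.linalg.norm(sol.y[:, -1]):.3g}"
        )
    amounts = {"gut_lumen": sol.y[0]}
    concentrations = {}
    for i, c in enumerate(COMPARTMENTS):
        amounts[c] = sol.y[1 + i]
        concentrations[c] = sol.y[1 + i] / model.physiology.tissue_volumes[c]
    amounts["urine"] = sol.y[1 + len(COMPARTMENTS)]
    amounts["metabolized_liver"] = sol.y[2 + len(COMPARTMENTS)]
    amounts["metabolized_blood"] = sol.y[3 + len(COMPARTMENTS)]
    if model.bcp_submodel is not None:
        for i, c in enumerate(COMPARTMENTS):
            amounts[f"bcp_{c}"] = sol.y[n_parent + i]
        amounts["bcp_glucuronide"] = sol.y[n_parent + len(COMPARTMENTS)]
        amounts["bcp_glucuronide_urine"] = sol.y[n_parent + len(COMPARTMENTS) + 1]
    body = sum(amounts[c] for c in COMPARTMENTS)
    recovered = (
        body
        + amounts["gut_lumen"]
        + amounts["urine"]
        + amounts["metabolized_liver"]
        + amounts["metabolized_blood"]
    )
    balance = recovered / dose_umol if dose_umol > 0 else np.ones_like(sol.t)
    result = SimulationResult(
        time=sol.t,
        amounts=amounts,
        concentrations=concentrations,
        dose_umol=dose_umol,
        fup=model.chem.fup,
        mass_balance=balance,
        _dense=sol.sol,
        _ven_index=1 + COMPARTMENTS.index("venous_blood"),
    )
    result.amounts_volume = model.physiology.tissue_volumes["venous_blood"]
    return result


def unbound_cmax(result: SimulationResult, chem: ChemicalProperties | None = None) -> float:
    """Peak unbound (free) venous blood concentration, uM.

    fup x max venous concentration, with the grid maximum refined by a
    local search on the dense solver output.
    """
    fup = chem.fup if chem is not None else result.fup
    c_ven = result.concentrations["venous_blood"]
    i_max = int(np.argmax(c_ven))
    peak = c_ven[i_max]
    if result._dense is not None and 0 < i_max < len(result.time) - 1:
        lo, hi = result.time[i_max - 1], result.time[i_max + 1]
        res = minimize_scalar(
            lambda t: -result.venous_concentration(t),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6 * max(hi, 1.0)},
        )
        peak = max(peak, -res.fun)
    return fup * float(peak)


@dataclass(frozen=True)
class DoseCmaxMap:
    """Strictly increasing oral-dose -> unbound-Cmax mapping with interpolator."""

    doses: np.ndarray  # mg/kg bw, sorted
    cmax_unbound: np.ndarray  # uM
    _interp: PchipInterpolator = field(repr=False)
    _inverse: PchipInterpolator = field(repr=False)

    def cmax(self, dose: float) -> float:
        return float(np.exp(self._interp(np.log(dose))))

    def dose(self, cmax_u: float) -> float:
        if not (self.cmax_unbound[0] <= cmax_u <= self.cmax_unbound[-1]):
            raise ValueError(
                f"unbound Cmax {cmax_u:.3g} uM outside mapped range "
                f"[{self.cmax_unbound[0]:.3g}, {self.cmax_unbound[-1]:.3g}]; "
                "extend the dose grid"
            )
        return float(np.exp(self._inverse(np.log(cmax_u))))


def dose_to_cmax_map(
    model: PBKModelSpec,
    dose_grid: Sequence[float],
    duration: float = 24.0,
    **sim_kwargs,
) -> DoseCmaxMap:
    """Simulate a sorted dose grid and return the monotone Cmax map."""
    doses = np.asarray(dose_grid, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    if np.any(np.diff(doses) <= 0):
        raise ValueError("dose grid must be strictly increasing")
    cm = np.array(
        [unbound_cmax(simulate(model, d, duration=duration, **sim_kwargs)) for d in doses]
    )
    if np.any(np.diff(cm) <= 0):
        raise SimulationError(
            "simulated unbound Cmax values are not strictly increasing; "
            "tighten solver tolerances"
        )
    log_d, log_c = np.log(doses), np.log(cm)
    return DoseCmaxMap(
        doses=doses,
        cmax_unbound=cm,
        _interp=PchipInterpolator(log_d, log_c),
        _inverse=PchipInterpolator(log_c, log_d),
    )


def simulate_urinary_excretion(
    model: PBKModelSpec,
    oral_dose: float,
    duration: float = 120.0,
    **sim_kwargs,
):
    """Cumulative urinary BCP-glucuronide excretion, % of molar dose vs h."""
    if model.bcp_submodel is None:
        raise ConfigError("urinary-excretion simulation requires the BCP sub-model")
    result = simulate(model, oral_dose, duration=duration, **sim_kwargs)
    if result.dose_umol > 0:
        pct = 100.0 * result.amounts["bcp_glucuronide_urine"] / result.dose_umol
    else:
        pct = np.zeros_like(result.time)
    return result.time, pct, result
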