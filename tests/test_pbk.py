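"""Whole-body PBK engine: conservation, limits, dose metrics, BCP sub-model."""

import numpy as np
import pytest

from profenofos_pbk import (
    ConfigError,
    MetabolismTerm,
    build_model,
    default_model,
    dose_to_cmax_map,
    simulate,
    simulate_urinary_excretion,
    unbound_cmax,
)
from profenofos_pbk.partition import PartitionSet
from profenofos_pbk.pbk import SimulationError, dose_to_umol


def _no_elimination(model):
    met = {k: MetabolismTerm(vmax=0.0, km=v.km) for k, v in model.metabolism.items()}
    return model.replace(metabolism=met, renal_clearance=1e-12)


def _metabolism_off(model):
    met = {k: MetabolismTerm(vmax=0.0, km=v.km) for k, v in model.metabolism.items()}
    return model.replace(metabolism=met)


def test_ka_defaults_to_one_per_hour(rat_model):
    m = build_model(
        rat_model.physiology,
        rat_model.chem,
        rat_model.partitions,
        rat_model.metabolism,
    )
    assert m.ka == 1.0


def test_missing_kp_rejected(rat_model):
    kp = {t: v for t, v in rat_model.partitions.kp.items() if t != "brain"}
    with pytest.raises(ConfigError, match="brain"):
        build_model(
            rat_model.physiology,
            rat_model.chem,
            PartitionSet(kp=kp, provenance={t: "estimated" for t in kp}),
            rat_model.metabolism,
        )


def test_zero_dose_all_states_zero(rat_model):
    res = simulate(rat_model, 0.0, duration=4.0)
    for name, arr in res.amounts.items():
        assert np.allclose(arr, 0.0, atol=1e-12), name


def test_conservation_without_elimination(rat_model):
    res = simulate(_no_elimination(rat_model), 1.0, duration=24.0)
    body_plus_lumen = res.amounts["gut_lumen"] + sum(
        res.amounts[c] for c in rat_model.partitions.kp
    )
    assert np.allclose(body_plus_lumen, res.dose_umol, rtol=1e-3)


@pytest.mark.parametrize("dose", [1e-4, 1e-1, 10.0, 1e3])
def test_mass_balance_within_point1_percent(rat_model, dose):
    res = simulate(rat_model, dose, duration=24.0)
    assert res.mass_balance.min() > 0.999
    assert res.mass_balance.max() < 1.001


def test_dose_conversion_to_micromol(rat_model):
    # 0.45 mg/kg x 0.25 kg / 373.63 g/mol
    assert dose_to_umol(rat_model, 0.45) == pytest.approx(0.3011, rel=1e-3)


def test_unbound_cmax_scales_with_fup(rat_model):
    import dataclasses

    res = simulate(rat_model, 1.0)
    cu = unbound_cmax(res)
    assert cu > 0
    total = unbound_cmax(res, dataclasses.replace(rat_model.chem, fup=1.0))
    # fup = 1 recovers the total venous peak; unbound never exceeds total
    assert cu == pytest.approx(rat_model.chem.fup * total, rel=1e-9)
    assert cu <= total


def test_unbound_cmax_refinement_at_least_grid_peak(rat_model):
    res = simulate(rat_model, 1.0, n_points=25)  # coarse grid
    grid_peak = rat_model.chem.fup * max(res.concentrations["venous_blood"])
    assert unbound_cmax(res) >= grid_peak


def test_terminal_decline_matches_one_compartment_limit(rat_model):
    """Metabolism off, renal only: log-linear slope ~ CL*fup/Vss within 5%."""
    model = _metabolism_off(rat_model)
    res = simulate(model, 1.0, duration=2000.0, n_points=1001)
    c = res.concentrations["venous_blood"]
    mask = res.time > 500
    slope = np.polyfit(res.time[mask], np.log(c[mask]), 1)[0]
    vss = sum(
        model.physiology.tissue_volumes[t] * model.partitions[t]
        for t in model.partitions.kp
    )
    expected = -model.renal_clearance * model.chem.fup / vss
    assert slope == pytest.approx(expected, rel=0.05)


def test_tolerance_convergence_of_unbound_cmax(rat_model):
    base = unbound_cmax(simulate(rat_model, 1.0, rtol=1e-8, atol=1e-10))
    tight = unbound_cmax(simulate(rat_model, 1.0, rtol=5e-9, atol=5e-11))
    assert abs(tight - base) / base < 1e-3


class TestDoseCmaxMap:
    def test_monotone(self, rat_cmax_map):
        assert np.all(np.diff(rat_cmax_map.cmax_unbound) > 0)
        assert rat_cmax_map.cmax(2.0) >= rat_cmax_map.cmax(1.0)

    def test_low_dose_linearity(self, rat_model):
        doses = np.array([1e-4, 2e-4, 5e-4, 1e-3])
        m = dose_to_cmax_map(rat_model, doses)
        ratios = m.cmax_unbound / doses
        assert ratios.max() / ratios.min() < 1.02

    def test_high_dose_supralinear(self, rat_model):
        """Saturating clearance makes Cmax grow faster than dose at high dose."""
        lo = dose_to_cmax_map(rat_model, np.array([1e-4, 1e-3]))
        hi = dose_to_cmax_map(rat_model, np.array([300.0, 3000.0]))
        slope_lo = np.log(lo.cmax_unbound[1] / lo.cmax_unbound[0]) / np.log(10.0)
        slope_hi = np.log(hi.cmax_unbound[1] / hi.cmax_unbound[0]) / np.log(10.0)
        assert slope_hi > slope_lo * 1.02

    def test_unsorted_grid_rejected(self, rat_model):
        with pytest.raises(ValueError):
            dose_to_cmax_map(rat_model, [1.0, 0.5])


class TestBCPSubmodel:
    def test_requires_submodel(self, rat_model):
        with pytest.raises(ConfigError, match="BCP"):
            simulate_urinary_excretion(rat_model, 35.8)

    def test_zero_dose_all_zero(self, rat_model_bcp):
        t, pct, _ = simulate_urinary_excretion(rat_model_bcp, 0.0, duration=24.0)
        assert np.allclose(pct, 0.0)

    def test_cumulative_nondecreasing_and_bounded(self, rat_model_bcp):
        t, pct, _ = simulate_urinary_excretion(rat_model_bcp, 35.8, duration=120.0)
        assert np.all(np.diff(pct) >= -1e-9)
        assert pct[-1] <= 100.0 + 1e-6
        # approaches a plateau: last 10% of the horizon adds little
        assert pct[-1] - np.interp(108.0, t, pct) < 2.0

    def test_plateau_equals_fraction_metabolized(self, rat_model_bcp):
        """Glucuronidation is BCP's only exit, so late-time urinary conjugate
        recovers the total fraction of parent metabolized."""
        t, pct, res = simulate_urinary_excretion(rat_model_bcp, 35.8, duration=400.0)
        metabolized = (
            res.amounts["metabolized_liver"][-1] + res.amounts["metabolized_blood"][-1]
        )
        assert pct[-1] / 100.0 == pytest.approx(metabolized / res.dose_umol, abs=0.01)

    def test_human_default_has_no_bcp(self, human_model):
        assert human_model.bcp_submodel is None
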