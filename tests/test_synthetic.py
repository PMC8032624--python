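"""Synthetic-data generators: purity, noise structure, design checks."""

import numpy as np
import pytest

from profenofos_pbk import (
    NoiseModel,
    gen_incubation_data,
    gen_inhibition_data,
    gen_urinary_dataset,
    michaelis_menten_rate,
)
from profenofos_pbk.ache import logistic_activity
from profenofos_pbk.synthetic import default_inhibition_grid


class TestIncubationGenerator:
    def test_zero_cv_lies_exactly_on_curve(self):
        d = gen_incubation_data(6.9, 1.2, noise=NoiseModel(cv=0.0, seed=9))
        expected = michaelis_menten_rate(d.concentration_uM, 6.9, 1.2)
        assert np.allclose(d.rate_nmol_min_mg, expected)

    def test_seed_reproducibility(self):
        a = gen_incubation_data(6.9, 1.2, noise=NoiseModel(cv=0.05, seed=11))
        b = gen_incubation_data(6.9, 1.2, noise=NoiseModel(cv=0.05, seed=11))
        assert np.array_equal(a.rate_nmol_min_mg, b.rate_nmol_min_mg)
        c = gen_incubation_data(6.9, 1.2, noise=NoiseModel(cv=0.05, seed=12))
        assert not np.array_equal(a.rate_nmol_min_mg, c.rate_nmol_min_mg)

    def test_replicate_mean_converges_to_curve(self):
        """Law of large numbers at n = 10^4 replicates."""
        d = gen_incubation_data(
            6.9, 1.2, concentrations=[5.0], noise=NoiseModel(cv=0.05, replicates=10_000, seed=2)
        )
        assert d.rate_nmol_min_mg.mean() == pytest.approx(
            michaelis_menten_rate(5.0, 6.9, 1.2), rel=0.01
        )

    def test_rates_truncated_at_zero(self):
        d = gen_incubation_data(6.9, 0.01, noise=NoiseModel(cv=2.0, replicates=50, seed=3))
        assert np.all(d.rate_nmol_min_mg >= 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gen_incubation_data(-1.0, 1.2)


class TestInhibitionGenerator:
    def test_zero_noise_at_ic50_gives_50(self):
        d = gen_inhibition_data(
            302.0, concentrations=[302.0], noise=NoiseModel(kind="additive", sd=0.0)
        )
        assert np.allclose(d.activity_pct, 50.0)

    def test_seed_reproducibility(self):
        a = gen_inhibition_data(302.0, noise=NoiseModel(kind="additive", sd=3.0, seed=4))
        b = gen_inhibition_data(302.0, noise=NoiseModel(kind="additive", sd=3.0, seed=4))
        assert np.array_equal(a.activity_pct, b.activity_pct)

    def test_default_grid_spans_transition(self):
        """8-point default grid centered on the IC50 reaches <10% and >90%."""
        grid = default_inhibition_grid(302.0)
        assert len(grid) == 8
        act = logistic_activity(np.log10(grid), np.log10(302.0))
        assert act.min() < 10.0
        assert act.max() > 90.0

    def test_activities_clipped(self):
        d = gen_inhibition_data(
            302.0, noise=NoiseModel(kind="additive", sd=50.0, replicates=10, seed=5)
        )
        assert d.activity_pct.min() >= 0.0
        assert d.activity_pct.max() <= 120.0


def test_end_to_end_parameter_recovery(rat_model, rat_cmax_map):
    """Full-pipeline self-consistency: a BMDL10 computed from noisy synthetic
    inhibition data stays within 25% of the BMDL10 from the noise-free
    generating parameters."""
    from profenofos_pbk import bmd_analysis, fit_ic50, predict_dose_response

    conc = np.logspace(np.log10(312.0) - 2.0, np.log10(312.0) + 0.8, 14)
    bmdl = {}
    for label, sd in (("clean", 0.0), ("noisy", 3.0)):
        data = gen_inhibition_data(
            312.0, noise=NoiseModel(kind="additive", sd=sd, seed=20210302)
        )
        curve = predict_dose_response(
            rat_model, fit_ic50(data), conc_grid_nM=conc, cmax_map=rat_cmax_map
        )
        bmdl[label] = bmd_analysis(curve, n_boot=100, seed=1).bmdl
    assert bmdl["noisy"] == pytest.approx(bmdl["clean"], rel=0.25)


class TestUrinaryGenerator:
    def test_zero_noise_matches_simulation(self, rat_model_bcp):
        from profenofos_pbk import simulate_urinary_excretion

        timepoints = np.array([6.0, 12.0, 24.0, 48.0, 96.0])
        df = gen_urinary_dataset(
            rat_model_bcp,
            35.8,
            timepoints=timepoints,
            noise=NoiseModel(kind="additive", sd=0.0, replicates=1),
        )
        t, pct, _ = simulate_urinary_excretion(rat_model_bcp, 35.8, duration=96.0)
        expected = np.interp(timepoints, t, pct)
        assert np.allclose(df["cumulative_pct_dose"].to_numpy(), expected, rtol=1e-3)

    def test_noisy_output_isotonic_and_bounded(self, rat_model_bcp):
        df = gen_urinary_dataset(
            rat_model_bcp,
            35.8,
            timepoints=np.linspace(4.0, 120.0, 15),
            noise=NoiseModel(kind="additive", sd=4.0, replicates=3, seed=6),
        )
        for _, g in df.groupby("replicate"):
            y = g["cumulative_pct_dose"].to_numpy()
            assert np.all(np.diff(y) >= 0)
            assert y[-1] <= 100.0
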