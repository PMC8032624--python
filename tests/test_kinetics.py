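"""Michaelis-Menten fitting, catalytic efficiency, and in vivo scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from profenofos_pbk import (
    FitError,
    IncubationDataset,
    ScalingFactors,
    catalytic_efficiency,
    fit_michaelis_menten,
    gen_incubation_data,
    in_vivo_km,
    michaelis_menten_rate,
    scale_vmax_to_in_vivo,
)
from profenofos_pbk.synthetic import NoiseModel

#: measured (Km uM, Vmax nmol/min/mg) per species and matrix
MEASURED = {
    ("human", "liver_microsomes"): (6.9, 1.2),
    ("human", "liver_cytosol"): (1.4, 1.1),
    ("human", "plasma"): (158.0, 0.99),
    ("rat", "liver_microsomes"): (8.1, 8.9),
    ("rat", "liver_cytosol"): (0.34, 0.95),
    ("rat", "plasma"): (3.6, 0.68),
}


class TestMichaelisMentenRate:
    def test_half_saturation_midpoint(self):
        assert michaelis_menten_rate(6.9, 6.9, 1.2) == pytest.approx(0.6)

    def test_zero_substrate(self):
        assert michaelis_menten_rate(0.0, 6.9, 1.2) == 0.0

    def test_direct_arithmetic_value(self):
        # 1.2 * 100 / (6.9 + 100)
        assert michaelis_menten_rate(100.0, 6.9, 1.2) == pytest.approx(
            1.1225444340505145, rel=1e-12
        )

    def test_negative_substrate_rejected(self):
        with pytest.raises(ValueError):
            michaelis_menten_rate(-1.0, 6.9, 1.2)

    @given(
        s=st.floats(0.0, 1e6),
        km=st.floats(1e-3, 1e4),
        vmax=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=50, deadline=None)
    def test_rate_bounded_below_vmax(self, s, km, vmax):
        v = michaelis_menten_rate(s, km, vmax)
        assert 0.0 <= v < vmax


class TestFit:
    def test_noiseless_recovery_four_significant_digits(self):
        data = gen_incubation_data(6.9, 1.2, noise=NoiseModel(cv=0.0, seed=1))
        fit = fit_michaelis_menten(data)
        assert fit.Km == pytest.approx(6.9, rel=1e-4)
        assert fit.Vmax == pytest.approx(1.2, rel=1e-4)
        assert fit.converged

    def test_noisy_rat_plasma_recovery_within_15pct(self):
        km, vmax = MEASURED[("rat", "plasma")]
        data = gen_incubation_data(km, vmax, noise=NoiseModel(cv=0.05, seed=20210302))
        fit = fit_michaelis_menten(data)
        assert fit.Km == pytest.approx(km, rel=0.15)
        assert fit.Vmax == pytest.approx(vmax, rel=0.15)

    def test_all_zero_rates_error(self):
        data = IncubationDataset(
            matrix="plasma",
            species="rat",
            concentration_uM=np.array([1.0, 5.0, 20.0, 100.0]),
            rate_nmol_min_mg=np.zeros(4),
            replicate=np.ones(4),
        )
        with pytest.raises(FitError, match="zero"):
            fit_michaelis_menten(data)

    def test_too_few_concentrations_error(self):
        data = IncubationDataset(
            matrix="plasma",
            species="rat",
            concentration_uM=np.array([1.0, 5.0, 20.0]),
            rate_nmol_min_mg=np.array([0.1, 0.3, 0.5]),
            replicate=np.ones(3),
        )
        with pytest.raises(FitError, match="4 distinct"):
            fit_michaelis_menten(data)

    @pytest.mark.parametrize("cv", [0.02, 0.005])
    def test_parameter_error_shrinks_with_noise(self, cv):
        """Mean |error| at lower CV is below the error at 5% CV (consistency)."""
        errs = {}
        for c in (0.05, cv):
            e = []
            for seed in range(5):
                data = gen_incubation_data(3.6, 0.68, noise=NoiseModel(cv=c, seed=seed))
                fit = fit_michaelis_menten(data)
                e.append(abs(fit.Km - 3.6) / 3.6)
            errs[c] = np.mean(e)
        assert errs[cv] < errs[0.05]


class TestCatalyticEfficiency:
    @pytest.mark.parametrize(
        "species, matrix, printed",
        [
            ("human", "liver_microsomes", 0.17),
            ("rat", "liver_microsomes", 1.1),
            ("human", "liver_cytosol", 0.79),
            ("rat", "liver_cytosol", 2.8),
            ("human", "plasma", 0.0063),
            ("rat", "plasma", 0.19),
        ],
    )
    def test_measured_pairs_reproduce_2sf_values(self, species, matrix, printed):
        km, vmax = MEASURED[(species, matrix)]
        eff = vmax / km
        assert float(f"{eff:.2g}") == pytest.approx(printed)

    def test_identity_with_fit_object(self):
        data = gen_incubation_data(6.9, 1.2, noise=NoiseModel(cv=0.0, seed=1))
        fit = fit_michaelis_menten(data)
        assert catalytic_efficiency(fit) == fit.Vmax / fit.Km

    def test_zero_vmax_gives_zero(self):
        fit = fit_michaelis_menten(
            gen_incubation_data(6.9, 1.2, noise=NoiseModel(cv=0.0, seed=1))
        )
        assert catalytic_efficiency(type(fit)(
            Km=fit.Km, Vmax=0.0, Km_se=0.0, Vmax_se=0.0, converged=True,
            residuals=fit.residuals,
        )) == 0.0


class TestScaling:
    def test_human_microsomal_example(self):
        assert scale_vmax_to_in_vivo(1.2, "liver_microsomes") == pytest.approx(2520.0)

    def test_human_plasma_example(self):
        assert scale_vmax_to_in_vivo(0.99, "plasma") == pytest.approx(32670.0)

    def test_zero_vmax(self):
        assert scale_vmax_to_in_vivo(0.0, "liver_cytosol") == 0.0

    def test_unknown_matrix_rejected(self):
        with pytest.raises(ValueError, match="matrix"):
            scale_vmax_to_in_vivo(1.0, "kidney_homogenate")

    def test_in_vivo_km_unbound_correction(self):
        sf = ScalingFactors(fu_incubation={"liver_microsomes": 0.5,
                                           "liver_cytosol": 1.0,
                                           "plasma": 1.0})
        assert in_vivo_km(8.0, "liver_microsomes", sf) == pytest.approx(4.0)
        assert in_vivo_km(8.0, "plasma", sf) == pytest.approx(8.0)
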