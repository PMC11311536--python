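import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driftchem import (
    PKaPair,
    ThermoTriple,
    crossover_ph,
    ph_of_max_monoprotonated,
    pka_from_gibbs,
    proton_gaq_constant,
    speciation,
)
from driftchem.constants import R_KJ
from driftchem.synthetic import _thermo_from_pka

RT_LN10 = R_KJ * 298.15 * math.log(10.0)


class TestProtonConstant:
    def test_kcal_value(self):
        assert proton_gaq_constant("kcal") == 265.6

    def test_kj_value_printed_rounding(self):
        assert proton_gaq_constant("kJ") == 1111.27

    def test_exact_conversion_consistency(self):
        assert round(265.6 * 4.184, 2) == proton_gaq_constant("kJ")

    def test_unknown_unit(self):
        with pytest.raises(ValueError):
            proton_gaq_constant("eV")


class TestPkaFromGibbs:
    def test_zero_deprotonation_energy_gives_zero(self):
        # G difference exactly cancels the aqueous proton free energy
        assert pka_from_gibbs(1111.27, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_unit_step_is_rt_ln10(self):
        assert pka_from_gibbs(1111.27 + RT_LN10, 0.0) == pytest.approx(1.0)

    def test_weak_base_scale(self):
        # hand value: (1154.137 − 1111.27) / (RT ln10) ≈ 7.51
        assert pka_from_gibbs(1154.137, 0.0) == pytest.approx(7.51, abs=0.005)

    def test_linear_in_g_difference(self):
        p1 = pka_from_gibbs(1120.0, 0.0)
        p2 = pka_from_gibbs(1130.0, 10.0)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_planted_pka_recovery_over_random_values(self):
        """Generating G values from a planted pKa and inverting reproduces
        it to 1e-10 across 1000 random pKa pairs in [-10, 15]."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            pka1, pka2 = sorted(rng.uniform(-10.0, 15.0, size=2))
            triple = _thermo_from_pka("T", pka1, pka2, 298.15)
            pair = triple.pka_pair()
            assert pair.pka1 == pytest.approx(pka1, abs=1e-10)
            assert pair.pka2 == pytest.approx(pka2, abs=1e-10)


class TestSpeciation:
    @given(
        pka1=st.floats(-10, 15),
        pka2=st.floats(-10, 15),
    )
    @settings(deadline=None, max_examples=60)
    def test_fractions_sum_to_one(self, pka1, pka2):
        curve = speciation(PKaPair(pka1, pka2), np.linspace(0, 14, 57))
        total = curve.alpha_MH2 + curve.alpha_MH + curve.alpha_M
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_symmetric_case_equal_thirds(self):
        curve = speciation(PKaPair(7.0, 7.0), [7.0])
        for a in (curve.alpha_MH2, curve.alpha_MH, curve.alpha_M):
            assert a[0] == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_crossover_identity_weak_diprotic_base(self):
        # at pH = pKa1 the dication and monocation are equally abundant
        curve = speciation(PKaPair(7.51, 12.34), [7.51])
        assert curve.alpha_MH2[0] == pytest.approx(curve.alpha_MH[0], rel=1e-12)

    def test_overflow_safe_extreme_negative_pka1(self):
        curve = speciation(PKaPair(-7.31, 7.96), np.linspace(0.0, 14.0, 141))
        assert np.all(np.isfinite(curve.alpha_MH2))
        total = curve.alpha_MH2 + curve.alpha_MH + curve.alpha_M
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_monotonicity_and_unimodality(self):
        ph = np.linspace(0, 14, 281)
        curve = speciation(PKaPair(4.0, 9.0), ph)
        assert np.all(np.diff(curve.alpha_MH2) <= 1e-15)
        assert np.all(np.diff(curve.alpha_M) >= -1e-15)
        d = np.diff(curve.alpha_MH)
        sign_changes = np.sum(np.diff(np.sign(d[np.abs(d) > 1e-15])) != 0)
        assert sign_changes <= 1


class TestCrossovers:
    def test_dication_monocation_crossover_is_pka1(self):
        assert crossover_ph(PKaPair(7.51, 12.34), "MH2-MH") == 7.51

    def test_monocation_neutral_crossover_is_pka2(self):
        assert crossover_ph(PKaPair(-7.31, 7.96), "MH-M") == 7.96

    def test_dication_neutral_crossover_is_mean(self):
        pair = PKaPair(3.0, 11.0)
        assert crossover_ph(pair, "MH2-M") == pytest.approx(
            0.5 * (crossover_ph(pair, "MH2-MH") + crossover_ph(pair, "MH-M"))
        )

    def test_unknown_pair_rejected(self):
        with pytest.raises(ValueError):
            crossover_ph(PKaPair(7.0, 8.0), "M-MH2")


class TestMaxMonoprotonated:
    def test_weak_diprotic_base_value(self):
        assert ph_of_max_monoprotonated(PKaPair(7.51, 12.34)) == pytest.approx(9.925)

    def test_symmetric_case(self):
        assert ph_of_max_monoprotonated(PKaPair(6.0, 6.0)) == 6.0

    def test_grid_search_agrees_with_analytic(self):
        pair = PKaPair(7.51, 12.34)
        ph = np.linspace(8.0, 12.0, 4_000_001)
        curve = speciation(pair, ph)
        ph_star = ph[np.argmax(curve.alpha_MH)]
        assert ph_star == pytest.approx(
            ph_of_max_monoprotonated(pair), abs=1e-6
        )


class TestThermoTriple:
    def test_missing_diprotonated_energy(self):
        t = ThermoTriple("M", 0.0, -1100.0)
        with pytest.raises(ValueError, match="pKa1"):
            t.pka_pair()

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            ThermoTriple("M", 0.0, -1100.0, temperature=0.0)
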