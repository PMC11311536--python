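import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from driftchem import (
    BufferGasModel,
    CandidateStructure,
    TMSettings,
    make_bead_molecule,
    nitrogen_gas,
    pa_ccs,
    spherical_ccs_oracle,
    tm_ccs,
)
from driftchem.constants import R_KJ
from tests.conftest import make_atom

# Ω⁽¹·¹⁾ for LJ(ε=0.5 kJ/mol, σ=3.5 Å) at 298 K, frozen from a one-off
# brute-force quadrature at 10x the default oracle resolution
# (n_energy=120, n_b=2400, n_theta=2000)
LJ_REFERENCE_OMEGA = 32.4934


def rotated(structure: CandidateStructure, seed=0) -> CandidateStructure:
    rot = Rotation.random(random_state=seed).as_matrix()
    shift = np.array([3.0, -2.0, 5.0])
    atoms = [
        make_atom(*(rot @ np.array(a.position) + shift), q=a.partial_charge,
                  eps=a.lj_epsilon, sigma=a.lj_sigma)
        for a in structure.atoms
    ]
    return CandidateStructure(structure.id, structure.molecule,
                              structure.charge_state, structure.site_label,
                              atoms)


class TestProjectionApproximation:
    def test_single_sphere_area(self, n2):
        # collision radius: 2^(1/6)σ/2 + gas radius; pick σ so it is 3 Å
        sigma = 2.0 * 3.0 / 2.0 ** (1.0 / 6.0)
        gas = BufferGasModel("g", 28.0, 298.0, ((0.0, 0.0, 0.3, 3.0),), 0.0)
        s = CandidateStructure("s", "M", 0, "none",
                               [make_atom(sigma=sigma)])
        res = pa_ccs(s, gas, n_samples=200_000, seed=1)
        assert abs(res.ccs - 9.0 * math.pi) < 3 * res.stderr

    def test_coincident_atoms_degenerate_union(self, n2):
        s1 = CandidateStructure("s", "M", 0, "none", [make_atom()])
        s2 = CandidateStructure("s", "M", 0, "none",
                                [make_atom(), make_atom()])
        r1 = pa_ccs(s1, n2, n_samples=100_000, seed=2)
        r2 = pa_ccs(s2, n2, n_samples=100_000, seed=3)
        assert abs(r1.ccs - r2.ccs) < 3 * math.hypot(r1.stderr, r2.stderr)

    def test_rotation_translation_invariance(self, n2):
        mol = make_bead_molecule(10, seed=5, structure_id="b", molecule="M")
        r1 = pa_ccs(mol, n2, n_samples=100_000, seed=4)
        r2 = pa_ccs(rotated(mol, seed=8), n2, n_samples=100_000, seed=9)
        assert abs(r1.ccs - r2.ccs) < 3 * math.hypot(r1.stderr, r2.stderr)

    def test_input_validation(self, n2):
        s = CandidateStructure("s", "M", 0, "none", [make_atom()])
        with pytest.raises(ValueError):
            pa_ccs(s, n2, n_samples=10)


class TestSphericalOracle:
    def test_hard_sphere_area(self):
        d = 4.0
        pot = lambda r: 1e12 if r < d else 0.0
        omega = spherical_ccs_oracle(pot, T=298.0, n_energy=4, n_b=2400)
        assert omega == pytest.approx(math.pi * d * d, rel=1e-4)

    def test_zero_potential_zero_cross_section(self):
        assert spherical_ccs_oracle(lambda r: 0.0, T=298.0) < 1e-10

    def test_lj_regression_value(self):
        pot = lambda r: 4 * 0.5 * ((3.5 / r) ** 12 - (3.5 / r) ** 6)
        omega = spherical_ccs_oracle(pot, T=298.0)
        assert omega == pytest.approx(LJ_REFERENCE_OMEGA, rel=2e-3)

    def test_takes_temperature_from_gas(self, single_site_gas):
        pot = lambda r: 4 * 0.5 * ((3.5 / r) ** 12 - (3.5 / r) ** 6)
        a = spherical_ccs_oracle(pot, gas=single_site_gas)
        b = spherical_ccs_oracle(pot, T=single_site_gas.temperature)
        assert a == pytest.approx(b, rel=1e-12)


class TestTrajectoryMethod:
    def test_two_seeds_agree_within_errors(self, single_site_gas, lone_atom_ion):
        st = dict(n_velocity_samples=8, n_impact_samples=60,
                  n_orientation_samples=10)
        r1 = tm_ccs(lone_atom_ion, single_site_gas, TMSettings(seed=1, **st))
        r2 = tm_ccs(lone_atom_ion, single_site_gas, TMSettings(seed=2, **st))
        assert abs(r1.ccs - r2.ccs) < 3 * math.hypot(r1.stderr, r2.stderr)

    def test_rotation_translation_invariance(self, n2):
        atoms = [make_atom(0, 0, 0, q=0.5), make_atom(2.5, 0, 0, q=0.3),
                 make_atom(0, 2.5, 0, q=0.2)]
        mol = CandidateStructure("m", "M", 1, "a", atoms)
        st = dict(n_velocity_samples=8, n_impact_samples=60,
                  n_orientation_samples=10)
        r1 = tm_ccs(mol, n2, TMSettings(seed=5, **st))
        r2 = tm_ccs(rotated(mol, seed=11), n2, TMSettings(seed=6, **st))
        assert abs(r1.ccs - r2.ccs) < 3 * math.hypot(r1.stderr, r2.stderr)

    def test_halving_samples_inflates_stderr_sqrt2(self, n2):
        """Halving the Monte-Carlo sample count inflates the reported
        standard error by ≈ √2 on average over 10 repeats."""
        mol = make_bead_molecule(8, seed=3, structure_id="b", molecule="M")
        ratios = []
        for seed in range(10):
            full = pa_ccs(mol, n2, n_samples=40_000, seed=seed)
            half = pa_ccs(mol, n2, n_samples=20_000, seed=seed + 100)
            ratios.append(half.stderr / full.stderr)
        mean_ratio = float(np.mean(ratios))
        assert abs(mean_ratio - math.sqrt(2.0)) / math.sqrt(2.0) < 0.20

    def test_reported_stderr_calibrated_against_seed_scatter(
        self, single_site_gas, lone_atom_ion
    ):
        """The TM standard error must be consistent with the actual
        spread of independent estimates across seeds."""
        runs = [
            tm_ccs(lone_atom_ion, single_site_gas,
                   TMSettings(n_velocity_samples=8, n_impact_samples=40,
                              n_orientation_samples=12, seed=seed))
            for seed in range(10)
        ]
        observed = float(np.std([r.ccs for r in runs], ddof=1))
        reported = float(np.mean([r.stderr for r in runs]))
        assert 0.4 < observed / reported < 2.5

    def test_empty_structure_rejected(self, n2):
        s = CandidateStructure("s", "M", 0, "none", [make_atom()])
        s.atoms = []
        with pytest.raises(ValueError):
            tm_ccs(s, n2)


class TestGasModel:
    def test_nitrogen_is_neutral_and_quadrupolar(self):
        gas = nitrogen_gas()
        charges = [s[1] for s in gas.sites]
        assert sum(charges) == pytest.approx(0.0, abs=1e-12)
        # outer sites negative, centre positive: a negative quadrupole
        assert charges[0] < 0 < charges[1]

    def test_charged_sites_must_balance(self):
        with pytest.raises(ValueError):
            BufferGasModel("bad", 28.0, 298.0, ((0.0, 0.5, 0.1, 3.0),), 1.0)
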