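import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanoconfine.constants import (
    ELEMENTARY_CHARGE,
    KB_KJMOL,
    NM,
    VACUUM_PERMITTIVITY,
    BOLTZMANN_J,
    joule_to_kj_per_mol,
)
from nanoconfine.potential import (
    PotentialConfig,
    PotentialProfile,
    constant_permittivity,
    coulomb_field,
    dipole_energy,
    effective_profile,
    langevin,
    lj_profile,
    local_delta,
    mean_delta,
)
from nanoconfine.sas import compute_sas
from nanoconfine.structures import SPCE, Atom, ParamStructure


def single_atom(eps=1.0, sig=0.3, q=0.0):
    return ParamStructure([Atom(0, "X", (0.0, 0.0, 0.0), eps, sig, q)])


class TestLangevin:
    def test_zero_limit(self):
        assert langevin(0.0) == 0.0

    def test_asymptote(self):
        x = 1e3
        assert langevin(x) == pytest.approx(1.0 - 1.0 / x, abs=1e-9)

    def test_reference_value_at_one(self):
        # coth(1) - 1 from high-precision evaluation
        assert langevin(1.0) == pytest.approx(0.3130352854993313, abs=1e-14)

    @given(st.floats(min_value=0.0, max_value=50.0))
    @settings(derandomize=True, max_examples=50)
    def test_bounded_and_nonnegative(self, x):
        v = langevin(x)
        assert 0.0 <= v < 1.0


class TestLJProfile:
    def test_zero_at_combined_sigma(self):
        s = single_atom(eps=1.0, sig=0.3)
        sig_c = 0.5 * (0.3 + SPCE.lj_sigma_O)
        u = lj_profile(0, s, normal=np.array([0, 0, 1.0]),
                       grid=np.array([sig_c]))
        assert u[0] == pytest.approx(0.0, abs=1e-12)

    def test_minimum_at_two_sixth_sigma(self):
        s = single_atom(eps=1.0, sig=0.3)
        sig_c = 0.5 * (0.3 + SPCE.lj_sigma_O)
        eps_c = math.sqrt(1.0 * SPCE.lj_epsilon_O)
        u = lj_profile(0, s, normal=np.array([0, 0, 1.0]),
                       grid=np.array([2 ** (1 / 6) * sig_c]))
        assert u[0] == pytest.approx(-eps_c, rel=1e-12)

    def test_three_atom_line_direct_summation(self):
        atoms = [
            Atom(0, "X", (0.0, 0.0, 0.0), 1.0, 0.3),
            Atom(1, "X", (0.0, 0.0, -0.3), 2.0, 0.28),
            Atom(2, "X", (0.3, 0.0, 0.0), 0.5, 0.35),
        ]
        s = ParamStructure(atoms)
        grid = np.array([0.25, 0.3, 0.4, 0.6, 0.9])
        u = lj_profile(0, s, normal=np.array([0, 0, 1.0]), grid=grid)
        for gi, n in enumerate(grid):
            point = np.array([0.0, 0.0, n])
            total = 0.0
            for a in atoms:
                sig = 0.5 * (a.lj_sigma + SPCE.lj_sigma_O)
                eps = math.sqrt(a.lj_epsilon * SPCE.lj_epsilon_O)
                r = np.linalg.norm(point - np.array(a.position))
                total += 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
            assert u[gi] == pytest.approx(total, rel=1e-12)


class TestCoulombField:
    def test_all_neutral_zero(self):
        E = coulomb_field(
            np.zeros(3), np.array([[0.3, 0, 0], [0, 0.4, 0]]),
            np.zeros(2),
        )
        assert E == 0.0

    def test_single_charge_coulomb_law(self):
        r = 0.5  # nm
        E = coulomb_field(
            np.zeros(3), np.array([[r, 0.0, 0.0]]), np.array([1.0]),
            constant_permittivity(1.0),
        )
        exact = ELEMENTARY_CHARGE / (
            4 * math.pi * VACUUM_PERMITTIVITY * (r * NM) ** 2
        )
        assert E == pytest.approx(exact, rel=1e-12)

    def test_symmetric_pair_cancels_tangential(self):
        # two equal charges mirrored across the z axis: lateral components
        # cancel, the axial resultant equals the brute-force vector sum
        pos = np.array([[0.3, 0.0, 0.4], [-0.3, 0.0, 0.4]])
        q = np.array([0.5, 0.5])
        E = coulomb_field(np.zeros(3), pos, q, constant_permittivity(1.0))
        vecs = []
        for p, qi in zip(pos, q):
            r = np.linalg.norm(p)
            mag = qi * ELEMENTARY_CHARGE / (
                4 * math.pi * VACUUM_PERMITTIVITY * (r * NM) ** 2
            )
            vecs.append(-p / r * mag)
        brute = np.linalg.norm(np.sum(vecs, axis=0))
        assert E == pytest.approx(brute, rel=1e-12)
        axial = abs(np.sum(vecs, axis=0)[2])
        assert E == pytest.approx(axial, rel=1e-12)


class TestDipoleEnergy:
    def test_zero_field(self):
        assert dipole_energy(0.0, SPCE, 300.0) == 0.0

    def test_weak_field_linearization(self):
        T = 300.0
        x = 1e-4
        E = x * BOLTZMANN_J * T / SPCE.dipole_moment
        expected = joule_to_kj_per_mol(
            -(SPCE.dipole_moment**2) * E**2 / (3 * BOLTZMANN_J * T)
        )
        assert dipole_energy(E, SPCE, T) == pytest.approx(expected, rel=1e-3)

    def test_strong_field_saturation(self):
        T = 300.0
        x = 1e3
        E = x * BOLTZMANN_J * T / SPCE.dipole_moment
        expected = joule_to_kj_per_mol(
            -SPCE.dipole_moment * E * (1 - 1.0 / x)
        )
        assert dipole_energy(E, SPCE, T) == pytest.approx(expected, rel=1e-6)


class TestEffectiveProfile:
    def test_neutral_reduces_to_lj(self, slab, slab_sas, config):
        neutral = slab.with_charges_zeroed()
        i = next(
            k for k, a in enumerate(neutral.atoms)
            if a.is_surface and a.id in slab_sas.normal
        )
        prof = effective_profile(i, neutral, slab_sas, config=config)
        np.testing.assert_array_equal(prof.U_c, 0.0)
        np.testing.assert_array_equal(prof.U_eff, prof.U_vdw)

    def test_profile_decays_at_cutoff(self, slab, slab_sas, config):
        i = next(
            k for k, a in enumerate(slab.atoms)
            if a.is_surface and a.id in slab_sas.normal
        )
        prof = effective_profile(i, slab, slab_sas, config=config)
        assert abs(prof.U_eff[-1]) < 0.05 * prof.well_depth

    def test_well_depth_against_refined_grid(self, slab, slab_sas, config):
        i = next(
            k for k, a in enumerate(slab.atoms)
            if a.is_surface and a.id in slab_sas.normal
        )
        coarse = effective_profile(i, slab, slab_sas, config=config)
        fine_cfg = PotentialConfig(grid_points=20000)
        fine = effective_profile(i, slab, slab_sas, config=fine_cfg)
        assert coarse.well_depth == pytest.approx(fine.well_depth, rel=0.01)

    def test_buried_atom_rejected(self, slab, slab_sas, config):
        # fabricate an id missing from the normals
        missing = max(a.id for a in slab.atoms) + 1
        s2 = ParamStructure(
            slab.atoms + [Atom(missing, "Si", (0.15, 0.15, 0.15), 2.5, 0.35)],
            box=slab.box,
        )
        with pytest.raises(ValueError, match="surface_atoms"):
            effective_profile(len(s2.atoms) - 1, s2, slab_sas, config=config)


def parabolic_profile(a, b, c, grid):
    u = -a + b * (grid - c) ** 2
    return PotentialProfile(n_grid=grid, U_vdw=u, U_c=np.zeros_like(u))


class TestLocalDelta:
    GRID = np.linspace(0.05, 1.0, 2000)

    def test_shallow_well_gives_zero(self):
        level = 0.25 * KB_KJMOL * 300.0
        prof = parabolic_profile(0.5 * level, 100.0, 0.3, self.GRID)
        assert local_delta(prof, 300.0, 0.25) == 0.0

    def test_parabolic_closed_form(self):
        a, b, c = 3.0, 50.0, 0.3
        level = 0.25 * KB_KJMOL * 300.0
        prof = parabolic_profile(a, b, c, self.GRID)
        exact = 2.0 * math.sqrt((a - level) / b)
        assert local_delta(prof, 300.0, 0.25) == pytest.approx(
            exact, abs=1e-6
        )

    def test_delta_does_not_grow_with_temperature(self):
        prof = parabolic_profile(3.0, 50.0, 0.3, self.GRID)
        d300 = local_delta(prof, 300.0, 0.25)
        d600 = local_delta(prof, 600.0, 0.25)
        assert d600 <= d300

    def test_nonfinite_profile_rejected(self):
        u = np.full_like(self.GRID, np.nan)
        prof = PotentialProfile(self.GRID, u, np.zeros_like(u))
        with pytest.raises(ValueError):
            local_delta(prof, 300.0)


class TestMeanDelta:
    def test_weighted_mean_identity(self, slab, slab_sas, config):
        res = mean_delta(slab, slab_sas, config=config)
        s_tot = slab_sas.S_tot
        oracle = sum(
            res.delta_i[i] * slab_sas.S_loc[i] for i in res.delta_i
        ) / s_tot
        assert res.delta_mean == pytest.approx(oracle, rel=1e-12)
        assert res.delta_mean <= max(res.delta_i.values())

    def test_single_atom_full_weight(self):
        s = single_atom(eps=3.0, sig=0.3)
        sas = compute_sas(s)
        # isolated atom has no defined outward normal: impose one
        sas.normal[0] = np.array([0.0, 0.0, 1.0])
        res = mean_delta(s, sas)
        assert res.delta_mean == pytest.approx(
            list(res.delta_i.values())[0], rel=1e-12
        )

    def test_charge_off_equals_pure_lj(self, slab, slab_sas, config):
        res_a = mean_delta(slab.with_charges_zeroed(), slab_sas, config=config)
        neutral_atoms = [
            Atom(a.id, a.element, a.position, a.lj_epsilon, a.lj_sigma, 0.0,
                 a.is_surface)
            for a in slab.atoms
        ]
        res_b = mean_delta(
            ParamStructure(neutral_atoms, box=slab.box), slab_sas,
            config=config,
        )
        assert res_a.delta_mean == res_b.delta_mean
        assert res_a.delta_i == res_b.delta_i

    def test_grid_halving_stability(self, slab, slab_sas):
        d = {}
        for pts in (1000, 2000):
            cfg = PotentialConfig(grid_points=pts)
            d[pts] = mean_delta(slab, slab_sas, config=cfg).delta_mean
        assert d[1000] == pytest.approx(d[2000], rel=5e-3)

    def test_weak_dependence_on_well_depth(self, slab, slab_sas, config):
        # a 10x deeper LJ well must change delta by far less than 10x
        deep_atoms = [
            Atom(a.id, a.element, a.position, 10 * a.lj_epsilon, a.lj_sigma,
                 a.charge, a.is_surface)
            for a in slab.atoms
        ]
        deep = ParamStructure(deep_atoms, box=slab.box)
        d1 = mean_delta(slab, slab_sas, config=config).delta_mean
        d10 = mean_delta(deep, slab_sas, config=config).delta_mean
        assert d10 / d1 < 2.0
        assert d10 >= d1
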