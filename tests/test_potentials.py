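"""Scalar potential kernels and force assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellmech.potentials import (BendParams, FeneParams, OverextensionError,
                                 PairPotentialParams, bend_energy,
                                 fene_energy, lj_energy, total_energy,
                                 total_forces, wca_energy)

from conftest import random_small_system


class TestLennardJones:
    @pytest.mark.parametrize("r, expected", [
        (1.0, -1.0),                       # minimum: 1 - 2 = -1
        (2.0, 1 / 4096 - 2 / 64),          # direct evaluation at 2 sigma
        (1e6, 0.0),                        # both terms vanish at long range
    ])
    def test_reference_values(self, r, expected):
        p = PairPotentialParams(epsilon=1.0, sigma=1.0, cutoff=math.inf)
        assert lj_energy(r, p) == pytest.approx(expected, abs=1e-12)

    def test_cutoff_shift_makes_energy_continuous(self):
        p = PairPotentialParams(epsilon=1.0, sigma=1.0, cutoff=2.5)
        assert lj_energy(2.499999, p) == pytest.approx(0.0, abs=1e-4)
        assert lj_energy(2.51, p) == 0.0

    def test_rejects_nonpositive_separation(self):
        p = PairPotentialParams(1.0, 1.0)
        with pytest.raises(ValueError):
            lj_energy(0.0, p)

    @settings(deadline=None, max_examples=50)
    @given(eps=st.floats(0.01, 10), sigma=st.floats(0.1, 5))
    def test_minimum_at_sigma_with_depth_eps(self, eps, sigma):
        p = PairPotentialParams(eps, sigma, cutoff=math.inf)
        r = sigma * np.linspace(0.8, 1.3, 201)
        u = lj_energy(r, p)
        assert u.min() == pytest.approx(-eps, rel=1e-4)
        assert abs(r[np.argmin(u)] - sigma) < sigma * 0.005


class TestWCA:
    @pytest.mark.parametrize("r, expected", [
        (1.0, 0.0),            # U_LJ(sigma) + eps = 0
        (1.5, 0.0),            # repulsive branch ends at sigma
    ])
    def test_reference_values(self, r, expected):
        p = PairPotentialParams(1.0, 1.0, kind="wca")
        assert wca_energy(r, p) == pytest.approx(expected, abs=1e-12)

    def test_below_sigma_is_lj_plus_eps(self):
        p = PairPotentialParams(1.0, 1.0, kind="wca")
        plj = PairPotentialParams(1.0, 1.0, cutoff=math.inf)
        assert wca_energy(0.9, p) == pytest.approx(lj_energy(0.9, plj) + 1.0)

    def test_continuous_at_sigma(self):
        p = PairPotentialParams(2.0, 1.3, kind="wca")
        eps_left = wca_energy(1.3 * (1 - 1e-8), p)
        assert eps_left == pytest.approx(0.0, abs=1e-6)


class TestFene:
    def test_zero_at_rest_length(self):
        assert fene_energy(1.0, FeneParams(1.0, 1.0, 0.5)) == 0.0

    def test_reference_value(self):
        # r = r0 + drmax/2, kF = 1, drmax = 1 -> -0.5 log(0.75)
        p = FeneParams(kF=1.0, r0=2.0, drmax=1.0)
        assert fene_energy(2.5, p) == pytest.approx(-0.5 * math.log(0.75))

    @settings(deadline=None, max_examples=50)
    @given(d=st.floats(0.001, 0.45))
    def test_symmetric_in_extension_and_compression(self, d):
        p = FeneParams(3.0, 1.0, 0.5)
        assert fene_energy(1.0 + d, p) == pytest.approx(
            fene_energy(1.0 - d, p), rel=1e-12)

    def test_overextension_raises(self):
        p = FeneParams(1.0, 1.0, 0.5)
        with pytest.raises(OverextensionError):
            fene_energy(1.5, p)


class TestBend:
    def test_zero_at_equilibrium_angle(self):
        assert bend_energy(2.0, BendParams(5.0, 2.0)) == pytest.approx(0.0)

    def test_reference_value(self):
        # theta = pi/2, theta0 = pi: 0.5 (0 - (-1))^2 = 0.5
        assert bend_energy(math.pi / 2, BendParams(1.0, math.pi)) == \
            pytest.approx(0.5)

    @settings(deadline=None, max_examples=50)
    @given(theta=st.floats(0, math.pi), theta0=st.floats(0.01, math.pi),
           kb=st.floats(0, 10))
    def test_nonnegative(self, theta, theta0, kb):
        assert bend_energy(theta, BendParams(kb, theta0)) >= 0.0


class TestForceAssembly:
    def test_relaxed_bond_and_straight_triple_give_zero_force(self):
        from cellmech.model_builder import (BeadConfiguration,
                                            InteractionTable)
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        table = InteractionTable(
            [[0, 1], [1, 2]], [0, 0], [5.0, 5.0], [1.0, 1.0], [0.5, 0.5],
            [[0, 1, 2]], [3.0], [math.pi],
            {(0, 0): PairPotentialParams(0.0, 1.0, 2.5, "lj")})
        beads = BeadConfiguration(pos, np.zeros_like(pos), [0, 0, 0],
                                  [0, 0, 0])
        assert np.abs(total_forces(beads, table)).max() < 1e-12

    def test_matches_finite_difference_gradient(self):
        rng = np.random.default_rng(7)
        h = 1e-5
        for _ in range(10):
            beads, table = random_small_system(rng)
            f = total_forces(beads, table)
            scale = max(1.0, np.abs(f).max())
            for i in range(beads.n_beads):
                for c in range(2):
                    p1 = beads.copy()
                    p1.positions[i, c] += h
                    p2 = beads.copy()
                    p2.positions[i, c] -= h
                    fd = -(total_energy(p1, table) -
                           total_energy(p2, table)) / (2 * h)
                    assert abs(fd - f[i, c]) / scale < 1e-6

    def test_internal_forces_sum_to_zero(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            beads, table = random_small_system(rng)
            f = total_forces(beads, table)
            assert np.abs(f.sum(axis=0)).max() < 1e-10

    def test_overextension_propagates_bond_index(self):
        from cellmech.model_builder import (BeadConfiguration,
                                            InteractionTable)
        pos = np.array([[0.0, 0.0], [2.0, 0.0]])
        table = InteractionTable(
            [[0, 1]], [0], [5.0], [1.0], [0.5], np.empty((0, 3)),
            np.empty(0), np.empty(0),
            {(0, 0): PairPotentialParams(0.0, 1.0, 2.5, "lj")})
        beads = BeadConfiguration(pos, np.zeros_like(pos), [0, 0], [0, 0])
        with pytest.raises(OverextensionError) as err:
            total_forces(beads, table)
        assert err.value.bond_index == 0
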