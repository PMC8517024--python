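"""Virtual AFM indentation and Hertz-Sneddon fitting."""

import math

import numpy as np
import pytest

from cellmech.md_engine import SimulationConfig
from cellmech.model_builder import build_cell
from cellmech.synthetic_data import make_sneddon_curve
from cellmech.virtual_afm import (ForceDistanceCurve, TipConfig,
                                  filter_moduli, fit_hertz, force_at_travel,
                                  run_indentation, stiffness_proxy)

# small, fast probe setup for the compact cell geometry
COMPACT_TIP = TipConfig(radius=4.0, max_travel=5.0, velocity=0.05)
COMPACT_SIM = SimulationConfig(damping=0.1, temperature=0.002, seed=1,
                               record_every=200)


@pytest.fixture(scope="module")
def compact_curve(compact_geometry):
    beads, table = build_cell(compact_geometry)
    return run_indentation(beads, table, COMPACT_TIP, COMPACT_SIM,
                           equilibrate_steps=6000)


class TestIndentation:
    def test_no_force_before_contact(self, compact_curve):
        c = compact_curve.contact_travel()
        pre = compact_curve.force[compact_curve.travel < c - 0.5]
        assert pre.size > 0
        assert np.abs(pre).max() < 0.02

    def test_contact_near_start_gap(self, compact_curve):
        # tip placed start_gap away from the equilibrated surface
        assert 0.5 < compact_curve.contact_travel() < 4.0

    def test_identical_seed_identical_curve(self, compact_geometry):
        beads, table = build_cell(compact_geometry)
        tip = TipConfig(radius=4.0, max_travel=2.0)
        a = run_indentation(beads, table, tip, COMPACT_SIM,
                            equilibrate_steps=2000)
        b = run_indentation(beads, table, tip, COMPACT_SIM,
                            equilibrate_steps=2000)
        assert np.array_equal(a.travel, b.travel)
        assert np.array_equal(a.force, b.force)

    def test_post_contact_force_not_attractive(self, compact_curve):
        c = compact_curve.contact_travel()
        post = compact_curve.force[compact_curve.travel > c + 0.5]
        # purely repulsive tip coupling: no significant negative force
        assert post.min() > -0.05

    def test_curve_csv_round_trip(self, tmp_path, compact_curve):
        p = tmp_path / "curve.csv"
        compact_curve.to_csv(p)
        back = ForceDistanceCurve.from_csv(p)
        assert np.allclose(back.travel, compact_curve.travel)
        assert np.allclose(back.force, compact_curve.force)
        assert back.metadata["eps03"] == compact_curve.metadata["eps03"]

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            ForceDistanceCurve([0.0, 1.0, 0.5], [0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            ForceDistanceCurve([0.0, 1.0], [0.0, np.inf])


class TestStiffnessProxy:
    def test_exact_linear_curve_recovers_slope(self):
        t = np.linspace(0, 10, 200)
        f = np.where(t > 2, 3.7 * (t - 2), 0.0)
        curve = ForceDistanceCurve(t, f)
        c = curve.contact_travel()
        s = stiffness_proxy(curve, window=(c + 1.0, c + 6.0))
        assert s == pytest.approx(3.7, abs=1e-9)

    def test_scaling_forces_scales_slope(self):
        t = np.linspace(0, 10, 200)
        f = np.where(t > 2, 1.4 * (t - 2), 0.0)
        a = stiffness_proxy(ForceDistanceCurve(t, f))
        b = stiffness_proxy(ForceDistanceCurve(t, 5 * f))
        assert b == pytest.approx(5 * a, rel=1e-9)

    def test_window_before_contact_rejected(self):
        t = np.linspace(0, 10, 200)
        f = np.where(t > 5, t - 5, 0.0)
        with pytest.raises(ValueError):
            stiffness_proxy(ForceDistanceCurve(t, f), window=(1.0, 4.0))

    def test_force_at_travel_band_average(self):
        t = np.linspace(0, 10, 101)
        curve = ForceDistanceCurve(t, t)
        assert force_at_travel(curve, 5.0, halfwidth=1.0) == pytest.approx(5.0)
        assert force_at_travel(curve, 5.0, halfwidth=0.0) == pytest.approx(5.0)


class TestQuasiStatics:
    def test_spring_stiffness_drops_out_against_rigid_wall(
            self, compact_geometry):
        """At slow approach against a fully pinned (rigid) cell, the force
        law is set by the tip-wall contact alone: doubling the anchor
        springs leaves force-vs-tip-position unchanged once the spring
        compliance (travel - F/k) is accounted for."""
        curves = {}
        for mult in (1.0, 2.0):
            beads, table = build_cell(compact_geometry, eps00=0.0, eps03=0.0)
            tip = TipConfig(radius=4.0, max_travel=2.5, velocity=0.02,
                            kx=50 * mult, ky=50 * mult)
            sim = SimulationConfig(damping=0.1, temperature=0.0, seed=1,
                                   record_every=200)
            curve = run_indentation(beads, table, tip, sim,
                                    equilibrate_steps=1000,
                                    pin_fraction=1.0, pin_k=200.0)
            coord = curve.travel - curve.force / (50 * mult)
            curves[mult] = (coord, curve.force)
        grid = np.arange(2.26, 2.38, 0.02)
        fa = np.interp(grid, *curves[1.0])
        fb = np.interp(grid, *curves[2.0])
        assert np.max(np.abs(fb - fa) / np.maximum(fa, 0.5)) < 0.05


class TestHertzFit:
    def test_noiseless_recovery_within_one_percent(self):
        curve, truth = make_sneddon_curve(E=2.2)
        fit = fit_hertz(curve)
        assert fit.modulus == pytest.approx(truth["E"], rel=0.01)
        assert fit.contact_point == pytest.approx(truth["contact_point"],
                                                  abs=0.02)

    def test_doubled_forces_double_the_modulus(self):
        curve, _ = make_sneddon_curve(E=3.0)
        doubled = ForceDistanceCurve(curve.travel, 2 * curve.force)
        assert fit_hertz(doubled).modulus == pytest.approx(
            2 * fit_hertz(curve).modulus, rel=1e-6)

    def test_pyramid_form_uses_its_constant(self):
        curve, truth = make_sneddon_curve(E=5.0, model_form="pyramid")
        fit = fit_hertz(curve, model_form="pyramid")
        assert fit.modulus == pytest.approx(truth["E"], rel=0.01)

    def test_noisy_recovery_median_error_under_5_percent(self):
        errs = []
        for seed in range(15):
            curve, truth = make_sneddon_curve(
                E=2.2, noise=("multiplicative", 0.02), seed=seed)
            fit = fit_hertz(curve)
            errs.append(abs(fit.modulus - truth["E"]) / truth["E"])
        assert np.median(errs) < 0.05

    def test_requires_enough_post_contact_samples(self):
        curve, _ = make_sneddon_curve(E=2.2, n_samples=25,
                                      contact_point=2.0, max_travel=2.3)
        with pytest.raises(ValueError):
            fit_hertz(curve)


class TestModulusFilter:
    def test_reference_example(self):
        out = filter_moduli([4.0, 25.0, 5.9])
        assert out.kept == (4.0, 5.9)
        assert out.n_removed == 1

    def test_empty_list(self):
        out = filter_moduli([])
        assert out.kept == ()
        assert out.n_removed == 0

    def test_all_below_threshold_is_identity(self):
        vals = [1.0, 19.9, 5.0]
        assert list(filter_moduli(vals).kept) == vals

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            filter_moduli([4.0, -1.0])
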