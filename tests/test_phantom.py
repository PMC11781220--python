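import numpy as np
import pytest
from scipy import stats

from dftomo.mesh import build_box_mesh
from dftomo.phantom import (
    NoiseModel,
    add_noise,
    apply_cutoff,
    calibrate_power,
    default_scenario,
    gt_field_gaussian,
    gt_field_sphere,
    perturb_fibers,
    simulate_measurements,
    twelve_fiber_scenario,
)
from dftomo.studies import gt_sphere_volume_cm3


class TestSphereField:
    def test_center_and_background_values(self, small_box):
        f = gt_field_sphere(small_box, (5, 5, 5), 2.0, 0.10, 0.01)
        from dftomo.mesh import locate_point

        _, _ = locate_point(small_box, (5, 5, 5))
        i = np.argmin(np.linalg.norm(small_box.node_coords - 5.0, axis=1))
        assert f[i] == 0.10
        corner = np.argmin(np.linalg.norm(small_box.node_coords, axis=1))
        assert f[corner] == 0.01

    def test_equal_values_give_constant_field(self, small_box):
        f = gt_field_sphere(small_box, (5, 5, 5), 2.0, 0.03, 0.03)
        assert np.ptp(f) == 0.0

    def test_r55_analytic_volume(self):
        assert np.isclose(gt_sphere_volume_cm3(5.5), 0.697, atol=5e-4)

    def test_nodal_volume_sum_approximates_sphere(self):
        mesh = build_box_mesh((50, 50, 40), None, target_nodes=6000, seed=0)
        f = gt_field_sphere(mesh, (25, 25, 20), 5.5, 1.0, 0.0)
        v = mesh.nodal_volume[f > 0].sum()
        assert abs(v - 0.697) / 0.697 < 0.15  # within discretization error


class TestGaussianField:
    def test_peak_at_center(self, small_box):
        f = gt_field_gaussian(small_box, small_box.node_coords[3], 12.0, 0.10, 0.01)
        assert np.isclose(f[3], 0.10)

    def test_continuous_at_radius(self):
        # profile value at r = R equals the background exactly
        r, peak, bg = 12.0, 0.10, 0.01
        val = peak * np.exp(-np.log(peak / bg) * r**2 / r**2)
        assert np.isclose(val, bg, rtol=1e-12)

    def test_half_radius_value(self, small_box):
        # peak 0.10, bg 0.01, R = 12 mm, r = 6 mm -> 0.10 * 10^(-1/4) = 0.05623
        center = np.array([5.0, 5.0, 5.0])
        mesh = small_box
        f = gt_field_gaussian(mesh, center, 12.0, 0.10, 0.01)
        r = np.linalg.norm(mesh.node_coords - center, axis=1)
        i = np.argmin(np.abs(r - 6.0))
        expect = 0.10 * np.exp(-np.log(10.0) * r[i] ** 2 / 144.0)
        assert np.isclose(f[i], expect, rtol=1e-12)
        assert np.isclose(0.10 * np.exp(-np.log(10.0) / 4.0), 0.05623, atol=1e-4)

    def test_zero_background_rejected(self, small_box):
        with pytest.raises(ValueError, match="log"):
            gt_field_gaussian(small_box, (5, 5, 5), 12.0, 0.1, 0.0)


class TestNoise:
    def test_zero_amplitude_identity(self):
        s = np.linspace(1.0, 5.0, 10)
        assert np.array_equal(add_noise(s, NoiseModel(0.0, 1)), s)

    def test_reproducible(self):
        s = np.ones(100)
        a = add_noise(s, NoiseModel(0.02, 42))
        b = add_noise(s, NoiseModel(0.02, 42))
        assert np.array_equal(a, b)

    def test_sample_std_matches_amplitude(self):
        s = np.full(10_000, 3.0)
        noisy = add_noise(s, NoiseModel(0.01, 0))
        ratio = np.std(noisy / s - 1.0)
        assert abs(ratio - 0.01) / 0.01 < 0.03

    def test_floor_keeps_signals_positive(self):
        s = np.ones(10_000)
        noisy = add_noise(s, NoiseModel(5.0, 0))  # huge amplitude
        assert noisy.min() >= 1e-3


class TestCutoff:
    def test_zero_threshold_keeps_all(self):
        assert apply_cutoff(np.array([1e-12, 5e-9]), 0.0).all()

    def test_toy_powers(self):
        mask = apply_cutoff(np.array([1e-10, 1e-12, 5e-11]), 4.5e-11)
        assert np.array_equal(mask, [True, False, True])

    def test_all_removed_rejected(self):
        with pytest.raises(ValueError, match="every"):
            apply_cutoff(np.array([1e-13, 1e-14]), 4.5e-11)


class TestPerturbFibers:
    def test_zero_width_identity(self, four_fiber_cfg):
        out = perturb_fibers(four_fiber_cfg, (0, 0), (0, 0), (0, 0), seed=1)
        assert np.allclose(out.tip_coords, four_fiber_cfg.tip_coords)

    def test_level1_bounds(self, four_fiber_cfg):
        for seed in range(20):
            out = perturb_fibers(
                four_fiber_cfg, (-0.5, 0.5), (-0.5, 0.5), (-1, 1), seed=seed
            )
            d = out.tip_coords - four_fiber_cfg.tip_coords
            assert np.all(np.abs(d[:, :2]) <= 0.5)
            assert np.all(np.abs(d[:, 2]) <= 1.0)

    def test_offsets_uniform(self, four_fiber_cfg):
        from dftomo.mesh import FiberConfig

        big = FiberConfig(np.full((10_000, 3), 10.0) + np.arange(10_000)[:, None] * 1e-6)
        out = perturb_fibers(big, (-0.5, 0.5), (-0.5, 0.5), (-1, 1), seed=3)
        dx = out.tip_coords[:, 0] - big.tip_coords[:, 0]
        p = stats.kstest(dx, stats.uniform(loc=-0.5, scale=1.0).cdf).pvalue
        assert p > 0.01

    def test_outside_box_rejected(self, four_fiber_cfg):
        with pytest.raises(ValueError, match="box"):
            perturb_fibers(
                four_fiber_cfg, (15, 15), (0, 0), (0, 0), seed=0, extent=(20, 20, 20)
            )


@pytest.fixture(scope="module")
def tiny_scenario():
    from dftomo.mesh import FiberConfig

    fibers = FiberConfig(
        np.array([[8.0, 10.0, 10.0], [12.0, 10.0, 10.0], [10.0, 13.0, 10.0]])
    )
    return default_scenario(
        extent=(20.0, 20.0, 20.0),
        fibers=fibers,
        gt={
            "kind": "sphere",
            "center": (10.0, 10.0, 10.0),
            "radius": 3.0,
            "mu_af_inclusion": 0.10,
            "mu_af_background": 0.01,
        },
        data_mesh_nodes=800,
    )


class TestSimulateMeasurements:

    def test_clean_born_equals_forward_of_ground_truth(self, tiny_scenario):
        from dftomo.forward import jacobian

        out = simulate_measurements(tiny_scenario)
        J = jacobian(out.greens, out.mesh.nodal_volume)
        assert np.allclose(out.measurements.born, J @ out.eta_gt, rtol=1e-12)

    def test_same_seed_reproducible(self, tiny_scenario):
        from dataclasses import replace

        sc = replace(tiny_scenario, noise_amplitude=0.02)
        a = simulate_measurements(sc)
        b = simulate_measurements(sc)
        assert np.array_equal(a.measurements.born, b.measurements.born)

    def test_cutoff_monotone_in_inclusion_strength(self, tiny_scenario):
        from dataclasses import replace

        low = replace(tiny_scenario, gt=dict(tiny_scenario.gt, mu_af_inclusion=0.02))
        ref = simulate_measurements(low)
        kappa = ref.power_calibration  # fixed instrument: calibrated at the lowest level
        flu = ref.measurements.raw_fluorescence
        p_cut = (flu.min() + np.median(flu)) / 2.0  # binds on the weakest pairs
        kept = []
        for mui in [0.02, 0.05, 0.10]:
            sc = replace(
                tiny_scenario,
                gt=dict(tiny_scenario.gt, mu_af_inclusion=mui),
                p_cut=p_cut,
                power_calibration=kappa,
            )
            out = simulate_measurements(sc, mesh=ref.mesh, greens=ref.greens)
            kept.append(out.measurements.nm_prime)
        assert kept[0] <= kept[1] <= kept[2]
        assert kept[0] < ref.measurements.nm  # the cut-off actually binds at the bottom

    def test_calibration_anchors_weakest_signal(self, tiny_scenario):
        out = simulate_measurements(tiny_scenario)
        assert np.isclose(out.measurements.raw_fluorescence.min(), 1e-11, rtol=1e-9)


def test_scenario_fixtures_carry_study_conditions():
    sc = default_scenario()
    assert sc.gt["mu_af_background"] == 0.01 and sc.gt["mu_af_inclusion"] == 0.10
    assert sc.mu_a == 0.50 and sc.mu_s_prime == 8.7
    assert tuple(sc.gt["center"]) == (19.0, 25.0, 18.0) and sc.gt["radius"] == 6.7
    assert sc.fibers.n_fibers == 13

    tw = twelve_fiber_scenario()
    assert tw.fibers.n_fibers == 12
    assert tuple(tw.gt["center"]) == (22.5, 27.5, 20.0) and tw.gt["radius"] == 5.5
    assert tw.mu_a == 0.24 and tw.mu_s_prime == 8.3
    assert tw.inclusion_mu_a == 0.20 and tw.inclusion_mu_s_prime == 15.7
    assert tw.p_cut == 4.5e-11


def test_sphere_outside_box_rejected():
    with pytest.raises(ValueError, match="inside"):
        default_scenario(
            gt={
                "kind": "sphere",
                "center": (2.0, 25.0, 18.0),
                "radius": 6.7,
                "mu_af_inclusion": 0.10,
                "mu_af_background": 0.01,
            }
        )
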