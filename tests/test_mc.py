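import numpy as np
import pytest

from qdri.mc import (
    BaselineSimulation,
    ChannelGeometry,
    LayeredMedium,
    PhotonExitRecord,
    channel_reflectance,
    channel_reflectance_explicit,
    collection_kernel,
    crosstalk_fraction,
    energy_balance,
    run_mc,
    scale_to_target,
)
from qdri.mc.forward import _arc_fraction
from qdri.optics import OpticalProperties

from ._oracles import channel_reflectance_se

TISSUE = dict(g=[0.9], n_medium=1.37)


def props(mu_a, musp):
    return OpticalProperties([mu_a], [musp], **TISSUE)


class TestTransport:
    def test_energy_conservation(self):
        sim = run_mc(LayeredMedium.semi_infinite(props(1.0, 10.0)), 20_000, seed=3)
        assert abs(energy_balance(sim)) / sim.photon_count < 1e-6

    def test_seed_determinism(self):
        a = run_mc(LayeredMedium.semi_infinite(props(2.0, 8.0)), 20_000, seed=11)
        b = run_mc(LayeredMedium.semi_infinite(props(2.0, 8.0)), 20_000, seed=11)
        np.testing.assert_array_equal(a.exit_radius, b.exit_radius)
        np.testing.assert_array_equal(a.weight, b.weight)

    def test_total_exit_weight_bounded(self):
        sim = run_mc(LayeredMedium.semi_infinite(props(0.5, 10.0)), 20_000, seed=5)
        assert sim.weight.sum() <= sim.photon_count

    def test_index_matched_conservative_limit(self):
        # mu_a = 0, matched indices, bounded slab: everything re-emerges
        medium = LayeredMedium.semi_infinite(
            OpticalProperties([0.0], [10.0], [0.9], 1.0)
        )
        sim = run_mc(medium, 30_000, seed=9, max_depth_cm=0.5)
        led = sim.ledger
        total_out = led["reflected"] + led["transmitted"] + led["leaked"]
        assert total_out / sim.photon_count == pytest.approx(1.0, abs=1e-9)
        assert led["absorbed"] == 0.0
        assert led["reflected"] / sim.photon_count > 0.5

    def test_reflectance_decreases_with_absorption(self, geometry):
        sims = [
            run_mc(LayeredMedium.semi_infinite(props(mu_a, 9.0)), 150_000, seed=21)
            for mu_a in (0.5, 2.0, 6.0)
        ]
        refl = [channel_reflectance(s, geometry) for s in sims]
        ses = [channel_reflectance_se(s, geometry) for s in sims]
        assert refl[0] - refl[1] > 3 * np.hypot(ses[0], ses[1])
        assert refl[1] - refl[2] > 3 * np.hypot(ses[1], ses[2])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            run_mc(LayeredMedium.semi_infinite(props(1.0, 10.0)), 0, seed=1)
        with pytest.raises(ValueError):
            LayeredMedium(())

    def test_two_layer_thin_scattering_over_absorber(self, geometry):
        # optics of the layered pressure assay: a thin scattering layer over
        # a strong absorber darkens more than a thick one
        top = props(0.3, 10.0)
        bottom = props(15.0, 10.0)
        refl = {}
        for thick in (0.2, 0.4):  # 2 mm and 4 mm
            medium = LayeredMedium(((top, thick), (bottom, None)))
            sim = run_mc(medium, 120_000, seed=31)
            refl[thick] = sim.ledger["reflected"] / sim.photon_count
        se = np.sqrt(0.5 / 120_000)  # binomial bound on each estimate
        assert refl[0.2] < refl[0.4] - 3 * se


class TestRecords:
    def test_exit_record_invariants(self):
        with pytest.raises(ValueError):
            PhotonExitRecord(0.1, 0.9, 0.0, np.array([0.1]))
        with pytest.raises(ValueError):
            PhotonExitRecord(-0.1, 0.9, 0.5, np.array([0.1]))
        rec = PhotonExitRecord(0.1, 0.9, 0.5, np.array([0.3]))
        assert rec.weight == 0.5

    def test_record_accessor(self, baseline):
        rec = baseline.record(0)
        assert rec.exit_radius_cm == baseline.exit_radius[0]

    def test_cache_roundtrip(self, baseline, tmp_path):
        path = tmp_path / "baseline.h5"
        baseline.save(path)
        loaded = BaselineSimulation.load(path)
        np.testing.assert_array_equal(loaded.exit_radius, baseline.exit_radius)
        np.testing.assert_array_equal(loaded.path_lengths, baseline.path_lengths)
        assert loaded.seed == baseline.seed
        assert loaded.ledger == baseline.ledger


class TestScaling:
    def test_identity(self, baseline, geometry):
        scaled = scale_to_target(baseline, props(0.0, 10.0))
        np.testing.assert_array_equal(scaled.exit_radius, baseline.exit_radius)
        assert channel_reflectance(scaled, geometry) == channel_reflectance(
            baseline, geometry
        )

    def test_single_record_weight(self):
        one = BaselineSimulation(
            exit_radius=np.array([0.05]),
            exit_cosine=np.array([0.99]),
            weight=np.array([0.8]),
            path_lengths=np.array([[2.0]]),
            mu_a=np.array([0.0]),
            mu_s=np.array([100.0]),
            g=np.array([0.9]),
            n_layers_index=np.array([1.37]),
            n_ambient=1.0,
            photon_count=1,
            seed=0,
        )
        scaled = scale_to_target(one, props(3.0, 10.0))
        assert scaled.weight[0] == pytest.approx(0.8 * np.exp(-3.0 * 2.0))

    def test_requires_zero_absorption_baseline(self, baseline, geometry):
        absorbing = run_mc(LayeredMedium.semi_infinite(props(1.0, 10.0)), 1000, seed=2)
        with pytest.raises(ValueError, match="zero-absorption"):
            scale_to_target(absorbing, props(0.5, 10.0))

    def test_out_of_range_warns(self, baseline):
        with pytest.warns(UserWarning, match="validated"):
            scale_to_target(baseline, props(0.0, 2.0))

    @pytest.mark.parametrize("target", [(0.5, 9.73), (8.86, 7.03)])
    def test_scaled_matches_direct(self, baseline, geometry, target):
        mu_a, musp = target
        scaled = scale_to_target(baseline, props(mu_a, musp))
        r_scaled = channel_reflectance(scaled, geometry)
        direct = run_mc(LayeredMedium.semi_infinite(props(mu_a, musp)), 200_000, seed=77)
        r_direct = channel_reflectance(direct, geometry)
        se = np.hypot(
            channel_reflectance_se(scaled, geometry),
            channel_reflectance_se(direct, geometry),
        )
        assert abs(r_scaled - r_direct) <= 3 * se


class TestCollection:
    def test_arc_fraction_limits(self):
        assert _arc_fraction(np.array([0.5]), np.array([3.0]), 1.0)[0] == 0.0
        assert _arc_fraction(np.array([0.1]), np.array([0.2]), 1.0)[0] == 1.0
        mid = _arc_fraction(np.array([1.0]), np.array([1.0]), 0.5)[0]
        assert 0.0 < mid < 0.5

    def test_kernel_normalisation(self):
        # source on top of a huge detector: everything collected
        r = np.linspace(0, 0.5, 100)
        k = collection_kernel(r, 0.0, 0.01, 1.0)
        np.testing.assert_allclose(k, 1.0)

    def test_completeness_limit(self, baseline):
        geom = ChannelGeometry(numerical_aperture=1.0)
        total = channel_reflectance(baseline, geom, det_radius_cm=10.0)
        assert total == pytest.approx(baseline.weight.sum() / baseline.photon_count)

    def test_empty_records(self, geometry):
        empty = type("R", (), {"exit_radius": np.array([]), "exit_cosine": np.array([]),
                               "weight": np.array([]), "photon_count": 1})()
        with pytest.raises(ValueError):
            channel_reflectance(empty, geometry)

    def test_explicit_geometry_oracle(self, baseline, geometry, rng):
        scaled = scale_to_target(baseline, props(1.0, 9.0))
        kernel_val = channel_reflectance(scaled, geometry)
        per_fiber = channel_reflectance_explicit(scaled, geometry, rng)
        se = channel_reflectance_se(scaled, geometry)
        # fibers agree with each other and with the convolution path
        assert per_fiber.mean() == pytest.approx(kernel_val, abs=3 * se + 0.1 * kernel_val)
        assert per_fiber.std() < per_fiber.mean()  # symmetric within MC noise


@pytest.fixture(scope="module")
def adipose_records():
    return run_mc(LayeredMedium.semi_infinite(props(4.6, 6.9)), 400_000, seed=13)


class TestCrosstalk:
    def test_far_pitch_vanishes(self, adipose_records):
        res = crosstalk_fraction(props(4.6, 6.9), 50.0, records=adipose_records)
        assert res.percent < 1e-6

    def test_monotone_in_pitch(self, adipose_records):
        results = {
            p: crosstalk_fraction(props(4.6, 6.9), p, records=adipose_records)
            for p in (5.0, 6.0, 7.0)
        }
        assert (
            results[5.0].percent - results[6.0].percent
            > 3 * np.hypot(results[5.0].stderr, results[6.0].stderr)
        )
        assert (
            results[6.0].percent - results[7.0].percent
            > 3 * np.hypot(results[6.0].stderr, results[7.0].stderr)
        )

    def test_adipose_bound(self, adipose_records):
        res = crosstalk_fraction(props(4.6, 6.9), 6.0, records=adipose_records)
        assert res.percent <= 2.4

    def test_invalid_pitch(self):
        with pytest.raises(ValueError):
            crosstalk_fraction(props(4.6, 6.9), 0.0)
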