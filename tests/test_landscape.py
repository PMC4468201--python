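import numpy as np
import pytest

from qdri.landscape import (
    DensityStratum,
    LandscapeDistribution,
    SiteRegion,
    compare_strata,
    ecdf,
    ks_two_sample,
    ratio_map,
)
from qdri.scan import ParameterMap
from qdri.synthetic import TISSUE_CLASSES, generate_margin

from ._oracles import ecdf_counting, ks_d_exhaustive


class TestDensityStratum:
    @pytest.mark.parametrize("score,label", [(1, "LBD"), (2, "LBD"), (3, "HBD"), (4, "HBD")])
    def test_binning(self, score, label):
        assert DensityStratum(score).label == label

    def test_invalid_score(self):
        with pytest.raises(ValueError):
            DensityStratum(5)


class TestEcdf:
    def test_three_values(self):
        d = ecdf([1.0, 2.0, 3.0])
        assert d.cdf(2.0) == pytest.approx(2 / 3)
        assert d.cdf(0.5) == 0.0
        assert d.cdf(3.0) == 1.0

    def test_all_equal(self):
        d = ecdf([4.0, 4.0, 4.0])
        assert d.cdf(3.999) == 0.0
        assert d.cdf(4.0) == 1.0

    def test_counting_oracle(self, rng):
        values = rng.standard_normal(100)
        d = ecdf(values)
        probes = rng.uniform(-3, 3, size=1000)
        np.testing.assert_array_equal(d.cdf(probes), ecdf_counting(values, probes))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ecdf([])

    def test_invariants(self, rng):
        d = ecdf(rng.random(37))
        xs = np.linspace(-1, 2, 200)
        f = d.cdf(xs)
        assert np.all(np.diff(f) >= 0)
        assert d.cdf(-np.inf) == 0.0
        assert d.cdf(d.values[-1]) == 1.0


class TestKs:
    def test_identical_samples(self, rng):
        x = rng.random(40)
        d, p = ks_two_sample(x, x.copy())
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self, rng):
        a = rng.random(30)
        b = rng.random(25) + 5.0
        d, _ = ks_two_sample(a, b)
        assert d == 1.0

    def test_exhaustive_oracle_50_samples(self, rng):
        for _ in range(5):
            a = rng.standard_normal(50)
            b = rng.standard_normal(50) * 1.3 + 0.2
            d, _ = ks_two_sample(a, b)
            assert d == pytest.approx(ks_d_exhaustive(a, b), abs=1e-12)

    def test_symmetry_and_range(self, rng):
        a = rng.random(20)
        b = rng.random(35) * 2
        dab, pab = ks_two_sample(a, b)
        dba, pba = ks_two_sample(b, a)
        assert dab == dba and pab == pba
        assert 0.0 <= dab <= 1.0

    def test_monotone_transform_invariance(self, rng):
        a = rng.random(30) + 0.1
        b = rng.random(30) * 1.5 + 0.1
        d1, _ = ks_two_sample(a, b)
        d2, _ = ks_two_sample(np.log(a), np.log(b))
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_exact_mode(self, rng):
        a = rng.random(12)
        b = rng.random(15)
        d, p = ks_two_sample(a, b, mode="exact")
        assert 0 <= p <= 1
        d2, _ = ks_two_sample(a, b)
        assert d == d2


class TestRatioMap:
    def _pm(self, arr):
        return ParameterMap(np.asarray(arr, dtype=float), pitch_mm=0.75)

    def test_uniform(self):
        r = ratio_map(self._pm(np.full((4, 4), 6.0)), self._pm(np.full((4, 4), 3.0)))
        np.testing.assert_allclose(r.values, 2.0)

    def test_homogeneity(self, rng):
        b = rng.random((5, 5)) + 0.5
        s = rng.random((5, 5)) + 1.0
        r1 = ratio_map(self._pm(b), self._pm(s))
        r3 = ratio_map(self._pm(3 * b), self._pm(s))
        np.testing.assert_allclose(r3.values, 3 * r1.values)

    def test_low_scatter_masked(self):
        b = np.full((2, 2), 1.0)
        s = np.array([[1.0, 0.005], [0.0, 2.0]])
        r = ratio_map(self._pm(b), self._pm(s))
        assert np.isnan(r.values[0, 1]) and np.isnan(r.values[1, 0])
        assert r.values[1, 1] == pytest.approx(0.5)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ratio_map(self._pm(np.ones((3, 3))), self._pm(np.ones((4, 4))))

    def test_adipose_above_fibroglandular(self):
        m = generate_margin("LBD", seed=5)
        from qdri.synthetic import CLASS_CODES

        adipose = m.ratio_true[m.class_map == CLASS_CODES["adipose"]]
        fg = m.ratio_true[m.class_map == CLASS_CODES["fibroglandular"]]
        assert np.median(adipose) > np.median(fg)


class TestSiteRegion:
    def test_window_extraction(self):
        pmap = ParameterMap(np.arange(56 * 56, dtype=float).reshape(56, 56), 0.75)
        site = SiteRegion(28, 28, "adipose")
        win = site.window(pmap, 8)
        assert win.shape == (8, 8)

    def test_out_of_bounds(self):
        pmap = ParameterMap(np.zeros((14, 14)), 3.0)
        with pytest.raises(ValueError):
            SiteRegion(0, 0, "adipose").window(pmap, 8)

    def test_bad_label(self):
        with pytest.raises(ValueError):
            SiteRegion(3, 3, "muscle")


class TestCompareStrata:
    def test_small_group_excluded(self, rng):
        groups = {
            "a": [rng.random(100)],
            "b": [rng.random(100) + 1],
            "tiny": [rng.random(4)],
        }
        table = compare_strata(groups)
        names = set(table["group_a"]) | set(table["group_b"])
        assert "tiny" not in names
        assert len(table) == 1

    def test_too_few_groups(self, rng):
        with pytest.raises(ValueError):
            compare_strata({"a": [rng.random(10)], "b": [rng.random(3)]})

    def test_null_calibration(self):
        # same parent distribution: p should look uniform (median > 0.1)
        ps = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            a = r.lognormal(0.8, 0.3, size=500)
            b = r.lognormal(0.8, 0.3, size=500)
            table = compare_strata({"a": [a], "b": [b]})
            ps.append(float(table["p"].iloc[0]))
        assert np.median(ps) > 0.1

    def test_hbd_lbd_power(self):
        # generator default separation: p < 0.02 in >= 90% of seeded runs
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            r = np.random.default_rng(seed)
            lbd = generate_margin("LBD", seed=2 * seed)
            hbd = generate_margin("HBD", seed=2 * seed + 1)
            a = lbd.ratio_true[np.isfinite(lbd.ratio_true)]
            b = hbd.ratio_true[np.isfinite(hbd.ratio_true)]
            a = r.choice(a, size=500, replace=False)
            b = r.choice(b, size=500, replace=False)
            _, p = ks_two_sample(a, b)
            if p < 0.02:
                hits += 1
        assert hits >= 90


class TestMaskingEffect:
    def test_low_resolution_masks_mixed_sites(self, rng):
        """Volume averaging at the native resolution makes predominantly
        adipose mixed sites statistically indistinguishable from pure
        adipose, while sub-pixel sampling resolves the minority component."""
        adipose = TISSUE_CLASSES["adipose"].ratio
        fg = TISSUE_CLASSES["fibroglandular"].ratio
        n_sites = 12
        # site-to-site biological spread dominates the within-site texture
        pure_means = rng.normal(adipose, 0.15 * adipose, size=n_sites)
        pure_px = np.concatenate(
            [rng.normal(m, 0.05 * m, size=64) for m in pure_means]
        )
        mixed_px = []  # n = 8: 64 pixels per site resolve the minority
        mixed_means = []  # n = 1: one volume-averaged value per site
        for _ in range(n_sites):
            m = rng.normal(adipose, 0.15 * adipose)
            frac = rng.uniform(0.08, 0.15)
            n_fg = int(round(64 * frac))
            px = np.concatenate([
                rng.normal(fg, 0.05 * fg, size=n_fg),
                rng.normal(m, 0.05 * m, size=64 - n_fg),
            ])
            mixed_px.append(px)
            mixed_means.append(px.mean())
        _, p_hi = ks_two_sample(np.concatenate(mixed_px), pure_px)
        _, p_lo = ks_two_sample(np.asarray(mixed_means), pure_means)
        assert p_hi < 0.001  # resolved at high resolution
        assert p_lo > 0.05  # masked at native resolution


def test_landscape_distribution_invariants(rng):
    with pytest.raises(ValueError):
        LandscapeDistribution(np.array([np.nan]))
    d = LandscapeDistribution(rng.random(10), provenance="margin-1")
    assert d.n == 10
    assert d.table().shape == (10, 2)
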