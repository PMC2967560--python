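import math

import numpy as np
import pytest

import densitygate as dg
from densitygate.simulate import truncation_radius


class QueuedRng:
    """Deterministic stand-in for a Generator: replays queued uniform draws."""

    def __init__(self, values):
        self.values = list(values)

    def random(self, size=None):
        value = self.values.pop(0)
        if size is None:
            return value
        return np.broadcast_to(np.asarray(value, dtype=float), size).copy()


class TestNormalDeviate:
    def test_box_muller_substitution(self):
        # u1 = e^-2, u2 = 0  ->  sqrt(-2 ln u1) * cos(0) = 2
        stub = QueuedRng([1.0 - math.exp(-2.0), 0.0])
        assert dg.normal_deviate(stub) == pytest.approx(2.0)

    def test_seed_determinism(self):
        a = dg.normal_deviate(np.random.default_rng(42), 100)
        b = dg.normal_deviate(np.random.default_rng(42), 100)
        assert np.array_equal(a, b)

    def test_moments(self):
        draws = dg.normal_deviate(np.random.default_rng(1), 100_000)
        assert abs(draws.mean()) < 0.02
        assert abs(draws.var() - 1.0) < 0.02


class TestSampleDistortedGaussian:
    def test_distortion_formulas(self):
        # deviate matrix (1, 2): delta1 = 2, delta = 1
        u1 = [[1.0 - math.exp(-2.0), 1.0 - math.exp(-0.5)]]
        u2 = [[0.0, 0.0]]
        spec = dg.ComponentSpec(
            mean=(100.0, 0.0), sd=(10.0, 5.0), count=1, k1=0, k2=1, s=0.002
        )
        event = dg.sample_distorted_gaussian(spec, QueuedRng([u1, u2]))[0]
        assert event[0] == pytest.approx(120.0)          # axis k1: 100 + 2*10
        assert event[1] == pytest.approx(5.8)            # 0 + 1*5 + 0.002*(2*10)^2

    def test_zero_distortion_reduces_to_plain_gaussian(self):
        spec = dg.ComponentSpec(
            mean=(3.0, -2.0, 7.0), sd=(1.0, 2.0, 0.5), count=100_000, s=0.0
        )
        draws = dg.sample_distorted_gaussian(spec, np.random.default_rng(5))
        for k in range(3):
            se = spec.sd[k] / math.sqrt(spec.count)
            assert abs(draws[:, k].mean() - spec.mean[k]) < 2 * se
        cov = np.cov(draws, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 0.05

    def test_quadratic_coupling_grows_with_delta1(self):
        spec = dg.ComponentSpec(
            mean=(0.0, 0.0), sd=(10.0, 1.0), count=200_000, k1=0, k2=1, s=0.004
        )
        draws = dg.sample_distorted_gaussian(spec, np.random.default_rng(8))
        d1sd = draws[:, 0]  # = delta1 * sd_k1
        slope = np.polyfit(d1sd**2, draws[:, 1], 1)[0]
        assert slope == pytest.approx(spec.s, rel=0.05)

    def test_truncation_bounds_the_deviates(self):
        spec = dg.ComponentSpec(
            mean=(0.0, 0.0), sd=(1.0, 1.0), count=50_000, s=0.0, truncate=2.0
        )
        draws = dg.sample_distorted_gaussian(spec, np.random.default_rng(2))
        assert np.all((draws**2).sum(axis=1) <= 4.0 + 1e-9)

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="k1 and k2"):
            dg.ComponentSpec(mean=(0, 0), sd=(1, 1), count=5, k1=1, k2=1)
        with pytest.raises(ValueError, match="positive"):
            dg.ComponentSpec(mean=(0, 0), sd=(1, 0), count=5)


class TestMakeMixture:
    def test_label_bookkeeping(self):
        specs = [
            dg.ComponentSpec(mean=(0, 0), sd=(1, 1), count=120),
            dg.ComponentSpec(mean=(5, 5), sd=(1, 1), count=80),
        ]
        events, labels = dg.make_mixture(specs, seed=0)
        assert events.shape == (200, 2)
        assert np.bincount(labels).tolist() == [120, 80]

    def test_seed_determinism(self):
        specs = [dg.ComponentSpec(mean=(0, 0), sd=(1, 1), count=500, s=0.002)]
        a, _ = dg.make_mixture(specs, seed=123)
        b, _ = dg.make_mixture(specs, seed=123)
        c, _ = dg.make_mixture(specs, seed=124)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_mismatched_dimensions_rejected(self):
        specs = [
            dg.ComponentSpec(mean=(0, 0), sd=(1, 1), count=10),
            dg.ComponentSpec(mean=(0, 0, 0), sd=(1, 1, 1), count=10),
        ]
        with pytest.raises(ValueError, match="dimension"):
            dg.make_mixture(specs, seed=0)


class TestBenchmarkFixtures:
    def test_four_gaussian_benchmark_recovered(self):
        events, labels = dg.four_gaussian_mixture_2d(n=50_000, seed=4)
        assert events.shape == (50_000, 2)
        clusters = dg.cluster(events)
        assert len(clusters) == 4
        for r in clusters:
            majority = np.bincount(labels[r.members]).argmax()
            purity = (labels[r.members] == majority).mean()
            assert purity > 0.95

    def test_truncation_radius_is_chi_square_quantile(self):
        assert truncation_radius(2) == pytest.approx(3.2552, abs=1e-3)
        assert truncation_radius(10) == pytest.approx(5.0188, abs=1e-3)

    def test_crescent_fixture_geometry(self):
        events, labels = dg.crescent_with_blob_2d(n=10_000, seed=0)
        arc = events[labels == 0]
        radii = np.hypot(arc[:, 0] - 500, arc[:, 1] - 500)
        assert 150 < radii.min() and radii.max() < 350
        theta = np.arctan2(arc[:, 1] - 500, arc[:, 0] - 500)
        assert np.abs(theta).max() < 0.9  # an arc, not a closed ring
        blob = events[labels == 1]
        assert np.hypot(blob[:, 0] - 1080, blob[:, 1] - 500).max() < 131

    def test_random_mixture_partitions(self):
        events, labels, specs = dg.random_distorted_mixture(n=8000, seed=1)
        assert events.shape == (8000, 10)
        assert len(specs) == 8
        assert np.bincount(labels).sum() == 8000
        for spec in specs:
            assert spec.k1 != spec.k2
            assert spec.s == 0.004
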