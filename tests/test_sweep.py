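import numpy as np
import pytest

import densitygate as dg
from densitygate.sweep import PeakType

from conftest import hist_from_counts


def random_structured_counts(rng, shape, n_bumps=3, scale=60):
    """Random non-negative count grid with a few smooth bumps plus noise."""
    counts = np.zeros(shape, dtype=float)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    for _ in range(n_bumps):
        center = [rng.uniform(0, s - 1) for s in shape]
        width = rng.uniform(1.0, 3.0)
        r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        counts += rng.uniform(0.3, 1.0) * scale * np.exp(-r2 / (2 * width**2))
    counts = rng.poisson(counts)
    return counts.astype(np.int64)


def cluster_signature(clusters):
    return [
        (r.code, r.peak_code, r.Lp, r.Ls, r.C, tuple(r.bins), tuple(r.members))
        for r in clusters
    ]


class TestReliability:
    @pytest.mark.parametrize(
        "Lp,Ls,expected",
        [(3385, 756, 0.777), (430, 5, 0.988), (1911, 102, 0.947), (777, 0, 1.0)],
    )
    def test_published_style_values(self, Lp, Ls, expected):
        assert round(dg.reliability(Lp, Ls), 3) == expected

    def test_invalid_levels(self):
        with pytest.raises(ValueError):
            dg.reliability(5, 10)


class TestSweepTraces:
    def test_two_major_peaks_with_shared_saddle(self):
        hist, events = hist_from_counts(np.array([0, 2000, 30, 1000, 0]))
        registry, final = dg.sweep_levels(hist)
        clusters = dg.extract_clusters(events, hist, final, registry)
        assert len(clusters) == 2
        big, small = clusters
        assert (big.Lp, big.Ls, big.C) == (1999, 29, 2000)
        assert big.bins.tolist() == [1]
        assert big.f == pytest.approx(0.9855, abs=5e-5)
        assert (small.Lp, small.Ls, small.C) == (999, 29, 1000)
        assert small.bins.tolist() == [3]
        assert small.f == pytest.approx(0.9710, abs=5e-5)

    def test_insignificant_twin_peaks_collapse_to_one_cluster(self):
        # both emergent peaks have local mean < 10, so both are "small"; the
        # highest is retained and survives alone to level 0
        hist, events = hist_from_counts(np.array([0, 5, 1, 4, 0]))
        registry, final = dg.sweep_levels(hist)
        clusters = dg.extract_clusters(events, hist, final, registry)
        assert len(clusters) == 1
        (only,) = clusters
        assert (only.Lp, only.Ls, only.C, only.f) == (4, 0, 10, 1.0)
        assert only.bins.tolist() == [1, 2, 3]

    def test_single_bin_peak(self):
        hist, events = hist_from_counts(np.array([0, 9, 0]))
        registry, final = dg.sweep_levels(hist)
        clusters = dg.extract_clusters(events, hist, final, registry)
        (only,) = clusters
        assert (only.Lp, only.Ls, only.C, only.f) == (8, 0, 9, 1.0)

    def test_peak_registry_case_transitions(self):
        hist, _ = hist_from_counts(np.array([0, 2000, 30, 1000, 0]))
        registry, _ = dg.sweep_levels(hist)
        assert registry.ncl == 2
        types = {rec.code: rec.ptype for rec in registry.peaks.values()}
        assert set(types.values()) == {PeakType.MERGED_MAJOR}
        assert all(rec.finalized for rec in registry.peaks.values())

    def test_empty_final_grid_warns(self):
        hist, events = hist_from_counts(np.array([0, 5, 1, 4, 0]))
        registry, _ = dg.sweep_levels(hist)
        empty = dg.FinalLabelGrid(shape=hist.shape)
        with pytest.warns(UserWarning, match="eliminated"):
            assert dg.extract_clusters(events, hist, empty, registry) == []


class TestLevelSkippingEquivalence:
    @pytest.mark.parametrize("shape", [(16,), (9, 9), (6, 6, 6)])
    def test_fast_equals_naive_engine(self, rng, shape):
        for rep in range(3):
            counts = random_structured_counts(rng, shape)
            if counts.max() == 0:
                continue
            hist, events = hist_from_counts(counts)
            reg_f, fin_f = dg.sweep_levels(hist)
            reg_n, fin_n = dg.sweep_levels(hist, every_level=True)
            assert fin_f.codes == fin_n.codes
            assert reg_f.ncl == reg_n.ncl
            for code, rec in reg_f.peaks.items():
                other = reg_n.peaks[code]
                assert (rec.char_bin, rec.top_bin, rec.ptype, rec.top_level,
                        rec.saddle_level, rec.finalized) == (
                    other.char_bin, other.top_bin, other.ptype, other.top_level,
                    other.saddle_level, other.finalized)
            cl_f = dg.extract_clusters(events, hist, fin_f, reg_f)
            cl_n = dg.extract_clusters(events, hist, fin_n, reg_n)
            assert cluster_signature(cl_f) == cluster_signature(cl_n)


class TestSweepInvariants:
    def test_cross_section_nesting(self, rng):
        counts = random_structured_counts(rng, (10, 10), n_bumps=4)
        hist, _ = hist_from_counts(counts)
        prev_mask = None
        for level in range(hist.level_max - 1, -1, -1):
            mask = dg.threshold_cross_section(hist, level)
            if prev_mask is not None:
                assert np.all(mask >= prev_mask)  # bin sets nest downward
                labels = dg.label_aggregates(mask).labels
                prev_labels = dg.label_aggregates(prev_mask).labels
                # every aggregate of the higher level lies inside exactly one
                # aggregate of this level
                for lab in np.unique(prev_labels[prev_labels > 0]):
                    parents = np.unique(labels[prev_labels == lab])
                    assert len(parents) == 1 and parents[0] > 0
            prev_mask = mask

    def test_cluster_disjointness_and_membership(self, rng):
        for rep in range(3):
            counts = random_structured_counts(rng, (12, 12), n_bumps=4, scale=300)
            hist, events = hist_from_counts(counts)
            registry, final = dg.sweep_levels(hist)
            clusters = dg.extract_clusters(events, hist, final, registry)
            all_bins = np.concatenate([r.bins for r in clusters])
            assert len(all_bins) == len(set(all_bins.tolist()))
            all_members = np.concatenate([r.members for r in clusters])
            assert len(all_members) == len(set(all_members.tolist()))
            assert sum(r.C for r in clusters) <= hist.total
            for r in clusters:
                assert r.Lp >= r.Ls >= 0
                assert 0 < r.f <= 1
                member_bins = set(hist.event_bins[r.members].tolist())
                assert member_bins <= set(r.bins.tolist())

    def test_codes_ordered_by_population(self, rng):
        counts = random_structured_counts(rng, (12, 12), n_bumps=4, scale=300)
        hist, events = hist_from_counts(counts)
        registry, final = dg.sweep_levels(hist)
        clusters = dg.extract_clusters(events, hist, final, registry)
        sizes = [r.C for r in clusters]
        assert sizes == sorted(sizes, reverse=True)
        assert [r.code for r in clusters] == list(range(1, len(clusters) + 1))


class TestClusterPipeline:
    def test_two_separated_gaussians_recovered(self):
        specs = [
            dg.ComponentSpec(mean=(0.0, 0.0), sd=(1.0, 1.0), count=10_000),
            dg.ComponentSpec(mean=(8.0, 8.0), sd=(1.0, 1.0), count=10_000),
        ]
        events, labels = dg.make_mixture(specs, seed=7)
        clusters = dg.cluster(events)
        centers = sorted((tuple(r.center) for r in clusters if r.C > 100))
        assert len(centers) == 2
        assert np.allclose(centers[0], (0, 0), atol=0.2)
        assert np.allclose(centers[1], (8, 8), atol=0.2)

    def test_background_noise_does_not_change_cluster_count(self):
        events, _ = dg.four_gaussian_mixture_2d(n=50_000, seed=11)
        base = dg.cluster(events)
        noisy, _ = dg.add_uniform_background(events, fraction=0.05, seed=11)
        withnoise = dg.cluster(noisy)
        assert len(base) == len(withnoise) == 4

    def test_input_validation(self, rng):
        with pytest.raises(ValueError, match="at least"):
            dg.cluster(rng.normal(size=(50, 2)))
        with pytest.raises(ValueError, match="identical"):
            dg.cluster(np.full((500, 2), 1.0))
        with pytest.raises(ValueError, match="critical dimension"):
            dg.cluster(rng.normal(size=(500, 6)))
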