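import itertools

import numpy as np
import pytest

from tumorseg.core_io import GrayImage, Histogram, ValidationError
from tumorseg.synthetic import make_histogram_fixture
from tumorseg.thresholding import (
    DEConfig,
    ThresholdVector,
    TsallisEvaluator,
    TsallisParams,
    aggregate_threshold,
    binarize,
    optimize_thresholds,
    shannon_limit,
    tsallis_objective,
)

# ---------------------------------------------------------------------------
# independent oracle: direct summation over classes, written before the
# implementation and kept deliberately naive
# ---------------------------------------------------------------------------


def tsallis_direct(probs, thresholds, gamma):
    edges = [-1] + list(thresholds) + [255]
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        seg = probs[a + 1 : b + 1]
        p = seg.sum()
        if p <= 0:
            continue
        inner = sum((x / p) ** gamma for x in seg if x > 0)
        total += (1 - inner) / (gamma - 1)
    return total


def exhaustive_max(hist, m, gamma):
    ev = TsallisEvaluator(hist, gamma)
    if m == 1:
        cands = np.arange(1, 255)[:, None]
    else:
        cands = np.array([(a, b) for a in range(1, 255) for b in range(a, 255)])
    return float(ev.objective_batch(cands).max())


class TestTsallisObjective:
    def test_single_bin_class_contributes_zero(self):
        h = np.zeros(256)
        h[10] = 0.5
        h[200] = 0.5
        hist = Histogram.from_probs(h)
        # threshold at 100 -> two single-bin classes -> total 0
        assert tsallis_objective(hist, (100,), gamma=2.0) == 0.0

    def test_two_bin_class_closed_form(self):
        # one class holding both equal bins: (1 - 2*(0.5)^2)/(2-1) = 0.5
        h = np.zeros(256)
        h[0] = h[1] = 0.5
        hist = Histogram.from_probs(h)
        assert tsallis_objective(hist, (100,), gamma=2.0) == pytest.approx(0.5, abs=1e-15)

    # frozen values computed by the direct-summation oracle ahead of the build
    @pytest.mark.parametrize(
        "gamma,expected",
        [
            (0.5, 3.927937249087595),
            (2.0, 1.46),
            (4.0, 0.6500666666666667),
        ],
    )
    def test_eight_level_fixture_frozen_oracle(self, gamma, expected):
        hist = make_histogram_fixture("eight_level")
        got = tsallis_objective(hist, (3,), gamma=gamma)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(tsallis_direct(hist.probs, (3,), gamma), abs=1e-12)

    @pytest.mark.parametrize("kind", ["two_spike", "uniform8", "uniform16", "trimodal"])
    @pytest.mark.parametrize("gamma", [0.5, 2.0, 4.0])
    def test_matches_direct_oracle_on_random_thresholds(self, kind, gamma, rng):
        hist = make_histogram_fixture(kind)
        for _ in range(10):
            m = int(rng.integers(1, 7))
            ts = tuple(sorted(int(v) for v in rng.integers(1, 255, size=m)))
            got = tsallis_objective(hist, ts, gamma=gamma)
            want = tsallis_direct(hist.probs, ts, gamma)
            assert got == pytest.approx(want, abs=1e-9)

    def test_gamma_one_rejected(self):
        hist = make_histogram_fixture("uniform8")
        with pytest.raises(ValidationError, match="Shannon"):
            tsallis_objective(hist, (100,), gamma=1.0)

    def test_unsorted_rejected(self):
        hist = make_histogram_fixture("uniform8")
        with pytest.raises(ValidationError):
            tsallis_objective(hist, (200, 100), gamma=0.5)

    def test_scale_invariance(self, rng):
        # objective depends on probs only; doubling counts changes nothing
        h = rng.random(256)
        hist1 = Histogram.from_probs(h)
        hist2 = Histogram(counts=hist1.counts * 2, probs=hist1.probs)
        ts = (60, 120, 190)
        assert tsallis_objective(hist1, ts, gamma=0.5) == tsallis_objective(
            hist2, ts, gamma=0.5
        )


class TestShannonLimit:
    def test_single_bin_class_zero(self):
        h = np.zeros(256)
        h[5] = 1.0
        assert shannon_limit(Histogram.from_probs(h), (100,)) == 0.0

    def test_uniform_two_bin_ln2(self):
        h = np.zeros(256)
        h[0] = h[1] = 0.5
        assert shannon_limit(Histogram.from_probs(h), (100,)) == pytest.approx(np.log(2))

    def test_eight_level_frozen_value(self):
        hist = make_histogram_fixture("eight_level")
        assert shannon_limit(hist, (3,)) == pytest.approx(2.6983378877793243, abs=1e-12)

    @pytest.mark.parametrize("kind", ["two_spike", "uniform8", "uniform16", "eight_level"])
    def test_gamma_to_one_limit(self, kind):
        hist = make_histogram_fixture(kind)
        for ts in [(50,), (40, 130), (30, 100, 210)]:
            lim = shannon_limit(hist, ts)
            near = tsallis_objective(hist, ts, gamma=1 + 1e-6)
            assert abs(near - lim) <= 1e-3


class TestOptimizeThresholds:
    def test_two_spike_attains_exhaustive_max(self):
        hist = make_histogram_fixture("two_spike")
        best = exhaustive_max(hist, 1, 0.5)
        tv = optimize_thresholds(hist, TsallisParams(gamma=0.5, m=1), DEConfig(seed=1))
        assert tv.objective == pytest.approx(best, abs=1e-12)

    @pytest.mark.parametrize("kind", ["two_spike", "uniform8", "uniform16", "eight_level"])
    @pytest.mark.parametrize("gamma", [0.5, 2.0, 4.0])
    @pytest.mark.parametrize("m", [1, 2])
    def test_oracle_equivalence_seed1(self, kind, gamma, m):
        hist = make_histogram_fixture(kind)
        best = exhaustive_max(hist, m, gamma)
        tv = optimize_thresholds(hist, TsallisParams(gamma=gamma, m=m), DEConfig(seed=1))
        assert tv.objective == pytest.approx(best, abs=1e-12)

    def test_monotone_best_so_far(self):
        hist = make_histogram_fixture("trimodal")
        for seed in (1, 2, 3):
            tv = optimize_thresholds(hist, TsallisParams(gamma=0.5, m=4), DEConfig(seed=seed))
            assert np.all(np.diff(tv.trace) >= 0)

    def test_degenerate_de_still_monotone(self):
        hist = make_histogram_fixture("uniform16")
        cfg = DEConfig(seed=3, weighting_factor=1e-9, crossover_prob=0.0)
        tv = optimize_thresholds(hist, TsallisParams(gamma=2.0, m=2), cfg)
        assert np.all(np.diff(tv.trace) >= 0)

    def test_deterministic_under_seed(self):
        hist = make_histogram_fixture("trimodal")
        a = optimize_thresholds(hist, TsallisParams(gamma=0.5, m=6), DEConfig(seed=9))
        b = optimize_thresholds(hist, TsallisParams(gamma=0.5, m=6), DEConfig(seed=9))
        assert a.values == b.values and a.objective == b.objective

    def test_small_population_rejected(self):
        hist = make_histogram_fixture("uniform8")
        with pytest.raises(ValidationError):
            optimize_thresholds(hist, TsallisParams(gamma=0.5, m=1), DEConfig(np_size=3))

    def test_objective_stored_consistently(self):
        hist = make_histogram_fixture("trimodal")
        tv = optimize_thresholds(hist, TsallisParams(gamma=0.5, m=3), DEConfig(seed=4))
        assert tv.objective == pytest.approx(
            tsallis_objective(hist, tv.values, gamma=0.5), abs=1e-12
        )


class TestAggregateThreshold:
    def test_six_values(self):
        tv = ThresholdVector(values=(10, 20, 30, 40, 50, 60), objective=0.0)
        assert aggregate_threshold(tv) == pytest.approx(50.0)

    def test_all_equal(self):
        tv = ThresholdVector(values=(7, 7, 7, 7), objective=0.0)
        assert aggregate_threshold(tv) == 7.0

    def test_m3_uses_all(self):
        tv = ThresholdVector(values=(5, 7, 100), objective=0.0)
        assert aggregate_threshold(tv) == pytest.approx(112 / 3)

    def test_m_below_three_rejected(self):
        tv = ThresholdVector(values=(5, 9), objective=0.0)
        with pytest.raises(ValidationError):
            aggregate_threshold(tv)


class TestBinarize:
    def test_below_lower_bound_all_true(self, rng):
        img = GrayImage(pixels=rng.random((6, 6)))
        assert binarize(img, -1.0).pixels.all()

    def test_at_upper_bound_all_false(self, rng):
        img = GrayImage(pixels=rng.random((6, 6)))
        assert not binarize(img, 255.0).pixels.any()

    def test_elementwise_strict_comparison(self):
        q = np.array([[10, 100], [150, 200]]) / 255.0
        img = GrayImage(pixels=q)
        mask = binarize(img, 120.0)
        np.testing.assert_array_equal(mask.pixels, [[False, False], [True, True]])
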