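"""Agreement statistics: Delta_R, Bland-Altman limits, detection, weighted kappa."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cacforge.evalstats import (
    BlandAltmanFit,
    ScorePair,
    ba_coverage,
    bland_altman,
    delta_r,
    detection_metrics,
    pair_delta_r,
    weighted_kappa,
)

from .oracles import weighted_kappa_oracle


def pairs_from(ctac, csct):
    return [ScorePair(f"p{i}", a, b) for i, (a, b) in enumerate(zip(ctac, csct))]


class TestDeltaR:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(100, 100, 0.0), (50, 100, 200 * 50 / 150), (0, 100, 200.0), (0, 0, 0.0)],
    )
    def test_pair_values(self, a, b, expected):
        assert pair_delta_r(a, b) == pytest.approx(expected)

    def test_concordant_average_restricted_to_double_positive(self):
        pairs = pairs_from([100, 0, 50], [100, 100, 100])
        all_avg, conc_avg = delta_r(pairs)
        assert all_avg == pytest.approx((0 + 200 + 200 / 3) / 3)
        assert conc_avg == pytest.approx((0 + 200 / 3) / 2)

    def test_no_concordant_pairs_gives_none(self):
        _, conc = delta_r(pairs_from([0, 0], [5, 7]))
        assert conc is None

    def test_double_zero_exclusion_flag(self):
        pairs = pairs_from([0, 100], [0, 100])
        incl, _ = delta_r(pairs, include_double_zero=True)
        excl, _ = delta_r(pairs, include_double_zero=False)
        assert incl == pytest.approx(0.0)
        assert excl == pytest.approx(0.0)
        pairs = pairs_from([0, 50], [0, 100])
        incl, _ = delta_r(pairs, include_double_zero=True)
        excl, _ = delta_r(pairs, include_double_zero=False)
        assert excl == pytest.approx(2 * incl)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            delta_r([])

    @given(
        a=st.floats(min_value=0, max_value=1e6, allow_nan=False),
        b=st.floats(min_value=0, max_value=1e6, allow_nan=False),
        c=st.floats(min_value=1e-3, max_value=1e3, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry_scale_invariance_and_range(self, a, b, c):
        v = pair_delta_r(a, b)
        assert v == pytest.approx(pair_delta_r(b, a))
        assert 0.0 <= v <= 200.0
        assert pair_delta_r(c * a, c * b) == pytest.approx(v, rel=1e-9, abs=1e-9)


class TestBlandAltman:
    def test_constant_difference_has_zero_spread(self):
        pairs = pairs_from([110, 210, 310], [100, 200, 300])
        fit = bland_altman(pairs)
        assert fit.b == pytest.approx(10.0)
        assert fit.a == pytest.approx(0.0, abs=1e-12)
        lo, hi = fit.limits([150.0])
        assert lo[0] == pytest.approx(10.0)
        assert hi[0] == pytest.approx(10.0)

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            bland_altman(pairs_from([1, 2], [1, 2]))

    def test_all_zero_means_raises(self):
        with pytest.raises(ValueError):
            bland_altman(pairs_from([0, 0, 0], [0, 0, 0]))

    def test_recovers_simulated_heteroscedastic_model(self):
        # d = b* + a* sqrt(mean) eps: recovered b within 2%, a (x sqrt(pi/2))
        # within 5%, limit curves cover 94-96% of points at n = 10,000
        rng = np.random.default_rng(2024)
        n = 10_000
        b_true, a_true = 500.0, 3.0
        means = rng.uniform(500, 3000, n)
        d = b_true + a_true * np.sqrt(means) * rng.standard_normal(n)
        ctac = means + d / 2
        csct = means - d / 2
        assert (ctac >= 0).all() and (csct >= 0).all()
        pairs = pairs_from(ctac, csct)
        fit = bland_altman(pairs)
        assert fit.b == pytest.approx(b_true, rel=0.02)
        # slope of |d-b| on sqrt(mean) estimates a* E|N(0,1)| = a* sqrt(2/pi);
        # the half-normal factor restores a*
        assert fit.a * math.sqrt(math.pi / 2) == pytest.approx(a_true, rel=0.05)
        assert 0.94 <= ba_coverage(pairs, fit) <= 0.96

    def test_limit_curves_widen_with_mean(self):
        fit = BlandAltmanFit(b=0.0, a=2.0)
        lo1, hi1 = fit.limits([100.0])
        lo2, hi2 = fit.limits([400.0])
        assert hi2[0] == pytest.approx(2 * hi1[0])
        assert lo2[0] == pytest.approx(2 * lo1[0])


class TestDetectionMetrics:
    def test_perfect_agreement(self):
        sens, spec, f1 = detection_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert (sens, spec, f1) == (1.0, 1.0, 1.0)

    def test_hand_computed_2x2(self):
        sens, spec, f1 = detection_metrics([1, 1, 0, 0], [1, 0, 1, 0])
        assert sens == pytest.approx(0.5)
        assert spec == pytest.approx(0.5)
        assert f1 == pytest.approx(0.5)

    def test_all_negative_predictions(self):
        sens, spec, f1 = detection_metrics([0, 0, 0], [1, 0, 1])
        assert sens == 0.0
        assert f1 == 0.0

    def test_undefined_sensitivity_reported_missing(self):
        sens, spec, f1 = detection_metrics([0, 1], [0, 0])
        assert sens is None
        assert spec == pytest.approx(0.5)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            detection_metrics([1, 0], [1])


class TestWeightedKappa:
    def test_identical_lists_give_one(self):
        kappa, lo, hi = weighted_kappa([1, 2, 3, 4, 5, 3], [1, 2, 3, 4, 5, 3])
        assert kappa == pytest.approx(1.0)
        assert hi >= kappa >= lo

    def test_independence_gives_zero(self):
        # both raters uniform, observed agreement equal to chance
        a = [1, 1, 2, 2] * 2
        b = [1, 2] * 4
        kappa, _, _ = weighted_kappa(a, b, n_categories=2)
        assert kappa == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_loop_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            a = rng.integers(1, 6, n).tolist()
            b = np.clip(np.array(a) + rng.integers(-2, 3, n), 1, 5).tolist()
            kappa, _, _ = weighted_kappa(a, b)
            oracle = weighted_kappa_oracle(a, b)
            if oracle is None:
                assert kappa is None
            else:
                assert kappa == pytest.approx(oracle, abs=1e-12)

    def test_matches_sklearn_linear_weights(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(8)
        a = rng.integers(1, 6, 80)
        b = np.clip(a + rng.integers(-1, 2, 80), 1, 5)
        kappa, _, _ = weighted_kappa(a.tolist(), b.tolist())
        ref = sklearn.cohen_kappa_score(a, b, labels=[1, 2, 3, 4, 5], weights="linear")
        assert kappa == pytest.approx(ref, abs=1e-12)

    def test_equals_unweighted_when_two_categories(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(9)
        a = rng.integers(1, 3, 60)
        b = rng.integers(1, 3, 60)
        kappa, _, _ = weighted_kappa(a.tolist(), b.tolist(), n_categories=2)
        ref = sklearn.cohen_kappa_score(a, b)
        assert kappa == pytest.approx(ref, abs=1e-12)

    def test_constant_identical_raters_undefined(self):
        kappa, lo, hi = weighted_kappa([3, 3, 3], [3, 3, 3])
        assert kappa is None

    def test_ci_shrinks_with_sample_size(self):
        rng = np.random.default_rng(10)
        a_small = rng.integers(1, 6, 30)
        b_small = np.clip(a_small + rng.integers(-1, 2, 30), 1, 5)
        a_big = np.tile(a_small, 10)
        b_big = np.tile(b_small, 10)
        _, lo_s, hi_s = weighted_kappa(a_small.tolist(), b_small.tolist())
        _, lo_b, hi_b = weighted_kappa(a_big.tolist(), b_big.tolist())
        assert (hi_b - lo_b) < (hi_s - lo_s)

    def test_out_of_range_category_raises(self):
        with pytest.raises(ValueError):
            weighted_kappa([0, 1], [1, 2])
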