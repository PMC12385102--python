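import numpy as np
import pytest
from scipy import stats

from mrpath.errors import InsufficientInstrumentsError, UndefinedRatioError
from mrpath.estimators import (
    ivw,
    mr_egger,
    triangulate,
    wald_ratio,
    weighted_median,
    weighted_median_point,
)
from mrpath.simulate import SimTruth, simulate_two_sample
from mrpath.summary_stats import harmonize

from conftest import make_dataset


class TestWaldRatio:
    def test_hand_value(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.01).beta == 0.0

    def test_sign_propagates(self):
        assert wald_ratio(-0.1, 0.01, 0.05, 0.01).beta == pytest.approx(-0.5)
        assert wald_ratio(-0.1, 0.01, 0.05, 0.01).se == pytest.approx(0.1)

    def test_zero_exposure_effect(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.01, 0.05, 0.01)


class TestIvw:
    def test_closed_form_equal_weights(self):
        data = make_dataset([0.1, 0.2, 0.3], [0.02, 0.05, 0.09], [0.01] * 3)
        est = ivw(data, model="fixed")
        assert est.beta == pytest.approx(0.039 / 0.14)

    def test_equal_weights_reduce_to_origin_ols(self, rng):
        bx = rng.normal(0.1, 0.05, 30)
        by = rng.normal(0.02, 0.01, 30)
        data = make_dataset(bx, by, np.full(30, 0.03))
        ols_slope = float(np.linalg.lstsq(bx[:, None], by, rcond=None)[0][0])
        assert ivw(data, model="fixed").beta == pytest.approx(ols_slope, rel=1e-12)

    def test_closed_form_on_random_instances(self, rng):
        for _ in range(100):
            k = rng.integers(3, 40)
            bx = rng.normal(0, 0.2, k)
            bx[np.abs(bx) < 1e-3] = 0.1
            by = rng.normal(0, 0.05, k)
            se_y = rng.uniform(0.01, 0.1, k)
            w = 1.0 / se_y**2
            expected = np.sum(w * bx * by) / np.sum(w * bx * bx)
            got = ivw(make_dataset(bx, by, se_y), model="fixed").beta
            assert abs(got - expected) <= 1e-10 * max(1.0, abs(expected))

    def test_degenerate_equal_ratios(self):
        bx = np.array([0.1, 0.2, 0.4])
        data = make_dataset(bx, 0.3 * bx, [0.01] * 3)
        est = ivw(data)
        assert est.beta == pytest.approx(0.3)
        # Q = 0 means the random-effects SE equals the fixed SE
        assert est.se == pytest.approx(ivw(data, model="fixed").se)

    def test_random_effects_never_tightens(self, rng):
        bx = rng.normal(0.2, 0.05, 20)
        by = rng.normal(0.05, 0.05, 20)
        data = make_dataset(bx, by, np.full(20, 0.01))
        assert ivw(data).se >= ivw(data, model="fixed").se
        assert ivw(data).beta == pytest.approx(ivw(data, model="fixed").beta)

    def test_single_row_is_insufficient(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_dataset([0.1], [0.02], [0.01]))

    def test_duplicated_row_matches_wald_point(self):
        w = wald_ratio(0.1, 0.01, 0.05, 0.02)
        data = make_dataset([0.1, 0.1], [0.05, 0.05], [0.02, 0.02])
        assert ivw(data).beta == pytest.approx(w.beta)


class TestMrEgger:
    def test_exact_linear_data_recovers_intercept_and_slope(self, rng):
        bx = np.abs(rng.normal(0.2, 0.05, 10))
        by = 0.02 + 0.3 * bx
        fit = mr_egger(make_dataset(bx, by, np.full(10, 0.01)))
        assert fit.intercept == pytest.approx(0.02, abs=1e-12)
        assert fit.slope.beta == pytest.approx(0.3, abs=1e-12)

    def test_orientation_invariance(self, rng):
        bx = rng.normal(0.1, 0.2, 15)
        by = rng.normal(0.0, 0.05, 15)
        se = rng.uniform(0.01, 0.05, 15)
        base = mr_egger(make_dataset(bx, by, se))
        flipped = mr_egger(make_dataset(-bx, -by, se))
        assert flipped.slope.beta == pytest.approx(base.slope.beta, rel=1e-10)
        assert flipped.intercept == pytest.approx(base.intercept, rel=1e-10)

    def test_balanced_pleiotropy_intercept_p_is_calibrated(self):
        """Zero-mean pleiotropy: the intercept test should reject ~5%."""
        rej = 0
        reps = 200
        for s in range(reps):
            b = simulate_two_sample(
                SimTruth(theta=0.11, pleiotropy_mean=0.0, pleiotropy_sd=0.03,
                         pleiotropy_fraction=1.0, seed=90_000 + s)
            )
            d = harmonize(b.exposure, b.outcome)
            rej += mr_egger(d).intercept_pvalue < 0.05
        assert 0.02 <= rej / reps <= 0.09

    def test_too_few_rows(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(make_dataset([0.1, 0.2], [0.02, 0.05], [0.01, 0.01]))


def weighted_quantile_oracle(ratios, weights, q=0.5):
    """Scalar restatement of the interpolated weighted-quantile definition."""
    order = np.argsort(ratios)
    r = [ratios[i] for i in order]
    w = [weights[i] / sum(weights) for i in order]
    s, cum = [], 0.0
    for wi in w:
        s.append(cum + wi / 2.0)
        cum += wi
    if q <= s[0]:
        return r[0]
    for j in range(1, len(s)):
        if q <= s[j]:
            frac = (q - s[j - 1]) / (s[j] - s[j - 1])
            return r[j - 1] + frac * (r[j] - r[j - 1])
    return r[-1]


class TestWeightedMedian:
    def test_odd_equal_weights_is_middle_ratio(self):
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.3, 0.8])
        assert weighted_median_point(bx, by, np.ones(3)) == pytest.approx(0.3)

    def test_matches_quantile_oracle_on_random_instances(self, rng):
        for _ in range(100):
            k = int(rng.integers(3, 30))
            bx = rng.normal(0.2, 0.1, k)
            bx[np.abs(bx) < 1e-3] = 0.05
            by = rng.normal(0.05, 0.05, k)
            se_y = rng.uniform(0.01, 0.1, k)
            got = weighted_median_point(bx, by, se_y)
            expected = weighted_quantile_oracle(by / bx, (bx / se_y) ** 2)
            assert abs(got - expected) <= 1e-10 * max(1.0, abs(expected))

    def test_bootstrap_se_is_seed_reproducible(self, rng):
        bx = rng.normal(0.2, 0.05, 10)
        by = rng.normal(0.05, 0.02, 10)
        data = make_dataset(bx, by, np.full(10, 0.02))
        a = weighted_median(data, n_boot=200, seed=42)
        b = weighted_median(data, n_boot=200, seed=42)
        assert a.se == b.se
        assert a.beta == b.beta

    def test_majority_valid_instruments_keep_consistency(self, rng):
        """>=50% of weight from valid instruments: gross pleiotropy in the
        minority should barely move the estimate."""
        theta = 0.3
        bx = np.abs(rng.normal(0.3, 0.05, 21))
        by = theta * bx
        by[:8] += 5.0  # grossly pleiotropic minority
        est = weighted_median_point(bx, by, np.full(21, 0.02))
        assert est == pytest.approx(theta, abs=0.05)


class TestTriangulate:
    def _est(self, beta, p, method="x"):
        from mrpath.estimators import MrEstimate
        return MrEstimate(method, beta, 0.1, beta - 0.2, beta + 0.2,
                          np.exp(beta), 1.0, 1.0, p, 10)

    def _egger(self, beta):
        from mrpath.estimators import EggerFit
        return EggerFit(self._est(beta, 0.2, "egger_slope"), 0.0, 0.01, 0.5)

    def test_all_aligned_and_significant(self):
        v = triangulate(self._est(0.1, 0.01), self._est(0.2, 0.2), self._egger(0.05))
        assert v.significant

    def test_direction_clash_blocks_significance(self):
        v = triangulate(self._est(0.1, 0.01), self._est(0.2, 0.2), self._egger(-0.05))
        assert not v.significant
        assert v.ivw_significant and not v.egger_direction_consistent

    def test_insignificant_ivw_blocks_regardless(self):
        v = triangulate(self._est(0.1, 0.35), self._est(0.2, 0.2), self._egger(0.05))
        assert not v.significant


def test_estimators_equivariant_under_global_sign_flip(rng):
    bx = rng.normal(0.15, 0.1, 12)
    by = rng.normal(0.04, 0.03, 12)
    se_y = rng.uniform(0.01, 0.05, 12)
    d_pos = make_dataset(bx, by, se_y)
    d_neg = make_dataset(-bx, -by, se_y)
    assert ivw(d_neg).beta == pytest.approx(ivw(d_pos).beta, rel=1e-12)
    assert weighted_median_point(-bx, -by, se_y) == pytest.approx(
        weighted_median_point(bx, by, se_y), rel=1e-10
    )
    assert mr_egger(d_neg).slope.beta == pytest.approx(
        mr_egger(d_pos).slope.beta, rel=1e-10
    )


def test_ivw_null_pvalue_roughly_uniform_small_batch():
    """Cheap sanity layer under the full calibration run: at theta=0 the IVW
    p-value distribution should not be visibly skewed."""
    ps = []
    for s in range(100):
        b = simulate_two_sample(SimTruth(theta=0.0, seed=95_000 + s))
        d = harmonize(b.exposure, b.outcome)
        ps.append(ivw(d).pvalue)
    assert stats.kstest(ps, "uniform").pvalue > 0.01
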