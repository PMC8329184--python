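"""Two-sample MR estimators, heterogeneity and the bidirectional driver."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kynscan.errors import (
    DegenerateInstrumentsError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from kynscan.mr import (
    MRInput,
    bidirectional_mr,
    egger,
    ivw,
    wald_ratio,
    weighted_median,
)
from kynscan.simdata import SimConfig, simulate_two_sample_sumstats


def minput(bx, by, sx=None, sy=None):
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    sy = np.full_like(by, 0.01) if sy is None else np.asarray(sy, float)
    return MRInput(bx=bx, sx=sx, by=by, sy=sy)


class TestWaldRatio:
    def test_arithmetic(self):
        r = wald_ratio(0.1, 0.01, 0.02, 0.01)
        assert r.estimate == pytest.approx(0.2)
        assert r.se == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.01).estimate == 0.0

    def test_orientation_invariance(self):
        a = wald_ratio(0.1, 0.01, 0.02, 0.01)
        b = wald_ratio(-0.1, 0.01, -0.02, 0.01)
        assert a.estimate == pytest.approx(b.estimate)
        assert a.se == pytest.approx(b.se)

    def test_zero_exposure_raises(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.01, 0.02, 0.01)


def wls_oracle(bx, by, sy, intercept=False):
    """Independent matrix-algebra weighted least squares."""
    w = 1.0 / np.asarray(sy) ** 2
    X = (np.column_stack([np.ones_like(bx), bx]) if intercept
         else np.asarray(bx)[:, None])
    W = np.diag(w)
    coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ np.asarray(by))
    cov = np.linalg.inv(X.T @ W @ X)
    return coef, np.sqrt(np.diag(cov))


class TestIvw:
    def test_single_variant_reduces_to_wald(self):
        inp = minput([0.1], [0.02])
        r = ivw(inp)
        w = wald_ratio(0.1, 0.01, 0.02, 0.01)
        assert r.estimate == pytest.approx(w.estimate)
        assert r.se == pytest.approx(w.se)

    def test_perfect_homogeneity(self):
        inp = minput([0.1, 0.2, 0.4], [0.03, 0.06, 0.12])
        r = ivw(inp)
        assert r.estimate == pytest.approx(0.3)
        assert r.Q == pytest.approx(0.0, abs=1e-20)

    def test_matches_zero_intercept_wls_closed_form(self):
        bx = np.array([0.1, 0.2, 0.15])
        by = np.array([0.025, 0.038, 0.031])
        sy = np.array([0.01, 0.01, 0.02])
        r = ivw(minput(bx, by, sy=sy))
        coef, se = wls_oracle(bx, by, sy)
        assert r.estimate == pytest.approx(coef[0], abs=1e-10)
        assert r.se == pytest.approx(se[0], abs=1e-10)

    def test_all_zero_exposure_raises(self):
        with pytest.raises(DegenerateInstrumentsError):
            ivw(minput([0.0, 0.0], [0.1, 0.2]))

    @given(st.lists(st.tuples(st.floats(0.05, 0.5), st.floats(-0.2, 0.2),
                              st.floats(0.005, 0.05)), min_size=2, max_size=8))
    def test_wls_equivalence_property(self, rows):
        bx = np.array([r[0] for r in rows])
        by = np.array([r[1] for r in rows])
        sy = np.array([r[2] for r in rows])
        r = ivw(minput(bx, by, sy=sy))
        coef, _ = wls_oracle(bx, by, sy)
        assert r.estimate == pytest.approx(coef[0], abs=1e-10)

    @given(st.integers(0, 2**31 - 1))
    def test_joint_sign_flip_invariance(self, seed):
        rng = np.random.default_rng(seed)
        m = 5
        bx = rng.uniform(0.05, 0.3, m)
        by = rng.normal(0.02, 0.02, m)
        signs = rng.choice([-1.0, 1.0], m)
        a = ivw(minput(bx, by))
        b = ivw(minput(bx * signs, by * signs))
        assert a.estimate == pytest.approx(b.estimate)
        assert a.Q == pytest.approx(b.Q)


class TestEgger:
    def test_no_pleiotropy_limit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        r = egger(minput(bx, 0.5 * bx))
        assert r.estimate == pytest.approx(0.5, abs=1e-10)
        assert r.egger_intercept == pytest.approx(0.0, abs=1e-10)

    def test_affine_recovery(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        r = egger(minput(bx, 0.02 + 0.5 * bx))
        assert r.estimate == pytest.approx(0.5, abs=1e-9)
        assert r.egger_intercept == pytest.approx(0.02, abs=1e-9)

    def test_requires_three_variants(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(minput([0.1, 0.2], [0.02, 0.04]))

    def test_sign_orientation_invariance(self):
        bx = np.array([0.1, -0.2, 0.3, 0.15])
        by = 0.03 + 0.4 * bx
        # a truly oriented copy: all bx positive
        a = egger(minput(bx, by))
        b = egger(minput(np.abs(bx), np.where(bx < 0, -by, by)))
        assert a.estimate == pytest.approx(b.estimate)
        assert a.egger_intercept == pytest.approx(b.egger_intercept)

    def test_less_biased_than_ivw_under_directional_pleiotropy(self):
        theta = 0.2
        reps, m = 60, 50
        egger_err, ivw_err = [], []
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            bx_true = rng.uniform(0.08, 0.2, m)
            alpha = rng.normal(0.03, 0.01, m)  # directional pleiotropy
            sy = np.full(m, 0.02)
            sx = np.full(m, 0.002)  # precise exposure effects (InSIDE regime)
            bx = rng.normal(bx_true, sx)
            by = rng.normal(theta * bx_true + alpha, sy)
            inp = MRInput(bx=bx, sx=sx, by=by, sy=sy)
            egger_err.append(egger(inp).estimate - theta)
            ivw_err.append(ivw(inp).estimate - theta)
        assert abs(np.mean(egger_err)) < abs(np.mean(ivw_err))
        assert abs(np.mean(ivw_err)) > 0.05  # IVW visibly biased upward


class TestWeightedMedian:
    def test_median_reduction_with_equal_weights(self):
        bx = np.ones(3)
        by = np.array([1.0, 2.0, 9.0])
        r = weighted_median(minput(bx, by), n_boot=200, seed=1)
        assert r.estimate == pytest.approx(2.0)

    def test_all_ratios_equal(self):
        bx = np.array([0.1, 0.2, 0.3])
        r = weighted_median(minput(bx, 0.7 * bx, sx=np.full(3, 1e-6),
                                   sy=np.full(3, 1e-6)), n_boot=200, seed=2)
        assert r.estimate == pytest.approx(0.7)
        assert r.se < 1e-4

    def test_robust_to_forty_percent_invalid(self):
        theta = 0.2
        reps, m = 60, 30
        wm_err, ivw_err = [], []
        for seed in range(reps):
            rng = np.random.default_rng(2000 + seed)
            bx_true = rng.uniform(0.08, 0.2, m)
            alpha = np.zeros(m)
            invalid = rng.choice(m, size=int(0.4 * m), replace=False)
            alpha[invalid] = rng.normal(0.08, 0.02, len(invalid))
            sy = np.full(m, 0.02)
            sx = np.full(m, 0.002)
            bx = rng.normal(bx_true, sx)
            by = rng.normal(theta * bx_true + alpha, sy)
            inp = MRInput(bx=bx, sx=sx, by=by, sy=sy)
            wm_err.append(weighted_median(inp, n_boot=200, seed=seed).estimate - theta)
            ivw_err.append(ivw(inp).estimate - theta)
        assert abs(np.mean(wm_err)) < abs(np.mean(ivw_err))

    def test_requires_three_variants(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(minput([0.1, 0.2], [0.02, 0.04]), n_boot=200, seed=0)


class TestCochranQ:
    def test_null_calibration(self):
        """Under homogeneous outcome noise, Q ~ chi2(m-1): rejection at the
        0.95 quantile stays inside the binomial envelope."""
        from scipy import stats

        reps, m, theta = 500, 10, 0.2
        rng = np.random.default_rng(77)
        bx = rng.uniform(0.08, 0.2, m)
        sy = np.full(m, 0.02)
        crit = stats.chi2.ppf(0.95, m - 1)
        rejections = 0
        for _ in range(reps):
            by = rng.normal(theta * bx, sy)
            inp = MRInput(bx=bx, sx=np.full(m, 1e-8), by=by, sy=sy)
            if ivw(inp).Q > crit:
                rejections += 1
        lo, hi = stats.binom.ppf([0.025, 0.975], reps, 0.05)
        assert lo <= rejections <= hi


class TestBidirectional:
    def test_forward_causation_recovered_reverse_null(self):
        """Pure forward causation: exposure instruments recover theta; the
        outcome's own instruments show no reverse effect."""
        cfg = SimConfig(seed=5, n_sample_exposure=8000, n_sample_outcome=8000)
        ts = simulate_two_sample_sumstats(
            cfg, theta=0.3,
            outcome_own_effects=[0.15] * 6, outcome_own_freqs=[0.4] * 6)
        res = bidirectional_mr(ts.exposure, ts.outcome,
                               ts.exposure_instrument_ids,
                               ts.outcome_instrument_ids, seed=9)
        fwd = {r.method: r for r in res.forward}
        rev = {r.method: r for r in res.reverse}
        assert abs(fwd["ivw"].estimate - 0.3) < 3 * fwd["ivw"].se
        assert abs(rev["ivw"].estimate) < 3 * rev["ivw"].se

    def test_symmetric_null_under_confounding(self):
        """No causal path in either direction, only a shared confounder:
        both directions stay within 3 SE of zero with valid instruments."""
        cfg = SimConfig(seed=15, confounder_to_metabolite=0.4,
                        confounder_to_disease=0.4,
                        n_sample_exposure=8000, n_sample_outcome=8000)
        ts = simulate_two_sample_sumstats(
            cfg, theta=0.0,
            outcome_own_effects=[0.15] * 6, outcome_own_freqs=[0.4] * 6)
        res = bidirectional_mr(ts.exposure, ts.outcome,
                               ts.exposure_instrument_ids,
                               ts.outcome_instrument_ids, seed=16)
        for direction in (res.forward, res.reverse):
            r = {x.method: x for x in direction}["ivw"]
            assert abs(r.estimate) < 3 * r.se

    def test_self_on_self_gives_unit_ratios(self):
        cfg = SimConfig(seed=6)
        ts = simulate_two_sample_sumstats(cfg, theta=0.0)
        ids = [r.variant_id for r in ts.exposure]
        res = bidirectional_mr(ts.exposure, ts.exposure, ids, ids, seed=1)
        fwd = {r.method: r for r in res.forward}
        assert fwd["ivw"].estimate == pytest.approx(1.0, abs=1e-10)

    def test_empty_direction_skipped_with_warning(self):
        cfg = SimConfig(seed=7)
        ts = simulate_two_sample_sumstats(cfg, theta=0.2)
        ids = [r.variant_id for r in ts.exposure]
        res = bidirectional_mr(ts.exposure, ts.outcome, ids, [], seed=2)
        assert res.forward and not res.reverse
        assert any("reverse" in w for w in res.warnings)
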