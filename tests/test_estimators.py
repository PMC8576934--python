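import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mr2s import estimators as est
from mr2s.exceptions import (
    CorrectionError,
    DegenerateInstrumentError,
    MethodGatingError,
)

from .conftest import make_inst, random_instruments


def flip_subset(instruments, mask):
    """Jointly negate (gamma, Gamma) for the masked subset."""
    out = []
    for inst, do_flip in zip(instruments, mask):
        if do_flip:
            out.append(
                dataclasses.replace(inst, gamma=-inst.gamma, Gamma=-inst.Gamma)
            )
        else:
            out.append(inst)
    return out


class TestWaldRatio:
    def test_exact_arithmetic(self):
        r = est.wald_ratio(make_inst(gamma=0.5, Gamma=0.25, se_Gamma=0.1))
        assert (r.beta_ratio, r.se_ratio) == (0.5, 0.2)

    def test_negative_gamma_sign_handling(self):
        r = est.wald_ratio(make_inst(gamma=-0.5, Gamma=0.25, se_Gamma=0.1))
        assert r.beta_ratio == -0.5
        assert r.se_ratio == pytest.approx(0.2)

    def test_zero_gamma_raises(self):
        with pytest.raises(DegenerateInstrumentError):
            est.wald_ratio(make_inst(gamma=0.0))

    def test_second_order_se_larger(self):
        inst = make_inst(gamma=0.5, se_gamma=0.1, Gamma=0.25, se_Gamma=0.1)
        first = est.wald_ratio(inst).se_ratio
        second = est.wald_ratio(inst, second_order=True).se_ratio
        assert second > first


class TestIvw:
    def test_single_instrument_equals_wald_ratio(self):
        inst = make_inst(gamma=0.5, Gamma=0.25, se_Gamma=0.1)
        fit = est.ivw([inst], model="auto")
        ratio = est.wald_ratio(inst)
        assert fit.method == est.IVW_FIXED
        assert fit.beta == pytest.approx(ratio.beta_ratio)
        assert fit.se == pytest.approx(ratio.se_ratio)

    def test_duplicated_instrument_halves_variance(self):
        inst = make_inst(gamma=0.5, Gamma=0.25, se_Gamma=0.1)
        one = est.ivw([inst], model="fixed")
        two = est.ivw([inst, dataclasses.replace(inst, rsid="rs2")], model="fixed")
        assert two.beta == pytest.approx(one.beta)
        assert two.se == pytest.approx(one.se / math.sqrt(2))

    def test_empty_set_raises(self):
        with pytest.raises(MethodGatingError):
            est.ivw([])

    def test_auto_model_switches_at_four(self, rng):
        three = random_instruments(rng, 3)
        four = random_instruments(rng, 4)
        assert est.ivw(three, model="auto").method == est.IVW_FIXED
        assert est.ivw(four, model="auto").method == est.IVW_RANDOM

    def test_random_se_never_below_fixed(self, rng):
        for _ in range(20):
            insts = random_instruments(rng, 6)
            assert est.ivw(insts, model="random").se >= est.ivw(insts, model="fixed").se

    def test_ci_brackets_beta(self, rng):
        fit = est.ivw(random_instruments(rng, 8))
        assert fit.ci_low <= fit.beta <= fit.ci_high

    def test_oracle_weighted_regression_through_origin(self, rng):
        """Closed form vs an independent WLS fit, 1000 random instances."""
        for _ in range(1000):
            insts = random_instruments(rng, int(rng.integers(2, 12)))
            g = np.array([i.gamma for i in insts])
            G = np.array([i.Gamma for i in insts])
            w = np.array([i.se_Gamma for i in insts]) ** -2
            # weighted least squares through the origin via lstsq on
            # sqrt(w)-scaled data: an independent numerical path
            X = (np.sqrt(w) * g)[:, None]
            y = np.sqrt(w) * G
            slope = np.linalg.lstsq(X, y, rcond=None)[0][0]
            se = float(np.sum(w * g * g)) ** -0.5
            fit = est.ivw(insts, model="fixed")
            assert fit.beta == pytest.approx(slope, abs=1e-10, rel=1e-10)
            assert fit.se == pytest.approx(se, rel=1e-10)

    def test_equivariant_under_reorientation(self, rng):
        insts = random_instruments(rng, 7)
        flipped = flip_subset(insts, rng.random(7) < 0.5)
        a, b = est.ivw(insts), est.ivw(flipped)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)


class TestCochranQ:
    def test_homogeneous_ratios_give_zero(self):
        insts = [
            make_inst(f"rs{j}", gamma=g, Gamma=0.3 * g, se_Gamma=0.1)
            for j, g in enumerate((0.2, 0.4, 0.5))
        ]
        q, p = est.cochran_q(insts, 0.3)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # ratios 0 and 1, unit ratio SEs, reference 0.5 -> Q = 0.5
        insts = [
            make_inst("rs1", gamma=1.0, Gamma=0.0, se_Gamma=1.0),
            make_inst("rs2", gamma=1.0, Gamma=1.0, se_Gamma=1.0),
        ]
        q, p = est.cochran_q(insts, 0.5)
        assert q == pytest.approx(0.5)
        assert p == pytest.approx(float(stats.chi2.sf(0.5, 1)))

    def test_permutation_invariance(self, rng):
        insts = random_instruments(rng, 6)
        q1, _ = est.cochran_q(insts, 0.1)
        q2, _ = est.cochran_q(insts[::-1], 0.1)
        assert q1 == pytest.approx(q2)

    def test_gating(self):
        with pytest.raises(MethodGatingError):
            est.cochran_q([make_inst()], 0.0)


class TestMrEgger:
    def test_exact_line_recovered(self):
        insts = [
            make_inst(f"rs{j}", gamma=g, Gamma=0.1 + 0.5 * g, se_Gamma=0.05)
            for j, g in enumerate((0.2, 0.4, 0.7))
        ]
        fit = est.mr_egger(insts)
        assert fit.beta == pytest.approx(0.5, abs=1e-12)
        assert fit.intercept == pytest.approx(0.1, abs=1e-12)
        assert fit.q_stat == pytest.approx(0.0, abs=1e-12)

    def test_gating_below_three(self, rng):
        with pytest.raises(MethodGatingError, match="minimum of 3"):
            est.mr_egger(random_instruments(rng, 2))

    def test_orientation_invariance_full_flip(self, rng):
        insts = random_instruments(rng, 8)
        flipped = flip_subset(insts, [True] * 8)
        a, b = est.mr_egger(insts), est.mr_egger(flipped)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)

    def test_equivariant_under_subset_reorientation(self, rng):
        insts = random_instruments(rng, 9)
        flipped = flip_subset(insts, rng.random(9) < 0.5)
        a, b = est.mr_egger(insts), est.mr_egger(flipped)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.intercept_pvalue == pytest.approx(b.intercept_pvalue, rel=1e-9)

    def test_constrained_intercept_equals_fixed_ivw(self, rng):
        """Dropping the intercept column reproduces fixed-effect IVW exactly."""
        insts = random_instruments(rng, 6)
        g = np.abs(np.array([i.gamma for i in insts]))
        G = np.array([i.Gamma for i in insts]) * np.sign([i.gamma for i in insts])
        w = np.array([i.se_Gamma for i in insts]) ** -2
        slope = float(np.sum(w * g * G) / np.sum(w * g * g))
        assert slope == pytest.approx(est.ivw(insts, model="fixed").beta, rel=1e-12)

    def test_unbiased_without_pleiotropy(self):
        """Simulation: intercept -> 0 and slope -> true beta at large J."""
        rng = np.random.default_rng(7)
        beta_true = 0.3
        slopes, intercepts = [], []
        for _ in range(300):
            J = 50
            g = rng.uniform(0.05, 0.5, J)
            sG = rng.uniform(0.01, 0.05, J)
            G = beta_true * g + rng.normal(0, sG)
            insts = [
                make_inst(f"rs{j}", gamma=g[j], se_gamma=0.001, Gamma=G[j], se_Gamma=sG[j])
                for j in range(J)
            ]
            fit = est.mr_egger(insts)
            slopes.append(fit.beta)
            intercepts.append(fit.intercept)
        assert np.mean(slopes) == pytest.approx(beta_true, abs=3 * np.std(slopes) / math.sqrt(300))
        assert np.mean(intercepts) == pytest.approx(
            0.0, abs=3 * np.std(intercepts) / math.sqrt(300)
        )


class TestWeightedMedian:
    def test_equal_weights_middle_ratio(self):
        assert est.weighted_median_point([1.0, 2.0, 3.0], [1.0, 1.0, 1.0]) == pytest.approx(2.0)

    def test_equal_weights_odd_J_middle_order_statistic(self, rng):
        for _ in range(10):
            values = rng.normal(size=7)
            got = est.weighted_median_point(values, np.ones(7))
            assert got == pytest.approx(float(np.sort(values)[3]))

    def test_interpolation_formula(self):
        # weights (0.6, 0.2, 0.2): S = (0.3, 0.7, 0.9); interpolating the
        # (S_j, b_(j)) grid at 0.5 gives 1 + (0.5-0.3)/(0.7-0.3) = 1.5,
        # frozen from a brute-force evaluation of the stated rule
        got = est.weighted_median_point([1.0, 2.0, 3.0], [0.6, 0.2, 0.2])
        s = np.array([0.3, 0.7, 0.9])
        brute = float(np.interp(0.5, s, [1.0, 2.0, 3.0]))
        assert got == pytest.approx(brute) == pytest.approx(1.5)

    def test_gating(self, rng):
        with pytest.raises(MethodGatingError):
            est.weighted_median(random_instruments(rng, 2))

    def test_deterministic_under_seed(self, rng):
        insts = random_instruments(rng, 6)
        a = est.weighted_median(insts, n_boot=100, seed=42)
        b = est.weighted_median(insts, n_boot=100, seed=42)
        assert a == b

    def test_row_vectorization_matches_scalar(self, rng):
        b = rng.normal(size=(50, 9))
        w = rng.uniform(0.1, 2.0, 9)
        rows = est._weighted_median_rows(b, w)
        for i in range(50):
            assert rows[i] == pytest.approx(est.weighted_median_point(b[i], w))

    def test_robust_to_minority_pleiotropy(self):
        """<=50% invalid instruments: WM stays near truth, IVW drifts."""
        rng = np.random.default_rng(11)
        beta_true = 0.2
        wm_err, ivw_err = [], []
        for _ in range(60):
            J = 20
            g = rng.uniform(0.1, 0.5, J)
            sG = np.full(J, 0.01)
            alpha = np.zeros(J)
            alpha[:6] = 0.15  # 30% invalid, strongly directional
            G = beta_true * g + alpha + rng.normal(0, sG)
            insts = [
                make_inst(f"rs{j}", gamma=g[j], se_gamma=0.001, Gamma=G[j], se_Gamma=sG[j])
                for j in range(J)
            ]
            wm_err.append(est.weighted_median(insts, n_boot=50, seed=1).beta - beta_true)
            ivw_err.append(est.ivw(insts, model="fixed").beta - beta_true)
        assert abs(np.mean(wm_err)) < abs(np.mean(ivw_err))
        assert abs(np.mean(wm_err)) < 0.02

    def test_equivariance_of_point_estimate(self, rng):
        insts = random_instruments(rng, 7)
        flipped = flip_subset(insts, rng.random(7) < 0.5)
        a = est.weighted_median(insts, n_boot=10, seed=0)
        b = est.weighted_median(flipped, n_boot=10, seed=0)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)


class TestMrPresso:
    def test_deterministic_under_seed(self, rng):
        insts = random_instruments(rng, 8)
        a = est.mr_presso(insts, n_sim=200, seed=5)
        b = est.mr_presso(insts, n_sim=200, seed=5)
        assert a == b

    def test_gating(self, rng):
        with pytest.raises(MethodGatingError):
            est.mr_presso(random_instruments(rng, 2))

    def test_global_p_in_admissible_range(self, rng):
        rep = est.mr_presso(random_instruments(rng, 8), n_sim=100, seed=0)
        assert 1 / 101 <= rep.global_pvalue <= 1.0

    def test_planted_outlier_flagged_and_corrected(self):
        rng = np.random.default_rng(3)
        beta_true = 0.2
        J = 12
        g = rng.uniform(0.1, 0.5, J)
        sG = np.full(J, 0.01)
        G = beta_true * g + rng.normal(0, sG)
        G[4] += 10 * sG[4]  # residual of 10 combined SEs
        insts = [
            make_inst(f"rs{j}", gamma=g[j], se_gamma=0.002, Gamma=G[j], se_Gamma=sG[j])
            for j in range(J)
        ]
        rep = est.mr_presso(insts, n_sim=1000, seed=9)
        assert "rs4" in rep.outlier_rsids
        assert rep.corrected_estimate is not None
        raw_err = abs(rep.raw_estimate.beta - beta_true)
        corr_err = abs(rep.corrected_estimate.beta - beta_true)
        assert corr_err < raw_err
        assert rep.distortion_pvalue is not None

    def test_outlier_rsids_subset_of_instruments(self, rng):
        insts = random_instruments(rng, 8)
        rep = est.mr_presso(insts, n_sim=100, seed=1)
        assert set(rep.outlier_rsids) <= {i.rsid for i in insts}

    def test_all_outliers_raises_correction_error(self):
        # four mutually inconsistent, ultra-precise instruments: every
        # leave-one-out residual is enormous relative to its SE
        insts = [
            make_inst("rs1", gamma=0.3, se_gamma=1e-4, Gamma=0.30, se_Gamma=1e-4),
            make_inst("rs2", gamma=0.3, se_gamma=1e-4, Gamma=-0.30, se_Gamma=1e-4),
            make_inst("rs3", gamma=0.3, se_gamma=1e-4, Gamma=0.90, se_Gamma=1e-4),
            make_inst("rs4", gamma=0.3, se_gamma=1e-4, Gamma=-0.90, se_Gamma=1e-4),
        ]
        with pytest.raises(CorrectionError):
            est.mr_presso(insts, n_sim=200, seed=2)

    def test_null_rejection_rate_near_alpha(self):
        """Global test calibrated under the null (moderate replicate count)."""
        rng = np.random.default_rng(17)
        rejections = 0
        n_reps = 300
        for _ in range(n_reps):
            J = 10
            g = rng.uniform(0.1, 0.5, J)
            sg = np.full(J, 0.005)
            sG = np.full(J, 0.02)
            G = 0.1 * g + rng.normal(0, sG)
            insts = [
                make_inst(f"rs{j}", gamma=float(rng.normal(g[j], sg[j])), se_gamma=sg[j],
                          Gamma=G[j], se_Gamma=sG[j])
                for j in range(J)
            ]
            rep = est.mr_presso(insts, n_sim=200, seed=int(rng.integers(2**31)))
            rejections += rep.global_pvalue < 0.05
        rate = rejections / n_reps
        # binomial 3-sigma band around 0.05
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n_reps)


class TestScaling:
    def test_scaled_estimate_linear_in_factor(self, rng):
        fit = est.ivw(random_instruments(rng, 5))
        scaled = fit.scaled(0.05)
        assert scaled.beta == pytest.approx(fit.beta * 0.05)
        assert scaled.se == pytest.approx(fit.se * 0.05)
        assert scaled.ci_low == pytest.approx(fit.ci_low * 0.05)
        assert scaled.pvalue == fit.pvalue
        assert scaled.q_stat == fit.q_stat


@given(st.integers(0, 2**32 - 1), st.integers(4, 12))
@settings(max_examples=25, deadline=None)
def test_all_estimators_equivariant_under_reorientation(seed, J):
    rng = np.random.default_rng(seed)
    insts = random_instruments(rng, J)
    mask = rng.random(J) < 0.5
    flipped = flip_subset(insts, mask)
    assert est.ivw(insts).beta == pytest.approx(est.ivw(flipped).beta, rel=1e-10)
    assert est.mr_egger(insts).beta == pytest.approx(est.mr_egger(flipped).beta, rel=1e-10)
    a = est.weighted_median(insts, n_boot=5, seed=0).beta
    b = est.weighted_median(flipped, n_boot=5, seed=0).beta
    assert a == pytest.approx(b, rel=1e-10)
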