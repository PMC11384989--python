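"""The five-estimator battery and effect-scale conversions."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from medimr.errors import InsufficientInstrumentsError, NoInstrumentsError
from medimr.estimators import (
    EggerEstimator,
    IVWEstimator,
    beta_to_or,
    egger,
    ivw,
    mode_estimators,
    wald_ratio,
    weighted_median,
)

from conftest import harmonized_truth


def frame(be, bo, se_o, se_e=None):
    be = np.asarray(be, float)
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(len(be))],
            "beta_exp": be,
            "se_exp": np.full(len(be), 0.01) if se_e is None else np.asarray(se_e, float),
            "beta_out": np.asarray(bo, float),
            "se_out": np.asarray(se_o, float),
        }
    )


class TestWaldRatio:
    def test_hand_value(self):
        assert wald_ratio(0.1, 0.02, 0.01) == (pytest.approx(0.2), pytest.approx(0.1))

    def test_zero_outcome(self):
        assert wald_ratio(0.5, 0.0, 0.01)[0] == 0.0

    def test_antisymmetry_in_exposure_sign(self):
        r1, s1 = wald_ratio(0.1, 0.02, 0.01)
        r2, s2 = wald_ratio(-0.1, 0.02, 0.01)
        assert r2 == -r1 and s2 == s1

    def test_zero_exposure_is_domain_error(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.02, 0.01)

    def test_second_order_adds_exposure_variance(self):
        _, s1 = wald_ratio(0.1, 0.02, 0.01)
        _, s2 = wald_ratio(0.1, 0.02, 0.01, se_exp=0.02, second_order=True)
        assert s2 > s1


class TestBetaToOr:
    def test_published_lung_cancer_pairs(self):
        """Log-odds -0.2454 is OR 0.7824; -0.1394 is OR 0.87."""
        assert beta_to_or(-0.2454, 0.1)[0] == pytest.approx(0.7824, abs=5e-5)
        assert beta_to_or(-0.1394, 0.1)[0] == pytest.approx(0.87, abs=5e-3)

    def test_null_effect(self):
        orp, orl, orh = beta_to_or(0.0, 0.1)
        assert orp == 1.0 and orl < 1.0 < orh

    def test_ci_uses_196(self):
        _, orl, orh = beta_to_or(0.5, 0.1)
        assert orl == pytest.approx(math.exp(0.5 - 0.196), rel=1e-12)
        assert orh == pytest.approx(math.exp(0.5 + 0.196), rel=1e-12)


class TestIvw:
    def test_worked_three_snp_example(self, three_snp_harmonized):
        res = ivw(three_snp_harmonized)
        assert res.beta == pytest.approx(0.0165 / 0.0725, rel=1e-12)
        assert res.k == 3

    def test_single_snp_equals_wald_ratio(self):
        H = frame([0.1], [0.02], [0.01])
        res = ivw(H)
        r, sr = wald_ratio(0.1, 0.02, 0.01)
        assert res.beta == pytest.approx(r, rel=1e-12)
        assert res.se == pytest.approx(sr, rel=1e-12)

    def test_linearity_in_outcome(self, three_snp_harmonized):
        base = ivw(three_snp_harmonized).beta
        scaled = three_snp_harmonized.assign(beta_out=three_snp_harmonized["beta_out"] * 3)
        assert ivw(scaled).beta == pytest.approx(3 * base, rel=1e-12)

    def test_fixed_effect_equals_wls_through_origin_oracle(self):
        """IVW == statsmodels WLS of beta_out on beta_exp, weights 1/se_out^2."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            k = rng.integers(2, 40)
            be = rng.normal(0, 0.1, k)
            be[np.abs(be) < 1e-4] = 0.05
            bo = rng.normal(0, 0.05, k)
            se_o = rng.uniform(0.001, 0.05, k)
            H = frame(be, bo, se_o)
            fit = sm.WLS(bo, be, weights=1.0 / se_o**2).fit()
            res = ivw(H, model="fixed")
            assert res.beta == pytest.approx(fit.params[0], abs=1e-12, rel=1e-12)

    def test_random_effects_never_deflates_se(self, three_snp_harmonized):
        fixed = ivw(three_snp_harmonized, model="fixed")
        random = ivw(three_snp_harmonized, model="random_multiplicative")
        assert random.se >= fixed.se

    def test_empty_input(self):
        with pytest.raises(NoInstrumentsError):
            ivw(frame([], [], []))

    def test_row_order_invariance(self, three_snp_harmonized):
        shuffled = three_snp_harmonized.iloc[[2, 0, 1]].reset_index(drop=True)
        assert ivw(shuffled).beta == ivw(three_snp_harmonized).beta

    def test_or_fields_consistent(self, three_snp_harmonized):
        res = ivw(three_snp_harmonized)
        assert res.or_point == pytest.approx(math.exp(res.beta), rel=1e-12)
        assert res.or_low < res.or_point < res.or_high


class TestEgger:
    def test_exact_line_recovered_to_machine_precision(self):
        be = np.array([0.05, 0.1, 0.15, 0.2])
        a, b = 0.01, 0.3
        H = frame(be, a + b * be, [0.01] * 4)
        est = EggerEstimator().fit(H)
        assert est.intercept_ == pytest.approx(a, rel=1e-10)
        assert est.beta_ == pytest.approx(b, rel=1e-10)
        assert "degenerate_fit" in est.result_.extra["flags"]
        assert math.isnan(est.intercept_pval_)

    def test_orientation_flip_invariance(self):
        rng = np.random.default_rng(5)
        be = rng.normal(0, 0.1, 10)
        bo = 0.02 + 0.3 * np.abs(be) * np.sign(be) + rng.normal(0, 0.01, 10)
        H = frame(be, bo, [0.01] * 10)
        flipped = H.copy()
        flipped["beta_exp"] *= -1
        flipped["beta_out"] *= -1
        a, b = EggerEstimator().fit(H), EggerEstimator().fit(flipped)
        assert a.beta_ == pytest.approx(b.beta_, rel=1e-12)
        assert a.intercept_ == pytest.approx(b.intercept_, rel=1e-12)

    def test_matches_statsmodels_wls_after_orientation(self):
        rng = np.random.default_rng(6)
        be = np.abs(rng.normal(0, 0.1, 20))
        bo = 0.01 + 0.25 * be + rng.normal(0, 0.02, 20)
        se_o = rng.uniform(0.005, 0.03, 20)
        est = EggerEstimator().fit(frame(be, bo, se_o))
        fit = sm.WLS(bo, sm.add_constant(be), weights=1.0 / se_o**2).fit()
        assert est.intercept_ == pytest.approx(fit.params[0], rel=1e-10)
        assert est.beta_ == pytest.approx(fit.params[1], rel=1e-10)

    def test_needs_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(frame([0.1, 0.2], [0.02, 0.05], [0.01, 0.01]))


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        H = frame([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], [0.01] * 3)
        assert weighted_median(H, n_boot=50, seed=1).beta == pytest.approx(0.2)

    def test_duplication_invariance(self):
        H = frame([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], [0.01] * 3)
        H2 = pd.concat([H, H], ignore_index=True)
        a = weighted_median(H, n_boot=50, seed=1).beta
        b = weighted_median(H2, n_boot=50, seed=1).beta
        assert a == pytest.approx(b)

    def test_row_order_invariance_with_seed(self):
        rng = np.random.default_rng(7)
        H = frame(rng.normal(0.1, 0.02, 8), rng.normal(0.03, 0.01, 8), [0.01] * 8)
        shuffled = H.iloc[rng.permutation(8)].reset_index(drop=True)
        a = weighted_median(H, n_boot=200, seed=3)
        b = weighted_median(shuffled, n_boot=200, seed=3)
        assert a.beta == b.beta and a.se == b.se

    def test_seed_required(self):
        H = frame([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], [0.01] * 3)
        with pytest.raises(ValueError, match="seed"):
            weighted_median(H)


class TestModes:
    def test_point_mass(self):
        H = frame([1.0, 1.0, 1.0], [0.25, 0.25, 0.25], [0.01] * 3)
        assert mode_estimators(H, n_boot=20, seed=1).beta == 0.25

    def test_majority_cluster_wins_over_mean(self):
        be = np.ones(10)
        bo = np.array([0.25] * 7 + [0.6] * 3) + np.linspace(-0.002, 0.002, 10)
        H = frame(be, bo, [0.005] * 10)
        for weighted in (False, True):
            est = mode_estimators(H, weighted=weighted, n_boot=50, seed=2)
            assert abs(est.beta - 0.25) < 0.05
            assert est.beta < np.mean(bo)  # not dragged to the mean

    def test_bandwidth_scaling_stays_in_support(self):
        rng = np.random.default_rng(9)
        bo = rng.normal(0.2, 0.05, 12)
        H = frame(np.ones(12), bo, [0.01] * 12)
        for phi in (0.5, 1.0, 2.0):
            est = mode_estimators(H, bandwidth_phi=phi, n_boot=20, seed=2)
            assert bo.min() <= est.beta <= bo.max()


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=20, derandomize=True)
def test_ivw_equals_closed_form_weighted_mean_of_ratios(seed):
    """Property: IVW == inverse-variance weighted mean of the Wald ratios."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, 30))
    be = rng.normal(0, 0.1, k)
    be[np.abs(be) < 1e-4] = 0.02
    bo = rng.normal(0, 0.03, k)
    se_o = rng.uniform(0.001, 0.05, k)
    r = bo / be
    w = (be / se_o) ** 2
    expected = np.sum(w * r) / np.sum(w)
    assert ivw(frame(be, bo, se_o), model="fixed").beta == pytest.approx(expected, rel=1e-10)


def test_all_five_estimators_recover_planted_effect(sim_factory):
    """Single strong-instrument simulation: every estimator lands near theta."""
    sim = sim_factory(seed=101, n_instruments=50, n_null_snps=0, theta=0.25,
                      n_exposure=200_000, gamma_sd=0.1)
    H = harmonized_truth(sim)
    estimates = {
        "ivw": ivw(H).beta,
        "egger": egger(H).beta,
        "wm": weighted_median(H, n_boot=200, seed=1).beta,
        "smode": mode_estimators(H, weighted=False, n_boot=100, seed=1).beta,
        "wmode": mode_estimators(H, weighted=True, n_boot=100, seed=1).beta,
    }
    for name, est in estimates.items():
        assert abs(est - 0.25) < 0.05, (name, est)
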