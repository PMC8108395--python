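"""Generator checks: structural sharing, convergence to implied moments,
determinism, and the bounded-scale skew transform."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import ndtr

from edtwin.synthetic import (
    MomentTarget,
    SimConfig,
    apply_skew_transform,
    calibrate_skew_transform,
    manifest_for,
    simulate_binary,
    simulate_bivariate,
    simulate_continuous,
    synthetic_flag_cohort,
)
from edtwin import bvn_cdf


def _zyg_corr(df, zyg):
    sub = df[df.zygosity == zyg]
    return np.corrcoef(sub.t1_score, sub.t2_score)[0, 1]


class TestContinuous:
    def test_pure_genetic_trait_makes_mz_twins_identical(self):
        df = simulate_continuous(SimConfig(n_mz=200, n_dz=200, a2=1.0, c2=0.0, e2=0.0))
        mz = df[df.zygosity == "MZ"]
        np.testing.assert_allclose(mz.t1_score, mz.t2_score, atol=1e-12)

    def test_pure_environment_trait_has_null_correlations(self):
        df = simulate_continuous(
            SimConfig(n_mz=5000, n_dz=5000, a2=0.0, c2=0.0, e2=1.0, seed=3))
        assert abs(_zyg_corr(df, "MZ")) < 0.04
        assert abs(_zyg_corr(df, "DZ")) < 0.04

    def test_correlations_converge_to_expected_covariance_algebra(self):
        # rMZ -> a2 + c2, rDZ -> 0.5*a2 + c2
        df = simulate_continuous(SimConfig(n_mz=50_000, n_dz=50_000, seed=7))
        assert _zyg_corr(df, "MZ") == pytest.approx(0.65, abs=0.01)
        assert _zyg_corr(df, "DZ") == pytest.approx(0.325, abs=0.01)

    def test_same_seed_is_bit_identical(self):
        a = simulate_continuous(SimConfig(seed=5))
        b = simulate_continuous(SimConfig(seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_component_sum_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(a2=0.5, c2=0.1, e2=0.3)


class TestBinary:
    def test_independence_at_median_split(self):
        cfg = SimConfig(n_mz=100_000, n_dz=1000, a2=0.0, c2=0.0, e2=1.0,
                        prevalence=0.5, seed=1)
        df = simulate_binary(cfg)
        mz = df[df.zygosity == "MZ"]
        c = int(((mz.t1_dx == 1) & (mz.t2_dx == 1)).sum())
        d = int(((mz.t1_dx + mz.t2_dx) == 1).sum())
        assert 2 * c / (2 * c + d) == pytest.approx(0.5, abs=0.01)

    def test_prevalence_converges_and_concordance_matches_orthant_oracle(self):
        cfg = SimConfig(n_mz=300_000, n_dz=300_000, prevalence=0.024, seed=2)
        df = simulate_binary(cfg)
        t = cfg.threshold()
        dx = np.concatenate([df.t1_dx, df.t2_dx])
        assert dx.mean() == pytest.approx(0.024, abs=0.002)
        # orthant oracle: P(both) = 1 - 2*Phi(t) + Phi2(t, t; r)
        q = 1.0 - ndtr(t)
        for zyg, r in (("MZ", 0.65), ("DZ", 0.325)):
            sub = df[df.zygosity == zyg]
            c = int(((sub.t1_dx == 1) & (sub.t2_dx == 1)).sum())
            d = int(((sub.t1_dx + sub.t2_dx) == 1).sum())
            p11 = 1.0 - 2.0 * ndtr(t) + bvn_cdf(t, t, r)
            expected = 2 * p11 / (2 * p11 + 2 * (q - p11))
            assert 2 * c / (2 * c + d) == pytest.approx(expected, abs=0.03)
        # MZ concordance exceeds DZ under genetic influence
        pw = {}
        for zyg in ("MZ", "DZ"):
            sub = df[df.zygosity == zyg]
            c = int(((sub.t1_dx == 1) & (sub.t2_dx == 1)).sum())
            d = int(((sub.t1_dx + sub.t2_dx) == 1).sum())
            pw[zyg] = 2 * c / (2 * c + d)
        assert pw["MZ"] > pw["DZ"]

    def test_infinite_threshold_gives_zero_cases(self):
        df = simulate_binary(SimConfig(n_mz=100, n_dz=100, threshold_z=np.inf))
        assert df.t1_dx.sum() == 0 and df.t2_dx.sum() == 0


class TestBivariate:
    def test_zero_cross_correlations_give_independent_traits(self):
        cfg = SimConfig(n_mz=20_000, n_dz=20_000, rA=0.0, rC=0.0, rE=0.0,
                        prevalence=0.1, a2_2=0.65, c2_2=0.0, e2_2=0.35, seed=4)
        df = simulate_bivariate(cfg)
        r = np.corrcoef(np.r_[df.t1_score, df.t2_score],
                        np.r_[df.t1_liab, df.t2_liab])[0, 1]
        assert abs(r) < 0.02

    def test_unit_cross_correlations_duplicate_the_trait(self):
        cfg = SimConfig(n_mz=500, n_dz=500, rA=1.0, rC=0.0, rE=1.0,
                        a2_2=0.65, c2_2=0.0, e2_2=0.35, prevalence=0.1, seed=5)
        df = simulate_bivariate(cfg)
        np.testing.assert_allclose(df.t1_score, df.t1_liab, atol=1e-10)
        np.testing.assert_allclose(df.t2_score, df.t2_liab, atol=1e-10)

    def test_manifest_phenotypic_correlation_identity(self):
        # closed form: rPH = rA*a1*a2 + rC*c1*c2 + rE*e1*e2
        cfg = SimConfig(a2_2=0.67, c2_2=0.0, e2_2=0.33, rA=0.52, rC=0.0,
                        rE=0.52, prevalence=0.033)
        m = manifest_for(cfg)
        assert m.expected_r_ph == pytest.approx(0.52, abs=0.005)

    def test_sample_cross_trait_correlation_converges(self, oed_bivariate_cohort):
        df = oed_bivariate_cohort
        r = np.corrcoef(np.r_[df.t1_score, df.t2_score],
                        np.r_[df.t1_liab, df.t2_liab])[0, 1]
        assert r == pytest.approx(0.52, abs=0.04)


class TestSkewTransform:
    def test_identity_when_no_target(self, rng):
        x = rng.standard_normal(100)
        np.testing.assert_array_equal(apply_skew_transform(x, None), x)

    def test_calibrated_moments_on_large_sample(self, rng):
        x = apply_skew_transform(rng.standard_normal(10**6), MomentTarget())
        assert x.mean() == pytest.approx(2.66, abs=0.02)
        assert x.std() == pytest.approx(0.90, abs=0.02)
        assert stats.skew(x) == pytest.approx(0.57, abs=0.05)
        assert x.min() >= 1.0 and x.max() <= 6.0

    def test_strict_monotonicity_preserves_ranks(self, rng):
        x = rng.standard_normal(5000)
        y = apply_skew_transform(x, MomentTarget())
        order = np.argsort(x)
        assert np.all(np.diff(y[order]) > 0)  # strictly increasing, no ties
        rho, _ = stats.spearmanr(x, y)
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_quadrature_moment_oracle(self):
        # calibration solves the population moments exactly; the oracle
        # here is adaptive quadrature against the normal density
        from scipy import integrate

        g, d, span = calibrate_skew_transform(MomentTarget())

        def moment(f):
            val, _ = integrate.quad(
                lambda z: f(1.0 + span / (1.0 + np.exp(-(z - g) / d)))
                * stats.norm.pdf(z), -12, 12, epsabs=1e-12)
            return val

        m = moment(lambda x: x)
        v = moment(lambda x: (x - m) ** 2)
        sk = moment(lambda x: (x - m) ** 3) / v**1.5
        assert m == pytest.approx(2.66, abs=1e-6)
        assert np.sqrt(v) == pytest.approx(0.90, abs=1e-6)
        assert sk == pytest.approx(0.57, abs=1e-6)


def test_flag_cohort_margins():
    df = synthetic_flag_cohort()
    assert len(df) == 2962
    assert int(df.npr_an.sum()) == 50 and int(df.npr_oed.sum()) == 43
    assert int(df.parent_treat_an.sum()) == 46
    assert int(df.parent_treat_bn.sum()) == 8
    assert int(df.self_purging.sum()) == 96
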