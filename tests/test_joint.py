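"""Joint categorical-continuous model: cross-twin cross-trait
correlations, likelihood factorization limits, identity constraints and
parameter recovery against a moment-method oracle."""

import math

import numpy as np
import pytest

from edtwin import biometric as bm
from edtwin import joint as jm
from edtwin.liability import _counts, _table_neg2ll
from edtwin.synthetic import SimConfig, simulate_bivariate, simulate_continuous


def _an_config(seed):
    # AN-like scenario: rarer trait, lower genetic overlap
    return SimConfig(a2_2=0.63, c2_2=0.0, e2_2=0.37, rA=0.26, rC=0.0, rE=0.60,
                     prevalence=0.024, seed=seed)


class TestCrossTwinCrossTrait:
    def test_null_correlations_when_traits_independent(self):
        cfg = SimConfig(n_mz=4000, n_dz=4000, rA=0.0, rC=0.0, rE=0.0,
                        a2_2=0.65, c2_2=0.0, e2_2=0.35, prevalence=0.1, seed=3)
        ctct = jm.cross_twin_cross_trait(simulate_bivariate(cfg))
        assert abs(ctct["MZ"]) < 0.05 and abs(ctct["DZ"]) < 0.05

    def test_genetic_overlap_orders_zygosities(self):
        cfg = SimConfig(n_mz=6000, n_dz=6000, a2_2=0.67, c2_2=0.0, e2_2=0.33,
                        rA=0.52, rC=0.0, rE=0.52, prevalence=0.033, seed=4)
        ctct = jm.cross_twin_cross_trait(simulate_bivariate(cfg))
        assert ctct["MZ"] > ctct["DZ"] > 0
        # model-implied: R * rA * a1 * a2
        implied_mz = 0.52 * math.sqrt(0.65) * math.sqrt(0.67)
        assert ctct["MZ"] == pytest.approx(implied_mz, abs=0.06)

    def test_dichotomized_same_trait_approaches_within_trait_correlation(self):
        df = simulate_continuous(SimConfig(n_mz=6000, n_dz=6000, seed=5))
        t = np.quantile(np.r_[df.t1_score, df.t2_score], 0.9)
        df = df.assign(t1_dx=(df.t1_score > t).astype(int),
                       t2_dx=(df.t2_score > t).astype(int))
        ctct = jm.cross_twin_cross_trait(df)
        assert ctct["MZ"] == pytest.approx(0.65, abs=0.06)

    def test_no_affected_cotwins_rejected(self):
        df = simulate_continuous(SimConfig(n_mz=50, n_dz=50, seed=6))
        df = df.assign(t1_dx=0, t2_dx=0)
        with pytest.raises(ValueError, match="no affected"):
            jm.cross_twin_cross_trait(df)


class TestIdentities:
    def test_bivariate_heritability_from_reported_style_estimates(self):
        # worked identity: rA*sqrt(h2_1*h2_2)/rPH
        assert jm.bivariate_heritability(0.26, 0.65, 0.63, 0.39) \
            == pytest.approx(0.43, abs=0.01)
        assert jm.bivariate_heritability(0.52, 0.65, 0.67, 0.52) \
            == pytest.approx(0.66, abs=0.01)

    def test_phenotypic_correlation_identity(self):
        r = jm.phenotypic_correlation(0.52, math.sqrt(0.65), math.sqrt(0.67),
                                      0.52, math.sqrt(0.35), math.sqrt(0.33))
        assert r == pytest.approx(0.52, abs=0.005)

    def test_fit_satisfies_decomposition_exactly(self, oed_bivariate_cohort):
        fit = jm.fit_joint(oed_bivariate_cohort, "AE", ci="none")
        a1, e1 = math.sqrt(fit.h2_continuous), math.sqrt(fit.e2_continuous)
        a2, e2 = math.sqrt(fit.h2_liability), math.sqrt(fit.e2_liability)
        implied = fit.rA * a1 * a2 + fit.rE * e1 * e2
        assert fit.r_ph == pytest.approx(implied, abs=1e-6)
        assert fit.bivariate_h2 == pytest.approx(
            fit.rA * a1 * a2 / fit.r_ph, abs=1e-9)

    def test_rA_inside_its_profile_ci(self, oed_bivariate_cohort):
        fit = jm.fit_joint(oed_bivariate_cohort, "AE", ci="profile",
                           ci_params=("rA",))
        lo, hi = fit.ci["rA"]
        assert lo < fit.rA < hi


class TestDegenerateLimits:
    def test_threshold_at_minus_infinity_reduces_to_continuous_model(
            self, oed_bivariate_cohort):
        df = oed_bivariate_cohort.assign(t1_dx=1, t2_dx=1)
        params = dict(mu=0.1, a1=0.8, e1=0.6, t=-np.inf, a2=0.8, rA=0.3, rE=0.2)
        joint = jm.joint_neg2ll(df, params)
        stats = bm._stats_by_zyg(df)
        v = 0.8**2 + 0.6**2
        cont = (stats["MZ"].neg2ll(0.1, 0.1, v, v, 0.64)
                + stats["DZ"].neg2ll(0.1, 0.1, v, v, 0.32))
        assert joint == pytest.approx(cont, abs=1e-8)

    def test_zero_cross_correlations_factorize_the_likelihood(
            self, oed_bivariate_cohort):
        df = oed_bivariate_cohort
        a2_liab = 0.67
        params = dict(mu=0.05, a1=0.8, e1=0.6, t=1.84,
                      a2=math.sqrt(a2_liab), rA=0.0, rE=0.0)
        joint = jm.joint_neg2ll(df, params)
        stats = bm._stats_by_zyg(df)
        v = 0.8**2 + 0.6**2
        cont = (stats["MZ"].neg2ll(0.05, 0.05, v, v, 0.64)
                + stats["DZ"].neg2ll(0.05, 0.05, v, v, 0.32))
        cts = _counts(df, ("t1_dx", "t2_dx"))
        liab = (_table_neg2ll(cts["MZ"], 1.84, 1.84, a2_liab)
                + _table_neg2ll(cts["DZ"], 1.84, 1.84, a2_liab / 2))
        assert joint == pytest.approx(cont + liab, abs=1e-4)


class TestRecovery:
    def test_oed_scenario_recovers_cross_trait_correlations(self):
        # scaled-down replicate study (12 cohorts at study size)
        rAs, rEs = [], []
        for s in range(12):
            cfg = SimConfig(a2_2=0.67, c2_2=0.0, e2_2=0.33, rA=0.52, rC=0.0,
                            rE=0.52, prevalence=0.033, seed=2000 + s)
            fit = jm.fit_joint(simulate_bivariate(cfg), "AE", ci="none")
            rAs.append(fit.rA)
            rEs.append(fit.rE)
        assert np.mean(rAs) == pytest.approx(0.52, abs=0.08)
        assert np.mean(rEs) == pytest.approx(0.52, abs=0.08)

    def test_joint_fit_agrees_with_fully_continuous_bivariate_ml(self):
        # dichotomizing a large fully-continuous bivariate cohort and
        # fitting the joint model must recover the rA a fully-continuous
        # bivariate ML fit estimates from the latent second trait
        from scipy import optimize

        cfg = SimConfig(n_mz=12_000, n_dz=12_000, a2_2=0.67, c2_2=0.0,
                        e2_2=0.33, rA=0.52, rC=0.0, rE=0.52,
                        prevalence=0.033, seed=8)
        df = simulate_bivariate(cfg)
        data = {}
        for zyg, R in (("MZ", 1.0), ("DZ", 0.5)):
            sub = df.loc[df.zygosity == zyg,
                         ["t1_score", "t1_liab", "t2_score", "t2_liab"]]
            x = sub.to_numpy()
            data[zyg] = (R, len(x), x.mean(axis=0), np.cov(x.T, bias=True),
                         x.mean(axis=0))

        def sigma(R, a1, e1, a2, e2, rA, rE):
            A = np.array([[a1 * a1, rA * a1 * a2], [rA * a1 * a2, a2 * a2]])
            E = np.array([[e1 * e1, rE * e1 * e2], [rE * e1 * e2, e2 * e2]])
            return np.block([[A + E, R * A], [R * A, A + E]])

        def neg2ll(theta):
            mu1, mu2, a1, e1, a2, e2, zrA, zrE = theta
            rA, rE = math.tanh(zrA), math.tanh(zrE)
            total = 0.0
            mu = np.array([mu1, mu2, mu1, mu2])
            for R, n, mean, S, _ in data.values():
                sig = sigma(R, a1, e1, a2, e2, rA, rE)
                sign, logdet = np.linalg.slogdet(sig)
                if sign <= 0:
                    return 1e15
                inv = np.linalg.inv(sig)
                dev = mean - mu
                total += n * (logdet + np.trace(inv @ S) + dev @ inv @ dev)
            return total

        res = optimize.minimize(
            neg2ll, [0, 0, 0.8, 0.6, 0.8, 0.6, 0.5, 0.5], method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 40000,
                     "maxfev": 40000})
        rA_continuous = math.tanh(res.x[6])

        fit = jm.fit_joint(df, "AE", ci="none")
        assert fit.rA == pytest.approx(rA_continuous, abs=0.05)
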