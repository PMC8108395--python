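"""Joint categorical-continuous bivariate twin model.

Hybrid of a continuous twin model (for the symptom score) and a
liability-threshold model (for the diagnosis): each twin carries a
continuous phenotype y and a latent standard-normal liability l whose
exceedance of a threshold t produces the observed diagnosis.  The four
latent variables of a pair, (y1, y2, l1, l2), are multivariate normal
with a correlated-factors A/C/E structure:

  cov(y1, y2)   = R a1^2 + c1^2                 (R = 1 MZ, 0.5 DZ)
  cov(l1, l2)   = R a2^2 + c2^2                 (a2^2 + c2^2 + e2^2 = 1)
  cov(y_i, l_i) = rA a1 a2 + rC c1 c2 + rE e1 e2
  cov(y_i, l_j) = R rA a1 a2 + rC c1 c2        (i != j)

where rA, rC, rE are the cross-trait factor correlations.  The
correlated-factors parameterization is used (rather than a Cholesky)
because the quantities of scientific interest — the genetic correlation
rA and the non-shared environmental correlation rE — are then direct
parameters with direct profile CIs; at two traits the two
parameterizations are likelihood-equivalent.

Per-pair likelihood: density of (y1, y2) times the conditional
probability of the two binary outcomes, i.e. a bivariate-normal orthant
probability of (l1, l2) | (y1, y2).  Because the model covariance is
constant within zygosity, the conditional covariance is too; only the
conditional means vary by pair, so one likelihood evaluation costs two
small matrix solves plus a vectorized deterministic orthant computation
(Owen's T, abs. error < 1e-10) over the pairs.

Derived quantities: the phenotypic correlation
``rPH = rA a1 a2 + rC c1 c2 + rE e1 e2`` (standardized paths) and the
*bivariate heritability* ``rA a1 a2 / rPH`` — the share of the
phenotypic correlation attributable to overlapping genetic factors.

The continuous trait is standardized (z-score of the log score) before
fitting, making estimates scale-free; the liability threshold is
estimated freely rather than fixed to a register prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr

from ._bvnorm import bvn_cdf
from .biometric import _profile_interval

__all__ = [
    "JointFit",
    "bivariate_heritability",
    "phenotypic_correlation",
    "cross_twin_cross_trait",
    "fit_joint",
    "joint_neg2ll",
]

_LN2PI = math.log(2.0 * math.pi)


def phenotypic_correlation(rA, a1, a2, rE, e1, e2, rC=0.0, c1=0.0, c2=0.0) -> float:
    """rPH = rA*a1*a2 + rC*c1*c2 + rE*e1*e2 (standardized paths)."""
    return float(rA * a1 * a2 + rC * c1 * c2 + rE * e1 * e2)


def bivariate_heritability(rA: float, h2_1: float, h2_2: float, r_ph: float) -> float:
    """Share of the phenotypic correlation due to overlapping A factors.

    ``rA * sqrt(h2_1 * h2_2) / r_ph``; undefined at r_ph = 0.
    """
    if r_ph == 0.0:
        raise ValueError("bivariate heritability undefined at rPH = 0")
    return float(rA * math.sqrt(h2_1 * h2_2) / r_ph)


# ---------------------------------------------------------------------------
# Model covariance and likelihood
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _JointParams:
    """Internal parameter bundle; paths are standardized for the liability."""

    mu: float
    a1: float
    c1: float
    e1: float          # continuous-trait paths on its own scale
    t: float           # liability threshold
    a2: float
    c2: float          # liability paths, e2 = sqrt(1 - a2^2 - c2^2)
    rA: float
    rC: float
    rE: float

    @property
    def e2(self) -> float:
        rest = 1.0 - self.a2**2 - self.c2**2
        return math.sqrt(max(rest, 0.0))

    def sigma(self, R: float) -> np.ndarray:
        """4x4 covariance of (y1, y2, l1, l2) for twin relatedness R."""
        a1, c1, e1 = self.a1, self.c1, self.e1
        a2, c2, e2 = self.a2, self.c2, self.e2
        vy = a1 * a1 + c1 * c1 + e1 * e1
        cyy = R * a1 * a1 + c1 * c1
        cll = R * a2 * a2 + c2 * c2
        w = self.rA * a1 * a2 + self.rC * c1 * c2 + self.rE * e1 * e2
        x = R * self.rA * a1 * a2 + self.rC * c1 * c2
        return np.array([
            [vy, cyy, w, x],
            [cyy, vy, x, w],
            [w, x, 1.0, cll],
            [x, w, cll, 1.0],
        ])


def _group_neg2ll(params: _JointParams, R: float, y: np.ndarray, d: np.ndarray) -> float:
    """-2LL of one zygosity group; y (n,2) continuous, d (n,2) binary."""
    sig = params.sigma(R)
    syy = sig[:2, :2]
    sly = sig[2:, :2]
    sll = sig[2:, 2:]
    det_yy = syy[0, 0] * syy[1, 1] - syy[0, 1] ** 2
    if det_yy <= 0 or np.any(np.linalg.eigvalsh(sig) < 1e-10):
        return 1e15
    inv_yy = np.array([[syy[1, 1], -syy[0, 1]], [-syy[0, 1], syy[0, 0]]]) / det_yy

    dev = y - params.mu                      # (n, 2)
    quad = np.einsum("ni,ij,nj->n", dev, inv_yy, dev)
    n = len(y)
    n2ll_cont = n * (2.0 * _LN2PI + math.log(det_yy)) + float(quad.sum())

    # Conditional distribution of (l1, l2) | y: constant covariance,
    # pair-specific means.
    B = sly @ inv_yy                          # (2, 2)
    cond_mean = dev @ B.T                     # (n, 2)
    cond_cov = sll - B @ sly.T
    s1 = math.sqrt(max(cond_cov[0, 0], 1e-12))
    s2 = math.sqrt(max(cond_cov[1, 1], 1e-12))
    rho = min(max(cond_cov[0, 1] / (s1 * s2), -1.0 + 1e-12), 1.0 - 1e-12)

    u1 = (params.t - cond_mean[:, 0]) / s1
    u2 = (params.t - cond_mean[:, 1]) / s2
    p00 = bvn_cdf(u1, u2, rho)
    f1 = ndtr(u1)
    f2 = ndtr(u2)
    d1 = d[:, 0].astype(bool)
    d2 = d[:, 1].astype(bool)
    prob = np.where(
        ~d1 & ~d2, p00,
        np.where(~d1 & d2, f1 - p00,
                 np.where(d1 & ~d2, f2 - p00, 1.0 - f1 - f2 + p00)),
    )
    prob = np.clip(prob, 1e-300, 1.0)
    return n2ll_cont - 2.0 * float(np.log(prob).sum())


def _data_arrays(pairs: pd.DataFrame, cont_cols, bin_cols):
    out = {}
    for zyg, R in (("MZ", 1.0), ("DZ", 0.5)):
        sub = pairs.loc[pairs.zygosity == zyg, list(cont_cols) + list(bin_cols)].dropna()
        if len(sub) < 2:
            raise ValueError(f"need >= 2 complete {zyg} pairs")
        y = sub[list(cont_cols)].to_numpy(dtype=float)
        d = sub[list(bin_cols)].to_numpy(dtype=int)
        out[zyg] = (R, y, d)
    return out


def joint_neg2ll(pairs: pd.DataFrame, params: dict,
                 cont_cols=("t1_score", "t2_score"),
                 bin_cols=("t1_dx", "t2_dx")) -> float:
    """-2 log likelihood at explicit parameter values.

    ``params`` keys: mu, a1, c1, e1, t, a2, c2, rA, rC, rE (missing keys
    default to 0; the threshold may be ``-inf``, in which case every
    binary outcome has probability one if affected and the likelihood
    reduces to the continuous model's).
    """
    p = _JointParams(
        mu=params.get("mu", 0.0), a1=params.get("a1", 0.0),
        c1=params.get("c1", 0.0), e1=params.get("e1", 1.0),
        t=params.get("t", 0.0), a2=params.get("a2", 0.0),
        c2=params.get("c2", 0.0), rA=params.get("rA", 0.0),
        rC=params.get("rC", 0.0), rE=params.get("rE", 0.0),
    )
    data = _data_arrays(pairs, cont_cols, bin_cols)
    return sum(_group_neg2ll(p, R, y, d) for R, y, d in data.values())


# ---------------------------------------------------------------------------
# Cross-twin cross-trait correlations
# ---------------------------------------------------------------------------

def cross_twin_cross_trait(pairs: pd.DataFrame,
                           cont_cols=("t1_score", "t2_score"),
                           bin_cols=("t1_dx", "t2_dx")) -> dict[str, float]:
    """Polyserial-type ML correlation between one twin's continuous score
    and the co-twin's liability, per zygosity, pooled over both orderings.

    Model: (y, l) bivariate normal with free continuous mean/variance, a
    free threshold, and correlation rho; the likelihood contribution of
    an entry is ``phi(y) * P(d | y)``.  A zygosity with no affected
    co-twins is inestimable and raises.
    """
    out = {}
    for zyg in ("MZ", "DZ"):
        sub = pairs.loc[pairs.zygosity == zyg,
                        list(cont_cols) + list(bin_cols)].dropna()
        y = np.concatenate([sub[cont_cols[0]].to_numpy(float),
                            sub[cont_cols[1]].to_numpy(float)])
        d = np.concatenate([sub[bin_cols[1]].to_numpy(int),
                            sub[bin_cols[0]].to_numpy(int)]).astype(bool)
        if d.sum() == 0:
            raise ValueError(f"no affected co-twins among {zyg} pairs")
        mu0, sd0 = float(y.mean()), float(y.std())
        from scipy.special import ndtri
        t0 = float(ndtri(1.0 - d.mean()))

        def neg2ll(x):
            mu, logsd, t, zr = x
            sd = math.exp(logsd)
            rho = math.tanh(zr)
            z = (y - mu) / sd
            n2_cont = len(y) * (_LN2PI + 2.0 * logsd) + float((z * z).sum())
            u = (t - rho * z) / math.sqrt(1.0 - rho * rho)
            p1 = np.clip(1.0 - ndtr(u), 1e-300, 1.0)
            p0 = np.clip(ndtr(u), 1e-300, 1.0)
            return n2_cont - 2.0 * float(np.log(np.where(d, p1, p0)).sum())

        res = optimize.minimize(neg2ll, [mu0, math.log(sd0), t0, 0.2],
                                method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-9,
                                         "maxiter": 20000})
        out[zyg] = float(math.tanh(res.x[3]))
    return out


# ---------------------------------------------------------------------------
# Full joint fit
# ---------------------------------------------------------------------------

@dataclass
class JointFit:
    model: str
    h2_continuous: float
    c2_continuous: float
    e2_continuous: float
    h2_liability: float
    c2_liability: float
    e2_liability: float
    threshold: float
    rA: float
    rC: float
    rE: float
    r_ph: float
    bivariate_h2: float | None
    ci: dict[str, tuple[float, float]]
    cross_twin_cross_trait: dict[str, float]
    minus2ll: float
    n_free: int
    aic: float
    bic: float
    converged: bool
    n_pairs: int
    diagnostics: dict = field(default_factory=dict)


_JOINT_FREE = {
    "ACE": ("a1", "c1", "e1", "a2", "c2", "rA", "rC", "rE"),
    "AE": ("a1", "e1", "a2", "rA", "rE"),
    "CE": ("c1", "e1", "c2", "rC", "rE"),
    "E": ("e1", "rE"),
}


def fit_joint(pairs: pd.DataFrame, model: str = "AE", ci: str = "profile",
              ci_params=("rA", "rE"), bic_n: str = "pairs",
              standardize: bool = True,
              cont_cols=("t1_score", "t2_score"),
              bin_cols=("t1_dx", "t2_dx")) -> JointFit:
    """ML fit of the joint categorical-continuous AE/ACE/CE/E model.

    Returns per-trait standardized components, the threshold, cross-trait
    correlations with profile-likelihood CIs (``ci_params`` limits which
    correlations get one, both rA and rE by default), the implied
    phenotypic correlation and the bivariate heritability.
    """
    if model not in _JOINT_FREE:
        raise ValueError(f"model must be one of {tuple(_JOINT_FREE)}")
    pairs = pairs.copy()
    if standardize:
        pooled = np.concatenate([pairs[c].to_numpy(float) for c in cont_cols])
        m, s = np.nanmean(pooled), np.nanstd(pooled)
        for c in cont_cols:
            pairs[c] = (pairs[c] - m) / s
    data = _data_arrays(pairs, cont_cols, bin_cols)
    n_pairs = sum(len(y) for _, y, _ in data.values())
    free = _JOINT_FREE[model]

    from scipy.special import ndtri
    all_d = np.concatenate([d.ravel() for _, _, d in data.values()])
    t_start = float(ndtri(1.0 - max(all_d.mean(), 1e-4)))

    def build(x, fixed: dict[str, float] | None = None) -> _JointParams:
        fixed = fixed or {}
        vals = {"mu": x[0], "t": x[1], "a1": 0.0, "c1": 0.0, "e1": 0.0,
                "a2": 0.0, "c2": 0.0, "rA": 0.0, "rC": 0.0, "rE": 0.0}
        i = 2
        for name in free:
            if name in fixed:
                vals[name] = fixed[name]
            else:
                raw = x[i]
                i += 1
                if name.startswith("r"):
                    vals[name] = math.tanh(raw)
                elif name in ("a2", "c2"):
                    vals[name] = math.sin(raw)  # keeps |path| <= 1
                else:
                    vals[name] = raw
        return _JointParams(**vals)

    def neg2ll(x, fixed=None):
        p = build(x, fixed)
        if p.a2**2 + p.c2**2 > 1.0 - 1e-10:
            return 1e15
        return sum(_group_neg2ll(p, R, y, d) for R, y, d in data.values())

    def start_vector(fixed=None):
        fixed = fixed or {}
        base = {"a1": 0.75, "c1": 0.3, "e1": 0.6,
                "a2": math.asin(0.75), "c2": math.asin(0.3),
                "rA": 0.3, "rC": 0.1, "rE": 0.3}
        return [0.0, t_start] + [base[n] for n in free if n not in fixed]

    def minimize(fixed=None):
        res = optimize.minimize(lambda x: neg2ll(x, fixed), start_vector(fixed),
                                method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-8,
                                         "maxiter": 50000, "maxfev": 50000})
        return res

    res = minimize()
    p = build(res.x)
    n2ll = float(res.fun)
    k = 2 + len(free)

    vy = p.a1**2 + p.c1**2 + p.e1**2
    comp1 = (p.a1**2 / vy, p.c1**2 / vy, p.e1**2 / vy)
    comp2 = (p.a2**2, p.c2**2, p.e2**2)
    # Standardized paths of the continuous trait.
    sa1, sc1, se1 = (math.sqrt(v) for v in comp1)
    sa2, sc2, se2 = abs(p.a2), abs(p.c2), p.e2
    r_ph = phenotypic_correlation(p.rA, sa1, sa2, p.rE, se1, se2, p.rC, sc1, sc2)
    biv_h2 = None
    if abs(r_ph) > 1e-12:
        biv_h2 = p.rA * sa1 * sa2 / r_ph

    boundary = [n for n in ("rA", "rC", "rE")
                if n in free and abs(abs(getattr(p, n)) - 1.0) < 1e-3]

    cis: dict[str, tuple[float, float]] = {}
    if ci == "profile":
        mles = {"rA": p.rA, "rC": p.rC, "rE": p.rE,
                "a2_liability": comp2[0], "h2_continuous": comp1[0]}
        for name in ci_params:
            if name not in free:
                continue
            mle = mles.get(name, getattr(p, name, None))

            def profiled(v, name=name):
                return float(minimize(fixed={name: v}).fun)

            cis[name] = _profile_interval(
                profiled, min(max(mle, -1 + 1e-9), 1 - 1e-9), n2ll,
                lo_bound=-1.0 + 1e-6, hi_bound=1.0 - 1e-6)

    ctct = cross_twin_cross_trait(pairs, cont_cols, bin_cols)
    n_bic = n_pairs if bic_n == "pairs" else 2 * n_pairs
    return JointFit(
        model=model,
        h2_continuous=comp1[0], c2_continuous=comp1[1], e2_continuous=comp1[2],
        h2_liability=comp2[0], c2_liability=comp2[1], e2_liability=comp2[2],
        threshold=p.t, rA=p.rA, rC=p.rC, rE=p.rE, r_ph=r_ph,
        bivariate_h2=biv_h2, ci=cis, cross_twin_cross_trait=ctct,
        minus2ll=n2ll, n_free=k, aic=n2ll + 2 * k,
        bic=n2ll + k * math.log(n_bic),
        converged=bool(res.success), n_pairs=n_pairs,
        diagnostics={"boundary": boundary, "mu": p.mu,
                     "paths": {"a1": p.a1, "c1": p.c1, "e1": p.e1,
                               "a2": p.a2, "c2": p.c2, "e2": p.e2}},
    )
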