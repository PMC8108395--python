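"""Univariate twin-model maximum likelihood (continuous phenotype).

The classical twin design decomposes the variance of a phenotype into
additive genetic (A), shared-environment (C) — or non-additive genetic
(D) — and non-shared-environment (E) parts by exploiting the different
genetic sharing of MZ (100%) and DZ (50% on average) co-twins.  Under
the model, a twin pair's scores are bivariate normal with common mean
and covariance

    cov_MZ = a^2 + c^2            cov_DZ = 0.5 a^2 + c^2        (ACE)
    cov_MZ = a^2 + d^2            cov_DZ = 0.5 a^2 + 0.25 d^2   (ADE)

This module fits the fully saturated model (free means/variances/
covariances per zygosity, with optional equality constraints for
assumption testing), constrained twin correlations, and the ACE family
(ACE/ADE/AE/CE/E) by raw-data maximum likelihood over complete pairs.

Numerical notes: the likelihood depends on the data only through
per-zygosity sufficient statistics, so each evaluation is O(1); models
are parameterized through path coefficients (components are squares, so
non-negativity is structural); confidence intervals are profile
likelihood (the 3.84 chi-square(1) cutoff), which respects the boundary
at zero unlike delta-method intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "PairSuffStats",
    "EqualitySpec",
    "SaturatedFit",
    "VarianceComponents",
    "FitResult",
    "pair_arrays",
    "fit_saturated",
    "saturated_ladder",
    "twin_correlations",
    "fit_ace",
    "MODEL_LABELS",
]

_LN2PI = math.log(2.0 * math.pi)
_CHI2_95_1DF = 3.841458820694124  # chi2.ppf(0.95, 1)

MODEL_LABELS = ("ACE", "ADE", "AE", "CE", "E")


# ---------------------------------------------------------------------------
# Data plumbing and sufficient statistics
# ---------------------------------------------------------------------------

def pair_arrays(pairs: pd.DataFrame, cols=("t1_score", "t2_score")) -> dict[str, np.ndarray]:
    """Complete-pair (n, 2) arrays keyed by zygosity.

    Listwise completeness is enforced here: pairs with any missing score
    are dropped, matching an analysis restricted to complete pairs.
    """
    out = {}
    for zyg in ("MZ", "DZ"):
        sub = pairs.loc[pairs["zygosity"] == zyg, list(cols)].dropna()
        y = sub.to_numpy(dtype=float)
        if len(y) < 2:
            raise ValueError(f"need >= 2 complete {zyg} pairs, got {len(y)}")
        out[zyg] = y
    return out


@dataclass(frozen=True)
class PairSuffStats:
    """Sufficient statistics of one zygosity group for the bivariate normal."""

    n: int
    s1: float
    s2: float
    q11: float
    q22: float
    q12: float

    @classmethod
    def from_array(cls, y: np.ndarray) -> "PairSuffStats":
        return cls(
            n=len(y),
            s1=float(y[:, 0].sum()),
            s2=float(y[:, 1].sum()),
            q11=float((y[:, 0] ** 2).sum()),
            q22=float((y[:, 1] ** 2).sum()),
            q12=float((y[:, 0] * y[:, 1]).sum()),
        )

    def neg2ll(self, mu1: float, mu2: float, v1: float, v2: float, cov: float) -> float:
        """-2 log likelihood of the group under N([mu1,mu2], [[v1,cov],[cov,v2]])."""
        det = v1 * v2 - cov * cov
        if det <= 0.0 or v1 <= 0.0 or v2 <= 0.0:
            return 1e15  # large finite penalty keeps simplex arithmetic clean
        m11 = self.q11 - 2.0 * mu1 * self.s1 + self.n * mu1 * mu1
        m22 = self.q22 - 2.0 * mu2 * self.s2 + self.n * mu2 * mu2
        m12 = self.q12 - mu1 * self.s2 - mu2 * self.s1 + self.n * mu1 * mu2
        quad = (v2 * m11 + v1 * m22 - 2.0 * cov * m12) / det
        return self.n * (2.0 * _LN2PI + math.log(det)) + quad

    def moments(self):
        """Sample means and (1/n) covariance entries."""
        n = self.n
        m1, m2 = self.s1 / n, self.s2 / n
        v1 = self.q11 / n - m1 * m1
        v2 = self.q22 / n - m2 * m2
        c = self.q12 / n - m1 * m2
        return m1, m2, v1, v2, c


def _stats_by_zyg(pairs: pd.DataFrame, cols=("t1_score", "t2_score")):
    arrays = pair_arrays(pairs, cols)
    return {z: PairSuffStats.from_array(y) for z, y in arrays.items()}


# ---------------------------------------------------------------------------
# Saturated model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EqualitySpec:
    """Equality constraints applied to the saturated model."""

    means_across_order: bool = False
    means_across_zygosity: bool = False
    vars_across_order: bool = False
    vars_across_zygosity: bool = False

    @property
    def label(self) -> str:
        parts = []
        if self.means_across_order:
            parts.append("means=order")
        if self.means_across_zygosity:
            parts.append("means=zyg")
        if self.vars_across_order:
            parts.append("vars=order")
        if self.vars_across_zygosity:
            parts.append("vars=zyg")
        return "+".join(parts) if parts else "free"


@dataclass
class SaturatedFit:
    means: dict[str, tuple[float, float]]
    variances: dict[str, tuple[float, float]]
    covariances: dict[str, float]
    correlations: dict[str, float]
    minus2ll: float
    n_free: int
    constraints: EqualitySpec
    converged: bool = True
    correlation_ci: dict[str, tuple[float, float]] | None = None


def _mean_layout(spec: EqualitySpec):
    """Index map (zyg, order) -> parameter slot, and the slot count."""
    if spec.means_across_order and spec.means_across_zygosity:
        idx = {("MZ", 0): 0, ("MZ", 1): 0, ("DZ", 0): 0, ("DZ", 1): 0}
        return idx, 1
    if spec.means_across_order:
        idx = {("MZ", 0): 0, ("MZ", 1): 0, ("DZ", 0): 1, ("DZ", 1): 1}
        return idx, 2
    if spec.means_across_zygosity:
        idx = {("MZ", 0): 0, ("MZ", 1): 1, ("DZ", 0): 0, ("DZ", 1): 1}
        return idx, 2
    idx = {("MZ", 0): 0, ("MZ", 1): 1, ("DZ", 0): 2, ("DZ", 1): 3}
    return idx, 4


def _var_layout(spec: EqualitySpec):
    s2 = EqualitySpec(
        means_across_order=spec.vars_across_order,
        means_across_zygosity=spec.vars_across_zygosity,
    )
    return _mean_layout(s2)


def fit_saturated(pairs: pd.DataFrame, constraints: EqualitySpec | None = None,
                  cols=("t1_score", "t2_score")) -> SaturatedFit:
    """ML fit of the saturated bivariate-normal twin model.

    Unconstrained, the MLE is closed form (sample moments with 1/n
    denominators); with equality constraints on means/variances across
    twin order and/or zygosity the fit is numerical.  The within-pair
    covariance (equivalently correlation) is always free per zygosity.
    """
    constraints = constraints or EqualitySpec()
    stats = _stats_by_zyg(pairs, cols)

    if constraints == EqualitySpec():
        means, varis, covs, corrs = {}, {}, {}, {}
        n2ll = 0.0
        for z, st in stats.items():
            m1, m2, v1, v2, c = st.moments()
            means[z] = (m1, m2)
            varis[z] = (v1, v2)
            covs[z] = c
            corrs[z] = c / math.sqrt(v1 * v2)
            n2ll += st.neg2ll(m1, m2, v1, v2, c)
        return SaturatedFit(means, varis, covs, corrs, n2ll, n_free=10,
                           constraints=constraints)

    m_idx, n_mu = _mean_layout(constraints)
    v_idx, n_v = _var_layout(constraints)
    n_free = n_mu + n_v + 2

    pooled = np.concatenate([np.ravel(pairs.loc[pairs.zygosity == z, list(cols)].dropna())
                             for z in ("MZ", "DZ")])
    mu0, v0 = float(pooled.mean()), float(pooled.var())

    def unpack(x):
        mus = x[:n_mu]
        logvs = x[n_mu:n_mu + n_v]
        zr = x[n_mu + n_v:]
        out = {}
        for iz, z in enumerate(("MZ", "DZ")):
            mu1 = mus[m_idx[(z, 0)]]
            mu2 = mus[m_idx[(z, 1)]]
            v1 = math.exp(logvs[v_idx[(z, 0)]])
            v2 = math.exp(logvs[v_idx[(z, 1)]])
            r = math.tanh(zr[iz])
            out[z] = (mu1, mu2, v1, v2, r * math.sqrt(v1 * v2))
        return out

    def objective(x):
        total = 0.0
        for z, (mu1, mu2, v1, v2, cov) in unpack(x).items():
            total += stats[z].neg2ll(mu1, mu2, v1, v2, cov)
        return total

    x0 = np.concatenate([
        np.full(n_mu, mu0), np.full(n_v, math.log(v0)), np.array([0.5, 0.25])
    ])
    res = optimize.minimize(objective, x0, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 2000})
    polish = optimize.minimize(objective, res.x, method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 10000})
    converged = polish.fun >= res.fun - 1e-6
    if polish.fun < res.fun:
        res = polish
    params = unpack(res.x)
    means = {z: (p[0], p[1]) for z, p in params.items()}
    varis = {z: (p[2], p[3]) for z, p in params.items()}
    covs = {z: p[4] for z, p in params.items()}
    corrs = {z: p[4] / math.sqrt(p[2] * p[3]) for z, p in params.items()}
    return SaturatedFit(means, varis, covs, corrs, float(res.fun), n_free,
                        constraints, converged=converged)


def saturated_ladder(pairs: pd.DataFrame, cols=("t1_score", "t2_score")):
    """Assumption-testing ladder: progressively constrained saturated fits.

    Returns a list of ``(EqualitySpec, SaturatedFit)`` ordered from the
    free model to the fully mean/variance-equated model, supporting
    likelihood-ratio assumption tests.
    """
    specs = [
        EqualitySpec(),
        EqualitySpec(means_across_order=True),
        EqualitySpec(means_across_order=True, means_across_zygosity=True),
        EqualitySpec(means_across_order=True, means_across_zygosity=True,
                     vars_across_order=True),
        EqualitySpec(means_across_order=True, means_across_zygosity=True,
                     vars_across_order=True, vars_across_zygosity=True),
    ]
    return [(s, fit_saturated(pairs, s, cols)) for s in specs]


def twin_correlations(pairs: pd.DataFrame, ci: bool = True,
                      cols=("t1_score", "t2_score")) -> dict:
    """Per-zygosity twin correlations from the constrained saturated model.

    Means and variances are equated within pairs and across zygosity;
    the two correlations remain free.  CIs are profile likelihood.
    """
    stats = _stats_by_zyg(pairs, cols)

    def fit(fixed: dict[str, float] | None = None):
        fixed = fixed or {}
        free_r = [z for z in ("MZ", "DZ") if z not in fixed]

        def objective(x):
            mu, logv = x[0], x[1]
            v = math.exp(logv)
            total = 0.0
            for iz, z in enumerate(("MZ", "DZ")):
                r = fixed[z] if z in fixed else math.tanh(x[2 + free_r.index(z)])
                total += stats[z].neg2ll(mu, mu, v, v, r * v)
            return total

        pooled_mu = (stats["MZ"].s1 + stats["MZ"].s2 + stats["DZ"].s1 + stats["DZ"].s2) / (
            2 * (stats["MZ"].n + stats["DZ"].n))
        x0 = [pooled_mu, 0.0] + [0.4] * len(free_r)
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 5000})
        rs = {}
        for z in ("MZ", "DZ"):
            rs[z] = fixed[z] if z in fixed else math.tanh(res.x[2 + free_r.index(z)])
        return float(res.fun), rs

    base_n2ll, rs = fit()
    out = {"r": rs, "minus2ll": base_n2ll, "ci": {}}
    if ci:
        for z in ("MZ", "DZ"):
            out["ci"][z] = _profile_interval(
                lambda r, zz=z: fit({zz: r})[0], rs[z], base_n2ll,
                lo_bound=-1.0 + 1e-9, hi_bound=1.0 - 1e-9)
    return out


def _profile_interval(profiled_neg2ll, mle, base, lo_bound, hi_bound,
                      crit: float = _CHI2_95_1DF, tol: float = 1e-5):
    """Invert the profile likelihood: the set where -2LL rises by < crit."""

    def f(x):
        return profiled_neg2ll(x) - base - crit

    lo = lo_bound
    if f(lo_bound) > 0:
        lo = optimize.brentq(f, lo_bound, mle, xtol=tol)
    hi = hi_bound
    if f(hi_bound) > 0:
        hi = optimize.brentq(f, mle, hi_bound, xtol=tol)
    return (float(lo), float(hi))


# ---------------------------------------------------------------------------
# ACE family
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """Standardized variance proportions and the underlying paths."""

    a2: float = 0.0
    c2: float = 0.0
    d2: float = 0.0
    e2: float = 1.0
    paths: dict = field(default_factory=dict)
    mean: float = 0.0
    total_var: float = 1.0

    def as_dict(self) -> dict:
        return {"a2": self.a2, "c2": self.c2, "d2": self.d2, "e2": self.e2}


@dataclass
class FitResult:
    model: str
    minus2ll: float
    n_free: int
    estimates: VarianceComponents
    ci: dict[str, tuple[float, float]]
    aic: float
    bic: float
    converged: bool
    n_pairs: int
    diagnostics: dict = field(default_factory=dict)


_MODEL_PATHS = {
    "ACE": ("a", "c", "e"),
    "ADE": ("a", "d", "e"),
    "AE": ("a", "e"),
    "CE": ("c", "e"),
    "E": ("e",),
}


def _covariances(paths: dict[str, float]):
    a2 = paths.get("a", 0.0) ** 2
    c2 = paths.get("c", 0.0) ** 2
    d2 = paths.get("d", 0.0) ** 2
    e2 = paths.get("e", 0.0) ** 2
    total = a2 + c2 + d2 + e2
    cov_mz = a2 + c2 + d2
    cov_dz = 0.5 * a2 + c2 + 0.25 * d2
    return total, cov_mz, cov_dz


def _ace_neg2ll(stats, mu: float, paths: dict[str, float]) -> float:
    total, cov_mz, cov_dz = _covariances(paths)
    return (stats["MZ"].neg2ll(mu, mu, total, total, cov_mz)
            + stats["DZ"].neg2ll(mu, mu, total, total, cov_dz))


def _moment_start(stats):
    n_tot = stats["MZ"].n + stats["DZ"].n
    mu = (stats["MZ"].s1 + stats["MZ"].s2 + stats["DZ"].s1 + stats["DZ"].s2) / (2 * n_tot)
    _, _, v1m, v2m, cm = stats["MZ"].moments()
    _, _, v1d, v2d, cd = stats["DZ"].moments()
    v = (stats["MZ"].n * (v1m + v2m) + stats["DZ"].n * (v1d + v2d)) / (2 * n_tot)
    rmz = cm / math.sqrt(v1m * v2m)
    rdz = cd / math.sqrt(v1d * v2d)
    return mu, v, rmz, rdz


def fit_ace(pairs: pd.DataFrame, model: str = "ACE", ci: str = "profile",
            bic_n: str = "pairs", cols=("t1_score", "t2_score")) -> FitResult:
    """ML fit of an ACE-family model (ACE / ADE / AE / CE / E).

    Means are equated across twin order and zygosity.  Returns
    standardized components, profile-likelihood 95% CIs on each free
    standardized component (``ci="profile"``; ``"none"`` skips them), and
    AIC / BIC (``bic_n`` chooses pairs or individuals as the BIC sample
    size; pairs is the default since the pair is the independent unit).
    """
    if model not in _MODEL_PATHS:
        raise ValueError(f"model must be one of {MODEL_LABELS}")
    stats = _stats_by_zyg(pairs, cols)
    path_names = _MODEL_PATHS[model]
    mu0, v0, rmz, rdz = _moment_start(stats)

    def objective(x):
        mu = x[0]
        paths = dict(zip(path_names, x[1:]))
        return _ace_neg2ll(stats, mu, paths)

    # Moment-informed and neutral starts, plus perturbations.
    starts = []
    a2_0 = max(2.0 * (rmz - rdz), 0.01) * v0
    c2_0 = max(2.0 * rdz - rmz, 0.01) * v0
    e2_0 = max(1.0 - rmz, 0.05) * v0
    guess = {"a": math.sqrt(a2_0), "c": math.sqrt(c2_0),
             "d": math.sqrt(a2_0 / 2.0), "e": math.sqrt(e2_0)}
    starts.append([mu0] + [guess[p] for p in path_names])
    starts.append([mu0] + [math.sqrt(v0 / len(path_names))] * len(path_names))
    for scale in (0.5, 1.5):
        starts.append([mu0] + [scale * guess[p] for p in path_names])

    best = None
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-10,
                                         "maxiter": 20000, "maxfev": 20000})
        res = optimize.minimize(objective, res.x, method="BFGS",
                                options={"gtol": 1e-9, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    # Convergence check: one more simplex polish must not find a lower value.
    polish = optimize.minimize(objective, best.x, method="Nelder-Mead",
                               options={"xatol": 1e-11, "fatol": 1e-11, "maxiter": 5000})
    stable = polish.fun >= best.fun - 1e-6
    if polish.fun < best.fun:
        best = polish

    mu_hat = float(best.x[0])
    paths = {p: abs(float(v)) for p, v in zip(path_names, best.x[1:])}
    total, _, _ = _covariances(paths)
    comp = VarianceComponents(
        a2=paths.get("a", 0.0) ** 2 / total,
        c2=paths.get("c", 0.0) ** 2 / total,
        d2=paths.get("d", 0.0) ** 2 / total,
        e2=paths.get("e", 0.0) ** 2 / total,
        paths=paths, mean=mu_hat, total_var=total,
    )
    n2ll = float(best.fun)
    k = 1 + len(path_names)
    n_pairs = stats["MZ"].n + stats["DZ"].n
    n_bic = n_pairs if bic_n == "pairs" else 2 * n_pairs
    grad_norm = float(np.linalg.norm(getattr(best, "jac", np.zeros(1))))
    boundary = [p for p in path_names if paths[p] ** 2 / total < 1e-6]

    cis: dict[str, tuple[float, float]] = {}
    if ci == "profile":
        for p in path_names:
            cis[p + "2"] = _profile_component_ci(stats, model, p, comp, n2ll)

    return FitResult(
        model=model, minus2ll=n2ll, n_free=k, estimates=comp, ci=cis,
        aic=n2ll + 2 * k, bic=n2ll + k * math.log(n_bic),
        converged=stable and math.isfinite(n2ll), n_pairs=n_pairs,
        diagnostics={"grad_norm": grad_norm, "boundary": boundary,
                     "n_starts": len(starts)},
    )


def _profile_component_ci(stats, model: str, comp_name: str,
                          mle: VarianceComponents, base_n2ll: float):
    """Profile-likelihood CI for one standardized component.

    The target component's standardized share is fixed at h; the mean,
    total variance and the split of the remaining share among the other
    components are re-optimized.
    """
    path_names = _MODEL_PATHS[model]
    others = [p for p in path_names if p != comp_name]

    def profiled(h: float) -> float:
        def objective(x):
            mu, logv = x[0], x[1]
            v = math.exp(logv)
            rest = 1.0 - h
            paths = {comp_name: math.sqrt(max(h, 0.0) * v)}
            if len(others) == 0:
                if rest > 1e-12:
                    return 1e15
            elif len(others) == 1:
                paths[others[0]] = math.sqrt(rest * v)
            else:
                s = 1.0 / (1.0 + math.exp(-x[2]))
                paths[others[0]] = math.sqrt(s * rest * v)
                paths[others[1]] = math.sqrt((1.0 - s) * rest * v)
            return _ace_neg2ll(stats, mu, paths)

        x0 = [mle.mean, math.log(mle.total_var)]
        if len(others) == 2:
            o2 = {p: mle.paths.get(p, 0.0) ** 2 / mle.total_var for p in others}
            tot = max(o2[others[0]] + o2[others[1]], 1e-9)
            s0 = min(max(o2[others[0]] / tot, 1e-6), 1 - 1e-6)
            x0.append(math.log(s0 / (1.0 - s0)))
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 10000})
        return float(res.fun)

    h_hat = getattr(mle, comp_name + "2")
    h_hat = min(max(h_hat, 1e-9), 1.0 - 1e-9)
    return _profile_interval(profiled, h_hat, base_n2ll, lo_bound=0.0, hi_bound=1.0)
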