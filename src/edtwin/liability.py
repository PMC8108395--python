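"""Liability-threshold twin models and probandwise concordance.

Binary twin outcomes (a diagnosis, or membership in an extreme-scoring
group) are modeled as an unobserved standard-normal *liability*
exceeding a threshold t.  Twin resemblance is the tetrachoric
correlation of the two liabilities, which under the ACE decomposition
equals ``a2 + c2`` (MZ) or ``0.5 a2 + c2`` (DZ).  The likelihood of a
zygosity group is multinomial over its 2x2 concordance table with cell
probabilities given by bivariate-normal orthant integrals; those are
computed with a deterministic Owen's-T algorithm (abs. error < 1e-10),
so fits are exactly reproducible.

Thresholds are equated across twin order and zygosity by default,
mirroring the equating of means and variances for the continuous trait;
per-zygosity thresholds are available as an assumption check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, ndtri

from ._bvnorm import bvn_cdf
from .biometric import _profile_interval

__all__ = [
    "ConcordanceTable",
    "LiabilityFit",
    "probandwise_concordance",
    "concordance_tables",
    "tetrachoric",
    "fit_liability",
    "pairs_from_continuous",
]


@dataclass
class ConcordanceTable:
    """Pair counts for one zygosity: concordant affected / discordant / unaffected."""

    zygosity: str
    concordant_affected: int
    discordant: int
    concordant_unaffected: int

    def __post_init__(self) -> None:
        if min(self.concordant_affected, self.discordant, self.concordant_unaffected) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_pairs(self) -> int:
        return self.concordant_affected + self.discordant + self.concordant_unaffected

    @property
    def probandwise(self) -> float:
        return probandwise_concordance(self.concordant_affected, self.discordant)


def probandwise_concordance(concordant: int, discordant: int) -> float:
    """2C / (2C + D): probability that a proband's co-twin is also affected."""
    if concordant < 0 or discordant < 0:
        raise ValueError("counts must be non-negative")
    if concordant == 0 and discordant == 0:
        raise ValueError("no affected pairs: concordance undefined")
    return 2.0 * concordant / (2.0 * concordant + discordant)


def concordance_tables(pairs: pd.DataFrame,
                       cols=("t1_dx", "t2_dx")) -> dict[str, ConcordanceTable]:
    """Per-zygosity concordance tables from a binary pair table."""
    c1, c2 = cols
    out = {}
    for zyg in ("MZ", "DZ"):
        sub = pairs.loc[pairs.zygosity == zyg, [c1, c2]].dropna().astype(int)
        both = int(((sub[c1] == 1) & (sub[c2] == 1)).sum())
        disc = int(((sub[c1] + sub[c2]) == 1).sum())
        neither = int(((sub[c1] == 0) & (sub[c2] == 0)).sum())
        out[zyg] = ConcordanceTable(zyg, both, disc, neither)
    return out


@dataclass
class LiabilityFit:
    model: str
    thresholds: dict[str, float]
    tetrachoric_r: dict[str, float]
    a2: float
    c2: float
    e2: float
    ci: dict[str, tuple[float, float]]
    minus2ll: float
    n_free: int
    aic: float
    bic: float
    converged: bool
    boundary: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


def _cell_probs(t1: float, t2: float, r: float) -> np.ndarray:
    """(p00, p01, p10, p11) for thresholds t1, t2 and liability correlation r."""
    p00 = bvn_cdf(t1, t2, r)
    p0_ = ndtr(t1)
    p_0 = ndtr(t2)
    p01 = max(p0_ - p00, 0.0)
    p10 = max(p_0 - p00, 0.0)
    p11 = max(1.0 - p0_ - p_0 + p00, 0.0)
    return np.array([p00, p01, p10, p11])


def _counts(pairs: pd.DataFrame, cols) -> dict[str, np.ndarray]:
    c1, c2 = cols
    out = {}
    for zyg in ("MZ", "DZ"):
        sub = pairs.loc[pairs.zygosity == zyg, [c1, c2]].dropna().astype(int)
        n00 = int(((sub[c1] == 0) & (sub[c2] == 0)).sum())
        n01 = int(((sub[c1] == 0) & (sub[c2] == 1)).sum())
        n10 = int(((sub[c1] == 1) & (sub[c2] == 0)).sum())
        n11 = int(((sub[c1] == 1) & (sub[c2] == 1)).sum())
        out[zyg] = np.array([n00, n01, n10, n11], dtype=float)
    return out


def _table_neg2ll(counts: np.ndarray, t1: float, t2: float, r: float) -> float:
    probs = _cell_probs(t1, t2, r)
    mask = counts > 0
    if np.any(probs[mask] <= 0):
        return 1e15
    return float(-2.0 * np.dot(counts[mask], np.log(probs[mask])))


def tetrachoric(counts: np.ndarray, equal_thresholds: bool = True):
    """ML tetrachoric correlation (and thresholds) of one 2x2 pair table.

    Returns ``(r, t1, t2, minus2ll, boundary)`` where ``boundary`` flags
    an estimate pinned at +/-1 (e.g. a zygosity group with no concordant
    affected pairs drives r to the boundary; such estimates are reported,
    never silently clipped into the interior).
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        raise ValueError("empty table")
    affected1 = (counts[2] + counts[3]) / n
    affected2 = (counts[1] + counts[3]) / n
    if affected1 in (0.0, 1.0) or affected2 in (0.0, 1.0):
        raise ValueError("a margin has no variation: correlation inestimable")
    t1_0 = ndtri(1.0 - affected1)
    t2_0 = ndtri(1.0 - affected2)

    if equal_thresholds:
        def obj(x):
            t, zr = x
            return _table_neg2ll(counts, t, t, math.tanh(zr))
        x0 = [(t1_0 + t2_0) / 2.0, 0.3]
    else:
        def obj(x):
            t1, t2, zr = x
            return _table_neg2ll(counts, t1, t2, math.tanh(zr))
        x0 = [t1_0, t2_0, 0.3]

    res = optimize.minimize(obj, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 20000})
    r = math.tanh(res.x[-1])
    t1 = res.x[0]
    t2 = res.x[0] if equal_thresholds else res.x[1]
    n2ll = float(res.fun)

    # Tables with an empty concordance cell leave the likelihood flat all
    # the way to r = +/-1 (e.g. no concordant-affected pairs).  Report such
    # estimates at the boundary, flagged, rather than at an arbitrary point
    # of the flat region.
    boundary = abs(abs(r) - 1.0) < 1e-3
    for edge in (-1.0, 1.0):
        zr_edge = math.atanh(edge * (1.0 - 1e-9))
        if equal_thresholds:
            e = optimize.minimize_scalar(
                lambda t: _table_neg2ll(counts, t, t, edge * (1.0 - 1e-9)),
                bounds=(t1 - 2.0, t1 + 2.0), method="bounded",
                options={"xatol": 1e-10})
            edge_fun = float(e.fun)
        else:
            e = optimize.minimize(
                lambda x: _table_neg2ll(counts, x[0], x[1], edge * (1.0 - 1e-9)),
                [t1, t2], method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-10})
            edge_fun = float(e.fun)
        if edge_fun <= n2ll + 1e-6:
            r, n2ll, boundary = edge, min(n2ll, edge_fun), True
            break
    return float(r), float(t1), float(t2), n2ll, boundary


_MODEL_FREE = {"ACE": ("a2", "c2"), "AE": ("a2",), "CE": ("c2",), "E": ()}


def fit_liability(pairs: pd.DataFrame, model: str = "ACE", ci: str = "profile",
                  equal_thresholds: bool = True, bic_n: str = "pairs",
                  cols=("t1_dx", "t2_dx")) -> LiabilityFit:
    """ML ACE-family fit on the liability scale.

    The per-zygosity 2x2 tables are fit jointly with liability
    correlations ``r_MZ = a2 + c2``, ``r_DZ = 0.5 a2 + c2`` and a
    threshold equated across twins and zygosity (set
    ``equal_thresholds=False`` for per-zygosity thresholds as an
    assumption check).  Standardized components carry profile-likelihood
    95% CIs.
    """
    if model not in _MODEL_FREE:
        raise ValueError(f"model must be one of {tuple(_MODEL_FREE)}")
    counts = _counts(pairs, cols)
    for zyg, c in counts.items():
        if c[1] + c[2] + c[3] == 0:
            raise ValueError(f"no affected individuals among {zyg} pairs")
    n_pairs = int(sum(c.sum() for c in counts.values()))
    prev = sum(c[1] + c[2] + 2 * c[3] for c in counts.values()) / (2 * n_pairs)
    t0 = float(ndtri(1.0 - prev))

    free = _MODEL_FREE[model]
    n_thresh = 1 if equal_thresholds else 2

    def build(comp: dict[str, float]):
        a2 = comp.get("a2", 0.0)
        c2 = comp.get("c2", 0.0)
        return {"MZ": a2 + c2, "DZ": 0.5 * a2 + c2}

    def neg2ll(x, fixed: dict[str, float] | None = None):
        fixed = fixed or {}
        i = 0
        th = {}
        if equal_thresholds:
            th["MZ"] = th["DZ"] = x[i]; i += 1
        else:
            th["MZ"] = x[i]; th["DZ"] = x[i + 1]; i += 2
        comp = dict(fixed)
        for name in free:
            if name not in comp:
                comp[name] = x[i] ** 2  # square keeps the component non-negative
                i += 1
        if comp.get("a2", 0.0) + comp.get("c2", 0.0) > 1.0:
            return 1e15
        rs = build(comp)
        return sum(_table_neg2ll(counts[z], th[z], th[z], rs[z]) for z in ("MZ", "DZ"))

    def minimize(fixed=None, start_extra=None):
        n_free_comp = len(free) - len(fixed or {})
        x0 = [t0] * n_thresh + list(start_extra if start_extra is not None
                                    else [0.6] * n_free_comp)
        res = optimize.minimize(lambda x: neg2ll(x, fixed), x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-10,
                                         "maxiter": 20000})
        return res

    res = minimize()
    i = n_thresh
    comp = {}
    for name in free:
        comp[name] = float(res.x[i] ** 2)
        i += 1
    a2 = comp.get("a2", 0.0)
    c2 = comp.get("c2", 0.0)
    e2 = 1.0 - a2 - c2
    th = {"MZ": float(res.x[0]), "DZ": float(res.x[0] if equal_thresholds else res.x[1])}
    rs = build(comp)
    n2ll = float(res.fun)
    k = n_thresh + len(free)

    boundary = [n for n, v in (("a2", a2), ("c2", c2), ("e2", e2)) if v < 1e-6]
    cis: dict[str, tuple[float, float]] = {}
    if ci == "profile":
        for name in free:
            mle = comp[name]
            other = [n for n in free if n != name]

            def profiled(v, name=name, other=other):
                r = minimize(fixed={name: v})
                return float(r.fun)

            cis[name] = _profile_interval(profiled, min(max(mle, 1e-9), 1 - 1e-9),
                                          n2ll, lo_bound=0.0, hi_bound=1.0)
        if model == "AE":
            cis["e2"] = tuple(sorted((1.0 - cis["a2"][1], 1.0 - cis["a2"][0])))

    n_bic = n_pairs if bic_n == "pairs" else 2 * n_pairs
    return LiabilityFit(
        model=model, thresholds=th, tetrachoric_r=rs,
        a2=a2, c2=c2, e2=e2, ci=cis, minus2ll=n2ll, n_free=k,
        aic=n2ll + 2 * k, bic=n2ll + k * math.log(n_bic),
        converged=bool(res.success), boundary=boundary,
        diagnostics={"counts": {z: c.tolist() for z, c in counts.items()},
                     "observed_prevalence": prev},
    )


def pairs_from_continuous(pairs: pd.DataFrame, percentile: float,
                          cols=("t1_score", "t2_score")) -> pd.DataFrame:
    """Dichotomize continuous pair scores at an extreme-percentile cut-off."""
    from .extremes import select_probands

    scores = np.concatenate([pairs[cols[0]].to_numpy(float),
                             pairs[cols[1]].to_numpy(float)])
    mask = select_probands(scores, percentile)
    n = len(pairs)
    out = pairs.copy()
    out["t1_dx"] = mask[:n].astype(int)
    out["t2_dx"] = mask[n:].astype(int)
    return out
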