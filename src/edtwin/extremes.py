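"""DeFries-Fulker (DF) extremes analysis.

DF analysis asks whether the genetic influences on *extreme* trait
scores are the same ones operating across the trait's continuous range.
Probands are individuals in the extreme (here: high-scoring, most
symptomatic) tail at a percentile cut-off; their co-twins' regression
toward the population mean indexes familial resemblance.  Scores are
affinely transformed so the population mean is 0 and the proband mean
is 1; the transformed co-twin means are then read like twin
correlations, and *group heritability* (h2g) measures the genetic
contribution to the proband-population mean difference.

Two estimation routes are provided:

* ``regression`` — the classical augmented DF regression
  ``C = B1*P + B2*R + A`` on double-entered transformed data, where C is
  the co-twin score, P the proband score and R the coefficient of
  relationship (1 for MZ, 0.5 for DZ); after the transformation the
  partial regression coefficient B2 estimates h2g.  Standard errors are
  cluster-robust on the twin pair (double-entry reuses concordant
  pairs).

* ``model-fitting`` — maximum likelihood for the equivalent
  group-components means model: transformed co-twin scores are normal
  with mean ``h2g * R + c2g`` (``c2g`` is the group shared-environment
  share, dropped in the AE variant) and per-zygosity residual variances.
  CIs are profile likelihood.

Selection is done on ranks, so any strictly monotone re-expression of
the raw scores (including the log transform applied upstream) yields
identical proband sets, and h2g is invariant to affine rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .biometric import _profile_interval

__all__ = [
    "ExtremesResult",
    "select_probands",
    "df_transform",
    "double_entry",
    "group_heritability",
    "extremes_table",
]


@dataclass
class ExtremesResult:
    percentile: float
    n_probands: int
    cotwin_mean: dict[str, float]
    h2g: float
    h2g_ci: tuple[float, float] | None
    c2g: float
    e2g: float
    method: str
    h2g_raw: float = 0.0
    minus2ll: float | None = None
    n_free: int | None = None
    diagnostics: dict = field(default_factory=dict)


def select_probands(scores: np.ndarray, percentile: float) -> np.ndarray:
    """Mask of probands: the extreme high-scoring ``percentile`` % tail.

    "1st percentile" denotes the most severe 1% of the sample.  The
    cut-off is the (100 - p)th sample quantile computed on ranks; ties at
    the cut-off are all included.
    """
    scores = np.asarray(scores, dtype=float)
    if not 0.0 < percentile <= 100.0:
        raise ValueError("percentile must lie in (0, 100]")
    if percentile == 100.0:
        return np.ones(len(scores), dtype=bool)
    # Rank-based selection: identical proband sets under any strictly
    # monotone transform of the scores.
    ranks = pd.Series(scores).rank(method="average").to_numpy()
    cut = np.quantile(ranks, 1.0 - percentile / 100.0)
    mask = ranks >= cut
    if not mask.any():
        raise ValueError("empty proband set")
    return mask


def df_transform(scores: np.ndarray, probands: np.ndarray) -> np.ndarray:
    """Affine map sending the population mean to 0 and the proband mean to 1."""
    scores = np.asarray(scores, dtype=float)
    probands = np.asarray(probands, dtype=bool)
    mean_pop = scores.mean()
    mean_pro = scores[probands].mean()
    denom = mean_pro - mean_pop
    if abs(denom) < 1e-12:
        raise ValueError("degenerate selection: proband mean equals population mean")
    return (scores - mean_pop) / denom


def double_entry(pairs: pd.DataFrame, proband1: np.ndarray, proband2: np.ndarray,
                 cols=("t1_score", "t2_score")) -> pd.DataFrame:
    """Double-entered proband/co-twin rows.

    Every twin flagged as a proband contributes one row (proband score,
    co-twin score, R, pair id); concordant pairs are therefore entered
    twice, once per proband.
    """
    c1, c2 = cols
    rel = pairs["zygosity"].map({"MZ": 1.0, "DZ": 0.5}).to_numpy()
    rows = []
    for pcol, ccol, mask in ((c1, c2, np.asarray(proband1, bool)),
                             (c2, c1, np.asarray(proband2, bool))):
        sub = pairs.loc[mask]
        rows.append(pd.DataFrame({
            "pair_id": sub["pair_id"].to_numpy(),
            "zygosity": sub["zygosity"].to_numpy(),
            "relatedness": rel[mask],
            "proband_score": sub[pcol].to_numpy(),
            "cotwin_score": sub[ccol].to_numpy(),
        }))
    out = pd.concat(rows, ignore_index=True)
    if len(out) == 0:
        raise ValueError("no proband pairs")
    return out


def _transformed_entries(pairs: pd.DataFrame, percentile: float,
                         cols=("t1_score", "t2_score")):
    c1, c2 = cols
    scores = np.concatenate([pairs[c1].to_numpy(float), pairs[c2].to_numpy(float)])
    mask = select_probands(scores, percentile)
    n = len(pairs)
    p1, p2 = mask[:n], mask[n:]
    tscores = df_transform(scores, mask)
    tp = pairs.copy()
    tp[c1] = tscores[:n]
    tp[c2] = tscores[n:]
    entries = double_entry(tp, p1, p2, cols)
    return entries, int(mask.sum())


def group_heritability(pairs: pd.DataFrame, percentile: float,
                       method: str = "model-fitting", model: str = "ACE",
                       ci: bool = True, cols=("t1_score", "t2_score")) -> ExtremesResult:
    """Group heritability of extreme scores at one percentile cut-off.

    ``method`` selects the regression or model-fitting route (see module
    docstring); ``model`` chooses whether the group shared-environment
    share c2g is estimated ("ACE") or fixed to zero ("AE").  h2g is
    clipped to [0, 1] for reporting; the raw value is kept in
    ``h2g_raw``.
    """
    entries, n_pro = _transformed_entries(pairs, percentile, cols)
    for zyg in ("MZ", "DZ"):
        if not (entries["zygosity"] == zyg).any():
            raise ValueError(f"no {zyg} probands: group heritability inestimable")
    cotwin_mean = {
        z: float(entries.loc[entries.zygosity == z, "cotwin_score"].mean())
        for z in ("MZ", "DZ")
    }

    if method == "regression":
        return _regression_route(entries, percentile, n_pro, cotwin_mean, model, ci)
    if method == "model-fitting":
        return _ml_route(entries, percentile, n_pro, cotwin_mean, model, ci)
    raise ValueError("method must be 'regression' or 'model-fitting'")


def _finish(h2g_raw, c2g, **kw) -> ExtremesResult:
    h2g = min(max(h2g_raw, 0.0), 1.0)
    e2g = 1.0 - h2g - c2g
    return ExtremesResult(h2g=h2g, h2g_raw=float(h2g_raw), c2g=float(c2g),
                          e2g=float(e2g), **kw)


def _regression_route(entries, percentile, n_pro, cotwin_mean, model, ci):
    y = entries["cotwin_score"].to_numpy()
    if model == "AE":
        # c2g = 0: the mean structure is h2g * R with no intercept shift.
        X = np.column_stack([entries["proband_score"].to_numpy() - 1.0,
                             entries["relatedness"].to_numpy()])
        names = ["proband_centered", "relatedness"]
        exog = pd.DataFrame(X, columns=names)
        res = sm.OLS(y, exog).fit(cov_type="cluster",
                                  cov_kwds={"groups": entries["pair_id"]})
        h2g_raw = float(res.params["relatedness"])
        c2g = 0.0
    else:
        X = sm.add_constant(pd.DataFrame({
            "proband_score": entries["proband_score"].to_numpy(),
            "relatedness": entries["relatedness"].to_numpy(),
        }))
        res = sm.OLS(y, X).fit(cov_type="cluster",
                               cov_kwds={"groups": entries["pair_id"]})
        h2g_raw = float(res.params["relatedness"])
        # Implied co-twin mean of an average (transformed score 1) proband at
        # R = 0 is the group shared-environment share.
        c2g = float(res.params["const"] + res.params["proband_score"])
        c2g = max(min(c2g, 1.0), 0.0)
    se = float(res.bse["relatedness"])
    interval = (h2g_raw - 1.96 * se, h2g_raw + 1.96 * se) if ci else None
    return _finish(
        h2g_raw, c2g, percentile=percentile, n_probands=n_pro,
        cotwin_mean=cotwin_mean, h2g_ci=interval, method="regression",
        diagnostics={"se_cluster": se, "n_entries": len(entries)},
    )


def _ml_route(entries, percentile, n_pro, cotwin_mean, model, ci):
    y = {z: entries.loc[entries.zygosity == z, "cotwin_score"].to_numpy()
         for z in ("MZ", "DZ")}
    p = {z: entries.loc[entries.zygosity == z, "proband_score"].to_numpy()
         for z in ("MZ", "DZ")}
    rel = {"MZ": 1.0, "DZ": 0.5}
    estimate_c = model == "ACE"

    def neg2ll(theta, h2g_fixed=None):
        i = 0
        if h2g_fixed is None:
            h2g = theta[i]; i += 1
        else:
            h2g = h2g_fixed
        c2g = theta[i] if estimate_c else 0.0
        i += 1 if estimate_c else 0
        b1 = theta[i]; i += 1
        total = 0.0
        for z in ("MZ", "DZ"):
            logv = theta[i]; i += 1
            v = math.exp(logv)
            mu = h2g * rel[z] + c2g + b1 * (p[z] - 1.0)
            resid = y[z] - mu
            total += len(resid) * (math.log(2 * math.pi) + logv) + float(resid @ resid) / v
        return total

    n_theta = 1 + (1 if estimate_c else 0) + 1 + 2
    x0 = np.array([0.6] + ([0.05] if estimate_c else [])
                  + [0.3, math.log(0.5), math.log(0.5)])

    def minimize(h2g_fixed=None):
        x_init = x0 if h2g_fixed is None else x0[1:]
        res = optimize.minimize(lambda t: neg2ll(t, h2g_fixed), x_init,
                                method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 20000})
        return res

    res = minimize()
    h2g_raw = float(res.x[0])
    c2g = float(res.x[1]) if estimate_c else 0.0
    base = float(res.fun)

    interval = None
    if ci:
        interval = _profile_interval(
            lambda h: float(minimize(h2g_fixed=h).fun), h2g_raw, base,
            lo_bound=h2g_raw - 1.5, hi_bound=h2g_raw + 1.5)
    return _finish(
        h2g_raw, max(min(c2g, 1.0), 0.0), percentile=percentile, n_probands=n_pro,
        cotwin_mean=cotwin_mean, h2g_ci=interval, method="model-fitting",
        minus2ll=base, n_free=n_theta,
        diagnostics={"converged": bool(res.success), "n_entries": len(entries)},
    )


def extremes_table(pairs: pd.DataFrame, percentiles=(1, 3, 5, 10),
                   method: str = "model-fitting", model: str = "ACE",
                   ci: bool = True, cols=("t1_score", "t2_score")) -> pd.DataFrame:
    """Per-percentile extremes summary (proband n, co-twin means, h2g, CI)."""
    rows = []
    for pct in percentiles:
        r = group_heritability(pairs, pct, method=method, model=model, ci=ci, cols=cols)
        rows.append({
            "percentile": pct,
            "n_probands": r.n_probands,
            "cotwin_mean_mz": r.cotwin_mean["MZ"],
            "cotwin_mean_dz": r.cotwin_mean["DZ"],
            "h2g": r.h2g,
            "h2g_lo": r.h2g_ci[0] if r.h2g_ci else np.nan,
            "h2g_hi": r.h2g_ci[1] if r.h2g_ci else np.nan,
            "c2g": r.c2g,
            "method": r.method,
        })
    return pd.DataFrame(rows)
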