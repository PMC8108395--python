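"""Model-selection machinery: likelihood-ratio tests, AIC/BIC, best model.

Nested twin models are compared by the likelihood-ratio chi-square
(difference in -2 log likelihood, df = difference in free parameters).
The default selection policy mirrors standard twin-analysis practice:
prefer the most reduced model whose fit does not deteriorate
significantly relative to its comparison model, breaking ties by BIC.
A pure lowest-BIC policy is also available.

Boundary caveat: when a variance component is dropped (e.g. AE vs ACE)
the true null distribution of the LRT is a 50:50 mixture of chi-square
distributions; the plain chi-square reference used by default is
conservative.  The mixture reference is available via ``boundary=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2

from .biometric import FitResult

__all__ = ["ComparisonRow", "lrt", "select_best", "comparison_table"]


@dataclass
class ComparisonRow:
    model: str
    minus2ll: float
    n_free: int
    delta_chi2: float | None
    delta_df: int | None
    p_value: float | None
    aic: float
    bic: float
    best: bool = False
    vs: str | None = None


def lrt(parent, nested, boundary: bool = False) -> ComparisonRow:
    """Likelihood-ratio test of ``nested`` against ``parent``.

    ``parent`` must strictly contain the nested model's free parameters;
    only the parameter counts are checkable here, so a nested model with
    at least as many free parameters is rejected.  ``boundary=True``
    switches to the 50:50 chi-square mixture reference appropriate when
    the constrained parameter sits on the boundary of its space.
    """
    if nested.n_free >= parent.n_free:
        raise ValueError(
            f"not nested: {nested.model} has {nested.n_free} free parameters, "
            f"parent {parent.model} has {parent.n_free}"
        )
    delta = nested.minus2ll - parent.minus2ll
    ddf = parent.n_free - nested.n_free
    if delta < -1e-6:
        raise ValueError(
            f"nested model fits better than parent (delta chi2 = {delta:.3g}); "
            "check convergence"
        )
    delta = max(delta, 0.0)
    if boundary and ddf == 1:
        p = 0.5 * chi2.sf(delta, 1) if delta > 0 else 1.0
    else:
        p = float(chi2.sf(delta, ddf))
    return ComparisonRow(
        model=nested.model, minus2ll=nested.minus2ll, n_free=nested.n_free,
        delta_chi2=float(delta), delta_df=ddf, p_value=p,
        aic=nested.aic, bic=nested.bic, vs=parent.model,
    )


def comparison_table(parent: FitResult, fits: list[FitResult],
                     boundary: bool = False) -> list[ComparisonRow]:
    """Rows comparing each fit against the common parent model."""
    rows = [ComparisonRow(parent.model, parent.minus2ll, parent.n_free,
                          None, None, None, parent.aic, parent.bic)]
    rows.extend(lrt(parent, f, boundary=boundary) for f in fits)
    return rows


def select_best(rows: list[ComparisonRow], rule: str = "paper",
                alpha: float = 0.05) -> str:
    """Best-model designation over a comparison family.

    ``rule="paper"``: among models not significantly worse than their
    comparison model (LRT p >= alpha, the parent row always qualifies),
    pick the most reduced (fewest free parameters), breaking ties by
    lowest BIC.  ``rule="bic"``: lowest BIC outright.  When the two
    policies disagree the returned label follows the requested rule; use
    both calls to surface the conflict.
    """
    if not rows:
        raise ValueError("no models to compare")
    for r in rows:
        r.best = False
    if rule == "bic":
        best = min(rows, key=lambda r: r.bic)
    elif rule == "paper":
        ok = [r for r in rows if r.p_value is None or r.p_value >= alpha]
        if not ok:
            ok = [r for r in rows if r.p_value is None]
        best = min(ok, key=lambda r: (r.n_free, r.bic))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    best.best = True
    return best.model
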