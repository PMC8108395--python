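"""Analysis-phenotype construction.

Two phenotypes drive every downstream model:

* the continuous **EDI-2 score** — the mean of the Drive for Thinness
  (7 items), Bulimia (7 items) and Body Dissatisfaction (9 items)
  subscales, each item on a 1 ("never") to 6 ("always") scale, computed
  only when at least 75% of items on *each* subscale were answered
  (>= 6/7, >= 6/7, >= 7/9), and subsequently log-transformed;

* the categorical **eating-disorder diagnosis**, assembled from three
  ascertainment sources (national patient-register ICD codes,
  parent-reported treatment, self-reported regular purging) and split
  into AN vs other eating disorders (OED), with AN taking precedence
  when both apply.

Missing source flags are treated as "not ascertained = not a case" for
classification (parent reports in the emulated cohort were available for
only ~72.5% of individuals); per-source availability is reported
separately in the cohort summary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "SUBSCALES",
    "Edi2ItemSet",
    "CaseSourceFlags",
    "EdGroup",
    "EdClassification",
    "score_edi2",
    "score_edi2_frame",
    "log_transform",
    "classify_ed",
    "classify_frame",
    "parse_icd_flags",
    "cohort_summary",
    "round_half_up",
]

log = logging.getLogger(__name__)

#: (name, item count, minimum answered for a valid score)
SUBSCALES = (
    ("drive_for_thinness", 7, 6),
    ("bulimia", 7, 6),
    ("body_dissatisfaction", 9, 7),
)

_AN_CODES = {"F500", "F501"}
_OED_CODES = {"F502", "F503", "F509"}
_EXCLUDED_CODES = {"F504", "F505", "F508", "F982", "F983"}


@dataclass
class Edi2ItemSet:
    """Item responses for one individual; ``None``/NaN marks a missing item."""

    drive_for_thinness: list
    bulimia: list
    body_dissatisfaction: list

    def __post_init__(self) -> None:
        for name, n_items, _ in SUBSCALES:
            vals = getattr(self, name)
            if len(vals) != n_items:
                raise ValueError(f"{name} must have {n_items} items, got {len(vals)}")
            for v in vals:
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    continue
                if not float(v).is_integer() or not 1 <= int(v) <= 6:
                    raise ValueError(f"{name} response {v!r} outside 1-6")


class EdGroup(str, Enum):
    AN = "AN"
    OED = "OED"
    NONE = "NONE"


@dataclass(frozen=True)
class CaseSourceFlags:
    """Tri-state (True/False/None) case indicators from the three sources."""

    npr_an: bool | None = False
    npr_oed: bool | None = False
    parent_treat_an: bool | None = False
    parent_treat_bn: bool | None = False
    self_purging: bool | None = False


@dataclass(frozen=True)
class EdClassification:
    group: EdGroup
    any_ed: bool


def score_edi2(items: Edi2ItemSet) -> float | None:
    """Total EDI-2 score: mean over all answered items, or None.

    Valid only when each subscale meets its completion minimum (at least
    6/7, 6/7 and 7/9 answered); otherwise the score is missing.  When
    valid, the score is the mean of the *answered* items pooled across
    the three subscales.
    """
    answered: list[float] = []
    for name, _, min_answered in SUBSCALES:
        vals = [
            float(v)
            for v in getattr(items, name)
            if v is not None and not (isinstance(v, float) and math.isnan(v))
        ]
        if len(vals) < min_answered:
            return None
        answered.extend(vals)
    return sum(answered) / len(answered)


def score_edi2_frame(df: pd.DataFrame, prefixes=("dt", "bu", "bd")) -> pd.Series:
    """Vectorized scoring over an individual-level frame.

    Expects item columns ``dt1..dt7``, ``bu1..bu7``, ``bd1..bd9`` (NaN for
    missing).  Returns a float Series with NaN where the 75%-per-subscale
    rule fails.
    """
    cols = {}
    for prefix, (name, n_items, min_answered) in zip(prefixes, SUBSCALES):
        names = [f"{prefix}{i}" for i in range(1, n_items + 1)]
        block = df[names].to_numpy(dtype=float)
        if np.nanmax(block, initial=1) > 6 or np.nanmin(block, initial=6) < 1:
            raise ValueError(f"{name} responses outside 1-6")
        cols[name] = (block, min_answered)
    blocks = np.concatenate([b for b, _ in cols.values()], axis=1)
    valid = np.ones(len(df), dtype=bool)
    for block, min_answered in cols.values():
        valid &= (~np.isnan(block)).sum(axis=1) >= min_answered
    with np.errstate(invalid="ignore"):
        score = np.nanmean(blocks, axis=1)
    score[~valid] = np.nan
    return pd.Series(score, index=df.index, name="edi2_score")


def log_transform(score):
    """Natural-log transform of the (>= 1) bounded score."""
    arr = np.asarray(score, dtype=float)
    if np.any(arr[~np.isnan(arr)] <= 0):
        raise ValueError("log transform requires positive scores")
    out = np.log(arr)
    return float(out) if out.ndim == 0 else out


def parse_icd_flags(codes) -> CaseSourceFlags:
    """NPR flags from raw ICD-10 code strings (dot optional).

    AN flags come from F50.0/F50.1, OED flags from F50.2/F50.3/F50.9;
    explicitly excluded feeding/eating codes (F50.4, F50.5, F50.8, F98.2,
    F98.3) are dropped with a logged count; unknown codes raise.
    """
    an = oed = False
    dropped = 0
    for raw in codes:
        code = str(raw).strip().upper().replace(".", "")
        if code in _AN_CODES:
            an = True
        elif code in _OED_CODES:
            oed = True
        elif code in _EXCLUDED_CODES:
            dropped += 1
        else:
            raise ValueError(f"unrecognized ICD code: {raw!r}")
    if dropped:
        log.info("dropped %d excluded feeding/eating-disorder codes", dropped)
    return CaseSourceFlags(npr_an=an, npr_oed=oed)


def classify_ed(flags: CaseSourceFlags) -> EdClassification:
    """Three-source classification with AN precedence.

    AN when the register or parent-reported treatment indicates AN;
    otherwise OED when the register, parent-reported BN treatment or
    self-reported regular purging indicates any other eating disorder;
    otherwise NONE.  Individuals qualifying for both groups land in AN.
    Missing (None) flags count as absent.
    """
    if bool(flags.npr_an) or bool(flags.parent_treat_an):
        return EdClassification(EdGroup.AN, True)
    if bool(flags.npr_oed) or bool(flags.parent_treat_bn) or bool(flags.self_purging):
        return EdClassification(EdGroup.OED, True)
    return EdClassification(EdGroup.NONE, False)


_FLAG_COLS = ["npr_an", "npr_oed", "parent_treat_an", "parent_treat_bn", "self_purging"]


def classify_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Add ``ed_group`` / ``any_ed`` columns from source-flag columns."""
    out = df.copy()
    f = {c: df[c].fillna(False).astype(bool) if c in df else pd.Series(False, index=df.index)
         for c in _FLAG_COLS}
    an = f["npr_an"] | f["parent_treat_an"]
    oed = ~an & (f["npr_oed"] | f["parent_treat_bn"] | f["self_purging"])
    out["ed_group"] = np.select([an, oed], [EdGroup.AN.value, EdGroup.OED.value], EdGroup.NONE.value)
    out["any_ed"] = an | oed
    return out


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Table-style rounding: one decimal, ties away from zero."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(num: int, den: int) -> float:
    return round_half_up(100.0 * num / den) if den else float("nan")


def cohort_summary(df: pd.DataFrame) -> dict:
    """Counts, prevalences and source overlaps for a classified cohort.

    Input is an individual-level frame with the five source-flag columns
    (tri-state; NaN = not ascertained).  Percentages are rounded to one
    decimal, half-up.  Overlap entries mirror the descriptive reporting
    of multi-source ascertainment: the share of cases carrying a register
    diagnosis, and the register confirmation rate of parent-reported
    treatment.
    """
    if len(df) == 0:
        raise ValueError("empty cohort")
    d = classify_frame(df)
    n = len(d)
    flags = {c: d[c].fillna(False).astype(bool) if c in d else pd.Series(False, index=d.index)
             for c in _FLAG_COLS}
    npr_any = flags["npr_an"] | flags["npr_oed"]
    n_any = int(d["any_ed"].sum())
    n_an = int((d["ed_group"] == EdGroup.AN.value).sum())
    n_oed = int((d["ed_group"] == EdGroup.OED.value).sum())

    summary = {
        "n_individuals": n,
        "groups": {
            "AN": {"n": n_an, "pct": _pct(n_an, n)},
            "OED": {"n": n_oed, "pct": _pct(n_oed, n)},
            "NONE": {"n": n - n_any, "pct": _pct(n - n_any, n)},
        },
        "any_ed": {"n": n_any, "pct": _pct(n_any, n)},
        "sources": {
            "npr_any": {"n": int(npr_any.sum()), "pct": _pct(int(npr_any.sum()), n)},
            "parent_treat_an": {"n": int(flags["parent_treat_an"].sum())},
            "parent_treat_bn": {"n": int(flags["parent_treat_bn"].sum())},
            "self_purging": {
                "n": int(flags["self_purging"].sum()),
                "pct": _pct(int(flags["self_purging"].sum()), n),
            },
        },
        "availability": {
            c: _pct(int(d[c].notna().sum()), n) if c in d else 0.0 for c in _FLAG_COLS
        },
        "overlap": {
            "any_ed_with_npr_pct": _pct(int((d["any_ed"] & npr_any).sum()), n_any),
            "parent_an_with_npr_an_pct": _pct(
                int((flags["parent_treat_an"] & flags["npr_an"]).sum()),
                int(flags["parent_treat_an"].sum()),
            ),
            "parent_bn_with_npr_bn_pct": _pct(
                int((flags["parent_treat_bn"] & flags["npr_oed"]).sum()),
                int(flags["parent_treat_bn"].sum()),
            ),
            "purging_with_npr_pct": _pct(
                int((flags["self_purging"] & npr_any).sum()),
                int(flags["self_purging"].sum()),
            ),
        },
    }
    return summary
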