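"""Synthetic twin-cohort generator with known ACE structure.

Simulates pair-level twin data — a continuous phenotype, a dichotomous
(liability-threshold) phenotype, or a mixed continuous + binary bivariate
pair — from explicit latent additive-genetic (A), shared-environment (C)
and non-shared-environment (E) factor draws.  MZ co-twins share their A
factor entirely; DZ co-twins share half of its variance, which is exactly
the structural assumption of the classical twin design (MZ twins share
all segregating alleles, DZ twins on average 50%).

The generator's defaults mirror the study cohort this package was built
around: 768 MZ + 713 DZ female same-sex pairs, an AE trait with
heritability 0.65, a bounded 1-6 symptom scale with mean 2.66, s.d. 0.90
and skew 0.57, and diagnosis prevalences of roughly 2.4% (AN), 3.3%
(other eating disorders) and 5.7% (any eating disorder).

All randomness flows from one master seed; named substreams are derived
deterministically with ``numpy.random.SeedSequence`` so that each
simulation mode is bit-reproducible given (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize
from scipy.special import ndtr, ndtri

__all__ = [
    "MomentTarget",
    "SimConfig",
    "GroundTruthManifest",
    "simulate_continuous",
    "simulate_binary",
    "simulate_bivariate",
    "apply_skew_transform",
    "calibrate_skew_transform",
    "write_pairs",
    "STUDY_CONFIG",
]

# Substream labels: stable small integers so seeds stay reproducible
# across releases even if code order changes.
_STREAMS = {"continuous": 1, "binary": 2, "bivariate": 3, "phenotype_fixture": 4}


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named substream of a master seed."""
    key = _STREAMS.get(name)
    if key is None:
        raise KeyError(f"unknown stream name: {name!r}")
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


@dataclass(frozen=True)
class MomentTarget:
    """Target mean / s.d. / skew for the bounded-scale transform."""

    mean: float = 2.66
    sd: float = 0.90
    skew: float = 0.57


@dataclass
class SimConfig:
    """Configuration of one simulated twin cohort.

    ``a2 + c2 + e2`` must equal 1 (standardized variance proportions).
    For the bivariate mode the second trait has its own components
    (``a2_2``/``c2_2``/``e2_2``, defaulting to the first trait's) and the
    cross-trait factor correlations ``rA``, ``rC``, ``rE``.  Exactly one
    of ``threshold_z`` / ``prevalence`` may be given for binary traits.
    """

    n_mz: int = 768
    n_dz: int = 713
    a2: float = 0.65
    c2: float = 0.0
    e2: float = 0.35
    threshold_z: float | None = None
    prevalence: float | None = None
    a2_2: float | None = None
    c2_2: float | None = None
    e2_2: float | None = None
    rA: float = 0.0
    rC: float = 0.0
    rE: float = 0.0
    skew_transform: MomentTarget | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mz < 0 or self.n_dz < 0:
            raise ValueError("pair counts must be non-negative")
        for name in ("a2", "c2", "e2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-9:
            raise ValueError("a2 + c2 + e2 must sum to 1 (within 1e-9)")
        if self.threshold_z is not None and self.prevalence is not None:
            raise ValueError("give threshold_z or prevalence, not both")
        if self.prevalence is not None and not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        second = [self.a2_2, self.c2_2, self.e2_2]
        if any(v is not None for v in second):
            if any(v is None for v in second):
                raise ValueError("give all of a2_2, c2_2, e2_2 or none")
            if any(v < 0 for v in second):
                raise ValueError("trait-2 components must be non-negative")
            if abs(sum(second) - 1.0) > 1e-9:
                raise ValueError("a2_2 + c2_2 + e2_2 must sum to 1 (within 1e-9)")
        for name in ("rA", "rC", "rE"):
            if abs(getattr(self, name)) > 1.0:
                raise ValueError(f"{name} must lie in [-1, 1]")

    @property
    def trait2(self) -> tuple[float, float, float]:
        if self.a2_2 is None:
            return (self.a2, self.c2, self.e2)
        return (self.a2_2, self.c2_2, self.e2_2)

    def threshold(self) -> float:
        if self.threshold_z is not None:
            return float(self.threshold_z)
        if self.prevalence is not None:
            return float(ndtri(1.0 - self.prevalence))
        raise ValueError("binary mode requires threshold_z or prevalence")


#: Configuration matching the study cohort used throughout the docs/tests.
STUDY_CONFIG = SimConfig(n_mz=768, n_dz=713, a2=0.65, c2=0.0, e2=0.35)


@dataclass
class GroundTruthManifest:
    """Echo of the config plus the implied population quantities."""

    config: dict
    expected_r_mz: float
    expected_r_dz: float
    expected_prevalence: float | None = None
    expected_r_ph: float | None = None
    transform_params: dict | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _manifest(cfg: SimConfig, **extra) -> GroundTruthManifest:
    d = asdict(cfg)
    if cfg.skew_transform is not None:
        d["skew_transform"] = asdict(cfg.skew_transform)
    return GroundTruthManifest(
        config=d,
        expected_r_mz=cfg.a2 + cfg.c2,
        expected_r_dz=0.5 * cfg.a2 + cfg.c2,
        **extra,
    )


# ---------------------------------------------------------------------------
# Latent-factor draws
# ---------------------------------------------------------------------------

def _ace_draw(rng, n: int, r_twin: float, comps: tuple[float, float, float]):
    """One zygosity group's (twin1, twin2) phenotypes, unit variance."""
    a2, c2, e2 = comps
    a, c, e = np.sqrt(a2), np.sqrt(c2), np.sqrt(e2)
    a_sh = rng.standard_normal(n)
    a_u = rng.standard_normal((2, n))
    A = np.sqrt(r_twin) * a_sh + np.sqrt(1.0 - r_twin) * a_u
    C = rng.standard_normal(n)
    E = rng.standard_normal((2, n))
    return a * A + c * C[None, :] + e * E


def simulate_continuous(cfg: SimConfig) -> pd.DataFrame:
    """Simulate a univariate continuous twin phenotype.

    Returns a pair-level table with columns ``pair_id``, ``zygosity``,
    ``t1_score``, ``t2_score``.  Before any skew transform the phenotype
    has population mean 0 and variance 1, with expected twin correlations
    ``a2 + c2`` (MZ) and ``0.5*a2 + c2`` (DZ).
    """
    rng = substream(cfg.seed, "continuous")
    comps = (cfg.a2, cfg.c2, cfg.e2)
    y_mz = _ace_draw(rng, cfg.n_mz, 1.0, comps)
    y_dz = _ace_draw(rng, cfg.n_dz, 0.5, comps)
    df = pd.DataFrame(
        {
            "pair_id": np.arange(cfg.n_mz + cfg.n_dz),
            "zygosity": np.repeat(["MZ", "DZ"], [cfg.n_mz, cfg.n_dz]),
            "t1_score": np.concatenate([y_mz[0], y_dz[0]]),
            "t2_score": np.concatenate([y_mz[1], y_dz[1]]),
        }
    )
    if cfg.skew_transform is not None:
        params = calibrate_skew_transform(cfg.skew_transform)
        for col in ("t1_score", "t2_score"):
            df[col] = apply_skew_transform(df[col].to_numpy(), cfg.skew_transform, _params=params)
    return df


def simulate_binary(cfg: SimConfig) -> pd.DataFrame:
    """Simulate a dichotomous twin phenotype via a liability threshold.

    The latent liability follows the same ACE structure as
    :func:`simulate_continuous`; the diagnosis indicator is
    ``liability > threshold`` with ``threshold = ndtri(1 - prevalence)``
    when a prevalence is given.  Columns ``t1_dx`` / ``t2_dx`` are 0/1;
    the latent liabilities are kept as ``t1_liab`` / ``t2_liab`` for
    diagnostics.
    """
    t = cfg.threshold()
    rng = substream(cfg.seed, "binary")
    comps = (cfg.a2, cfg.c2, cfg.e2)
    l_mz = _ace_draw(rng, cfg.n_mz, 1.0, comps)
    l_dz = _ace_draw(rng, cfg.n_dz, 0.5, comps)
    liab1 = np.concatenate([l_mz[0], l_dz[0]])
    liab2 = np.concatenate([l_mz[1], l_dz[1]])
    return pd.DataFrame(
        {
            "pair_id": np.arange(cfg.n_mz + cfg.n_dz),
            "zygosity": np.repeat(["MZ", "DZ"], [cfg.n_mz, cfg.n_dz]),
            "t1_liab": liab1,
            "t2_liab": liab2,
            "t1_dx": (liab1 > t).astype(int),
            "t2_dx": (liab2 > t).astype(int),
        }
    )


def _bivariate_factor(rng, n: int, r_twin: float, r_cross: float):
    """(2 twins, 2 traits, n pairs) factor draws.

    Cross-twin same-trait correlation ``r_twin``; within-twin cross-trait
    correlation ``r_cross``; cross-twin cross-trait ``r_twin * r_cross``
    (the covariance is the Kronecker product of the twin-sharing and
    trait-correlation matrices, so the factorized construction below is
    exact).
    """

    def corr2(m):
        z = rng.standard_normal((2, m))
        return np.stack([z[0], r_cross * z[0] + np.sqrt(1 - r_cross**2) * z[1]])

    shared = corr2(n)  # (trait, n)
    unique = np.stack([corr2(n), corr2(n)])  # (twin, trait, n)
    return np.sqrt(r_twin) * shared[None, :, :] + np.sqrt(1.0 - r_twin) * unique


def implied_rph(comps1, comps2, rA, rC, rE) -> float:
    """Phenotypic correlation implied by the correlated-factors model."""
    a1, c1, e1 = np.sqrt(comps1)
    a2, c2, e2 = np.sqrt(comps2)
    return float(rA * a1 * a2 + rC * c1 * c2 + rE * e1 * e2)


def simulate_bivariate(cfg: SimConfig) -> pd.DataFrame:
    """Simulate a continuous trait plus a correlated threshold trait.

    Trait 1 is continuous (columns ``t1_score``/``t2_score``); trait 2 is
    a liability dichotomized at the configured threshold (columns
    ``t1_dx``/``t2_dx``).  Cross-trait A/C/E factor correlations are
    ``rA``/``rC``/``rE``; the implied phenotypic correlation
    ``rA*a1*a2 + rC*c1*c2 + rE*e1*e2`` is recorded in the manifest.
    """
    comps1 = (cfg.a2, cfg.c2, cfg.e2)
    comps2 = cfg.trait2
    # PSD check: each factor's 2x2 cross-trait correlation matrix.
    for name, r in (("rA", cfg.rA), ("rC", cfg.rC), ("rE", cfg.rE)):
        m = np.array([[1.0, r], [r, 1.0]])
        if np.linalg.eigvalsh(m)[0] < -1e-12:
            raise ValueError(f"cross-trait matrix for {name} not PSD:\n{m}")
    t = cfg.threshold()
    rng = substream(cfg.seed, "bivariate")
    paths1 = np.sqrt(comps1)
    paths2 = np.sqrt(comps2)

    blocks = []
    for zyg, n, r_twin in (("MZ", cfg.n_mz, 1.0), ("DZ", cfg.n_dz, 0.5)):
        A = _bivariate_factor(rng, n, r_twin, cfg.rA)
        C = _bivariate_factor(rng, n, 1.0, cfg.rC)  # C fully shared within pair
        E = _bivariate_factor(rng, n, 0.0, cfg.rE)  # E independent across twins
        y = np.empty((2, 2, n))
        for trait, paths in enumerate((paths1, paths2)):
            a, c, e = paths
            y[:, trait, :] = a * A[:, trait, :] + c * C[:, trait, :] + e * E[:, trait, :]
        blocks.append((zyg, y))

    frames = []
    offset = 0
    for zyg, y in blocks:
        n = y.shape[2]
        frames.append(
            pd.DataFrame(
                {
                    "pair_id": offset + np.arange(n),
                    "zygosity": zyg,
                    "t1_score": y[0, 0],
                    "t2_score": y[1, 0],
                    "t1_liab": y[0, 1],
                    "t2_liab": y[1, 1],
                    "t1_dx": (y[0, 1] > t).astype(int),
                    "t2_dx": (y[1, 1] > t).astype(int),
                }
            )
        )
        offset += n
    df = pd.concat(frames, ignore_index=True)
    if cfg.skew_transform is not None:
        params = calibrate_skew_transform(cfg.skew_transform)
        for col in ("t1_score", "t2_score"):
            df[col] = apply_skew_transform(df[col].to_numpy(), cfg.skew_transform, _params=params)
    return df


def manifest_for(cfg: SimConfig) -> GroundTruthManifest:
    """Ground-truth manifest (expected correlations, prevalence, rPH)."""
    extra: dict = {}
    if cfg.threshold_z is not None or cfg.prevalence is not None:
        extra["expected_prevalence"] = float(1.0 - ndtr(cfg.threshold()))
    if cfg.a2_2 is not None or cfg.rA or cfg.rC or cfg.rE:
        extra["expected_r_ph"] = implied_rph(
            (cfg.a2, cfg.c2, cfg.e2), cfg.trait2, cfg.rA, cfg.rC, cfg.rE
        )
    if cfg.skew_transform is not None:
        g, d, span = calibrate_skew_transform(cfg.skew_transform)
        extra["transform_params"] = {
            "family": "johnson_sb",
            "gamma": g,
            "delta": d,
            "span": span,
            "note": "bounded-scale map is a modeling choice; only the three "
            "target moments are constrained by the emulated instrument",
        }
    return _manifest(cfg, **extra)


# ---------------------------------------------------------------------------
# Bounded-scale skew transform
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = hermegauss(201)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()

_CALIBRATION_CACHE: dict[tuple[float, float, float], tuple[float, float, float]] = {}


def _sb_map(z: np.ndarray, gamma: float, delta: float, span: float) -> np.ndarray:
    """Johnson-SB map of a standard-normal deviate onto (1, 1 + span)."""
    return 1.0 + span / (1.0 + np.exp(-(z - gamma) / delta))


def _sb_moments(gamma: float, delta: float, span: float):
    x = _sb_map(_GH_NODES, gamma, delta, span)
    m = float(np.dot(_GH_WEIGHTS, x))
    v = float(np.dot(_GH_WEIGHTS, (x - m) ** 2))
    sk = float(np.dot(_GH_WEIGHTS, (x - m) ** 3)) / v**1.5
    return m, np.sqrt(v), sk


def calibrate_skew_transform(target: MomentTarget) -> tuple[float, float, float]:
    """Solve the Johnson-SB parameters reproducing the target moments.

    Moments of the transform are evaluated with 201-point Gauss-Hermite
    quadrature (exact to machine precision for this smooth bounded map),
    and the three parameters (gamma, delta, span) are solved so that the
    population mean, s.d. and skew equal the target.
    """
    key = (target.mean, target.sd, target.skew)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]

    def resid(p):
        g, d, span = p
        if d <= 0 or span <= 0:
            return [1e3, 1e3, 1e3]
        m, s, sk = _sb_moments(g, d, span)
        return [m - target.mean, s - target.sd, sk - target.skew]

    sol, info, ier, msg = optimize.fsolve(resid, [0.8, 1.0, 5.0], full_output=True)
    if ier != 1 or max(abs(r) for r in resid(sol)) > 1e-8:
        raise ValueError(f"skew-transform calibration failed for {target}: {msg}")
    g, d, span = (float(v) for v in sol)
    if span > 5.0 + 1e-6:
        raise ValueError("calibrated transform exceeds the 1-6 scale")
    _CALIBRATION_CACHE[key] = (g, d, span)
    return g, d, span


def apply_skew_transform(
    values: np.ndarray,
    target: MomentTarget | None,
    _params: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Map standard-normal phenotypes onto the bounded right-skewed scale.

    Strictly monotone (rank-preserving, no ties introduced); ``target=None``
    is the identity.  The map is Johnson-SB: the log-odds of the position
    within the bounded support is linear in the normal deviate, so a log
    transform of the output restores approximate symmetry.
    """
    values = np.asarray(values, dtype=float)
    if target is None:
        return values
    g, d, span = _params if _params is not None else calibrate_skew_transform(target)
    return _sb_map(values, g, d, span)


def synthetic_flag_cohort(n: int = 2962) -> pd.DataFrame:
    """Synthetic individual-level source-flag cohort with realistic margins.

    A deterministic stand-in for register/questionnaire ascertainment
    data (no real records): 2962 individuals with the three diagnosis
    sources laid out so the margins match the emulated study cohort —
    93 register diagnoses (50 AN, 43 other), 46 parent-reported AN
    treatments (26 register-confirmed), 8 parent-reported BN treatments
    (1 register-confirmed, 6 overlapping AN treatment), 96 self-reported
    regular purgers, 169 individuals with any eating disorder (70 AN /
    99 OED after AN-precedence), and parent reports available for 2147
    individuals.  Useful for exercising classification and summary
    arithmetic end to end.
    """
    if n < 2962:
        raise ValueError("cohort layout needs at least 2962 individuals")
    df = pd.DataFrame({
        "npr_an": False, "npr_oed": False,
        "parent_treat_an": pd.array([False] * n, dtype="boolean"),
        "parent_treat_bn": pd.array([False] * n, dtype="boolean"),
        "self_purging": False,
    }, index=range(n))
    df.loc[0:49, "npr_an"] = True                       # 50 register AN
    df.loc[50:92, "npr_oed"] = True                     # 43 register OED
    df.loc[0:25, "parent_treat_an"] = True              # 26 register-confirmed
    df.loc[93:112, "parent_treat_an"] = True            # 20 parent-report only
    df.loc[0:5, "parent_treat_bn"] = True               # 6 treated for both
    df.loc[50:50, "parent_treat_bn"] = True             # 1 register-confirmed BN
    df.loc[113:113, "parent_treat_bn"] = True
    purging = list(range(30, 50)) + list(range(51, 63)) \
        + list(range(93, 102)) + list(range(114, 169))  # 96 total, 32 with register dx
    df.loc[purging, "self_purging"] = True
    df.loc[2147:, ["parent_treat_an", "parent_treat_bn"]] = pd.NA  # not ascertained
    return df


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_pairs(df: pd.DataFrame, path, manifest: GroundTruthManifest | None = None) -> None:
    """Write a pair table as CSV, with an optional JSON manifest alongside."""
    df.to_csv(path, index=False)
    if manifest is not None:
        with open(str(path) + ".manifest.json", "w") as fh:
            fh.write(manifest.to_json())
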