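"""Two-sample Mendelian randomization estimators.

Given per-variant effects of the instruments on an exposure (bx, sx) and an
outcome (by, sy) from two non-overlapping samples, the causal effect of the
exposure on the outcome is estimated by:

* the Wald ratio by/bx for a single instrument,
* the inverse-variance-weighted (IVW) average — equivalently a zero-intercept
  weighted regression of by on bx with weights 1/sy^2 (first-order weights),
* MR-Egger — the same regression with an intercept, whose intercept estimates
  average directional pleiotropy under the InSIDE assumption,
* the weighted median of the per-variant ratios, consistent when instruments
  carrying at least half the weight are valid, with a parametric-bootstrap
  standard error.

Cochran's Q over the per-variant ratios quantifies heterogeneity; inflation
beyond its chi-squared null suggests horizontal pleiotropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateInstrumentsError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
    ValidationError,
)
from .sumstats import HarmonizedPair, SumstatRecord, harmonize_pair


@dataclass
class MRInput:
    """Harmonized per-variant exposure/outcome effects with SEs."""

    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    variant_ids: Optional[list[str]] = None

    def __post_init__(self):
        self.bx = np.atleast_1d(np.asarray(self.bx, dtype=float))
        self.sx = np.atleast_1d(np.asarray(self.sx, dtype=float))
        self.by = np.atleast_1d(np.asarray(self.by, dtype=float))
        self.sy = np.atleast_1d(np.asarray(self.sy, dtype=float))
        m = len(self.bx)
        if not (len(self.sx) == len(self.by) == len(self.sy) == m):
            raise ValidationError("bx, sx, by, sy must have equal length")
        if m < 1:
            raise InsufficientInstrumentsError("need at least one variant")
        if np.any(self.sx <= 0) or np.any(self.sy <= 0):
            raise ValidationError("all SEs must be positive")

    @property
    def m(self) -> int:
        return len(self.bx)

    @classmethod
    def from_pairs(cls, pairs: Sequence[HarmonizedPair]) -> "MRInput":
        return cls(
            bx=[p.exposure.beta for p in pairs],
            sx=[p.exposure.se for p in pairs],
            by=[p.outcome.beta for p in pairs],
            sy=[p.outcome.se for p in pairs],
            variant_ids=[p.variant_id for p in pairs],
        )


@dataclass
class MRResult:
    """One estimator's causal-effect estimate with heterogeneity statistics.

    ``estimate`` is the change in outcome (log odds-ratio for binary
    outcomes) per unit (typically per SD) change in the exposure.
    """

    method: str
    estimate: float
    se: float
    p: float
    n_variants: int
    Q: float = float("nan")
    Q_df: int = 0
    Q_p: float = float("nan")
    egger_intercept: float = float("nan")
    intercept_se: float = float("nan")
    intercept_p: float = float("nan")


def _normal_p(z: float) -> float:
    return float(np.clip(2 * stats.norm.sf(abs(z)), np.nextafter(0, 1), 1.0))


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> MRResult:
    """Single-instrument ratio estimate with first-order delta-method SE."""
    if bx == 0:
        raise UndefinedRatioError("exposure effect is zero: ratio undefined")
    est = by / bx
    se = sy / abs(bx)
    return MRResult("wald", float(est), float(se), _normal_p(est / se), 1)


def cochran_q(inp: MRInput, estimate: float) -> tuple[float, int, float]:
    """Cochran's Q of the outcome betas around ``estimate * bx`` with
    first-order weights 1/sy^2; chi-squared on m-1 df."""
    q = float(np.sum((inp.by - estimate * inp.bx) ** 2 / inp.sy**2))
    df = inp.m - 1
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    return q, df, q_p


def ivw(inp: MRInput) -> MRResult:
    """Fixed-effect inverse-variance-weighted estimate.

    Equivalent to zero-intercept WLS of by on bx with weights 1/sy^2:
    estimate = sum(bx*by/sy^2) / sum(bx^2/sy^2), se = sum(bx^2/sy^2)^-1/2.
    """
    w = inp.bx**2 / inp.sy**2
    denom = float(w.sum())
    if denom == 0:
        raise DegenerateInstrumentsError("all exposure effects are zero")
    est = float(np.sum(inp.bx * inp.by / inp.sy**2) / denom)
    se = denom ** -0.5
    q, df, q_p = cochran_q(inp, est)
    return MRResult("ivw", est, se, _normal_p(est / se), inp.m, Q=q, Q_df=df, Q_p=q_p)


def egger(inp: MRInput) -> MRResult:
    """MR-Egger: weighted regression of by on bx with an intercept.

    Variants are first oriented so bx > 0 (negating both betas where
    needed), as the intercept is only interpretable under a common exposure
    orientation. The slope estimates the causal effect; the intercept
    estimates average directional pleiotropy.
    """
    if inp.m < 3:
        raise InsufficientInstrumentsError(f"Egger needs >= 3 variants, got {inp.m}")
    sign = np.where(inp.bx < 0, -1.0, 1.0)
    bx, by = inp.bx * sign, inp.by * sign
    w = 1.0 / inp.sy**2

    X = np.column_stack([np.ones(inp.m), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    dof = inp.m - 2
    # scale SEs by residual dispersion, floored at 1 (the convention of the
    # standard MR implementations: never deflate below the fixed-effect SE)
    sigma2 = max(float(resid @ (w * resid)) / dof, 1.0)
    cov = sigma2 * np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov))
    t_slope = coef[1] / se[1]
    t_int = coef[0] / se[0]
    p_slope = float(np.clip(2 * stats.t.sf(abs(t_slope), dof), np.nextafter(0, 1), 1.0))
    p_int = float(np.clip(2 * stats.t.sf(abs(t_int), dof), np.nextafter(0, 1), 1.0))
    q = float(np.sum(w * resid**2))
    q_p = float(stats.chi2.sf(q, dof))
    return MRResult("egger", float(coef[1]), float(se[1]), p_slope, inp.m,
                    Q=q, Q_df=dof, Q_p=q_p,
                    egger_intercept=float(coef[0]), intercept_se=float(se[0]),
                    intercept_p=p_int)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: percentile of the j-th order statistic
    is the cumulative weight minus half its own weight."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w)
    perc = s - w / 2
    return float(np.interp(0.5, perc, r))


def weighted_median(inp: MRInput, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted median of per-variant ratios; SE by parametric bootstrap.

    Ratios by/bx are weighted by bx^2/sy^2 (the inverse variance of each
    ratio, first order). The bootstrap resamples (bx, by) from
    Normal(bx, sx) and Normal(by, sy) and recomputes the weighted median.
    """
    if inp.m < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 variants, got {inp.m}")
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    ratios = inp.by / inp.bx
    weights = inp.bx**2 / inp.sy**2
    est = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(inp.bx, inp.sx, size=(n_boot, inp.m))
    by_b = rng.normal(inp.by, inp.sy, size=(n_boot, inp.m))
    ratios_b = by_b / bx_b
    weights_b = bx_b**2 / inp.sy[None, :] ** 2

    order = np.argsort(ratios_b, axis=1)
    r_sorted = np.take_along_axis(ratios_b, order, axis=1)
    w_sorted = np.take_along_axis(weights_b, order, axis=1)
    w_sorted = w_sorted / w_sorted.sum(axis=1, keepdims=True)
    s = np.cumsum(w_sorted, axis=1)
    perc = s - w_sorted / 2
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = np.interp(0.5, perc[i], r_sorted[i])
    se = float(boots.std(ddof=1))
    if se == 0:
        se = np.finfo(float).tiny ** 0.5
    q, df, q_p = cochran_q(inp, est)
    return MRResult("weighted_median", est, se, _normal_p(est / se), inp.m,
                    Q=q, Q_df=df, Q_p=q_p)


def all_estimators(inp: MRInput, n_boot: int = 1000, seed: int = 0) -> list[MRResult]:
    """Run every applicable estimator for one direction.

    A single instrument yields only the Wald ratio (reported as IVW, to
    which it is identical); Egger and the weighted median require >= 3.
    """
    results = [ivw(inp)]
    if inp.m >= 3:
        results.append(egger(inp))
        results.append(weighted_median(inp, n_boot=n_boot, seed=seed))
    return results


@dataclass
class BidirectionalResult:
    forward: list[MRResult] = field(default_factory=list)
    reverse: list[MRResult] = field(default_factory=list)
    forward_drops: list[tuple[str, str]] = field(default_factory=list)
    reverse_drops: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def bidirectional_mr(
    exposure_sumstats: Sequence[SumstatRecord],
    outcome_sumstats: Sequence[SumstatRecord],
    instruments_fwd: Sequence[str],
    instruments_rev: Sequence[str],
    palindrome_maf_cutoff: float = 0.42,
    n_boot: int = 1000,
    seed: int = 0,
) -> BidirectionalResult:
    """Run all estimators in both causal directions.

    ``instruments_fwd`` are variant ids selected in the exposure study (for
    exposure -> outcome); ``instruments_rev`` in the outcome study (for
    outcome -> exposure). Directions with no harmonizable instruments are
    skipped with a warning rather than raising.
    """
    res = BidirectionalResult()
    exp_ids = set(instruments_fwd)
    rev_ids = set(instruments_rev)

    fwd_exp = [r for r in exposure_sumstats if r.variant_id in exp_ids]
    pairs, drops = harmonize_pair(fwd_exp, list(outcome_sumstats), palindrome_maf_cutoff)
    res.forward_drops = drops
    if pairs:
        res.forward = all_estimators(MRInput.from_pairs(pairs), n_boot=n_boot, seed=seed)
    else:
        res.warnings.append("forward direction skipped: no harmonizable instruments")

    rev_exp = [r for r in outcome_sumstats if r.variant_id in rev_ids]
    pairs_r, drops_r = harmonize_pair(rev_exp, list(exposure_sumstats), palindrome_maf_cutoff)
    res.reverse_drops = drops_r
    if pairs_r:
        res.reverse = all_estimators(MRInput.from_pairs(pairs_r), n_boot=n_boot, seed=seed + 1)
    else:
        res.warnings.append("reverse direction skipped: no harmonizable instruments")
    return res


def mr_report(result: BidirectionalResult) -> pd.DataFrame:
    rows = []
    for direction, results in (("forward", result.forward), ("reverse", result.reverse)):
        for r in results:
            rows.append({
                "direction": direction, "method": r.method, "n_variants": r.n_variants,
                "estimate": r.estimate, "se": r.se, "p": r.p,
                "intercept": r.egger_intercept, "intercept_p": r.intercept_p,
                "Q": r.Q, "Q_df": r.Q_df, "Q_p": r.Q_p,
            })
    return pd.DataFrame(rows, columns=["direction", "method", "n_variants", "estimate",
                                       "se", "p", "intercept", "intercept_p",
                                       "Q", "Q_df", "Q_p"])
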