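"""Genotype–phenotype association engine.

Implements the regression machinery for phenome scans from first principles:
maximum-likelihood logistic regression via iteratively reweighted least
squares (IRLS) with Wald tests, ordinary least squares with classical
standard errors, additive and recessive genotype encodings, and weighted
polygenic scores.

The IRLS fit flags (rather than raises on) quasi-separation so that a scan
across hundreds of phenotypes can continue past degenerate ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DesignError, MissingVariantError
from .instruments import GenotypeMatrix
from .phenome import CASE, CONTROL, PhenomeCohort
from .sumstats import SumstatRecord

MAX_IRLS_ITER = 25
SCORE_TOL = 1e-8
SEPARATION_BETA = 15.0
RECESSIVE_CUT = 1.5


@dataclass(frozen=True)
class GeneticEncoding:
    """How a dosage vector enters the regression.

    ``additive`` uses the dosage as-is (0..2 copies of the effect allele);
    ``recessive`` codes 1 only for effect-allele homozygotes, with imputed
    dosages hard-called at ``recessive_cut`` (round-to-nearest).
    """

    model: str = "additive"
    effect_allele: str = ""
    recessive_cut: float = RECESSIVE_CUT

    def __post_init__(self):
        if self.model not in ("additive", "recessive"):
            raise ConfigError(f"unknown genetic model {self.model!r}")


def encode_genotype(dosages: np.ndarray, enc: GeneticEncoding) -> np.ndarray:
    """Encode effect-allele dosages under the additive or recessive model."""
    d = np.asarray(dosages, dtype=float)
    if enc.model == "additive":
        return d.copy()
    out = np.where(np.isfinite(d), (d >= enc.recessive_cut).astype(float), np.nan)
    return out


@dataclass
class FitResult:
    """Coefficients, classical SEs and Wald/t p-values for one regression."""

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    converged: bool = True
    separation: bool = False
    n: int = 0
    n_iter: int = 0

    def coef(self, j: int = -1) -> tuple[float, float, float]:
        return float(self.beta[j]), float(self.se[j]), float(self.p[j])


def _check_design(X: np.ndarray, names: Optional[Sequence[str]]) -> None:
    n, k = X.shape
    if n <= k:
        raise DesignError(f"need more observations ({n}) than columns ({k})")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name the offending columns via small R-diagonal entries of a QR
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [i for i, d in enumerate(diag) if d < tol]
        labels = ([names[i] for i in bad] if names is not None else bad)
        raise DesignError(f"rank-deficient design (rank {rank} < {k} columns): "
                          f"collinear columns {labels}", columns=labels)


def linear_fit(y: np.ndarray, X: np.ndarray, names: Optional[Sequence[str]] = None) -> FitResult:
    """Ordinary least squares with classical (homoskedastic) SEs and t tests."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_design(X, names)
    n, k = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - k
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2 * stats.t.sf(np.abs(t), dof)
    p = np.where(se > 0, p, 0.0)
    return FitResult(beta=beta, se=se, p=np.clip(p, np.nextafter(0, 1), 1.0), n=n)


def logistic_fit(y: np.ndarray, X: np.ndarray, names: Optional[Sequence[str]] = None) -> FitResult:
    """Maximum-likelihood logistic regression by IRLS with Wald z tests.

    Converges when the maximum absolute score (gradient of the
    log-likelihood) drops below 1e-8, up to 25 iterations. Quasi-separation
    is flagged when any |coefficient| exceeds 15 or the fit fails to
    converge; flagged fits still return estimates.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ConfigError("logistic outcome must be binary 0/1")
    _check_design(X, names)
    n, k = X.shape

    beta = np.zeros(k)
    converged = False
    it = 0
    if y.min() == y.max():
        # constant outcome: no information; flag as degenerate separation
        se = np.full(k, np.inf)
        return FitResult(beta=beta, se=se, p=np.ones(k), converged=False,
                         separation=True, n=n, n_iter=0)

    for it in range(1, MAX_IRLS_ITER + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        XtWX = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step

    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    XtWX = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(XtWX)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k, np.inf)

    separation = (not converged) or bool(np.any(np.abs(beta) > SEPARATION_BETA))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    return FitResult(beta=beta, se=se, p=np.clip(p, np.nextafter(0, 1), 1.0),
                     converged=converged, separation=separation, n=n, n_iter=it)


@dataclass
class PrsResult:
    raw: np.ndarray
    standardized: np.ndarray
    zero_variance: bool = False


def compute_prs(
    G: GenotypeMatrix,
    weights: Sequence[tuple[str, str, float]],
) -> PrsResult:
    """Weighted allele-dosage score: sum of dosage x per-allele effect.

    ``weights`` rows are (variant_id, effect_allele, beta). If a weight's
    effect allele is the matrix's ref allele the dosage is flipped (2 - d) so
    the score always counts effect alleles. Missing dosages are mean-imputed
    within the cohort. Both the raw score and its cohort-standardized
    version ((s - mean)/SD) are returned; zero score variance is flagged and
    the standardized score set to zeros.
    """
    s = np.zeros(G.n_persons)
    meta = G.variants.set_index("variant_id")
    for variant_id, effect_allele, beta in weights:
        if variant_id not in meta.index:
            raise MissingVariantError(f"PRS weight variant {variant_id!r} not in genotypes")
        row = meta.loc[variant_id]
        d = G.dosage_vector(variant_id).astype(float)
        mean_d = np.nanmean(d)
        d = np.where(np.isfinite(d), d, mean_d)
        if effect_allele == row["alt"]:
            pass
        elif effect_allele == row["ref"]:
            d = 2.0 - d
        else:
            raise MissingVariantError(
                f"{variant_id}: effect allele {effect_allele!r} matches neither "
                f"ref {row['ref']!r} nor alt {row['alt']!r}")
        s = s + beta * d
    sd = s.std()
    if sd == 0:
        return PrsResult(raw=s, standardized=np.zeros_like(s), zero_variance=True)
    return PrsResult(raw=s, standardized=(s - s.mean()) / sd)


@dataclass
class ScanResult:
    """One phenotype x one predictor association row."""

    phenotype: str
    predictor: str
    beta: float
    se: float
    p: float
    n_cases: int
    n_controls: int
    converged: bool = True
    failed: bool = False
    label: str = ""
    model: str = "additive"
    q: float = float("nan")

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


def scan_to_frame(results: Sequence[ScanResult]) -> pd.DataFrame:
    rows = [{
        "phenotype": r.phenotype, "label": r.label, "predictor": r.predictor,
        "model": r.model, "beta": r.beta, "se": r.se, "OR": r.odds_ratio,
        "p": r.p, "q": r.q, "n_cases": r.n_cases, "n_controls": r.n_controls,
        "converged": r.converged, "failed": r.failed,
    } for r in results]
    return pd.DataFrame(rows)


def phewas_scan(
    cohort: PhenomeCohort,
    predictor: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    predictor_name: str = "SNP",
    model: str = "additive",
) -> list[ScanResult]:
    """Logistic scan of one predictor across every retained phecode.

    ``predictor`` and ``covariates`` are aligned to ``cohort.persons``.
    Excluded persons are dropped per phenotype; each retained phenotype gets
    one logistic fit of case status on intercept + predictor + covariates.
    Phenotypes whose fit degenerates (constant predictor, separation,
    design failure) yield a flagged row and the scan continues.
    """
    predictor = np.asarray(predictor, dtype=float)
    n = len(cohort.persons)
    if predictor.shape[0] != n:
        raise ConfigError("predictor not aligned to cohort persons")
    if covariates is None:
        covariates = np.empty((n, 0))
    covariates = np.asarray(covariates, dtype=float)

    labels = dict(zip(cohort.phecode_info["phecode"], cohort.phecode_info["label"])) \
        if not cohort.phecode_info.empty else {}
    results: list[ScanResult] = []
    for phecode in cohort.retained_phecodes:
        col = cohort.status[phecode].to_numpy()
        keep = (col == CASE) | (col == CONTROL)
        y = (col[keep] == CASE).astype(float)
        x = predictor[keep]
        Z = covariates[keep]
        n_cases = int(y.sum())
        n_controls = int(len(y) - y.sum())

        finite = np.isfinite(x)
        y, x, Z = y[finite], x[finite], Z[finite]

        if len(np.unique(x)) < 2 or y.min() == y.max():
            results.append(ScanResult(phecode, predictor_name, 0.0, float("inf"), 1.0,
                                      n_cases, n_controls, converged=False, failed=True,
                                      label=labels.get(phecode, ""), model=model))
            continue
        X = np.column_stack([np.ones(len(y)), x, Z])
        try:
            fit = logistic_fit(y, X)
        except DesignError:
            results.append(ScanResult(phecode, predictor_name, 0.0, float("inf"), 1.0,
                                      n_cases, n_controls, converged=False, failed=True,
                                      label=labels.get(phecode, ""), model=model))
            continue
        b, se, p = fit.beta[1], fit.se[1], fit.p[1]
        results.append(ScanResult(phecode, predictor_name, float(b), float(se), float(p),
                                  n_cases, n_controls,
                                  converged=fit.converged and not fit.separation,
                                  failed=fit.separation,
                                  label=labels.get(phecode, ""), model=model))
    return results


def align_weights(records: Sequence[SumstatRecord]) -> list[tuple[str, str, float]]:
    """Turn sumstat records into PRS weight triples (id, effect allele, beta)."""
    return [(r.variant_id, r.effect_allele, r.beta) for r in records]


def volcano_plot(results: Sequence[ScanResult], path, q_threshold: float = 0.05) -> None:
    """OR vs -log10(p) volcano of a scan; significant points highlighted."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = scan_to_frame(results)
    df = df[~df["failed"]]
    fig, ax = plt.subplots(figsize=(7, 5))
    sig = df["q"] < q_threshold
    ax.scatter(df.loc[~sig, "OR"], -np.log10(df.loc[~sig, "p"]), s=12, c="grey", label="n.s.")
    ax.scatter(df.loc[sig, "OR"], -np.log10(df.loc[sig, "p"]), s=16, c="green",
               label=f"q < {q_threshold}")
    ax.axvline(1.0, ls="--", lw=0.6, c="k")
    ax.set_xlabel("odds ratio")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
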