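"""Synthetic data with the statistical structure the pipeline assumes.

Generates every input the analysis consumes, with known ground truth:

* LD-block genotypes at chosen allele frequencies (latent-Gaussian haplotype
  thresholding, AR(rho) correlation within blocks);
* a quantitative plasma metabolite with known per-allele effects, a shared
  confounder, and unit marginal variance;
* binary diseases under a configurable causal graph — metabolite -> disease
  effects, per-variant direct (horizontally pleiotropic) disease effects and
  confounding — together with ICD-9/ICD-10 event streams consistent with
  case status;
* two-sample exposure/outcome summary-statistic pairs with a known causal
  effect, for exercising the MR estimators.

The default configuration emulates a metabolite GWAS discovery of six
instrument SNPs in four-ish regions at realistic frequencies and
standardized effect sizes, a biobank-scale cohort, and an EHR phenome of a
dozen common diagnoses; all randomness flows from a single mandatory seed,
and identical configurations give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import ConfigError
from .instruments import GenotypeMatrix, VARIANT_COLUMNS
from .phenome import PhecodeMap
from .sumstats import SumstatRecord

# Default instrument set: six SNPs, frequencies and standardized per-allele
# metabolite effects on the scale typical of a ~8k-person metabolite GWAS.
DEFAULT_FREQS = (0.37, 0.02, 0.48, 0.43, 0.64, 0.21)
DEFAULT_EFFECTS = (-0.10, 0.32, 0.14, 0.11, 0.14, 0.21)

_DATE_WINDOW_DAYS = 3652  # ten years
_DATE_ORIGIN = np.datetime64("2010-01-01")


@dataclass
class SimConfig:
    """Parameters of the generative model. ``seed`` is mandatory.

    ``ld_blocks`` is a list of (block_size, within_block_rho); block sizes
    must sum to the number of variants. ``snp_disease_effects`` is an
    optional (n_variants x n_phecodes) matrix of direct per-allele log-odds
    effects (horizontal pleiotropy); ``causal_effect`` is the log-odds
    effect of the metabolite (per SD) on each disease, scalar or
    per-disease.
    """

    seed: int
    n_individuals: int = 10000
    allele_freqs: Sequence[float] = DEFAULT_FREQS
    ld_blocks: Optional[Sequence[tuple[int, float]]] = None
    metabolite_effects: Sequence[float] = DEFAULT_EFFECTS
    confounder_to_metabolite: float = 0.2
    confounder_to_disease: float = 0.2
    causal_effect: float | Sequence[float] = 0.0
    snp_disease_effects: Optional[np.ndarray] = None
    disease_base_rates: float | Sequence[float] = 0.08
    n_phecodes: int = 12
    icd_noise_rate: float = 1.0
    # two-sample summary-statistic generation
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_frac: float = 0.0
    n_sample_exposure: int = 5000
    n_sample_outcome: int = 5000

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        self.allele_freqs = tuple(float(f) for f in self.allele_freqs)
        self.metabolite_effects = tuple(float(g) for g in self.metabolite_effects)
        if any(not (0.01 < f < 0.99) for f in self.allele_freqs):
            raise ConfigError("allele frequencies must lie in (0.01, 0.99)")
        m = len(self.allele_freqs)
        if len(self.metabolite_effects) != m:
            raise ConfigError("metabolite_effects must match allele_freqs in length")
        if self.ld_blocks is None:
            self.ld_blocks = [(1, 0.0)] * m
        self.ld_blocks = [(int(s), float(r)) for s, r in self.ld_blocks]
        if sum(s for s, _ in self.ld_blocks) != m:
            raise ConfigError("ld_blocks sizes must sum to the number of variants")
        if any(not (0 <= r < 1) for _, r in self.ld_blocks):
            raise ConfigError("LD correlations must lie in [0, 1)")
        rates = (np.full(self.n_phecodes, float(self.disease_base_rates))
                 if np.isscalar(self.disease_base_rates)
                 else np.asarray(self.disease_base_rates, dtype=float))
        if len(rates) != self.n_phecodes:
            raise ConfigError("disease_base_rates must match n_phecodes")
        if np.any((rates <= 0) | (rates >= 1)):
            raise ConfigError("disease base rates must lie in (0, 1)")
        self.disease_base_rates = rates
        self.causal_effect = (np.full(self.n_phecodes, float(self.causal_effect))
                              if np.isscalar(self.causal_effect)
                              else np.asarray(self.causal_effect, dtype=float))
        if len(self.causal_effect) != self.n_phecodes:
            raise ConfigError("causal_effect must be scalar or one per phecode")
        if self.snp_disease_effects is not None:
            self.snp_disease_effects = np.asarray(self.snp_disease_effects, dtype=float)
            if self.snp_disease_effects.shape != (m, self.n_phecodes):
                raise ConfigError("snp_disease_effects must be (n_variants x n_phecodes)")
        if not (0 <= self.pleiotropy_frac <= 1):
            raise ConfigError("pleiotropy_frac must lie in [0, 1]")
        if self.icd_noise_rate < 0:
            raise ConfigError("icd_noise_rate must be >= 0")

    @property
    def n_variants(self) -> int:
        return len(self.allele_freqs)

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic per-stage generator derived from the single seed."""
        return np.random.default_rng([int(self.seed), int(stage)])


def variant_table(cfg: SimConfig) -> pd.DataFrame:
    """Variant metadata: blocks laid out contiguously on one chromosome,
    10 kb apart within a block and 1.5 Mb between blocks (so distinct blocks
    fall outside a 1000-kb clumping window)."""
    rows = []
    pos = 1_000_000
    j = 0
    for b, (size, _) in enumerate(cfg.ld_blocks):
        for k in range(size):
            rows.append({"variant_id": f"var{j:04d}", "chrom": "1", "pos": pos,
                         "ref": "A", "alt": "G"})
            pos += 10_000
            j += 1
        pos += 1_500_000
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Diploid dosages by thresholded latent-Gaussian haplotypes.

    Each haplotype's latent vector is multivariate normal with AR(rho)
    correlation inside each LD block; an allele is carried when the latent
    value falls below the frequency quantile, so marginal allele frequencies
    are exact in expectation and within-block dosages are positively
    correlated (monotonically in rho).
    """
    rng = cfg.rng(1)
    n, m = cfg.n_individuals, cfg.n_variants
    freqs = np.asarray(cfg.allele_freqs)
    thresholds = stats.norm.ppf(freqs)

    haplotypes = np.empty((2 * n, m))
    j = 0
    for size, rho in cfg.ld_blocks:
        if size == 1 or rho == 0.0:
            z = rng.standard_normal((2 * n, size))
        else:
            corr = rho ** np.abs(np.subtract.outer(np.arange(size), np.arange(size)))
            chol = np.linalg.cholesky(corr)
            z = rng.standard_normal((2 * n, size)) @ chol.T
        haplotypes[:, j:j + size] = z
        j += size
    alleles = (haplotypes < thresholds[None, :]).astype(float)
    dosages = alleles[0::2] + alleles[1::2]
    person_ids = [f"P{i:06d}" for i in range(n)]
    return GenotypeMatrix(person_ids=person_ids, variants=variant_table(cfg), dosages=dosages)


def simulate_metabolite(G: GenotypeMatrix, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Quantitative metabolite with unit marginal variance.

    y_i = sum_j gamma_j g_ij + delta * C_i + eps_i, with C standard normal
    and the residual SD chosen so the realized systematic variance plus the
    residual variance equals one. Returns (y, C).
    """
    rng = cfg.rng(2)
    gamma = np.asarray(cfg.metabolite_effects)
    if len(gamma) != G.n_variants:
        raise ConfigError("metabolite_effects must match the genotype matrix")
    C = rng.standard_normal(G.n_persons)
    systematic = G.dosages @ gamma + cfg.confounder_to_metabolite * C
    var_sys = float(systematic.var())
    if var_sys >= 1.0:
        raise ConfigError(
            f"systematic variance {var_sys:.3f} >= 1; shrink effects to keep unit variance")
    eps_sd = np.sqrt(1.0 - var_sys)
    y = systematic - systematic.mean() + eps_sd * rng.standard_normal(G.n_persons)
    return y, C


def toy_phecode_map(n_phecodes: int = 12, include_sex_restricted: bool = False) -> PhecodeMap:
    """A small synthetic phecode map for simulated phenomes.

    Phecode d has value 100 + 10*d, one ICD-9-CM and one ICD-10 source code
    and a +/-2 exclusion range (ranges of adjacent phecodes never overlap).
    Optionally appends one sex-restricted phecode to exercise that filter.
    """
    rows = []
    for d in range(n_phecodes):
        val = 100.0 + 10 * d
        for icd, vocab in ((f"D{d:02d}.9", "ICD9CM"), (f"D{d:02d}.X", "ICD10")):
            rows.append({"icd": icd, "vocab": vocab, "phecode": f"{val:.1f}",
                         "label": f"disease_{d:02d}", "exclusion_min": val - 2,
                         "exclusion_max": val + 2, "sex": "none"})
    if include_sex_restricted:
        val = 100.0 + 10 * n_phecodes
        rows.append({"icd": "SX0.9", "vocab": "ICD9CM", "phecode": f"{val:.1f}",
                     "label": "sex_restricted", "exclusion_min": val - 2,
                     "exclusion_max": val + 2, "sex": "female"})
    return PhecodeMap(pd.DataFrame(rows))


def simulate_demographics(cfg: SimConfig) -> pd.DataFrame:
    """Per-person sex, age, birth decade and 5 principal components."""
    rng = cfg.rng(5)
    n = cfg.n_individuals
    df = pd.DataFrame({
        "person_id": [f"P{i:06d}" for i in range(n)],
        "sex": rng.choice(["male", "female"], size=n),
        "age": rng.integers(30, 80, size=n),
    })
    df["birth_decade"] = (2020 - df["age"]) // 10 * 10
    for k in range(1, 6):
        df[f"pc{k}"] = rng.standard_normal(n)
    return df.set_index("person_id")


def _solve_intercept(eta: np.ndarray, rate: float) -> float:
    def gap(a):
        return special.expit(a + eta).mean() - rate
    return float(optimize.brentq(gap, -30, 30))


def simulate_diseases_and_icd(
    G: GenotypeMatrix,
    y: np.ndarray,
    C: np.ndarray,
    cfg: SimConfig,
    pmap: Optional[PhecodeMap] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary diseases under the configured causal graph, plus ICD events.

    Per disease d: logit P(D=1) = alpha_d + theta_d * y + sum_j pi_jd g_ij
    + lambda_d * C, with alpha_d solved so the marginal prevalence matches
    the configured base rate. Every case emits two events of the disease's
    mapped ICD codes on distinct dates within a ten-year window (one ICD-9,
    one ICD-10); every person additionally emits Poisson(icd_noise_rate)
    unrelated (unmapped) noise codes, so true controls never carry
    exclusion-range codes.

    Returns (disease status DataFrame person x phecode, ICD event DataFrame).
    """
    rng = cfg.rng(3)
    pmap = pmap or toy_phecode_map(cfg.n_phecodes)
    phe_info = pmap.phecodes().sort_values("phecode", key=lambda s: s.astype(float))
    scan_phecodes = [p for p, s in zip(phe_info["phecode"], phe_info["sex"]) if s == "none"]
    if len(scan_phecodes) < cfg.n_phecodes:
        raise ConfigError("phecode map has fewer unrestricted phecodes than n_phecodes")
    scan_phecodes = scan_phecodes[: cfg.n_phecodes]

    pi = (cfg.snp_disease_effects if cfg.snp_disease_effects is not None
          else np.zeros((G.n_variants, cfg.n_phecodes)))
    status = np.empty((G.n_persons, cfg.n_phecodes), dtype=int)
    for d in range(cfg.n_phecodes):
        eta = (cfg.causal_effect[d] * y + G.dosages @ pi[:, d]
               + cfg.confounder_to_disease * C)
        alpha = _solve_intercept(eta, cfg.disease_base_rates[d])
        prob = special.expit(alpha + eta)
        status[:, d] = rng.random(G.n_persons) < prob

    disease = pd.DataFrame(status, index=G.person_ids, columns=scan_phecodes)

    code_lookup = pmap.lookup()
    events = []
    person_arr = np.asarray(G.person_ids)
    for d, phecode in enumerate(scan_phecodes):
        codes = code_lookup[code_lookup["phecode"] == phecode]
        code9 = codes[codes["vocab"] == "ICD9CM"]["icd"].iloc[0]
        code10 = codes[codes["vocab"] == "ICD10"]["icd"].iloc[0]
        cases = person_arr[status[:, d] == 1]
        k = len(cases)
        if k == 0:
            continue
        d1 = rng.integers(0, _DATE_WINDOW_DAYS, size=k)
        d2 = (d1 + 1 + rng.integers(0, _DATE_WINDOW_DAYS - 1, size=k)) % _DATE_WINDOW_DAYS
        events.append(pd.DataFrame({
            "person_id": cases, "date": _DATE_ORIGIN + d1.astype("timedelta64[D]"),
            "code": code9, "vocabulary": "ICD9CM"}))
        events.append(pd.DataFrame({
            "person_id": cases, "date": _DATE_ORIGIN + d2.astype("timedelta64[D]"),
            "code": code10, "vocabulary": "ICD10"}))

    if cfg.icd_noise_rate > 0:
        n_noise = rng.poisson(cfg.icd_noise_rate, size=G.n_persons)
        total = int(n_noise.sum())
        if total:
            persons = np.repeat(person_arr, n_noise)
            days = rng.integers(0, _DATE_WINDOW_DAYS, size=total)
            events.append(pd.DataFrame({
                "person_id": persons,
                "date": _DATE_ORIGIN + days.astype("timedelta64[D]"),
                "code": "Z99.9", "vocabulary": "ICD10"}))

    event_df = (pd.concat(events, ignore_index=True) if events
                else pd.DataFrame(columns=["person_id", "date", "code", "vocabulary"]))
    event_df["date"] = event_df["date"].astype(str)
    event_df = event_df.sort_values(["person_id", "date", "code"]).reset_index(drop=True)
    return disease, event_df


def _marginal_sumstats(dosages: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant simple-regression slopes, classical SEs and p-values.

    SEs come from each regression's own residuals (not an asymptotic
    approximation), vectorized across variants.
    """
    n, m = dosages.shape
    gc = dosages - dosages.mean(axis=0)
    yc = y - y.mean()
    ssg = (gc**2).sum(axis=0)
    beta = gc.T @ yc / ssg
    rss = (yc**2).sum() - beta**2 * ssg
    se = np.sqrt(rss / (n - 2) / ssg)
    t = beta / se
    p = np.clip(2 * stats.t.sf(np.abs(t), n - 2), np.nextafter(0, 1), 1.0)
    return beta, se, p


@dataclass
class TwoSampleSumstats:
    exposure: list[SumstatRecord]
    outcome: list[SumstatRecord]
    theta: float
    pleiotropy: np.ndarray = field(default_factory=lambda: np.empty(0))
    invalid_mask: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    exposure_instrument_ids: list[str] = field(default_factory=list)
    outcome_instrument_ids: list[str] = field(default_factory=list)


def simulate_two_sample_sumstats(
    cfg: SimConfig,
    theta: float = 0.2,
    outcome_own_effects: Optional[Sequence[float]] = None,
    outcome_own_freqs: Optional[Sequence[float]] = None,
) -> TwoSampleSumstats:
    """Exposure and outcome summary statistics from two disjoint samples.

    Sample 1 (size ``n_sample_exposure``) yields per-variant exposure betas.
    Sample 2 (``n_sample_outcome``) regenerates the exposure latently and an
    outcome Y = theta * X + sum_j pi_j g_j + lambda * U + noise, where a
    configured fraction of variants carry direct (horizontally pleiotropic)
    outcome effects drawn from Normal(pleiotropy_mean, pleiotropy_sd) and U
    is a confounder shared by exposure and outcome within each sample.
    Variants are independent (instruments are post-clumping by construction).

    ``outcome_own_effects`` optionally appends variants that act on the
    outcome only (the outcome's own genetic instruments, for reverse-MR
    scenarios); both tables then cover all variants, and the ids of each
    trait's true instruments are reported.
    """
    rng = cfg.rng(4)
    m = cfg.n_variants
    freqs = np.asarray(cfg.allele_freqs)
    gamma = np.asarray(cfg.metabolite_effects)
    own = np.asarray(outcome_own_effects, dtype=float) if outcome_own_effects is not None \
        else np.empty(0)
    m_own = len(own)
    own_freqs = (np.asarray(outcome_own_freqs, dtype=float) if outcome_own_freqs is not None
                 else np.full(m_own, 0.3))
    if len(own_freqs) != m_own:
        raise ConfigError("outcome_own_freqs must match outcome_own_effects")
    all_freqs = np.concatenate([freqs, own_freqs])

    n_invalid = int(round(cfg.pleiotropy_frac * m))
    invalid = np.zeros(m, dtype=bool)
    invalid[rng.choice(m, size=n_invalid, replace=False)] = True
    pi = np.zeros(m)
    pi[invalid] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n_invalid)

    delta = cfg.confounder_to_metabolite
    lam = cfg.confounder_to_disease

    def draw_sample(n):
        g = rng.binomial(2, all_freqs, size=(n, m + m_own)).astype(float)
        u = rng.standard_normal(n)
        sys = g[:, :m] @ gamma + delta * u
        var_sys = float(sys.var())
        if var_sys >= 1.0:
            raise ConfigError("instrument effects too large for unit exposure variance")
        x = sys + np.sqrt(1 - var_sys) * rng.standard_normal(n)
        return g, x, u

    g1, x1, _ = draw_sample(cfg.n_sample_exposure)
    bx, sx, px = _marginal_sumstats(g1, x1)

    g2, x2, u2 = draw_sample(cfg.n_sample_outcome)
    y_out = (theta * x2 + g2[:, :m] @ pi + g2[:, m:] @ own + lam * u2
             + rng.standard_normal(cfg.n_sample_outcome))
    by, sy, py = _marginal_sumstats(g2, y_out)

    meta = variant_table(cfg)
    ids = list(meta["variant_id"]) + [f"ovar{j:04d}" for j in range(m_own)]
    chroms = list(meta["chrom"]) + ["2"] * m_own
    positions = list(meta["pos"]) + [1_000_000 + 1_500_000 * j for j in range(m_own)]

    def records(beta, se, p, n):
        return [
            SumstatRecord(
                variant_id=ids[j], chrom=chroms[j], pos=int(positions[j]),
                ref_allele="A", alt_allele="G", effect_allele="G",
                eaf=float(all_freqs[j]), beta=float(beta[j]),
                se=float(se[j]), p=float(p[j]), n=float(n))
            for j in range(m + m_own)
        ]

    return TwoSampleSumstats(
        exposure=records(bx, sx, px, cfg.n_sample_exposure),
        outcome=records(by, sy, py, cfg.n_sample_outcome),
        theta=float(theta), pleiotropy=pi, invalid_mask=invalid,
        exposure_instrument_ids=ids[:m], outcome_instrument_ids=ids[m:])
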