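"""Cross-cohort synthesis: meta-analysis and false-discovery-rate control.

Two meta-analysis schemes are provided. The default combines per-study z
statistics weighted by the square root of the sample size (the scheme used
by METAL under default settings); the alternative is a fixed-effect
inverse-variance weighting of the effect sizes themselves. Multiple testing
across a phenome scan is controlled with the Benjamini–Hochberg step-up
procedure; associations with q < 0.05 are conventionally called significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclass
class MetaInput:
    """Per-study effect estimates for one phenotype."""

    betas: np.ndarray
    ses: np.ndarray
    ns: np.ndarray

    def __post_init__(self):
        self.betas = np.atleast_1d(np.asarray(self.betas, dtype=float))
        self.ses = np.atleast_1d(np.asarray(self.ses, dtype=float))
        self.ns = np.atleast_1d(np.asarray(self.ns, dtype=float))
        if not (len(self.betas) == len(self.ses) == len(self.ns)):
            raise ValidationError("betas, ses, ns must have equal length")
        if len(self.betas) < 1:
            raise ValidationError("need at least one study")
        if np.any(self.ses <= 0):
            raise ValidationError("all ses must be positive")
        if np.any(self.ns <= 0):
            raise ValidationError("all ns must be positive")


@dataclass
class MetaResult:
    z: float
    p: float
    directions: str
    beta: float = float("nan")
    se: float = float("nan")
    scheme: str = "sample_size"


def _directions(betas: np.ndarray) -> str:
    return "".join("+" if b > 0 else "-" if b < 0 else "0" for b in betas)


def meta_sample_weighted(inp: MetaInput) -> MetaResult:
    """Sample-size-weighted z-score combination:
    z_meta = sum(z_i * sqrt(n_i)) / sqrt(sum n_i)."""
    z = inp.betas / inp.ses
    z_meta = float(np.sum(z * np.sqrt(inp.ns)) / np.sqrt(np.sum(inp.ns)))
    p = float(np.clip(2 * stats.norm.sf(abs(z_meta)), np.nextafter(0, 1), 1.0))
    return MetaResult(z=z_meta, p=p, directions=_directions(inp.betas))


def meta_ivw(inp: MetaInput) -> MetaResult:
    """Fixed-effect inverse-variance-weighted effect-size combination."""
    w = 1.0 / inp.ses**2
    beta = float(np.sum(w * inp.betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = float(np.clip(2 * stats.norm.sf(abs(z)), np.nextafter(0, 1), 1.0))
    return MetaResult(z=float(z), p=p, directions=_directions(inp.betas),
                      beta=beta, se=se, scheme="ivw")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} (m * p_(j) / j) over the sorted p-values, mapped
    back to the input order. Ties are handled by a stable sort on input
    index. All q lie in (0, 1].
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def annotate_fdr(scan: pd.DataFrame, p_column: str = "p", q_column: str = "q") -> pd.DataFrame:
    """Attach BH q-values to a scan table, skipping failed rows.

    The FDR family is the set of non-failed rows of the one table passed in
    (one predictor against one phenome); combine tables first to use a wider
    family.
    """
    out = scan.copy()
    ok = ~out.get("failed", pd.Series(False, index=out.index)).astype(bool)
    out[q_column] = np.nan
    if ok.any():
        out.loc[ok, q_column] = bh_fdr(out.loc[ok, p_column].to_numpy())
    return out


def meta_report(
    phenotypes: Sequence[str],
    per_study: Sequence[MetaInput],
    scheme: str = "sample_size",
) -> pd.DataFrame:
    """Meta-analyze many phenotypes and attach BH q-values."""
    rows = []
    for phe, inp in zip(phenotypes, per_study):
        res = meta_sample_weighted(inp) if scheme == "sample_size" else meta_ivw(inp)
        rows.append({"phenotype": phe, "z_meta": res.z, "beta_meta": res.beta,
                     "se_meta": res.se, "p": res.p, "directions": res.directions})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = bh_fdr(df["p"].to_numpy())
    return df
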