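"""Instrument selection: LD computation, significance filtering, greedy
clumping, and cohort-level QC (imputation-quality and relatedness filters).

The clumping rule mirrors the standard GWAS practice of retaining an
"independent" set of index variants: repeatedly take the most significant
remaining variant, absorb everything on the same chromosome within a window
and above an r-squared threshold, and continue until nothing is left.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, MissingVariantError, MonomorphicVariantError
from .sumstats import SumstatRecord

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Person x variant dosage matrix in [0, 2] with variant metadata.

    ``dosages`` is a float array of shape (n_persons, n_variants); missing
    values are NaN. ``variants`` is a DataFrame with columns
    ``variant_id, chrom, pos, ref, alt``.
    """

    person_ids: list
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.person_ids), len(self.variants)):
            raise ConfigError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.person_ids)} persons x {len(self.variants)} variants"
            )
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ConfigError("dosages must lie in [0, 2]")

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def index_of(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise MissingVariantError(f"variant {variant_id!r} not in genotype matrix")
        return int(idx[0])

    def dosage_vector(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.index_of(variant_id)]

    @classmethod
    def from_dosage_tsv(cls, path) -> "GenotypeMatrix":
        """Read a dosage TSV: variant metadata columns then one column per person."""
        df = pd.read_csv(path, sep="\t")
        meta = df[VARIANT_COLUMNS].copy()
        person_cols = [c for c in df.columns if c not in VARIANT_COLUMNS]
        dosages = df[person_cols].to_numpy(dtype=float).T
        return cls(person_ids=list(person_cols), variants=meta.reset_index(drop=True), dosages=dosages)

    def to_dosage_tsv(self, path) -> None:
        dos = pd.DataFrame(self.dosages.T, columns=[str(p) for p in self.person_ids])
        pd.concat([self.variants.reset_index(drop=True), dos], axis=1).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read dosages from a VCF, preferring the DS FORMAT field, else GT."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        person_ids = list(vcf.samples)
        meta_rows, dosage_cols = [], []
        for var in vcf:
            alt = var.ALT[0] if var.ALT else "."
            meta_rows.append({
                "variant_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM), "pos": int(var.POS),
                "ref": var.REF, "alt": alt,
            })
            try:
                ds = np.asarray(var.format("DS"), dtype=float).ravel()
            except (KeyError, TypeError, ValueError):
                # gt_types codes: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
                gt = np.asarray(var.gt_types, dtype=float)
                ds = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
            dosage_cols.append(ds)
        dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(person_ids), 0))
        return cls(person_ids=person_ids, variants=pd.DataFrame(meta_rows, columns=VARIANT_COLUMNS),
                   dosages=dosages)


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Uses pairwise-complete observations; raises
    :class:`MonomorphicVariantError` if either vector has zero variance (or
    fewer than two complete pairs).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ConfigError("dosage vectors must have equal length")
    mask = np.isfinite(g1) & np.isfinite(g2)
    if mask.sum() < 2:
        raise MonomorphicVariantError("fewer than 2 complete dosage pairs")
    a, b = g1[mask], g2[mask]
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        raise MonomorphicVariantError("monomorphic variant: zero dosage variance")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def significance_filter(records: Sequence[SumstatRecord], threshold: float) -> list[SumstatRecord]:
    """Retain records with p strictly below ``threshold``; order preserved."""
    if not (0 < threshold < 1):
        raise ConfigError(f"significance threshold must be in (0,1), got {threshold}")
    return [r for r in records if r.p < threshold]


@dataclass
class ClumpResult:
    """Greedy clumping output: ordered index variants and member assignments.

    ``assignments`` maps every input variant_id either to its index variant's
    id or to the string ``"index"`` for the index variants themselves.
    """

    index_variants: list[str] = field(default_factory=list)
    assignments: dict[str, str] = field(default_factory=dict)

    def to_frame(self, ref: Optional[GenotypeMatrix] = None) -> pd.DataFrame:
        rows = []
        pos = {}
        if ref is not None:
            pos = dict(zip(ref.variants["variant_id"], ref.variants["pos"]))
        for member, index in self.assignments.items():
            idx = member if index == "index" else index
            row = {"index_variant": idx, "member_variant": member}
            if ref is not None and member in pos and idx in pos:
                row["distance_kb"] = abs(pos[member] - pos[idx]) / 1000.0
                try:
                    row["r2"] = 1.0 if member == idx else ld_r2(
                        ref.dosage_vector(member), ref.dosage_vector(idx))
                except MonomorphicVariantError:
                    row["r2"] = np.nan
            rows.append(row)
        return pd.DataFrame(rows)


def clump(
    records: Sequence[SumstatRecord],
    ref: GenotypeMatrix,
    r2_threshold: float = 0.05,
    window_kb: float = 1000.0,
) -> ClumpResult:
    """Greedy LD clumping of significance-filtered records.

    Repeatedly takes the remaining record with the smallest p-value as an
    index variant and assigns to it every remaining variant on the same
    chromosome within ``window_kb`` (center-to-center) whose r-squared with
    the index meets ``r2_threshold``. Ties in p are broken by (chrom, pos,
    variant_id) so the result does not depend on input row order.
    """
    if not (0 <= r2_threshold <= 1):
        raise ConfigError(f"r2_threshold must be in [0,1], got {r2_threshold}")
    if window_kb <= 0:
        raise ConfigError(f"window_kb must be positive, got {window_kb}")

    for rec in records:
        ref.index_of(rec.variant_id)  # raises MissingVariantError

    remaining = sorted(records, key=lambda r: (r.p, r.chrom, r.pos, r.variant_id))
    result = ClumpResult()
    while remaining:
        index = remaining.pop(0)
        result.index_variants.append(index.variant_id)
        result.assignments[index.variant_id] = "index"
        g_index = ref.dosage_vector(index.variant_id)
        kept = []
        for rec in remaining:
            same_chrom = rec.chrom == index.chrom
            within = abs(rec.pos - index.pos) <= window_kb * 1000
            if same_chrom and within and ld_r2(g_index, ref.dosage_vector(rec.variant_id)) >= r2_threshold:
                result.assignments[rec.variant_id] = index.variant_id
            else:
                kept.append(rec)
        remaining = kept
    return result


def qc_filter(
    records: Sequence[SumstatRecord], info_min: float = 0.3
) -> tuple[list[SumstatRecord], list[str]]:
    """Drop records whose imputation quality is strictly below ``info_min``.

    Records with missing info are kept; their ids are returned so callers can
    log them. Returns ``(kept_records, missing_info_ids)``.
    """
    if not (0 <= info_min <= 1):
        raise ConfigError(f"info_min must be in [0,1], got {info_min}")
    kept, missing = [], []
    for rec in records:
        if rec.info is None:
            missing.append(rec.variant_id)
            kept.append(rec)
        elif rec.info >= info_min:
            kept.append(rec)
    return kept, missing


def relatedness_prune(
    person_ids: Sequence,
    pihat: Mapping[tuple, float],
    threshold: float = 0.2,
    seed: int = 0,
) -> list:
    """Randomly exclude one member of each related pair (pi-hat > threshold).

    Iterates until no retained pair exceeds the threshold; the excluded
    member of each offending pair is chosen by a seeded draw, so the result
    is deterministic given the seed. Returns retained ids in input order.
    """
    if threshold < 0:
        raise ConfigError(f"pi-hat threshold must be >= 0, got {threshold}")
    rng = random.Random(seed)
    retained = list(person_ids)
    retained_set = set(retained)

    def sym(a, b):
        return max(pihat.get((a, b), 0.0), pihat.get((b, a), 0.0))

    while True:
        offending = [
            (a, b)
            for i, a in enumerate(retained)
            for b in retained[i + 1:]
            if sym(a, b) > threshold
        ]
        if not offending:
            break
        a, b = offending[0]
        drop = a if rng.random() < 0.5 else b
        retained_set.discard(drop)
        retained = [p for p in retained if p in retained_set]
    return retained
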