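"""GWAS summary-statistics records: reading, validation, allele flipping and
two-study harmonization.

A summary-statistic row describes one variant's association with one trait on
the additive per-allele scale. Effect sizes are always interpreted relative to
an explicit effect allele, which must be one of the variant's two alleles;
flipping the effect allele negates the effect and complements the allele
frequency but leaves the standard error and p-value untouched.

Harmonization between an exposure study and an outcome study aligns the
outcome rows to the exposure's effect alleles, accepting strand-complement
matches and resolving palindromic (A/T, C/G) variants by allele frequency
when the minor-allele frequency is informative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import AlleleMismatchError, ConfigError, ValidationError

#: canonical column order for the on-disk TSV representation
CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "ref_allele", "alt_allele",
    "effect_allele", "eaf", "beta", "se", "p", "n", "info",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SumstatRecord:
    """One variant's association with one trait.

    ``beta`` is the per-effect-allele effect (trait units or log-odds);
    ``eaf`` is the effect-allele frequency. ``n`` and ``info`` may be missing
    (``None``). Positions are 1-based.
    """

    variant_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    effect_allele: str
    beta: float
    se: float
    p: float
    eaf: Optional[float] = None
    n: Optional[float] = None
    info: Optional[float] = None

    def validate(self) -> None:
        if self.effect_allele not in (self.ref_allele, self.alt_allele):
            raise ValidationError(
                f"{self.variant_id}: effect allele {self.effect_allele!r} is "
                f"neither ref ({self.ref_allele!r}) nor alt ({self.alt_allele!r})"
            )
        if not self.se > 0:
            raise ValidationError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not (0 < self.p <= 1):
            raise ValidationError(f"{self.variant_id}: p must be in (0,1], got {self.p}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValidationError(f"{self.variant_id}: eaf must be in (0,1), got {self.eaf}")
        if self.info is not None and not (0 <= self.info <= 1):
            raise ValidationError(f"{self.variant_id}: info must be in [0,1], got {self.info}")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G SNVs, never for indels."""
        a, b = self.ref_allele.upper(), self.alt_allele.upper()
        if len(a) != 1 or len(b) != 1:
            return False
        return _COMPLEMENT.get(a) == b

    @property
    def other_allele(self) -> str:
        return self.alt_allele if self.effect_allele == self.ref_allele else self.ref_allele


def _maybe_float(value) -> Optional[float]:
    if value is None:
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(f) else f


DEFAULT_COLUMN_MAP = {
    "variant": "variant_id", "chrom": "chrom", "pos": "pos",
    "ref": "ref_allele", "alt": "alt_allele", "effect_allele": "effect_allele",
    "eaf": "eaf", "beta": "beta", "se": "se", "p": "p", "n": "n", "info": "info",
}

_REQUIRED = ["variant", "chrom", "pos", "ref", "alt", "effect_allele", "beta", "se", "p"]
_OPTIONAL = ["eaf", "n", "info"]


def read_sumstats(path, column_map: Optional[dict] = None) -> list[SumstatRecord]:
    """Read a delimited sumstats table into validated records.

    ``column_map`` maps logical field names (``variant``, ``chrom``, ``pos``,
    ``ref``, ``alt``, ``effect_allele``, ``eaf``, ``beta``, ``se``, ``p``,
    ``n``, ``info``) to the file's column headers. Delimiter (tab or comma)
    is sniffed from the header line. Row order is preserved.

    Raises :class:`ConfigError` if a required column is absent and
    :class:`ValidationError` listing every offending row if any row violates
    the record invariants.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)

    for field in _REQUIRED:
        if cmap[field] not in df.columns:
            raise ConfigError(f"required column {cmap[field]!r} (field {field!r}) not in {list(df.columns)}")

    records, bad = [], []
    for i, row in df.iterrows():
        rec = SumstatRecord(
            variant_id=str(row[cmap["variant"]]),
            chrom=str(row[cmap["chrom"]]),
            pos=int(row[cmap["pos"]]),
            ref_allele=str(row[cmap["ref"]]).upper(),
            alt_allele=str(row[cmap["alt"]]).upper(),
            effect_allele=str(row[cmap["effect_allele"]]).upper(),
            beta=float(row[cmap["beta"]]),
            se=float(row[cmap["se"]]),
            p=float(row[cmap["p"]]),
            eaf=_maybe_float(row[cmap["eaf"]]) if cmap["eaf"] in df.columns else None,
            n=_maybe_float(row[cmap["n"]]) if cmap["n"] in df.columns else None,
            info=_maybe_float(row[cmap["info"]]) if cmap["info"] in df.columns else None,
        )
        try:
            rec.validate()
        except ValidationError as exc:
            bad.append((i, str(exc)))
        else:
            records.append(rec)
    if bad:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad)
        raise ValidationError(f"{len(bad)} invalid row(s): {detail}", rows=bad)
    return records


def to_frame(records: Iterable[SumstatRecord]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in CANONICAL_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def write_sumstats(records: Iterable[SumstatRecord], path) -> None:
    """Write records as a canonical TSV (fixed column order)."""
    to_frame(records).to_csv(path, sep="\t", index=False)


def flip_to_effect_allele(rec: SumstatRecord, target_allele: str) -> SumstatRecord:
    """Re-express a record relative to ``target_allele``.

    If the target already is the effect allele the record is returned
    unchanged; otherwise beta is negated and eaf complemented. se and p do
    not change under reorientation.
    """
    target_allele = target_allele.upper()
    if target_allele not in (rec.ref_allele, rec.alt_allele):
        raise AlleleMismatchError(
            f"{rec.variant_id}: allele {target_allele!r} not in "
            f"({rec.ref_allele!r}, {rec.alt_allele!r})"
        )
    if target_allele == rec.effect_allele:
        return rec
    return replace(
        rec,
        effect_allele=target_allele,
        beta=-rec.beta,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
    )


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome records for one variant, effect alleles aligned."""

    variant_id: str
    exposure: SumstatRecord
    outcome: SumstatRecord


def _strand_complement_alleles(rec: SumstatRecord) -> Optional[tuple[str, str]]:
    try:
        return ("".join(_COMPLEMENT[b] for b in rec.ref_allele),
                "".join(_COMPLEMENT[b] for b in rec.alt_allele))
    except KeyError:
        return None


def harmonize_pair(
    exposure: Sequence[SumstatRecord],
    outcome: Sequence[SumstatRecord],
    palindrome_maf_cutoff: float = 0.42,
) -> tuple[list[HarmonizedPair], list[tuple[str, str]]]:
    """Align an outcome study's rows to the exposure's effect alleles.

    Returns ``(pairs, drops)`` where ``drops`` lists ``(variant_id, reason)``
    for variants that could not be harmonized. Only variants present in both
    tables are returned.

    Alleles are matched directly or, failing that, after strand
    complementation of the outcome alleles (A<->T, C<->G on both alleles).
    Palindromic variants, whose strand cannot be told from the letters, are
    kept only if the minor-allele frequency is below ``palindrome_maf_cutoff``
    in both studies and the frequencies agree in orientation (both eafs on the
    same side of 0.5 once aligned); otherwise they are dropped. Palindromic
    variants missing eaf in either study are dropped. Indels are never
    treated as palindromic.
    """
    out_by_id = {r.variant_id: r for r in outcome}
    pairs: list[HarmonizedPair] = []
    drops: list[tuple[str, str]] = []

    for exp in exposure:
        out = out_by_id.get(exp.variant_id)
        if out is None:
            continue

        exp_alleles = {exp.ref_allele, exp.alt_allele}
        if {out.ref_allele, out.alt_allele} == exp_alleles:
            aligned = out
        else:
            comp = _strand_complement_alleles(out)
            if comp is not None and set(comp) == exp_alleles and not out.is_palindromic:
                aligned = replace(
                    out,
                    ref_allele="".join(_COMPLEMENT[b] for b in out.ref_allele),
                    alt_allele="".join(_COMPLEMENT[b] for b in out.alt_allele),
                    effect_allele="".join(_COMPLEMENT[b] for b in out.effect_allele),
                )
            else:
                drops.append((exp.variant_id, "allele_mismatch"))
                continue

        if exp.is_palindromic:
            if exp.eaf is None or aligned.eaf is None:
                drops.append((exp.variant_id, "palindromic_missing_eaf"))
                continue
            maf_exp = min(exp.eaf, 1 - exp.eaf)
            maf_out = min(aligned.eaf, 1 - aligned.eaf)
            if maf_exp >= palindrome_maf_cutoff or maf_out >= palindrome_maf_cutoff:
                drops.append((exp.variant_id, "palindromic_ambiguous_frequency"))
                continue
            aligned = flip_to_effect_allele(aligned, exp.effect_allele)
            # after alignment the frequencies must agree in orientation
            if (exp.eaf - 0.5) * (aligned.eaf - 0.5) < 0:
                drops.append((exp.variant_id, "palindromic_frequency_discordant"))
                continue
        else:
            aligned = flip_to_effect_allele(aligned, exp.effect_allele)

        pairs.append(HarmonizedPair(exp.variant_id, exp, aligned))

    return pairs, drops


def write_drop_log(drops: Sequence[tuple[str, str]], path) -> None:
    pd.DataFrame(drops, columns=["variant_id", "reason"]).to_csv(path, sep="\t", index=False)
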