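"""Phecode cohort construction from ICD event streams.

EHR billing codes (ICD-9-CM / ICD-10) are grouped into clinical phenotypes
("phecodes"), each carrying an exclusion range — nearby phecodes whose
carriers are ineligible as controls — and an optional sex restriction.

The case/control rule: a person is a case for a phecode if they have at
least ``min_code_instances`` (default 2) code instances on distinct dates; a
person with some but fewer instances, or carrying any code in the phecode's
exclusion range, is excluded; everyone else is a control, further restricted
to the age (or birth-decade) range observed among the cases. Phenotypes with
too few cases or restricted to one sex are dropped from the scan set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, MissingDemographicsError, ValidationError

VOCABULARIES = {"ICD9CM", "ICD10"}

CASE, CONTROL, EXCLUDED = "case", "control", "excluded"


@dataclass(frozen=True)
class IcdEvent:
    person_id: str
    date: str  # ISO-8601
    code: str
    vocabulary: str


@dataclass
class PhecodeMap:
    """ICD -> phecode mapping with exclusion ranges and sex restrictions.

    ``table`` columns: icd, vocab, phecode, label, exclusion_min,
    exclusion_max, sex (one of none/male/female). Phecodes are strings
    ("401.1"); exclusion ranges are closed numeric intervals on the phecode
    value and always contain the phecode itself.
    """

    table: pd.DataFrame

    REQUIRED = ["icd", "vocab", "phecode", "label", "exclusion_min", "exclusion_max", "sex"]

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ConfigError(f"phecode map missing columns: {missing}")
        bad_vocab = set(self.table["vocab"]) - VOCABULARIES
        if bad_vocab:
            raise ValidationError(f"unknown vocabularies in phecode map: {sorted(bad_vocab)}")
        t = self.table
        val = t["phecode"].astype(float)
        inside = (t["exclusion_min"].astype(float) <= val) & (val <= t["exclusion_max"].astype(float))
        if not inside.all():
            bad = t.loc[~inside, "phecode"].tolist()
            raise ValidationError(f"exclusion range does not contain its own phecode: {bad}")

    @classmethod
    def from_csv(cls, path) -> "PhecodeMap":
        return cls(pd.read_csv(path, dtype={"icd": str, "phecode": str}))

    def phecodes(self) -> pd.DataFrame:
        """One row per phecode: label, exclusion range, sex restriction."""
        return (self.table.groupby("phecode", as_index=False)
                .agg(label=("label", "first"),
                     exclusion_min=("exclusion_min", "min"),
                     exclusion_max=("exclusion_max", "max"),
                     sex=("sex", "first")))

    def lookup(self) -> pd.DataFrame:
        return self.table[["icd", "vocab", "phecode"]]


def map_events_to_phecodes(
    events: Sequence[IcdEvent] | pd.DataFrame, pmap: PhecodeMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count distinct-date phecode instances per person.

    Counts distinct (person, phecode, date) triples, so same-day duplicate
    codes mapping to one phecode count once. Returns ``(counts, unmapped)``:
    ``counts`` has columns person_id/phecode/n_instances, ``unmapped`` lists
    the codes (with vocabularies) that had no map entry.
    """
    if isinstance(events, pd.DataFrame):
        df = events.copy()
    else:
        df = pd.DataFrame([e.__dict__ for e in events])
    if df.empty:
        return (pd.DataFrame(columns=["person_id", "phecode", "n_instances"]),
                pd.DataFrame(columns=["code", "vocabulary"]))

    bad_vocab = set(df["vocabulary"]) - VOCABULARIES
    if bad_vocab:
        raise ValidationError(f"unknown vocabulary values: {sorted(bad_vocab)}")

    merged = df.merge(
        pmap.lookup(), left_on=["code", "vocabulary"], right_on=["icd", "vocab"], how="left"
    )
    unmapped = (merged.loc[merged["phecode"].isna(), ["code", "vocabulary"]]
                .drop_duplicates().reset_index(drop=True))
    mapped = merged.dropna(subset=["phecode"])
    counts = (mapped.drop_duplicates(["person_id", "phecode", "date"])
              .groupby(["person_id", "phecode"], as_index=False)
              .size().rename(columns={"size": "n_instances"}))
    return counts, unmapped


@dataclass
class PhenomeCohort:
    """Per-(person, phecode) case/control/excluded status plus covariates.

    ``status`` is a person x phecode DataFrame of strings; ``demographics``
    carries per-person sex, age (or birth decade) and principal components;
    ``phecode_info`` describes the retained phenotypes.
    """

    status: pd.DataFrame
    demographics: pd.DataFrame
    phecode_info: pd.DataFrame
    dropped_phecodes: pd.DataFrame

    @property
    def persons(self) -> list:
        return list(self.status.index)

    @property
    def retained_phecodes(self) -> list[str]:
        return list(self.status.columns)

    def counts(self, phecode: str) -> tuple[int, int]:
        col = self.status[phecode]
        return int((col == CASE).sum()), int((col == CONTROL).sum())

    def to_long_tsv(self, path) -> None:
        long = self.status.stack().rename("status").reset_index()
        long.columns = ["person_id", "phecode", "status"]
        long.to_csv(path, sep="\t", index=False)


def build_cohort(
    counts: pd.DataFrame,
    pmap: PhecodeMap,
    demographics: pd.DataFrame,
    min_cases: int = 300,
    min_code_instances: int = 2,
    age_column: Optional[str] = "age",
) -> PhenomeCohort:
    """Assign case/control/excluded status for every person and phecode.

    ``counts`` is the output of :func:`map_events_to_phecodes`;
    ``demographics`` is indexed by person_id (or has a person_id column) and
    must cover every person in ``counts``; persons present in demographics
    but absent from counts are code-free control candidates.

    Rules, per phecode:

    * count >= ``min_code_instances``  -> case
    * 0 < count < ``min_code_instances`` -> excluded
    * any code instance in the phecode's exclusion range -> excluded
      (unless already a case)
    * otherwise control, but only if the person's ``age_column`` value lies
      within the [min, max] range observed among the cases (persons outside
      the range are excluded)

    Phecodes with fewer than ``min_cases`` cases, or with a sex restriction,
    are dropped from the scan set (recorded in ``dropped_phecodes``).
    """
    if min_cases < 1 or min_code_instances < 1:
        raise ConfigError("min_cases and min_code_instances must be >= 1")

    demo = demographics.copy()
    if "person_id" in demo.columns:
        demo = demo.set_index("person_id")

    persons_with_codes = set(counts["person_id"]) if not counts.empty else set()
    missing = persons_with_codes - set(demo.index)
    if missing:
        raise MissingDemographicsError(
            f"{len(missing)} person(s) with codes lack demographics: {sorted(missing)[:5]}"
        )

    persons = list(demo.index)
    info = pmap.phecodes()
    count_mat = (counts.pivot(index="person_id", columns="phecode", values="n_instances")
                 .reindex(index=persons).fillna(0)
                 if not counts.empty else pd.DataFrame(0.0, index=persons, columns=[]))

    status_cols: dict[str, pd.Series] = {}
    kept_rows, dropped_rows = [], []
    phe_values = info.set_index("phecode")

    for phecode, row in phe_values.iterrows():
        n_inst = count_mat[phecode] if phecode in count_mat.columns else pd.Series(0.0, index=persons)
        is_case = n_inst >= min_code_instances
        partial = (n_inst > 0) & ~is_case

        lo, hi = float(row["exclusion_min"]), float(row["exclusion_max"])
        in_range_cols = [c for c in count_mat.columns if lo <= float(c) <= hi]
        carries_excl = (count_mat[in_range_cols].sum(axis=1) > 0
                        if in_range_cols else pd.Series(False, index=persons))

        status = pd.Series(CONTROL, index=persons)
        status[carries_excl | partial] = EXCLUDED
        status[is_case] = CASE

        n_cases = int(is_case.sum())
        if row["sex"] != "none":
            dropped_rows.append({"phecode": phecode, "reason": f"sex_restricted_{row['sex']}"})
            continue
        if n_cases < min_cases:
            dropped_rows.append({"phecode": phecode, "reason": f"cases_{n_cases}_lt_{min_cases}"})
            continue

        if age_column is not None and age_column in demo.columns:
            ages = demo[age_column]
            case_ages = ages[is_case]
            out_of_range = (ages < case_ages.min()) | (ages > case_ages.max())
            status[(status == CONTROL) & out_of_range] = EXCLUDED

        status_cols[phecode] = status
        kept_rows.append({"phecode": phecode, "label": row["label"],
                          "n_cases": n_cases,
                          "n_controls": int((status == CONTROL).sum())})

    status_df = (pd.DataFrame(status_cols, index=persons) if status_cols
                 else pd.DataFrame(index=persons))
    return PhenomeCohort(
        status=status_df,
        demographics=demo,
        phecode_info=pd.DataFrame(kept_rows, columns=["phecode", "label", "n_cases", "n_controls"]),
        dropped_phecodes=pd.DataFrame(dropped_rows, columns=["phecode", "reason"]),
    )


def read_icd_events(path) -> pd.DataFrame:
    """Read an ICD event CSV (person_id, date, code, vocabulary)."""
    df = pd.read_csv(path, dtype={"person_id": str, "code": str})
    needed = {"person_id", "date", "code", "vocabulary"}
    if not needed <= set(df.columns):
        raise ConfigError(f"ICD event table must have columns {sorted(needed)}")
    return df
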