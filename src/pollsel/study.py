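"""Data model and I/O for individual-level study tables.

The unit of analysis is an individual plant observed in one population,
one floral morph (L = long-styled, S = short-styled) and one pollination
treatment (C = open pollination, HP = supplemental hand pollination).
Five phenotypic traits are carried per individual — flowering onset
(Julian day), plant height (cm), number of flowers, corolla tube length
(mm) and corolla tube width (mm) — together with female reproductive
output (fruit production, seeds per fruit, and total seed production as
the female-fitness proxy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger("pollsel")

TRAITS: tuple[str, ...] = (
    "flowering_onset",
    "plant_height",
    "n_flowers",
    "corolla_tube_length",
    "corolla_tube_width",
)

MORPH_LEVELS: tuple[str, str] = ("L", "S")
TREATMENT_LEVELS: tuple[str, str] = ("C", "HP")

CANONICAL_COLUMNS: tuple[str, ...] = (
    "individual_id",
    "population",
    "morph",
    "treatment",
    "flowering_onset",
    "plant_height",
    "n_flowers",
    "corolla_tube_length",
    "corolla_tube_width",
    "fruit_production",
    "seeds_per_fruit",
    "female_fitness",
)

_NUMERIC_COLUMNS = CANONICAL_COLUMNS[4:]
_COUNT_COLUMNS = ("n_flowers", "fruit_production")


@dataclass(frozen=True, order=True)
class GroupKey:
    """Identifier of one standardization stratum.

    ``treatment`` is ``None`` for morph-level (population x morph)
    summaries such as pollen limitation, where the two arms are
    compared rather than pooled.
    """

    population: str
    morph: str
    treatment: str | None = None

    def __str__(self) -> str:
        parts = [self.population, self.morph]
        if self.treatment is not None:
            parts.append(self.treatment)
        return "/".join(parts)


class StudyTable:
    """Validated rectangular table of individual plant records.

    Wraps a :class:`pandas.DataFrame` with the canonical columns and
    keeps factor-level registries (population levels in order of first
    appearance; morph and treatment in their conventional L/S and C/HP
    order). Construction validates every record; invalid rows raise
    :class:`~pollsel.errors.ValidationError` with row indices.
    """

    def __init__(self, df: pd.DataFrame, populations: Sequence[str] | None = None):
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        if len(df) == 0:
            raise ValidationError("study table is empty")
        df = df.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True).copy()
        df["individual_id"] = df["individual_id"].astype(str)
        for c in ("population", "morph", "treatment"):
            df[c] = df[c].astype(str)
        for c in _NUMERIC_COLUMNS:
            df[c] = df[c].astype(float)
        self._validate(df)
        self._df = df
        if populations is None:
            populations = tuple(dict.fromkeys(df["population"]))
        else:
            populations = tuple(populations)
            unknown = set(df["population"]) - set(populations)
            if unknown:
                raise ValidationError(f"unregistered population levels: {sorted(unknown)}")
        self.populations: tuple[str, ...] = populations
        self.morphs: tuple[str, ...] = MORPH_LEVELS
        self.treatments: tuple[str, ...] = TREATMENT_LEVELS

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        problems: list[str] = []

        def bad(mask: pd.Series, msg: str) -> None:
            idx = list(df.index[mask][:10])
            if idx:
                problems.append(f"{msg} (rows {idx})")

        dup = df["individual_id"].duplicated(keep=False)
        bad(dup, "duplicate individual_id")
        bad(~df["morph"].isin(MORPH_LEVELS), f"morph not in {MORPH_LEVELS}")
        bad(~df["treatment"].isin(TREATMENT_LEVELS), f"treatment not in {TREATMENT_LEVELS}")
        num = df[list(_NUMERIC_COLUMNS)]
        bad(~np.isfinite(num).all(axis=1), "non-finite numeric value")
        for c in TRAITS:
            bad(df[c] <= 0, f"{c} must be > 0")
        bad(df["female_fitness"] < 0, "female_fitness must be >= 0")
        bad(df["fruit_production"] < 0, "fruit_production must be >= 0")
        bad(df["seeds_per_fruit"] < 0, "seeds_per_fruit must be >= 0")
        for c in _COUNT_COLUMNS:
            bad(df[c] != np.round(df[c]), f"{c} must be an integer count")
        bad(df["fruit_production"] > df["n_flowers"], "fruit_production exceeds n_flowers")
        if problems:
            raise ValidationError("; ".join(problems))

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._df)

    @property
    def df(self) -> pd.DataFrame:
        """The underlying records as a DataFrame (do not mutate)."""
        return self._df

    def equals(self, other: "StudyTable") -> bool:
        return self.populations == other.populations and self._df.equals(other._df)

    # -- stratification -----------------------------------------------------

    def group_keys(self, with_treatment: bool = True) -> list[GroupKey]:
        """All realized strata, ordered by registry order."""
        present = set(
            zip(self._df["population"], self._df["morph"], self._df["treatment"])
        )
        keys = []
        for pop in self.populations:
            for morph in self.morphs:
                if with_treatment:
                    for trt in self.treatments:
                        if (pop, morph, trt) in present:
                            keys.append(GroupKey(pop, morph, trt))
                else:
                    if any(p == pop and m == morph for p, m, _ in present):
                        keys.append(GroupKey(pop, morph))
        return keys

    def group(self, key: GroupKey) -> pd.DataFrame:
        mask = (self._df["population"] == key.population) & (
            self._df["morph"] == key.morph
        )
        if key.treatment is not None:
            mask &= self._df["treatment"] == key.treatment
        return self._df[mask]

    def iter_groups(self, with_treatment: bool = True) -> Iterator[tuple[GroupKey, pd.DataFrame]]:
        for key in self.group_keys(with_treatment):
            yield key, self.group(key)

    def subset_treatment(self, treatment: str) -> "StudyTable":
        if treatment not in TREATMENT_LEVELS:
            raise ValidationError(f"unknown treatment {treatment!r}")
        sub = self._df[self._df["treatment"] == treatment]
        if len(sub) == 0:
            raise ValidationError(f"no records with treatment {treatment!r}")
        return StudyTable(sub, populations=self.populations)


def read_study_table(path, schema: Mapping[str, str] | None = None) -> StudyTable:
    """Read a study table from CSV.

    Parameters
    ----------
    path
        CSV file with a header row, or an Excel workbook (``.xlsx`` /
        ``.xls``; first sheet) such as a raw field-data deposit.
    schema
        Optional mapping from file column names to canonical column
        names, for importing files whose headers differ.

    Rows with missing values in any analysis column are dropped with a
    logged count (field attrition is not imputed); rows with invalid
    values raise :class:`~pollsel.errors.ValidationError`.
    """
    if str(path).lower().endswith((".xlsx", ".xls")):
        raw = pd.read_excel(path, dtype=str)
    else:
        raw = pd.read_csv(path, dtype=str)
    if schema:
        raw = raw.rename(columns=dict(schema))
    missing = [c for c in CANONICAL_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if len(raw) == 0:
        raise ValidationError(f"{path}: no data rows")
    raw = raw.loc[:, list(CANONICAL_COLUMNS)]
    for c in _NUMERIC_COLUMNS:
        try:
            # astype goes through numpy's correctly-rounded parser, so
            # full-precision values survive the round trip exactly
            raw[c] = raw[c].astype(float)
        except ValueError:
            converted = pd.to_numeric(raw[c], errors="coerce")
            bad = converted.isna() & raw[c].notna()
            rows = list(raw.index[bad][:10])
            raise SchemaError(f"column {c!r}: non-numeric value at rows {rows}") from None
    n_before = len(raw)
    raw = raw.dropna(subset=list(CANONICAL_COLUMNS))
    dropped = n_before - len(raw)
    if dropped:
        logger.info("read_study_table: dropped %d rows with missing values", dropped)
    if len(raw) == 0:
        raise ValidationError(f"{path}: all rows had missing values")
    return StudyTable(raw)


def write_study_table(table: StudyTable, path) -> None:
    """Write a study table as CSV with canonical column order.

    Floats are written with full (shortest round-tripping) precision, so
    ``read_study_table(write_study_table(t))`` reproduces ``t`` exactly.
    """
    table.df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def aggregate_flowers(flowers: pd.DataFrame, base: StudyTable) -> StudyTable:
    """Replace per-individual corolla traits by flower-level means.

    ``flowers`` holds repeated caliper measurements (the first one to
    three open flowers per individual) with columns ``individual_id``,
    ``flower_index``, ``corolla_tube_length``, ``corolla_tube_width``.
    The per-individual trait is the unweighted arithmetic mean over that
    individual's measured flowers; individuals absent from ``flowers``
    keep their existing values. No other field changes.
    """
    required = ("individual_id", "flower_index", "corolla_tube_length", "corolla_tube_width")
    missing = [c for c in required if c not in flowers.columns]
    if missing:
        raise SchemaError(f"flower table missing columns: {missing}")
    flowers = flowers.copy()
    flowers["individual_id"] = flowers["individual_id"].astype(str)
    idx = flowers["flower_index"].astype(int)
    if ((idx < 1) | (idx > 3)).any():
        raise ValidationError("flower_index must be between 1 and 3")
    known = set(base.df["individual_id"])
    orphans = sorted(set(flowers["individual_id"]) - known)
    if orphans:
        raise ValidationError(f"flower rows for unknown individuals: {orphans[:10]}")
    means = flowers.groupby("individual_id")[["corolla_tube_length", "corolla_tube_width"]].mean()
    df = base.df.copy()
    matched = df["individual_id"].map(means["corolla_tube_length"])
    df["corolla_tube_length"] = matched.fillna(df["corolla_tube_length"])
    df["corolla_tube_width"] = (
        df["individual_id"].map(means["corolla_tube_width"]).fillna(df["corolla_tube_width"])
    )
    return StudyTable(df, populations=base.populations)
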