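"""Long-format record ingestion and the country x variable working table.

Country-level indicator data arrive as a long "vector file": one row per
datum, carrying its source, category, driver assignment, variable name, year,
country and value. The analysis substrate is a wide working table holding,
for each (country, variable), the latest available value, together with the
year that supplied it. Derived variables (ratios relativizing a quantity by
country size/population/GDP, and log transforms of skewed quantities) are
appended as new columns.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import CATEGORIES, DRIVERS

logger = logging.getLogger(__name__)

_ISO_RE = re.compile(r"^[A-Z]{3}$")

#: Default column mapping: canonical field -> CSV column name.
DEFAULT_SCHEMA = {
    "source": "source",
    "category": "category",
    "driver": "driver",
    "variable": "variable",
    "year": "year",
    "country": "country",
    "value": "value",
}


@dataclass(frozen=True)
class VariableRecord:
    """One datum: who measured what, where, when."""

    source: str
    category: str  # human | environmental | intrinsic | ""
    driver: str    # one of DRIVERS or "" (unassigned)
    variable: str
    year: int | None
    country: str
    value: float | None

    def __post_init__(self):
        if not _ISO_RE.match(self.country):
            raise ValueError(f"country {self.country!r} is not an ISO alpha-3 code")
        if self.driver and self.driver not in DRIVERS:
            raise ValueError(f"unknown driver {self.driver!r}")
        if self.category and self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class DerivationRule:
    """Construction recipe for a derived variable.

    ``ratio`` divides ``numerator`` by ``denominator`` (relativization by a
    size-like variable); ``log`` takes the natural log of ``numerator``.
    """

    kind: str  # "ratio" | "log"
    numerator: str
    output: str
    denominator: str | None = None

    def __post_init__(self):
        if self.kind not in ("ratio", "log"):
            raise ValueError(f"unknown derivation kind {self.kind!r}")
        if self.kind == "ratio" and not self.denominator:
            raise ValueError(f"ratio rule {self.output!r} needs a denominator")
        inputs = {self.numerator, self.denominator} - {None}
        if self.output in inputs:
            raise ValueError(f"derived id {self.output!r} collides with an input")


@dataclass
class IngestResult:
    """Records plus the ingestion audit trail."""

    records: list[VariableRecord]
    n_rejected: int = 0
    n_duplicates: int = 0
    rejected_reasons: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


@dataclass
class WorkingTable:
    """Country x variable grid of latest-available values.

    ``values`` and ``provenance_year`` share index (ISO codes) and columns
    (variable ids); ``provenance_year`` records which calendar year supplied
    each cell. ``drivers`` maps variable id -> driver tag ("" if unassigned).
    """

    values: pd.DataFrame
    provenance_year: pd.DataFrame
    drivers: dict[str, str]

    @property
    def countries(self) -> list[str]:
        return list(self.values.index)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def variables_for_driver(self, driver: str) -> list[str]:
        return [v for v in self.variables if self.drivers.get(v, "") == driver]

    def to_records(self) -> list[VariableRecord]:
        """Flatten back to long form, one record per cell.

        Missing cells are emitted with a missing value so that rebuilding the
        table from its own records reproduces it exactly (including countries
        with no data at all).
        """
        out = []
        for var in self.values.columns:
            drv = self.drivers.get(var, "")
            col = self.values[var]
            yrs = self.provenance_year[var]
            for country, val in col.items():
                yr = yrs.loc[country]
                out.append(VariableRecord(
                    source="workingtable", category="", driver=drv,
                    variable=var, year=None if pd.isna(yr) else int(yr),
                    country=country,
                    value=None if pd.isna(val) else float(val),
                ))
        return out

    def write(self, values_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write the wide CSV plus a JSON sidecar with provenance years."""
        import json

        self.values.to_csv(values_path, index_label="country")
        if sidecar_path is not None:
            side = {
                "drivers": self.drivers,
                "provenance_year": {
                    var: {
                        c: int(y)
                        for c, y in self.provenance_year[var].items()
                        if not pd.isna(y)
                    }
                    for var in self.provenance_year.columns
                },
            }
            with open(sidecar_path, "w") as fh:
                json.dump(side, fh, indent=1, sort_keys=True)


def _parse_value(token: str, sentinels: Sequence[str]) -> float | None:
    token = token.strip()
    if token == "" or token in sentinels:
        return None
    return float(token)  # may raise ValueError -> row rejected by caller


def load_long_records(
    path: str | Path,
    schema: dict[str, str] | None = None,
    *,
    delimiter: str = ",",
    missing_sentinels: Sequence[str] = ("NA", "NaN", "..", "-"),
    year_min: int = 1990,
    year_max: int = 2009,
) -> IngestResult:
    """Read a long-format CSV into validated records.

    Rows with unparseable year/value or a malformed country code are rejected
    and logged, never fatal. Duplicate (variable, country, year) keys are
    resolved last-wins with a warning. Missing-value tokens become missing
    values, not zeros.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    by_key: dict[tuple[str, str, int | None], VariableRecord] = {}
    n_rejected = 0
    n_duplicates = 0
    reasons: list[str] = []

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header row required")
        missing_cols = [c for c in schema.values() if c not in reader.fieldnames]
        if missing_cols:
            raise ValueError(f"{path}: missing mapped columns {missing_cols}")
        for lineno, row in enumerate(reader, start=2):
            try:
                year_tok = (row[schema["year"]] or "").strip()
                year = int(year_tok) if year_tok else None
                if year is not None and not (year_min <= year <= year_max):
                    raise ValueError(f"year {year} outside [{year_min}, {year_max}]")
                rec = VariableRecord(
                    source=(row[schema["source"]] or "").strip(),
                    category=(row[schema["category"]] or "").strip(),
                    driver=(row[schema["driver"]] or "").strip(),
                    variable=(row[schema["variable"]] or "").strip(),
                    year=year,
                    country=(row[schema["country"]] or "").strip(),
                    value=_parse_value(row[schema["value"]] or "", missing_sentinels),
                )
            except (ValueError, KeyError) as exc:
                n_rejected += 1
                reasons.append(f"line {lineno}: {exc}")
                logger.warning("rejected row at line %d: %s", lineno, exc)
                continue
            key = (rec.variable, rec.country, rec.year)
            if key in by_key:
                n_duplicates += 1
                logger.warning(
                    "duplicate (variable, country, year)=%s at line %d: keeping last",
                    key, lineno,
                )
            by_key[key] = rec

    return IngestResult(
        records=list(by_key.values()),
        n_rejected=n_rejected,
        n_duplicates=n_duplicates,
        rejected_reasons=reasons,
    )


def build_working_table(records: Iterable[VariableRecord]) -> WorkingTable:
    """Collapse long records to the latest-available country x variable grid.

    For each (country, variable) the cell takes the value of the greatest
    year holding a non-missing value; variables with no value anywhere are
    dropped (logged). Countries appearing in any record keep a row even if
    entirely missing.
    """
    records = list(records)
    if not records:
        raise ValueError("no records: cannot build a working table")

    frame = pd.DataFrame(
        {
            "variable": [r.variable for r in records],
            "country": [r.country for r in records],
            "year": [np.nan if r.year is None else r.year for r in records],
            "value": [np.nan if r.value is None else r.value for r in records],
            "driver": [r.driver for r in records],
        }
    )
    countries = sorted(frame["country"].unique())

    # driver tag per variable: most common non-empty tag
    drivers: dict[str, str] = {}
    for var, grp in frame.groupby("variable"):
        tags = [t for t in grp["driver"] if t]
        if tags:
            counts = pd.Series(tags).value_counts()
            if len(counts) > 1:
                logger.warning("variable %s has conflicting driver tags %s; using %s",
                               var, list(counts.index), counts.index[0])
            drivers[var] = counts.index[0]
        else:
            drivers[var] = ""

    valued = frame.dropna(subset=["value"]).copy()
    dropped = sorted(set(frame["variable"]) - set(valued["variable"]))
    for var in dropped:
        logger.info("variable %s has no values anywhere: dropped", var)

    if valued.empty:
        raise ValueError("every variable is entirely missing")

    # latest non-missing year wins; unknown year sorts before any known year
    valued["_yearkey"] = valued["year"].fillna(-np.inf)
    valued = valued.sort_values("_yearkey", kind="stable")
    latest = valued.groupby(["country", "variable"]).tail(1)

    variables = sorted(latest["variable"].unique())
    values = latest.pivot(index="country", columns="variable", values="value")
    values = values.reindex(index=countries, columns=variables)
    prov = latest.pivot(index="country", columns="variable", values="year")
    prov = prov.reindex(index=countries, columns=variables)

    return WorkingTable(
        values=values,
        provenance_year=prov,
        drivers={v: drivers.get(v, "") for v in variables},
    )


def apply_derivations(table: WorkingTable, rules: Iterable[DerivationRule]) -> WorkingTable:
    """Append derived variables; originals stay untouched.

    Ratio cells are missing where either input is missing or the denominator
    is zero; log cells are missing for nonpositive inputs. Derived columns
    inherit the numerator's driver tag.
    """
    values = table.values.copy()
    prov = table.provenance_year.copy()
    drivers = dict(table.drivers)

    for rule in rules:
        missing_inputs = [
            v for v in (rule.numerator, rule.denominator)
            if v is not None and v not in values.columns
        ]
        if missing_inputs:
            raise KeyError(
                f"derivation {rule.output!r} references absent variable(s) {missing_inputs}"
            )
        if rule.output in values.columns:
            raise ValueError(f"derived id {rule.output!r} already exists")
        num = values[rule.numerator]
        if rule.kind == "ratio":
            den = values[rule.denominator]
            out = num / den.where(den != 0)
            # provenance: the later of the two input years
            p = pd.concat([prov[rule.numerator], prov[rule.denominator]], axis=1).max(axis=1)
        else:  # log
            out = np.log(num.where(num > 0))
            p = prov[rule.numerator]
        values[rule.output] = out
        prov[rule.output] = p.where(out.notna())
        drivers[rule.output] = drivers.get(rule.numerator, "")

    return WorkingTable(values=values, provenance_year=prov, drivers=drivers)
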