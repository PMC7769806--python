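"""Panel data model for regional health-resource accounts.

A :class:`ResourcePanel` is a long-format table of decision-making units
(DMUs, typically provinces) observed over several years.  Each record
carries the input quantities of the health system (institutions, beds,
health staff), the service outputs (outpatient visits, discharged
patients), the population and land area used as equity bases, and a
region-group label.  Every downstream stage — Lorenz/Gini/Theil equity
measurement, DEA efficiency and the Malmquist productivity index — reads
this one container.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "INPUT_QUANTITIES",
    "OUTPUT_QUANTITIES",
    "DEFAULT_COLUMNS",
    "PanelRecord",
    "ResourcePanel",
    "PanelSchemaError",
    "PanelValidationError",
    "load_panel",
    "write_panel",
    "density_table",
]

#: canonical input quantities, in report order
INPUT_QUANTITIES: tuple[str, ...] = ("institutions", "beds", "staff")
#: canonical output quantities, in report order
OUTPUT_QUANTITIES: tuple[str, ...] = ("outpatient_visits", "discharged_patients")

#: default CSV column names (canonical name -> file column)
DEFAULT_COLUMNS: dict[str, str] = {
    "dmu": "dmu",
    "year": "year",
    "group": "group",
    "institutions": "institutions",
    "beds": "beds",
    "staff": "staff",
    "outpatient_visits": "outpatient_visits",
    "discharged_patients": "discharged_patients",
    "population": "population",
    "area_km2": "area_km2",
}

_NUMERIC_FIELDS = INPUT_QUANTITIES + OUTPUT_QUANTITIES + ("population", "area_km2")


class PanelSchemaError(ValueError):
    """A required column is missing or unparseable."""


class PanelValidationError(ValueError):
    """The table violates a panel invariant (duplicates, nonpositive bases...)."""


@dataclass(frozen=True)
class PanelRecord:
    """One DMU observed in one year."""

    dmu: str
    year: int
    group: str
    inputs: dict[str, float]
    outputs: dict[str, float]
    population: float
    area_km2: float

    def quantity(self, name: str) -> float:
        if name in self.inputs:
            return self.inputs[name]
        if name in self.outputs:
            return self.outputs[name]
        if name == "population":
            return self.population
        if name == "area_km2":
            return self.area_km2
        raise KeyError(name)


@dataclass(frozen=True)
class ResourcePanel:
    """A validated DMU x year panel.

    ``years`` and ``dmus`` are the ordered distinct labels; ``groups`` maps
    each DMU to its single region-group label.  Record order is normalised
    (year, then DMU) so file row order never affects results.
    """

    records: tuple[PanelRecord, ...]
    years: tuple[int, ...] = field(init=False)
    dmus: tuple[str, ...] = field(init=False)
    groups: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        recs = tuple(
            sorted(self.records, key=lambda r: (r.year, r.dmu))
        )
        object.__setattr__(self, "records", recs)
        _validate(recs)
        object.__setattr__(self, "years", tuple(sorted({r.year for r in recs})))
        object.__setattr__(self, "dmus", tuple(sorted({r.dmu for r in recs})))
        object.__setattr__(self, "groups", {r.dmu: r.group for r in recs})

    def __len__(self) -> int:
        return len(self.records)

    def year_records(self, year: int) -> list[PanelRecord]:
        out = [r for r in self.records if r.year == year]
        if not out:
            raise PanelValidationError(f"year {year!r} not present in panel")
        return out

    def to_frame(self, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Long-format DataFrame, one row per (dmu, year)."""
        cols = dict(DEFAULT_COLUMNS if columns is None else columns)
        rows = []
        for r in self.records:
            row = {
                cols["dmu"]: r.dmu,
                cols["year"]: r.year,
                cols["group"]: r.group,
                cols["population"]: r.population,
                cols["area_km2"]: r.area_km2,
            }
            for q in INPUT_QUANTITIES:
                row[cols[q]] = r.inputs[q]
            for q in OUTPUT_QUANTITIES:
                row[cols[q]] = r.outputs[q]
            rows.append(row)
        ordered = [cols[k] for k in DEFAULT_COLUMNS]
        return pd.DataFrame(rows, columns=ordered)


def _validate(records: Sequence[PanelRecord]) -> None:
    seen: set[tuple[str, int]] = set()
    group_of: dict[str, str] = {}
    bad_base: list[tuple[str, int]] = []
    for r in records:
        key = (r.dmu, r.year)
        if key in seen:
            raise PanelValidationError(f"duplicate (dmu, year) record: {key}")
        seen.add(key)
        prev = group_of.setdefault(r.dmu, r.group)
        if prev != r.group:
            raise PanelValidationError(
                f"DMU {r.dmu!r} carries two group labels: {prev!r} and {r.group!r}"
            )
        if not (r.population > 0 and r.area_km2 > 0):
            bad_base.append(key)
        for name, v in list(r.inputs.items()) + list(r.outputs.items()):
            if not (v == v and abs(v) != float("inf")):  # NaN / inf guard
                raise PanelValidationError(f"non-finite {name} for {key}")
            if v < 0:
                raise PanelValidationError(f"negative {name} for {key}")
        if set(r.inputs) != set(INPUT_QUANTITIES) or set(r.outputs) != set(OUTPUT_QUANTITIES):
            raise PanelValidationError(f"record {key} has a nonstandard quantity set")
    if bad_base:
        raise PanelValidationError(
            f"nonpositive population/area for records: {sorted(bad_base)}"
        )


def load_panel(
    path: str | Path | io.TextIOBase,
    schema: Mapping[str, str] | None = None,
) -> ResourcePanel:
    """Read a long-format CSV into a validated :class:`ResourcePanel`.

    ``schema`` maps canonical field names to the column names actually used
    in the file; omitted keys fall back to :data:`DEFAULT_COLUMNS`.
    """
    cols = dict(DEFAULT_COLUMNS)
    if schema:
        cols.update(schema)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [cols[k] for k in DEFAULT_COLUMNS if cols[k] not in df.columns]
    if missing:
        raise PanelSchemaError(f"missing column(s): {', '.join(missing)}")
    records = []
    for _, row in df.iterrows():
        try:
            rec = PanelRecord(
                dmu=str(row[cols["dmu"]]),
                year=int(row[cols["year"]]),
                group=str(row[cols["group"]]),
                inputs={q: float(row[cols[q]]) for q in INPUT_QUANTITIES},
                outputs={q: float(row[cols[q]]) for q in OUTPUT_QUANTITIES},
                population=float(row[cols["population"]]),
                area_km2=float(row[cols["area_km2"]]),
            )
        except (TypeError, ValueError) as exc:
            raise PanelSchemaError(f"unparseable row {dict(row)}: {exc}") from exc
        records.append(rec)
    return ResourcePanel(tuple(records))


def write_panel(
    panel: ResourcePanel,
    path: str | Path | io.TextIOBase,
    schema: Mapping[str, str] | None = None,
) -> None:
    """Write the panel as UTF-8 CSV whose re-load reproduces it exactly.

    Numerals are emitted at full repr precision so load/write is the
    identity on valid panels.
    """
    cols = dict(DEFAULT_COLUMNS)
    if schema:
        cols.update(schema)
    df = panel.to_frame(cols)
    df.to_csv(path, index=False, float_format=None, encoding="utf-8")


def density_table(panel: ResourcePanel) -> pd.DataFrame:
    """Per (year, resource) totals and densities per 1,000 persons / 1,000 km².

    Totals are sums over DMUs present in the year; the density base is the
    matching aggregate population (or area) of the same DMUs.
    """
    rows = []
    for year in panel.years:
        recs = panel.year_records(year)
        pop = sum(r.population for r in recs)
        area = sum(r.area_km2 for r in recs)
        if pop <= 0:
            raise PanelValidationError(f"year {year}: zero aggregate population")
        if area <= 0:
            raise PanelValidationError(f"year {year}: zero aggregate area")
        for q in INPUT_QUANTITIES:
            total = sum(r.inputs[q] for r in recs)
            rows.append(
                {
                    "year": year,
                    "resource": q,
                    "total": total,
                    "per_1000_persons": total / (pop / 1000.0),
                    "per_1000_km2": total / (area / 1000.0),
                }
            )
    return pd.DataFrame(rows)


def subset_years(panel: ResourcePanel, years: Sequence[int]) -> ResourcePanel:
    """Panel restricted to the given years."""
    keep = set(years)
    return ResourcePanel(tuple(r for r in panel.records if r.year in keep))


def relabel_group(panel: ResourcePanel, groups: Mapping[str, str]) -> ResourcePanel:
    """Panel with group labels replaced by an explicit DMU -> group mapping."""
    missing = [d for d in panel.dmus if d not in groups]
    if missing:
        raise PanelValidationError(f"no group label for DMUs: {missing}")
    recs = tuple(replace(r, group=groups[r.dmu]) for r in panel.records)
    return ResourcePanel(recs)
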