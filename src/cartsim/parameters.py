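"""Kinetic parameter registry.

The registry holds every rate constant of the reduced signalling network:
its frozen default (the population mean used by the variability engine and
the reference value p0 of the optimizer's fold-change penalty), the value
currently in force, hard bounds, and a flag marking whether the Monte Carlo
engine varies it across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

#: Parameter names that must exist in any registry used with the bundled
#: network: the catalytic rates singled out by the sensitivity analysis.
REQUIRED_NAMES = (
    "Kcat_LCKPU_CD3z",
    "CSKon",
    "Kcat_ZAP",
    "Kcat_CD45_LCK505",
    "Kcat_CD45_A1",
)

TABLE_COLUMNS = ["name", "default", "lower", "upper", "varied", "units", "description"]


class ParameterTableError(ValueError):
    """Raised when a parameter table violates the registry invariants."""


@dataclass(frozen=True)
class ParameterEntry:
    name: str
    default: float
    current: float
    lower: float
    upper: float
    varied: bool
    units: str = ""
    description: str = ""

    def validate(self) -> None:
        if not (self.default > 0 and self.current > 0):
            raise ParameterTableError(
                f"parameter {self.name!r}: default/current must be > 0"
            )
        if not (self.lower > 0 and self.upper > 0):
            raise ParameterTableError(f"parameter {self.name!r}: bounds must be > 0")
        if not (self.lower <= self.current <= self.upper):
            raise ParameterTableError(
                f"parameter {self.name!r}: require lower <= current <= upper "
                f"({self.lower} <= {self.current} <= {self.upper} fails)"
            )


@dataclass
class KineticParameterSet:
    """Named registry of positive rate constants with defaults and bounds."""

    entries: dict[str, ParameterEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for entry in self.entries.values():
            entry.validate()

    # -- mapping-style access -------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> float:
        return self.entries[name].current

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    @property
    def varied_names(self) -> list[str]:
        return [n for n, e in self.entries.items() if e.varied]

    def default(self, name: str) -> float:
        return self.entries[name].default

    def bounds(self, name: str) -> tuple[float, float]:
        e = self.entries[name]
        return e.lower, e.upper

    # -- functional updates ---------------------------------------------------
    def with_values(self, values: Mapping[str, float]) -> "KineticParameterSet":
        """Return a copy with ``current`` overridden for the given names."""
        entries = dict(self.entries)
        for name, value in values.items():
            if name not in entries:
                raise KeyError(f"unknown parameter {name!r}")
            entries[name] = replace(entries[name], current=float(value))
            entries[name].validate()
        return KineticParameterSet(entries)

    def with_defaults(self, values: Mapping[str, float]) -> "KineticParameterSet":
        """Return a copy where both default and current are overridden.

        Used to re-baseline a registry on engineered (optimized) parameter
        values: population variability then samples around the new values.
        """
        entries = dict(self.entries)
        for name, value in values.items():
            if name not in entries:
                raise KeyError(f"unknown parameter {name!r}")
            entries[name] = replace(
                entries[name], default=float(value), current=float(value)
            )
            entries[name].validate()
        return KineticParameterSet(entries)

    def reset(self) -> "KineticParameterSet":
        return KineticParameterSet(
            {n: replace(e, current=e.default) for n, e in self.entries.items()}
        )

    def current_values(self, names: Iterable[str] | None = None) -> dict[str, float]:
        names = self.names if names is None else list(names)
        return {n: self.entries[n].current for n in names}

    # -- IO -------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": e.name,
                "default": e.default,
                "lower": e.lower,
                "upper": e.upper,
                "varied": e.varied,
                "units": e.units,
                "description": e.description,
            }
            for e in self.entries.values()
        ]
        return pd.DataFrame(rows, columns=TABLE_COLUMNS)

    def write_table(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _coerce_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ParameterTableError(f"cannot interpret {value!r} as boolean")


def load_parameter_registry(table: str | Path | pd.DataFrame) -> KineticParameterSet:
    """Load a registry from a CSV parameter table (or an equivalent frame).

    The table must have columns ``name, default, lower, upper, varied``
    (plus optional ``units`` and ``description``); validation failures are
    reported with the offending row number (0-based data row).
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table)
    missing = {"name", "default", "lower", "upper", "varied"} - set(df.columns)
    if missing:
        raise ParameterTableError(f"parameter table missing columns: {sorted(missing)}")

    entries: dict[str, ParameterEntry] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        name = str(row.name).strip()
        if name in entries:
            raise ParameterTableError(f"row {i}: duplicate parameter name {name!r}")
        entry = ParameterEntry(
            name=name,
            default=float(row.default),
            current=float(row.default),
            lower=float(row.lower),
            upper=float(row.upper),
            varied=_coerce_bool(row.varied),
            units=str(getattr(row, "units", "")) if hasattr(row, "units") else "",
            description=(
                str(getattr(row, "description", "")) if hasattr(row, "description") else ""
            ),
        )
        try:
            entry.validate()
        except ParameterTableError as err:
            raise ParameterTableError(f"row {i}: {err}") from None
        entries[name] = entry
    return KineticParameterSet(entries)


def default_registry() -> KineticParameterSet:
    """The committed default parameter table shipped with the package."""
    with resources.as_file(
        resources.files("cartsim.data").joinpath("default_parameters.csv")
    ) as path:
        return load_parameter_registry(path)
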