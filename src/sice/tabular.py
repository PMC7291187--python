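"""Mixed-type rectangular tables with explicit missing cells.

The data model is deliberately minimal: a table is a list of
:class:`VariableSpec` (the schema) plus a grid of cells, where each cell
holds either a value or the dedicated :data:`MISSING` sentinel.  Categorical
columns (binary / nominal / ordinal) store their original string labels —
never a numeric encoding and never the literal token ``"NA"`` — so that a
missing cell can never be silently imputed with the string that happened to
represent it on disk.  Encoding to numbers happens only inside the imputation
kernels.

On disk the format is plain RFC-4180 CSV with a mandatory header row; a
missing cell is written as ``NA`` and both ``NA`` and the empty string parse
back to :data:`MISSING`.  The schema travels in a YAML sidecar file mapping
each column to its variable type and, for categorical columns, its ordered
level list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "MISSING",
    "VariableSpec",
    "DataTable",
    "SchemaError",
    "read_table",
    "write_table",
    "read_schema",
    "write_schema",
]

VARTYPES = ("binary", "nominal", "ordinal", "numeric")
CATEGORICAL_VARTYPES = ("binary", "nominal", "ordinal")


class _MissingType:
    """Singleton marker for a missing cell."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"

    def __bool__(self) -> bool:
        return False


#: The one and only missing-cell marker.
MISSING = _MissingType()


def is_missing(value: Any) -> bool:
    """True for the sentinel, ``None``, and float NaN (tolerated on input)."""
    if value is MISSING or value is None:
        return True
    return isinstance(value, float) and math.isnan(value)


class SchemaError(ValueError):
    """A cell value or schema definition violates the declared schema."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one column: its name, type, and (ordered) levels.

    ``levels`` is required for binary/nominal/ordinal columns and must be
    absent for numeric ones.  For ordinal columns the order of ``levels`` is
    meaningful (it defines the integer ranks used by rank-based imputers) and
    is preserved through file round-trips.
    """

    name: str
    vartype: str
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.vartype not in VARTYPES:
            raise SchemaError(
                f"column {self.name!r}: unknown vartype {self.vartype!r}; "
                f"expected one of {VARTYPES}"
            )
        if self.vartype == "numeric":
            if self.levels is not None:
                raise SchemaError(f"column {self.name!r}: numeric columns take no levels")
            return
        if self.levels is not None and not isinstance(self.levels, tuple):
            object.__setattr__(self, "levels", tuple(self.levels))
        if not self.levels:
            raise SchemaError(f"column {self.name!r}: categorical columns require levels")
        if len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"column {self.name!r}: levels must be unique")
        if self.vartype == "binary" and len(self.levels) != 2:
            raise SchemaError(
                f"column {self.name!r}: binary columns need exactly 2 levels, "
                f"got {len(self.levels)}"
            )

    @property
    def is_categorical(self) -> bool:
        return self.vartype in CATEGORICAL_VARTYPES


def _validate_cell(spec: VariableSpec, value: Any, row: int) -> Any:
    """Normalise and validate one cell; 1-based rows in error messages."""
    if is_missing(value):
        return MISSING
    if spec.vartype == "numeric":
        try:
            out = float(value)
        except (TypeError, ValueError):
            raise SchemaError(
                f"row {row + 1}, column {spec.name!r}: "
                f"cannot parse {value!r} as a number"
            ) from None
        if not math.isfinite(out):
            raise SchemaError(
                f"row {row + 1}, column {spec.name!r}: non-finite value {value!r}"
            )
        return out
    value = str(value)
    if value not in spec.levels:
        raise SchemaError(
            f"row {row + 1}, column {spec.name!r}: label {value!r} is not one of "
            f"the declared levels {list(spec.levels)}"
        )
    return value


class DataTable:
    """A schema-validated rectangular table with explicit missing cells.

    Rows are addressed by 0-based index, columns by name; row order is
    significant and preserved by every operation in this package.
    """

    def __init__(self, schema: Sequence[VariableSpec], rows: Iterable[Sequence[Any]]):
        self.schema: list[VariableSpec] = list(schema)
        names = [s.name for s in self.schema]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate column names in schema")
        self._columns: dict[str, list[Any]] = {n: [] for n in names}
        for r, row in enumerate(rows):
            row = list(row)
            if len(row) != len(self.schema):
                raise SchemaError(
                    f"row {r + 1}: expected {len(self.schema)} cells, got {len(row)}"
                )
            for spec, value in zip(self.schema, row):
                self._columns[spec.name].append(_validate_cell(spec, value, r))
        self._n_rows = len(next(iter(self._columns.values()))) if names else 0

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_columns(
        cls, schema: Sequence[VariableSpec], columns: dict[str, Sequence[Any]]
    ) -> "DataTable":
        names = [s.name for s in schema]
        lengths = {len(columns[n]) for n in names} if names else {0}
        if len(lengths) > 1:
            raise SchemaError(f"columns have unequal lengths {sorted(lengths)}")
        n = lengths.pop() if lengths else 0
        return cls(schema, ([columns[c][r] for c in names] for r in range(n)))

    # -- basic accessors ------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self._n_rows

    @property
    def n_cols(self) -> int:
        return len(self.schema)

    @property
    def column_names(self) -> list[str]:
        return [s.name for s in self.schema]

    def spec(self, column: str) -> VariableSpec:
        for s in self.schema:
            if s.name == column:
                return s
        raise KeyError(f"no column named {column!r}")

    def column(self, name: str) -> list[Any]:
        return list(self._columns[name])

    def get(self, row: int, column: str) -> Any:
        return self._columns[column][row]

    def set(self, row: int, column: str, value: Any) -> None:
        spec = self.spec(column)
        self._columns[column][row] = _validate_cell(spec, value, row)

    def missing_mask(self, column: str) -> list[bool]:
        return [v is MISSING for v in self._columns[column]]

    def n_missing(self, column: str) -> int:
        return sum(self.missing_mask(column))

    def incomplete_columns(self) -> list[str]:
        return [s.name for s in self.schema if self.n_missing(s.name) > 0]

    def is_complete(self) -> bool:
        return not self.incomplete_columns()

    def copy(self) -> "DataTable":
        out = DataTable(self.schema, [])
        out._columns = {n: list(v) for n, v in self._columns.items()}
        out._n_rows = self._n_rows
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DataTable):
            return NotImplemented
        return self.schema == other.schema and self._columns == other._columns

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DataTable({self.n_rows} rows x {self.n_cols} cols)"

    def to_dataframe(self) -> pd.DataFrame:
        """Export to pandas with NaN for missing cells (analysis convenience)."""
        data = {}
        for s in self.schema:
            col = [float("nan") if v is MISSING else v for v in self._columns[s.name]]
            data[s.name] = col
        return pd.DataFrame(data, columns=self.column_names)


# -- CSV serialisation --------------------------------------------------------

_NA_TOKEN = "NA"


def _format_cell(spec: VariableSpec, value: Any) -> str:
    if value is MISSING:
        return _NA_TOKEN
    if spec.vartype == "numeric":
        f = float(value)
        if f.is_integer() and abs(f) < 1e15:
            return str(int(f))
        return repr(f)
    return str(value)


def write_table(table: DataTable, path) -> None:
    """Write a table as CSV: header row from the schema, missing cells as NA.

    Numeric cells are written with ``repr`` precision (integers without a
    decimal point) so that ``read_table(write_table(t)) == t`` exactly.
    """
    df = pd.DataFrame(
        {
            s.name: [_format_cell(s, v) for v in table.column(s.name)]
            for s in table.schema
        },
        columns=table.column_names,
        dtype=object,
    )
    df.to_csv(path, index=False)


def read_table(path, schema: Sequence[VariableSpec]) -> DataTable:
    """Read a CSV with header row into a validated :class:`DataTable`.

    Both the empty string and the literal token ``NA`` denote a missing cell;
    every other cell is validated against the schema (unknown categorical
    labels and unparseable numbers raise :class:`SchemaError` naming the
    offending row and column).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_filter=False)
    names = [s.name for s in schema]
    if list(df.columns) != names:
        raise SchemaError(
            f"header {list(df.columns)} does not match schema columns {names}"
        )
    rows = (
        [
            MISSING if cell in ("", _NA_TOKEN) else cell
            for cell in record
        ]
        for record in df.itertuples(index=False, name=None)
    )
    return DataTable(schema, rows)


# -- schema sidecar -----------------------------------------------------------

def write_schema(schema: Sequence[VariableSpec], path) -> None:
    doc = {
        "columns": [
            {"name": s.name, "type": s.vartype}
            | ({"levels": list(s.levels)} if s.levels else {})
            for s in schema
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_schema(path) -> list[VariableSpec]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "columns" not in doc:
        raise SchemaError(f"{path}: schema file must contain a 'columns' list")
    out = []
    for entry in doc["columns"]:
        levels = entry.get("levels")
        out.append(
            VariableSpec(
                name=str(entry["name"]),
                vartype=str(entry["type"]),
                levels=tuple(str(x) for x in levels) if levels else None,
            )
        )
    return out
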