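"""Simulation tables and observed-statistics files.

Both formats are whitespace-delimited text with a header row, the lingua
franca through which likelihood-free samplers, external simulators and the
posterior estimator exchange data:

* a *simulation table* has one header line naming parameter and statistic
  columns, followed by one numeric row per simulation; an optional trailing
  ``weight`` column carries importance weights (populated by the PMC
  sampler);
* an *observed-statistics file* has exactly two lines: the statistic names
  and their values.

Values are written with 17 significant digits so a write/read round trip
is bit-faithful for IEEE doubles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import TableFormatError

#: Reserved column name for importance weights.
WEIGHT_COLUMN = "weight"


def _fmt(value: float) -> str:
    return format(float(value), ".17g")


@dataclass
class ObservedStats:
    """Observed summary statistics: parallel name and value vectors."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.names = list(self.names)
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.names) != self.values.size:
            raise TableFormatError(
                f"observed statistics: {len(self.names)} names but {self.values.size} values")
        if len(set(self.names)) != len(self.names):
            raise TableFormatError("observed statistics: duplicate statistic names")
        if not np.all(np.isfinite(self.values)):
            raise TableFormatError("observed statistics: non-finite value")

    def values_for(self, names) -> np.ndarray:
        """Values reordered to match ``names`` (matching by identifier)."""
        index = {n: i for i, n in enumerate(self.names)}
        try:
            return self.values[[index[n] for n in names]]
        except KeyError as exc:
            raise TableFormatError(f"observed statistics: missing statistic {exc.args[0]!r}") from None


@dataclass
class SimulationTable:
    """Named-column matrix of parameter vectors and summary statistics.

    ``param_names`` and ``stat_names`` partition (a subset of) the columns;
    downstream operations address columns by name, never by position.
    """

    column_names: list[str]
    values: np.ndarray
    param_names: list[str]
    stat_names: list[str]
    weights: np.ndarray | None = None
    _col_index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.column_names = list(self.column_names)
        self.param_names = list(self.param_names)
        self.stat_names = list(self.stat_names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(-1, len(self.column_names))
        self.validate()
        self._col_index = {n: i for i, n in enumerate(self.column_names)}

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.column_names)) != len(self.column_names):
            raise TableFormatError("duplicate column names in table")
        if self.values.shape[1] != len(self.column_names):
            raise TableFormatError(
                f"table has {self.values.shape[1]} value columns but "
                f"{len(self.column_names)} names")
        if self.values.size and not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise TableFormatError(
                f"non-finite value at row {bad[0] + 1}, column {self.column_names[bad[1]]!r}")
        if set(self.param_names) & set(self.stat_names):
            raise TableFormatError("parameter and statistic columns overlap")
        known = set(self.column_names)
        for name in self.param_names + self.stat_names:
            if name not in known:
                raise TableFormatError(f"column {name!r} not present in table")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float).ravel()
            if self.weights.size != self.values.shape[0]:
                raise TableFormatError("weights length does not match row count")
            if self.weights.size and (not np.all(self.weights > 0)
                                      or not math.isfinite(float(self.weights.sum()))):
                raise TableFormatError("weights must be positive with a finite sum")

    # -- accessors ----------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def columns(self, names) -> np.ndarray:
        return self.values[:, [self._col_index[n] for n in names]]

    def params(self) -> np.ndarray:
        return self.columns(self.param_names)

    def stats(self) -> np.ndarray:
        return self.columns(self.stat_names)

    def normalized_weights(self) -> np.ndarray:
        """Per-row weights summing to one (uniform when unweighted)."""
        if self.weights is None:
            return np.full(self.n_rows, 1.0 / self.n_rows) if self.n_rows else np.empty(0)
        return self.weights / self.weights.sum()

    def take(self, indices) -> "SimulationTable":
        return replace(self, values=self.values[indices],
                       weights=None if self.weights is None else self.weights[indices])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        if self.weights is not None:
            df[WEIGHT_COLUMN] = self.weights
        return df


def write_table(table: SimulationTable, path) -> None:
    """Write a simulation table; a weighted table gains a trailing ``weight`` column."""
    names = list(table.column_names)
    values = table.values
    if table.weights is not None:
        names.append(WEIGHT_COLUMN)
        values = np.column_stack([values, table.weights])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(names) + "\n")
        for row in values:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _parse_rows(lines, n_cols: int, header: list[str], path: str):
    rows = np.empty((len(lines), n_cols))
    for i, (lineno, fields) in enumerate(lines):
        if len(fields) != n_cols:
            raise TableFormatError(
                f"{path}: row {lineno}: expected {n_cols} fields, got {len(fields)}")
        for j, token in enumerate(fields):
            try:
                rows[i, j] = float(token)
            except ValueError:
                raise TableFormatError(
                    f"{path}: row {lineno}, column {header[j]!r}: "
                    f"not a number: {token!r}") from None
    return rows


def read_table(path, *, observed: ObservedStats | None = None,
               param_names=None, stat_names=None) -> SimulationTable:
    """Read a simulation table, resolving the parameter/statistic partition.

    Statistic columns are, in order of precedence: ``stat_names`` if given,
    the columns whose names appear in ``observed``, or every non-weight
    column when neither is given.  Remaining columns are parameters unless
    ``param_names`` narrows them explicitly.  A column named ``weight`` is
    always read as importance weights.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw_lines = fh.read().splitlines()
    content = [(lineno, line.split()) for lineno, line in enumerate(raw_lines, start=1)
               if line.strip()]
    if not content:
        raise TableFormatError(f"{path}: empty file (no header)")
    header = content[0][1]
    if len(set(header)) != len(header):
        raise TableFormatError(f"{path}: duplicate column names in header")
    values = _parse_rows(content[1:], len(header), header, str(path))

    weights = None
    if WEIGHT_COLUMN in header:
        w_idx = header.index(WEIGHT_COLUMN)
        weights = values[:, w_idx]
        keep = [i for i in range(len(header)) if i != w_idx]
        header = [header[i] for i in keep]
        values = values[:, keep]

    if stat_names is not None:
        stats = [n for n in header if n in set(stat_names)]
    elif observed is not None:
        obs_names = set(observed.names)
        stats = [n for n in header if n in obs_names]
    elif param_names is not None:
        stats = [n for n in header if n not in set(param_names)]
    else:
        stats = list(header)
    if param_names is not None:
        params = [n for n in header if n in set(param_names)]
    else:
        params = [n for n in header if n not in set(stats)]
    return SimulationTable(column_names=header, values=values,
                           param_names=params, stat_names=stats, weights=weights)


def write_observed(observed: ObservedStats, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(observed.names) + "\n")
        fh.write("\t".join(_fmt(v) for v in observed.values) + "\n")


def read_observed(path) -> ObservedStats:
    """Read the 2-line observed-statistics format (header + values)."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if len(lines) != 2:
        raise TableFormatError(
            f"{path}: observed-statistics file must have exactly 2 non-blank lines, "
            f"found {len(lines)}")
    names = lines[0].split()
    fields = lines[1].split()
    values = _parse_rows([(2, fields)], len(names), names, str(path))[0]
    return ObservedStats(names=names, values=values)
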