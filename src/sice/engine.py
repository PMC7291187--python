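"""The chained-equations (MICE) engine.

Multiple imputation by chained equations treats each incomplete variable as
the dependent variable of a regression on all the other variables, cycling
through the incomplete columns and re-imputing each from the current
completed values of the rest.  Running the cycle to quiescence once per
chain, with m independent chains, produces m completed datasets whose
missing-cell values differ according to the imputation model's uncertainty.

Each chain starts from an independent random initial fill (a draw from the
column's observed values) and owns an RNG substream spawned from
``(seed, chain index)``, so a run is bit-reproducible from ``(table, spec)``
while the chains remain mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .imputers import ImputationTask, apply_method, method_compatible
from .tabular import MISSING, DataTable

__all__ = ["ChainSpec", "ImputationStack", "run_mice", "collect_stack"]


@dataclass
class ChainSpec:
    """Configuration of one engine run.

    Parameters
    ----------
    m:
        Number of imputations (chains), i.e. completed datasets produced.
        Defaults to 7.
    n_cycles:
        Chained-equation sweeps over the incomplete columns per chain.
    method_map:
        Column name -> kernel name for every incomplete column (see
        :data:`sice.imputers.METHOD_NAMES`).
    visit_order:
        Order in which incomplete columns are re-imputed within a sweep.
        Default: ascending missing count, ties by schema order.
    seed:
        Master seed; chain j uses the substream spawned as (seed, j).
    """

    method_map: dict[str, str]
    seed: int
    m: int = 7
    n_cycles: int = 5
    visit_order: list[str] | None = None
    method_options: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.n_cycles < 1:
            raise ValueError(f"n_cycles must be >= 1, got {self.n_cycles}")


def _resolve_visit_order(table: DataTable, spec: ChainSpec) -> list[str]:
    incomplete = table.incomplete_columns()
    if spec.visit_order is not None:
        missing = set(incomplete) - set(spec.visit_order)
        if missing:
            raise ValueError(f"visit_order omits incomplete columns {sorted(missing)}")
        return [c for c in spec.visit_order if c in incomplete]
    schema_pos = {s.name: i for i, s in enumerate(table.schema)}
    return sorted(incomplete, key=lambda c: (table.n_missing(c), schema_pos[c]))


def _validate(table: DataTable, spec: ChainSpec, order: list[str]) -> None:
    for col in order:
        n_miss = table.n_missing(col)
        if n_miss == table.n_rows:
            raise ValueError(f"column {col!r} is fully missing and cannot be imputed")
        if col not in spec.method_map:
            raise ValueError(f"no method configured for incomplete column {col!r}")
        method = spec.method_map[col]
        vartype = table.spec(col).vartype
        if not method_compatible(method, vartype):
            raise ValueError(
                f"method {method!r} is incompatible with {vartype} column {col!r}"
            )


def run_mice(table: DataTable, spec: ChainSpec) -> list[DataTable]:
    """Run the chained-equations engine; returns ``spec.m`` completed tables.

    Observed cells are identical to the input in every chain; only the
    originally missing cells differ between chains.
    """
    order = _resolve_visit_order(table, spec)
    _validate(table, spec, order)
    masks = {c: np.asarray(table.missing_mask(c), dtype=bool) for c in order}
    observed_pool = {
        c: [v for v in table.column(c) if v is not MISSING] for c in order
    }
    root = np.random.SeedSequence(spec.seed)
    chains: list[DataTable] = []
    for child in root.spawn(spec.m):
        rng = np.random.default_rng(child)
        work = table.copy()
        # initial fill: random draws from the column's observed values
        for col in order:
            pool = observed_pool[col]
            for row in np.flatnonzero(masks[col]):
                work.set(int(row), col, pool[int(rng.integers(len(pool)))])
        predictors = {
            c: [name for name in table.column_names if name != c] for c in order
        }
        for _ in range(spec.n_cycles):
            for col in order:
                task = ImputationTask(
                    table=work,
                    target=col,
                    predictors=predictors[col],
                    mask=masks[col],
                    rng=rng,
                )
                values = apply_method(spec.method_map[col], task)
                for row, value in zip(task.impute_rows, values):
                    work.set(row, col, value)
        chains.append(work)
    return chains


@dataclass
class ImputationStack:
    """Per missing cell, the ordered array of m candidate values.

    ``cells[(row, column)]`` holds ``[x^1, ..., x^m]`` in chain order.
    """

    m: int
    cells: dict[tuple[int, str], list[Any]]

    def columns(self) -> list[str]:
        return sorted({c for _, c in self.cells})


def collect_stack(completed: list[DataTable], source: DataTable) -> ImputationStack:
    """Gather the m chains' values at each originally missing cell of ``source``.

    Raises if any chain left a cell missing, altered an observed cell, or has
    a schema differing from the source's.
    """
    if not completed:
        raise ValueError("no completed tables")
    cells: dict[tuple[int, str], list[Any]] = {}
    for j, chain in enumerate(completed):
        if chain.schema != source.schema:
            raise ValueError(f"chain {j} schema differs from the source table's")
        for s in source.schema:
            src_col = source.column(s.name)
            chain_col = chain.column(s.name)
            for r, (sv, cv) in enumerate(zip(src_col, chain_col)):
                if sv is MISSING:
                    if cv is MISSING:
                        raise ValueError(
                            f"chain {j} left cell (row {r + 1}, {s.name!r}) missing"
                        )
                    cells.setdefault((r, s.name), []).append(cv)
                elif cv != sv:
                    raise ValueError(
                        f"chain {j} altered observed cell (row {r + 1}, {s.name!r})"
                    )
    return ImputationStack(m=len(completed), cells=cells)
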