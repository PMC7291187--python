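"""MCAR amputation: mask known values to create benchmark ground truth.

Given a fully observed target column, ``ampute_mcar`` removes exactly
``floor(rate * n_rows)`` cells chosen uniformly at random, independent of
every value in the table (missing completely at random), and keeps the
removed values so the imputation can later be scored against them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any

import numpy as np

from .tabular import MISSING, DataTable

__all__ = ["AmputedTable", "ampute_mcar"]


@dataclass
class AmputedTable:
    """A table with injected missingness plus the held-out truth.

    ``mask`` is a per-row boolean vector for the target column (True =
    artificially masked); ``truth`` pairs each masked 0-based row index with
    the original value.
    """

    table: DataTable
    target: str
    mask: np.ndarray
    truth: list[tuple[int, Any]]

    def restore(self) -> DataTable:
        """Put the held-out values back; returns the original table."""
        out = self.table.copy()
        for row, value in self.truth:
            out.set(row, self.target, value)
        return out


def _n_masked(rate: float, n_rows: int) -> int:
    # floor(rate*n) in exact arithmetic; the 9-decimal pre-round only strips
    # binary-float dust (0.1*21614 -> 2161.4000000000003 etc.)
    return math.floor(round(rate * n_rows, 9))


def ampute_mcar(table: DataTable, target: str, rate: float, seed: int) -> AmputedTable:
    """Mask ``floor(rate * n_rows)`` cells of ``target`` uniformly at random.

    Parameters
    ----------
    table:
        Source table; the target column must be fully observed.
    target:
        Name of the column to ampute.
    rate:
        Fraction of rows to mask, in ``[0, 1)``.
    seed:
        Seed for the uniform row draw; the same seed always yields the same
        mask.

    Raises
    ------
    ValueError
        If ``rate`` is outside ``[0, 1)`` or the target already has missing
        cells.
    """
    if not 0 <= rate < 1:
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    if table.n_missing(target) > 0:
        raise ValueError(
            f"target column {target!r} already has "
            f"{table.n_missing(target)} missing cells; amputation requires a "
            "fully observed target"
        )
    n = table.n_rows
    k = _n_masked(rate, n)
    rng = np.random.default_rng(seed)
    rows = np.sort(rng.choice(n, size=k, replace=False)) if k else np.empty(0, int)
    mask = np.zeros(n, dtype=bool)
    mask[rows] = True
    out = table.copy()
    truth = []
    for r in rows:
        truth.append((int(r), table.get(int(r), target)))
        out.set(int(r), target, MISSING)
    return AmputedTable(table=out, target=target, mask=mask, truth=truth)
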